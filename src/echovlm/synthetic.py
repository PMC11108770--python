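"""Synthetic paired echocardiography videos and templated reports.

Each synthetic patient carries a latent clinical state (LVEF, pulmonary
artery pressure, chamber-dilation grades, device flags, pericardial
effusion). A study draws a per-study perturbation of that state, renders a
handful of ultrasound-like videos whose pixel content deterministically
reflects the state, and fills a report template grammar from the same state.
Because image and text share the latent attributes, contrastive training,
zero-shot prompting, retrieval and trajectory analytics are all testable
end to end with no external data.

Rendering emulates an apical-four-chamber framing: a 90-degree scan sector
(fan) with apex at top-center, four elliptical chambers (dark blood pools
with bright walls), a bright myocardial wall whose thickness grows with
hypertrophy grade, chamber axes that grow with dilation grade, a left
ventricle whose area oscillates over the cardiac cycle with relative
amplitude LVEF/100, dark pericardial-effusion rims, and fixed bright
geometric primitives for implanted devices. Additive Gaussian pixel noise
(s.d. 5/255) sits inside the sector; everything outside the fan is zero.
"""
from __future__ import annotations

import datetime as dt
import re
import zlib
from dataclasses import dataclass, field

import numpy as np

from .tokenizer import TemplateVocabulary, tokenize, UNK_ID

FRAME_SIZE = 224
NOISE_SD = 5.0  # pixel noise s.d. on the 0-255 scale
CARDIAC_PERIOD = 8  # frames per synthetic cardiac cycle

GRADES = ("normal", "mild", "moderate", "severe")
EFFUSION_GRADES = ("none", "small", "moderate", "large", "tamponade")
DEVICES = ("pacemaker", "TAVR", "MitraClip", "Impella")
STRUCTURES = ("left ventricle", "left atrium", "right ventricle",
              "right atrium", "LV wall")

_DILATION_SCALE = {"normal": 1.0, "mild": 1.15, "moderate": 1.3, "severe": 1.5}
_WALL_EXTRA = {"normal": 0.0, "mild": 2.0, "moderate": 5.0, "severe": 8.0}
_EFFUSION_THICK = {"none": 0.0, "small": 4.0, "moderate": 8.0,
                   "large": 14.0, "tamponade": 18.0}

# latent channel order: lvef, pap, 4 chamber grades, wall grade, 4 devices, effusion
_N_LATENT = 12
_GRADE_CUTS = (0.15, 0.8, 1.4)
_DEVICE_CUT = 1.04  # ~15% prevalence
_EFFUSION_CUTS = (0.9, 1.5, 2.0, 2.5)

FILLER_SENTENCES = (
    "Study performed in the apical four chamber view.",
    "Image quality is adequate.",
    "The aortic valve is trileaflet.",
    "No intracardiac mass is seen.",
    "The interatrial septum is intact.",
    "Normal sinus rhythm during acquisition.",
    "The aortic root is normal in size.",
    "No left ventricular thrombus is identified.",
    "The inferior vena cava is normal in caliber.",
    "Mitral inflow pattern is normal.",
    "The pulmonic valve is structurally normal.",
)


@dataclass(frozen=True)
class LatentAttributes:
    lvef: int
    pap: float
    severity_grades: dict[str, str]
    devices: frozenset[str]
    effusion: str

    def __post_init__(self):
        if not 0 <= self.lvef <= 100:
            raise ValueError(f"lvef {self.lvef} outside [0, 100]")
        if self.pap < 0:
            raise ValueError("pap must be >= 0")
        for k, g in self.severity_grades.items():
            if k not in STRUCTURES or g not in GRADES:
                raise ValueError(f"bad grade {k}={g}")
        if self.effusion not in EFFUSION_GRADES:
            raise ValueError(f"bad effusion grade {self.effusion}")
        if not set(self.devices) <= set(DEVICES):
            raise ValueError(f"unknown devices {set(self.devices) - set(DEVICES)}")

    def to_dict(self) -> dict:
        return {"lvef": self.lvef, "pap": self.pap,
                "severity_grades": dict(self.severity_grades),
                "devices": sorted(self.devices), "effusion": self.effusion}

    @classmethod
    def from_dict(cls, d: dict) -> "LatentAttributes":
        return cls(lvef=int(d["lvef"]), pap=float(d["pap"]),
                   severity_grades=dict(d["severity_grades"]),
                   devices=frozenset(d["devices"]), effusion=d["effusion"])


@dataclass
class PairedStudyRecord:
    study_id: str
    patient_id: str
    acquisition_date: dt.date
    videos: list[np.ndarray]  # each (T, 224, 224, 3) uint8
    report_text: str
    attributes: LatentAttributes
    split: str | None = None
    video_paths: list[str] = field(default_factory=list)
    event_date: dt.date | None = None  # procedure date, set on event patients


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int
    studies_per_patient: tuple[int, int] = (2, 2)
    videos_per_study: tuple[int, int] = (1, 2)
    frames_per_video: tuple[int, int] = (8, 12)
    seed: int = 0
    event_fraction: float = 0.0
    within_patient_drift: float = 0.15
    event_redraw: bool = True
    date_span_days: int = 1461  # 4-year acquisition window

    def __post_init__(self):
        for name in ("studies_per_patient", "videos_per_study", "frames_per_video"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"{name} range ({lo}, {hi}) invalid")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.event_fraction <= 1.0:
            raise ValueError("event_fraction outside [0, 1]")
        if not 0.0 <= self.within_patient_drift <= 1.0:
            raise ValueError("within_patient_drift outside [0, 1]")


def standard_cohort_spec(seed: int = 0) -> CohortSpec:
    """The reference cohort: 132 patients x 2 studies = 264 studies, so a
    100/32-patient split yields 200 training and 64 validation studies."""
    return CohortSpec(n_patients=132, studies_per_patient=(2, 2),
                      videos_per_study=(1, 2), frames_per_video=(8, 12),
                      seed=seed, event_fraction=0.0, within_patient_drift=0.15)


def event_cohort_spec(seed: int = 0, n_patients: int = 50,
                      redraw: bool = True) -> CohortSpec:
    """Procedure-trajectory cohort: every patient has an event date placed
    between two studies; dates span one year so studies fall inside the
    +/-200-day analysis window. With ``redraw`` the post-event latent state
    is re-drawn (a planted change-point); without it the event is a null."""
    return CohortSpec(n_patients=n_patients, studies_per_patient=(3, 4),
                      videos_per_study=(1, 2), frames_per_video=(8, 12),
                      seed=seed, event_fraction=1.0, within_patient_drift=0.15,
                      event_redraw=redraw, date_span_days=360)


# --------------------------------------------------------------------------
# latent state -> clinical attributes
# --------------------------------------------------------------------------

def _ladder(z: float, cuts: tuple, labels: tuple) -> str:
    for cut, label in zip(cuts, labels):
        if z < cut:
            return label
    return labels[len(cuts)]


def attributes_from_latent(z: np.ndarray) -> LatentAttributes:
    """Deterministic map from a 12-channel standard-normal latent vector to
    clinical attributes; monotone in every channel."""
    lvef = int(np.clip(round(60 + 15 * z[0]), 15, 80))
    pap = float(int(np.clip(round(25 + 12 * z[1]), 10, 90)))
    grades = {}
    for i, s in enumerate(STRUCTURES):
        grades[s] = _ladder(float(z[2 + i]), _GRADE_CUTS, GRADES)
    devices = frozenset(d for i, d in enumerate(DEVICES) if z[7 + i] > _DEVICE_CUT)
    effusion = _ladder(float(z[11]), _EFFUSION_CUTS, EFFUSION_GRADES)
    return LatentAttributes(lvef=lvef, pap=pap, severity_grades=grades,
                            devices=devices, effusion=effusion)


def _study_latent(patient_z: np.ndarray, drift: float,
                  rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(_N_LATENT)
    if drift == 0.0:
        return patient_z.copy()
    norm = np.sqrt((1 - drift) ** 2 + drift ** 2)
    return ((1 - drift) * patient_z + drift * eps) / norm


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

_YY, _XX = np.mgrid[0:FRAME_SIZE, 0:FRAME_SIZE].astype(np.float32)


def sector_mask(size: int = FRAME_SIZE) -> np.ndarray:
    """Boolean 90-degree fan with apex at top-center."""
    yy, xx = (_YY, _XX) if size == FRAME_SIZE else np.mgrid[0:size, 0:size].astype(np.float32)
    ax, ay = size / 2.0, size * 8.0 / 224.0
    dx, dy = xx - ax, yy - ay
    r = np.sqrt(dx * dx + dy * dy)
    ang = np.abs(np.arctan2(dx, np.maximum(dy, 1e-6)))
    return (dy >= 0) & (ang <= np.pi / 4) & (r <= size * 205.0 / 224.0)

_FAN = sector_mask()


def _ellipse(cx, cy, a, b):
    return ((_XX - cx) / a) ** 2 + ((_YY - cy) / b) ** 2 <= 1.0

_CHAMBER_GEOM = {
    "left ventricle": (78.0, 84.0, 26.0, 36.0),
    "right ventricle": (146.0, 80.0, 20.0, 30.0),
    "left atrium": (82.0, 152.0, 22.0, 24.0),
    "right atrium": (146.0, 150.0, 20.0, 22.0),
}

_BG, _BLOOD, _WALL_I, _DEVICE_I, _EFFUSION_I = 90.0, 25.0, 170.0, 235.0, 8.0


def device_region_mask(device: str) -> np.ndarray:
    """Fixed location of each device's bright primitive."""
    if device == "pacemaker":
        return (_XX >= 143) & (_XX <= 149) & (_YY >= 34) & (_YY <= 86)
    if device == "TAVR":
        r2 = (_XX - 112.0) ** 2 + (_YY - 116.0) ** 2
        return (r2 >= 12.0 ** 2) & (r2 <= 17.0 ** 2)
    if device == "MitraClip":
        return (_XX >= 70) & (_XX <= 90) & (_YY >= 114) & (_YY <= 124)
    if device == "Impella":
        return (_XX >= 74) & (_XX <= 82) & (_YY >= 52) & (_YY <= 100)
    raise KeyError(device)


def _lv_area_factor(lvef: int, t: int, phase: float) -> float:
    return 1.0 - (lvef / 100.0) * (0.5 + 0.5 * np.sin(2 * np.pi * t / CARDIAC_PERIOD + phase))


def _lv_shape_axes(a0: float, b0: float, lvef: int) -> tuple[float, float]:
    """Area-preserving sphericity remodeling: low ejection fraction rounds
    the ventricle (axis ratio 1.0 at LVEF 15 up to 1.5 at LVEF 80), the
    static single-frame correlate of systolic function seen in real
    echocardiograms; the cyclic area modulation is applied on top."""
    ratio = 1.0 + 0.5 * np.clip((lvef - 15.0) / 65.0, 0.0, 1.0)
    area = a0 * b0
    return float(np.sqrt(area / ratio)), float(np.sqrt(area * ratio))


def render_video(attributes: LatentAttributes, n_frames: int,
                 seed: int) -> np.ndarray:
    """Render one video (T, 224, 224, 3) uint8, deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    phase = float(rng.uniform(0, 2 * np.pi))

    static = np.full((FRAME_SIZE, FRAME_SIZE), _BG, dtype=np.float32)
    # pericardial effusion: dark rim around the heart silhouette
    thick = _EFFUSION_THICK[attributes.effusion]
    if thick > 0:
        outer = _ellipse(112.0, 118.0, 80.0 + thick, 92.0 + thick)
        inner = _ellipse(112.0, 118.0, 80.0, 92.0)
        static[outer & ~inner] = _EFFUSION_I

    wall_extra = _WALL_EXTRA[attributes.severity_grades["LV wall"]]
    static_chambers = []
    for name, (cx, cy, a, b) in _CHAMBER_GEOM.items():
        s = _DILATION_SCALE[attributes.severity_grades[name]]
        a, b = a * s, b * s
        wall = 4.0 + (wall_extra if name == "left ventricle" else 0.0)
        if name == "left ventricle":
            a, b = _lv_shape_axes(a, b, attributes.lvef)
            lv_geom = (cx, cy, a, b, wall)
            continue
        static[_ellipse(cx, cy, a + wall, b + wall)] = _WALL_I
        static[_ellipse(cx, cy, a, b)] = _BLOOD
        static_chambers.append(name)

    device_mask = np.zeros((FRAME_SIZE, FRAME_SIZE), dtype=bool)
    for d in sorted(attributes.devices):
        device_mask |= device_region_mask(d)

    frames = np.empty((n_frames, FRAME_SIZE, FRAME_SIZE, 3), dtype=np.uint8)
    cx, cy, a0, b0, wall = lv_geom
    for t in range(n_frames):
        img = static.copy()
        m = np.sqrt(max(_lv_area_factor(attributes.lvef, t, phase), 0.05))
        a, b = a0 * m, b0 * m
        img[_ellipse(cx, cy, a + wall, b + wall)] = _WALL_I
        img[_ellipse(cx, cy, a, b)] = _BLOOD
        img[device_mask] = _DEVICE_I
        img = img + rng.normal(0.0, NOISE_SD, img.shape).astype(np.float32)
        img[~_FAN] = 0.0
        gray = np.clip(img, 0, 255).astype(np.uint8)
        frames[t] = gray[..., None]
    return frames


# --------------------------------------------------------------------------
# report generation
# --------------------------------------------------------------------------

def _attribute_sentences(attributes: LatentAttributes) -> list[tuple[str, str]]:
    """(attribute name, sentence) pairs covering every latent attribute."""
    out = [("lvef", f"Left ventricular ejection fraction is {attributes.lvef}%."),
           ("pap", f"Estimated pulmonary artery systolic pressure is "
                   f"{int(attributes.pap) if float(attributes.pap).is_integer() else attributes.pap} mmHg.")]
    wall = attributes.severity_grades["LV wall"]
    out.append(("LV wall", "No left ventricular hypertrophy." if wall == "normal"
                else f"{wall.capitalize()} left ventricular hypertrophy."))
    for name in ("left ventricle", "left atrium", "right ventricle", "right atrium"):
        g = attributes.severity_grades[name]
        out.append((name, f"The {name} is normal in size." if g == "normal"
                    else f"The {name} is {g} dilated."))
    eff = attributes.effusion
    if eff == "none":
        out.append(("effusion", "No pericardial effusion."))
    elif eff == "tamponade":
        out.append(("effusion", "Pericardial effusion with tamponade physiology."))
    else:
        out.append(("effusion", f"There is a {eff} pericardial effusion."))
    dev_sentence = {
        "pacemaker": "A pacemaker lead is visualized in the right heart.",
        "MitraClip": "A MitraClip device is present on the mitral valve.",
        "TAVR": "A TAVR prosthesis is seen in the aortic position.",
        "Impella": "An Impella device is visualized in the left ventricle.",
    }
    for d in sorted(attributes.devices):
        out.append((f"device:{d}", dev_sentence[d]))
    return out


def render_report(attributes: LatentAttributes, grammar: TemplateVocabulary,
                  seed: int) -> str:
    """Fill the template grammar from the attributes; deterministic in seed.

    Every attribute sentence must match a grammar template (no-UNK check);
    boilerplate sentences pad the report to 8-15 sentences and the final
    sentence order is a seeded shuffle.
    """
    rng = np.random.default_rng(np.uint32(seed))
    sentences = []
    for attr_name, sentence in _attribute_sentences(attributes):
        seq = tokenize(sentence, grammar)
        if UNK_ID in seq.tokens:
            raise ValueError(f"grammar has no template covering attribute "
                             f"{attr_name!r} (sentence: {sentence!r})")
        sentences.append(sentence)
    n_fill = int(rng.integers(0, max(15 - len(sentences), 0) + 1))
    if n_fill:
        idx = rng.choice(len(FILLER_SENTENCES), size=n_fill, replace=False)
        sentences.extend(FILLER_SENTENCES[i] for i in sorted(idx))
    order = rng.permutation(len(sentences))
    return " ".join(sentences[i] for i in order)


_RE_LVEF = re.compile(r"Left ventricular ejection fraction is (\d+(?:\.\d+)?)%",
                      re.IGNORECASE)
_RE_PAP = re.compile(r"pulmonary artery systolic pressure is (\d+(?:\.\d+)?) mmHg",
                     re.IGNORECASE)
_RE_WALL = re.compile(r"(mild|moderate|severe) left ventricular hypertrophy",
                      re.IGNORECASE)
_RE_DIL = re.compile(r"The (left ventricle|left atrium|right ventricle|right atrium)"
                     r" is (mild|moderate|severe) dilated", re.IGNORECASE)
_RE_EFF = re.compile(r"There is a (small|moderate|large) pericardial effusion",
                     re.IGNORECASE)


def extract_attributes(report: str) -> LatentAttributes:
    """Inverse of ``render_report``: recover the latent attributes from text
    by pattern matching. Used to verify report faithfulness and to label
    validation reports for sampled-prompt construction."""
    lvef = int(float(_RE_LVEF.search(report).group(1)))
    pap = float(_RE_PAP.search(report).group(1))
    grades = {s: "normal" for s in STRUCTURES}
    m = _RE_WALL.search(report)
    if m:
        grades["LV wall"] = m.group(1).lower()
    for m in _RE_DIL.finditer(report):
        grades[m.group(1).lower()] = m.group(2).lower()
    devices = set()
    for d, needle in (("pacemaker", "pacemaker lead"), ("MitraClip", "MitraClip"),
                      ("TAVR", "TAVR"), ("Impella", "Impella")):
        if needle.lower() in report.lower():
            devices.add(d)
    if "tamponade" in report.lower():
        effusion = "tamponade"
    else:
        m = _RE_EFF.search(report)
        effusion = m.group(1).lower() if m else "none"
    return LatentAttributes(lvef=lvef, pap=pap, severity_grades=grades,
                            devices=frozenset(devices), effusion=effusion)


# --------------------------------------------------------------------------
# cohort generation
# --------------------------------------------------------------------------

def _seed32(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2 ** 31 - 1))


def generate_cohort(spec: CohortSpec,
                    grammar: TemplateVocabulary | None = None) -> list[PairedStudyRecord]:
    """Generate a deterministic cohort of paired study records.

    Studies of one patient share a persistent latent vector perturbed per
    study by ``within_patient_drift`` (0: identical, 1: independent). For
    event patients a procedure date is placed between two studies; when
    ``event_redraw`` is set the patient latent is re-drawn for post-event
    studies, planting a change-point.
    """
    if grammar is None:
        grammar = default_grammar()
    rng = np.random.default_rng(spec.seed)
    base_date = dt.date(2018, 1, 1)
    records: list[PairedStudyRecord] = []
    study_counter = 0
    for p in range(spec.n_patients):
        patient_id = f"P{p:04d}"
        n_studies = int(rng.integers(spec.studies_per_patient[0],
                                     spec.studies_per_patient[1] + 1))
        is_event = bool(rng.random() < spec.event_fraction) and n_studies >= 2
        offsets = np.sort(rng.choice(spec.date_span_days, size=n_studies,
                                     replace=False))
        dates = [base_date + dt.timedelta(days=int(o)) for o in offsets]
        event_date = None
        if is_event:
            k = int(rng.integers(1, n_studies))
            gap = (dates[k] - dates[k - 1]).days
            event_date = dates[k - 1] + dt.timedelta(days=max(gap // 2, 1))
        z_pre = rng.standard_normal(_N_LATENT)
        z_post = rng.standard_normal(_N_LATENT)  # always drawn: keeps stream aligned
        for s, date in enumerate(dates):
            post = event_date is not None and date > event_date
            z_patient = z_post if (post and spec.event_redraw) else z_pre
            z_study = _study_latent(z_patient, spec.within_patient_drift, rng)
            attributes = attributes_from_latent(z_study)
            report_seed = _seed32(rng)
            report = render_report(attributes, grammar, report_seed)
            n_videos = int(rng.integers(spec.videos_per_study[0],
                                        spec.videos_per_study[1] + 1))
            videos = []
            for _ in range(n_videos):
                T = int(rng.integers(spec.frames_per_video[0],
                                     spec.frames_per_video[1] + 1))
                videos.append(render_video(attributes, T, _seed32(rng)))
            records.append(PairedStudyRecord(
                study_id=f"S{study_counter:05d}", patient_id=patient_id,
                acquisition_date=date, videos=videos, report_text=report,
                attributes=attributes))
            study_counter += 1
        if event_date is not None:
            records[-1].event_date = event_date  # attach to the patient's last study
    return records


def event_dates_from_cohort(records: list[PairedStudyRecord]) -> dict[str, dt.date]:
    """Recover the per-patient procedure dates attached by generate_cohort."""
    out = {}
    for r in records:
        d = getattr(r, "event_date", None)
        if d is not None:
            out[r.patient_id] = d
    return out


_DEFAULT_GRAMMAR = None


def default_grammar() -> TemplateVocabulary:
    global _DEFAULT_GRAMMAR
    if _DEFAULT_GRAMMAR is None:
        from importlib.resources import files
        from .tokenizer import build_vocabulary
        _DEFAULT_GRAMMAR = build_vocabulary(str(files("echovlm.data") / "grammar.yaml"))
    return _DEFAULT_GRAMMAR


def video_uid(record: PairedStudyRecord, video_index: int) -> str:
    return f"{record.study_id}:{video_index}"


def stable_hash32(s: str) -> int:
    return zlib.crc32(s.encode()) & 0x7FFFFFFF


__all__ = [
    "LatentAttributes", "PairedStudyRecord", "CohortSpec",
    "standard_cohort_spec", "event_cohort_spec", "generate_cohort",
    "render_video", "render_report", "extract_attributes",
    "attributes_from_latent", "sector_mask", "device_region_mask",
    "event_dates_from_cohort", "default_grammar", "video_uid", "stable_hash32",
    "GRADES", "EFFUSION_GRADES", "DEVICES", "STRUCTURES", "NOISE_SD",
    "FILLER_SENTENCES",
]
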