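"""Zero-shot adaptation of a frozen dual encoder via prompts.

Binary tasks score a video by the mean cosine similarity between the frame
embeddings (first ``n_frames`` at a fixed temporal stride) and a set of
positive-case prompt embeddings. Regression tasks sweep a candidate grid
(for LVEF, the integers 0..100 substituted into a base prompt), rank the
candidates per frame, discard the bottom 80%, average surviving candidates'
similarities across the frames where they survived, and return the median
of the top fifth of candidates. The long-context "sampled prompts" strategy
replaces synthetic short prompts with full reports drawn from a validation
set, which keeps the text encoder in-distribution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .encoders import DualEncoder
from .synthetic import PairedStudyRecord, extract_attributes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FramePlan:
    n_frames: int = 20
    stride: int = 2

    def __post_init__(self):
        if self.n_frames < 1 or self.stride < 1:
            raise ValueError("n_frames and stride must be >= 1")


@dataclass
class PromptSet:
    """Prompts for one task.

    ``mode="binary"``: ``prompts`` lists positive-case strings (or, for the
    sampled strategy, full positive reports). ``mode="regression"``:
    ``template`` contains a ``{value}`` placeholder and ``candidates`` is a
    strictly increasing value grid; alternatively ``candidate_prompts`` maps
    each candidate to a list of report texts (sampled-prompt strategy).
    """
    task_name: str
    mode: str
    prompts: list[str] = field(default_factory=list)
    template: str | None = None
    candidates: list[float] = field(default_factory=list)
    candidate_prompts: dict[float, list[str]] | None = None
    _emb_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if self.mode not in ("binary", "regression"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "binary" and not self.prompts:
            raise ValueError("binary prompt set needs at least one prompt")
        if self.mode == "regression":
            c = list(self.candidates)
            if len(c) < 1 or any(b <= a for a, b in zip(c, c[1:])):
                raise ValueError("candidates must be strictly increasing")


def lvef_prompt_set(candidates=range(0, 101)) -> PromptSet:
    """The standard ejection-fraction sweep: one prompt per integer value."""
    return PromptSet(task_name="lvef", mode="regression",
                     template="Left ventricular ejection fraction is {value}%.",
                     candidates=[float(v) for v in candidates])


def select_frames(video: np.ndarray, plan: FramePlan = FramePlan()) -> np.ndarray:
    """Frames at indices 0, stride, 2*stride, ... capped at ``n_frames``
    indices and at the video length; always at least one frame."""
    T = video.shape[0]
    if T < 1:
        raise ValueError("empty video")
    idx = np.arange(0, min(plan.n_frames * plan.stride, T), plan.stride)
    return video[idx]


def _prompt_embeddings(prompt_set: PromptSet, model: DualEncoder) -> np.ndarray:
    """Prompt embedding matrix, cached per model.

    For sampled prompts each candidate row is the *mean* of its reports'
    unit embeddings: the mean of cosines over reports equals the cosine with
    the mean embedding, so one row per candidate is exact.
    """
    key = id(model)
    if key in prompt_set._emb_cache:
        return prompt_set._emb_cache[key]
    if prompt_set.mode == "binary":
        emb = model.embed_text(prompt_set.prompts)
    elif prompt_set.candidate_prompts is not None:
        emb = np.stack([model.embed_text(prompt_set.candidate_prompts[v]).mean(axis=0)
                        for v in prompt_set.candidates])
    else:
        emb = model.embed_text([prompt_set.template.format(value=_fmt(v))
                                for v in prompt_set.candidates])
    prompt_set._emb_cache[key] = emb
    return emb


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else str(v)


def binary_score(video: np.ndarray, prompt_set: PromptSet, model: DualEncoder,
                 plan: FramePlan = FramePlan()) -> float:
    """Mean over selected frames of the mean over prompts of cosine
    similarity; a continuous score suitable for AUC evaluation."""
    if prompt_set.mode != "binary":
        raise ValueError("binary_score requires a binary prompt set")
    frames = select_frames(video, plan)
    img = model.encode_image(frames)
    return float((img @ _prompt_embeddings(prompt_set, model).T).mean())


def _frame_candidate_similarity(video: np.ndarray, prompt_set: PromptSet,
                                model: DualEncoder, plan: FramePlan) -> np.ndarray:
    """(n_frames, n_candidates) cosine-similarity matrix."""
    frames = select_frames(video, plan)
    img = model.encode_image(frames)
    return img @ _prompt_embeddings(prompt_set, model).T


def _retention(k: int) -> int:
    """Candidates kept after the bottom-80% discard: floor(0.2 K), >= 1.
    For the 101-value grid this is the printed 20 surviving values."""
    return max(int(np.floor(0.2 * k)), 1)


def regression_from_similarity(sims: np.ndarray,
                               candidates: np.ndarray,
                               zero_fill: bool = False) -> float:
    """Candidate-sweep regression from a (frames x candidates) matrix.

    Per frame the top fifth of candidates by similarity survive (ties broken
    toward the lower candidate value); each surviving candidate's similarity
    is averaged over the frames where it survived (or over all frames with
    zeros elsewhere when ``zero_fill``); the top fifth of candidates by that
    average is kept and the median of their values returned. Deterministic,
    shift-invariant, and always inside [min, max] of the candidate grid.
    """
    sims = np.asarray(sims, dtype=np.float64)
    F, K = sims.shape
    if K < 5:
        raise ValueError("need at least 5 candidate values")
    keep = _retention(K)
    mask = np.zeros_like(sims, dtype=bool)
    for f in range(F):
        # stable argsort ascending on (-sim, candidate): lower value wins ties
        order = np.lexsort((candidates, -sims[f]))
        mask[f, order[:keep]] = True
    retained_any = mask.any(axis=0)
    sums = np.where(mask, sims, 0.0).sum(axis=0)
    if zero_fill:
        avg = sums / F
    else:
        counts = np.maximum(mask.sum(axis=0), 1)
        avg = sums / counts
    avg[~retained_any] = -np.inf
    order = np.lexsort((candidates, -avg))
    final = order[:keep]
    vals = np.sort(candidates[final])
    return float(vals[len(vals) // 2])  # upper-middle element for even counts


def regression_predict(video: np.ndarray, prompt_set: PromptSet,
                       model: DualEncoder, plan: FramePlan = FramePlan(),
                       zero_fill: bool = False) -> float:
    """Zero-shot regression for one video via the candidate-sweep rule."""
    if prompt_set.mode != "regression":
        raise ValueError("regression_predict requires a regression prompt set")
    sims = _frame_candidate_similarity(video, prompt_set, model, plan)
    return regression_from_similarity(sims, np.asarray(prompt_set.candidates),
                                      zero_fill=zero_fill)


def sampled_prompts(validation_records: list[PairedStudyRecord], task: str,
                    per_value_cap: int = 10, n_binary: int = 200,
                    seed: int = 0) -> PromptSet:
    """Build a prompt set from full validation reports (long-context models
    are trained on whole reports, so short prompts are out-of-distribution).

    Regression (``task="lvef"``): up to ``per_value_cap`` reports per
    observed value; a value's similarity is the mean over its reports.
    Binary (``task="device:<name>"``): up to ``n_binary`` positive reports.
    """
    rng = np.random.default_rng(np.uint32(seed))
    if task == "lvef":
        by_value: dict[float, list[str]] = {}
        for r in validation_records:
            v = float(extract_attributes(r.report_text).lvef)
            by_value.setdefault(v, []).append(r.report_text)
        n_absent = sum(1 for v in range(0, 101) if float(v) not in by_value)
        if n_absent:
            logger.warning("sampled prompts: %d candidate values have no "
                           "validation reports and are dropped", n_absent)
        candidates, cand_prompts = [], {}
        for v in sorted(by_value):
            reports = by_value[v]
            if len(reports) > per_value_cap:
                idx = rng.choice(len(reports), size=per_value_cap, replace=False)
                reports = [reports[i] for i in sorted(idx)]
            candidates.append(v)
            cand_prompts[v] = reports
        return PromptSet(task_name="lvef-sampled", mode="regression",
                         candidates=candidates, candidate_prompts=cand_prompts)
    if task.startswith("device:"):
        device = task.split(":", 1)[1]
        pos = [r.report_text for r in validation_records
               if device in r.attributes.devices]
        if not pos:
            raise ValueError(f"no positive validation reports for {device!r}")
        if len(pos) > n_binary:
            idx = rng.choice(len(pos), size=n_binary, replace=False)
            pos = [pos[i] for i in sorted(idx)]
        return PromptSet(task_name=task, mode="binary", prompts=pos)
    raise ValueError(f"unknown sampled-prompt task {task!r}")


def study_ensemble(video_predictions: list[float]) -> float:
    """Study-level prediction: the mean of the per-video outputs."""
    if not video_predictions:
        raise ValueError("need at least one video prediction")
    return float(np.mean(video_predictions))


def predict_study_lvef(record: PairedStudyRecord, prompt_set: PromptSet,
                       model: DualEncoder, plan: FramePlan = FramePlan()) -> float:
    return study_ensemble([regression_predict(v, prompt_set, model, plan)
                           for v in record.videos])


__all__ = ["FramePlan", "PromptSet", "lvef_prompt_set", "select_frames",
           "binary_score", "regression_predict", "regression_from_similarity",
           "sampled_prompts", "study_ensemble", "predict_study_lvef"]
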