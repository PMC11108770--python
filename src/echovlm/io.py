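"""Shared plumbing: video and manifest readers/writers, preprocessing,
patient-level splitting, and reproducibility snapshots.

Videos are stored as lossless multi-frame 8-bit RGB TIFF stacks so that the
writer-reader round trip is exact; manifests are JSONL with one study per
line (ids, ISO-8601 date, report text, attribute record, video paths, split
tag). Conventions: frame indices are 0-based, retrieval ranks 1-based.
"""
from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .synthetic import LatentAttributes, PairedStudyRecord, sector_mask

logger = logging.getLogger(__name__)

MANIFEST_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class PreprocessSpec:
    target_size: tuple[int, int] = (224, 224)
    sector_mask: str = "none"  # "none" | "fan"
    channel_mode: str = "RGB"


# ---------------------------------------------------------------------------
# videos
# ---------------------------------------------------------------------------

def write_video(frames: np.ndarray, path) -> None:
    """Write a (T, H, W, 3) uint8 stack as a lossless multi-frame TIFF."""
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[-1] != 3 or frames.dtype != np.uint8:
        raise ValueError("expected a (T, H, W, 3) uint8 frame stack")
    tifffile.imwrite(str(path), frames, photometric="rgb")


def read_video(path) -> np.ndarray:
    """Read a video file into a (T, H, W, 3) uint8 stack."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"video file not found: {p}")
    arr = tifffile.imread(str(p))
    if arr.ndim == 3:  # single-frame file
        arr = arr[None]
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"unexpected video layout {arr.shape} in {p}")
    logger.debug("read %s: %d frames of %dx%d", p, *arr.shape[:3])
    return arr


def preprocess(frames: np.ndarray, spec: PreprocessSpec = PreprocessSpec()) -> np.ndarray:
    """Resize to the target size and optionally zero pixels outside the scan
    sector; idempotent once at target size."""
    frames = np.asarray(frames)
    th, tw = spec.target_size
    if frames.shape[1:3] != (th, tw):
        out = np.empty((frames.shape[0], th, tw, 3), dtype=np.uint8)
        for i, f in enumerate(frames):
            out[i] = np.asarray(Image.fromarray(f).resize((tw, th),
                                                          Image.BILINEAR))
        frames = out
    if spec.sector_mask == "fan":
        frames = frames.copy()
        frames[:, ~sector_mask(th)] = 0
    return frames


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _record_row(r: PairedStudyRecord) -> dict:
    return {
        "study_id": r.study_id,
        "patient_id": r.patient_id,
        "acquisition_date": r.acquisition_date.isoformat(),
        "report_text": r.report_text,
        "attributes": r.attributes.to_dict(),
        "video_paths": list(r.video_paths),
        "split": r.split,
        "event_date": r.event_date.isoformat() if r.event_date else None,
    }


def write_cohort(records: list[PairedStudyRecord], out_dir,
                 write_videos: bool = True) -> Path:
    """Write videos plus a JSONL manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    (out_dir / "videos").mkdir(parents=True, exist_ok=True)
    rows = []
    for r in records:
        if write_videos:
            r.video_paths = []
            for i, v in enumerate(r.videos):
                rel = f"videos/{r.study_id}_{i}.tif"
                write_video(v, out_dir / rel)
                r.video_paths.append(rel)
        rows.append(_record_row(r))
    manifest = out_dir / "manifest.jsonl"
    with open(manifest, "w") as fh:
        fh.write(json.dumps({"schema_version": MANIFEST_SCHEMA_VERSION}) + "\n")
        for row in rows:
            fh.write(json.dumps(row, sort_keys=True) + "\n")
    return manifest


def read_manifest(path, load_videos: bool = True) -> list[PairedStudyRecord]:
    """Read a JSONL manifest back into study records (round-trips exactly).

    Checks study-id uniqueness and, when loading videos, that every
    referenced file exists.
    """
    path = Path(path)
    base = path.parent
    records = []
    seen = set()
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("schema_version") != MANIFEST_SCHEMA_VERSION:
            raise ValueError(f"unsupported manifest schema {header!r}")
        for line in fh:
            row = json.loads(line)
            if row["study_id"] in seen:
                raise ValueError(f"duplicate study_id {row['study_id']}")
            seen.add(row["study_id"])
            if row.get("split") not in (None, "train", "val", "test"):
                raise ValueError(f"bad split tag {row.get('split')!r}")
            videos = []
            if load_videos:
                for rel in row["video_paths"]:
                    videos.append(read_video(base / rel))
            records.append(PairedStudyRecord(
                study_id=row["study_id"], patient_id=row["patient_id"],
                acquisition_date=dt.date.fromisoformat(row["acquisition_date"]),
                videos=videos, report_text=row["report_text"],
                attributes=LatentAttributes.from_dict(row["attributes"]),
                split=row.get("split"), video_paths=list(row["video_paths"]),
                event_date=(dt.date.fromisoformat(row["event_date"])
                            if row.get("event_date") else None)))
    return records


def split_by_patient(records: list[PairedStudyRecord],
                     fractions: tuple[float, ...] = (0.8, 0.1, 0.1),
                     seed: int = 0,
                     names: tuple[str, ...] = ("train", "val", "test")) -> list[PairedStudyRecord]:
    """Assign split tags so that all of a patient's studies share one tag.

    Patients are shuffled and partitioned by cumulative rounded counts, so
    10 patients at (0.8, 0.1, 0.1) give an 8/1/1 patient split exactly.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if len(fractions) != len(names):
        raise ValueError("one name per fraction required")
    patients = sorted({r.patient_id for r in records})
    n_nonzero = sum(1 for f in fractions if f > 0)
    if len(patients) < n_nonzero:
        raise ValueError(f"{len(patients)} patients cannot fill "
                         f"{n_nonzero} splits")
    rng = np.random.default_rng(np.uint32(seed))
    order = [patients[i] for i in rng.permutation(len(patients))]
    bounds = np.round(np.cumsum(fractions) * len(patients)).astype(int)
    tag_of = {}
    start = 0
    for name, stop in zip(names, bounds):
        for pid in order[start:stop]:
            tag_of[pid] = name
        start = stop
    for r in records:
        r.split = tag_of[r.patient_id]
    return records


# ---------------------------------------------------------------------------
# reproducibility snapshots
# ---------------------------------------------------------------------------

def content_hash(paths) -> str:
    """sha256 over the bytes of the given files, in order."""
    h = hashlib.sha256()
    for p in paths:
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def write_run_snapshot(out_dir, command: str, config: dict,
                       input_paths=(), seed: int | None = None) -> Path:
    """Write the config snapshot + input content hash next to the outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    snap = {"command": command, "config": config, "seed": seed,
            "input_hash": content_hash(input_paths) if input_paths else None}
    path = out_dir / "run_snapshot.json"
    path.write_text(json.dumps(snap, indent=2, sort_keys=True, default=str))
    return path


__all__ = ["PreprocessSpec", "write_video", "read_video", "preprocess",
           "write_cohort", "read_manifest", "split_by_patient",
           "content_hash", "write_run_snapshot", "MANIFEST_SCHEMA_VERSION"]
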