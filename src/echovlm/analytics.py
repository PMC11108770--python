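"""Pairwise-embedding clinical analytics.

Cosine similarity between image embeddings of two echocardiogram videos
carries clinical signal: videos of the same patient on the same day are most
similar, the same patient on different days less so, and different patients
least. Treating pair similarity as a continuous score yields a patient
re-identification AUC; study-level similarity to an earliest baseline around
a procedure date yields trajectory timelines and a pre/post-procedure AUC.
AUCs use the Mann-Whitney rank formulation with midrank ties.
"""
from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .synthetic import PairedStudyRecord

logger = logging.getLogger(__name__)

WINDOW_DAYS = 200


@dataclass(frozen=True)
class PairSample:
    emb_a: np.ndarray
    emb_b: np.ndarray
    same_patient: bool
    same_day: bool
    similarity: float

    def __post_init__(self):
        if self.same_day and not self.same_patient:
            raise ValueError("same_day implies same_patient")


@dataclass
class StudyTrajectory:
    patient_id: str
    baseline_study_id: str
    points: list[tuple[int, float]]  # (days_from_event, similarity_to_baseline)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of ``scores`` for predicting ``labels`` (midranks)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # midrank ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def patient_reid_auc(pairs: list[PairSample]) -> float:
    """AUC of pair similarity as a score for 'both videos are the same
    patient'."""
    scores = np.array([p.similarity for p in pairs])
    labels = np.array([p.same_patient for p in pairs])
    return rank_auc(scores, labels)


def make_pair_sample(emb_a: np.ndarray, emb_b: np.ndarray, same_patient: bool,
                     same_day: bool) -> PairSample:
    return PairSample(emb_a=emb_a, emb_b=emb_b, same_patient=same_patient,
                      same_day=same_day,
                      similarity=float(np.dot(emb_a, emb_b)))


def sample_pairs(records: list[PairedStudyRecord],
                 video_embs: dict[str, np.ndarray],
                 n_per_class: int = 5000, seed: int = 0) -> list[PairSample]:
    """Stratified random video pairs: same patient + same day (within-study),
    same patient + different day, and different patient. ``video_embs`` maps
    study_id to the (n_videos, D) embedding array. Classes with fewer than
    ``n_per_class`` available pairs contribute every distinct pair once.
    """
    rng = np.random.default_rng(np.uint32(seed))
    by_patient: dict[str, list[PairedStudyRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)

    same_day_pool = []
    for r in records:
        n = len(r.videos)
        same_day_pool += [(r.study_id, i, r.study_id, j)
                          for i in range(n) for j in range(i + 1, n)]
    same_pat_pool = []
    for recs in by_patient.values():
        for a in range(len(recs)):
            for b in range(a + 1, len(recs)):
                ra, rb = recs[a], recs[b]
                if ra.acquisition_date == rb.acquisition_date:
                    continue
                same_pat_pool += [(ra.study_id, i, rb.study_id, j)
                                  for i in range(len(ra.videos))
                                  for j in range(len(rb.videos))]

    def draw(pool, n):
        if len(pool) <= n:
            return pool
        idx = rng.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in idx]

    pairs = []
    for sid_a, i, sid_b, j in draw(same_day_pool, n_per_class):
        pairs.append(make_pair_sample(video_embs[sid_a][i], video_embs[sid_b][j],
                                      same_patient=True, same_day=True))
    for sid_a, i, sid_b, j in draw(same_pat_pool, n_per_class):
        pairs.append(make_pair_sample(video_embs[sid_a][i], video_embs[sid_b][j],
                                      same_patient=True, same_day=False))
    # different-patient pairs: rejection-sample study pairs
    sids = [r.study_id for r in records]
    pat_of = {r.study_id: r.patient_id for r in records}
    nvid = {r.study_id: len(r.videos) for r in records}
    n_drawn = 0
    while n_drawn < n_per_class:
        a, b = rng.integers(len(sids), size=2)
        sa, sb = sids[a], sids[b]
        if pat_of[sa] == pat_of[sb]:
            continue
        i = int(rng.integers(nvid[sa]))
        j = int(rng.integers(nvid[sb]))
        pairs.append(make_pair_sample(video_embs[sa][i], video_embs[sb][j],
                                      same_patient=False, same_day=False))
        n_drawn += 1
    return pairs


def class_means(pairs: list[PairSample]) -> dict[str, tuple[float, float, int]]:
    """Mean similarity, standard error and count per pair class."""
    out = {}
    for name, sel in (("same_day", lambda p: p.same_day),
                      ("same_patient_other_day",
                       lambda p: p.same_patient and not p.same_day),
                      ("different_patient", lambda p: not p.same_patient)):
        vals = np.array([p.similarity for p in pairs if sel(p)])
        out[name] = (float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(len(vals))),
                     len(vals))
    return out


def study_similarity(embs_a: np.ndarray, embs_b: np.ndarray) -> float:
    """Mean cosine similarity over all cross pairs of two studies' videos."""
    a = np.atleast_2d(embs_a)
    b = np.atleast_2d(embs_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both studies must have at least one video embedding")
    return float((a @ b.T).mean())


def build_trajectories(records: list[PairedStudyRecord],
                       video_embs: dict[str, np.ndarray],
                       event_dates: dict[str, dt.date],
                       window_days: int = WINDOW_DAYS) -> list[StudyTrajectory]:
    """Per event patient: keep studies within the closed +/-window around the
    event, take the earliest as baseline, and score each later study by its
    study-level similarity to baseline."""
    by_patient: dict[str, list[PairedStudyRecord]] = {}
    for r in records:
        if r.patient_id in event_dates:
            by_patient.setdefault(r.patient_id, []).append(r)
    out = []
    for pid, event in event_dates.items():
        recs = [r for r in by_patient.get(pid, ())
                if abs((r.acquisition_date - event).days) <= window_days]
        if not recs:
            logger.info("patient %s has no studies within +/-%d days; excluded",
                        pid, window_days)
            continue
        recs.sort(key=lambda r: r.acquisition_date)
        base = recs[0]
        points = [((r.acquisition_date - event).days,
                   study_similarity(video_embs[base.study_id],
                                    video_embs[r.study_id]))
                  for r in recs[1:]]
        out.append(StudyTrajectory(patient_id=pid, baseline_study_id=base.study_id,
                                   points=points))
    return out


def pre_post_auc(trajectories: list[StudyTrajectory]) -> float:
    """AUC for classifying trajectory points as post-event, pooled across
    patients, scoring by negated similarity-to-baseline (similarity drops
    after a substantive clinical change, so -similarity rises)."""
    scores, labels = [], []
    for t in trajectories:
        for days, sim in t.points:
            scores.append(-sim)
            labels.append(days > 0)
    if not scores:
        raise ValueError("no trajectory points")
    return rank_auc(np.array(scores), np.array(labels))


def bootstrap_ci(values_fn, n_items: int, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap CI for a statistic computed by ``values_fn`` on a
    resampled index array."""
    rng = np.random.default_rng(np.uint32(seed))
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_items, size=n_items)
        stats.append(values_fn(idx))
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


__all__ = ["PairSample", "StudyTrajectory", "rank_auc", "patient_reid_auc",
           "make_pair_sample", "sample_pairs", "class_means",
           "study_similarity", "build_trajectories", "pre_post_auc",
           "bootstrap_ci", "WINDOW_DAYS"]
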