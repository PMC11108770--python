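"""Similarity analytics: re-identification AUC, study similarity,
trajectories and pre/post-procedure AUC."""
import datetime as dt
import itertools

import numpy as np
import pytest

from echovlm.analytics import (PairSample, StudyTrajectory, build_trajectories,
                               class_means, make_pair_sample, patient_reid_auc,
                               pre_post_auc, rank_auc, sample_pairs,
                               study_similarity)
from echovlm.synthetic import CohortSpec, generate_cohort

from conftest import unit_vectors


def pair(sim, same_patient, same_day=False):
    e = np.zeros(2)
    return PairSample(emb_a=e, emb_b=e, same_patient=same_patient,
                      same_day=same_day, similarity=sim)


def brute_force_auc(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPatientReidAuc:
    def test_perfectly_separable(self):
        pairs = [pair(0.9, True), pair(0.8, True), pair(0.7, False), pair(0.1, False)]
        assert patient_reid_auc(pairs) == 1.0

    def test_worked_example_with_swap(self):
        pairs = [pair(0.9, True), pair(0.65, True), pair(0.7, False), pair(0.1, False)]
        scores = [p.similarity for p in pairs]
        labels = [p.same_patient for p in pairs]
        assert patient_reid_auc(pairs) == pytest.approx(
            brute_force_auc(scores, labels))
        assert patient_reid_auc(pairs) == pytest.approx(3 / 4)

    def test_exchangeable_null_near_half(self):
        """Scores from one common distribution for both classes: AUC 0.5 within
        sampling error on 10,000 pairs."""
        rng = np.random.default_rng(0)
        pairs = [pair(float(s), bool(l)) for s, l in
                 zip(rng.normal(size=10000), rng.integers(0, 2, size=10000))]
        assert abs(patient_reid_auc(pairs) - 0.5) < 0.02

    def test_matches_exhaustive_concordance_with_ties(self):
        """Midrank AUC equals the exhaustive concordant-pair count on inputs
        of up to 200 pairs, including ties."""
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 8, size=n) / 7.0  # force ties
            labels = rng.integers(0, 2, size=n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert rank_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(2)
        scores = rng.normal(size=500)
        labels = rng.integers(0, 2, size=500).astype(bool)
        assert rank_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            patient_reid_auc([pair(0.5, True), pair(0.4, True)])

    def test_same_day_implies_same_patient(self):
        with pytest.raises(ValueError):
            pair(0.5, same_patient=False, same_day=True)


class TestStudySimilarity:
    def test_identical_single_videos(self):
        v = unit_vectors(1, 8, seed=0)
        assert study_similarity(v, v) == pytest.approx(1.0)

    def test_two_by_two_hand_values(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0]])
        # cross similarities: 1, 0, 0, 1 -> mean 0.5
        assert study_similarity(a, a) == pytest.approx(0.5)

    def test_symmetry(self):
        a = unit_vectors(3, 16, seed=1)
        b = unit_vectors(2, 16, seed=2)
        assert study_similarity(a, b) == pytest.approx(study_similarity(b, a))

    def test_isotropy_null(self):
        """Random unit embeddings in D=128: expected similarity 0 within 3
        s.e. over 200 draws."""
        rng = np.random.default_rng(3)
        vals = [study_similarity(unit_vectors(2, 128, seed=i),
                                 unit_vectors(2, 128, seed=1000 + i))
                for i in range(200)]
        se = np.std(vals, ddof=1) / np.sqrt(200)
        assert abs(np.mean(vals)) < 3 * se

    def test_empty_study_rejected(self):
        with pytest.raises(ValueError):
            study_similarity(np.zeros((0, 4)), np.ones((1, 4)))


def _traj_setup(days_and_sims):
    """Build records + embeddings with given (days_from_event, target_sim)."""
    base_emb = np.array([[1.0, 0.0]])
    event = dt.date(2020, 6, 1)
    records, embs = [], {}
    records.append(_rec("S0", "P0", event - dt.timedelta(days=150)))
    embs["S0"] = base_emb
    for i, (days, sim) in enumerate(days_and_sims, start=1):
        sid = f"S{i}"
        records.append(_rec(sid, "P0", event + dt.timedelta(days=days)))
        embs[sid] = np.array([[sim, np.sqrt(max(1 - sim * sim, 0.0))]])
    return records, embs, {"P0": event}


def _rec(sid, pid, date):
    from echovlm.synthetic import LatentAttributes, PairedStudyRecord, STRUCTURES
    attrs = LatentAttributes(lvef=60, pap=25.0,
                             severity_grades={s: "normal" for s in STRUCTURES},
                             devices=frozenset(), effusion="none")
    return PairedStudyRecord(study_id=sid, patient_id=pid, acquisition_date=date,
                             videos=[], report_text="", attributes=attrs)


class TestTrajectories:
    def test_one_pre_one_post_gives_one_point(self):
        records, embs, events = _traj_setup([(30, 0.2)])
        trajs = build_trajectories(records, embs, events)
        assert len(trajs) == 1 and len(trajs[0].points) == 1
        assert trajs[0].points[0][0] == 30

    def test_exactly_200_days_included(self):
        records, embs, events = _traj_setup([(200, 0.3), (201, 0.4)])
        trajs = build_trajectories(records, embs, events)
        days = [d for d, _ in trajs[0].points]
        assert 200 in days and 201 not in days

    def test_baseline_is_earliest_in_window(self):
        records, embs, events = _traj_setup([(-20, 0.9), (40, 0.1)])
        trajs = build_trajectories(records, embs, events)
        assert trajs[0].baseline_study_id == "S0"
        assert len(trajs[0].points) == 2

    def test_patient_without_in_window_studies_excluded(self):
        records, embs, events = _traj_setup([(30, 0.5)])
        events["P1"] = dt.date(2020, 6, 1)  # no studies at all
        trajs = build_trajectories(records, embs, events)
        assert {t.patient_id for t in trajs} == {"P0"}


class TestPrePostAuc:
    def test_separable_planted_change(self):
        records, embs, events = _traj_setup([(-40, 0.95), (-10, 0.9),
                                             (20, 0.2), (60, 0.1)])
        trajs = build_trajectories(records, embs, events)
        assert pre_post_auc(trajs) == 1.0

    def test_three_point_worked_example(self):
        trajs = [StudyTrajectory("P", "S", points=[(-10, 0.8), (5, 0.6), (9, 0.9)])]
        # scores (-sim): pre -0.8; post -0.6, -0.9 -> concordant pairs:
        # (-0.6 > -0.8) yes, (-0.9 > -0.8) no -> AUC = 1/2
        assert pre_post_auc(trajs) == pytest.approx(0.5)

    def test_null_near_half_over_seeds(self):
        rng = np.random.default_rng(4)
        aucs = []
        for _ in range(20):
            pts = [(int(d), float(s)) for d, s in
                   zip(rng.integers(-200, 201, size=400), rng.normal(size=400))]
            trajs = [StudyTrajectory("P", "S", points=pts)]
            aucs.append(pre_post_auc(trajs))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            pre_post_auc([StudyTrajectory("P", "S", points=[(5, 0.5)])])


class TestSamplePairs:
    def test_stratified_classes_and_flags(self):
        cohort = generate_cohort(CohortSpec(
            n_patients=10, studies_per_patient=(2, 2), videos_per_study=(2, 2),
            frames_per_video=(2, 2), seed=41))
        rng = np.random.default_rng(0)
        embs = {r.study_id: unit_vectors(len(r.videos), 8, seed=i)
                for i, r in enumerate(cohort)}
        pairs = sample_pairs(cohort, embs, n_per_class=50, seed=0)
        cm = class_means(pairs)
        assert set(cm) == {"same_day", "same_patient_other_day", "different_patient"}
        assert all(n > 0 for _, _, n in cm.values())
        for p in pairs:
            assert -1 - 1e-9 <= p.similarity <= 1 + 1e-9
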