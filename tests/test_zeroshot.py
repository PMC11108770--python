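"""Zero-shot adapters: frame selection, prompt ensembling, candidate-sweep
regression, sampled prompts and study ensembling."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from echovlm.synthetic import CohortSpec, generate_cohort
from echovlm.zeroshot import (FramePlan, PromptSet, binary_score,
                              lvef_prompt_set, regression_from_similarity,
                              regression_predict, sampled_prompts,
                              select_frames, study_ensemble)


class MockEncoder:
    """Stand-in dual encoder whose similarities are scripted (synthetic; used
    only to isolate the adapter arithmetic from model quality)."""

    def __init__(self, frame_score):
        self.frame_score = frame_score  # (frame, text) -> similarity

    def encode_image(self, frames):
        return frames  # adapters only pass embeddings onward via matmul

    def embed_text(self, texts):
        return texts


class TestSelectFrames:
    def test_first_twenty_at_stride_two(self):
        v = np.arange(40)[:, None, None, None] * np.ones((1, 2, 2, 3))
        out = select_frames(v, FramePlan(20, 2))
        assert out.shape[0] == 20
        assert list(out[:, 0, 0, 0].astype(int)) == list(range(0, 40, 2))

    def test_short_video_truncates(self):
        v = np.arange(10)[:, None, None, None] * np.ones((1, 2, 2, 3))
        out = select_frames(v, FramePlan(20, 2))
        assert list(out[:, 0, 0, 0].astype(int)) == [0, 2, 4, 6, 8]

    def test_single_frame(self):
        v = np.zeros((1, 2, 2, 3))
        assert select_frames(v, FramePlan(20, 2)).shape[0] == 1

    def test_invalid_plan(self):
        with pytest.raises(ValueError):
            FramePlan(0, 2)


class _DotModel:
    """Model whose image/text embeddings are the inputs themselves, so
    similarity is a plain dot product (unit test harness)."""

    def encode_image(self, frames):
        return np.asarray(frames, dtype=float).reshape(len(frames), -1)

    def embed_text(self, texts):
        return np.stack([t for t in texts])


class TestBinaryScore:
    def test_single_prompt_single_frame_is_the_cosine(self):
        model = _DotModel()
        v = np.full((1, 1, 1, 2), 1.0)
        v[..., 1] = 0.0
        pset = PromptSet(task_name="t", mode="binary",
                         prompts=[np.array([0.6, 0.8])])
        s = binary_score(v, pset, model, FramePlan(1, 1))
        assert s == pytest.approx(0.6)

    def test_duplicated_prompts_leave_score_unchanged(self):
        model = _DotModel()
        rng = np.random.default_rng(0)
        v = rng.normal(size=(4, 1, 1, 2))
        p = [np.array([0.6, 0.8]), np.array([1.0, 0.0])]
        s1 = binary_score(v, PromptSet(task_name="t", mode="binary", prompts=p),
                          model, FramePlan(4, 1))
        s2 = binary_score(v, PromptSet(task_name="t", mode="binary", prompts=p * 3),
                          model, FramePlan(4, 1))
        assert s1 == pytest.approx(s2)

    def test_prompt_and_frame_order_invariance(self):
        model = _DotModel()
        rng = np.random.default_rng(1)
        v = rng.normal(size=(6, 1, 1, 3))
        p = [rng.normal(size=3) for _ in range(4)]
        base = binary_score(v, PromptSet(task_name="t", mode="binary", prompts=p),
                            model, FramePlan(6, 1))
        perm = binary_score(v, PromptSet(task_name="t", mode="binary",
                                         prompts=p[::-1]), model, FramePlan(6, 1))
        assert base == perm

    def test_separable_scores_give_perfect_auc(self):
        """With similarity 0.9 for positives and 0.1 for negatives, AUC is 1."""
        from echovlm.analytics import rank_auc
        scores = np.array([0.9] * 25 + [0.1] * 25)
        labels = np.array([True] * 25 + [False] * 25)
        assert rank_auc(scores, labels) == 1.0

    def test_empty_prompt_list_rejected(self):
        with pytest.raises(ValueError):
            PromptSet(task_name="t", mode="binary", prompts=[])


class TestRegressionSweep:
    def test_symmetric_peak_recovers_sixty(self):
        """Oracle similarity -(|v-60|) over candidates 0..100: the retained
        set has 20 members (floor rule) and the median is exactly 60."""
        cands = np.arange(101, dtype=float)
        sims = -np.abs(cands - 60.0)[None, :].repeat(7, axis=0)
        from echovlm.zeroshot import _retention
        assert _retention(101) == 20
        assert regression_from_similarity(sims, cands) == 60.0

    def test_brute_force_oracle_general(self):
        """Against an independent step-by-step implementation on random
        similarity matrices."""
        rng = np.random.default_rng(3)
        cands = np.arange(0.0, 101.0)
        for _ in range(25):
            sims = rng.normal(size=(5, 101))
            got = regression_from_similarity(sims, cands)

            keep = 20
            retained = []
            for f in range(5):
                order = sorted(range(101), key=lambda j: (-sims[f, j], cands[j]))
                retained.append(set(order[:keep]))
            avg = {}
            for j in range(101):
                vals = [sims[f, j] for f in range(5) if j in retained[f]]
                if vals:
                    avg[j] = np.mean(vals)
            final = sorted(avg, key=lambda j: (-avg[j], cands[j]))[:keep]
            expect = float(sorted(cands[j] for j in final)[keep // 2])
            assert got == expect

    def test_peak_at_fifty_with_small_grid(self):
        cands = np.array([40.0, 50.0, 60.0, 70.0, 80.0])
        sims = -np.abs(cands - 50.0)[None, :]
        assert regression_from_similarity(sims, cands) == 50.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        cands = np.arange(0.0, 101.0)
        sims = rng.normal(size=(4, 101))
        assert (regression_from_similarity(sims, cands)
                == regression_from_similarity(sims + 3.7, cands))

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            regression_from_similarity(np.zeros((2, 3)), np.arange(3.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_prediction_within_candidate_range(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(5, 40))
        cands = np.sort(rng.choice(200, size=k, replace=False)).astype(float)
        sims = rng.normal(size=(int(rng.integers(1, 6)), k))
        pred = regression_from_similarity(sims, cands)
        assert cands.min() <= pred <= cands.max()
        assert pred in cands

    def test_frame_order_invariance(self):
        rng = np.random.default_rng(5)
        cands = np.arange(0.0, 101.0)
        sims = rng.normal(size=(6, 101))
        assert (regression_from_similarity(sims, cands)
                == regression_from_similarity(sims[::-1], cands))

    def test_zero_fill_variant_differs_only_by_flag(self):
        rng = np.random.default_rng(6)
        cands = np.arange(0.0, 101.0)
        sims = rng.normal(size=(4, 101))
        a = regression_from_similarity(sims, cands, zero_fill=False)
        b = regression_from_similarity(sims, cands, zero_fill=True)
        assert a in cands and b in cands


class TestSampledPrompts:
    @pytest.fixture(scope="class")
    def val_records(self):
        return generate_cohort(CohortSpec(
            n_patients=30, studies_per_patient=(1, 1), videos_per_study=(1, 1),
            frames_per_video=(2, 2), seed=31))

    def test_per_value_cap_counts(self, val_records):
        ps = sampled_prompts(val_records, "lvef", per_value_cap=1, seed=0)
        assert all(len(v) == 1 for v in ps.candidate_prompts.values())
        assert len(ps.candidates) == len({r.attributes.lvef for r in val_records})

    def test_single_value_degenerate(self, val_records):
        one = [r for r in val_records if r.attributes.lvef
               == val_records[0].attributes.lvef][:1]
        ps = sampled_prompts(one, "lvef", seed=0)
        assert ps.candidates == [float(one[0].attributes.lvef)]

    def test_binary_task_requires_positives(self, val_records):
        with_dev = [r for r in val_records if r.attributes.devices]
        if with_dev:
            d = sorted(with_dev[0].attributes.devices)[0]
            ps = sampled_prompts(val_records, f"device:{d}", seed=0)
            assert ps.mode == "binary" and len(ps.prompts) >= 1
        with pytest.raises(ValueError):
            sampled_prompts([r for r in val_records if not r.attributes.devices],
                            "device:TAVR", seed=0)


class TestStudyEnsemble:
    def test_identity_and_equal_values(self):
        assert study_ensemble([0.7]) == 0.7
        assert study_ensemble([0.4, 0.4]) == pytest.approx(0.4)

    def test_mean_oracle_on_random_studies(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            preds = rng.normal(size=int(rng.integers(1, 8))).tolist()
            assert study_ensemble(preds) == pytest.approx(np.mean(preds))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            study_ensemble([])


def test_lvef_prompt_set_grid():
    ps = lvef_prompt_set()
    assert ps.candidates[0] == 0.0 and ps.candidates[-1] == 100.0
    assert len(ps.candidates) == 101
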