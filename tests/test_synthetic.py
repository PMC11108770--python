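"""Synthetic cohort generator: determinism, latent coupling, report
faithfulness, and pixel-attribute coupling."""
import numpy as np
import pytest

from echovlm.synthetic import (CohortSpec, LatentAttributes, NOISE_SD,
                               attributes_from_latent, default_grammar,
                               device_region_mask, event_dates_from_cohort,
                               event_cohort_spec, extract_attributes,
                               generate_cohort, render_report, render_video,
                               sector_mask, standard_cohort_spec)


def small_spec(seed=1, **kw):
    base = dict(n_patients=6, studies_per_patient=(1, 2),
                videos_per_study=(1, 2), frames_per_video=(3, 4), seed=seed)
    base.update(kw)
    return CohortSpec(**base)


def test_cohort_deterministic_given_seed():
    a = generate_cohort(small_spec())
    b = generate_cohort(small_spec())
    assert len(a) == len(b)
    for ra, rb in zip(a, b):
        assert ra.study_id == rb.study_id
        assert ra.report_text == rb.report_text
        assert ra.acquisition_date == rb.acquisition_date
        assert all(np.array_equal(x, y) for x, y in zip(ra.videos, rb.videos))


def test_counts_and_frame_shapes():
    cohort = generate_cohort(CohortSpec(n_patients=10, studies_per_patient=(1, 1),
                                        videos_per_study=(1, 1),
                                        frames_per_video=(3, 3), seed=2))
    assert len(cohort) == 10
    assert len({r.patient_id for r in cohort}) == 10
    for r in cohort:
        assert len(r.videos) >= 1
        for v in r.videos:
            assert v.shape[1:] == (224, 224, 3) and v.dtype == np.uint8


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        CohortSpec(n_patients=0)
    with pytest.raises(ValueError):
        CohortSpec(n_patients=1, videos_per_study=(0, 1))
    with pytest.raises(ValueError):
        CohortSpec(n_patients=1, event_fraction=1.5)


def test_drift_zero_gives_identical_attributes_and_one_independent():
    """drift=0: studies of a patient share attributes exactly; drift=1: the
    across-study LVEF correlation over 500 patients is near zero (brute-force
    correlation oracle)."""
    c0 = generate_cohort(CohortSpec(n_patients=60, studies_per_patient=(2, 2),
                                    videos_per_study=(1, 1),
                                    frames_per_video=(2, 2), seed=3,
                                    within_patient_drift=0.0))
    for i in range(0, len(c0), 2):
        assert c0[i].attributes == c0[i + 1].attributes

    c1 = generate_cohort(CohortSpec(n_patients=500, studies_per_patient=(2, 2),
                                    videos_per_study=(1, 1),
                                    frames_per_video=(2, 2), seed=4,
                                    within_patient_drift=1.0))
    first = np.array([c1[i].attributes.lvef for i in range(0, len(c1), 2)], float)
    second = np.array([c1[i + 1].attributes.lvef for i in range(0, len(c1), 2)], float)
    r = np.corrcoef(first, second)[0, 1]
    assert abs(r) < 3.0 / np.sqrt(500)  # 3 s.e. of a null correlation


def test_attribute_validation():
    with pytest.raises(ValueError):
        LatentAttributes(lvef=120, pap=20.0, severity_grades={}, devices=frozenset(),
                         effusion="none")
    with pytest.raises(ValueError):
        LatentAttributes(lvef=50, pap=20.0, severity_grades={"left ventricle": "huge"},
                         devices=frozenset(), effusion="none")


def test_device_pixels_separate_from_background():
    """Mean intensity in a device's region differs between device-present and
    device-absent renders by at least 5x the pixel-noise s.d. (100 renders)."""
    base = attributes_from_latent(np.zeros(12))
    for device in ("pacemaker", "TAVR", "MitraClip", "Impella"):
        with_dev = LatentAttributes(lvef=base.lvef, pap=base.pap,
                                    severity_grades=base.severity_grades,
                                    devices=frozenset([device]),
                                    effusion=base.effusion)
        region = device_region_mask(device)
        diffs = []
        for i in range(100):
            on = render_video(with_dev, 1, seed=i)[0, ..., 0].astype(float)
            off = render_video(base, 1, seed=i)[0, ..., 0].astype(float)
            diffs.append(abs(on[region].mean() - off[region].mean()))
        assert min(diffs) >= 5 * NOISE_SD


def test_lv_motion_amplitude_scales_with_lvef():
    """The dark LV blood-pool area varies over the cardiac cycle with a range
    that grows with ejection fraction."""
    def area_range(lvef):
        attrs = LatentAttributes(lvef=lvef, pap=25.0,
                                 severity_grades={s: "normal" for s in
                                                  ("left ventricle", "left atrium",
                                                   "right ventricle", "right atrium",
                                                   "LV wall")},
                                 devices=frozenset(), effusion="none")
        v = render_video(attrs, 8, seed=5).astype(float)
        # count dark pixels in the LV quadrant across the cycle
        dark = (v[:, 40:130, 40:120, 0] < 60).sum(axis=(1, 2))
        return dark.max() - dark.min()

    assert area_range(20) < area_range(50) < area_range(80)


def test_frames_zero_outside_fan():
    attrs = attributes_from_latent(np.zeros(12))
    v = render_video(attrs, 2, seed=0)
    assert (v[:, ~sector_mask()] == 0).all()


def test_report_contains_worked_example_phrases(vocab):
    grades = {s: "normal" for s in ("left ventricle", "left atrium",
                                    "right ventricle", "right atrium")}
    grades["LV wall"] = "moderate"
    attrs = LatentAttributes(lvef=60, pap=30.0, severity_grades=grades,
                             devices=frozenset(), effusion="none")
    text = render_report(attrs, vocab, seed=0)
    assert "Moderate left ventricular hypertrophy." in text
    assert "ejection fraction is 60%" in text


def test_no_device_sentence_when_no_devices(vocab):
    attrs = attributes_from_latent(np.zeros(12))
    assert attrs.devices == frozenset()
    text = render_report(attrs, vocab, seed=1)
    for needle in ("pacemaker", "MitraClip", "TAVR", "Impella"):
        assert needle.lower() not in text.lower()


def test_report_faithfulness_1000_draws(vocab):
    """Every latent attribute is recoverable from the report text by pattern
    matching, for 1,000 random attribute draws."""
    rng = np.random.default_rng(12)
    for _ in range(1000):
        attrs = attributes_from_latent(rng.standard_normal(12))
        text = render_report(attrs, vocab, seed=int(rng.integers(2**31)))
        assert extract_attributes(text) == attrs


def test_report_sentence_count_in_band(vocab):
    rng = np.random.default_rng(13)
    for _ in range(50):
        attrs = attributes_from_latent(rng.standard_normal(12))
        text = render_report(attrs, vocab, seed=int(rng.integers(2**31)))
        n = text.count(".")
        assert 8 <= n <= 15


def test_grammar_coverage_error_names_attribute():
    from echovlm.tokenizer import build_vocabulary
    bare = build_vocabulary({"templates": [
        {"canonical_form": "Left ventricular ejection fraction is _%.",
         "slots": ["NUMBER"], "units": ["%"]}]})
    attrs = attributes_from_latent(np.zeros(12))
    with pytest.raises(ValueError, match="pap"):
        render_report(attrs, bare, seed=0)


def test_event_cohort_plants_change_and_null_does_not():
    planted = generate_cohort(event_cohort_spec(seed=6, n_patients=20))
    events = event_dates_from_cohort(planted)
    assert len(events) == 20
    for pid, date in events.items():
        recs = [r for r in planted if r.patient_id == pid]
        assert any(r.acquisition_date < date for r in recs)
        assert any(r.acquisition_date > date for r in recs)

    null = generate_cohort(event_cohort_spec(seed=6, n_patients=20, redraw=False))
    # with redraw disabled, pre and post studies share the patient latent:
    # LVEF jumps across the event should be smaller on average
    def mean_jump(cohort, events):
        jumps = []
        for pid, date in events.items():
            recs = sorted((r for r in cohort if r.patient_id == pid),
                          key=lambda r: r.acquisition_date)
            pre = [r.attributes.lvef for r in recs if r.acquisition_date < date]
            post = [r.attributes.lvef for r in recs if r.acquisition_date > date]
            jumps.append(abs(np.mean(pre) - np.mean(post)))
        return np.mean(jumps)

    assert mean_jump(null, event_dates_from_cohort(null)) < mean_jump(planted, events)
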