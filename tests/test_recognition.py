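import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octcca.cca import cca, max_canonical_corr
from octcca.recognition import (
    classify,
    classify_cca,
    classify_itcca,
    fit,
    score,
    signed_square_combine,
)
from octcca.references import StimulusConfig, build_reference, build_reference_set
from octcca.signal_model import bandpass, extract_window
from octcca.synthetic import SimConfig, generate_dataset
from octcca.templates import SubjectTemplate, TemplateBank, build_bank


@pytest.fixture(scope="module")
def fitted(small_dataset_module):
    ds = small_dataset_module
    n_p = next(iter(ds)).n_samples
    refs = build_reference_set(ds.stimulus_config, n_p)
    bank = build_bank(ds, [0, 1])
    return ds, refs, bank


@pytest.fixture(scope="module")
def small_dataset_module():
    cfg = SimConfig(n_subjects=3, n_blocks=3, duration=1.5, snr_db=10, seed=42)
    return generate_dataset(cfg).map(lambda e: bandpass(e, 7.0, 80.0))


class TestSignedSquare:
    @pytest.mark.parametrize(
        "components, expected",
        [((1.0, 1.0, 1.0), 3.0), ((-0.5, 0.0, 0.0), -0.25), ((0.6, -0.2, 0.1), 0.33)],
    )
    def test_arithmetic(self, components, expected):
        assert signed_square_combine(components) == pytest.approx(expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(-1, 1), b=st.floats(-1, 1),
        rest=st.tuples(st.floats(-1, 1), st.floats(-1, 1)),
    )
    def test_monotone_in_each_component(self, a, b, rest):
        # sign(r)*r**2 is strictly increasing, so improving one component
        # while others are held fixed never lowers the combined score
        lo, hi = min(a, b), max(a, b)
        s_lo = signed_square_combine((lo,) + rest)
        s_hi = signed_square_combine((hi,) + rest)
        assert s_hi >= s_lo


class TestFit:
    def test_octcca_builds_one_filter_per_frequency(self, fitted):
        ds, refs, bank = fitted
        model = fit("OCTCCA", bank, refs)
        assert len(model.filters_u) == 6
        assert len(model.template_proj) == 6
        assert model.filters_u[0].shape[0] == bank.n_subjects

    def test_template_inside_reference_span_gives_unit_correlation(self, rng):
        # subject templates are channel mixtures of the reference's first
        # harmonic pair, so the optimized template stays inside its span
        y = build_reference(10.0, 3, 256.0, 512)
        subs = tuple(
            SubjectTemplate(
                subject_id=i,
                templates=(rng.normal(size=(4, 2)) @ y[:2],),
                n_trials_averaged=1,
            )
            for i in range(2)
        )
        cfg = StimulusConfig(frequencies=(10.0,), n_harmonics=3, fs=256.0)
        bank = TemplateBank(subjects=subs, stimulus_config=cfg)
        model = fit("OCTCCA", bank, build_reference_set(cfg, 512))
        lead = cca(model.oct_model.xhat[0], y).correlations[0]
        assert lead == pytest.approx(1.0, abs=1e-6)

    def test_refit_is_deterministic(self, fitted):
        ds, refs, bank = fitted
        m1, m2 = fit("OCTCCA", bank, refs), fit("OCTCCA", bank, refs)
        for k in range(6):
            np.testing.assert_array_equal(m1.template_proj[k], m2.template_proj[k])

    def test_unknown_method_and_missing_bank_rejected(self, fitted):
        ds, refs, bank = fitted
        with pytest.raises(ValueError, match="unknown method"):
            fit("FBCCA", bank, refs)
        with pytest.raises(ValueError, match="template bank"):
            fit("ITCCA", None, refs)


class TestScore:
    def test_high_snr_trial_recovers_stimulus(self):
        cfg = SimConfig(n_subjects=3, n_blocks=3, duration=1.5, snr_db=5, seed=9)
        ds = generate_dataset(cfg).map(lambda e: bandpass(e, 7.0, 80.0))
        n_p = next(iter(ds)).n_samples
        refs = build_reference_set(ds.stimulus_config, n_p)
        model = fit("OCTCCA", build_bank(ds, [0, 1]), refs)
        trial = ds.get("S01", 2, 3)  # 12 Hz target
        assert score(model, trial).predicted_index == 3

    def test_component_ranges(self, fitted):
        ds, refs, bank = fitted
        model = fit("OCTCCA", bank, refs)
        sv = score(model, ds.get("S02", 2, 1))
        assert sv.components.shape == (6, 3)
        assert np.all(sv.components[:, 1:] >= 0)
        assert np.all(np.abs(sv.components) <= 1 + 1e-9)
        assert np.all(sv.scores >= -1 - 1e-9) and np.all(sv.scores <= 3 + 1e-9)
        assert sv.predicted_index == int(np.argmax(sv.scores))

    def test_own_template_maximizes_template_correlation(self, fitted):
        ds, refs, bank = fitted
        model = fit("OCTCCA", bank, refs)
        k = 2
        x = bank.subjects[0].templates[k]
        sv = score(model, x)
        assert sv.components[k, 1] == pytest.approx(max(sv.components[:, 1]))

    def test_window_length_mismatch_reported(self, fitted):
        ds, refs, bank = fitted
        model = fit("OCTCCA", bank, refs)
        short = extract_window(ds.get("S01", 2, 0), 0.0, 1.0)
        with pytest.raises(ValueError, match="samples"):
            score(model, short)


class TestClassifyCCA:
    def test_noise_free_mixture_recovered_with_unit_score(self, rng):
        cfg = StimulusConfig(frequencies=(9, 10, 11, 12, 13, 14), fs=256.0)
        refs = build_reference_set(cfg, 512)
        y11 = build_reference(11.0, 2, 256.0, 512)
        x = rng.normal(size=(6, 4)) @ y11
        sv = classify_cca(x, refs)
        assert sv.predicted_index == 2
        assert sv.scores[2] >= 0.999

    def test_white_noise_scores_stay_moderate(self, rng):
        cfg = StimulusConfig(frequencies=(9, 10, 11, 12, 13, 14), fs=256.0)
        refs = build_reference_set(cfg, 2048)
        sv = classify_cca(rng.normal(size=(6, 2048)), refs)
        assert np.all(sv.scores < 0.5)

    def test_single_class_always_predicts_zero(self, rng):
        cfg = StimulusConfig(frequencies=(10.0,), fs=256.0)
        refs = build_reference_set(cfg, 256)
        assert classify_cca(rng.normal(size=(4, 256)), refs).predicted_index == 0


class TestClassifyITCCA:
    def test_own_template_perfectly_matched(self, fitted):
        ds, refs, bank = fitted
        model = fit("ITCCA", bank, refs)
        k = 4
        x = bank.subjects[1].templates[k]
        sv = classify_itcca(x, model, subject_id=bank.subjects[1].subject_id)
        assert sv.predicted_index == k
        assert sv.scores[k] == pytest.approx(1.0, abs=1e-8)

    def test_invariant_to_channel_mixing(self, fitted, rng):
        ds, refs, bank = fitted
        model = fit("ITCCA", bank, refs)
        x = ds.get("S01", 2, 0)
        base = classify_itcca(x, model, subject_id="S01").scores
        p = rng.normal(size=(6, 6)) + 2 * np.eye(6)
        mixed = classify_itcca(p @ x.data, model, subject_id="S01").scores
        np.testing.assert_allclose(base, mixed, atol=1e-6)

    def test_unknown_subject_rejected(self, fitted):
        ds, refs, bank = fitted
        model = fit("ITCCA", bank, refs)
        with pytest.raises(KeyError, match="ghost"):
            classify_itcca(ds.get("S01", 2, 0), model, subject_id="ghost")

    def test_noise_only_templates_classify_at_chance(self):
        # templates from a -60 dB training set carry no stimulus information
        cfg = SimConfig(n_subjects=2, n_blocks=3, duration=1.0, snr_db=-60, seed=5)
        ds = generate_dataset(cfg).map(lambda e: bandpass(e, 7.0, 80.0))
        n_p = next(iter(ds)).n_samples
        refs = build_reference_set(ds.stimulus_config, n_p)
        model = fit("ITCCA", build_bank(ds, [0, 1]), refs)
        correct = total = 0
        for e in ds:
            if e.block_id != 2:
                continue
            sv = classify_itcca(e, model, subject_id=e.subject_id)
            correct += sv.predicted_index == e.target_index
            total += 1
        assert correct / total < 0.55  # well below any systematic recovery


def test_dispatch_matches_direct_calls(fitted):
    ds, refs, bank = fitted
    x = ds.get("S03", 2, 5)
    m_cca = fit("CCA", None, refs)
    np.testing.assert_array_equal(
        classify(m_cca, x).scores, classify_cca(x, refs).scores
    )
    m_it = fit("ITCCA", bank, refs)
    np.testing.assert_array_equal(
        classify(m_it, x, subject_id="S03").scores,
        classify_itcca(x, m_it, subject_id="S03").scores,
    )


def test_multi_pair_pooling_option(fitted):
    ds, refs, bank = fitted
    model = fit("OCTCCA", bank, refs)
    trial = ds.get("S01", 2, 2)
    sv1 = score(model, trial)
    sv2 = score(model, trial, n_pairs=2)
    # first-pair component identical; pooled scores may differ
    np.testing.assert_allclose(sv1.components[:, 0], sv2.components[:, 0])
    assert sv2.scores.shape == sv1.scores.shape
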