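"""Observer model: psychometric responses, suppression, degradation, cohorts."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from stereosim import (
    BANGERTER_DEFAULTS,
    BangerterEffect,
    CohortSpec,
    PsychometricParams,
    SimulatedObserver,
    TruncatedDist,
    apply_bangerter,
    cr_report_probability,
    sample_cohort,
    simulate_trial,
    stereo_percent_correct,
    true_threshold,
)
from stereosim._rng import substream


def make_observer(alpha=math.log2(40.0), beta=1.0, lapse=0.0, **kw):
    return SimulatedObserver(stereo=PsychometricParams(alpha, beta, lapse=lapse), **kw)


class TestPsychometricParams:
    @pytest.mark.parametrize(
        "kw",
        [
            {"alpha": 5.0, "beta": 0.0},
            {"alpha": 5.0, "beta": -1.0},
            {"alpha": 5.0, "beta": 1.0, "lapse": 0.2},
            {"alpha": 5.0, "beta": 1.0, "gamma": 0.95, "lapse": 0.1},
        ],
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            PsychometricParams(**kw)


class TestStereoPercentCorrect:
    def test_threshold_definition_midpoint(self, reference_observer):
        # 62.5% is the midpoint of the 4AFC range [0.25, 1] at the threshold
        assert stereo_percent_correct(reference_observer, 40.0, 80, 80) == pytest.approx(0.625)

    def test_guess_rate_floor_far_below_threshold(self, reference_observer):
        assert stereo_percent_correct(reference_observer, 1.0, 80, 80) == pytest.approx(0.25, abs=0.01)

    def test_contrast_decrement_shifts_threshold_by_kappa(self, reference_observer):
        # 10% dominant-eye decrement elevates the threshold by 10**0.35
        d = 40.0 * 10**0.35
        assert stereo_percent_correct(reference_observer, d, 70, 80) == pytest.approx(0.625)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"disparity": 0.5}, {"disparity": 5000.0},
            {"disparity": 40.0, "contrast_dominant": 0.5},
            {"disparity": 40.0, "contrast_nondominant": 101.0},
        ],
    )
    def test_out_of_range_inputs_rejected(self, reference_observer, kwargs):
        kw = {"contrast_dominant": 80, "contrast_nondominant": 80, **kwargs}
        with pytest.raises(ValueError):
            stereo_percent_correct(reference_observer, **kw)

    @settings(derandomize=True, max_examples=60)
    @given(
        alpha=st.floats(2.0, 10.0),
        beta=st.floats(0.3, 3.0),
        kappa=st.floats(0.0, 0.6),
        d1=st.floats(1.0, 4096.0),
        d2=st.floats(1.0, 4096.0),
        c1=st.floats(1.0, 80.0),
        c2=st.floats(1.0, 80.0),
    )
    def test_monotone_in_disparity_and_dominant_decrement(self, alpha, beta, kappa, d1, d2, c1, c2):
        """For balance-1 observers, p is nondecreasing in disparity and
        nonincreasing in the dominant-eye contrast decrement."""
        obs = make_observer(alpha, beta, lapse=0.01, kappa=kappa)
        lo, hi = sorted((d1, d2))
        assert stereo_percent_correct(obs, lo, 80, 80) <= stereo_percent_correct(obs, hi, 80, 80) + 1e-12
        chi, clo = sorted((c1, c2))[::-1]
        assert (
            stereo_percent_correct(obs, 40.0, clo, 80)
            <= stereo_percent_correct(obs, 40.0, chi, 80) + 1e-12
        )

    def test_amblyope_minimum_at_balance_point(self):
        """An amblyope's effective threshold is V-shaped in dominant contrast
        with its minimum where the presented ratio equals the true CR."""
        obs = make_observer(alpha=9.0, kappa=0.2, cr_true=4.0, kappa_release=0.3, group="amblyopic")
        balanced = 80.0 / 4.0
        t_bal = true_threshold(obs, balanced, 80.0)
        for c_dom in (80.0, 40.0, 30.0, 15.0, 10.0, 5.0):
            assert true_threshold(obs, c_dom, 80.0) >= t_bal - 1e-9
        assert true_threshold(obs, 80.0, 80.0) > t_bal  # strict release at equality


class TestCRReport:
    def test_balance_point_is_half(self, amblyopic_cohort):
        for obs in amblyopic_cohort:
            assert cr_report_probability(obs, obs.cr_true) == pytest.approx(0.5)

    def test_equal_contrast_symmetry(self):
        obs = make_observer(cr_true=1.0)
        assert cr_report_probability(obs, 1.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        obs = make_observer(cr_true=10.0, sigma_cr=0.3, group="amblyopic")
        assert cr_report_probability(obs, 10**1.3) == pytest.approx(0.8413, abs=2e-4)

    def test_nonpositive_ratio_rejected(self, reference_observer):
        with pytest.raises(ValueError):
            cr_report_probability(reference_observer, 0.0)


class TestSimulateTrial:
    def test_degenerate_always_correct(self):
        obs = make_observer(alpha=1.0, lapse=0.0)
        rng = substream(0, "trial")
        assert all(simulate_trial(obs, 4096.0, (80, 80), rng) for _ in range(200))

    def test_fixed_seed_replays(self, reference_observer):
        seqs = []
        for _ in range(2):
            rng = substream(7, "trial")
            seqs.append([simulate_trial(reference_observer, 40.0, (80, 80), rng) for _ in range(100)])
        assert seqs[0] == seqs[1]

    def test_long_run_frequency(self, reference_observer):
        rng = substream(3, "freq")
        hits = sum(simulate_trial(reference_observer, 40.0, (80, 80), rng) for _ in range(10_000))
        assert hits / 10_000 == pytest.approx(0.625, abs=0.015)


class TestBangerter:
    def test_identity_effect_is_noop_and_idempotent(self, normal_cohort):
        ident = BangerterEffect("id", 0.0, 1.0, 1.0)
        obs = normal_cohort[0]
        out = obs
        for _ in range(3):
            out = apply_bangerter(out, ident)
        assert out == obs

    def test_densest_filter_default_effects(self):
        base = make_observer(cr_true=1.44)
        deg = apply_bangerter(base, "<0.1")
        assert 2.0**deg.stereo.alpha == pytest.approx(88.0)  # 40 -> 88 arcsec
        assert deg.cr_true == pytest.approx(1.44 * 6.8)  # -> 9.79, near the 9.84 group mean
        assert base.cr_true == 1.44  # original untouched

    def test_unknown_label_rejected(self, normal_cohort):
        with pytest.raises(ValueError):
            apply_bangerter(normal_cohort[0], "0.3")

    def test_amblyope_rejected(self, amblyopic_cohort):
        with pytest.raises(ValueError):
            apply_bangerter(amblyopic_cohort[0], "0.8")

    def test_defaults_nondecreasing_with_density(self):
        order = ["0.8", "0.6", "0.4", "0.1", "<0.1"]
        effects = [BANGERTER_DEFAULTS[o] for o in order]
        for a, b in zip(effects, effects[1:]):
            assert b.va_decrement >= a.va_decrement
            assert b.cr_multiplier >= a.cr_multiplier
            assert b.stereo_multiplier >= a.stereo_multiplier


class TestCohortSampling:
    def test_fixed_seed_identical_cohorts(self):
        spec = CohortSpec.amblyopic(n=10, seed=5)
        assert sample_cohort(spec) == sample_cohort(spec)

    def test_normal_cr_location(self):
        cohort = sample_cohort(CohortSpec.normal(n=1000, seed=11))
        assert np.mean([o.cr_true for o in cohort]) == pytest.approx(1.45, abs=0.1)

    def test_amblyopic_dissociation_by_construction(self):
        cohort = sample_cohort(CohortSpec.amblyopic(n=1000, seed=11))
        log_thr = [o.stereo.alpha for o in cohort]
        log_cr = [math.log10(o.cr_true) for o in cohort]
        va = [o.va_difference for o in cohort]
        assert spearmanr(log_thr, log_cr).statistic >= 0.6
        assert abs(spearmanr(log_thr, va).statistic) <= 0.3

    def test_truncation_bounds_respected(self):
        for spec in (CohortSpec.normal(n=300, seed=2), CohortSpec.amblyopic(n=300, seed=2)):
            for obs in sample_cohort(spec):
                assert spec.cr.lower <= obs.cr_true <= spec.cr.upper
                assert spec.va_diff.lower <= obs.va_difference <= spec.va_diff.upper + 1e-12

    def test_impossible_truncation_rejected(self):
        with pytest.raises(ValueError):
            TruncatedDist("lognormal", 10.0, 5.0, 20.0, 10.0)

    def test_invalid_group_and_size(self):
        with pytest.raises(ValueError):
            dataclasses.replace(CohortSpec.normal(), n=0)
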