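"""Normalization, decay fitting, rate profiles, comparisons, state calls."""

import numpy as np
import pytest

from mad2nmr.kinetics import (build_rate_profile, classify_state,
                              compare_profiles, completion_time, fit_decay,
                              half_rise_time, intermediate_score,
                              normalize_conversion, normalize_series,
                              rate_for_completion)
from mad2nmr.spectra import PeakAssignment, SpectrumSeries, sliding_add

from conftest import three_state_series, two_state_series


class TestNormalization:
    def test_first_point_is_one_and_scale_invariant(self, short_acq):
        series, _ = two_state_series(acq=short_acq, noise_sd=0.02, seed=1)
        norm = normalize_series(series, "O_first")
        scaled = SpectrumSeries(series.times, series.peaks,
                                10.0 * series.intensities, series.meta)
        norm10 = normalize_series(scaled, "O_first")
        for res in (1, 2, 3):
            assert norm.row(res, "O")[0] == pytest.approx(1.0)
            assert np.allclose(norm.row(res, "O"), norm10.row(res, "O"))

    def test_c_last_mode(self, short_acq):
        series, _ = two_state_series(k1=0.05, acq=short_acq)
        norm = normalize_series(series, "C_last")
        assert norm.row(1, "C_empty")[-1] == pytest.approx(1.0)
        # O rows pass through unchanged in C_last mode
        assert np.allclose(norm.row(1, "O"), series.row(1, "O"))

    def test_noiseless_normalized_o_equals_populations(self, short_acq):
        """Normalized O-decay equals exp(-k t) rescaled to the first point."""
        series, truth = two_state_series(k1=0.03, acq=short_acq)
        norm = normalize_series(series, "O_first")
        t = series.times
        expected = np.exp(-0.03 * t) / np.exp(-0.03 * t[0])
        assert np.allclose(norm.row(2, "O"), expected, atol=1e-12)

    def test_zero_reference_excluded_with_reason(self, short_acq):
        series, _ = two_state_series(acq=short_acq)
        dead = SpectrumSeries(series.times,
                              series.peaks + [(99, "O")],
                              np.vstack([series.intensities,
                                         np.zeros(series.n_times)]))
        norm = normalize_series(dead, "O_first")
        assert (99, "O") not in norm.peaks
        excl = norm.meta["excluded_normalization"]
        assert excl and excl[0]["residue"] == 99 and "floor" in excl[0]["reason"]

    def test_unknown_mode_rejected(self, short_acq):
        series, _ = two_state_series(acq=short_acq)
        with pytest.raises(ValueError):
            normalize_series(series, "bogus")


class TestFitDecay:
    def test_exact_recovery(self):
        t = np.linspace(5, 2500, 497)
        y = 0.9 * np.exp(-0.02 * t) + 0.1
        fit = fit_decay(t, y)
        assert fit.converged
        assert fit.k == pytest.approx(0.02, abs=1e-6)
        assert fit.y0 == pytest.approx(1.0, abs=1e-6)
        assert fit.y_min == pytest.approx(0.1, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_series_not_converged(self):
        fit = fit_decay(np.arange(1.0, 11.0), np.full(10, 0.7))
        assert not fit.converged and fit.k is None

    def test_scale_invariance_of_rate(self):
        rng = np.random.default_rng(0)
        t = np.linspace(5, 2500, 200)
        y = np.exp(-0.01 * t) + rng.normal(0, 0.02, t.size)
        k1 = fit_decay(t, y).k
        k2 = fit_decay(t, 37.5 * y).k
        assert k1 == pytest.approx(k2, rel=1e-9)

    def test_estimate_within_three_se_of_truth(self, full_acq):
        """Monte-Carlo sanity: k-hat within 3 se of truth on the standard
        noisy acquisition (single fixed seed; distributional property checked
        by the recovery suite in the acceptance tests)."""
        series, _ = two_state_series(k1=0.01, residues=(1,), noise_sd=0.02,
                                     seed=11, acq=full_acq)
        norm = normalize_series(series, "O_first")
        fit = fit_decay(norm.times, norm.row(1, "O"))
        assert fit.converged
        assert abs(fit.k - 0.01) <= 3.0 * fit.se_k

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_decay([1, 2, 3, 4], [1, 0.5, 0.3, 0.2])


class TestCompletionTime:
    def test_inverse_of_definition(self):
        k = rate_for_completion(30.0)
        fit = fit_decay(np.linspace(1, 200, 100),
                        np.exp(-k * np.linspace(1, 200, 100)))
        assert completion_time(fit) == pytest.approx(30.0, rel=1e-6)

    def test_half_life(self):
        t = np.linspace(1, 500, 100)
        fit = fit_decay(t, np.exp(-0.01 * t))
        assert completion_time(fit, fraction=0.5) == pytest.approx(np.log(2) / 0.01,
                                                                   rel=1e-6)

    def test_printed_eightfold_slowdown(self):
        """Completion at 250 min vs 30 min is an 8.33-fold rate difference,
        rounding to the printed 8-fold."""
        ratio = rate_for_completion(30.0) / rate_for_completion(250.0)
        assert ratio == pytest.approx(250.0 / 30.0, rel=1e-12)
        assert round(ratio) == 8


class TestRateProfile:
    def test_uniform_rates_mutually_consistent(self, full_acq):
        series, truth = two_state_series(k1=0.01, residues=(1, 2, 3, 4),
                                         noise_sd=0.02, seed=2, acq=full_acq)
        norm = normalize_conversion(sliding_add(series, 4))
        prof = build_rate_profile(norm, condition="uniform")
        rates = prof.converged_rates()
        assert len(rates) == 4
        # merged-series residuals are autocorrelated, so assert on relative
        # error rather than the (iid-assuming) regression standard error
        for r, k in rates.items():
            assert k == pytest.approx(0.01, rel=0.10)

    def test_slow_subset_recovered(self, full_acq):
        """A 0.2x rate multiplier on a residue subset shows up as ~5x slower
        fitted rates (the slow-strand phenotype)."""
        slow = {11: 0.2, 12: 0.2}
        series, _ = two_state_series(k1=0.02, residues=(1, 2, 11, 12),
                                     rate_scales=slow, noise_sd=0.02,
                                     seed=3, acq=full_acq)
        norm = normalize_conversion(sliding_add(series, 4))
        prof = build_rate_profile(norm)
        rates = prof.converged_rates()
        for r in (11, 12):
            assert rates[r] == pytest.approx(0.004, rel=0.15)
        for r in (1, 2):
            assert rates[r] == pytest.approx(0.02, rel=0.15)

    def test_empty_profile_is_valid(self):
        series = SpectrumSeries(np.arange(1.0, 11.0), [], np.empty((0, 10)))
        prof = build_rate_profile(series)
        assert prof.o_fits == {} and prof.c_appearance == {}

    def test_excluded_peaks_reported(self, short_acq):
        series, _ = two_state_series(acq=short_acq)
        norm = normalize_conversion(series)
        prof = build_rate_profile(norm, exclude={(2, "O")})
        assert 2 in prof.excluded and 2 not in prof.o_fits

    def test_json_round_trip(self, short_acq):
        from mad2nmr.kinetics import RateProfile
        series, _ = two_state_series(acq=short_acq, noise_sd=0.01, seed=4)
        prof = build_rate_profile(normalize_conversion(series), condition="x")
        back = RateProfile.from_dict(prof.to_dict())
        assert back.condition == "x"
        assert back.converged_rates().keys() == prof.converged_rates().keys()
        for r in prof.o_fits:
            if prof.o_fits[r].converged:
                assert back.o_fits[r].k == pytest.approx(prof.o_fits[r].k)


class TestCompareProfiles:
    @staticmethod
    def _profiles(extra=None, seed=0, noise=0.0, acq=None, k=0.002):
        from conftest import FULL_ACQ
        acq = acq or FULL_ACQ
        residues = tuple(range(1, 16))
        a_series, _ = two_state_series(k1=k, residues=residues,
                                       noise_sd=noise, seed=seed, acq=acq)
        scales = dict(extra or {})
        b_series, _ = two_state_series(k1=8 * k, residues=residues,
                                       rate_scales=scales, noise_sd=noise,
                                       seed=seed + 1000, acq=acq)
        pa = build_rate_profile(normalize_conversion(sliding_add(a_series, 4)))
        pb = build_rate_profile(normalize_conversion(sliding_add(b_series, 4)))
        return pa, pb

    def test_identical_profiles_unflagged(self, full_acq):
        pa, _ = self._profiles()
        cmp_ = compare_profiles(pa, pa)
        assert cmp_.median_ratio == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in cmp_.ratio.values())
        assert cmp_.flagged == []

    def test_uniform_acceleration_scales_out(self):
        pa, pb = self._profiles()
        cmp_ = compare_profiles(pa, pb, scaling="median_ratio")
        assert cmp_.median_ratio == pytest.approx(8.0, rel=0.02)
        assert all(v == pytest.approx(1.0, rel=0.05)
                   for v in cmp_.scaled_ratio.values())
        assert cmp_.flagged == []

    def test_extra_multiplier_flagged_exactly(self):
        """Global 8x speed-up plus 3x extra on residues 11-15: exactly those
        residues flagged after median scaling."""
        pa, pb = self._profiles(extra={r: 3.0 for r in (11, 12, 13, 14, 15)})
        cmp_ = compare_profiles(pa, pb, scaling="median_ratio")
        assert cmp_.flagged == [11, 12, 13, 14, 15]

    def test_disjoint_profiles_rejected(self, full_acq):
        from mad2nmr.kinetics import KineticFit, RateProfile
        a = RateProfile("a", {1: KineticFit(0.1, 1, 0, 0.001, 1.0, True)})
        b = RateProfile("b", {2: KineticFit(0.1, 1, 0, 0.001, 1.0, True)})
        with pytest.raises(ValueError, match="no residues"):
            compare_profiles(a, b)


class TestIntermediateScore:
    def test_two_state_is_not_intermediate(self, full_acq):
        series, _ = two_state_series(k1=0.01, residues=(1, 2, 3), acq=full_acq)
        prof = build_rate_profile(normalize_conversion(sliding_add(series, 4)))
        score = intermediate_score(prof)
        assert not score.intermediate_consistent
        assert score.median_nonexp < 1e-4

    def test_three_state_lag_detected(self, full_acq):
        series, _ = three_state_series(k1=0.01, k2=0.001, acq=full_acq)
        prof = build_rate_profile(normalize_conversion(sliding_add(series, 4)))
        score = intermediate_score(prof)
        assert score.intermediate_consistent
        assert score.median_nonexp > 2e-3

    def test_noisy_two_state_not_misclassified(self, full_acq):
        """Intensity noise on merged two-state data must not masquerade as
        an intermediate: the noise correction accounts for the raw-spectrum
        overlap between merged points, and near-uniform rates keep the rank
        correlation out of the verdict."""
        for seed in (0, 1, 2):
            series, _ = two_state_series(k1=0.01, residues=(1, 2, 3),
                                         noise_sd=0.05, seed=seed,
                                         acq=full_acq)
            prof = build_rate_profile(normalize_conversion(sliding_add(series, 4)))
            score = intermediate_score(prof)
            assert not score.intermediate_consistent

    def test_half_rise_of_exponential(self):
        t = np.linspace(1, 1000, 500)
        y = 1 - np.exp(-0.01 * t)
        # final value ~1: half-rise near t where 1-exp(-kt)=0.5*(final)
        got = half_rise_time(t, y)
        expected = -np.log(1 - 0.5 * y[-1]) / 0.01
        assert got == pytest.approx(expected, rel=1e-3)

    def test_single_residue_correlation_not_computable(self, short_acq):
        series, _ = two_state_series(k1=0.05, residues=(1,), acq=short_acq)
        prof = build_rate_profile(normalize_conversion(series))
        score = intermediate_score(prof)
        assert score.rank_correlation is None
        assert any("correlation" in w for w in score.warnings)

    def test_missing_c_trajectories_warned(self, short_acq):
        from mad2nmr.kinetics import RateProfile
        series, _ = two_state_series(k1=0.05, residues=(1, 2), acq=short_acq)
        norm = normalize_conversion(series)
        o_only = norm.subset([(1, "O"), (2, "O")])
        prof = build_rate_profile(o_only)
        score = intermediate_score(prof)
        assert score.warnings


class TestClassifyState:
    @staticmethod
    def _reference():
        return {
            "O": [PeakAssignment(75, "W", "O", 10.10, 129.5, True),
                  PeakAssignment(167, "W", "O", 10.00, 129.9, True)],
            "C_empty": [PeakAssignment(75, "W", "C_empty", 10.30, 130.8, True),
                        PeakAssignment(167, "W", "C_empty", 9.80, 128.5, True)],
            "C_bound": [PeakAssignment(75, "W", "C_bound", 10.55, 131.5, True),
                        PeakAssignment(167, "W", "C_bound", 9.70, 127.9, True)],
        }

    def test_exact_match_distance_zero(self):
        ref = self._reference()
        call = classify_state(ref["O"], ref)
        assert call.state == "O" and call.distance == pytest.approx(0.0)
        assert not call.ambiguous

    def test_small_perturbation_still_classified(self):
        ref = self._reference()
        observed = [PeakAssignment(p.residue_index, "W", "C_bound",
                                   p.delta_H + 0.01, p.delta_N, True)
                    for p in ref["C_bound"]]
        call = classify_state(observed, ref)
        assert call.state == "C_bound"
        assert call.distance == pytest.approx(0.01, rel=1e-6)

    def test_equidistant_is_ambiguous(self):
        ref = {
            "O": [PeakAssignment(75, "W", "O", 10.0, 129.0, True),
                  PeakAssignment(167, "W", "O", 10.0, 129.0, True)],
            "C_empty": [PeakAssignment(75, "W", "C_empty", 10.2, 129.0, True),
                        PeakAssignment(167, "W", "C_empty", 10.2, 129.0, True)],
        }
        observed = [PeakAssignment(75, "W", "O", 10.1, 129.0, True),
                    PeakAssignment(167, "W", "O", 10.1, 129.0, True)]
        assert classify_state(observed, ref).ambiguous

    def test_missing_reporter_warns(self):
        ref = self._reference()
        call = classify_state(ref["O"][:1], ref)
        assert call.state == "O"
        assert any("missing reporter" in w for w in call.warnings)
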