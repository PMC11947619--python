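"""Residue-resolved conversion kinetics from time-resolved 2D NMR series.

The open-state (O) resonances of a converting metamorphic protein decay as
the molecule leaves its initial conformation; closed-state (C) resonances
appear as molecules reach the final conformation.  The pipeline here:

1. normalize O-trajectories to the first merged spectrum (all molecules
   assumed open at t=0) and C-trajectories to the last merged spectrum
   (all molecules assumed converted at the end of the measurement, with no
   reverse reaction);
2. fit each O-decay to y = (y0 - ymin) exp(-k x) + ymin by nonlinear least
   squares, reporting the rate constant with its standard regression error;
3. leave C-appearance unfitted (it need not follow an exponential when
   intermediate states are populated) and characterize it instead by a
   half-rise time and a non-exponentiality score;
4. compare rate profiles between conditions after median-ratio scaling, so
   residue-specific deviations stand out from a global rate shift;
5. score the consistency of the data with on-pathway intermediate states.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .spectra import PeakAssignment, SpectrumSeries

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# normalization

def normalize_series(series: SpectrumSeries, mode: str,
                     floor: float = 1e-6) -> SpectrumSeries:
    """Normalize trajectories to a reference point.

    ``O_first`` divides every open-state trajectory by its first value;
    ``C_last`` divides every closed-state trajectory by its last value.
    Trajectories of other states pass through unchanged.  Trajectories whose
    reference value falls below ``floor`` (in absolute value) are dropped and
    the exclusion is recorded in ``meta['excluded_normalization']``.
    """
    if mode not in ("O_first", "C_last"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    target_state = (lambda s: s == "O") if mode == "O_first" else (lambda s: s.startswith("C"))
    ref_index = 0 if mode == "O_first" else -1

    keep_peaks, rows, excluded = [], [], []
    for (res, state), traj in zip(series.peaks, series.intensities):
        if not target_state(state):
            keep_peaks.append((res, state))
            rows.append(traj.copy())
            continue
        ref = traj[ref_index]
        if abs(ref) < floor:
            reason = f"reference intensity {ref:.3g} below floor {floor:.3g}"
            logger.warning("excluding residue %d state %s: %s", res, state, reason)
            excluded.append({"residue": res, "state": state, "reason": reason})
            continue
        keep_peaks.append((res, state))
        rows.append(traj / ref)
    meta = dict(series.meta)
    meta.setdefault("excluded_normalization", []).extend(excluded)
    return SpectrumSeries(series.times.copy(), keep_peaks, np.vstack(rows), meta)


def normalize_conversion(series: SpectrumSeries, floor: float = 1e-6) -> SpectrumSeries:
    """Apply O_first to O-trajectories and C_last to C-trajectories."""
    return normalize_series(normalize_series(series, "O_first", floor), "C_last", floor)


# ---------------------------------------------------------------------------
# exponential decay fitting

@dataclass
class KineticFit:
    """Exponential-decay parameters for one trajectory.

    ``k`` is None when the fit did not converge (optimizer failure or a rate
    indistinguishable from zero at two standard errors).
    """

    k: float | None
    y0: float
    y_min: float
    se_k: float
    r_squared: float
    converged: bool

    @property
    def initial_slope(self) -> float | None:
        """k (y0 - ymin): the true initial rate of intensity change."""
        if self.k is None:
            return None
        return self.k * (self.y0 - self.y_min)


def _decay(x, y0, y_min, k):
    return (y0 - y_min) * np.exp(-k * x) + y_min


def fit_decay(times, values) -> KineticFit:
    """Nonlinear least-squares fit of y = (y0 - ymin) exp(-k x) + ymin.

    Requires at least 5 finite points.  A constant (or non-decaying) series
    yields a non-converged fit rather than an exception.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 5:
        raise ValueError(f"need >= 5 points to fit a decay, got {t.size}")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite")

    y_range = y.max() - y.min()
    if y_range <= 0:
        return KineticFit(None, float(y[0]), float(y[-1]), np.inf, 0.0, False)

    # log-linear starting estimate for k from the upper part of the decay
    k0 = 1.0 / max(t[-1] / 3.0, t[0])
    span = t[-1] - t[0]
    p0 = (float(y[0]), float(y[-1]), k0)
    try:
        popt, pcov = curve_fit(_decay, t, y, p0=p0,
                               bounds=([-np.inf, -np.inf, 0.0],
                                       [np.inf, np.inf, np.inf]),
                               maxfev=20000)
    except (RuntimeError, ValueError):
        return KineticFit(None, float(y[0]), float(y[-1]), np.inf, 0.0, False)

    y0_hat, ymin_hat, k_hat = popt
    resid = y - _decay(t, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0

    se_k = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.inf
    if not np.isfinite(se_k) and np.sqrt(ss_res / t.size) < 1e-9 * y_range:
        se_k = 0.0  # an exact (noiseless) fit has a singular covariance

    converged = np.isfinite(se_k) and k_hat > 2.0 * se_k and k_hat * span > 1e-8
    if not converged:
        return KineticFit(None, float(y0_hat), float(ymin_hat), se_k, r2, False)
    return KineticFit(float(k_hat), float(y0_hat), float(ymin_hat), se_k, r2, True)


def completion_time(fit: KineticFit, fraction: float = 0.97) -> float:
    """Time (min) at which the fitted decay has completed ``fraction`` of
    its total change: t = ln(1/(1-fraction)) / k."""
    if not fit.converged or fit.k is None or fit.k <= 0:
        raise ValueError("completion time requires a converged fit with k > 0")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    return float(np.log(1.0 / (1.0 - fraction)) / fit.k)


def rate_for_completion(t_complete: float, fraction: float = 0.97) -> float:
    """Inverse of :func:`completion_time`: the rate constant whose
    ``fraction``-completion time equals ``t_complete`` minutes."""
    if t_complete <= 0:
        raise ValueError("completion time must be positive")
    return float(np.log(1.0 / (1.0 - fraction)) / t_complete)


# ---------------------------------------------------------------------------
# C-appearance characterization

def _rise(x, y_inf, y_start, k):
    return y_inf - (y_inf - y_start) * np.exp(-k * x)


def half_rise_time(times, values) -> float | None:
    """First time the trajectory crosses half of its final value
    (linear interpolation between bracketing points); None if it never does."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    target = 0.5 * y[-1]
    above = y >= target
    if not above.any():
        return None
    i = int(np.argmax(above))
    if i == 0:
        return float(t[0])
    f = (target - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def nonexponentiality_score(times, values, merge_window: int = 1) -> float:
    """Noise-corrected residual of the best exponential-plateau fit.

    The trajectory is fitted to y = y_inf - (y_inf - y_start) exp(-k t); the
    RMS residual is corrected for point noise (estimated robustly from first
    differences) and normalized by the trajectory range.  A two-state
    appearance curve scores ~0 regardless of noise; a lagged (sigmoidal)
    appearance produced by an on-pathway intermediate scores positive.

    ``merge_window`` is the sliding-addition window of the series: adjacent
    merged points share ``merge_window - 1`` raw spectra, so their
    difference sees only two independent raw-noise terms while each point
    accumulates ``merge_window`` of them; the noise estimate is rescaled by
    sqrt(merge_window / 2) accordingly.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    rng = y.max() - y.min()
    if rng <= 0:
        return 0.0
    p0 = (float(y[-1]), float(y[0]), 1.0 / max(t[-1] / 3.0, t[0]))
    try:
        popt, _ = curve_fit(_rise, t, y, p0=p0,
                            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                            maxfev=20000)
        resid = y - _rise(t, *popt)
    except (RuntimeError, ValueError):
        resid = y - y.mean()
    rms = float(np.sqrt(np.mean(resid ** 2)))
    # robust point-noise estimate from first differences, corrected for the
    # raw-spectrum overlap between adjacent merged points
    diff_sd = float(np.median(np.abs(np.diff(y))) / 0.6744897501960817)
    noise = diff_sd * np.sqrt(max(merge_window, 1) / 2.0)
    excess = np.sqrt(max(rms ** 2 - noise ** 2, 0.0))
    return excess / rng


@dataclass
class AppearanceTrajectory:
    """Descriptor of a C-state appearance curve (never force-fitted)."""

    times: np.ndarray
    values: np.ndarray
    half_rise: float | None
    nonexp_score: float


# ---------------------------------------------------------------------------
# rate profiles

@dataclass
class RateProfile:
    """Per-residue conversion kinetics for one condition (construct + ligand)."""

    condition: str
    o_fits: dict[int, KineticFit] = field(default_factory=dict)
    c_appearance: dict[int, AppearanceTrajectory] = field(default_factory=dict)
    excluded: dict[int, str] = field(default_factory=dict)

    def converged_rates(self) -> dict[int, float]:
        return {r: f.k for r, f in self.o_fits.items() if f.converged}

    def to_dict(self) -> dict:
        return {
            "schema": "mad2nmr.rate_profile/1",
            "condition": self.condition,
            "o_fits": {str(r): {"k": f.k, "y0": f.y0, "y_min": f.y_min,
                                "se_k": f.se_k, "r_squared": f.r_squared,
                                "converged": f.converged}
                       for r, f in self.o_fits.items()},
            "c_appearance": {str(r): {"times": a.times.tolist(),
                                      "values": a.values.tolist(),
                                      "half_rise": a.half_rise,
                                      "nonexp_score": a.nonexp_score}
                             for r, a in self.c_appearance.items()},
            "excluded": {str(r): why for r, why in self.excluded.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateProfile":
        if d.get("schema") != "mad2nmr.rate_profile/1":
            raise ValueError("unrecognized rate-profile schema")
        prof = cls(condition=d["condition"])
        for r, f in d["o_fits"].items():
            prof.o_fits[int(r)] = KineticFit(f["k"], f["y0"], f["y_min"],
                                             f["se_k"], f["r_squared"], f["converged"])
        for r, a in d["c_appearance"].items():
            prof.c_appearance[int(r)] = AppearanceTrajectory(
                np.asarray(a["times"]), np.asarray(a["values"]),
                a["half_rise"], a["nonexp_score"])
        prof.excluded = {int(r): why for r, why in d["excluded"].items()}
        return prof


def build_rate_profile(series: SpectrumSeries, condition: str = "",
                       exclude: set[tuple[int, str]] | None = None) -> RateProfile:
    """Fit all O-decays and describe all C-appearances in a normalized series.

    ``exclude`` holds (residue, state) pairs already discarded upstream
    (e.g. overlap-flagged peaks); they are listed in ``profile.excluded``.
    The series must already be normalized (see :func:`normalize_conversion`).
    """
    exclude = exclude or set()
    window = int(series.meta.get("merge_window", 1))
    profile = RateProfile(condition=condition)
    for (res, state), traj in zip(series.peaks, series.intensities):
        if (res, state) in exclude:
            profile.excluded[res] = f"state {state} excluded upstream (overlap)"
            continue
        if state == "O":
            profile.o_fits[res] = fit_decay(series.times, traj)
        elif state.startswith("C"):
            profile.c_appearance[res] = AppearanceTrajectory(
                series.times.copy(), traj.copy(),
                half_rise_time(series.times, traj),
                nonexponentiality_score(series.times, traj, window))
    for item in series.meta.get("excluded_normalization", []):
        profile.excluded.setdefault(item["residue"], item["reason"])
    return profile


# ---------------------------------------------------------------------------
# profile comparison

@dataclass
class ProfileComparison:
    """Per-residue rate comparison between two conditions."""

    residues: list[int]
    ratio: dict[int, float]           # k_b / k_a
    median_ratio: float
    scaled_ratio: dict[int, float]    # ratio / median_ratio (median_ratio mode)
    flagged: list[int]

    def to_dict(self) -> dict:
        return {"schema": "mad2nmr.profile_comparison/1",
                "residues": self.residues,
                "ratio": {str(r): v for r, v in self.ratio.items()},
                "median_ratio": self.median_ratio,
                "scaled_ratio": {str(r): v for r, v in self.scaled_ratio.items()},
                "flagged": self.flagged}


def compare_profiles(a: RateProfile, b: RateProfile, scaling: str = "median_ratio",
                     flag_factor: float = 1.5) -> ProfileComparison:
    """Compare per-residue rates of condition b against condition a.

    Reports the per-residue rate ratio b/a and the global median ratio.  In
    ``median_ratio`` mode, ratios are rescaled by the global median so a
    uniform acceleration maps to 1 everywhere and residue-specific deviations
    stand out; residues whose scaled ratio deviates from 1 by more than
    ``flag_factor`` (in either direction) are flagged.
    """
    if scaling not in ("none", "median_ratio"):
        raise ValueError(f"unknown scaling mode {scaling!r}")
    ka, kb = a.converged_rates(), b.converged_rates()
    common = sorted(set(ka) & set(kb))
    if not common:
        raise ValueError("profiles share no residues with converged fits")
    ratio = {r: kb[r] / ka[r] for r in common}
    med = float(np.median(list(ratio.values())))
    if scaling == "median_ratio":
        scaled = {r: v / med for r, v in ratio.items()}
    else:
        scaled = dict(ratio)
    flagged = [r for r, v in scaled.items()
               if v > flag_factor or v < 1.0 / flag_factor]
    return ProfileComparison(common, ratio, med, scaled, flagged)


# ---------------------------------------------------------------------------
# intermediate-state scoring

@dataclass
class IntermediateScore:
    """Evidence for on-pathway intermediates in a conversion profile."""

    per_residue_nonexp: dict[int, float]
    median_nonexp: float
    rank_correlation: float | None    # O-decay rate vs C appearance rate (1/half-rise)
    intermediate_consistent: bool
    warnings: list[str]


def intermediate_score(profile: RateProfile, nonexp_threshold: float = 2e-3,
                       corr_threshold: float = 0.5,
                       min_rate_spread: float = 1.5) -> IntermediateScore:
    """Score whether O-disappearance and C-appearance are mutually consistent
    with direct two-state conversion.

    A direct correspondence between per-residue O-decay rates and C-appearance
    rates, with exponential C-appearance, indicates no resolvable intermediate.
    Lagged (non-exponential) C-appearance, or a breakdown of the rank
    correlation between O-decay rates and C half-rise rates, is consistent
    with intermediate states.  The correlation enters the verdict only when
    the fitted rates genuinely vary across residues (max/min ratio at least
    ``min_rate_spread``); with near-uniform rates the ranking is dominated by
    fit noise and carries no pathway information.
    """
    warnings: list[str] = []
    if not profile.c_appearance:
        warnings.append("no C-appearance trajectories: verdict based on nothing, "
                        "returning non-intermediate with warning")
        return IntermediateScore({}, 0.0, None, False, warnings)

    nonexp = {r: a.nonexp_score for r, a in profile.c_appearance.items()}
    med = float(np.median(list(nonexp.values())))

    corr = None
    corr_informative = False
    rates = profile.converged_rates()
    common = sorted(r for r in rates
                    if r in profile.c_appearance
                    and profile.c_appearance[r].half_rise is not None)
    if len(common) >= 3:
        k_o = [rates[r] for r in common]
        k_c = [1.0 / profile.c_appearance[r].half_rise for r in common]
        if len(set(np.round(k_o, 12))) > 1 and len(set(np.round(k_c, 12))) > 1:
            rho = stats.spearmanr(k_o, k_c).statistic
            if np.isfinite(rho):
                corr = float(rho)
                corr_informative = max(k_o) / min(k_o) >= min_rate_spread
                if not corr_informative:
                    warnings.append(
                        "fitted rates are nearly uniform across residues; "
                        "rank correlation reported but not used in the verdict")
        else:
            warnings.append("rates are tied across residues; rank correlation not computable")
    else:
        warnings.append("fewer than 3 residues with both O-fit and C half-rise; "
                        "rank correlation not computable")

    verdict = med > nonexp_threshold or (corr_informative and corr < corr_threshold)
    return IntermediateScore(nonexp, med, corr, bool(verdict), warnings)


# ---------------------------------------------------------------------------
# state fingerprinting

@dataclass
class StateCall:
    state: str
    distance: float
    ambiguous: bool
    warnings: list[str]


def classify_state(observed: list[PeakAssignment],
                   reference: dict[str, list[PeakAssignment]],
                   margin: float = 0.02, w_hn: float = 1.0,
                   w_n: float = 0.16) -> StateCall:
    """Nearest-reference-state classification from reporter (indole) peaks.

    The distance to each reference state is the RMS weighted chemical-shift
    perturbation over reporter peaks matched by residue index.  The call is
    ambiguous when the two best distances differ by less than ``margin`` ppm;
    missing reporters reduce confidence and attach a warning.
    """
    from .shifts import weighted_csp

    if len(reference) < 2:
        raise ValueError("reference table must hold at least 2 states")
    obs_by_res = {p.residue_index: p for p in observed}
    warnings: list[str] = []
    distances: dict[str, float] = {}
    for state, ref_peaks in reference.items():
        if len(ref_peaks) < 2:
            raise ValueError(f"state {state!r} must provide both reporter peaks")
        d2, n = 0.0, 0
        for rp in ref_peaks:
            op = obs_by_res.get(rp.residue_index)
            if op is None:
                warnings.append(f"missing reporter residue {rp.residue_index} "
                                f"for state {state}: reduced confidence")
                continue
            d2 += weighted_csp(op.delta_H - rp.delta_H, op.delta_N - rp.delta_N,
                               w_hn, w_n) ** 2
            n += 1
        distances[state] = np.sqrt(d2 / n) if n else np.inf
    ranked = sorted(distances.items(), key=lambda kv: kv[1])
    best_state, best_d = ranked[0]
    ambiguous = len(ranked) > 1 and (ranked[1][1] - best_d) < margin
    return StateCall(best_state, float(best_d), ambiguous, warnings)
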