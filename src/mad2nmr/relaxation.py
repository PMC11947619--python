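"""T1/T2 relaxation fitting, heteronuclear NOE ratios, flexibility flagging.

Longitudinal (T1) and transverse (T2) 15N relaxation report backbone
mobility on the ps-ns timescale; long T2 and low hetNOE indicate flexible,
predominantly unstructured segments.  Intensities measured at a series of
mixing times are fitted per residue to I(tau) = I0 exp(-tau / T).  A
repeated mixing time (interleaved acquisitions commonly repeat the first
delay) is retained as a separate point and used as a replicate to estimate
measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

# Mixing-time lists for interleaved pseudo-3D relaxation series: eleven
# distinct delays plus a repeat of the first (12 points in total).
T2_DELAYS_S = np.array([7.84, 15.68, 31.36, 47.04, 62.72, 78.4, 94.08,
                        109.76, 125.44, 141.12, 156.8, 7.84]) / 1000.0
T1_DELAYS_S = np.array([0.01, 0.02, 0.04, 0.08, 0.12, 0.16, 0.32, 0.64,
                        0.96, 1.28, 1.60, 0.01])


@dataclass
class RelaxationSeries:
    """Per-residue intensities over a shared mixing-time axis (seconds)."""

    kind: str                               # T1 | T2 | hetNOE
    mixing_times: np.ndarray
    intensities: dict[int, np.ndarray]      # residue -> intensities
    saturated: dict[int, np.ndarray] = field(default_factory=dict)  # hetNOE only

    def __post_init__(self) -> None:
        if self.kind not in ("T1", "T2", "hetNOE"):
            raise ValueError(f"unknown relaxation kind {self.kind!r}")
        self.mixing_times = np.asarray(self.mixing_times, dtype=float)
        if self.kind in ("T1", "T2") and np.unique(self.mixing_times).size < 3:
            raise ValueError("T1/T2 series need >= 3 distinct mixing times")
        self.intensities = {int(r): np.asarray(v, dtype=float)
                            for r, v in self.intensities.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, v in sorted(self.intensities.items()):
            rows.append(pd.DataFrame({"residue": r, "mixing_time_s": self.mixing_times,
                                      "intensity": v}))
        return pd.concat(rows, ignore_index=True)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, kind: str) -> "RelaxationSeries":
        first = df[df["residue"] == df["residue"].iloc[0]].sort_index()
        tau = first["mixing_time_s"].to_numpy(dtype=float)
        intens = {}
        for r, grp in df.groupby("residue"):
            intens[int(r)] = grp.sort_index()["intensity"].to_numpy(dtype=float)
        return cls(kind=kind, mixing_times=tau, intensities=intens)


@dataclass
class RelaxationFit:
    T: float | None              # relaxation time, seconds (None if not converged)
    I0: float
    se_T: float
    converged: bool
    replicate_noise: float | None   # sd estimated from repeated-delay pairs


def _exp_tau(tau, I0, T):
    return I0 * np.exp(-tau / T)


def fit_relaxation(series: RelaxationSeries, residue: int) -> RelaxationFit:
    """Least-squares fit of I = I0 exp(-tau/T) for one residue.

    Repeated-delay pairs are used to estimate replicate noise (sd of the
    within-pair differences / sqrt(2)).  A non-decaying series returns a
    non-converged fit rather than raising.
    """
    tau = series.mixing_times
    y = series.intensities[residue]

    # replicate noise from repeated delays
    noise = None
    diffs = []
    seen: dict[float, float] = {}
    for t_i, y_i in zip(tau, y):
        if t_i in seen:
            diffs.append(y_i - seen[t_i])
        else:
            seen[t_i] = y_i
    if diffs:
        noise = float(np.std(diffs, ddof=0) / np.sqrt(2.0)) if len(diffs) > 1 \
            else float(abs(diffs[0]) / np.sqrt(2.0))

    if y.max() <= 0 or np.ptp(y) == 0:
        return RelaxationFit(None, float(y[0]), np.inf, False, noise)
    T0 = max((tau.max() - tau.min()) / 3.0, tau[tau > 0].min() if (tau > 0).any() else 1.0)
    try:
        popt, pcov = curve_fit(_exp_tau, tau, y, p0=(float(y.max()), T0),
                               bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError):
        return RelaxationFit(None, float(y[0]), np.inf, False, noise)
    I0_hat, T_hat = float(popt[0]), float(popt[1])
    se_T = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else np.inf
    resid = y - _exp_tau(tau, *popt)
    if not np.isfinite(se_T) and np.sqrt(np.mean(resid ** 2)) < 1e-9 * y.max():
        se_T = 0.0  # exact fit: singular covariance
    # T must be distinguishable from "no decay": finite uncertainty smaller
    # than the estimate, and measurable decay within the sampled window
    converged = np.isfinite(se_T) and se_T < T_hat
    if T_hat > 100.0 * tau.max():
        converged = False
    if not converged:
        return RelaxationFit(None, I0_hat, se_T, False, noise)
    return RelaxationFit(T_hat, I0_hat, se_T, True, noise)


def hetnoe_ratio(sat: dict[int, float], unsat: dict[int, float]) -> dict[int, float]:
    """Per-residue heteronuclear NOE ratio: saturated / unsaturated intensity."""
    out = {}
    for r in sorted(set(sat) & set(unsat)):
        if unsat[r] == 0:
            raise ZeroDivisionError(f"residue {r}: unsaturated intensity is zero")
        out[r] = sat[r] / unsat[r]
    return out


def flag_flexible(values: dict[int, float], metric: str = "T2",
                  c: float = 2.0, min_length: int = 3,
                  direction: str | None = None,
                  gap_tolerance: int = 1) -> list[tuple[int, int]]:
    """Contiguous residue runs whose metric marks them as flexible.

    The robust threshold is median +/- c * scale, where the scale is a
    one-sided MAD estimated from the half of the data on the *quiet* side of
    the median, so that the flexible residues themselves do not inflate the
    spread estimate.  For T1, T2 and RMSF, flexibility means values *above*
    the threshold; for hetNOE and peak heights, values *below* (low NOE
    ratios and attenuated peaks indicate mobile residues); ``direction``
    ('above'/'below') overrides the metric default.  Flagged runs separated
    by at most ``gap_tolerance`` unflagged residues are bridged, runs
    shorter than ``min_length`` are dropped, and intervals are returned as
    inclusive 1-based (start, end) residue ranges.
    """
    if metric not in ("T1", "T2", "hetNOE", "RMSF", "peak_height"):
        raise ValueError(f"unknown metric {metric!r}")
    if not values:
        raise ValueError("need at least one residue")
    if direction is None:
        direction = "below" if metric in ("hetNOE", "peak_height") else "above"

    residues = np.array(sorted(values))
    v = np.array([values[r] for r in residues], dtype=float)
    med = np.median(v)
    quiet = med - v[v <= med] if direction == "above" else v[v >= med] - med
    scale = np.median(quiet[quiet >= 0]) / 0.6744897501960817 if quiet.size else 0.0
    if scale == 0:
        # degenerate spread: a majority of identical values; anything that
        # deviates at all (in the flexible direction) is flagged, and a fully
        # flat profile yields no regions
        exceeds = v > med if direction == "above" else v < med
    else:
        exceeds = v > med + c * scale if direction == "above" else v < med - c * scale

    # raw runs of consecutive flagged residues
    runs: list[list[int]] = []
    for r, flag in zip(residues, exceeds):
        if flag and runs and r - runs[-1][1] == 1:
            runs[-1][1] = int(r)
        elif flag:
            runs.append([int(r), int(r)])
    # bridge short gaps between runs (missed residues inside a mobile segment)
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] - 1 <= gap_tolerance:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    return [(a, b) for a, b in merged if b - a + 1 >= min_length]
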