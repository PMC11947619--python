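"""Secondary chemical shifts, weighted CSPs and binding-isotherm fitting.

Secondary chemical shifts, (dCa_obs - dCa_rc) - (dCb_obs - dCb_rc), report
deviation from random-coil values: positive values indicate helical
propensity, negative values beta-strand propensity.  Random-coil reference
shifts come from a static shipped table (no neighbor/pH/temperature
corrections; see the package methods note).

Chemical-shift perturbations between conditions are combined across the
1H and 15N dimensions as the weighted Euclidean norm
sqrt((dH * W_HN)^2 + (dN * W_N)^2) with W_HN = 1 and W_N = 0.16 by default.
Binding affinities are estimated by fitting CSPs along a ligand titration
to the single-site quadratic (tight-binding) isotherm; when the titration
does not constrain the affinity from above (weak binding that never
approaches saturation), the fit is reported as a lower bound on K_D rather
than a point estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

GLYCINE = "G"


# ---------------------------------------------------------------------------
# random-coil reference table

def _load_random_coil_table() -> dict[str, tuple[float, float | None]]:
    with resources.files("mad2nmr.data").joinpath("random_coil_shifts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    table = {}
    for row in df.itertuples(index=False):
        cb = None if pd.isna(row.cb_rc) else float(row.cb_rc)
        table[str(row.residue)] = (float(row.ca_rc), cb)
    return table


RANDOM_COIL: dict[str, tuple[float, float | None]] = _load_random_coil_table()


def random_coil_lookup(sequence: str, index: int, temperature: float = 298.0,
                       pH: float = 7.0) -> tuple[float, float | None]:
    """Random-coil (Ca, Cb) shifts for residue ``index`` (1-based) of ``sequence``.

    The shipped table is sequence-type only; neighbor, pH and temperature
    corrections are not applied (a note is logged once per call site).
    """
    if not 1 <= index <= len(sequence):
        raise IndexError(f"index {index} outside sequence of length {len(sequence)}")
    code = sequence[index - 1].upper()
    if code not in RANDOM_COIL:
        raise KeyError(f"unknown residue code {code!r} at position {index}")
    logger.debug("random-coil lookup for %s%d: static table, no neighbor/pH/T "
                 "corrections applied", code, index)
    return RANDOM_COIL[code]


# ---------------------------------------------------------------------------
# secondary chemical shifts

@dataclass(frozen=True)
class ShiftRecord:
    """Observed and random-coil Ca/Cb shifts for one residue.

    Glycine records carry no Cb terms (both None).
    """

    residue_index: int
    ca_obs: float
    ca_rc: float
    cb_obs: float | None = None
    cb_rc: float | None = None


@dataclass(frozen=True)
class SecondaryShift:
    value: float
    label: str            # helix / strand / coil
    reduced_confidence: bool


def secondary_shift(rec: ShiftRecord, threshold: float = 0.7) -> SecondaryShift:
    """(dCa_obs - dCa_rc) - (dCb_obs - dCb_rc), classified at ``|threshold|``.

    Records with only Ca data (non-glycine residues missing Cb) are computed
    from the Ca term alone and flagged reduced-confidence.
    """
    d_ca = rec.ca_obs - rec.ca_rc
    have_cb = rec.cb_obs is not None and rec.cb_rc is not None
    partial_cb = (rec.cb_obs is None) != (rec.cb_rc is None)
    if partial_cb:
        raise ValueError(f"residue {rec.residue_index}: Cb observed/random-coil "
                         "shifts must both be present or both absent")
    value = d_ca - (rec.cb_obs - rec.cb_rc) if have_cb else d_ca
    if value > threshold:
        label = "helix"
    elif value < -threshold:
        label = "strand"
    else:
        label = "coil"
    return SecondaryShift(float(value), label, reduced_confidence=not have_cb)


# ---------------------------------------------------------------------------
# chemical-shift perturbations

@dataclass(frozen=True)
class CSPRecord:
    residue_index: int
    d_H: float
    d_N: float
    w_HN: float = 1.0
    w_N: float = 0.16

    def __post_init__(self) -> None:
        if self.w_HN <= 0 or self.w_N <= 0:
            raise ValueError("CSP weights must be positive")


def weighted_csp(d_H: float, d_N: float, w_HN: float = 1.0, w_N: float = 0.16) -> float:
    """sqrt((d_H W_HN)^2 + (d_N W_N)^2) in ppm."""
    return float(np.hypot(d_H * w_HN, d_N * w_N))


def csp_of(rec: CSPRecord) -> float:
    return weighted_csp(rec.d_H, rec.d_N, rec.w_HN, rec.w_N)


# ---------------------------------------------------------------------------
# titrations and K_D fitting

@dataclass
class TitrationSeries:
    """Ligand-concentration-resolved CSPs (uM concentrations, ppm shifts)."""

    P: float                              # total protein concentration
    L: np.ndarray                         # total ligand concentrations, increasing
    dd_obs: dict[int, np.ndarray]         # residue -> observed CSPs

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.P <= 0:
            raise ValueError("protein concentration must be positive")
        if np.any(self.L < 0) or np.any(np.diff(self.L) < 0):
            raise ValueError("ligand concentrations must be non-negative, increasing")
        self.dd_obs = {int(r): np.asarray(v, dtype=float) for r, v in self.dd_obs.items()}
        for r, v in self.dd_obs.items():
            if v.shape != self.L.shape:
                raise ValueError(f"residue {r}: CSP array does not match titration points")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, v in sorted(self.dd_obs.items()):
            rows.append(pd.DataFrame({"residue": r, "L_uM": self.L, "dd_obs_ppm": v}))
        df = pd.concat(rows, ignore_index=True)
        df.insert(0, "P_uM", self.P)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TitrationSeries":
        P = float(df["P_uM"].iloc[0])
        L = np.sort(df["L_uM"].unique())
        dd = {}
        for r, grp in df.groupby("residue"):
            grp = grp.sort_values("L_uM")
            dd[int(r)] = grp["dd_obs_ppm"].to_numpy(dtype=float)
        return cls(P=P, L=L, dd_obs=dd)


class FitRefusedError(RuntimeError):
    """The titration data do not support an isotherm fit (e.g. no signal or
    non-monotone CSPs beyond noise)."""


@dataclass
class BindingFit:
    """Fitted single-site binding parameters.

    ``mode`` is ``point_estimate`` when K_D is constrained on both sides and
    ``lower_bound`` when the titration only excludes affinities tighter than
    ``kd`` (reported then as "K_D > kd").
    """

    kd: float
    ddmax: float
    mode: str                     # point_estimate | lower_bound
    residue: int | None           # None for a global (shared-K_D) fit
    se_kd: float | None
    saturation: float             # fitted bound fraction at L_max
    r_squared: float

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.mode not in ("point_estimate", "lower_bound"):
            raise ValueError(f"unknown binding-fit mode {self.mode!r}")


def _isotherm(L, kd, ddmax, P):
    from .synthetic import binding_isotherm
    return binding_isotherm(L, kd, ddmax, P)


def _profile_sse(t: TitrationSeries, dd: np.ndarray, kd: float) -> tuple[float, float]:
    """SSE minimized over ddmax at fixed kd (ddmax enters linearly)."""
    shape = _isotherm(t.L, kd, 1.0, t.P)
    denom = float(shape @ shape)
    ddmax = float(shape @ dd) / denom if denom > 0 else 0.0
    resid = dd - ddmax * shape
    return float(resid @ resid), ddmax


def _check_response(dd: np.ndarray, label: str, noise_floor: float,
                    drop_tolerance: float) -> None:
    span = float(dd.max() - dd.min())
    if span < noise_floor or abs(dd[-1]) < noise_floor:
        raise FitRefusedError(f"{label}: no CSP signal above {noise_floor} ppm")
    drops = np.diff(dd) < -drop_tolerance * span
    if drops.any():
        raise FitRefusedError(
            f"{label}: CSPs decrease beyond noise (more than "
            f"{drop_tolerance:.0%} of the response span) at titration "
            f"point(s) {np.nonzero(drops)[0] + 1}")


def _global_sse(t: TitrationSeries, residues, kd: float) -> float:
    """SSE over residues, each ddmax profiled out (shared kd)."""
    return sum(_profile_sse(t, t.dd_obs[r], kd)[0] for r in residues)


def fit_kd(t: TitrationSeries, residue: int | None = None,
           selection: str = "max_csp", saturation_floor: float = 0.5,
           confidence: float = 0.95, noise_floor: float = 1e-4,
           drop_tolerance: float = 0.25) -> BindingFit:
    """Fit the quadratic single-site isotherm to titration CSPs.

    Selection modes: ``max_csp`` fits the single residue with the largest
    final CSP; ``explicit`` fits ``residue``; ``global`` fits one shared K_D
    across every residue in the series, with an independent ddmax per residue
    profiled out linearly (the standard global CSP fit, which pools the
    affinity information of all reporting residues).  Requires >= 4 titration
    points; a response that decreases by more than ``drop_tolerance`` of its
    span between consecutive points is refused as non-monotone beyond noise.

    Lower-bound semantics: when the fitted curve reaches less than
    ``saturation_floor`` of ddmax at the highest ligand concentration, or the
    K_D profile-likelihood confidence interval is unbounded above, the result
    is a lower bound; ``kd`` is then the largest K_D rejected at
    ``confidence`` by an F-test on the profiled sum of squares.
    """
    if t.L.size < 4:
        raise FitRefusedError(f"need >= 4 titration points, got {t.L.size}")
    if selection not in ("max_csp", "explicit", "global"):
        raise ValueError(f"unknown selection mode {selection!r}")

    if selection == "global":
        residues = sorted(t.dd_obs)
        for r in residues:
            _check_response(t.dd_obs[r], f"residue {r}", noise_floor,
                            drop_tolerance)
        n = t.L.size * len(residues)
        n_par = 1 + len(residues)

        def sse_of(kd):
            return _global_sse(t, residues, kd)

        report_residue = None
        lead = max(residues, key=lambda r: abs(t.dd_obs[r][-1]))
        dd_lead = t.dd_obs[lead]
    else:
        if selection == "max_csp":
            residue = max(t.dd_obs, key=lambda r: abs(t.dd_obs[r][-1]))
        if residue not in t.dd_obs:
            raise KeyError(f"no titration data for residue {residue}")
        dd_lead = t.dd_obs[residue]
        _check_response(dd_lead, f"residue {residue}", noise_floor,
                        drop_tolerance)
        n, n_par = t.L.size, 2

        def sse_of(kd):
            return _profile_sse(t, dd_lead, kd)[0]

        report_residue = int(residue)

    # profile the (shared) kd on a log grid, then polish locally
    from scipy.optimize import minimize_scalar
    grid = np.geomspace(1e-3, max(t.L[-1], t.P) * 1e4, 240)
    sse_grid = np.array([sse_of(kd) for kd in grid])
    i_best = int(np.argmin(sse_grid))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, grid.size - 1)]
    res = minimize_scalar(lambda lnk: sse_of(np.exp(lnk)),
                          bounds=(np.log(lo), np.log(hi)), method="bounded",
                          options={"xatol": 1e-12})
    kd_hat = float(np.exp(res.x))
    sse_min = max(float(res.fun), 1e-30)

    _, ddmax_hat = _profile_sse(t, dd_lead, kd_hat)
    pred = _isotherm(t.L, kd_hat, ddmax_hat, t.P)
    ss_tot = float(np.sum((dd_lead - dd_lead.mean()) ** 2))
    r2 = 1.0 - _profile_sse(t, dd_lead, kd_hat)[0] / ss_tot if ss_tot > 0 else 0.0
    saturation = float(pred[-1] / ddmax_hat) if ddmax_hat > 0 else 0.0

    # profile-likelihood confidence region via an F-test on the SSE ratio
    dof = n - n_par
    f_crit = sps.f.ppf(confidence, 1, dof)
    sse_cut = sse_min * (1.0 + f_crit / dof)
    se_kd = None
    # curvature-based standard error on ln kd, mapped back to kd
    h = 1e-4
    d2 = (np.log(sse_of(kd_hat * np.exp(h))) + np.log(sse_of(kd_hat * np.exp(-h)))
          - 2.0 * np.log(sse_min)) / h ** 2
    if d2 > 0:
        se_kd = float(kd_hat * np.sqrt(2.0 / (dof * d2)))

    upper = grid > kd_hat
    upper_unbounded = bool(np.all(sse_grid[upper] <= sse_cut)) if upper.any() else True

    if saturation < saturation_floor or upper_unbounded:
        rejected = grid[(grid < kd_hat) & (sse_grid > sse_cut)]
        kd_bound = float(rejected.max()) if rejected.size else kd_hat
        return BindingFit(kd=kd_bound, ddmax=ddmax_hat, mode="lower_bound",
                          residue=report_residue, se_kd=se_kd,
                          saturation=saturation, r_squared=r2)
    return BindingFit(kd=kd_hat, ddmax=ddmax_hat, mode="point_estimate",
                      residue=report_residue, se_kd=se_kd,
                      saturation=saturation, r_squared=r2)
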