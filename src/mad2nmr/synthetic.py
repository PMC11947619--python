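"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here: peak
intensity time series under two-state (O -> C) or three-state (O -> I -> C)
first-order conversion kinetics, ligand titrations on the single-site
quadratic binding isotherm, relaxation decay series, and coordinate
ensembles with prescribed per-residue fluctuation.

The kinetic scheme mirrors a metamorphic protein converting irreversibly
from an open to a closed conformer: conversion is complete at the end of
the measurement and there is no reverse reaction.  The three-state scheme
inserts a sequential intermediate, which produces the lagged (sigmoidal)
appearance of closed-state signal that distinguishes it from simple
two-state kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import PeakAssignment, SpectrumSeries


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration (names the residue/state)."""


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition schedule: ``n_spectra`` spectra of ``dt`` minutes each.

    Spectrum i (0-based) is timestamped at its completion time
    ``start_time + dt * (i + 1)``.
    """

    n_spectra: int = 500
    dt: float = 5.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.n_spectra < 1:
            raise ValueError("n_spectra must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.dt * (np.arange(self.n_spectra) + 1)

    @property
    def total_minutes(self) -> float:
        return float(self.n_spectra * self.dt)


@dataclass(frozen=True)
class KineticModelSpec:
    """First-order conversion model O -> C (two_state) or O -> I -> C.

    ``k1`` (min^-1) is the O-depletion rate (scaled per residue by
    ``per_residue_rate_scale``); ``k2`` the I -> C rate for the three-state
    scheme.  ``amplitudes`` maps (residue, state) to the peak amplitude of
    that resonance at full population.  ``noise_sd`` is additive Gaussian
    intensity noise expressed as a fraction of each residue's initial
    (full-population) amplitude.
    """

    scheme: str = "two_state"
    k1: float = 0.01
    k2: float | None = None
    per_residue_rate_scale: dict[int, float] = field(default_factory=dict)
    amplitudes: dict[tuple[int, str], float] = field(default_factory=dict)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in ("two_state", "three_state"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.k1 <= 0:
            raise ValueError("k1 must be positive")
        if self.scheme == "three_state" and (self.k2 is None or self.k2 <= 0):
            raise ValueError("three_state scheme requires k2 > 0")
        if any(s <= 0 for s in self.per_residue_rate_scale.values()):
            raise ValueError("per-residue rate scales must be positive")
        if any(a <= 0 for a in self.amplitudes.values()):
            raise ValueError("amplitudes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rate_for(self, residue: int) -> float:
        return self.k1 * self.per_residue_rate_scale.get(residue, 1.0)


def populations(t, k1: float, k2: float | None = None, scheme: str = "two_state"):
    """Closed-form state populations (P_O, P_I, P_C) at time(s) ``t``.

    Two-state: P_O = exp(-k1 t), P_C = 1 - P_O, P_I = 0.
    Three-state sequential first-order kinetics:
    P_I = k1/(k2-k1) (exp(-k1 t) - exp(-k2 t)) with the k1 == k2 limit
    P_I = k1 t exp(-k1 t).
    """
    t = np.asarray(t, dtype=float)
    p_o = np.exp(-k1 * t)
    if scheme == "two_state":
        p_i = np.zeros_like(p_o)
    elif scheme == "three_state":
        if k2 is None:
            raise ValueError("three_state populations require k2")
        if np.isclose(k1, k2, rtol=1e-12, atol=0.0):
            p_i = k1 * t * np.exp(-k1 * t)
        else:
            p_i = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    p_c = 1.0 - p_o - p_i
    return p_o, p_i, p_c


@dataclass(frozen=True)
class GroundTruth:
    """The generating model, with analytic populations for any residue/time."""

    model: KineticModelSpec

    def populations_for(self, residue: int, t):
        return populations(t, self.model.rate_for(residue), self.model.k2,
                           self.model.scheme)


_STATE_TO_POP = {"O": 0, "I": 1, "C_empty": 2, "C_bound": 2}


def simulate_conversion_series(model: KineticModelSpec, acq: AcquisitionSpec,
                               peak_map: list[PeakAssignment],
                               ) -> tuple[SpectrumSeries, GroundTruth]:
    """Per-residue peak intensities following the conversion kinetics.

    O-state intensity tracks P_O(t) x amplitude; closed-state intensity
    tracks P_C(t) x amplitude; intermediate peaks (three-state only) track
    P_I(t).  Additive Gaussian noise of sd ``noise_sd`` x initial amplitude
    is applied per point.  Every residue present in ``peak_map`` must carry
    an amplitude for each of its peaks' states.
    """
    times = acq.times
    rng = np.random.default_rng(model.seed)
    residues = sorted({p.residue_index for p in peak_map})
    pop_cache = {r: populations(times, model.rate_for(r), model.k2, model.scheme)
                 for r in residues}

    peaks: list[tuple[int, str]] = []
    rows = []
    for p in sorted(peak_map, key=lambda p: (p.residue_index, p.state_label)):
        key = (p.residue_index, p.state_label)
        if p.state_label == "I" and model.scheme != "three_state":
            raise ConfigurationError(
                f"residue {p.residue_index}: intermediate peak requires three_state scheme")
        if key not in model.amplitudes:
            raise ConfigurationError(
                f"missing amplitude for residue {p.residue_index} state {p.state_label}")
        amp = model.amplitudes[key]
        pop = pop_cache[p.residue_index][_STATE_TO_POP[p.state_label]]
        signal = amp * pop
        if model.noise_sd > 0:
            signal = signal + rng.normal(0.0, model.noise_sd * amp, size=times.size)
        peaks.append(key)
        rows.append(signal)

    series = SpectrumSeries(times, peaks, np.vstack(rows),
                            meta={"n_spectra": acq.n_spectra, "dt": acq.dt,
                                  "start_time": acq.start_time,
                                  "scheme": model.scheme, "seed": model.seed})
    return series, GroundTruth(model)


def binding_isotherm(L, kd: float, ddmax: float, P: float) -> np.ndarray:
    """Single-site quadratic (tight-binding) isotherm.

    ddobs = ddmax * [(P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)] / (2 P),
    with total protein concentration P and total ligand concentration L.
    """
    L = np.asarray(L, dtype=float)
    b = P + L + kd
    return ddmax * (b - np.sqrt(b * b - 4.0 * P * L)) / (2.0 * P)


def simulate_titration(kd: float, ddmax, P: float, L_series,
                       noise_sd: float = 0.0, seed: int = 0,
                       residue: int = 1):
    """Chemical-shift perturbations along a ligand titration.

    ``ddmax`` may be a scalar (one residue, index ``residue``) or a mapping
    residue -> ddmax (several residues sharing the same K_D, as for a single
    binding site reported by multiple resonances).  Concentrations in uM,
    shifts in ppm.  Returns a :class:`~mad2nmr.shifts.TitrationSeries`.
    """
    from .shifts import TitrationSeries
    L = np.asarray(L_series, dtype=float)
    if kd <= 0 or P <= 0:
        raise ValueError("kd and P must be positive")
    if np.any(L < 0) or np.any(np.diff(L) < 0):
        raise ValueError("L_series must be non-negative and increasing")
    ddmax_map = ddmax if isinstance(ddmax, dict) else {residue: ddmax}
    rng = np.random.default_rng(seed)
    dd_obs = {}
    for res, dmax in sorted(ddmax_map.items()):
        dd = binding_isotherm(L, kd, dmax, P)
        if noise_sd > 0:
            dd = dd + rng.normal(0.0, noise_sd, size=L.size)
        dd_obs[int(res)] = dd
    return TitrationSeries(P=P, L=L, dd_obs=dd_obs)


def simulate_relaxation(T: float, I0: float, mixing_times, noise_sd: float = 0.0,
                        seed: int = 0, kind: str = "T2", residue: int = 1):
    """Exponential relaxation decay I(tau) = I0 exp(-tau / T) plus noise.

    ``mixing_times`` in seconds; repeats allowed (and retained) to mirror
    interleaved acquisitions with a repeated first delay.  Returns a
    :class:`~mad2nmr.relaxation.RelaxationSeries`.
    """
    from .relaxation import RelaxationSeries
    tau = np.asarray(mixing_times, dtype=float)
    if T <= 0:
        raise ValueError("T must be positive")
    if np.any(tau < 0):
        raise ValueError("mixing times must be non-negative")
    I = I0 * np.exp(-tau / T)
    if noise_sd > 0:
        I = I + np.random.default_rng(seed).normal(0.0, noise_sd * I0, size=tau.size)
    return RelaxationSeries(kind=kind, mixing_times=tau, intensities={residue: I})


def simulate_ensemble(reference, per_residue_sigma: dict[int, float],
                      n_frames: int, frame_period_ns: float = 0.2,
                      rigid_motion: bool = False, seed: int = 0):
    """Gaussian-fluctuation ensemble around a reference structure.

    Each frame displaces every atom of residue r by isotropic Gaussian
    noise of sd sigma_r per coordinate (Angstrom); the analytic Calpha RMSF
    of such a frame set is sigma_r * sqrt(3).  With ``rigid_motion`` each
    frame is additionally given a random global rotation and translation,
    which superposition must remove exactly.
    """
    from .ensemble import CoordinateEnsemble
    from scipy.spatial.transform import Rotation

    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if any(s < 0 for s in per_residue_sigma.values()):
        raise ValueError("per-residue sigma must be non-negative")
    rng = np.random.default_rng(seed)
    ref_coords = np.asarray(reference.coords[0] if reference.coords.ndim == 3
                            else reference.coords, dtype=float)
    atoms = reference.atoms
    sigma_atom = atoms["residue_index"].map(
        lambda r: per_residue_sigma.get(int(r), 0.0)).to_numpy(dtype=float)

    frames = np.empty((n_frames, ref_coords.shape[0], 3))
    for f in range(n_frames):
        disp = rng.normal(0.0, 1.0, size=ref_coords.shape) * sigma_atom[:, None]
        coords = ref_coords + disp
        if rigid_motion:
            R = Rotation.random(random_state=rng).as_matrix()
            t = rng.normal(0.0, 10.0, size=3)
            coords = coords @ R.T + t
        frames[f] = coords
    return CoordinateEnsemble(frames, atoms.copy(), frame_period_ns)


def build_reference_structure(n_residues: int, chain: str = "A",
                              glycines: tuple[int, ...] = (),
                              ligand_sequence: str | None = None,
                              ligand_chain: str = "B",
                              ligand_offset: float = 6.0, seed: int = 0):
    """A compact synthetic protein backbone for ensemble fixtures.

    Calpha atoms trace an ideal alpha-helical curve (rise 1.5 A, radius
    2.3 A, 100 degrees per residue); N, C and CB atoms are placed at fixed
    offsets from each Calpha (glycines get no CB).  When ``ligand_sequence``
    is given, a second chain is laid alongside at ``ligand_offset`` Angstrom.
    Synthetic: a geometric stand-in for a folded domain, adequate for
    superposition/RMSF/contact statistics but without real stereochemistry.
    """
    import pandas as pd
    from .ensemble import CoordinateEnsemble
    from .constructs import AA3

    def chain_atoms(n_res, seq_codes, chain_id, origin):
        rows, coords = [], []
        for i in range(n_res):
            theta = np.deg2rad(100.0 * i)
            ca = origin + np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta),
                                    1.5 * i])
            code = seq_codes[i]
            res_name = AA3[code]
            for name, off in (("N", (-0.5, 0.9, -0.9)), ("CA", (0, 0, 0)),
                              ("C", (0.6, -0.8, 0.7)), ("O", (1.4, -0.5, 1.4)),
                              ("CB", (1.0, 1.0, 0.2))):
                if name == "CB" and code == "G":
                    continue
                rows.append({"residue_index": i + 1, "residue_name": res_name,
                             "atom_name": name, "chain": chain_id})
                coords.append(ca + np.array(off))
        return rows, coords

    seq = "".join("G" if (i + 1) in glycines else "A" for i in range(n_residues))
    rows, coords = chain_atoms(n_residues, seq, chain, np.zeros(3))
    if ligand_sequence:
        lrows, lcoords = chain_atoms(len(ligand_sequence), ligand_sequence,
                                     ligand_chain,
                                     np.array([ligand_offset, 0.0, 0.0]))
        rows += lrows
        coords += lcoords
    atoms = pd.DataFrame(rows)
    return CoordinateEnsemble(np.asarray(coords)[None], atoms, frame_period_ns=0.2)


# ---------------------------------------------------------------------------
# convenience builders used by the CLI demo and tests

def default_peak_map(residues, states=("O", "C_empty"), seed: int = 0,
                     ) -> tuple[list[PeakAssignment], dict[tuple[int, str], float]]:
    """A well-dispersed synthetic peak map with unit-scale amplitudes.

    Peak positions are spread over typical amide ppm ranges (1H 6.5-10.5,
    15N 103-133) with spacing large enough to avoid accidental overlap;
    amplitudes are drawn uniformly from [0.5, 2.0].
    """
    rng = np.random.default_rng(seed)
    codes = "ACDEFHIKLMNQRSTVWY"  # no Gly/Pro specialization needed here
    peaks, amps = [], {}
    for i, res in enumerate(residues):
        code = codes[i % len(codes)]
        for j, state in enumerate(states):
            h = 6.5 + 4.0 * ((i * len(states) + j) / max(1, len(residues) * len(states)))
            n = 103.0 + rng.uniform(0, 30)
            peaks.append(PeakAssignment(res, code, state, delta_H=h, delta_N=n))
            amps[(res, state)] = float(rng.uniform(0.5, 2.0))
    return peaks, amps
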