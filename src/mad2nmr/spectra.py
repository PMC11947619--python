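"""Time-resolved 2D spectral data: peak lists, intensity series, planes.

The central container is :class:`SpectrumSeries`, a per-peak intensity
matrix on a shared time axis.  Peaks are identified by residue index and
conformational-state label (``O`` for the open state, ``C_empty``/``C_bound``
for the closed state without/with ligand, ``I`` for a kinetic intermediate).

The sliding-addition step used to boost signal-to-noise in long
acquisition series sums ``window`` consecutive spectra with stride 1, so
consecutive merged points keep the single-spectrum time offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

STATE_LABELS = ("O", "C_empty", "C_bound", "I")

# one-letter amino acid codes
AA1 = set("ACDEFGHIKLMNPQRSTVWY")


class PeakListError(ValueError):
    """Malformed peak list content (carries a line number when parsing)."""


@dataclass(frozen=True)
class PeakAssignment:
    """An assigned 2D resonance: residue, state and ppm coordinates."""

    residue_index: int
    residue_code: str
    state_label: str
    delta_H: float
    delta_N: float
    is_sidechain_indole: bool = False

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if self.residue_code not in AA1:
            raise ValueError(f"unknown residue code {self.residue_code!r}")
        if self.state_label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.state_label!r}")
        if not (np.isfinite(self.delta_H) and np.isfinite(self.delta_N)):
            raise ValueError("peak ppm coordinates must be finite")

    @property
    def key(self) -> tuple[int, str, bool]:
        return (self.residue_index, self.state_label, self.is_sidechain_indole)

    def sparky_label(self) -> str:
        if self.is_sidechain_indole:
            return f"{self.residue_code}{self.residue_index}NE1-HE1"
        return f"{self.residue_code}{self.residue_index}N-H"


def validate_peak_list(peaks: list[PeakAssignment]) -> list[PeakAssignment]:
    """Check (residue, state, indole) uniqueness; return the list unchanged."""
    seen: dict[tuple, PeakAssignment] = {}
    for p in peaks:
        if p.key in seen:
            raise PeakListError(f"duplicate peak for residue {p.residue_index} "
                                f"state {p.state_label} (indole={p.is_sidechain_indole})")
        seen[p.key] = p
    return peaks


_SPARKY_LABEL = re.compile(r"^([A-Z])(\d+)([A-Z][A-Z0-9]*)-([A-Z][A-Z0-9]*)$")


def parse_sparky_label(label: str) -> tuple[str, int, bool]:
    """Decompose a Sparky assignment label like ``A123N-H`` or ``W167NE1-HE1``.

    Returns (residue one-letter code, residue index, is_sidechain_indole).
    """
    m = _SPARKY_LABEL.match(label.strip())
    if m is None:
        raise PeakListError(f"unparseable Sparky label {label!r}")
    code, idx, atom_n, atom_h = m.group(1), int(m.group(2)), m.group(3), m.group(4)
    indole = atom_n == "NE1" and atom_h == "HE1"
    return code, idx, indole


def read_peak_list(path, dialect: str = "sparky") -> list[PeakAssignment]:
    """Read a peak list; ``dialect`` is ``sparky`` or ``delimited``.

    The Sparky dialect is whitespace-separated ``Assignment  w1(15N)  w2(1H)``
    with an optional trailing ``state`` column (``O`` assumed when absent).
    The delimited dialect is the CSV written by :func:`write_peak_list`.
    """
    if dialect == "delimited":
        df = pd.read_csv(path)
        required = {"residue_index", "residue_code", "state_label",
                    "delta_H", "delta_N", "is_sidechain_indole"}
        missing = required - set(df.columns)
        if missing:
            raise PeakListError(f"delimited peak list missing columns {sorted(missing)}")
        peaks = [PeakAssignment(int(r.residue_index), str(r.residue_code),
                                str(r.state_label), float(r.delta_H), float(r.delta_N),
                                bool(r.is_sidechain_indole))
                 for r in df.itertuples(index=False)]
        return validate_peak_list(peaks)
    if dialect != "sparky":
        raise ValueError(f"unknown peak-list dialect {dialect!r}")

    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.lower().startswith("assignment"):
                continue
            fields = line.split()
            if len(fields) not in (3, 4):
                raise PeakListError(f"line {lineno}: expected 3 or 4 fields, got {len(fields)}")
            try:
                code, idx, indole = parse_sparky_label(fields[0])
                w1, w2 = float(fields[1]), float(fields[2])
            except (PeakListError, ValueError) as exc:
                raise PeakListError(f"line {lineno}: {exc}") from exc
            state = fields[3] if len(fields) == 4 else "O"
            peaks.append(PeakAssignment(idx, code, state, delta_H=w2, delta_N=w1,
                                        is_sidechain_indole=indole))
    return validate_peak_list(peaks)


def write_peak_list(peaks: list[PeakAssignment], path, dialect: str = "sparky") -> None:
    validate_peak_list(peaks)
    if dialect == "delimited":
        pd.DataFrame(
            [{"residue_index": p.residue_index, "residue_code": p.residue_code,
              "state_label": p.state_label, "delta_H": p.delta_H, "delta_N": p.delta_N,
              "is_sidechain_indole": p.is_sidechain_indole} for p in peaks]
        ).to_csv(path, index=False)
        return
    if dialect != "sparky":
        raise ValueError(f"unknown peak-list dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(f"{'Assignment':>17} {'w1':>8} {'w2':>8}  state\n")
        for p in peaks:
            fh.write(f"{p.sparky_label():>17} {p.delta_N:8.3f} {p.delta_H:8.3f}  {p.state_label}\n")


@dataclass
class SpectrumSeries:
    """Per-peak intensity trajectories on a shared time axis (minutes).

    ``peaks`` are (residue_index, state_label) pairs indexing the rows of
    ``intensities``; ``meta`` carries acquisition parameters and, for merged
    series, the sliding-addition window and stride.
    """

    times: np.ndarray                      # (n_times,) minutes
    peaks: list[tuple[int, str]]           # (residue_index, state_label)
    intensities: np.ndarray                # (n_peaks, n_times)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.intensities.shape != (len(self.peaks), self.times.size):
            raise ValueError(
                f"intensity matrix shape {self.intensities.shape} inconsistent with "
                f"{len(self.peaks)} peaks x {self.times.size} times")

    @property
    def n_times(self) -> int:
        return self.times.size

    def row(self, residue: int, state: str) -> np.ndarray:
        try:
            i = self.peaks.index((residue, state))
        except ValueError:
            raise KeyError(f"no trajectory for residue {residue} state {state}") from None
        return self.intensities[i]

    def residues(self, state: str | None = None) -> list[int]:
        return sorted({r for r, s in self.peaks if state is None or s == state})

    def subset(self, keep: list[tuple[int, str]]) -> "SpectrumSeries":
        idx = [self.peaks.index(p) for p in keep]
        return SpectrumSeries(self.times.copy(), list(keep),
                              self.intensities[idx].copy(), dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (residue, state, time_min, intensity)."""
        rows = []
        for (res, state), traj in zip(self.peaks, self.intensities):
            rows.append(pd.DataFrame({"residue": res, "state": state,
                                      "time_min": self.times, "intensity": traj}))
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "SpectrumSeries":
        times = np.sort(df["time_min"].unique())
        peaks, mat = [], []
        for (res, state), grp in df.groupby(["residue", "state"], sort=True):
            grp = grp.sort_values("time_min")
            if not np.allclose(grp["time_min"].to_numpy(), times):
                raise ValueError(f"residue {res} state {state} not on the shared time axis")
            peaks.append((int(res), str(state)))
            mat.append(grp["intensity"].to_numpy(dtype=float))
        return cls(times, peaks, np.vstack(mat), dict(meta or {}))

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "SpectrumSeries":
        return cls.from_frame(pd.read_csv(path), meta)


def sliding_add(series: SpectrumSeries, window: int) -> SpectrumSeries:
    """Sum ``window`` consecutive spectra with stride 1.

    Merged point j is the sum of spectra j..j+window-1; its timestamp is the
    mean of the window's timestamps, so consecutive merged points keep the
    per-spectrum time offset.  Output length is n - window + 1.
    """
    n = series.n_times
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    if window == 1:
        out = SpectrumSeries(series.times.copy(), list(series.peaks),
                             series.intensities.copy(), dict(series.meta))
        out.meta.update(merge_window=1, merge_stride=1)
        return out
    kernel = np.ones(window)
    merged = np.apply_along_axis(lambda v: np.convolve(v, kernel, mode="valid"),
                                 1, series.intensities)
    times = np.convolve(series.times, kernel / window, mode="valid")
    meta = dict(series.meta)
    meta.update(merge_window=window, merge_stride=1)
    return SpectrumSeries(times, list(series.peaks), merged, meta)


@dataclass
class SpectralPlane:
    """A synthetic 2D intensity grid with ppm axes (H horizontal, N vertical)."""

    grid: np.ndarray        # (n_N, n_H)
    h_ppm: np.ndarray       # (n_H,) monotone
    n_ppm: np.ndarray       # (n_N,) monotone
    linewidth_H: float = 0.02   # ppm FWHM used at synthesis
    linewidth_N: float = 0.2

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.h_ppm = np.asarray(self.h_ppm, dtype=float)
        self.n_ppm = np.asarray(self.n_ppm, dtype=float)
        for ax in (self.h_ppm, self.n_ppm):
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("plane axes must be monotone")
        if self.grid.shape != (self.n_ppm.size, self.h_ppm.size):
            raise ValueError("grid shape inconsistent with axes")
        if self.linewidth_H < 0 or self.linewidth_N < 0:
            raise ValueError("linewidths must be non-negative")


def synthesize_plane(peaks: list[PeakAssignment], amplitudes: dict[tuple[int, str], float],
                     h_ppm: np.ndarray, n_ppm: np.ndarray,
                     linewidth_H: float = 0.02, linewidth_N: float = 0.2) -> SpectralPlane:
    """Render assigned peaks as 2D Gaussians of the given FWHM linewidths."""
    H, N = np.meshgrid(np.asarray(h_ppm, float), np.asarray(n_ppm, float))
    sig_h = linewidth_H / 2.3548200450309493  # FWHM -> sd
    sig_n = linewidth_N / 2.3548200450309493
    grid = np.zeros_like(H)
    for p in peaks:
        amp = amplitudes.get((p.residue_index, p.state_label), 0.0)
        grid += amp * np.exp(-0.5 * (((H - p.delta_H) / sig_h) ** 2
                                     + ((N - p.delta_N) / sig_n) ** 2))
    return SpectralPlane(grid, np.asarray(h_ppm, float), np.asarray(n_ppm, float),
                         linewidth_H, linewidth_N)


@dataclass
class ExtractionResult:
    intensity: float
    drift_H: float   # argmax position minus assigned position, ppm
    drift_N: float


def extract_intensity(plane: SpectralPlane, peak: PeakAssignment,
                      search_radius: tuple[float, float] = (0.05, 0.5)) -> ExtractionResult:
    """Maximum grid intensity within a search box centred on the assignment.

    ``search_radius`` is the (H, N) half-width of the box in ppm.  Raises a
    bounds error when the assigned position lies outside the plane axes.
    """
    rH, rN = search_radius
    hmin, hmax = min(plane.h_ppm), max(plane.h_ppm)
    nmin, nmax = min(plane.n_ppm), max(plane.n_ppm)
    if not (hmin <= peak.delta_H <= hmax and nmin <= peak.delta_N <= nmax):
        raise ValueError(f"peak {peak.sparky_label()} outside plane axes")
    sel_h = np.abs(plane.h_ppm - peak.delta_H) <= rH
    sel_n = np.abs(plane.n_ppm - peak.delta_N) <= rN
    sub = plane.grid[np.ix_(sel_n, sel_h)]
    if sub.size == 0:
        raise ValueError("search box contains no grid points")
    i_n, i_h = np.unravel_index(np.argmax(sub), sub.shape)
    h_at = plane.h_ppm[sel_h][i_h]
    n_at = plane.n_ppm[sel_n][i_n]
    return ExtractionResult(float(sub[i_n, i_h]),
                            float(h_at - peak.delta_H), float(n_at - peak.delta_N))


def flag_overlaps(peaks: list[PeakAssignment], linewidth_H: float,
                  linewidth_N: float, factor: float = 1.0) -> set[tuple[int, str, bool]]:
    """Mutually flag peaks whose assigned positions fall within ``factor``
    full linewidths in both dimensions; flagged peaks should be excluded
    from downstream intensity fitting."""
    flagged: set[tuple[int, str, bool]] = set()
    for i, a in enumerate(peaks):
        for b in peaks[i + 1:]:
            if (abs(a.delta_H - b.delta_H) < factor * linewidth_H
                    and abs(a.delta_N - b.delta_N) < factor * linewidth_N):
                flagged.add(a.key)
                flagged.add(b.key)
    return flagged
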