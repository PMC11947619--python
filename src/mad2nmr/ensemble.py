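"""Coordinate-ensemble statistics: superposition, RMSD, RMSF, contacts.

Ensembles are ordered snapshots of atomic coordinates (Angstrom) with
per-atom residue/atom metadata and a fixed frame period (ns).  Multi-model
PDB is the interchange format.  The statistics follow standard trajectory
analysis practice:

* RMSD per frame to a fixed reference (the first frame by default), after
  least-squares rigid-body superposition of the backbone;
* per-residue Calpha RMSF about the ensemble-average coordinates, with the
  average obtained by iterated fit-to-average and the profile averaged over
  independent simulation repeats;
* per-residue ligand contact probability: the fraction of retained frames
  in which the residue's Cbeta (Calpha for glycine) lies within a distance
  cutoff of any ligand Cbeta, after dropping an initial equilibration
  window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class SuperpositionError(ValueError):
    """Degenerate atom selection (fewer than 3 non-collinear atoms)."""


@dataclass
class CoordinateEnsemble:
    """Frames of atomic coordinates with shared atom metadata.

    ``atoms`` columns: residue_index (1-based int), residue_name (3-letter),
    atom_name, chain.
    """

    coords: np.ndarray          # (n_frames, n_atoms, 3), Angstrom
    atoms: pd.DataFrame
    frame_period_ns: float = 0.2

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom metadata does not match coordinate count")
        if self.frame_period_ns <= 0:
            raise ValueError("frame_period_ns must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_mask(self, atom_names=None, residues=None, chain=None) -> np.ndarray:
        mask = np.ones(len(self.atoms), dtype=bool)
        if atom_names is not None:
            mask &= self.atoms["atom_name"].isin(atom_names).to_numpy()
        if residues is not None:
            mask &= self.atoms["residue_index"].isin(residues).to_numpy()
        if chain is not None:
            mask &= (self.atoms["chain"] == chain).to_numpy()
        return mask

    # ----- multi-model PDB interchange -------------------------------------
    def to_pdb(self, path, b_factors: np.ndarray | None = None) -> None:
        n_atoms = len(self.atoms)
        arrays = []
        for frame in self.coords:
            arr = struc.AtomArray(n_atoms)
            arr.coord = np.asarray(frame, dtype=np.float32)
            arr.res_id = self.atoms["residue_index"].to_numpy(dtype=int)
            arr.res_name = self.atoms["residue_name"].to_numpy(dtype="U3")
            arr.atom_name = self.atoms["atom_name"].to_numpy(dtype="U4")
            arr.chain_id = self.atoms["chain"].to_numpy(dtype="U1")
            arr.element = np.array([n[0] for n in self.atoms["atom_name"]], dtype="U1")
            arr.set_annotation("b_factor",
                               np.zeros(n_atoms) if b_factors is None
                               else np.asarray(b_factors, dtype=float))
            arrays.append(arr)
        stack = struc.stack(arrays)
        pdb = PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))

    @classmethod
    def from_pdb(cls, path, frame_period_ns: float = 0.2) -> "CoordinateEnsemble":
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, extra_fields=["b_factor"])
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        atoms = pd.DataFrame({
            "residue_index": stack.res_id,
            "residue_name": stack.res_name,
            "atom_name": stack.atom_name,
            "chain": stack.chain_id,
        })
        return cls(np.asarray(stack.coord, dtype=float), atoms, frame_period_ns)


# ---------------------------------------------------------------------------
# superposition

@dataclass
class Superposition:
    rotation: np.ndarray      # (3, 3), applied after centering
    translation: np.ndarray   # (3,)
    rmsd: float
    transformed: np.ndarray   # mobile coordinates after superposition

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None) -> Superposition:
    """Least-squares rigid-body superposition of ``mobile`` onto ``reference``.

    The optimal rotation is the closed-form Kabsch solution computed on
    ``selection`` (boolean mask or index array; all atoms when None); the
    returned transform applies to the full mobile coordinate set, and the
    RMSD (over the selection) is the global minimum over rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise SuperpositionError("mobile and reference selections differ in size")
    sel_m = mobile if selection is None else mobile[selection]
    sel_r = reference if selection is None else reference[selection]
    if sel_m.shape[0] < 3:
        raise SuperpositionError("need at least 3 atoms to superpose")
    cm, cr = sel_m.mean(axis=0), sel_r.mean(axis=0)
    a, b = sel_m - cm, sel_r - cr
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise SuperpositionError("degenerate (collinear or coincident) selection")
    rot, _ = Rotation.align_vectors(b, a)
    R = rot.as_matrix()
    translation = cr - cm @ R.T
    transformed = mobile @ R.T + translation
    sel_t = transformed if selection is None else transformed[selection]
    rmsd = float(np.sqrt(np.mean(np.sum((sel_t - sel_r) ** 2, axis=1))))
    return Superposition(R, translation, rmsd, transformed)


def rmsd_series(ens: CoordinateEnsemble, reference: np.ndarray | None = None,
                selection: np.ndarray | None = None) -> np.ndarray:
    """Per-frame backbone RMSD to a fixed reference after superposition.

    ``reference`` defaults to frame 0; ``selection`` defaults to all
    backbone atoms (N, CA, C, O).
    """
    if selection is None:
        selection = ens.atom_mask(atom_names=BACKBONE_ATOMS)
    if reference is None:
        reference = ens.coords[0]
    return np.array([superpose(frame, reference, selection).rmsd
                     for frame in ens.coords])


# ---------------------------------------------------------------------------
# RMSF

@dataclass
class FlexibilityProfile:
    """Per-residue Calpha RMSF (Angstrom), averaged over simulation repeats."""

    rmsf: dict[int, float]
    per_repeat: list[dict[int, float]] = field(default_factory=list)
    n_repeats: int = 1


def _iterated_average(frames: np.ndarray, fit_sel: np.ndarray,
                      max_iter: int = 10, tol: float = 1e-6,
                      one_pass: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Superpose frames to their average, iterating until the average moves
    by less than ``tol`` Angstrom (mean atom displacement). Returns the
    fitted frames and the converged average."""
    fitted = frames.copy()
    avg = fitted.mean(axis=0)
    for _ in range(1 if one_pass else max_iter):
        fitted = np.stack([superpose(f, avg, fit_sel).transformed for f in fitted])
        new_avg = fitted.mean(axis=0)
        shift = float(np.mean(np.linalg.norm(new_avg - avg, axis=1)))
        avg = new_avg
        if shift < tol:
            break
    return fitted, avg


def rmsf(ens: CoordinateEnsemble, n_repeats: int = 1, fit_selection: str = "CA",
         max_iter: int = 10, tol: float = 1e-6,
         one_pass: bool = False) -> FlexibilityProfile:
    """Per-residue Calpha RMSF with fit-to-average, averaged over repeats.

    The ensemble is partitioned into ``n_repeats`` contiguous blocks
    (independent simulation repeats).  Within each repeat, every snapshot is
    superposed on the average coordinates, the average is recomputed to
    convergence (``max_iter`` iterations, ``tol`` Angstrom displacement
    tolerance), and RMSF_r(residue) = sqrt(mean over frames of the squared
    Calpha distance to the converged average).  The profile is the mean over
    repeats.  ``fit_selection`` is ``CA`` (default) or ``backbone``.
    """
    fit_sel = ens.atom_mask(atom_names=("CA",) if fit_selection == "CA"
                            else BACKBONE_ATOMS)
    ca_mask = ens.atom_mask(atom_names=("CA",))
    ca_res = ens.atoms.loc[ca_mask, "residue_index"].to_numpy(dtype=int)

    per_repeat: list[dict[int, float]] = []
    for block in np.array_split(np.arange(ens.n_frames), n_repeats):
        if block.size < 2:
            logger.warning("repeat with %d frame(s) skipped (need >= 2)", block.size)
            continue
        fitted, avg = _iterated_average(ens.coords[block], fit_sel,
                                        max_iter, tol, one_pass)
        d2 = np.sum((fitted[:, ca_mask, :] - avg[ca_mask]) ** 2, axis=2)
        vals = np.sqrt(d2.mean(axis=0))
        per_repeat.append({int(r): float(v) for r, v in zip(ca_res, vals)})
    if not per_repeat:
        raise ValueError("no repeat had at least 2 frames")
    mean_profile = {int(r): float(np.mean([rep[r] for rep in per_repeat]))
                    for r in ca_res}
    return FlexibilityProfile(mean_profile, per_repeat, len(per_repeat))


# ---------------------------------------------------------------------------
# contact probability

def _contact_atom_mask(ens: CoordinateEnsemble, residues=None, chain=None) -> np.ndarray:
    """Cbeta per residue, Calpha for glycine."""
    is_gly = (ens.atoms["residue_name"] == "GLY").to_numpy()
    name = ens.atoms["atom_name"].to_numpy()
    mask = np.where(is_gly, name == "CA", name == "CB")
    if residues is not None:
        mask &= ens.atoms["residue_index"].isin(residues).to_numpy()
    if chain is not None:
        mask &= (ens.atoms["chain"] == chain).to_numpy()
    return mask


def contact_probability(ens: CoordinateEnsemble, receptor_residues,
                        ligand_chain: str, cutoff: float = 8.0,
                        exclude_initial_ns: float = 200.0,
                        receptor_chain: str | None = None) -> dict[int, float]:
    """Fraction of retained frames with a receptor-ligand Cbeta contact.

    For each receptor residue, the contact atom is its Cbeta (Calpha for
    glycine); the ligand side uses all Cbeta atoms of ``ligand_chain``.  The
    first ``exclude_initial_ns / frame_period_ns`` frames are dropped as
    equilibration.
    """
    n_excl = int(round(exclude_initial_ns / ens.frame_period_ns))
    if n_excl >= ens.n_frames:
        raise ValueError(f"exclusion window ({n_excl} frames) >= trajectory "
                         f"length ({ens.n_frames} frames): nothing to analyze")
    frames = ens.coords[n_excl:]

    lig_mask = (ens.atoms["atom_name"] == "CB").to_numpy() \
        & (ens.atoms["chain"] == ligand_chain).to_numpy()
    if not lig_mask.any():
        raise ValueError(f"ligand chain {ligand_chain!r} has no CB atoms")

    not_ligand = (ens.atoms["chain"] != ligand_chain).to_numpy()
    out: dict[int, float] = {}
    for res in sorted(receptor_residues):
        rec_mask = _contact_atom_mask(ens, residues=[res], chain=receptor_chain)
        rec_mask &= not_ligand
        if not rec_mask.any():
            logger.warning("receptor residue %d has no contact atom; skipped", res)
            continue
        rec = frames[:, rec_mask, :]          # (F, 1, 3)
        lig = frames[:, lig_mask, :]          # (F, M, 3)
        dmin = np.sqrt(((rec - lig) ** 2).sum(axis=2)).min(axis=1)
        out[res] = float(np.mean(dmin < cutoff))
    return out


# ---------------------------------------------------------------------------
# mapping per-residue values onto a structure

def write_mapped_structure(ens: CoordinateEnsemble, values: dict[int, float],
                           path, fill_value: float = 0.0,
                           frame: int = 0) -> dict:
    """Write one frame as a PDB with per-residue values in the B-factor column.

    Values are constant within a residue; residues without a value get
    ``fill_value`` and are listed in the returned report.  The fixed-width
    column holds at most 999.99, so overflowing values are uniformly scaled
    and the scale factor recorded in the report.
    """
    res_idx = ens.atoms["residue_index"].to_numpy(dtype=int)
    b = np.array([values.get(int(r), fill_value) for r in res_idx], dtype=float)
    unmapped = sorted(set(res_idx.tolist()) - set(values))
    scale = 1.0
    vmax = np.abs(b).max() if b.size else 0.0
    if vmax > 999.99:
        scale = 999.99 / vmax
        b = b * scale
        logger.warning("B-factor overflow: values scaled by %.3g", scale)
    if unmapped:
        logger.info("residues without mapped values (fill=%.2f): %s",
                    fill_value, unmapped)
    single = CoordinateEnsemble(ens.coords[frame][None], ens.atoms,
                                ens.frame_period_ns)
    single.to_pdb(path, b_factors=b)
    return {"scale": scale, "unmapped_residues": unmapped, "fill_value": fill_value}


def read_mapped_values(path) -> dict[int, float]:
    """Read back per-residue B-factor values from a mapped PDB file."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1, extra_fields=["b_factor"])
    out: dict[int, float] = {}
    for res in np.unique(arr.res_id):
        out[int(res)] = float(arr.b_factor[arr.res_id == res][0])
    return out
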