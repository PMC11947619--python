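"""Sequence-variant utilities: construct edits, composition, mass.

A construct is a named variant of a base protein defined by an ordered
list of edit operations -- point substitutions, inclusive-range deletions,
and segment replacements -- with 1-based coordinates interpreted on the
current sequence state at the time each edit is applied.  Replacement and
deletion edits accept an optional guard string: the residues expected at
the edited range in the original sequence, protecting against off-by-one
coordinate mistakes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight

AA3 = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
       "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
       "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
       "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR"}
VALID_AA = set(AA3)


class EditError(ValueError):
    """Out-of-range edit coordinates or a guard mismatch."""


def _check_sequence(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - VALID_AA
    if bad:
        raise ValueError(f"invalid residue code(s) {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class Substitute:
    position: int
    new_aa: str

    def apply(self, seq: str) -> str:
        if not 1 <= self.position <= len(seq):
            raise EditError(f"substitution position {self.position} outside "
                            f"sequence of length {len(seq)}")
        return seq[:self.position - 1] + self.new_aa.upper() + seq[self.position:]


@dataclass(frozen=True)
class Delete:
    start: int
    end: int          # inclusive
    guard: str | None = None

    def apply(self, seq: str) -> str:
        if not 1 <= self.start <= self.end <= len(seq):
            raise EditError(f"deletion {self.start}-{self.end} outside "
                            f"sequence of length {len(seq)}")
        segment = seq[self.start - 1:self.end]
        if self.guard is not None and segment != self.guard.upper():
            raise EditError(f"guard mismatch at {self.start}-{self.end}: "
                            f"expected {self.guard!r}, found {segment!r}")
        return seq[:self.start - 1] + seq[self.end:]


@dataclass(frozen=True)
class Replace:
    start: int
    end: int          # inclusive
    new_segment: str
    guard: str | None = None

    def apply(self, seq: str) -> str:
        if not 1 <= self.start <= self.end <= len(seq):
            raise EditError(f"replacement {self.start}-{self.end} outside "
                            f"sequence of length {len(seq)}")
        segment = seq[self.start - 1:self.end]
        if self.guard is not None and segment != self.guard.upper():
            raise EditError(f"guard mismatch at {self.start}-{self.end}: "
                            f"expected {self.guard!r}, found {segment!r}")
        return seq[:self.start - 1] + self.new_segment.upper() + seq[self.end:]


@dataclass
class Construct:
    """A named sequence variant: base sequence plus ordered edits."""

    name: str
    base_sequence: str
    edits: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.base_sequence = _check_sequence(self.base_sequence)


def apply_variant(construct: Construct) -> str:
    """Apply the construct's edits sequentially; positions are interpreted on
    the current sequence state at each edit.  Raises on out-of-range edits,
    guard mismatches, or an empty final sequence."""
    seq = construct.base_sequence
    for edit in construct.edits:
        seq = _check_sequence(edit.apply(seq))
    if not seq:
        raise EditError(f"construct {construct.name!r} yields an empty sequence")
    return seq


def count_non_proline(sequence: str) -> int:
    """Number of non-proline residues (the residues with an observable
    backbone amide in 15N correlation spectra)."""
    seq = _check_sequence(sequence)
    return len(seq) - seq.count("P")


def molecular_mass(sequence: str, n_copies: int = 1) -> float:
    """Average-isotopic molecular mass in kDa.

    Sum of average residue masses plus one water per chain, times
    ``n_copies`` (an n-mer of identical chains).
    """
    seq = _check_sequence(sequence)
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    mono = molecular_weight(seq, seq_type="protein", monoisotopic=False)
    return n_copies * mono / 1000.0
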