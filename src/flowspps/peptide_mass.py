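"""Peptide sequence handling and mass bookkeeping for the ArgTag workflow.

Aggregation-prone peptides are synthesized with six extra C-terminal
arginines (the "ArgTag") that keep the growing chain soluble on resin;
Carboxypeptidase B later removes the whole trailing Arg run, restoring
the native C-terminal acid.  This module computes neutral monoisotopic
and average masses from a residue-mass table, appends/strips the tag,
and verifies detagging from an observed mass difference: a complete
removal of n arginines shifts the neutral mass by exactly
n x 156.10111 Da.

Masses are formula-free: sum of residue masses plus a terminal
adjustment (water for the free acid; amide = acid - 0.984016 Da for
the OH->NH2 substitution).  No protecting groups, PTMs or adducts —
these are post-cleavage, side-chain-free masses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .exceptions import SequenceError

__all__ = [
    "PeptideSequence",
    "MassReport",
    "DetagVerdict",
    "ARG_RESIDUE_MASS",
    "WATER_MONO",
    "parse_sequence",
    "monoisotopic_mass",
    "average_mass",
    "mass_report",
    "append_argtag",
    "strip_argtag",
    "verify_detag",
]

# Monoisotopic residue (amino-acid minus water) masses, Da.
MONO_RESIDUE = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

# Average residue masses, Da.
AVG_RESIDUE = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVG = 18.01528
#: amide C-terminus: OH replaced by NH2 (monoisotopic)
AMIDE_DELTA_MONO = -0.984016
AMIDE_DELTA_AVG = -0.98476

ARG_RESIDUE_MASS = MONO_RESIDUE["R"]

_CANONICAL = frozenset(MONO_RESIDUE)
_TERMINI = ("acid", "amide")


@dataclass(frozen=True)
class PeptideSequence:
    """One-letter peptide sequence (N→C) with terminus chemistry.

    The N-terminus is always free; the C-terminus is either the free
    carboxylic acid or the amide.
    """

    residues: str
    c_terminus: str = "acid"
    label: str = ""

    def __post_init__(self) -> None:
        if self.c_terminus not in _TERMINI:
            raise SequenceError(
                f"c_terminus must be one of {_TERMINI}, got {self.c_terminus!r}"
            )
        if len(self.residues) < 1:
            raise SequenceError("empty sequence")
        bad = [
            (i + 1, c) for i, c in enumerate(self.residues) if c not in _CANONICAL
        ]
        if bad:
            detail = ", ".join(f"{c!r} at position {i}" for i, c in bad)
            raise SequenceError(f"non-canonical residue(s): {detail}")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


@dataclass(frozen=True)
class MassReport:
    label: str
    length: int
    c_terminus: str
    monoisotopic_da: float
    average_da: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "length": self.length,
            "c_terminus": self.c_terminus,
            "monoisotopic_da": round(self.monoisotopic_da, 4),
            "average_da": round(self.average_da, 2),
        }


def parse_sequence(text: str, c_terminus: str = "acid", label: str = "") -> PeptideSequence:
    """Parse a one-letter sequence string, tolerating whitespace and case."""
    cleaned = "".join(text.split()).upper()
    return PeptideSequence(cleaned, c_terminus=c_terminus, label=label)


def monoisotopic_mass(seq: PeptideSequence) -> float:
    """Neutral monoisotopic mass in Da."""
    m = sum(MONO_RESIDUE[r] for r in seq.residues) + WATER_MONO
    if seq.c_terminus == "amide":
        m += AMIDE_DELTA_MONO
    return m


def average_mass(seq: PeptideSequence) -> float:
    """Neutral average mass in Da."""
    m = sum(AVG_RESIDUE[r] for r in seq.residues) + WATER_AVG
    if seq.c_terminus == "amide":
        m += AMIDE_DELTA_AVG
    return m


def mass_report(seq: PeptideSequence) -> MassReport:
    return MassReport(
        label=seq.label,
        length=len(seq),
        c_terminus=seq.c_terminus,
        monoisotopic_da=monoisotopic_mass(seq),
        average_da=average_mass(seq),
    )


def append_argtag(seq: PeptideSequence, n: int = 6) -> PeptideSequence:
    """Append n C-terminal arginines (the ArgTag)."""
    if n < 1:
        raise SequenceError("ArgTag length must be >= 1")
    label = f"{seq.label}-ArgTag" if seq.label else ""
    return replace(seq, residues=seq.residues + "R" * n, label=label)


def strip_argtag(seq: PeptideSequence) -> tuple[PeptideSequence, int]:
    """Remove the maximal trailing Arg run; return (stripped, n_removed).

    The strip is greedy — Carboxypeptidase B removes every C-terminal
    basic residue until it hits a non-Arg, and no partially detagged
    intermediates survive — so the whole run goes, however long.
    """
    n = 0
    while n < len(seq.residues) and seq.residues[-1 - n] == "R":
        n += 1
    if n == 0:
        raise SequenceError("no tag found: sequence has no trailing R")
    if n == len(seq.residues):
        raise SequenceError("cannot strip: sequence is all arginine")
    label = seq.label.removesuffix("-ArgTag") if seq.label else ""
    return replace(seq, residues=seq.residues[:-n], label=label), n


@dataclass(frozen=True)
class DetagVerdict:
    """Outcome of mass-based detag verification."""

    status: str  # complete | partial | none | inconsistent
    n_removed: int | None = None
    delta_da: float = 0.0
    expected_delta_da: float = 0.0

    def __str__(self) -> str:
        if self.status == "partial":
            return f"partial({self.n_removed})"
        return self.status


def verify_detag(
    mass_before: float,
    mass_after: float,
    n_expected: int = 6,
    tol_ppm: float = 20.0,
) -> DetagVerdict:
    """Classify a detagging outcome from masses before/after treatment.

    The observed shift Δ = mass_before − mass_after is matched against
    k x 156.10111 Da within ``tol_ppm`` of ``mass_before``:
    ``complete`` for k = n_expected, ``partial(k)`` for 0 < k < n_expected,
    ``none`` for Δ ≈ 0 and ``inconsistent`` otherwise.  A mass *gain*
    beyond tolerance is an error — no detag chemistry adds mass.
    """
    if mass_before <= 0 or mass_after <= 0:
        raise SequenceError("masses must be positive")
    if n_expected < 1:
        raise SequenceError("n_expected must be >= 1")
    delta = mass_before - mass_after
    tol = tol_ppm * 1e-6 * mass_before
    expected = n_expected * ARG_RESIDUE_MASS
    if delta < -tol:
        raise SequenceError("mass gain — inconsistent with detagging")
    if abs(delta) <= tol:
        return DetagVerdict("none", n_removed=0, delta_da=delta, expected_delta_da=expected)
    for k in range(1, n_expected + 1):
        if abs(delta - k * ARG_RESIDUE_MASS) <= tol:
            status = "complete" if k == n_expected else "partial"
            return DetagVerdict(
                status, n_removed=k, delta_da=delta, expected_delta_da=expected
            )
    return DetagVerdict("inconsistent", n_removed=None, delta_da=delta, expected_delta_da=expected)
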