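"""Sequence-derived thermostability metrics.

Thermophilic proteins tend to accumulate charged residues (Lys, Arg, Glu,
Asp) at the expense of polar ones (Asn, Ser, Gln, Thr); this module
computes those class percentages, the theoretical average molecular mass
(for interpreting light-scattering masses as oligomer stoichiometries), and
the swap-hinge motif check (a Pro inside a short hinge favours domain
swapping by restraining the monomeric closed state).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "CompositionReport",
    "composition",
    "theoretical_mass",
    "stoichiometry",
    "hinge_motif_check",
    "read_fasta",
    "AVERAGE_RESIDUE_MASS",
    "WATER_MASS",
]

CHARGED = set("KRED")
POLAR = set("NSQT")
AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# Average (not monoisotopic) residue masses, Da — standard Expasy table.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01528


@dataclass
class SequenceRecord:
    one_letter: str
    first_number: int = 1  # author number of the first residue (e.g. 20 for a truncated construct)

    def __post_init__(self) -> None:
        self.one_letter = self.one_letter.upper()
        _validate(self.one_letter)
        if not self.one_letter:
            raise ValueError("empty sequence")

    def subsequence(self, start: int, end: int) -> str:
        """Inclusive author-numbered slice."""
        i = start - self.first_number
        j = end - self.first_number + 1
        if i < 0 or j > len(self.one_letter) or start > end:
            raise IndexError(
                f"range {start}-{end} outside sequence numbered "
                f"{self.first_number}-{self.first_number + len(self.one_letter) - 1}"
            )
        return self.one_letter[i:j]


@dataclass
class CompositionReport:
    length: int
    n_charged: int
    n_polar: int
    pct_charged: float  # percent, 1 decimal
    pct_polar: float


def _validate(seq: str) -> None:
    for k, ch in enumerate(seq):
        if ch not in AA20:
            raise ValueError(f"invalid amino-acid character {ch!r} at position {k + 1}")


def composition(seq: str | SequenceRecord) -> CompositionReport:
    """Charged (K,R,E,D) and polar (N,S,Q,T) percentages; His in neither class."""
    s = seq.one_letter if isinstance(seq, SequenceRecord) else seq.upper()
    _validate(s)
    if not s:
        raise ValueError("empty sequence")
    nc = sum(1 for ch in s if ch in CHARGED)
    np_ = sum(1 for ch in s if ch in POLAR)
    return CompositionReport(
        length=len(s),
        n_charged=nc,
        n_polar=np_,
        pct_charged=round(100.0 * nc / len(s), 1),
        pct_polar=round(100.0 * np_ / len(s), 1),
    )


def theoretical_mass(seq: str | SequenceRecord) -> float:
    """Average molecular mass in Da: sum of residue masses plus one water."""
    s = seq.one_letter if isinstance(seq, SequenceRecord) else seq.upper()
    _validate(s)
    if not s:
        raise ValueError("empty sequence")
    return sum(AVERAGE_RESIDUE_MASS[ch] for ch in s) + WATER_MASS


def stoichiometry(measured_mass_kda: float, monomer_mass_da: float,
                  tolerance: float = 0.15) -> tuple[float, int, bool]:
    """Interpret a weight-average molar mass as an oligomer.

    Returns (ratio, nearest integer n, ok) where ``ok`` is False when the
    ratio is further than ``tolerance`` from an integer (ambiguous state).
    """
    if measured_mass_kda <= 0 or monomer_mass_da <= 0:
        raise ValueError("masses must be positive")
    ratio = measured_mass_kda / (monomer_mass_da / 1000.0)
    n = round(ratio)
    return ratio, int(n), abs(ratio - n) <= tolerance


def hinge_motif_check(seq: SequenceRecord, hinge_range: tuple[int, int]) -> dict:
    """Extract the hinge subsequence (author numbering) and report Pro presence."""
    sub = seq.subsequence(*hinge_range)
    return {
        "range": tuple(hinge_range),
        "sequence": sub,
        "contains_proline": "P" in sub,
    }


def read_fasta(path: str | Path, first_number: int = 1) -> SequenceRecord:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceRecord(str(records[0].seq), first_number=first_number)
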