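"""Strands, tube conditions, and FASTA I/O.

A :class:`Strand` is a named single-stranded oligonucleotide, always written
5'→3'.  The polymer type (RNA or DNA) controls the alphabet, which
nearest-neighbor tables apply, and whether G·U wobble pairing is permitted.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = {
    "RNA": {"A": "U", "U": "A", "C": "G", "G": "C"},
    "DNA": {"A": "T", "T": "A", "C": "G", "G": "C"},
}

# Watson-Crick partners across polymers (row base, col base); wobble handled
# separately because it is conformation-, not sequence-, level information.
_WC_CROSS = {
    ("A", "U"), ("U", "A"), ("A", "T"), ("T", "A"),
    ("C", "G"), ("G", "C"), ("U", "T"),  # U:T never pairs; removed below
}
_WC_CROSS.discard(("U", "T"))


class StrandError(ValueError):
    """Invalid strand definition (alphabet, polymer, emptiness)."""


@dataclass(frozen=True)
class Strand:
    """A named RNA or DNA oligonucleotide, 5'→3'."""

    name: str
    polymer: str  # "RNA" | "DNA"
    sequence: str

    def __post_init__(self) -> None:
        if self.polymer not in ("RNA", "DNA"):
            raise StrandError(f"unknown polymer {self.polymer!r}")
        if not self.sequence:
            raise StrandError(f"strand {self.name!r}: empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        alphabet = RNA_ALPHABET if self.polymer == "RNA" else DNA_ALPHABET
        bad = set(seq) - alphabet
        if bad:
            raise StrandError(
                f"strand {self.name!r}: characters {sorted(bad)} not in "
                f"{self.polymer} alphabet"
            )
        if not self.name:
            raise StrandError("strand name must be non-empty")

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self, name: str | None = None,
                           polymer: str | None = None) -> "Strand":
        """Reverse complement, optionally transcribing to the other polymer.

        ``polymer`` selects the output chemistry, e.g. the DNA input that
        binds an RNA arm is ``arm.reverse_complement(polymer="DNA")``.
        """
        polymer = polymer or self.polymer
        table = _COMPLEMENT[polymer]
        src = self.sequence.replace("T", "U") if polymer == "RNA" else \
            self.sequence.replace("U", "T")
        rc = "".join(table[b] for b in reversed(src))
        return Strand(name or f"{self.name}_rc", polymer, rc)


def can_pair(base_i: str, base_j: str, polymer_i: str, polymer_j: str,
             wobble: bool = True) -> bool:
    """Watson-Crick (any chemistry) or G·U wobble (RNA/RNA only) pairing."""
    if (base_i, base_j) in _WC_CROSS:
        return True
    if wobble and polymer_i == "RNA" and polymer_j == "RNA":
        return (base_i, base_j) in (("G", "U"), ("U", "G"))
    return False


@dataclass(frozen=True)
class Conditions:
    """Tube conditions: temperature, salts, and per-strand totals.

    Defaults mirror a TMS-buffer experiment at 22 °C (100 mM Na+, 10 mM
    Mg2+).  ``concentrations`` maps strand name → total concentration in M.
    """

    temperature: float = 22.0  # °C
    monovalent: float = 0.100  # M
    divalent: float = 0.010    # M
    concentrations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.temperature < 100.0):
            raise ValueError("temperature must be in (0, 100) °C")
        if self.monovalent < 0 or self.divalent < 0:
            raise ValueError("salt concentrations must be non-negative")
        for name, c in self.concentrations.items():
            if c <= 0:
                raise ValueError(f"concentration of {name!r} must be positive")

    @property
    def kelvin(self) -> float:
        return self.temperature + 273.15

    @property
    def sodium_equivalent(self) -> float:
        """Monovalent-equivalent salt with divalent folded in (M)."""
        return self.monovalent + 3.3 * self.divalent ** 0.5

    def with_concentrations(self, conc: dict) -> "Conditions":
        return Conditions(self.temperature, self.monovalent, self.divalent,
                          dict(conc))


def _infer_polymer(seq: str, header: str) -> str:
    h = header.lower()
    if "polymer=rna" in h or h.endswith(" rna"):
        return "RNA"
    if "polymer=dna" in h or h.endswith(" dna"):
        return "DNA"
    if "U" in seq.upper():
        return "RNA"
    if "T" in seq.upper():
        return "DNA"
    # Ambiguous (no U and no T): default to RNA, the dominant chemistry here.
    return "RNA"


def read_fasta(handle) -> list[Strand]:
    """Read strands from FASTA.  Polymer comes from a ``polymer=rna|dna``
    header tag when present, else is inferred from the U/T alphabet."""
    if isinstance(handle, str):
        with open(handle) as fh:
            return read_fasta(fh)
    strands = []
    for rec in SeqIO.parse(handle, "fasta"):
        seq = str(rec.seq).upper()
        desc = rec.description
        strands.append(Strand(rec.id, _infer_polymer(seq, desc), seq))
    return strands


def write_fasta(strands: list[Strand], handle) -> None:
    """Write strands as FASTA with an explicit polymer tag in the header."""
    if isinstance(handle, str):
        with open(handle, "w") as fh:
            write_fasta(strands, fh)
            return
    records = [
        SeqRecord(Seq(s.sequence), id=s.name,
                  description=f"polymer={s.polymer.lower()}")
        for s in strands
    ]
    SeqIO.write(records, handle, "fasta")


def fasta_string(strands: list[Strand]) -> str:
    buf = io.StringIO()
    write_fasta(strands, buf)
    return buf.getvalue()
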