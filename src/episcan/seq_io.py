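"""Sequence input/output and degenerate-primer handling.

Protein sequences use the 20 canonical one-letter codes, uppercased on read;
ambiguous codes (B, Z, X, U) are rejected because every downstream propensity
lookup requires a canonical residue.  Coordinates are 1-based inclusive
throughout the package.

Nucleotide primers may contain IUPAC degeneracy codes (R = A/G, M = A/C,
W = A/T, ... N = A/C/G/T); :func:`expand_primer` enumerates the concrete
primer set a degenerate oligo encodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import (
    AlignmentLengthError,
    FastaFormatError,
    IllegalResidueError,
    InvalidIUPACCodeError,
)

#: The 20 canonical amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: IUPAC nucleotide codes mapped to the concrete bases each one stands for.
IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class ProteinSequence:
    """A validated protein sequence with a 1-based coordinate system."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("protein record has an empty identifier")
        if not self.residues:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in _AA_SET:
                raise IllegalResidueError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {i}",
                    record_id=self.id,
                    position=i,
                )

    @property
    def length(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Return the peptide at 1-based inclusive positions ``start..end``."""
        if not (1 <= start <= end <= self.length):
            raise IndexError(f"slice {start}-{end} outside 1..{self.length}")
        return self.residues[start - 1 : end]


@dataclass(frozen=True)
class NucleotideSequence:
    """A nucleotide sequence; IUPAC ambiguity codes are permitted."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("nucleotide record has an empty identifier")
        if not self.bases:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        for i, ch in enumerate(self.bases, start=1):
            if ch not in IUPAC_DNA:
                raise IllegalResidueError(
                    f"record {self.id!r}: illegal base {ch!r} at position {i}",
                    record_id=self.id,
                    position=i,
                )

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class AlignedRecord:
    """One row of a multiple alignment: gapped protein residues ('-' allowed)."""

    id: str
    gapped: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("aligned record has an empty identifier")
        if not self.gapped:
            raise FastaFormatError(f"record {self.id!r} has an empty row")
        for i, ch in enumerate(self.gapped, start=1):
            if ch != "-" and ch not in _AA_SET:
                raise IllegalResidueError(
                    f"record {self.id!r}: illegal character {ch!r} at column {i}",
                    record_id=self.id,
                    position=i,
                )

    @property
    def ungapped(self) -> str:
        return self.gapped.replace("-", "")


def read_fasta(path: str | Path, alphabet: str = "protein"):
    """Read a FASTA file under a declared alphabet.

    Parameters
    ----------
    path:
        FASTA file, single- or multi-record; multi-line bodies accepted.
    alphabet:
        ``"protein"`` (canonical residues only), ``"nucleotide"`` (IUPAC
        codes permitted) or ``"gapped-protein"`` (alignment rows; all
        records must share one length).

    Returns
    -------
    list of :class:`ProteinSequence`, :class:`NucleotideSequence` or
    :class:`AlignedRecord` according to ``alphabet``.
    """
    if alphabet not in ("protein", "nucleotide", "gapped-protein"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).strip().upper()
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if alphabet == "protein":
            records.append(ProteinSequence(id=rec.id, residues=seq))
        elif alphabet == "nucleotide":
            records.append(NucleotideSequence(id=rec.id, bases=seq))
        else:
            records.append(AlignedRecord(id=rec.id, gapped=seq))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    if alphabet == "gapped-protein":
        lengths = {len(r.gapped) for r in records}
        if len(lengths) > 1:
            raise AlignmentLengthError(
                f"{path}: gapped records have unequal lengths {sorted(lengths)}"
            )
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 60) -> None:
    """Write records (any type with ``id`` and a sequence attribute) as FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            seq = getattr(rec, "residues", None) or getattr(rec, "bases", None) \
                or getattr(rec, "gapped", None)
            if seq is None:
                raise TypeError(f"cannot serialize record of type {type(rec)!r}")
            fh.write(f">{rec.id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass(frozen=True)
class DegeneratePrimer:
    """An oligonucleotide over IUPAC codes, encoding ``degeneracy`` concrete primers."""

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise InvalidIUPACCodeError(f"primer {self.id!r} is empty")
        for i, ch in enumerate(self.bases.upper(), start=1):
            if ch not in IUPAC_DNA:
                raise InvalidIUPACCodeError(
                    f"primer {self.id!r}: invalid IUPAC code {ch!r} at position {i}"
                )
        object.__setattr__(self, "bases", self.bases.upper())

    @property
    def degeneracy(self) -> int:
        n = 1
        for ch in self.bases:
            n *= len(IUPAC_DNA[ch])
        return n


def expand_primer(primer: DegeneratePrimer | str) -> list[str]:
    """Enumerate every concrete primer a degenerate oligo encodes.

    Returns the full Cartesian product of per-position base sets,
    lexicographically sorted; its size equals the primer's degeneracy.
    """
    if isinstance(primer, str):
        primer = DegeneratePrimer(id="primer", bases=primer)
    sets = [sorted(IUPAC_DNA[ch]) for ch in primer.bases]
    return ["".join(combo) for combo in product(*sets)]


def iupac_match(primer_char: str, base: str) -> bool:
    """True if a concrete base is among the expansions of an IUPAC code."""
    try:
        return base in IUPAC_DNA[primer_char]
    except KeyError:
        raise InvalidIUPACCodeError(f"invalid IUPAC code {primer_char!r}") from None


def primer_match_positions(primer: DegeneratePrimer | str,
                           target: NucleotideSequence | str) -> list[int]:
    """1-based start positions where the degenerate primer matches the target.

    A match at position p requires every primer position to be IUPAC-compatible
    with the target base; the target itself must be concrete (A/C/G/T).
    """
    if isinstance(primer, str):
        primer = DegeneratePrimer(id="primer", bases=primer)
    bases = target.bases if isinstance(target, NucleotideSequence) else target.upper()
    k = len(primer.bases)
    hits = []
    for p in range(len(bases) - k + 1):
        if all(iupac_match(primer.bases[j], bases[p + j]) for j in range(k)):
            hits.append(p + 1)
    return hits


def read_primer_list(path: str | Path) -> list[DegeneratePrimer]:
    """Read primers from plain text: one per line, optional ``id<TAB>sequence``."""
    primers = []
    for n, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "\t" in line:
            pid, seq = line.split("\t", 1)
        else:
            pid, seq = f"primer{n}", line
        primers.append(DegeneratePrimer(id=pid.strip(), bases=seq.strip()))
    return primers
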