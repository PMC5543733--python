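"""Seeded synthetic proteins and alignments with planted ground truth.

The generators emulate the statistical structure the analysis assumes rather
than any real protein family: background residues are i.i.d. from a declared
frequency table (uniform by default), "epitope-like" planted segments draw
from a hydrophilic/turn-forming vocabulary and "buried-helix" segments from a
hydrophobic/helix-forming one, which separates the hydrophilicity, surface
and structure tracks by construction.  Synthetic alignments mutate copies of
a root sequence i.i.d. per column and can fix distinct residues per sequence
group at declared discordant columns.  Everything is a pure function of
(spec, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .conservation import AlignmentSet
from .errors import SyntheticSpecError
from .seq_io import AMINO_ACIDS, AlignedRecord, ProteinSequence

#: Hydrophilic / turn-forming vocabulary for epitope-like segments.
EPITOPE_RESIDUES = "RKDENQSTGP"
#: Hydrophobic / helix- and sheet-forming vocabulary for buried segments.
BURIED_RESIDUES = "ALIVFMW"

SEGMENT_KINDS = ("epitope-like", "buried-helix")
_KIND_VOCAB = {"epitope-like": EPITOPE_RESIDUES, "buried-helix": BURIED_RESIDUES}


@dataclass(frozen=True)
class PlantedSegment:
    """Ground-truth annotation, 1-based inclusive like every candidate."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise SyntheticSpecError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise SyntheticSpecError(f"invalid segment {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SyntheticSpec:
    """Declarative recipe for one synthetic protein."""

    length: int = 200
    planted_segments: tuple[PlantedSegment, ...] = ()
    background_freqs: tuple[float, ...] | None = None  # over AMINO_ACIDS order
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SyntheticSpecError(f"length must be positive, got {self.length}")
        if self.background_freqs is not None:
            freqs = np.asarray(self.background_freqs, dtype=float)
            if freqs.shape != (20,) or (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
                raise SyntheticSpecError(
                    "background_freqs must be 20 nonnegative values summing to 1.0"
                )
        segs = sorted(self.planted_segments, key=lambda s: s.start)
        for seg in segs:
            if seg.end > self.length:
                raise SyntheticSpecError(
                    f"segment {seg.start}-{seg.end} exceeds length {self.length}"
                )
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise SyntheticSpecError(
                    f"overlapping planted segments {a.start}-{a.end} and {b.start}-{b.end}"
                )


def generate_protein(spec: SyntheticSpec) -> tuple[ProteinSequence, list[PlantedSegment]]:
    """Sample one protein from the spec, returning it with its ground truth."""
    rng = np.random.default_rng(spec.seed)
    freqs = (
        np.full(20, 1 / 20)
        if spec.background_freqs is None
        else np.asarray(spec.background_freqs, dtype=float)
    )
    residues = rng.choice(list(AMINO_ACIDS), size=spec.length, p=freqs)
    for seg in spec.planted_segments:
        vocab = list(_KIND_VOCAB[seg.kind])
        residues[seg.start - 1 : seg.end] = rng.choice(vocab, size=seg.length)
    seq = ProteinSequence(id=f"synthetic_seed{spec.seed}", residues="".join(residues))
    return seq, sorted(spec.planted_segments, key=lambda s: s.start)


def default_protein_spec(
    seed: int,
    length: int = 200,
    epitope_length_range: tuple[int, int] = (15, 25),
    buried_length: int = 15,
    margin: int = 10,
) -> SyntheticSpec:
    """The study conditions used throughout the tests: one epitope-like
    segment of 15-25 residues and one buried-helix segment of 15 residues,
    placed at seeded random non-overlapping interior positions of a 200-mer.
    """
    rng = np.random.default_rng(seed)
    ep_len = int(rng.integers(epitope_length_range[0], epitope_length_range[1] + 1))
    for _ in range(1000):
        ep_start = int(rng.integers(margin + 1, length - margin - ep_len + 1))
        bh_start = int(rng.integers(margin + 1, length - margin - buried_length + 1))
        ep = PlantedSegment("epitope-like", ep_start, ep_start + ep_len - 1)
        bh = PlantedSegment("buried-helix", bh_start, bh_start + buried_length - 1)
        gap = 5  # keep the planted segments from abutting
        if ep.end + gap < bh.start or bh.end + gap < ep.start:
            return SyntheticSpec(
                length=length, planted_segments=(ep, bh), seed=seed
            )
    raise SyntheticSpecError("could not place non-overlapping segments")


def generate_alignment(
    n_seqs: int,
    ncols: int,
    groups: dict[str, str],
    discordant_columns: list[int] | tuple[int, ...] = (),
    mutation_rate: float = 0.0,
    seed: int = 0,
) -> tuple[AlignmentSet, dict]:
    """Star-topology synthetic alignment with declared group-discordant columns.

    A root sequence is sampled uniformly; each row copies it and mutates each
    column independently with probability ``mutation_rate`` (replacement drawn
    uniformly from the 20 residues, so a "mutation" coincides with the root
    with probability 1/20).  At each discordant column, every group is then
    fixed to its own residue, all groups distinct.  Returns the alignment and
    a ground-truth dict (root, discordant columns and their group residues).
    """
    if not (0.0 <= mutation_rate < 1.0):
        raise SyntheticSpecError(f"mutation_rate must be in [0,1), got {mutation_rate}")
    if n_seqs < 2:
        raise SyntheticSpecError(f"need >= 2 sequences, got {n_seqs}")
    ids = list(groups)
    if len(ids) != n_seqs:
        raise SyntheticSpecError(
            f"groups must label exactly n_seqs={n_seqs} ids, got {len(ids)}"
        )
    for col in discordant_columns:
        if not (1 <= col <= ncols):
            raise SyntheticSpecError(f"discordant column {col} outside 1..{ncols}")
    labels = sorted(set(groups.values()))

    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    root = rng.choice(aa, size=ncols)
    rows = {}
    for sid in ids:
        row = root.copy()
        mut = rng.random(ncols) < mutation_rate
        row[mut] = rng.choice(aa, size=int(mut.sum()))
        rows[sid] = row

    fixed: dict[int, dict[str, str]] = {}
    for col in discordant_columns:
        chosen = rng.choice(aa, size=len(labels), replace=False)
        fixed[int(col)] = dict(zip(labels, chosen))
        for sid in ids:
            rows[sid][col - 1] = fixed[int(col)][groups[sid]]

    records = [AlignedRecord(id=sid, gapped="".join(rows[sid])) for sid in ids]
    truth = {
        "root": "".join(root),
        "mutation_rate": mutation_rate,
        "discordant_columns": sorted(int(c) for c in discordant_columns),
        "group_residues": fixed,
    }
    return AlignmentSet(records=records, groups=dict(groups)), truth


def expected_pairwise_identity(mutation_rate: float, n_residues: int = 20) -> float:
    """Closed-form expected identity between two rows of the star alignment.

    Per column, two rows agree when both kept the root ((1-r)^2), when exactly
    one mutated and hit the root residue (2 r (1-r) / n), or when both mutated
    to the same residue (r^2 / n).
    """
    r = mutation_rate
    return (1 - r) ** 2 + 2 * r * (1 - r) / n_residues + r * r / n_residues


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
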