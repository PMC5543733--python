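"""Conservation of an epitope window across a multiple alignment.

Works on pre-aligned gapped multi-FASTA.  Per column, conservation is the
fraction held by the modal residue (gaps excluded from the denominator by
default, or counted as mismatches); a column below the variability threshold
is flagged, and, when sequence groups are declared (e.g. venomous vs
non-venomous species), per-group modal residues identify discordant columns
where the groups fix different residues.

A minimal Needleman-Wunsch pairwise aligner is included only for projecting
an epitope onto a single unaligned homolog; multiple alignment itself is out
of scope and expected from standard tools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GroupLabelError, RegionError
from .seq_io import AlignedRecord, read_fasta

GAP = "-"


@dataclass
class AlignmentSet:
    """A multiple alignment with optional per-record group labels."""

    records: list[AlignedRecord]
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise RegionError("an alignment needs at least 2 records")
        lengths = {len(r.gapped) for r in self.records}
        if len(lengths) > 1:
            raise RegionError(f"alignment rows have unequal lengths {sorted(lengths)}")

    @property
    def ncols(self) -> int:
        return len(self.records[0].gapped)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def column(self, col: int) -> list[str]:
        """Residues (and gaps) in 1-based column ``col``."""
        return [r.gapped[col - 1] for r in self.records]

    @classmethod
    def from_fasta(
        cls, path: str | Path, groups_path: str | Path | None = None
    ) -> "AlignmentSet":
        records = read_fasta(path, alphabet="gapped-protein")
        groups = None
        if groups_path is not None:
            groups = {}
            for line in Path(groups_path).read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sid, _, label = line.partition("\t")
                groups[sid.strip()] = label.strip()
        return cls(records=records, groups=groups)


def _modal_residue(residues: list[str]) -> tuple[str | None, int]:
    """Modal non-gap residue and its count; ties break alphabetically."""
    counts = Counter(r for r in residues if r != GAP)
    if not counts:
        return None, 0
    best = max(counts.values())
    residue = min(r for r, n in counts.items() if n == best)
    return residue, best


def _check_region(region: tuple[int, int], ncols: int) -> tuple[int, int]:
    start, end = region
    if start > end:
        raise RegionError(f"empty region {start}-{end}")
    if not (1 <= start and end <= ncols):
        raise RegionError(f"region {start}-{end} outside alignment columns 1..{ncols}")
    return start, end


@dataclass
class ConservationReport:
    region: tuple[int, int]
    per_column_identity: dict[int, float]
    region_mean_identity: float
    variable_positions: list[dict]
    gap_policy: str
    variable_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": list(self.per_column_identity),
                "identity": list(self.per_column_identity.values()),
                "variable": [
                    col in {v["column"] for v in self.variable_positions}
                    for col in self.per_column_identity
                ],
            }
        )

    def to_dict(self) -> dict:
        return {
            "region": list(self.region),
            "region_mean_identity": self.region_mean_identity,
            "per_column_identity": {str(k): v for k, v in self.per_column_identity.items()},
            "variable_positions": self.variable_positions,
            "gap_policy": self.gap_policy,
            "variable_threshold": self.variable_threshold,
        }


def region_conservation(
    aln: AlignmentSet,
    region: tuple[int, int],
    gap_policy: str = "exclude",
    variable_threshold: float = 1.0,
) -> ConservationReport:
    """Per-column modal-residue identity over a 1-based column interval.

    ``gap_policy="exclude"`` divides the modal count by the number of non-gap
    residues in the column; ``"count-as-mismatch"`` divides by the number of
    records.  A column is variable when its identity falls below
    ``variable_threshold`` (default 1.0: any substitution flags it); for
    variable columns the per-group modal residues are reported when groups
    are declared.
    """
    if gap_policy not in ("exclude", "count-as-mismatch"):
        raise RegionError(f"unknown gap policy {gap_policy!r}")
    start, end = _check_region(region, aln.ncols)
    identities: dict[int, float] = {}
    variable: list[dict] = []
    for col in range(start, end + 1):
        residues = aln.column(col)
        modal, count = _modal_residue(residues)
        denom = (
            sum(1 for r in residues if r != GAP)
            if gap_policy == "exclude"
            else len(residues)
        )
        identity = count / denom if denom else 0.0
        identities[col] = identity
        if identity < variable_threshold:
            entry = {"column": col, "identity": identity, "modal_residue": modal}
            if aln.groups:
                entry["group_modal"] = {
                    g: _modal_residue(
                        [r.gapped[col - 1] for r in aln.records if aln.groups.get(r.id) == g]
                    )[0]
                    for g in sorted(set(aln.groups.values()))
                }
            variable.append(entry)
    return ConservationReport(
        region=(start, end),
        per_column_identity=identities,
        region_mean_identity=float(np.mean(list(identities.values()))),
        variable_positions=variable,
        gap_policy=gap_policy,
        variable_threshold=variable_threshold,
    )


def group_contrast(aln: AlignmentSet, region: tuple[int, int]) -> dict:
    """Per-column group modal residues and the columns where groups disagree.

    Requires every record to carry a group label and at least two distinct
    groups.  A column is discordant when two groups have different modal
    (non-gap) residues; groups with no residues in a column are ignored there.
    """
    if not aln.groups:
        raise GroupLabelError("group contrast requested but no group labels provided")
    missing = [r.id for r in aln.records if r.id not in aln.groups]
    if missing:
        raise GroupLabelError(f"records without group labels: {missing}")
    labels = sorted(set(aln.groups.values()))
    if len(labels) < 2:
        raise GroupLabelError(f"group contrast needs >= 2 groups, got {labels}")
    start, end = _check_region(region, aln.ncols)

    per_column: dict[int, dict[str, str | None]] = {}
    discordant: list[int] = []
    for col in range(start, end + 1):
        modals = {}
        for g in labels:
            rows = [r.gapped[col - 1] for r in aln.records if aln.groups[r.id] == g]
            modals[g] = _modal_residue(rows)[0]
        per_column[col] = modals
        present = [m for m in modals.values() if m is not None]
        if len(set(present)) > 1:
            discordant.append(col)
    return {"region": (start, end), "group_modal": per_column, "discordant_columns": discordant}


def map_epitope_to_alignment(
    seq_id: str, seq_region: tuple[int, int], aln: AlignmentSet
) -> tuple[int, int]:
    """Project 1-based ungapped positions of one record onto alignment columns."""
    rec = next((r for r in aln.records if r.id == seq_id), None)
    if rec is None:
        raise RegionError(f"sequence {seq_id!r} not in alignment")
    start, end = seq_region
    if start > end or start < 1:
        raise RegionError(f"invalid region {start}-{end}")
    positions = [i + 1 for i, ch in enumerate(rec.gapped) if ch != GAP]
    if end > len(positions):
        raise RegionError(
            f"region {start}-{end} exceeds ungapped length {len(positions)} of {seq_id!r}"
        )
    return positions[start - 1], positions[end - 1]


def alignment_column_to_position(
    seq_id: str, column: int, aln: AlignmentSet
) -> int | None:
    """Inverse projection: 1-based ungapped position at a column, None on a gap."""
    rec = next((r for r in aln.records if r.id == seq_id), None)
    if rec is None:
        raise RegionError(f"sequence {seq_id!r} not in alignment")
    if not (1 <= column <= aln.ncols):
        raise RegionError(f"column {column} outside 1..{aln.ncols}")
    if rec.gapped[column - 1] == GAP:
        return None
    return sum(1 for ch in rec.gapped[:column] if ch != GAP)


def needleman_wunsch(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> tuple[str, str]:
    """Global pairwise alignment (utility for projecting an epitope onto one
    unaligned homolog).  Ties prefer diagonal, then up (gap in ``b``)."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = gap * np.arange(n + 1)
    score[0, :] = gap * np.arange(m + 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1, j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            up = score[i - 1, j] + gap
            left = score[i, j - 1] + gap
            score[i, j] = max(diag, up, left)
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            match if a[i - 1] == b[j - 1] else mismatch
        ):
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + gap:
            out_a.append(a[i - 1]); out_b.append(GAP); i -= 1
        else:
            out_a.append(GAP); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))
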