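"""Candidate linear epitope extraction, multi-criterion filtering and ranking.

Candidates are maximal runs of positions whose antigenic index and
hydrophilicity both clear their seed thresholds (nearby runs merged across
small gaps).  Each candidate is then tested, in a fixed order, against the
selection rules a practitioner applies when nominating a peptide for
immunization: it must avoid declared active-site regions, be at least eight
residues long, avoid rigid alpha-helix/beta-sheet structure, and show high
surface probability, hydrophilicity and flexibility.  The first failed rule
names the rejection reason; passed candidates are ranked by a composite
z-score across the criterion means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .antigenic_index import AntigenicIndexTrack
from .errors import CriteriaError
from .profiles import Profile
from .secstruct import SecondaryStructureTrack
from .seq_io import ProteinSequence

#: Fixed order in which the selection rules are tested; the first failure
#: becomes the candidate's rejection reason.
REJECTION_ORDER = (
    "overlaps_forbidden",
    "too_short",
    "rigid_structure",
    "low_surface",
    "low_hydrophilicity",
    "low_flexibility",
)


@dataclass(frozen=True)
class SelectionCriteria:
    """Numeric thresholds behind the qualitative selection rules.

    The minimum length of eight residues is the one hard number the rules
    state; the remaining thresholds quantify "good hydrophilicity, high
    accessibility, high flexibility and strong antigenicity" and are
    configuration with documented defaults.
    """

    min_length: int = 8
    ai_threshold: float = 0.15
    hydrophilicity_min: float = 0.0
    surface_min: float = 1.0
    flexibility_min: float = 1.0
    max_rigid_fraction: float = 0.3
    gap_merge: int = 1
    forbidden_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise CriteriaError(f"min_length must be >= 1, got {self.min_length}")
        if not (0.0 <= self.max_rigid_fraction <= 1.0):
            raise CriteriaError(
                f"max_rigid_fraction must be in [0,1], got {self.max_rigid_fraction}"
            )
        if self.gap_merge < 0:
            raise CriteriaError(f"gap_merge must be >= 0, got {self.gap_merge}")
        for s, e in self.forbidden_regions:
            if not (1 <= s <= e):
                raise CriteriaError(f"invalid forbidden region {s}-{e}")


@dataclass
class EpitopeCandidate:
    """A 1-based inclusive candidate segment with its per-criterion summaries."""

    start: int
    end: int
    peptide: str
    mean_ai: float = float("nan")
    mean_hydrophilicity: float = float("nan")
    mean_surface: float = float("nan")
    mean_flexibility: float = float("nan")
    rigid_fraction: float = float("nan")
    passed: bool = False
    rejection_reason: str = "none"
    rank: int | None = None
    composite_score: float = float("nan")
    criterion_flags: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, start: int, end: int) -> bool:
        return self.start <= end and start <= self.end

    def jaccard(self, start: int, end: int) -> float:
        """Jaccard overlap with another 1-based inclusive interval."""
        inter = max(0, min(self.end, end) - max(self.start, start) + 1)
        union = self.length + (end - start + 1) - inter
        return inter / union

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "peptide": self.peptide,
            "length": self.length,
            "mean_ai": self.mean_ai,
            "mean_hydrophilicity": self.mean_hydrophilicity,
            "mean_surface": self.mean_surface,
            "mean_flexibility": self.mean_flexibility,
            "rigid_fraction": self.rigid_fraction,
            "passed": self.passed,
            "rejection_reason": self.rejection_reason,
            "rank": self.rank,
            "composite_score": self.composite_score,
        }


def extract_segments(
    ai: AntigenicIndexTrack,
    hydro: Profile,
    seq: ProteinSequence,
    criteria: SelectionCriteria,
) -> list[EpitopeCandidate]:
    """Maximal runs where antigenic index and hydrophilicity clear their seeds.

    Positions must be defined in both tracks; runs separated by at most
    ``criteria.gap_merge`` positions are merged.  Candidates come back
    unfiltered, carrying mean AI and mean hydrophilicity.
    """
    if len(ai) != seq.length or len(hydro) != seq.length:
        raise CriteriaError(
            f"track lengths ({len(ai)}, {len(hydro)}) do not match sequence length {seq.length}"
        )
    good = (
        ai.defined
        & hydro.defined
        & (np.nan_to_num(ai.values, nan=-np.inf) >= criteria.ai_threshold)
        & (np.nan_to_num(hydro.values, nan=-np.inf) >= criteria.hydrophilicity_min)
    )
    runs: list[list[int]] = []
    for i in np.flatnonzero(good):
        if runs and i - runs[-1][1] - 1 <= criteria.gap_merge:
            runs[-1][1] = int(i)
        else:
            runs.append([int(i), int(i)])

    out = []
    for s0, e0 in runs:
        start, end = s0 + 1, e0 + 1  # to 1-based inclusive
        out.append(
            EpitopeCandidate(
                start=start,
                end=end,
                peptide=seq.slice(start, end),
                mean_ai=ai.region_mean(start, end),
                mean_hydrophilicity=hydro.region_mean(start, end),
            )
        )
    return out


def filter_candidates(
    candidates: list[EpitopeCandidate],
    structure: SecondaryStructureTrack,
    surface: Profile,
    flex: Profile,
    criteria: SelectionCriteria,
) -> list[EpitopeCandidate]:
    """Apply the selection rules in fixed order; first failure names the reason.

    Order: overlaps_forbidden -> too_short -> rigid_structure -> low_surface
    -> low_hydrophilicity -> low_flexibility.  The full per-criterion boolean
    vector is retained in ``criterion_flags`` alongside the single reason.
    """
    for c in candidates:
        c.mean_surface = surface.region_mean(c.start, c.end)
        c.mean_flexibility = flex.region_mean(c.start, c.end)
        c.rigid_fraction = structure.rigid_fraction(c.start, c.end)
        flags = {
            "overlaps_forbidden": any(
                c.overlaps(s, e) for s, e in criteria.forbidden_regions
            ),
            "too_short": c.length < criteria.min_length,
            "rigid_structure": c.rigid_fraction > criteria.max_rigid_fraction,
            "low_surface": not (c.mean_surface >= criteria.surface_min),
            "low_hydrophilicity": not (
                c.mean_hydrophilicity >= criteria.hydrophilicity_min
            ),
            "low_flexibility": not (c.mean_flexibility >= criteria.flexibility_min),
        }
        c.criterion_flags = flags
        c.rejection_reason = next(
            (reason for reason in REJECTION_ORDER if flags[reason]), "none"
        )
        c.passed = c.rejection_reason == "none"
        if not c.passed:
            c.rank = None
            c.composite_score = float("nan")
    return candidates


#: Criterion means entering the composite ranking score.
RANKING_CRITERIA = ("mean_ai", "mean_hydrophilicity", "mean_surface", "mean_flexibility")


def rank_candidates(
    candidates: list[EpitopeCandidate],
    weights: dict[str, float] | None = None,
) -> list[EpitopeCandidate]:
    """Rank passed candidates by a weighted sum of z-scored criterion means.

    Each criterion mean is standardized across the passed cohort (a zero
    spread contributes 0), weighted (default: equal) and summed.  Sort is by
    descending composite score, ties broken by longer length then smaller
    start.  Returns the passed candidates in rank order with ``rank`` set.
    """
    passed = [c for c in candidates if c.passed]
    if not passed:
        return []
    w = {k: 1.0 for k in RANKING_CRITERIA} if weights is None else dict(weights)
    if set(w) != set(RANKING_CRITERIA):
        raise CriteriaError(f"ranking weights must cover {RANKING_CRITERIA}")
    if any(v < 0 for v in w.values()):
        raise CriteriaError(f"ranking weights must be nonnegative: {w}")

    mat = np.array([[getattr(c, k) for k in RANKING_CRITERIA] for c in passed])
    mu = mat.mean(axis=0)
    sd = mat.std(axis=0)
    z = np.where(sd > 0, (mat - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    wv = np.array([w[k] for k in RANKING_CRITERIA])
    for c, zi in zip(passed, z):
        c.composite_score = float(zi @ wv)
    passed.sort(key=lambda c: (-c.composite_score, -c.length, c.start))
    for r, c in enumerate(passed, start=1):
        c.rank = r
    return passed


def terminal_cys_note(candidate: EpitopeCandidate) -> str:
    """Conjugation annotation: maleimide coupling to a carrier protein needs a
    terminal cysteine thiol.  Never changes pass/fail."""
    if candidate.peptide.startswith("C"):
        return "conjugation-ready (N-terminal Cys)"
    if candidate.peptide.endswith("C"):
        return "conjugation-ready (C-terminal Cys)"
    return "requires added terminal Cys for carrier conjugation"


def candidates_to_frame(candidates: list[EpitopeCandidate]) -> pd.DataFrame:
    frame = pd.DataFrame([c.to_dict() for c in candidates])
    if not frame.empty:
        frame["conjugation_note"] = [terminal_cys_note(c) for c in candidates]
    return frame


def candidates_to_bed(
    candidates: list[EpitopeCandidate], sequence_id: str
) -> pd.DataFrame:
    """BED-like export: 0-based half-open conversion happens here and only here."""
    return pd.DataFrame(
        {
            "chrom": sequence_id,
            "chromStart": [c.start - 1 for c in candidates],
            "chromEnd": [c.end for c in candidates],
            "name": [f"candidate_{c.start}_{c.end}" for c in candidates],
            "score": [0 if np.isnan(c.composite_score) else c.composite_score
                      for c in candidates],
        }
    )
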