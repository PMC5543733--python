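"""Composite antigenic index from five discretized per-residue components.

The index follows the Jameson-Wolf construction: each component track
(hydrophilicity, surface probability, flexibility, and the two
secondary-structure tracks) is first discretized onto a bounded score set,
then combined as a convex weighted sum per position.  Component thresholds,
score levels, state mappings and weights are configuration, not code — the
packaged defaults live in ``data/default_config.yaml``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ThresholdError, TrackLengthError, WeightError
from .profiles import Profile
from .secstruct import SecondaryStructureTrack

#: Canonical component order for the composite index.
COMPONENTS = ("hydrophilicity", "surface", "flexibility", "structure_cf", "structure_gr")

#: Default bounded score levels shared by all components.
DEFAULT_LEVELS = (-0.6, -0.3, -0.1, 0.0, 0.1, 0.3, 0.6)

#: Default weights (sum 1.0): hydrophilicity carries the most weight.
DEFAULT_WEIGHTS = {
    "hydrophilicity": 0.3,
    "surface": 0.15,
    "flexibility": 0.15,
    "structure_cf": 0.2,
    "structure_gr": 0.2,
}

#: Default state scores: turn/coil are epitope-permissive, helix/sheet are not.
DEFAULT_STATE_SCORES = {"T": 0.6, "C": 0.3, "E": -0.3, "H": -0.6}


@dataclass
class DiscretizedTrack:
    """A component track reduced to bounded score levels, with a defined mask."""

    name: str
    scores: np.ndarray
    defined: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.scores.shape != self.defined.shape:
            raise TrackLengthError(f"component {self.name!r}: scores/mask length mismatch")


def discretize_profile(
    profile: Profile,
    thresholds: tuple[float, ...],
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    name: str | None = None,
) -> DiscretizedTrack:
    """Bin a numeric profile onto score levels.

    ``thresholds`` must be strictly increasing with exactly one more level
    than thresholds; a value lands in bin k when ``thresholds[k-1] < value
    <= thresholds[k]`` (values equal to a threshold stay in the lower bin).
    Undefined positions keep score 0 but remain masked.
    """
    t = np.asarray(thresholds, dtype=float)
    lv = np.asarray(levels, dtype=float)
    if len(lv) != len(t) + 1:
        raise ThresholdError(
            f"need exactly one more score level than thresholds: {len(lv)} levels, {len(t)} thresholds"
        )
    if len(t) and not (np.diff(t) > 0).all():
        raise ThresholdError(f"thresholds must be strictly increasing: {thresholds}")
    scores = np.zeros(len(profile))
    vals = profile.values[profile.defined]
    bins = np.searchsorted(t, vals, side="left")
    scores[profile.defined] = lv[bins]
    return DiscretizedTrack(name or profile.method, scores, profile.defined.copy())


def discretize_structure(
    track: SecondaryStructureTrack,
    state_scores: dict[str, float] | None = None,
    name: str | None = None,
) -> DiscretizedTrack:
    """Map a secondary-structure track directly to component scores."""
    mapping = dict(DEFAULT_STATE_SCORES if state_scores is None else state_scores)
    missing = set(track.states) - set(mapping)
    if missing:
        raise ThresholdError(f"no score for structure states {sorted(missing)}")
    scores = np.array([mapping[s] for s in track.states], dtype=float)
    return DiscretizedTrack(
        name or f"structure_{track.method}", scores, np.ones(len(track), dtype=bool)
    )


@dataclass
class AntigenicIndexTrack:
    """Weighted composite of the five discretized components."""

    sequence_id: str
    values: np.ndarray
    defined: np.ndarray
    components: dict[str, DiscretizedTrack]
    weights: dict[str, float]

    def __len__(self) -> int:
        return len(self.values)

    def region_mean(self, start: int, end: int) -> float:
        sel = self.defined[start - 1 : end]
        vals = self.values[start - 1 : end][sel]
        return float(vals.mean()) if vals.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "sequence_id": self.sequence_id,
                "position": np.arange(1, len(self.values) + 1),
                "antigenic_index": self.values,
                "defined": self.defined,
            }
        )
        for name in COMPONENTS:
            frame[name] = self.components[name].scores
        return frame


def antigenic_index(
    sequence_id: str,
    components: dict[str, DiscretizedTrack],
    weights: dict[str, float] | None = None,
) -> AntigenicIndexTrack:
    """Convex weighted sum of the five components per position.

    Weights must be nonnegative and sum to 1.0 (tolerance 1e-9); the result
    is masked wherever any component is masked, and is therefore bounded by
    the component score range at every defined position.
    """
    w = dict(DEFAULT_WEIGHTS if weights is None else weights)
    if set(w) != set(COMPONENTS):
        raise WeightError(f"weights must cover exactly {COMPONENTS}, got {sorted(w)}")
    wv = np.array([w[c] for c in COMPONENTS])
    if (wv < 0).any():
        raise WeightError(f"weights must be nonnegative: {w}")
    if abs(wv.sum() - 1.0) > 1e-9:
        raise WeightError(f"weights must sum to 1.0, got {wv.sum()!r}")
    if set(components) != set(COMPONENTS):
        raise TrackLengthError(
            f"components must be exactly {COMPONENTS}, got {sorted(components)}"
        )
    lengths = {len(c.scores) for c in components.values()}
    if len(lengths) != 1:
        raise TrackLengthError(f"component tracks differ in length: {sorted(lengths)}")

    score_matrix = np.stack([components[c].scores for c in COMPONENTS])
    defined = np.logical_and.reduce([components[c].defined for c in COMPONENTS])
    values = wv @ score_matrix
    values[~defined] = np.nan
    return AntigenicIndexTrack(sequence_id, values, defined, dict(components), w)
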