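"""Sliding-window per-residue profiles: hydrophilicity, surface probability,
chain flexibility.

A profile assigns one real value per residue position.  For an odd window
``w`` the window statistic is anchored at the center residue; positions where
the full window does not fit are masked out by default (``edge_policy =
"mask"``) or computed over the clipped window (``"shrink"``, for display
parity with full-length plots).  The Emini surface statistic uses an even
hexapeptide window anchored, by convention, at the window's first residue
(``anchor="first"``; ``"center-left"`` selects position 3 of 6 instead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ScaleError, SequenceTooShortError, WindowError
from .scales import ResidueScale
from .seq_io import ProteinSequence

#: Emini normalization constant: expected surface fraction of a random residue.
EMINI_RANDOM_FRACTION = 0.37

#: Default center-peaked weights for the 7-residue flexibility window.
FLEX_WINDOW_WEIGHTS_7 = (0.25, 0.4375, 0.625, 1.0, 0.625, 0.4375, 0.25)


@dataclass
class Profile:
    """A per-residue numeric track from a named windowed scale."""

    sequence_id: str
    method: str
    window: int
    values: np.ndarray
    defined: np.ndarray  # bool, same length; False where the window did not fit

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.values.shape != self.defined.shape:
            raise WindowError("profile values and defined mask differ in length")

    def __len__(self) -> int:
        return len(self.values)

    def region_mean(self, start: int, end: int) -> float:
        """Mean over defined positions in 1-based inclusive ``start..end``."""
        sel = self.defined[start - 1 : end]
        vals = self.values[start - 1 : end][sel]
        return float(vals.mean()) if vals.size else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence_id": self.sequence_id,
                "position": np.arange(1, len(self.values) + 1),
                "method": self.method,
                "value": self.values,
                "defined": self.defined,
            }
        )


def _residue_values(seq: ProteinSequence, scale: ResidueScale) -> np.ndarray:
    return np.array([scale.values[r] for r in seq.residues], dtype=float)


def windowed_profile(
    seq: ProteinSequence,
    scale: ResidueScale,
    window: int,
    edge_policy: str = "mask",
) -> Profile:
    """Arithmetic-mean sliding-window profile, anchored at the window center.

    ``window`` must be odd and no longer than the sequence; ``window=1``
    returns the raw per-residue scale values.
    """
    if window < 1:
        raise WindowError(f"window must be >= 1, got {window}")
    if window % 2 == 0:
        raise WindowError(f"window must be odd for center anchoring, got {window}")
    L = seq.length
    if window > L:
        raise WindowError(f"window {window} exceeds sequence length {L}")
    if edge_policy not in ("mask", "shrink"):
        raise WindowError(f"unknown edge policy {edge_policy!r}")

    raw = _residue_values(seq, scale)
    half = window // 2
    values = np.full(L, np.nan)
    defined = np.zeros(L, dtype=bool)
    csum = np.concatenate([[0.0], np.cumsum(raw)])
    for i in range(L):
        lo = max(0, i - half)
        hi = min(L, i + half + 1)
        full = (i - half >= 0) and (i + half < L)
        if full or edge_policy == "shrink":
            values[i] = (csum[hi] - csum[lo]) / (hi - lo)
            defined[i] = True
    if edge_policy == "mask":
        defined[:] = False
        defined[half : L - half] = True
        values[~defined] = np.nan
    return Profile(seq.id, scale.name, window, values, defined)


def surface_probability_profile(
    seq: ProteinSequence,
    scale: ResidueScale,
    anchor: str = "first",
) -> Profile:
    """Emini-style hexapeptide surface probability.

    Each full window of six residues scores ``prod(f_i) / 0.37**6`` where
    ``f_i`` is the residue's fractional surface probability; values above 1
    indicate above-random surface exposure.  The window value is assigned to
    the window's first residue (``anchor="first"``) or to its third
    (``anchor="center-left"``).
    """
    if scale.combine_mode != "product-ratio":
        raise ScaleError(
            f"surface probability requires a product-ratio scale, got "
            f"{scale.combine_mode!r} ({scale.name!r})"
        )
    if anchor not in ("first", "center-left"):
        raise WindowError(f"unknown anchor {anchor!r}")
    L = seq.length
    W = 6
    if L < W:
        raise SequenceTooShortError(
            f"sequence {seq.id!r} length {L} is shorter than the hexapeptide window"
        )
    raw = _residue_values(seq, scale)
    offset = 0 if anchor == "first" else 2
    values = np.full(L, np.nan)
    defined = np.zeros(L, dtype=bool)
    denom = EMINI_RANDOM_FRACTION ** W
    windows = np.lib.stride_tricks.sliding_window_view(raw, W)
    prods = windows.prod(axis=1) / denom
    idx = np.arange(L - W + 1) + offset
    values[idx] = prods
    defined[idx] = True
    return Profile(seq.id, scale.name, W, values, defined)


def flexibility_profile(
    seq: ProteinSequence,
    scale: ResidueScale,
    window: int = 7,
    weights: tuple[float, ...] | None = None,
) -> Profile:
    """Weighted-window chain-flexibility profile.

    The window mean is weighted by a symmetric, center-peaked vector
    (renormalized to sum 1).  Defaults: window 7 with weights
    ``(0.25, 0.4375, 0.625, 1.0, 0.625, 0.4375, 0.25)``.
    """
    if window < 1 or window % 2 == 0:
        raise WindowError(f"flexibility window must be odd and positive, got {window}")
    L = seq.length
    if window > L:
        raise WindowError(f"window {window} exceeds sequence length {L}")
    if weights is None:
        if window == 7:
            weights = FLEX_WINDOW_WEIGHTS_7
        else:
            # triangular center-peaked fallback for non-default windows
            half = window // 2
            weights = tuple(1.0 - abs(i - half) / (half + 1) for i in range(window))
    w = np.asarray(weights, dtype=float)
    if w.shape != (window,):
        raise WindowError(f"expected {window} weights, got {len(w)}")
    if (w < 0).any() or w.sum() <= 0:
        raise WindowError("flexibility weights must be nonnegative with positive sum")
    w = w / w.sum()

    raw = _residue_values(seq, scale)
    half = window // 2
    values = np.full(L, np.nan)
    defined = np.zeros(L, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(raw, window)
    values[half : L - half] = windows @ w
    defined[half : L - half] = True
    return Profile(seq.id, scale.name, window, values, defined)


def profiles_to_tsv(profiles: list[Profile], path) -> None:
    """Export profiles as TSV: sequence_id, position (1-based), method, value, defined."""
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
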