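"""Secondary-structure assignment by two classical propensity methods.

Chou-Fasman: nucleation/extension on conformational propensities P_alpha,
P_beta, plus the tetrapeptide bend product p_t(i) = f(i)·f(i+1)·f(i+2)·f(i+3)
for beta-turns.  Garnier-Robson (GOR-style): per-residue state scores summed
from directional information contributed by neighbors at offsets -8..+8,
minus a per-state decision constant, argmax assigned.

States: H (alpha-helix), E (beta-sheet), T (beta-turn), C (random coil).
Ties and method disagreements resolve toward the "softer" state in the fixed
order T > C > E > H, so a position is only called rigid when the evidence is
unambiguous — the downstream epitope filter consumes the rigid (H+E) fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParamTableError, SequenceTooShortError, TrackLengthError
from .scales import data_path
from .seq_io import AMINO_ACIDS, ProteinSequence

STATES = ("H", "E", "T", "C")
#: Softness / tie-break preference: turn first, helix last.
SOFT_ORDER = ("T", "C", "E", "H")
_SOFT_RANK = {s: i for i, s in enumerate(SOFT_ORDER)}

# Classical Chou-Fasman decision constants (kept in one place, overridable).
HELIX_FORMER_CUTOFF = 1.03
STRAND_FORMER_CUTOFF = 1.05
TURN_PRODUCT_CUTOFF = 7.5e-5


@dataclass
class SecondaryStructureTrack:
    sequence_id: str
    method: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set(STATES)
        if bad:
            raise ParamTableError(f"invalid structure states {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)

    def rigid_fraction(self, start: int, end: int) -> float:
        """Fraction of H+E states in 1-based inclusive ``start..end``."""
        seg = self.states[start - 1 : end]
        return sum(1 for s in seg if s in "HE") / len(seg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sequence_id": self.sequence_id,
                "position": np.arange(1, len(self.states) + 1),
                "method": self.method,
                "state": list(self.states),
            }
        )


@dataclass
class TurnPropensityTrack:
    """Tetrapeptide bend products, defined for start positions 1..L-3."""

    sequence_id: str
    p_turn: np.ndarray


@dataclass(frozen=True)
class ChouFasmanParams:
    p_alpha: dict[str, float]
    p_beta: dict[str, float]
    p_turn: dict[str, float]
    bend_freqs: dict[str, tuple[float, float, float, float]]


def load_chou_fasman_params(path: str | Path | None = None) -> ChouFasmanParams:
    path = Path(path) if path else data_path("chou_fasman.tsv")
    pa, pb, pt, f = {}, {}, {}, {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 8:
            raise ParamTableError(f"{path}: expected 8 columns, got {line!r}")
        r = parts[0].upper()
        pa[r], pb[r], pt[r] = map(float, parts[1:4])
        f[r] = tuple(map(float, parts[4:8]))
    missing = sorted(set(AMINO_ACIDS) - set(pa))
    if missing:
        raise ParamTableError(f"{path}: missing residues {missing}")
    return ChouFasmanParams(pa, pb, pt, f)


def _runs(mask: np.ndarray):
    """Maximal runs of True, as 0-based inclusive (start, end) pairs."""
    runs = []
    i = 0
    L = len(mask)
    while i < L:
        if mask[i]:
            j = i
            while j + 1 < L and mask[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def turn_propensity(seq: ProteinSequence, params: ChouFasmanParams) -> TurnPropensityTrack:
    L = seq.length
    if L < 4:
        raise SequenceTooShortError(f"turn product needs >= 4 residues, got {L}")
    f = params.bend_freqs
    p = np.array(
        [
            f[seq.residues[i]][0]
            * f[seq.residues[i + 1]][1]
            * f[seq.residues[i + 2]][2]
            * f[seq.residues[i + 3]][3]
            for i in range(L - 3)
        ]
    )
    return TurnPropensityTrack(seq.id, p)


def chou_fasman(
    seq: ProteinSequence,
    params: ChouFasmanParams | None = None,
    helix_cutoff: float = HELIX_FORMER_CUTOFF,
    strand_cutoff: float = STRAND_FORMER_CUTOFF,
    turn_cutoff: float = TURN_PRODUCT_CUTOFF,
) -> SecondaryStructureTrack:
    """Chou-Fasman nucleation/extension assignment.

    Helix nucleates where >= 4 of 6 consecutive residues exceed the
    helix-former cutoff and extends while the running tetrapeptide mean
    P_alpha stays >= 1.0; strand nucleates where >= 3 of 5 exceed the
    strand cutoff, extending analogously on P_beta.  A turn is called over
    tetrapeptide i..i+3 when the bend product exceeds the turn cutoff, the
    tetrapeptide mean P_turn exceeds 1.0 and exceeds both the mean P_alpha
    and mean P_beta there.  Helix/strand overlaps go to the larger regional
    mean propensity (equal means soften to E); remaining positions are coil.
    """
    if params is None:
        params = load_chou_fasman_params()
    L = seq.length
    if L < 6:
        raise SequenceTooShortError(
            f"Chou-Fasman needs >= 6 residues, got {L} for {seq.id!r}"
        )
    pa = np.array([params.p_alpha[r] for r in seq.residues])
    pb = np.array([params.p_beta[r] for r in seq.residues])
    pt = np.array([params.p_turn[r] for r in seq.residues])

    def nucleate_extend(p: np.ndarray, nuc_win: int, nuc_need: int, cutoff: float):
        mask = np.zeros(L, dtype=bool)
        for i in range(L - nuc_win + 1):
            if (p[i : i + nuc_win] > cutoff).sum() >= nuc_need:
                mask[i : i + nuc_win] = True
        # extend each maximal nucleated run while the running 4-mer mean holds
        out = mask.copy()
        for s, e in _runs(mask):
            j = e
            while j + 1 < L and p[max(0, j - 2) : j + 2].mean() >= 1.0:
                j += 1
                out[j] = True
            j = s
            while j - 1 >= 0 and p[j - 1 : min(L, j + 3)].mean() >= 1.0:
                j -= 1
                out[j] = True
        return out

    helix = nucleate_extend(pa, 6, 4, helix_cutoff)
    strand = nucleate_extend(pb, 5, 3, strand_cutoff)

    states = np.array(list("C" * L))
    both = helix & strand
    only_h = helix & ~strand
    only_e = strand & ~helix
    states[only_h] = "H"
    states[only_e] = "E"
    for s, e in _runs(both):
        ma, mb = pa[s : e + 1].mean(), pb[s : e + 1].mean()
        if ma > mb:
            states[s : e + 1] = "H"
        else:  # mb > ma, or tie -> softer of {E, H} is E
            states[s : e + 1] = "E"

    bend = turn_propensity(seq, params).p_turn
    for i in range(L - 3):
        tet = slice(i, i + 4)
        if (
            bend[i] > turn_cutoff
            and pt[tet].mean() > 1.0
            and pt[tet].mean() > pa[tet].mean()
            and pt[tet].mean() > pb[tet].mean()
        ):
            states[tet] = "T"

    return SecondaryStructureTrack(seq.id, "chou-fasman", "".join(states))


@dataclass(frozen=True)
class GorInfoTables:
    """Directional information: value(state, residue, offset) for offsets -8..+8."""

    table: np.ndarray  # shape (4 states, 20 residues, 17 offsets)
    source: str = ""

    HALF_WINDOW = 8

    def value(self, state: str, residue: str, offset: int) -> float:
        return float(
            self.table[STATES.index(state), AMINO_ACIDS.index(residue), offset + 8]
        )


def load_gor_info(path: str | Path | None = None) -> GorInfoTables:
    path = Path(path) if path else data_path("gor_info_synthetic.tsv")
    table = np.full((4, 20, 17), np.nan)
    source = ""
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "source:" in line:
                source += line.split("source:", 1)[1].strip() + " "
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ParamTableError(f"{path}: expected 'state residue offset value'")
        state, res, off, val = parts
        try:
            table[STATES.index(state), AMINO_ACIDS.index(res), int(off) + 8] = float(val)
        except (ValueError, IndexError):
            raise ParamTableError(f"{path}: bad entry {line!r}") from None
    if np.isnan(table).any():
        raise ParamTableError(f"{path}: incomplete table (missing state/residue/offset entries)")
    return GorInfoTables(table=table, source=source.strip())


def garnier_robson(
    seq: ProteinSequence,
    info: GorInfoTables | None = None,
    decision_constants: dict[str, float] | None = None,
) -> SecondaryStructureTrack:
    """GOR-style assignment: per-state directional-information sums, argmax.

    score(i, s) = sum over offsets d in -8..+8 of the information the residue
    at i+d contributes to state s at distance d, minus the state's decision
    constant.  Ties resolve in the order T, C, E, H.
    """
    if info is None:
        info = load_gor_info()
    dc = {s: 0.0 for s in STATES}
    if decision_constants:
        unknown = set(decision_constants) - set(STATES)
        if unknown:
            raise ParamTableError(f"decision constants for unknown states {sorted(unknown)}")
        dc.update(decision_constants)
    L = seq.length
    res_idx = np.array([AMINO_ACIDS.index(r) for r in seq.residues])
    scores = np.zeros((L, 4))
    H = GorInfoTables.HALF_WINDOW
    for d in range(-H, H + 1):
        lo, hi = max(0, -d), min(L, L - d)
        if lo >= hi:
            continue
        contrib = info.table[:, res_idx[lo + d : hi + d], d + 8]  # (4, span)
        scores[lo:hi] += contrib.T
    scores -= np.array([dc[s] for s in STATES])

    out = []
    soft = sorted(range(4), key=lambda k: _SOFT_RANK[STATES[k]])
    for i in range(L):
        best = scores[i].max()
        for k in soft:
            if scores[i, k] == best:
                out.append(STATES[k])
                break
    return SecondaryStructureTrack(seq.id, "garnier-robson", "".join(out))


def consensus_track(
    cf: SecondaryStructureTrack, gr: SecondaryStructureTrack
) -> SecondaryStructureTrack:
    """Two-method consensus: agreement keeps the state, disagreement takes the
    softer one (T > C > E > H), so rigid calls require both methods."""
    if len(cf) != len(gr):
        raise TrackLengthError(
            f"track lengths differ: {len(cf)} (chou-fasman) vs {len(gr)} (garnier-robson)"
        )
    if cf.sequence_id != gr.sequence_id:
        raise TrackLengthError(
            f"tracks belong to different sequences: {cf.sequence_id!r} vs {gr.sequence_id!r}"
        )
    merged = "".join(
        a if a == b else min(a, b, key=_SOFT_RANK.get) for a, b in zip(cf.states, gr.states)
    )
    return SecondaryStructureTrack(cf.sequence_id, "consensus", merged)
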