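"""Segment extraction, the ordered rejection rules, and candidate ranking."""

import numpy as np
import pytest

from episcan.antigenic_index import AntigenicIndexTrack, DiscretizedTrack
from episcan.epitope_select import (
    EpitopeCandidate,
    SelectionCriteria,
    candidates_to_bed,
    extract_segments,
    filter_candidates,
    rank_candidates,
    terminal_cys_note,
)
from episcan.errors import CriteriaError
from episcan.profiles import Profile
from episcan.secstruct import SecondaryStructureTrack
from episcan.seq_io import ProteinSequence


def make_ai(values, sequence_id="s"):
    values = np.asarray(values, dtype=float)
    comps = {
        name: DiscretizedTrack(name, np.zeros_like(values), ~np.isnan(values))
        for name in ("hydrophilicity", "surface", "flexibility", "structure_cf", "structure_gr")
    }
    return AntigenicIndexTrack(
        sequence_id, values, ~np.isnan(values), comps,
        {"hydrophilicity": 0.3, "surface": 0.15, "flexibility": 0.15,
         "structure_cf": 0.2, "structure_gr": 0.2},
    )


def make_profile(values, method="test"):
    values = np.asarray(values, dtype=float)
    return Profile("s", method, 1, values, ~np.isnan(values))


def make_seq(length):
    return ProteinSequence(id="s", residues="A" * length)


CRIT = SelectionCriteria(ai_threshold=0.5, hydrophilicity_min=0.0)


def brute_force_runs(ai_vals, hydro_vals, thr_ai, thr_h, gap_merge):
    """Independent run-finding oracle: scan, then merge small gaps."""
    good = [
        (a >= thr_ai and h >= thr_h and not (np.isnan(a) or np.isnan(h)))
        for a, h in zip(ai_vals, hydro_vals)
    ]
    runs = []
    for i, g in enumerate(good):
        if g:
            if runs and i - runs[-1][1] - 1 <= gap_merge:
                runs[-1][1] = i
            else:
                runs.append([i, i])
    return [(s + 1, e + 1) for s, e in runs]


class TestExtractSegments:
    def test_constant_high_track_is_one_segment(self):
        ai = make_ai([0.6] * 10)
        hydro = make_profile([2.0] * 10)
        (c,) = extract_segments(ai, hydro, make_seq(10), CRIT)
        assert (c.start, c.end) == (1, 10)
        assert c.peptide == "A" * 10

    def test_isolated_high_position_is_length_one_segment(self):
        vals = [0.0] * 11
        vals[5] = 0.9
        (c,) = extract_segments(make_ai(vals), make_profile([1.0] * 11), make_seq(11), CRIT)
        assert (c.start, c.end, c.length) == (6, 6, 1)

    def test_two_planted_runs_with_valley(self):
        vals = [0.0] * 30
        vals[4:10] = [0.8] * 6
        vals[20:27] = [0.7] * 7
        segs = extract_segments(make_ai(vals), make_profile([1.0] * 30), make_seq(30), CRIT)
        assert [(c.start, c.end) for c in segs] == brute_force_runs(
            vals, [1.0] * 30, 0.5, 0.0, 1
        ) == [(5, 10), (21, 27)]

    def test_gap_merge_joins_nearby_runs(self):
        vals = [0.0] * 20
        vals[3:8] = [0.9] * 5
        vals[9:14] = [0.9] * 5  # single low position at index 8
        (c,) = extract_segments(make_ai(vals), make_profile([1.0] * 20), make_seq(20), CRIT)
        assert (c.start, c.end) == (4, 14)
        no_merge = SelectionCriteria(ai_threshold=0.5, hydrophilicity_min=0.0, gap_merge=0)
        segs = extract_segments(make_ai(vals), make_profile([1.0] * 20), make_seq(20), no_merge)
        assert [(s.start, s.end) for s in segs] == [(4, 8), (10, 14)]

    def test_matches_brute_force_on_random_tracks(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            ai_vals = rng.uniform(-0.6, 0.6, size=80)
            hydro_vals = rng.uniform(-2, 2, size=80)
            segs = extract_segments(
                make_ai(ai_vals), make_profile(hydro_vals), make_seq(80), CRIT
            )
            assert [(c.start, c.end) for c in segs] == brute_force_runs(
                ai_vals, hydro_vals, CRIT.ai_threshold, CRIT.hydrophilicity_min, CRIT.gap_merge
            )

    def test_hydrophilicity_gate_applies(self):
        ai = make_ai([0.9] * 12)
        hydro_vals = [2.0] * 6 + [-2.0] * 6
        (c,) = extract_segments(ai, make_profile(hydro_vals), make_seq(12), CRIT)
        assert (c.start, c.end) == (1, 6)


def run_filter(candidates, states, surface_vals, flex_vals, criteria):
    structure = SecondaryStructureTrack("s", "consensus", states)
    return filter_candidates(
        candidates, structure, make_profile(surface_vals, "surface"),
        make_profile(flex_vals, "flex"), criteria,
    )


class TestFilterReasons:
    """The three narrative failure modes: too short, buried, rigid helix."""

    def test_six_residue_candidate_is_too_short(self):
        c = EpitopeCandidate(start=3, end=8, peptide="AAAAAA",
                             mean_hydrophilicity=2.0, mean_ai=0.5)
        run_filter([c], "C" * 10, [5.0] * 10, [1.1] * 10, SelectionCriteria())
        assert not c.passed and c.rejection_reason == "too_short"

    def test_buried_candidate_fails_on_low_surface(self):
        # good hydrophilicity, flexibility and AI, but mean surface below the
        # minimum: the segment would be hidden inside the folded protein
        c = EpitopeCandidate(start=1, end=10, peptide="A" * 10,
                             mean_hydrophilicity=2.0, mean_ai=0.5)
        run_filter([c], "C" * 10, [0.2] * 10, [1.1] * 10, SelectionCriteria())
        assert not c.passed and c.rejection_reason == "low_surface"

    def test_helix_candidate_fails_on_rigid_structure(self):
        c = EpitopeCandidate(start=1, end=10, peptide="A" * 10,
                             mean_hydrophilicity=2.0, mean_ai=0.5)
        run_filter([c], "H" * 10, [5.0] * 10, [1.1] * 10, SelectionCriteria())
        assert not c.passed and c.rejection_reason == "rigid_structure"

    def test_passing_candidate_has_reason_none(self):
        c = EpitopeCandidate(start=1, end=10, peptide="A" * 10,
                             mean_hydrophilicity=2.0, mean_ai=0.5)
        run_filter([c], "T" * 5 + "C" * 5, [5.0] * 10, [1.1] * 10, SelectionCriteria())
        assert c.passed and c.rejection_reason == "none"
        assert not any(c.criterion_flags.values())

    def test_first_failure_in_fixed_order_names_the_reason(self):
        # short AND rigid AND buried: too_short precedes the others,
        # forbidden-region overlap precedes everything
        c = EpitopeCandidate(start=1, end=6, peptide="A" * 6,
                             mean_hydrophilicity=2.0, mean_ai=0.5)
        run_filter([c], "H" * 10, [0.2] * 10, [0.9] * 10, SelectionCriteria())
        assert c.rejection_reason == "too_short"
        assert c.criterion_flags["rigid_structure"] and c.criterion_flags["low_surface"]

        c2 = EpitopeCandidate(start=1, end=6, peptide="A" * 6,
                              mean_hydrophilicity=2.0, mean_ai=0.5)
        run_filter([c2], "H" * 10, [0.2] * 10, [0.9] * 10,
                   SelectionCriteria(forbidden_regions=((5, 9),)))
        assert c2.rejection_reason == "overlaps_forbidden"

    def test_forbidden_region_only_rejects_overlaps(self):
        crit = SelectionCriteria(forbidden_regions=((87, 96),))
        inside = EpitopeCandidate(start=90, end=99, peptide="A" * 10,
                                  mean_hydrophilicity=2.0, mean_ai=0.5)
        outside = EpitopeCandidate(start=100, end=110, peptide="A" * 11,
                                   mean_hydrophilicity=2.0, mean_ai=0.5)
        run_filter([inside, outside], "C" * 120, [5.0] * 120, [1.1] * 120, crit)
        assert inside.rejection_reason == "overlaps_forbidden"
        assert outside.passed

    def test_filter_is_deterministic(self):
        rng = np.random.default_rng(5)
        cands = [
            EpitopeCandidate(start=s, end=s + 9, peptide="A" * 10,
                             mean_hydrophilicity=float(rng.normal()), mean_ai=0.5)
            for s in range(1, 50, 10)
        ]
        states = "".join(rng.choice(list("HETC"), size=60))
        surface = rng.uniform(0, 5, size=60)
        flex = rng.uniform(0.9, 1.1, size=60)

        def snapshot():
            import copy
            cs = copy.deepcopy(cands)
            run_filter(cs, states, surface, flex, SelectionCriteria())
            rank_candidates(cs)
            return [(c.rejection_reason, c.rank, repr(c.composite_score)) for c in cs]

        assert snapshot() == snapshot()


class TestRanking:
    def _passed(self, **kw):
        c = EpitopeCandidate(
            start=kw.pop("start", 1), end=kw.pop("end", 10), peptide="A" * 10,
            mean_ai=kw.pop("mean_ai", 0.3),
            mean_hydrophilicity=kw.pop("mean_hydrophilicity", 1.0),
            mean_surface=kw.pop("mean_surface", 2.0),
            mean_flexibility=kw.pop("mean_flexibility", 1.05),
        )
        c.passed, c.rejection_reason = True, "none"
        return c

    def test_single_candidate_gets_rank_one(self):
        (c,) = rank_candidates([self._passed()])
        assert c.rank == 1 and c.composite_score == 0.0

    def test_dominating_candidate_is_rank_one(self):
        rng = np.random.default_rng(6)
        cohort = [
            self._passed(start=10 * i + 1, end=10 * i + 10,
                         mean_ai=float(rng.uniform(0.1, 0.3)),
                         mean_hydrophilicity=float(rng.uniform(0, 1)),
                         mean_surface=float(rng.uniform(1, 3)),
                         mean_flexibility=float(rng.uniform(1.0, 1.05)))
            for i in range(5)
        ]
        dominant = self._passed(start=100, end=109, mean_ai=0.6,
                                mean_hydrophilicity=2.5, mean_surface=9.0,
                                mean_flexibility=1.15)
        ranked = rank_candidates(cohort + [dominant])
        assert ranked[0] is dominant and dominant.rank == 1

    def test_ties_break_by_length_then_start(self):
        a = self._passed(start=20, end=29)
        b = self._passed(start=5, end=16)   # longer
        c = self._passed(start=2, end=11)   # same length as a, earlier start
        ranked = rank_candidates([a, b, c])
        assert [x.start for x in ranked] == [5, 2, 20]

    def test_empty_input_returns_empty(self):
        assert rank_candidates([]) == []

    def test_failed_candidates_are_never_ranked(self):
        good, bad = self._passed(), self._passed(start=30, end=39)
        bad.passed, bad.rejection_reason = False, "too_short"
        ranked = rank_candidates([good, bad])
        assert ranked == [good] and bad.rank is None


class TestAnnotationsAndExports:
    @pytest.mark.parametrize(
        "peptide,expected",
        [
            ("CPVLRLSNRTHEANRNDLIKVA", "conjugation-ready (N-terminal Cys)"),
            ("PVLC", "conjugation-ready (C-terminal Cys)"),
            ("PVLR", "requires added terminal Cys for carrier conjugation"),
        ],
    )
    def test_terminal_cys_note(self, peptide, expected):
        c = EpitopeCandidate(start=1, end=len(peptide), peptide=peptide)
        assert terminal_cys_note(c) == expected

    def test_bed_export_converts_to_zero_based_half_open(self):
        c = EpitopeCandidate(start=151, end=172, peptide="A" * 22)
        bed = candidates_to_bed([c], "seq1")
        assert (bed.loc[0, "chromStart"], bed.loc[0, "chromEnd"]) == (150, 172)

    def test_invalid_criteria_rejected(self):
        with pytest.raises(CriteriaError):
            SelectionCriteria(min_length=0)
        with pytest.raises(CriteriaError):
            SelectionCriteria(max_rigid_fraction=1.5)
        with pytest.raises(CriteriaError):
            SelectionCriteria(forbidden_regions=((10, 5),))
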