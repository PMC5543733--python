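"""Sliding-window profiles against brute-force oracles and their invariants."""

import numpy as np
import pytest

from episcan.errors import ScaleError, SequenceTooShortError, WindowError
from episcan.profiles import (
    EMINI_RANDOM_FRACTION,
    FLEX_WINDOW_WEIGHTS_7,
    flexibility_profile,
    surface_probability_profile,
    windowed_profile,
)
from episcan.scales import ResidueScale, builtin_scale, parse_scale, verify_data_checksums
from episcan.seq_io import AMINO_ACIDS, ProteinSequence

from conftest import random_protein


def brute_window_mean(raw, window):
    """Independent double-loop oracle for the center-anchored window mean."""
    L, half = len(raw), window // 2
    out = np.full(L, np.nan)
    for i in range(half, L - half):
        total = 0.0
        for j in range(i - half, i + half + 1):
            total += raw[j]
        out[i] = total / window
    return out


class TestScales:
    def test_builtin_scales_are_total_over_20_residues(self):
        for name in ("hopp-woods", "kyte-doolittle", "emini-surface", "flexibility"):
            scale = builtin_scale(name)
            assert set(scale.values) == set(AMINO_ACIDS)
            assert scale.source  # citation header survived parsing

    def test_parameter_files_match_pinned_checksums(self):
        assert all(verify_data_checksums(strict=False).values())

    def test_incomplete_scale_rejected(self):
        with pytest.raises(ScaleError):
            ResidueScale(name="partial", values={"A": 1.0})

    def test_negated_scale_flips_sign(self):
        kd = builtin_scale("kyte-doolittle")
        inv = kd.negated()
        assert inv.values["I"] == -kd.values["I"] < 0

    def test_scale_parse_rejects_garbage(self):
        with pytest.raises(ScaleError):
            parse_scale("# name: x\nA 1.0 extra\n")


class TestWindowedProfile:
    def test_window_one_is_identity(self, hopp_woods):
        seq = ProteinSequence(id="s", residues="ARNDC")
        prof = windowed_profile(seq, hopp_woods, 1)
        assert prof.defined.all()
        np.testing.assert_allclose(
            prof.values, [hopp_woods[r] for r in seq.residues]
        )

    def test_glycine_homopolymer_center_is_zero(self, hopp_woods):
        prof = windowed_profile(ProteinSequence(id="g", residues="G" * 7), hopp_woods, 7)
        assert prof.values[3] == 0.0
        assert prof.defined.sum() == 1

    def test_charged_heptapeptide_matches_hand_mean(self, hopp_woods):
        seq = ProteinSequence(id="c", residues="RRRKKKD")
        prof = windowed_profile(seq, hopp_woods, 7)
        expected = sum(hopp_woods[r] for r in seq.residues) / 7
        assert prof.values[3] == pytest.approx(expected)

    @pytest.mark.parametrize("length,window", [(50, 7), (213, 9), (500, 7)])
    def test_matches_brute_force_on_random_sequences(self, hopp_woods, length, window):
        rng = np.random.default_rng(length * window)
        seq = random_protein(rng, length)
        prof = windowed_profile(seq, hopp_woods, window)
        raw = [hopp_woods[r] for r in seq.residues]
        oracle = brute_window_mean(raw, window)
        np.testing.assert_allclose(
            prof.values[prof.defined], oracle[~np.isnan(oracle)], atol=1e-9
        )

    def test_monotone_in_any_window_residue(self, hopp_woods):
        rng = np.random.default_rng(7)
        seq = random_protein(rng, 40)
        prof = windowed_profile(seq, hopp_woods, 7)
        ordered = sorted(AMINO_ACIDS, key=lambda r: hopp_woods[r])
        for _ in range(25):
            i = int(rng.integers(0, 40))
            cur = seq.residues[i]
            higher = [r for r in ordered if hopp_woods[r] > hopp_woods[cur]]
            if not higher:
                continue
            mutated = ProteinSequence(
                id="m", residues=seq.residues[:i] + higher[-1] + seq.residues[i + 1 :]
            )
            prof2 = windowed_profile(mutated, hopp_woods, 7)
            affected = prof.defined & (np.abs(np.arange(40) - i) <= 3)
            assert (prof2.values[affected] > prof.values[affected]).all()

    def test_translation_equivariance(self, hopp_woods):
        rng = np.random.default_rng(11)
        seq = random_protein(rng, 30)
        prefix = "GGGGG"
        shifted = ProteinSequence(id="s2", residues=prefix + seq.residues)
        p1 = windowed_profile(seq, hopp_woods, 7)
        p2 = windowed_profile(shifted, hopp_woods, 7)
        k = len(prefix)
        np.testing.assert_allclose(
            p2.values[k + 3 : k + 30 - 3], p1.values[3:-3], atol=1e-12
        )

    def test_shrink_policy_defines_all_positions(self, hopp_woods):
        seq = ProteinSequence(id="s", residues="ARNDCEQGHI")
        prof = windowed_profile(seq, hopp_woods, 7, edge_policy="shrink")
        assert prof.defined.all()
        assert prof.values[0] == pytest.approx(
            np.mean([hopp_woods[r] for r in seq.residues[:4]])
        )

    @pytest.mark.parametrize("window", [0, 4, 11])
    def test_bad_windows_are_named_failures(self, hopp_woods, window):
        with pytest.raises(WindowError):
            windowed_profile(ProteinSequence(id="s", residues="ARNDCEQGHI"), hopp_woods, window)


class TestSurfaceProbability:
    def test_hexapeptide_at_random_fraction_scores_one(self):
        scale = ResidueScale(
            name="const", values={r: EMINI_RANDOM_FRACTION for r in AMINO_ACIDS},
            combine_mode="product-ratio",
        )
        prof = surface_probability_profile(ProteinSequence(id="s", residues="A" * 6), scale)
        assert prof.values[0] == pytest.approx(1.0)

    def test_zero_fraction_annihilates_window(self):
        values = {r: 0.5 for r in AMINO_ACIDS}
        values["W"] = 0.0
        scale = ResidueScale(name="z", values=values, combine_mode="product-ratio")
        prof = surface_probability_profile(
            ProteinSequence(id="s", residues="AAWAAA"), scale
        )
        assert prof.values[0] == 0.0

    def test_matches_brute_force_product(self, emini):
        rng = np.random.default_rng(5)
        seq = random_protein(rng, 120)
        prof = surface_probability_profile(seq, emini)
        for i in range(120 - 5):
            product = 1.0
            for r in seq.residues[i : i + 6]:
                product *= emini[r]
            assert prof.values[i] == pytest.approx(
                product / EMINI_RANDOM_FRACTION**6, rel=1e-9
            )

    def test_center_left_anchor_shifts_by_two(self, emini):
        rng = np.random.default_rng(6)
        seq = random_protein(rng, 40)
        first = surface_probability_profile(seq, emini, anchor="first")
        center = surface_probability_profile(seq, emini, anchor="center-left")
        np.testing.assert_allclose(center.values[2:36], first.values[0:34])

    def test_short_sequence_fails(self, emini):
        with pytest.raises(SequenceTooShortError):
            surface_probability_profile(ProteinSequence(id="s", residues="ARNDC"), emini)

    def test_mean_mode_scale_rejected(self, hopp_woods):
        with pytest.raises(ScaleError):
            surface_probability_profile(
                ProteinSequence(id="s", residues="ARNDCQ"), hopp_woods
            )


class TestFlexibility:
    def test_homopolymer_is_constant(self, flex_scale):
        prof = flexibility_profile(ProteinSequence(id="s", residues="K" * 15), flex_scale)
        np.testing.assert_allclose(
            prof.values[prof.defined], flex_scale["K"], atol=1e-12
        )

    def test_equal_weights_reduce_to_plain_window_mean(self, flex_scale):
        rng = np.random.default_rng(9)
        seq = random_protein(rng, 60)
        flat = flexibility_profile(seq, flex_scale, weights=(1.0,) * 7)
        plain = windowed_profile(seq, flex_scale, 7)
        np.testing.assert_allclose(
            flat.values[flat.defined], plain.values[plain.defined], atol=1e-12
        )

    def test_matches_brute_force_weighted_sum(self, flex_scale):
        rng = np.random.default_rng(10)
        seq = random_protein(rng, 80)
        prof = flexibility_profile(seq, flex_scale)
        w = np.array(FLEX_WINDOW_WEIGHTS_7)
        w = w / w.sum()
        raw = [flex_scale[r] for r in seq.residues]
        for i in range(3, 77):
            expected = sum(w[k] * raw[i - 3 + k] for k in range(7))
            assert prof.values[i] == pytest.approx(expected, abs=1e-9)

    def test_negative_weights_rejected(self, flex_scale):
        with pytest.raises(WindowError):
            flexibility_profile(
                ProteinSequence(id="s", residues="A" * 10), flex_scale,
                weights=(1, 1, 1, -1, 1, 1, 1),
            )
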