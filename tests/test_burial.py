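"""Buried-residue prediction: windowed tracks, calibration, region calls."""

import math

import numpy as np
import pytest

from tsplasmid.burial import (
    EISENBERG_CONSENSUS,
    BurialProfile,
    calibrate_probability,
    find_buried_regions,
    hydrophobic_moment,
    moment_of_window,
    predict_profile,
    windowed_hydrophobicity,
)

from conftest import random_protein


def brute_force_avg(h, window):
    """Independent recomputation: explicit truncated-window mean per position."""
    half = window // 2
    n = len(h)
    return np.array([np.mean(h[max(0, i - half): min(n, i + half + 1)]) for i in range(n)])


def brute_force_moment(h, window, delta):
    """Independent recomputation: explicit complex vector sum per window."""
    half = window // 2
    n = len(h)
    out = np.empty(n)
    for i in range(n):
        vals = h[max(0, i - half): min(n, i + half + 1)]
        z = sum(v * np.exp(1j * math.radians(delta) * k) for k, v in enumerate(vals))
        out[i] = abs(z) / len(vals)
    return out


class TestWindowedHydrophobicity:
    def test_constant_sequence_gives_constant_track(self, eisenberg):
        track = windowed_hydrophobicity("I" * 30, eisenberg, window=7)
        assert np.allclose(track, eisenberg["I"])

    def test_hand_computed_three_mer(self, toy_scale):
        # ADA with H(A)=1, H(D)=-2: truncated means are (1-2)/2, (1-2+1)/3, (-2+1)/2
        track = windowed_hydrophobicity("ADA", toy_scale, window=3)
        assert np.allclose(track, [-0.5, 0.0, -0.5])

    def test_window_one_is_identity(self, eisenberg, rng):
        seq = random_protein(rng, 25)
        track = windowed_hydrophobicity(seq, eisenberg, window=1)
        assert np.allclose(track, [eisenberg[a] for a in seq])

    @pytest.mark.parametrize("window", [1, 3, 5, 7, 9])
    def test_matches_brute_force(self, eisenberg, rng, window):
        for _ in range(5):
            seq = random_protein(rng, 40)
            h = eisenberg.encode(seq)
            got = windowed_hydrophobicity(seq, eisenberg, window)
            assert np.allclose(got, brute_force_avg(h, window), atol=1e-12)

    def test_rejects_nonstandard_residue_with_position(self, eisenberg):
        with pytest.raises(ValueError, match="position 3"):
            windowed_hydrophobicity("AAXAA", eisenberg, window=3)

    def test_rejects_empty_and_even_window(self, eisenberg):
        with pytest.raises(ValueError):
            windowed_hydrophobicity("", eisenberg, window=3)
        with pytest.raises(ValueError):
            windowed_hydrophobicity("AAAA", eisenberg, window=4)


class TestHydrophobicMoment:
    def test_zero_hydrophobicity_gives_zero_moment(self, toy_scale):
        # G has H=0 in the toy scale
        track = hydrophobic_moment("G" * 20, toy_scale, window=11, delta=100)
        assert np.allclose(track, 0.0)

    def test_single_residue_window_is_abs_value(self, toy_scale):
        assert moment_of_window(np.array([1.0]), 100) == pytest.approx(1.0)

    def test_opposed_unit_vectors_cancel(self):
        # two residues, H = [1, 1], vectors at 0° and 180°
        assert moment_of_window(np.array([1.0, 1.0]), 180) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("window,delta", [(3, 100), (5, 160), (7, 100), (9, 80)])
    def test_matches_brute_force(self, eisenberg, rng, window, delta):
        for _ in range(5):
            seq = random_protein(rng, 40)
            h = eisenberg.encode(seq)
            got = hydrophobic_moment(seq, eisenberg, window, delta)
            assert np.allclose(got, brute_force_moment(h, window, delta), atol=1e-12)

    def test_phase_shift_invariance(self, rng):
        # rotating every vector by a common angle leaves the magnitude alone
        for _ in range(20):
            vals = rng.normal(size=9)
            ang = np.deg2rad(100) * np.arange(9)
            base = abs(np.sum(vals * np.exp(1j * ang))) / 9
            for phase in rng.uniform(0, 2 * np.pi, size=3):
                shifted = abs(np.sum(vals * np.exp(1j * (ang + phase)))) / 9
                assert shifted == pytest.approx(base, abs=1e-12)

    def test_triangle_inequality(self, eisenberg, rng):
        for _ in range(20):
            seq = random_protein(rng, 30)
            h = eisenberg.encode(seq)
            track = hydrophobic_moment(seq, eisenberg, window=9, delta=100)
            # interior positions have full windows: 0 <= muH * w <= sum |H|
            for i in range(4, 26):
                bound = np.sum(np.abs(h[i - 4: i + 5]))
                assert 0.0 <= track[i] * 9 <= bound + 1e-12

    def test_amphipathic_pattern_beats_shuffles(self, eisenberg):
        # hydrophobic every ~3.6 residues: the idealised buried helix face
        rng = np.random.default_rng(7)
        seq = "".join("I" if (i % 3.6) < 1.0 else "S" for i in range(36))
        ideal = hydrophobic_moment(seq, eisenberg, window=11, delta=100).mean()
        beaten = 0
        letters = list(seq)
        for _ in range(100):
            rng.shuffle(letters)
            shuf = hydrophobic_moment("".join(letters), eisenberg, 11, 100).mean()
            beaten += ideal > shuf
        assert beaten >= 95


class TestCalibration:
    def test_midpoint_maps_to_half(self):
        assert calibrate_probability(np.array([1.7]), s0=1.7, k=0.3)[0] == pytest.approx(0.5)

    def test_asymptotes(self):
        p = calibrate_probability(np.array([-1e6, 1e6]), s0=0.0, k=1.0)
        assert p[0] == pytest.approx(0.0, abs=1e-12)
        assert p[1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_inverted_logistic(self):
        # logit(0.9) = ln 9 = 2.1972...
        p = calibrate_probability(np.array([2.1972]), s0=0.0, k=1.0)
        assert p[0] == pytest.approx(0.90, abs=1e-4)

    def test_monotone_in_raw_score(self, rng):
        raw = rng.normal(size=50)
        p = calibrate_probability(raw, s0=0.2, k=0.5)
        assert np.array_equal(np.argsort(raw), np.argsort(p))

    def test_rejects_nonpositive_steepness(self):
        with pytest.raises(ValueError):
            calibrate_probability(np.zeros(3), s0=0.0, k=0.0)


def _profile_from_p(p_avg, p_moment=None):
    n = len(p_avg)
    p_avg = np.asarray(p_avg, dtype=float)
    p_moment = np.zeros(n) if p_moment is None else np.asarray(p_moment, dtype=float)
    return BurialProfile(
        sequence="A" * n,
        avg_hydro=np.zeros(n),
        moment=np.zeros(n),
        p_avg=p_avg,
        p_moment=p_moment,
    )


class TestFindBuriedRegions:
    def test_nothing_above_threshold_gives_empty(self):
        prof = _profile_from_p([0.1] * 20)
        assert find_buried_regions(prof) == []

    def test_single_block_bounds_and_peak(self):
        p = [0.1] * 20
        p[9:14] = [0.95] * 5  # positions 10-14, 1-based
        regions = find_buried_regions(_profile_from_p(p))
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end) == (10, 14)
        assert r.criterion == "average-hydrophobicity"
        assert r.peak == 10  # tie within the block resolves to the lowest position

    def test_moment_only_region_labelled_moment(self):
        p_m = [0.0] * 15
        p_m[4:7] = [0.85, 0.95, 0.9]
        regions = find_buried_regions(_profile_from_p([0.1] * 15, p_m))
        assert len(regions) == 1
        assert regions[0].criterion == "moment"
        assert regions[0].peak == 6

    def test_avg_wins_exact_tie(self):
        p_a = [0.0] * 9
        p_m = [0.0] * 9
        p_a[4] = 0.95
        p_m[4] = 0.95
        (r,) = find_buried_regions(_profile_from_p(p_a, p_m))
        assert r.criterion == "average-hydrophobicity"

    def test_adjacent_hits_merge_separated_hits_do_not(self):
        p = [0.1] * 12
        p[2] = p[3] = 0.95
        p[6] = 0.95
        regions = find_buried_regions(_profile_from_p(p))
        assert [(r.start, r.end) for r in regions] == [(3, 4), (7, 7)]

    def test_rejects_out_of_range_thresholds(self):
        with pytest.raises(ValueError):
            find_buried_regions(_profile_from_p([0.1] * 5), threshold_avg=1.0)


class TestDefaultCalibrationSemantics:
    def test_poly_ile_buried_poly_asp_not(self):
        buried = predict_profile("I" * 21)
        polar = predict_profile("D" * 21)
        assert buried.p_avg.min() >= 0.99
        assert polar.p_avg.max() <= 0.01

    def test_profile_export_columns(self):
        df = predict_profile("IDIDIDIDIDIDI").to_frame()
        assert list(df.columns) == [
            "position", "residue", "avg_hydro", "moment", "p_avg", "p_moment",
        ]
        assert df["position"].iloc[0] == 1
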