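"""Normalization, log2-ratio, trimmed-mean smoothing and .sgr round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hoxchip.signal import (ProbePanel, RatioTrack, SmoothingConfig,
                            log2_ratio, median_scale, quantile_normalize,
                            read_intensity_tsv, read_sgr, smooth_trimmed_mean,
                            write_intensity_tsv, write_sgr)


def make_panel(values, condition="specific", positions=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n = values.shape[1]
    if positions is None:
        positions = np.arange(n) * 36
    return ProbePanel(np.full(n, "chr1"), positions, values, condition)


class TestMedianScale:
    def test_already_at_target_unchanged(self):
        panel = make_panel([[1.0, 2.0, 3.0]])
        out = median_scale([panel], target_median=2.0)
        np.testing.assert_allclose(out[0].intensities, panel.intensities)

    def test_halving(self):
        panel = make_panel([[1.0, 2.0, 4.0]])
        out = median_scale([panel], target_median=1.0)
        np.testing.assert_allclose(out[0].intensities, [[0.5, 1.0, 2.0]])

    def test_replicate_medians_equalized(self, rng):
        panel = make_panel(rng.lognormal(0, 1, (3, 101)))
        out = median_scale([panel])
        medians = np.median(out[0].intensities, axis=1)
        assert np.ptp(medians) < 1e-9


class TestQuantileNormalize:
    def test_identical_replicates_unchanged(self):
        panel = make_panel([[3.0, 1.0, 2.0], [3.0, 1.0, 2.0]])
        out = quantile_normalize([panel])
        np.testing.assert_allclose(out[0].intensities, panel.intensities)

    def test_hand_computed_row_means(self):
        # sorted columns average to (2.5, 3.5, 4.5), mapped back by rank
        panel = make_panel([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        out = quantile_normalize([panel])
        np.testing.assert_allclose(out[0].intensities,
                                   [[2.5, 3.5, 4.5], [2.5, 3.5, 4.5]])

    def test_rank_order_preserved(self, rng):
        panel = make_panel(rng.lognormal(0, 1, (3, 50)))
        out = quantile_normalize([panel])
        for raw, norm in zip(panel.intensities, out[0].intensities):
            assert (np.argsort(raw, kind="stable")
                    == np.argsort(norm, kind="stable")).all()

    @given(st.integers(0, 2**31 - 1))
    def test_sorted_vectors_identical_and_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        panels = [make_panel(rng.lognormal(0, 1, (2, 20)), "specific"),
                  make_panel(rng.lognormal(0, 1, (2, 20)), "control")]
        once = quantile_normalize(panels)
        rows = np.vstack([p.intensities for p in once])
        ref = np.sort(rows[0])
        for row in rows[1:]:
            np.testing.assert_allclose(np.sort(row), ref)
        twice = quantile_normalize(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.intensities, b.intensities)


class TestLog2Ratio:
    def test_equal_means_zero_score(self):
        s = make_panel([[2.0, 4.0], [4.0, 4.0]], "specific")
        c = make_panel([[3.0, 2.0], [3.0, 6.0]], "control")
        track = log2_ratio(s, c)
        assert track.score[0] == 0.0

    def test_fourfold_is_two(self):
        s = make_panel([[8.0]], "specific")
        c = make_panel([[2.0]], "control")
        assert log2_ratio(s, c).score[0] == 2.0

    def test_self_ratio_is_zero(self, rng):
        panel = make_panel(rng.lognormal(0, 1, (3, 30)))
        track = log2_ratio(panel, panel)
        np.testing.assert_allclose(track.score, 0.0, atol=1e-12)

    def test_brute_force_equivalence(self, rng):
        s = make_panel(rng.lognormal(0, 1, (3, 40)), "specific")
        c = make_panel(rng.lognormal(0, 1, (2, 40)), "control")
        track = log2_ratio(s, c)
        for i in range(40):
            expected = np.log2(s.intensities[:, i].mean() / c.intensities[:, i].mean())
            assert track.score[i] == pytest.approx(expected)

    def test_position_mismatch_fails(self):
        s = make_panel([[1.0, 1.0]], positions=np.array([0, 36]))
        c = make_panel([[1.0, 1.0]], positions=np.array([0, 40]))
        with pytest.raises(ValueError):
            log2_ratio(s, c)


def smoothing_oracle(positions, scores, window_bp, trim):
    """Independent sort-trim-average smoother."""
    out = np.empty_like(scores)
    for i, p in enumerate(positions):
        lo, hi = p - window_bp // 2, p + (window_bp - window_bp // 2)
        vals = np.sort(scores[(positions >= lo) & (positions < hi)])
        k = int(trim * vals.size)
        if 2 * k >= vals.size:
            k = (vals.size - 1) // 2
        out[i] = vals[k:vals.size - k].mean()
    return out


class TestSmoothing:
    def test_constant_track_unchanged(self):
        track = RatioTrack(np.full(10, "chr1"), np.arange(10) * 36, np.full(10, 1.5))
        out = smooth_trimmed_mean(track, SmoothingConfig(675, 0.1))
        np.testing.assert_allclose(out.score, 1.5)

    def test_isolated_probe_keeps_own_value(self):
        track = RatioTrack(np.array(["chr1", "chr1"]), np.array([0, 10_000]),
                          np.array([2.0, -3.0]))
        out = smooth_trimmed_mean(track, SmoothingConfig(675, 0.1))
        np.testing.assert_allclose(out.score, [2.0, -3.0])

    def test_outlier_oracle_equivalence(self):
        positions = np.arange(21) * 36
        scores = np.zeros(21)
        scores[10] = 50.0  # single outlier
        track = RatioTrack(np.full(21, "chr1"), positions, scores)
        out = smooth_trimmed_mean(track, SmoothingConfig(675, 0.1))
        np.testing.assert_allclose(
            out.score, smoothing_oracle(positions, scores, 675, 0.1))

    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.0, 0.1, 0.25]))
    def test_random_tracks_match_oracle(self, seed, trim):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        positions = np.sort(rng.choice(5000, size=n, replace=False))
        scores = rng.normal(size=n)
        track = RatioTrack(np.full(n, "chr1"), positions, scores)
        out = smooth_trimmed_mean(track, SmoothingConfig(675, trim))
        np.testing.assert_allclose(
            out.score, smoothing_oracle(positions, scores, 675, trim))

    def test_zero_trim_is_windowed_mean(self, rng):
        n = 50
        positions = np.arange(n) * 36
        scores = rng.normal(size=n)
        track = RatioTrack(np.full(n, "chr1"), positions, scores)
        out = smooth_trimmed_mean(track, SmoothingConfig(675, 0.0))
        oracle = np.array([
            scores[(positions >= p - 337) & (positions < p + 338)].mean()
            for p in positions])
        np.testing.assert_allclose(out.score, oracle)

    def test_smoothing_respects_chromosome_boundaries(self, rng):
        chroms = np.array(["chr1"] * 5 + ["chr2"] * 5)
        positions = np.concatenate([np.arange(5) * 36, np.arange(5) * 36])
        scores = np.concatenate([np.zeros(5), np.full(5, 10.0)])
        out = smooth_trimmed_mean(RatioTrack(chroms, positions, scores),
                                  SmoothingConfig(675, 0.0))
        np.testing.assert_allclose(out.score[:5], 0.0)
        np.testing.assert_allclose(out.score[5:], 10.0)


class TestSgrIO:
    def test_round_trip(self, tmp_path, rng):
        n = 100
        track = RatioTrack(np.full(n, "chr1"), np.arange(n) * 36,
                          np.round(rng.normal(size=n), 6))
        path = tmp_path / "t.sgr"
        write_sgr(track, path)
        back = read_sgr(path)
        np.testing.assert_array_equal(back.positions, track.positions)
        np.testing.assert_allclose(back.score, track.score, atol=5e-7)

    def test_known_lines(self, tmp_path):
        path = tmp_path / "t.sgr"
        path.write_text("chr1\t1\t0.500000\nchr1\t37\t-1.250000\nchr2\t1\t2.000000\n")
        track = read_sgr(path)
        assert track.n_probes == 3
        np.testing.assert_array_equal(track.positions, [0, 36, 0])
        np.testing.assert_allclose(track.score, [0.5, -1.25, 2.0])

    def test_one_line_per_probe(self, tmp_path):
        n = 1234
        track = RatioTrack(np.full(n, "chr1"), np.arange(n), np.zeros(n))
        path = tmp_path / "t.sgr"
        write_sgr(track, path)
        assert sum(1 for _ in open(path)) == n

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.sgr"
        path.write_text("chr1\t1\t0.5\nchr1\toops\n")
        with pytest.raises(ValueError, match="line 2"):
            read_sgr(path)

    def test_intensity_tsv_round_trip(self, tmp_path, rng):
        panel = make_panel(rng.lognormal(0, 1, (3, 20)))
        path = tmp_path / "p.tsv"
        write_intensity_tsv(panel, path)
        back = read_intensity_tsv(path, "specific")
        np.testing.assert_allclose(back.intensities, panel.intensities)
        np.testing.assert_array_equal(back.positions, panel.positions)


class TestValidation:
    def test_nonpositive_intensities_rejected(self):
        with pytest.raises(ValueError):
            make_panel([[1.0, 0.0, 2.0]])

    def test_unsorted_positions_rejected(self):
        with pytest.raises(ValueError):
            make_panel([[1.0, 1.0]], positions=np.array([36, 0]))

    def test_bad_smoothing_config(self):
        with pytest.raises(ValueError):
            SmoothingConfig(window_bp=0)
        with pytest.raises(ValueError):
            SmoothingConfig(trim_fraction=0.5)
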