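"""CAAFD statistic, sliding-window scan, and peak-region calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bsamap.scan import caafd, call_peak_region, scan_genome

from conftest import random_marker_table


def brute_force_scan(markers, window_size, step, chrom_lengths=None):
    """Independent per-window recomputation of the scan (no rolling sums)."""
    rows = []
    for chrom in pd.unique(markers["chrom"]):
        grp = markers[markers["chrom"] == chrom]
        pos = grp["pos"].to_numpy(dtype=float)
        extent = chrom_lengths[chrom] if chrom_lengths else pos.max()
        c = 0.0
        while c < extent:
            start, end = max(0.0, c - window_size / 2), c + window_size / 2
            inside = grp[(pos >= start) & (pos < end)]
            if len(inside) >= 1:
                rows.append({
                    "chrom": chrom, "center": int(c), "n": len(inside),
                    "caafd": caafd(inside),
                })
            c += step
    return pd.DataFrame(rows)


def window(m1, m2, n1, n2):
    return pd.DataFrame({"m1": m1, "m2": m2, "n1": n1, "n2": n2})


class TestCaafd:
    def test_equal_pool_frequencies_give_zero(self):
        assert caafd(window([3, 10], [3, 10], [6, 5], [6, 5])) == 0.0

    def test_cube_of_window_mean(self):
        # diffs 0.6 and 0.6 -> mean 0.6 -> 0.216
        assert caafd(window([12, 8], [0, 2], [4, 2], [6, 8])) == pytest.approx(0.216)

    def test_lower_bound_at_reciprocal_fixation(self):
        assert caafd(window([0], [10], [10], [0])) == pytest.approx(-1.0)

    def test_cube_applies_to_mean_not_per_marker(self):
        # diffs 1.0 and 0.0: mean^3 = 0.125, mean of cubes would be 0.5
        val = caafd(window([10, 5], [0, 5], [0, 5], [10, 5]))
        assert val == pytest.approx(0.125)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            caafd(window([], [], [], []))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(st.lists(
        st.tuples(st.integers(0, 50), st.integers(0, 50),
                  st.integers(0, 50), st.integers(0, 50)),
        min_size=1, max_size=20,
    ))
    def test_bounds_and_antisymmetry(self, counts):
        counts = [(m1 + 1, m2, n1 + 1, n2) for m1, m2, n1, n2 in counts]
        m1, m2, n1, n2 = map(list, zip(*counts))
        v = caafd(window(m1, m2, n1, n2))
        assert -1.0 <= v <= 1.0
        swapped = caafd(window(n1, n2, m1, m2))
        assert swapped == -v


class TestScanGenome:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            markers = random_marker_table(rng, n=rng.integers(5, 200), span=5_000_000)
            got = scan_genome(markers, window_size=1_000_000, step=100_000)
            exp = brute_force_scan(markers, window_size=1_000_000, step=100_000)
            assert len(got) == len(exp)
            assert np.array_equal(got["n"].to_numpy(), exp["n"].to_numpy())
            assert np.max(np.abs(got["caafd"].to_numpy() - exp["caafd"].to_numpy())) <= 1e-12

    def test_chromosome_without_markers_emits_no_windows(self):
        markers = pd.DataFrame({
            "chrom": ["chr1"], "pos": [100], "m1": [5], "m2": [5], "n1": [5], "n2": [5],
        })
        scores = scan_genome(markers, window_size=1000, step=100,
                             chrom_lengths={"chr1": 2000, "chrX": 2000})
        assert set(scores["chrom"]) == {"chr1"}

    def test_identical_marker_multiset_identical_score(self):
        markers = pd.DataFrame({
            "chrom": "chr1", "pos": [1_000_000, 1_003_000, 1_006_000],
            "m1": [8, 9, 10], "m2": [2, 1, 0], "n1": [4, 5, 6], "n2": [6, 5, 4],
        })
        scores = scan_genome(markers, window_size=2_000_000, step=10_000)
        full = scores[scores["n"] == 3]
        assert len(full) > 1
        assert full["caafd"].nunique() == 1

    def test_unsorted_markers_rejected(self):
        markers = pd.DataFrame({
            "chrom": "chr1", "pos": [500, 100],
            "m1": [5, 5], "m2": [5, 5], "n1": [5, 5], "n2": [5, 5],
        })
        with pytest.raises(ValueError, match="sorted"):
            scan_genome(markers)

    def test_pool_swap_negates_profile_exactly(self):
        markers = random_marker_table(np.random.default_rng(7), n=300)
        swapped = markers.rename(columns={"m1": "n1", "n1": "m1", "m2": "n2", "n2": "m2"})
        a = scan_genome(markers, window_size=1_000_000, step=50_000)
        b = scan_genome(swapped, window_size=1_000_000, step=50_000)
        assert np.array_equal(a["caafd"].to_numpy(), -b["caafd"].to_numpy())


class TestPeakRegion:
    def scores(self, vals, chrom="chr1"):
        step = 10_000
        return pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(len(vals)) * step,
            "end": np.arange(1, len(vals) + 1) * step,
            "center": np.arange(len(vals)) * step,
            "n": 1,
            "caafd": vals,
        })

    def test_single_window(self):
        region = call_peak_region(self.scores([0.4]))
        assert region.peak_center == 0
        assert region.n_windows == 1

    def test_tied_peak_takes_first_and_region_spans_half_height(self):
        region = call_peak_region(self.scores([0.1, 0.3, 0.3, 0.1]), alpha=0.5)
        assert region.peak_center == 10_000       # first of the tied pair
        assert region.n_windows == 2              # 0.1 < 0.15 threshold
        assert region.start == 10_000 and region.end == 30_000

    def test_negative_peak_keeps_sign(self):
        region = call_peak_region(self.scores([-0.1, -0.5, -0.4, 0.2]))
        assert region.peak_caafd == -0.5
        assert region.n_windows == 2

    def test_empty_scores_raise(self):
        with pytest.raises(ValueError):
            call_peak_region(self.scores([]).iloc[:0])

    def test_region_confined_to_peak_chromosome(self):
        scores = pd.concat([
            self.scores([0.3, 0.3], chrom="chr1"),
            self.scores([0.32, 0.3], chrom="chr2"),
        ], ignore_index=True)
        region = call_peak_region(scores, alpha=0.5)
        assert region.chrom == "chr2"
        assert region.n_windows == 2


def test_demo_experiment_peak_near_causal_locus(demo_cfg, demo_selected):
    """End-to-end scan of one simulated experiment localizes the causal locus."""
    selected, _ = demo_selected
    scores = scan_genome(selected, chrom_lengths=demo_cfg.chrom_lengths)
    region = call_peak_region(scores)
    chrom, pos = demo_cfg.causal_locus
    assert region.chrom == chrom
    assert abs(region.peak_center - pos) <= 1_000_000
    assert region.start <= pos <= region.end
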