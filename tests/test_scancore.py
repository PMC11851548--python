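"""Genome scan: indices, filtering, windows, threshold, peaks, triage."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.scancore import (
    FilterSpec,
    ThresholdSpec,
    WindowSpec,
    add_indices,
    call_peaks,
    compute_index,
    compute_threshold,
    filter_variants,
    read_bulk_vcf,
    sliding_windows,
    triage_candidates,
)
from bsamap.simpop import GenomeSpec

from conftest import write_vcf


def random_table(rng, n, chrom="chr1", span=2_000_000):
    pos = np.sort(rng.choice(np.arange(1, span + 1), size=n, replace=False))
    t = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "ref": "G",
            "alt": "A",
            "vtype": rng.choice(["SNP", "InDel"], size=n, p=[0.9, 0.1]),
            "is_causal": False,
            "mut_ref_depth": rng.poisson(15, n),
            "mut_alt_depth": rng.poisson(15, n),
            "wt_ref_depth": rng.poisson(15, n),
            "wt_alt_depth": rng.poisson(15, n),
        }
    )
    return add_indices(t)


class TestIndex:
    @pytest.mark.parametrize(
        "ref,alt,expect", [(15, 15, 0.5), (0, 20, 1.0), (20, 0, 0.0), (0, 25, 1.0), (12, 13, 0.52)]
    )
    def test_direct_ratios(self, ref, alt, expect):
        assert compute_index(ref, alt) == pytest.approx(expect)

    def test_zero_depth_is_undefined(self):
        assert math.isnan(compute_index(0, 0))

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            compute_index(-1, 5)

    def test_delta_is_mut_minus_wt(self):
        t = add_indices(
            pd.DataFrame(
                {"mut_ref_depth": [0], "mut_alt_depth": [25],
                 "wt_ref_depth": [12], "wt_alt_depth": [13]}
            )
        )
        assert t.mut_index[0] == 1.0
        assert t.wt_index[0] == pytest.approx(0.52)
        assert t.delta_index[0] == pytest.approx(0.48)


class TestReadVcf:
    def test_reads_depths_and_indices(self, tmp_path):
        path = write_vcf(
            tmp_path / "x.vcf",
            [dict(chrom="chr1", pos=100, ref="G", alt="A", mut_ref=0, mut_alt=25, wt_ref=12, wt_alt=13)],
        )
        t = read_bulk_vcf(path)
        assert len(t) == 1
        assert t.mut_index[0] == 1.0 and t.wt_index[0] == pytest.approx(0.52)
        assert t.vtype[0] == "SNP"

    def test_zero_depth_record_retained_with_undefined_index(self, tmp_path):
        path = write_vcf(
            tmp_path / "x.vcf",
            [dict(chrom="chr1", pos=100, ref="G", alt="AT", mut_ref=0, mut_alt=0, wt_ref=10, wt_alt=10)],
        )
        t = read_bulk_vcf(path)
        assert len(t) == 1 and math.isnan(t.mut_index[0]) and t.vtype[0] == "InDel"

    def test_missing_sample_raises(self, tmp_path):
        path = write_vcf(
            tmp_path / "x.vcf",
            [dict(chrom="chr1", pos=100, ref="G", alt="A", mut_ref=1, mut_alt=1, wt_ref=1, wt_alt=1)],
        )
        with pytest.raises(ValueError, match="NOPE"):
            read_bulk_vcf(path, mut_sample="NOPE")


class TestFilter:
    def test_low_depth_in_one_bulk_dropped(self):
        t = add_indices(
            pd.DataFrame(
                {"chrom": ["chr1"], "pos": [10], "vtype": ["SNP"],
                 "mut_ref_depth": [9], "mut_alt_depth": [10],
                 "wt_ref_depth": [20], "wt_alt_depth": [20]}
            )
        )
        assert len(filter_variants(t, FilterSpec(min_depth=20))) == 0
        assert len(filter_variants(t, FilterSpec(min_depth=19))) == 1

    def test_identity_filter(self):
        t = random_table(np.random.default_rng(0), 50)
        out = filter_variants(t, FilterSpec(min_depth=0, drop_parental_het=False))
        pd.testing.assert_frame_equal(out, t)

    def test_matches_row_by_row_oracle(self):
        rng = np.random.default_rng(1)
        t = random_table(rng, 1000)
        spec = FilterSpec(min_depth=20, drop_parental_het=True, parental_het_band=(0.35, 0.65))
        out = filter_variants(t, spec)
        keep = []
        for _, r in t.iterrows():
            ok = (r.mut_ref_depth + r.mut_alt_depth) >= 20
            ok &= (r.wt_ref_depth + r.wt_alt_depth) >= 20
            ok &= not (np.isnan(r.mut_index) or np.isnan(r.wt_index))
            ok &= not (0.35 <= r.wt_index <= 0.65)
            keep.append(bool(ok))
        assert list(out.index) == list(t.index[keep])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.integers(0, 60), min_size=4, max_size=40), st.integers(0, 40), st.integers(0, 40))
    def test_raising_min_depth_is_monotone(self, depths, d1, d2):
        """A stricter depth cutoff never retains more variants."""
        n = len(depths) // 4
        if n == 0:
            return
        t = add_indices(
            pd.DataFrame(
                {"chrom": "chr1", "pos": np.arange(1, n + 1), "vtype": "SNP",
                 "mut_ref_depth": depths[:n], "mut_alt_depth": depths[n : 2 * n],
                 "wt_ref_depth": depths[2 * n : 3 * n], "wt_alt_depth": depths[3 * n : 4 * n]}
            )
        )
        lo, hi = sorted((d1, d2))
        assert len(filter_variants(t, FilterSpec(min_depth=hi))) <= len(
            filter_variants(t, FilterSpec(min_depth=lo))
        )


GENOME_1CHR = GenomeSpec(chromosomes=(("chr1", 2_000_000),), seed=0)


class TestWindows:
    def test_empty_table_gives_empty_windows(self):
        t = random_table(np.random.default_rng(0), 5).iloc[:0]
        w = sliding_windows(t, WindowSpec(500_000, 10_000), GENOME_1CHR)
        assert (w.n_variants == 0).all() and w.mean_delta.isna().all()
        # full windows advance by step; at most one truncated final window
        assert (w.end - w.start == 500_000).sum() >= len(w) - 1

    def test_single_variant_fills_covering_windows(self):
        t = random_table(np.random.default_rng(0), 1, span=15_000)
        t.loc[:, "pos"] = 5_000
        t.loc[:, "delta_index"] = 0.8
        g = GenomeSpec(chromosomes=(("chr1", 15_000),), seed=0)
        w = sliding_windows(t, WindowSpec(10_000, 5_000), g)
        covering = w[(w.start < 5_000) & (5_000 <= w.end)]
        outside = w[~((w.start < 5_000) & (5_000 <= w.end))]
        assert (covering.mean_delta == 0.8).all() and (covering.n_variants == 1).all()
        assert outside.mean_delta.isna().all()

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        t = random_table(rng, 2000)
        spec = WindowSpec(500_000, 10_000)
        w = sliding_windows(t, spec, GENOME_1CHR)
        for _, row in w.sample(60, random_state=0).iterrows():
            members = t[(t.pos > row.start) & (t.pos <= row.end)]
            assert row.n_variants == len(members)
            if len(members):
                assert row.mean_delta == pytest.approx(members.delta_index.mean())
            else:
                assert math.isnan(row.mean_delta)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(4)
        t = random_table(rng, 300)
        shuffled = t.sample(frac=1, random_state=1).reset_index(drop=True)
        a = sliding_windows(t, WindowSpec(), GENOME_1CHR)
        b = sliding_windows(shuffled, WindowSpec(), GENOME_1CHR)
        pd.testing.assert_frame_equal(a, b)

    def test_vtype_selection(self):
        rng = np.random.default_rng(5)
        t = random_table(rng, 400)
        w_snp = sliding_windows(t, WindowSpec(), GENOME_1CHR, vtype="SNP")
        w_both = sliding_windows(t, WindowSpec(), GENOME_1CHR, vtype="both")
        assert w_snp.n_variants.sum() < w_both.n_variants.sum()

    def test_window_must_be_at_least_step(self):
        with pytest.raises(ValueError):
            WindowSpec(window=5_000, step=10_000)


class TestThreshold:
    def test_zero_variance(self):
        t = random_table(np.random.default_rng(0), 10)
        t["delta_index"] = 0.3
        th = compute_threshold(t, k=3)
        assert th.sigma == pytest.approx(0.0, abs=1e-12)
        assert th.upper == pytest.approx(0.3) and th.lower == pytest.approx(0.3)

    def test_two_point_hand_calculation(self):
        """deltas {0, 1}: mu 0.5, sample SD 1/sqrt(2), upper 0.5 + 3/sqrt(2)."""
        t = random_table(np.random.default_rng(0), 2)
        t["delta_index"] = [0.0, 1.0]
        th = compute_threshold(t, k=3)
        assert th.mu == pytest.approx(0.5)
        assert th.sigma == pytest.approx(0.7071, abs=1e-4)
        assert th.upper == pytest.approx(2.6213, abs=1e-4)

    def test_fewer_than_two_deltas_rejected(self):
        t = random_table(np.random.default_rng(0), 1)
        with pytest.raises(ValueError):
            compute_threshold(t)

    def test_antisymmetry_under_bulk_swap(self):
        """Swapping bulk labels negates every delta and mirrors the threshold."""
        rng = np.random.default_rng(6)
        t = random_table(rng, 200)
        swapped = t.rename(
            columns={
                "mut_ref_depth": "wt_ref_depth", "mut_alt_depth": "wt_alt_depth",
                "wt_ref_depth": "mut_ref_depth", "wt_alt_depth": "mut_alt_depth",
            }
        )
        swapped = add_indices(swapped[[c for c in t.columns if "index" not in c]])
        assert np.allclose(swapped.delta_index, -t.delta_index, equal_nan=True)
        th, th_s = compute_threshold(t), compute_threshold(swapped)
        assert th_s.mu == pytest.approx(-th.mu)
        assert th_s.sigma == pytest.approx(th.sigma)
        assert th_s.lower == pytest.approx(-th.upper)
        # exceedance mirrors to the lower tail
        w = sliding_windows(t, WindowSpec(), GENOME_1CHR)
        w_s = sliding_windows(swapped, WindowSpec(), GENOME_1CHR)
        up = call_peaks(w, th)
        down = call_peaks(w_s, th_s, lower_tail=True)
        assert [(p.chromosome, p.start, p.end) for p in up] == [
            (p.chromosome, p.start, p.end) for p in down
        ]


class TestPeaks:
    def _windows(self, means):
        n = len(means)
        return pd.DataFrame(
            {"chrom": "chr1",
             "start": np.arange(n) * 10_000,
             "end": np.arange(n) * 10_000 + 500_000,
             "n_variants": 5,
             "mean_delta": means}
        )

    def test_null_scan_is_empty(self):
        w = self._windows([0.1, 0.0, np.nan, 0.2])
        assert call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3)) == []

    def test_consecutive_run_merges_to_one_region(self):
        w = self._windows([0.1, 0.5, 0.5, 0.5, 0.1])
        peaks = call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3))
        assert len(peaks) == 1
        p = peaks[0]
        assert p.start == 10_000 and p.end == 3 * 10_000 + 500_000 and p.n_windows == 3

    def test_nearby_runs_merge_into_non_overlapping_regions(self):
        means = [0.5, 0.1, 0.5] + [0.0] * 60 + [0.5]
        w = self._windows(means)
        peaks = call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3))
        for a, b in zip(peaks, peaks[1:]):
            assert a.end <= b.start
        assert len(peaks) == 2  # the two spaced runs; the first pair overlaps and merges

    def test_min_windows_discards_short_runs(self):
        w = self._windows([0.5, 0.1] + [0.0] * 60 + [0.5, 0.5, 0.5])
        peaks = call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3), min_windows=2)
        assert len(peaks) == 1 and peaks[0].n_windows == 3


class TestTriage:
    def _region_table(self):
        t = random_table(np.random.default_rng(7), 6, span=400_000)
        t["delta_index"] = [0.9, 0.5, 0.4, 0.3, 0.25, 0.1]
        return t

    def test_singleton_protein_changing_ranked_first(self):
        t = self._region_table().iloc[:1]
        w = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000], "n_variants": [1], "mean_delta": [0.9]}
        )
        peaks = call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3), table=t)
        effects = {(r.chrom, int(r.pos)): "stop_gained" for r in t.itertuples()}
        cand = triage_candidates(peaks[0], t, effects)
        assert len(cand) == 1 and cand.category[0] == "stop_gained"

    def test_all_below_cutoff_gives_empty_list(self):
        t = self._region_table()
        w = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000], "n_variants": [6], "mean_delta": [0.5]}
        )
        peaks = call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3), table=t)
        effects = {(r.chrom, int(r.pos)): "missense" for r in t.itertuples()}
        cand = triage_candidates(peaks[0], t, effects, delta_cutoff=0.95)
        assert len(cand) == 0

    def test_causal_protein_changing_outranks_silent_neighbours(self):
        """A stop-gained variant ranks first even when silent variants have
        larger delta, mirroring how the causal indel was singled out."""
        t = self._region_table()
        stop_pos = int(t.pos.iloc[3])
        effects = {}
        for r in t.itertuples():
            effects[(r.chrom, int(r.pos))] = "stop_gained" if r.pos == stop_pos else "synonymous"
        w = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000], "n_variants": [6], "mean_delta": [0.5]}
        )
        peaks = call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3), table=t)
        cand = triage_candidates(peaks[0], t, effects, delta_cutoff=0.22)
        assert cand.pos[0] == stop_pos
        # remaining candidates sorted by descending delta
        rest = cand.delta_index[1:].to_list()
        assert rest == sorted(rest, reverse=True)

    def test_unknown_variant_in_effects_map_raises(self):
        t = self._region_table()
        w = pd.DataFrame(
            {"chrom": ["chr1"], "start": [0], "end": [500_000], "n_variants": [6], "mean_delta": [0.5]}
        )
        peaks = call_peaks(w, ThresholdSpec(mu=0, sigma=0.1, k=3), table=t)
        with pytest.raises(KeyError):
            triage_candidates(peaks[0], t, {})
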