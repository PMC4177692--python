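import numpy as np
import pandas as pd
import pytest

from landgen.pa_regions import (
    BinCoverage,
    PARegionSet,
    TEMask,
    call_pa_bins,
    jaccard_distance,
    merge_pa_regions,
    merge_intervals,
    nj_from_pa,
    split_regions_to_bins,
    te_enrichment,
)


def _coverage(counts, bin_size=1000, chrom="chr1", samples=None):
    counts = np.asarray(counts)
    n_bins = counts.shape[0]
    samples = samples or [f"s{i}" for i in range(counts.shape[1])]
    bins = pd.DataFrame(
        {
            "chrom": [chrom] * n_bins,
            "start": np.arange(n_bins) * bin_size,
            "end": (np.arange(n_bins) + 1) * bin_size,
        }
    )
    return BinCoverage(bins=bins, counts=counts, samples=samples)


def _groups(labels, samples=None):
    samples = samples or [f"s{i}" for i in range(len(labels))]
    return pd.Series(labels, index=samples)


class TestCallPABins:
    def test_absent_group_qualifies(self):
        # group A all-zero, groups B..H well covered
        counts = np.zeros((1, 8), dtype=int)
        counts[0, 2:] = 12
        cov = _coverage(counts)
        groups = _groups(["A", "A", "B", "B", "C", "C", "D", "D"])
        out = call_pa_bins(cov, groups, min_presence_mean=1)
        assert bool(out["is_pa"][0])
        assert not out["present_A"][0]
        assert out["present_B"][0]

    def test_all_groups_covered_not_pa(self):
        counts = np.ones((1, 6), dtype=int)
        cov = _coverage(counts)
        out = call_pa_bins(cov, _groups(["A"] * 2 + ["B"] * 2 + ["C"] * 2))
        assert not out["is_pa"][0]

    def test_all_groups_absent_not_pa(self):
        counts = np.zeros((1, 4), dtype=int)
        cov = _coverage(counts)
        out = call_pa_bins(cov, _groups(["A", "A", "B", "B"]))
        assert not out["is_pa"][0]

    def test_presence_mean_threshold(self):
        # presence group mean below the threshold: bin does not qualify
        counts = np.array([[0, 0, 1, 0]])
        cov = _coverage(counts)
        groups = _groups(["A", "A", "B", "B"])
        assert not call_pa_bins(cov, groups, min_presence_mean=1)["is_pa"][0]
        assert call_pa_bins(cov, groups, min_presence_mean=0.5)["is_pa"][0]

    def test_empty_group_error(self):
        counts = np.ones((1, 2), dtype=int)
        cov = _coverage(counts)
        groups = pd.Series(["A", "B"], index=["s0", "other"])
        with pytest.raises(ValueError, match="without group"):
            call_pa_bins(cov, groups)

    def test_recovers_generator_truth_exactly(self, small_bundle):
        b = small_bundle
        bins = call_pa_bins(b.coverage, b.sample_sheet.groups)
        regions = merge_pa_regions(bins)
        called = set(map(tuple, regions.regions.to_numpy()))
        truth = set(
            map(tuple, b.pa_truth[["chrom", "start", "end"]].to_numpy())
        )
        assert called == truth

    def test_truth_table_counts_regions(self):
        from landgen.synthetic_data import SimConfig, simulate_dataset

        b = simulate_dataset(
            SimConfig(n_loci=20, n_pa_regions=50, genome_length_bp=500_000,
                      seed=77)
        )
        assert len(b.pa_truth) == 50
        # every region is all-zero in its absent groups
        lab = b.sample_sheet.groups.reindex(b.coverage.samples).to_numpy()
        for row in b.pa_truth.itertuples(index=False):
            absent = row.absent_groups.split(",")
            mask = (
                (b.coverage.bins["chrom"] == row.chrom)
                & (b.coverage.bins["start"] >= row.start)
                & (b.coverage.bins["end"] <= row.end)
            ).to_numpy()
            sub = b.coverage.counts[mask][:, np.isin(lab, absent)]
            assert (sub == 0).all()


class TestMergeRegions:
    def _bins(self, rows):
        cols = ["chrom", "start", "end", "is_pa", "present_A", "present_B"]
        return pd.DataFrame(rows, columns=cols)

    def test_adjacent_same_pattern_merge(self):
        bins = self._bins(
            [("chr1", 0, 1000, True, True, False),
             ("chr1", 1000, 2000, True, True, False)]
        )
        out = merge_pa_regions(bins)
        assert out.regions.iloc[0].tolist() == ["chr1", 0, 2000]
        assert len(out.regions) == 1

    def test_different_patterns_stay_split(self):
        bins = self._bins(
            [("chr1", 0, 1000, True, True, False),
             ("chr1", 1000, 2000, True, False, True)]
        )
        out = merge_pa_regions(bins)
        assert len(out.regions) == 2

    def test_mean_length(self):
        bins = self._bins(
            [("chr1", 0, 1000, True, True, False),
             ("chr1", 5000, 6000, True, True, False),
             ("chr1", 8000, 9000, True, False, True),
             ("chr1", 9000, 10000, True, False, True),
             ("chr1", 10000, 11000, True, False, True)]
        )
        out = merge_pa_regions(bins)
        assert out.summary()["mean_length"] == pytest.approx(1666.6667, abs=0.01)

    def test_round_trip_regions_to_bins(self, small_bundle):
        b = small_bundle
        bins = call_pa_bins(b.coverage, b.sample_sheet.groups)
        regions = merge_pa_regions(bins)
        back = split_regions_to_bins(regions, b.config.bin_size_bp)
        orig = bins[bins["is_pa"]].drop(columns="is_pa").reset_index(drop=True)
        pd.testing.assert_frame_equal(
            back.sort_values(["chrom", "start"]).reset_index(drop=True),
            orig.sort_values(["chrom", "start"]).reset_index(drop=True),
            check_dtype=False,
        )

    def test_region_needs_absent_and_present(self):
        with pytest.raises(ValueError, match="absent"):
            PARegionSet(
                regions=pd.DataFrame(
                    [("chr1", 0, 1000)], columns=["chrom", "start", "end"]
                ),
                group_presence=pd.DataFrame({"r1": [1, 1]}, index=["A", "B"]),
            )


class TestJaccard:
    def test_identical_rows(self):
        gp = pd.DataFrame([[1, 0, 1], [1, 0, 1]], index=["A", "B"])
        assert jaccard_distance(gp).iloc[0, 1] == 0.0

    def test_disjoint_rows(self):
        gp = pd.DataFrame([[1, 0], [0, 1]], index=["A", "B"])
        assert jaccard_distance(gp).iloc[0, 1] == 1.0

    def test_enumerated_example(self):
        gp = pd.DataFrame([[1, 1, 0, 1], [1, 0, 0, 1]], index=["A", "B"])
        assert jaccard_distance(gp).iloc[0, 1] == pytest.approx(1 - 2 / 3)

    def test_joint_absence_ignored(self):
        gp = pd.DataFrame([[1, 0, 0, 0], [1, 0, 0, 0]], index=["A", "B"])
        assert jaccard_distance(gp).iloc[0, 1] == 0.0

    def test_all_zero_rows_warn(self):
        gp = pd.DataFrame([[0, 0], [0, 0]], index=["A", "B"])
        with pytest.warns(UserWarning):
            d = jaccard_distance(gp)
        assert d.iloc[0, 1] == 0.0


def _region_set(regions, presence, groups):
    names = [f"{c}:{s}-{e}" for c, s, e in regions]
    return PARegionSet(
        regions=pd.DataFrame(regions, columns=["chrom", "start", "end"]),
        group_presence=pd.DataFrame(presence, index=groups, columns=names),
    )


class TestTEEnrichment:
    def _genome_bins(self, n=10, size=1000):
        return pd.DataFrame(
            {"chrom": "chr1", "start": np.arange(n) * size,
             "end": (np.arange(n) + 1) * size}
        )

    def test_full_mask(self):
        bins = self._genome_bins()
        mask = TEMask(pd.DataFrame([("chr1", 0, 10000)],
                                   columns=["chrom", "start", "end"]))
        pa = _region_set([("chr1", 1000, 2000)], [[1], [0]], ["A", "B"])
        out = te_enrichment(pa, mask, bins, seed=0)
        assert out == {"genome_fraction": 1.0, "pa_fraction": 1.0,
                       "control_fraction": 1.0}

    def test_empty_mask(self):
        bins = self._genome_bins()
        mask = TEMask(pd.DataFrame(columns=["chrom", "start", "end"]))
        pa = _region_set([("chr1", 1000, 2000)], [[1], [0]], ["A", "B"])
        out = te_enrichment(pa, mask, bins, seed=0)
        assert out == {"genome_fraction": 0.0, "pa_fraction": 0.0,
                       "control_fraction": 0.0}

    def test_toy_fractions(self):
        # mask covers bins 1-2 of 10; P/A = bin 1 only
        bins = self._genome_bins()
        mask = TEMask(pd.DataFrame([("chr1", 1000, 3000)],
                                   columns=["chrom", "start", "end"]))
        pa = _region_set([("chr1", 1000, 2000)], [[1], [0]], ["A", "B"])
        out = te_enrichment(pa, mask, bins, seed=0)
        assert out["pa_fraction"] == 1.0
        assert out["genome_fraction"] == pytest.approx(0.2)

    def test_seed_reproducible(self, small_bundle):
        b = small_bundle
        regions = merge_pa_regions(call_pa_bins(b.coverage, b.sample_sheet.groups))
        r1 = te_enrichment(regions, b.te_mask, b.coverage.bins, seed=9)
        r2 = te_enrichment(regions, b.te_mask, b.coverage.bins, seed=9)
        assert r1 == r2

    def test_bundle_reproduces_published_ordering(self, small_bundle):
        # P/A masked fraction > genome fraction > matched control
        b = small_bundle
        regions = merge_pa_regions(call_pa_bins(b.coverage, b.sample_sheet.groups))
        out = te_enrichment(regions, b.te_mask, b.coverage.bins, seed=0)
        assert out["pa_fraction"] > out["genome_fraction"] > out["control_fraction"]

    def test_control_converges_to_non_pa_fraction(self, small_bundle):
        b = small_bundle
        regions = merge_pa_regions(call_pa_bins(b.coverage, b.sample_sheet.groups))
        pa_bins = split_regions_to_bins(regions, b.config.bin_size_bp)
        key = set(map(tuple, pa_bins[["chrom", "start", "end"]].to_numpy()))
        non_pa = b.coverage.bins[
            ~b.coverage.bins.apply(tuple, axis=1).isin(key)
        ]
        target = sum(
            b.te_mask.masked_bp(c, s, e)
            for c, s, e in non_pa.itertuples(index=False)
        ) / (non_pa["end"] - non_pa["start"]).sum()
        fracs = [
            te_enrichment(regions, b.te_mask, b.coverage.bins, seed=s)[
                "control_fraction"
            ]
            for s in range(100)
        ]
        se = np.std(fracs, ddof=1) / np.sqrt(len(fracs))
        assert abs(np.mean(fracs) - target) <= 2 * se + 1e-4


class TestMergeIntervals:
    def test_overlaps_merged(self):
        df = pd.DataFrame(
            [("chr1", 0, 100), ("chr1", 50, 150), ("chr1", 200, 300)],
            columns=["chrom", "start", "end"],
        )
        out = merge_intervals(df)
        assert out.to_numpy().tolist() == [["chr1", 0, 150], ["chr1", 200, 300]]


class TestNJFromPA:
    def test_three_groups_closed_form(self):
        rng = np.random.default_rng(0)
        raw = rng.integers(0, 2, size=(3, 80))
        mixed = (raw.sum(axis=0) > 0) & (raw.sum(axis=0) < 3)
        presence = pd.DataFrame(raw[:, mixed][:, :40], index=["A", "B", "C"])
        tree, _ = nj_from_pa(
            _region_set(
                [("chr1", i * 1000, (i + 1) * 1000) for i in range(40)],
                presence.to_numpy(), ["A", "B", "C"],
            )
        )
        d = jaccard_distance(presence)
        got = tree.cophenetic(["A", "B", "C"])
        np.testing.assert_allclose(got, d.to_numpy(), atol=1e-9)

    def test_identical_groups_zero_pair(self):
        presence = np.array([[1, 0, 1, 1], [1, 0, 1, 1], [0, 1, 0, 1],
                             [1, 1, 0, 0]])
        pa = _region_set(
            [("chr1", i * 1000, (i + 1) * 1000) for i in range(4)],
            presence, ["A", "B", "C", "D"],
        )
        tree, _ = nj_from_pa(pa)
        d = tree.cophenetic(["A", "B", "C", "D"])
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_too_few_groups(self):
        pa = _region_set([("chr1", 0, 1000)], [[1], [0]], ["A", "B"])
        with pytest.raises(ValueError):
            nj_from_pa(pa)
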