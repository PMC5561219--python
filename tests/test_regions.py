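"""Candidate calling, merging, permutation test, uni/bi split, annotation."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.io import GeneRecord, Window
from sweepscan.regions import (
    SelectedRegion,
    annotate_genes,
    call_candidate_windows,
    deg_proximity_enrichment,
    intersect_common,
    merge_windows_to_regions,
    perm_p,
    permutation_test,
    region_zfst_summary,
    split_uni_bi,
)

from .conftest import make_dataset
from .oracles import chi2_2x2


def _rows(zvals, start0=0):
    return pd.DataFrame(
        {
            "contig": ["chr1"] * len(zvals),
            "start": [start0 + 10_000 * i for i in range(len(zvals))],
            "end": [start0 + 10_000 * i + 20_000 for i in range(len(zvals))],
            "n_snps": [50] * len(zvals),
            "zfst": zvals,
        }
    )


class TestCandidateWindows:
    def test_strict_threshold(self):
        wins = call_candidate_windows(_rows([1.9, 2.0, 2.1]))
        assert [w.start for w in wins] == [20_000]

    def test_empty_input(self):
        assert call_candidate_windows(_rows([])) == []

    def test_nan_never_qualifies(self):
        assert call_candidate_windows(_rows([np.nan, 3.0]))[0].start == 10_000


class TestMerging:
    def test_overlapping_windows_merge(self):
        regions = merge_windows_to_regions(
            [Window("chr1", 0, 20_000), Window("chr1", 10_000, 30_000)]
        )
        assert [(r.start, r.end) for r in regions] == [(0, 30_000)]

    def test_disjoint_windows_stay_separate(self):
        regions = merge_windows_to_regions(
            [Window("chr1", 0, 20_000), Window("chr1", 40_000, 60_000)]
        )
        assert len(regions) == 2

    def test_staggered_chain_length(self):
        chain = [Window("chr1", 10_000 * i, 10_000 * i + 20_000) for i in range(5)]
        regions = merge_windows_to_regions(chain)
        assert len(regions) == 1
        assert regions[0].length == 20_000 + 4 * 10_000

    def test_idempotent(self):
        wins = [Window("chr1", 0, 20_000), Window("chr1", 10_000, 30_000),
                Window("chr2", 0, 20_000)]
        once = merge_windows_to_regions(wins)
        again = merge_windows_to_regions(
            [Window(r.contig, r.start, r.end) for r in once]
        )
        assert [(r.contig, r.start, r.end) for r in once] == [
            (r.contig, r.start, r.end) for r in again
        ]


class TestIntersect:
    def test_partial_overlap(self):
        a = [SelectedRegion("chr1", 0, 30_000)]
        b = [SelectedRegion("chr1", 20_000, 50_000)]
        common = intersect_common(a, b)
        assert [(r.start, r.end) for r in common] == [(20_000, 30_000)]
        assert common[0].classification == "common"

    def test_touching_extents_do_not_intersect(self):
        a = [SelectedRegion("chr1", 0, 20_000)]
        b = [SelectedRegion("chr1", 20_000, 40_000)]
        assert intersect_common(a, b) == []

    def test_identical_sets_give_identity(self):
        a = [SelectedRegion("chr1", 0, 20_000), SelectedRegion("chr2", 10_000, 40_000)]
        common = intersect_common(a, a)
        assert [(r.contig, r.start, r.end) for r in common] == [
            (r.contig, r.start, r.end) for r in a
        ]

    def test_symmetric(self):
        a = [SelectedRegion("chr1", 0, 30_000)]
        b = [SelectedRegion("chr1", 15_000, 50_000)]
        ab = intersect_common(a, b)
        ba = intersect_common(b, a)
        assert [(r.start, r.end) for r in ab] == [(r.start, r.end) for r in ba]


class TestPermutation:
    @pytest.mark.parametrize("n,expected", [(0, 1 / 1001), (10, 11 / 1001), (1000, 1.0)])
    def test_empirical_p_formula(self, n, expected):
        assert perm_p(n, 1000) == pytest.approx(expected)

    def _sweep_dataset(self, rng):
        # strong fixed difference between domestic and wild in both contrasts
        n = 8
        chw = rng.integers(0, 2, size=(n, 60, 2))
        euw = rng.integers(0, 2, size=(n, 60, 2))
        chd = np.ones((n, 60, 2), dtype=int)
        eud = np.ones((n, 60, 2), dtype=int)
        g = np.concatenate([chw, chd, euw, eud]).astype(np.int8)
        return make_dataset(g, ["CHW"] * n + ["CHD"] * n + ["EUW"] * n + ["EUD"] * n)

    def test_observed_exceeding_all_permutations(self, rng):
        ds = self._sweep_dataset(rng)
        region = SelectedRegion("chr1", 0, 10_000)
        res = permutation_test(ds, region, [("CHD", "CHW"), ("EUD", "EUW")],
                               n_perm=200, seed=1)
        assert res.p == pytest.approx(1 / 201)

    def test_reproducible_with_fixed_seed(self, rng):
        ds = self._sweep_dataset(rng)
        region = SelectedRegion("chr1", 0, 10_000)
        args = (ds, region, [("CHD", "CHW"), ("EUD", "EUW")])
        a = permutation_test(*args, n_perm=100, seed=9)
        b = permutation_test(*args, n_perm=100, seed=9)
        assert a.p == b.p and a.per_contrast_p == b.per_contrast_p

    def test_joint_rule_not_larger_than_max_rule(self, rng):
        ds = self._sweep_dataset(rng)
        region = SelectedRegion("chr1", 0, 10_000)
        args = (ds, region, [("CHD", "CHW"), ("EUD", "EUW")])
        pj = permutation_test(*args, n_perm=100, seed=3, rule="joint").p
        pm = permutation_test(*args, n_perm=100, seed=3, rule="max").p
        assert pj <= pm

    def test_region_without_snps_errors(self, rng):
        ds = self._sweep_dataset(rng)
        with pytest.raises(ValueError):
            permutation_test(ds, SelectedRegion("chr1", 50_000, 60_000),
                             [("CHD", "CHW")], n_perm=10, seed=0)


class TestSplitUniBi:
    def _h12_frames(self, chd=0.6, chw=0.2, eud=0.5, euw=0.3):
        def frame(val):
            return pd.DataFrame(
                {"contig": ["chr1"], "center_pos": [10_001], "h12": [val]}
            )

        return {"CHW": frame(chw), "CHD": frame(chd), "EUW": frame(euw), "EUD": frame(eud)}

    def _region(self):
        w = Window("chr1", 0, 20_000)
        return SelectedRegion("chr1", 0, 20_000, member_windows=[w], classification="common")

    def test_unidirectional_rule(self):
        regions = split_uni_bi([self._region()], _rows([-1.5]), self._h12_frames())
        assert regions[0].classification == "unidirectional"

    def test_bidirectional_requires_strict_h12_inequality(self):
        regions = split_uni_bi(
            [self._region()], _rows([2.5]), self._h12_frames(eud=0.3, euw=0.3)
        )
        assert regions[0].classification == "common"

    def test_bidirectional_rule(self):
        regions = split_uni_bi([self._region()], _rows([2.5]), self._h12_frames())
        assert regions[0].classification == "bidirectional"

    def test_intermediate_z_stays_common(self):
        regions = split_uni_bi([self._region()], _rows([0.5]), self._h12_frames())
        assert regions[0].classification == "common"

    def test_missing_h12_leaves_region_unclassified(self):
        frames = self._h12_frames()
        frames["EUD"] = frames["EUD"].iloc[:0]
        regions = split_uni_bi([self._region()], _rows([-1.5]), frames)
        assert regions[0].classification == "common"
        assert np.isnan(regions[0].h12["EUD"])

    def test_partition_property(self):
        """uni + bi + unclassified-common partition the passing regions."""
        regions = [self._region() for _ in range(3)]
        out = split_uni_bi(regions, _rows([-1.5, 2.5, 0.0][:1] * 1), self._h12_frames())
        labels = {r.classification for r in out}
        assert labels <= {"unidirectional", "bidirectional", "common"}
        assert len(out) == 3


class TestRegionZSummary:
    def test_contained_member_windows_preferred(self):
        rows = _rows([-0.2, -1.4, -0.3])  # windows at 0, 10k, 20k
        region = SelectedRegion(
            "chr1", 10_000, 30_000,
            member_windows=[Window("chr1", 0, 20_000), Window("chr1", 10_000, 30_000)],
        )
        # only [10k,30k) lies inside the extent
        assert region_zfst_summary(region, rows) == pytest.approx(-1.4)

    def test_max_summary(self):
        rows = _rows([0.5, 2.5, 1.0])
        region = SelectedRegion("chr1", 0, 40_000)
        assert region_zfst_summary(region, rows, how="max") == pytest.approx(2.5)


class TestGeneAnnotation:
    def test_distance_rule(self):
        region = SelectedRegion("chr1", 0, 4_000)
        genes = [
            GeneRecord("near", "chr1", 5_000, 6_000),
            GeneRecord("far", "chr1", 7_000, 8_000),
            GeneRecord("inside", "chr1", 1_000, 2_000),
            GeneRecord("edge", "chr1", 6_000, 6_500),
        ]
        hits = annotate_genes([region], genes, max_dist=2_000)
        assert [g.gene_id for g in hits[0]] == ["near", "inside", "edge"]


class TestDegEnrichment:
    def _setup(self, n_deg_in=10, n_deg_out=90, n_bg_in=10, n_bg_out=890):
        regions = [SelectedRegion("chr1", 0, 20_000)]
        genes, flags = [], {}
        gid = 0

        def add(n, deg, in_zone):
            nonlocal gid
            for _ in range(n):
                start = 50_000 if in_zone else 1_000_000  # 30 kb vs far away
                genes.append(GeneRecord(f"g{gid}", "chr1", start + gid, start + gid + 100))
                flags[f"g{gid}"] = deg
                gid += 1

        add(n_deg_in, True, True)
        add(n_deg_out, True, False)
        add(n_bg_in, False, True)
        add(n_bg_out, False, False)
        return regions, genes, flags

    def test_chi2_matches_hand_oracle(self):
        regions, genes, flags = self._setup()
        count, chi2, p = deg_proximity_enrichment(regions, genes, flags)
        assert count == 10
        assert chi2 == pytest.approx(chi2_2x2([[10, 90], [10, 890]]), rel=1e-12)
        assert 0 < p < 1

    def test_degenerate_margin_flagged(self):
        regions, genes, flags = self._setup(n_deg_out=0, n_bg_out=0)
        count, chi2, p = deg_proximity_enrichment(regions, genes, flags)
        assert count == 10
        assert np.isnan(chi2) and np.isnan(p)

    def test_missing_flag_errors(self):
        regions, genes, flags = self._setup()
        del flags["g0"]
        with pytest.raises(ValueError, match="g0"):
            deg_proximity_enrichment(regions, genes, flags)
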