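"""Weir–Cockerham Fst, ZFst, ΔAF and Tajima's D against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.io import Window
from sweepscan.windowstats import (
    contrast_table,
    delta_af,
    site_fst_components,
    tajimas_d,
    windowed_fst,
    zscore,
)

from .conftest import make_dataset
from .oracles import tajimas_d_bruteforce, wc_site_components, wc_windowed_fst


def _geno_lists(g):
    """(n, v, 2) int8 array -> per-site list of (a, b) tuples with None for missing."""
    out = []
    for j in range(g.shape[1]):
        site = []
        for i in range(g.shape[0]):
            a, b = int(g[i, j, 0]), int(g[i, j, 1])
            site.append((None if a < 0 else a, None if b < 0 else b))
        out.append(site)
    return out


class TestSiteComponents:
    def test_fixed_difference_gives_fst_one(self):
        a = np.tile([1, 1], (10, 1, 1))
        b = np.tile([0, 0], (10, 1, 1))
        comp = site_fst_components(a[:, 0], b[:, 0])
        assert comp.fst == pytest.approx(1.0)

    def test_identical_groups_nonpositive_ratio(self):
        g = np.array([[0, 1], [0, 0], [1, 1], [0, 1], [0, 0]], dtype=np.int8)[:, None, :]
        comp = site_fst_components(g[:, 0], g[:, 0])
        assert comp.fst <= 0

    def test_handworked_example_matches_oracle(self):
        # A: 5 heterozygotes + 5 ref homozygotes; B: 10 ref homozygotes
        ga = np.array([[0, 1]] * 5 + [[0, 0]] * 5, dtype=np.int8)
        gb = np.array([[0, 0]] * 10, dtype=np.int8)
        comp = site_fst_components(ga, gb)
        a, b, c = wc_site_components(
            [(int(x), int(y)) for x, y in ga], [(int(x), int(y)) for x, y in gb]
        )
        assert comp.a == pytest.approx(a, abs=1e-12)
        assert comp.b == pytest.approx(b, abs=1e-12)
        assert comp.c == pytest.approx(c, abs=1e-12)

    def test_fully_missing_group_raises(self):
        ga = np.full((4, 2), -1, dtype=np.int8)
        gb = np.zeros((4, 2), dtype=np.int8)
        with pytest.raises(ValueError):
            site_fst_components(ga, gb)


class TestWindowedFst:
    def test_all_sites_fixed_different(self):
        g = np.concatenate(
            [np.ones((5, 20, 2), dtype=np.int8), np.zeros((5, 20, 2), dtype=np.int8)]
        )
        ds = make_dataset(g, ["A"] * 5 + ["B"] * 5)
        w = Window("chr1", 0, 3000)
        df = windowed_fst(ds, ("A", "B"), [w])
        assert df["fst"].iloc[0] == pytest.approx(1.0)

    def test_monomorphic_window_undefined(self):
        g = np.zeros((6, 5, 2), dtype=np.int8)
        ds = make_dataset(g, ["A"] * 3 + ["B"] * 3)
        df = windowed_fst(ds, ("A", "B"), [Window("chr1", 0, 1000)])
        assert np.isnan(df["fst"].iloc[0])

    def test_random_windows_match_bruteforce_oracle(self, rng):
        """Ratio-of-sums windowed Fst equals the per-site oracle to 1e-10."""
        for _ in range(200):
            nA = rng.integers(2, 11)
            nB = rng.integers(2, 11)
            n_sites = rng.integers(1, 101)
            g = rng.integers(0, 2, size=(nA + nB, n_sites, 2)).astype(np.int8)
            miss = rng.random(g.shape) < 0.1
            g[miss] = -1
            ds = make_dataset(g, ["A"] * int(nA) + ["B"] * int(nB))
            w = Window("chr1", 0, int(n_sites) * 100 + 100)
            got = windowed_fst(ds, ("A", "B"), [w])["fst"].iloc[0]
            lists = _geno_lists(g)
            want = wc_windowed_fst(
                [[s[i] for i in range(nA)] for s in lists],
                [[s[i] for i in range(nA, nA + nB)] for s in lists],
            )
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-10)

    def test_fst_symmetric_in_groups(self, rng):
        g = rng.integers(0, 2, size=(12, 40, 2)).astype(np.int8)
        ds = make_dataset(g, ["A"] * 6 + ["B"] * 6)
        w = [Window("chr1", 0, 5000)]
        ab = windowed_fst(ds, ("A", "B"), w)["fst"].iloc[0]
        ba = windowed_fst(ds, ("B", "A"), w)["fst"].iloc[0]
        assert ab == pytest.approx(ba, abs=1e-14)

    def test_empty_window_set_errors(self, rng):
        g = rng.integers(0, 2, size=(4, 5, 2)).astype(np.int8)
        ds = make_dataset(g, ["A"] * 2 + ["B"] * 2)
        with pytest.raises(ValueError):
            windowed_fst(ds, ("A", "B"), [])


class TestZscore:
    def test_simple_sequences(self):
        np.testing.assert_allclose(zscore([1, 2, 3]), [-1, 0, 1])
        np.testing.assert_allclose(zscore([0, 0, 0, 4]), [-0.5, -0.5, -0.5, 1.5])

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError):
            zscore([2.0, 2.0, 2.0])

    def test_nan_propagates(self):
        out = zscore([1.0, np.nan, 3.0])
        assert np.isnan(out[1]) and not np.isnan(out[0])

    @settings(deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(-50, 50), min_size=3, max_size=30),
        a=st.floats(0.1, 10),
        b=st.floats(-100, 100),
    )
    def test_affine_invariance(self, values, a, b):
        x = np.asarray(values)
        if np.asarray(x).std(ddof=1) < 1e-6:
            return
        np.testing.assert_allclose(zscore(a * x + b), zscore(x), atol=1e-6)


class TestDeltaAF:
    @pytest.mark.parametrize(
        "freqsA,freqsB,expected",
        [
            ([(9, 1)], [(1, 9)], 0.8),  # 0.9 vs 0.1 at one site
            ([(10, 0), (5, 5)], [(0, 10), (5, 5)], 0.5),
        ],
    )
    def test_examples(self, freqsA, freqsB, expected):
        def build(counts):
            sites = []
            for alt, ref in counts:
                alleles = [1] * alt + [0] * ref
                sites.append(np.array(alleles).reshape(5, 2))
            return np.stack(sites, axis=1).astype(np.int8)

        g = np.concatenate([build(freqsA), build(freqsB)])
        ds = make_dataset(g, ["A"] * 5 + ["B"] * 5)
        assert delta_af(ds, ("A", "B"), Window("chr1", 0, 10_000)) == pytest.approx(expected)

    def test_identical_groups_zero(self, rng):
        g = rng.integers(0, 2, size=(8, 30, 2)).astype(np.int8)
        both = np.concatenate([g, g])
        ds = make_dataset(both, ["A"] * 8 + ["B"] * 8)
        assert delta_af(ds, ("A", "B"), Window("chr1", 0, 10_000)) == pytest.approx(0.0)


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        g = np.zeros((5, 10, 2), dtype=np.int8)
        ds = make_dataset(g, ["A"] * 5)
        assert np.isnan(tajimas_d(ds, "A", Window("chr1", 0, 10_000)))

    def test_matches_constants_oracle_on_random_fixtures(self, rng):
        """Complete-data windows match the literature-constants oracle to 1e-10."""
        checked = 0
        while checked < 50:
            n_dip = rng.integers(2, 9)
            n_sites = rng.integers(3, 40)
            g = rng.integers(0, 2, size=(n_dip, n_sites, 2)).astype(np.int8)
            ds = make_dataset(g, ["A"] * int(n_dip))
            got = tajimas_d(ds, "A", Window("chr1", 0, int(n_sites) * 100 + 100))
            seqs = [
                [int(g[i, j, k]) for j in range(n_sites)]
                for i in range(n_dip)
                for k in (0, 1)
            ]
            want = tajimas_d_bruteforce(seqs)
            if np.isnan(want):
                assert np.isnan(got)
                continue
            assert got == pytest.approx(want, abs=1e-10)
            checked += 1

    def test_singleton_excess_negative(self):
        # every site a singleton on a distinct haplotype: excess of rare variants
        g = np.zeros((6, 12, 2), dtype=np.int8)
        for j in range(12):
            g[j % 6, j, j % 2] = 1
        ds = make_dataset(g, ["A"] * 6)
        assert tajimas_d(ds, "A", Window("chr1", 0, 10_000)) < 0


class TestContrastTable:
    def test_low_snp_windows_flagged_and_excluded_from_z(self, small_cohort):
        ds, _ = small_cohort
        from sweepscan.io import make_windows

        windows = make_windows(ds.contig_lengths)
        t = contrast_table(ds, ("CHD", "CHW"), windows, min_snps=10)
        assert (t.loc[t["low_snp"], "zfst"].isna()).all()
        zvals = t.loc[~t["zfst"].isna(), "zfst"]
        assert zvals.mean() == pytest.approx(0.0, abs=1e-9)
        assert zvals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_mean_fst_increases_with_divergence(self):
        from sweepscan.io import make_windows
        from sweepscan.simulate import SimulationConfig, simulate_cohort

        means = []
        for theta in (0.02, 0.1, 0.3):
            cfg = SimulationConfig(
                n_contigs=1,
                contig_length=300_000,
                samples_per_group={"CHW": 10, "CHD": 10, "EUW": 10, "EUD": 10, "AP": 1},
                wild_divergence=theta,
                seed=5,
            )
            ds, _ = simulate_cohort(cfg)
            t = windowed_fst(ds, ("CHW", "EUW"), make_windows(ds.contig_lengths))
            means.append(np.nanmean(t["fst"]))
        assert means[0] < means[1] < means[2]
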