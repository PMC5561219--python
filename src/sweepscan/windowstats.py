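"""Per-window population statistics.

Fst uses the Weir & Cockerham (1984) two-population estimator — the estimator
vcftools implements — with windowed values formed as the ratio of summed
variance components over sites (vcftools' "weighted" windowed Fst). Missing
genotypes are excluded from the per-site sample sizes. Negative window values
are retained (not clamped) so the genome-wide Z-transform sees the full null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset, Window


@dataclass
class FstComponents:
    """Weir–Cockerham per-site variance components.

    ``a``: among-population, ``b``: among-individual-within-population,
    ``c``: within-individual. The ratio a/(a+b+c) is undefined when the
    denominator is 0 (monomorphic site).
    """

    a: float
    b: float
    c: float

    @property
    def total(self) -> float:
        return self.a + self.b + self.c

    @property
    def fst(self) -> float:
        t = self.total
        return self.a / t if t != 0.0 else float("nan")


def _per_sample_site_arrays(g: np.ndarray):
    """From (n_samples, n_sites, 2) allele codes: called, alt-count, het flags.

    A sample is treated as missing at a site unless both alleles are called.
    """
    called = (g >= 0).all(axis=2)
    alt = np.where(called, g.clip(min=0).sum(axis=2), 0)
    het = called & (g[:, :, 0] != g[:, :, 1])
    return called.astype(np.float64), alt.astype(np.float64), het.astype(np.float64)


def wc_components_from_counts(n1, ac1, het1, n2, ac2, het2):
    """Vectorised Weir–Cockerham (1984) a, b, c from per-group counts.

    Parameters are per-site arrays: ``n`` called diploids, ``ac`` ALT allele
    count, ``het`` heterozygote count, for each of the two populations.
    Returns (a, b, c, defined) where ``defined`` marks sites with at least one
    called diploid in each group and nbar > 1.
    """
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    ac1 = np.asarray(ac1, dtype=np.float64)
    ac2 = np.asarray(ac2, dtype=np.float64)
    het1 = np.asarray(het1, dtype=np.float64)
    het2 = np.asarray(het2, dtype=np.float64)

    defined = (n1 >= 1) & (n2 >= 1) & (n1 + n2 > 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        nbar = (n1 + n2) / 2.0
        nsum = n1 + n2
        nc = 2.0 * nbar - (n1**2 + n2**2) / nsum  # r=2, so (r-1)=1
        p1 = ac1 / (2.0 * n1)
        p2 = ac2 / (2.0 * n2)
        pbar = (ac1 + ac2) / (2.0 * nsum)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (het1 + het2) / nsum
        inner = pbar * (1.0 - pbar) - s2 / 2.0
        a = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
        c = hbar / 2.0
    for arr in (a, b, c):
        arr[~defined] = np.nan
    return a, b, c, defined


def site_fst_components(genotypesA: np.ndarray, genotypesB: np.ndarray) -> FstComponents:
    """Weir–Cockerham components for one site.

    Each argument is an (n_diploids, 2) array of allele codes {0, 1, -1}.
    Raises ValueError if both groups are entirely missing or nbar <= 1.
    """
    a, b, c = _site_components_vec(genotypesA[:, None, :], genotypesB[:, None, :])
    if np.isnan(a[0]):
        raise ValueError("site undefined: needs >=1 called diploid per group and nbar > 1")
    return FstComponents(float(a[0]), float(b[0]), float(c[0]))


def _site_components_vec(gA: np.ndarray, gB: np.ndarray):
    cA, aA, hA = _per_sample_site_arrays(gA)
    cB, aB, hB = _per_sample_site_arrays(gB)
    a, b, c, _ = wc_components_from_counts(
        cA.sum(0), (aA * cA).sum(0), hA.sum(0), cB.sum(0), (aB * cB).sum(0), hB.sum(0)
    )
    return a, b, c


def windowed_fst(
    dataset: GenotypeDataset,
    contrast: tuple[str, str],
    windows: list[Window],
) -> pd.DataFrame:
    """Ratio-of-sums windowed Weir–Cockerham Fst for one group contrast.

    Returns a frame with one row per window: contig, start, end, n_snps,
    n_defined_sites, fst (NaN where no site is defined), delta_af.
    """
    if not windows:
        raise ValueError("empty window set")
    gA = dataset.genotypes[dataset.group_indices(contrast[0])]
    gB = dataset.genotypes[dataset.group_indices(contrast[1])]
    a, b, c = _site_components_vec(gA, gB)
    tot = a + b + c
    defined = ~np.isnan(a)
    a_f = np.where(defined, a, 0.0)
    tot_f = np.where(defined, tot, 0.0)

    # per-site |ALT frequency difference| for delta_af
    cA, aA, _ = _per_sample_site_arrays(gA)
    cB, aB, _ = _per_sample_site_arrays(gB)
    nA, nB = cA.sum(0), cB.sum(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        pA = (aA * cA).sum(0) / (2.0 * nA)
        pB = (aB * cB).sum(0) / (2.0 * nB)
        dif = np.abs(pA - pB)
    af_defined = (nA >= 1) & (nB >= 1)
    dif = np.where(af_defined, dif, 0.0)

    rows = []
    for w in windows:
        sl = dataset.window_variant_slice(w)
        nd = int(defined[sl].sum())
        denom = tot_f[sl].sum()
        fst = a_f[sl].sum() / denom if nd > 0 and denom != 0.0 else np.nan
        naf = int(af_defined[sl].sum())
        daf = dif[sl].sum() / naf if naf > 0 else np.nan
        rows.append(
            (w.contig, w.start, w.end, sl.stop - sl.start, nd, fst, daf)
        )
    return pd.DataFrame(
        rows,
        columns=["contig", "start", "end", "n_snps", "n_defined", "fst", "delta_af"],
    )


def zscore(values) -> np.ndarray:
    """(x - mean)/sd with sample sd (ddof=1); NaN inputs propagate as NaN."""
    x = np.asarray(values, dtype=np.float64)
    ok = ~np.isnan(x)
    if ok.sum() < 2:
        raise ValueError("z-transform needs at least 2 defined values")
    sd = x[ok].std(ddof=1)
    if sd == 0.0:
        raise ValueError("z-transform undefined: all values identical (degenerate scan)")
    out = np.full_like(x, np.nan)
    out[ok] = (x[ok] - x[ok].mean()) / sd
    return out


def delta_af(dataset: GenotypeDataset, contrast: tuple[str, str], window: Window) -> float:
    """Mean per-site |ALT-frequency difference| over the window's defined sites."""
    df = windowed_fst(dataset, contrast, [window])
    return float(df["delta_af"].iloc[0])


_TAJIMA_CACHE: dict[int, tuple[float, ...]] = {}


def tajima_constants(n: int) -> tuple[float, float, float, float]:
    """(a1, a2, e1, e2) from Tajima (1989) for sample size n chromosomes."""
    if n in _TAJIMA_CACHE:
        return _TAJIMA_CACHE[n]
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    _TAJIMA_CACHE[n] = (a1, a2, e1, e2)
    return a1, a2, e1, e2


def tajimas_d(dataset: GenotypeDataset, group: str, window: Window) -> float:
    """Tajima's D for one group in one window; NaN when S = 0 or n < 4.

    With missing data, each site is restricted to its called chromosomes;
    the constants use n = floor of the mean per-site called chromosome count.
    """
    sl = dataset.window_variant_slice(window)
    g = dataset.genotypes[dataset.group_indices(group), sl]
    if g.shape[1] == 0:
        return float("nan")
    called = (g >= 0).sum(axis=(0, 2)).astype(np.float64)  # chromosomes per site
    alt = g.clip(min=0).sum(axis=(0, 2)).astype(np.float64)
    usable = called >= 2
    if not usable.any():
        return float("nan")
    k = called[usable]
    x = alt[usable]
    seg = (x > 0) & (x < k)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    pi = float((2.0 * x * (k - x) / (k * (k - 1.0))).sum())
    n = int(np.floor(k.mean()))
    if n < 4:
        return float("nan")
    a1, _, e1, e2 = tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    return (pi - S / a1) / np.sqrt(var)


def contrast_table(
    dataset: GenotypeDataset,
    contrast: tuple[str, str],
    windows: list[Window],
    min_snps: int = 10,
    tajima: bool = False,
) -> pd.DataFrame:
    """Windowed Fst/ΔAF table for one contrast, with genome-wide ZFst.

    Windows with fewer than ``min_snps`` SNPs are flagged ``low_snp`` and
    excluded from the Z-transform (their zfst is NaN) but kept in the table.
    """
    df = windowed_fst(dataset, contrast, windows)
    df["low_snp"] = df["n_snps"] < min_snps
    fst_for_z = df["fst"].where(~df["low_snp"], np.nan).to_numpy()
    df["zfst"] = zscore(fst_for_z)
    if tajima:
        for grp in contrast:
            df[f"tajima_d_{grp}"] = [
                tajimas_d(dataset, grp, w) for w in windows
            ]
    return df
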