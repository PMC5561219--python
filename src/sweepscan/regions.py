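"""From window statistics to classified selection regions.

Candidate windows (ZFst > 2 against the local wild group) are merged into
regions per domestic population; regions shared by both domestic populations
("common") are permutation-tested and then split by the between-domestic ZFst
plus the H12 filter into unidirectional (selected toward the same alleles in
both centers) and bidirectional (opposite alleles) regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GenotypeDataset, GeneRecord, Window
from .windowstats import _per_sample_site_arrays, wc_components_from_counts

CANDIDATE = "candidate"
COMMON = "common"
UNIDIRECTIONAL = "unidirectional"
BIDIRECTIONAL = "bidirectional"
REJECTED = "rejected"


@dataclass
class SelectedRegion:
    contig: str
    start: int
    end: int
    member_windows: list[Window] = field(default_factory=list)
    classification: str = CANDIDATE
    zfst_chd_eud: float = float("nan")
    perm_p: float = float("nan")
    h12: dict[str, float] = field(default_factory=dict)
    ancient_call: str = "not_applicable"
    is_ap_chd: float = float("nan")
    is_ap_euw: float = float("nan")

    @property
    def length(self) -> int:
        return self.end - self.start

    def windows_in_extent(self) -> list[Window]:
        """Member windows fully contained in the region extent.

        Falls back to all member windows when none is contained, and to the
        extent itself when the region records no member windows. Windows
        poking outside the common extent carry flanking sequence; summaries
        over the region proper use the contained ones.
        """
        inside = [
            w for w in self.member_windows if w.start >= self.start and w.end <= self.end
        ]
        if inside:
            return inside
        if self.member_windows:
            return list(self.member_windows)
        return [Window(self.contig, self.start, self.end)]


@dataclass
class PermutationResult:
    n_exceed: int  # count backing the reported p (max rule: the larger count)
    n_perm: int
    p: float
    per_contrast_p: dict[tuple[str, str], float] = field(default_factory=dict)


def perm_p(n_exceed: int, n_perm: int = 1000) -> float:
    """Empirical p-value (n + 1)/(n_perm + 1)."""
    return (n_exceed + 1) / (n_perm + 1)


def call_candidate_windows(rows: pd.DataFrame, z_threshold: float = 2.0) -> list[Window]:
    """Windows whose ZFst strictly exceeds the threshold (low-SNP windows never qualify)."""
    hits = rows[rows["zfst"] > z_threshold]
    return [
        Window(r.contig, int(r.start), int(r.end), int(r.n_snps))
        for r in hits.itertuples(index=False)
    ]


def merge_windows_to_regions(windows: list[Window]) -> list[SelectedRegion]:
    """Merge overlapping or book-ended windows into maximal runs per contig."""
    regions: list[SelectedRegion] = []
    by_contig: dict[str, list[Window]] = {}
    for w in windows:
        by_contig.setdefault(w.contig, []).append(w)
    for contig in by_contig:
        ws = sorted(by_contig[contig], key=lambda w: (w.start, w.end))
        cur: SelectedRegion | None = None
        for w in ws:
            if cur is not None and w.start <= cur.end:
                cur.end = max(cur.end, w.end)
                cur.member_windows.append(w)
            else:
                cur = SelectedRegion(contig, w.start, w.end, [w])
                regions.append(cur)
    return regions


def intersect_common(
    chd_regions: list[SelectedRegion], eud_regions: list[SelectedRegion]
) -> list[SelectedRegion]:
    """Regions selected in both domestic populations; extent = the intersection."""
    out: list[SelectedRegion] = []
    for a in chd_regions:
        for b in eud_regions:
            if a.contig != b.contig:
                continue
            lo = max(a.start, b.start)
            hi = min(a.end, b.end)
            if hi > lo:
                out.append(
                    SelectedRegion(
                        a.contig,
                        lo,
                        hi,
                        member_windows=sorted(
                            {(w.contig, w.start, w.end): w
                             for w in a.member_windows + b.member_windows}.values(),
                            key=lambda w: w.start,
                        ),
                        classification=COMMON,
                    )
                )
    out.sort(key=lambda r: (r.contig, r.start))
    return out


# ---------------------------------------------------------------------------
# permutation test


def _region_count_arrays(dataset: GenotypeDataset, idx: np.ndarray, sl: slice):
    g = dataset.genotypes[idx, sl]
    called, alt, het = _per_sample_site_arrays(g)
    return called, alt * called, het


def _fst_from_assignment(assign, called, alt, het):
    """Ratio-of-sums Fst for each row of a (n_perm, n_pool) assignment matrix."""
    n1 = assign @ called
    ac1 = assign @ alt
    h1 = assign @ het
    n2 = called.sum(0) - n1
    ac2 = alt.sum(0) - ac1
    h2 = het.sum(0) - h1
    a, b, c, defined = wc_components_from_counts(n1, ac1, h1, n2, ac2, h2)
    a = np.where(defined, a, 0.0)
    tot = np.where(defined, a + np.where(defined, b, 0.0) + np.where(defined, c, 0.0), 0.0)
    num = a.sum(axis=-1)
    den = tot.sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def permutation_test(
    dataset: GenotypeDataset,
    region: SelectedRegion,
    contrasts: list[tuple[str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    rule: str = "max",
) -> PermutationResult:
    """Label-permutation test of the region's Fst in the given contrasts.

    Within each contrast, domestic/wild labels are shuffled over the pooled
    samples with group sizes held fixed and the region Fst (ratio of sums)
    recomputed ``n_perm`` times. Rules:

    - ``max`` (default): per-contrast p = (n_c + 1)/(n_perm + 1) with n_c the
      count of permuted Fst >= observed; the region p is the max over
      contrasts (every contrast must be individually significant).
    - ``joint``: a permutation counts once if it meets or exceeds the
      observed Fst in all contrasts simultaneously.
    """
    if rule not in ("max", "joint"):
        raise ValueError(f"unknown permutation rule {rule!r}")
    sl = dataset.window_variant_slice(Window(region.contig, region.start, region.end))
    if sl.stop <= sl.start:
        raise ValueError("permutation test requires >=1 SNP in the region")
    rng = np.random.default_rng(seed)
    exceed_flags = []
    per_contrast: dict[tuple[str, str], float] = {}
    for g1, g2 in contrasts:
        i1 = dataset.group_indices(g1)
        i2 = dataset.group_indices(g2)
        pool = np.concatenate([i1, i2])
        called, alt, het = _region_count_arrays(dataset, pool, sl)
        obs_assign = np.zeros((1, pool.size))
        obs_assign[0, : i1.size] = 1.0
        obs = _fst_from_assignment(obs_assign, called, alt, het)[0]
        order = np.argsort(rng.random((n_perm, pool.size)), axis=1)
        assign = np.zeros((n_perm, pool.size))
        np.put_along_axis(assign, order[:, : i1.size], 1.0, axis=1)
        permuted = _fst_from_assignment(assign, called, alt, het)
        exceed = np.nan_to_num(permuted, nan=-np.inf) >= obs
        exceed_flags.append(exceed)
        per_contrast[(g1, g2)] = perm_p(int(exceed.sum()), n_perm)
    if rule == "joint":
        n_ex = int(np.logical_and.reduce(exceed_flags).sum())
        p = perm_p(n_ex, n_perm)
    else:
        p = max(per_contrast.values())
        n_ex = round(p * (n_perm + 1)) - 1
    return PermutationResult(n_ex, n_perm, p, per_contrast)


# ---------------------------------------------------------------------------
# classification


def region_zfst_summary(
    region: SelectedRegion, contrast_rows: pd.DataFrame, how: str = "mean"
) -> float:
    """Region-level ZFst over a contrast's window table.

    The summary is taken over the contrast's rows at the member windows lying
    inside the region extent (see ``SelectedRegion.windows_in_extent``); when
    none of those rows exist, all windows overlapping the extent are used.
    ``mean``: overlap-length-weighted mean; ``max``: maximum. Windows without
    a defined ZFst are ignored.
    """
    sub = contrast_rows[
        (contrast_rows["contig"] == region.contig)
        & (contrast_rows["end"] > region.start)
        & (contrast_rows["start"] < region.end)
    ]
    keys = {(w.start, w.end) for w in region.windows_in_extent()}
    member = sub[[(s, e) in keys for s, e in zip(sub["start"], sub["end"])]]
    if not member.empty:
        sub = member
    sub = sub[~sub["zfst"].isna()]
    if sub.empty:
        return float("nan")
    if how == "max":
        return float(sub["zfst"].max())
    if how != "mean":
        raise ValueError(f"unknown summary {how!r}")
    overlap = np.minimum(sub["end"], region.end) - np.maximum(sub["start"], region.start)
    return float(np.average(sub["zfst"], weights=overlap))


def split_uni_bi(
    common_regions: list[SelectedRegion],
    chd_eud_rows: pd.DataFrame,
    h12_by_group: dict[str, pd.DataFrame],
    uni_threshold: float = -1.0,
    bi_threshold: float = 2.0,
    z_summary: str = "mean",
    roles: dict[str, str] | None = None,
) -> list[SelectedRegion]:
    """Classify permutation-passing common regions as uni-/bidirectional.

    Unidirectional: region ZFst(CHD vs EUD) < ``uni_threshold`` AND
    H12_CHD > H12_CHW AND H12_EUD > H12_EUW (strict). Bidirectional: the same
    H12 inequalities with region ZFst(CHD vs EUD) > ``bi_threshold``.
    Otherwise the region stays common. Missing H12 leaves the region common
    with h12 recorded as NaN.
    """
    from .haplostats import region_h12

    roles = roles or {g: g for g in ("CHW", "CHD", "EUW", "EUD")}
    for region in common_regions:
        region.zfst_chd_eud = region_zfst_summary(region, chd_eud_rows, z_summary)
        for role in ("CHW", "CHD", "EUW", "EUD"):
            rows = h12_by_group[roles[role]]
            region.h12[role] = region_h12(rows, region.contig, region.start, region.end)
        h = region.h12
        if any(np.isnan(h[r]) for r in ("CHW", "CHD", "EUW", "EUD")):
            continue
        h12_pass = h["CHD"] > h["CHW"] and h["EUD"] > h["EUW"]
        if not h12_pass or np.isnan(region.zfst_chd_eud):
            continue
        if region.zfst_chd_eud < uni_threshold:
            region.classification = UNIDIRECTIONAL
        elif region.zfst_chd_eud > bi_threshold:
            region.classification = BIDIRECTIONAL
    return common_regions


# ---------------------------------------------------------------------------
# gene annotation and DEG proximity enrichment


def _span_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp between two half-open spans; 0 when they overlap or touch."""
    if a_start < b_end and b_start < a_end:
        return 0
    return max(a_start - b_end, b_start - a_end, 0)


def annotate_genes(
    regions: list[SelectedRegion], genes: list[GeneRecord], max_dist: int = 0
) -> dict[int, list[GeneRecord]]:
    """Genes overlapping or within ``max_dist`` bp of each region (by index)."""
    out: dict[int, list[GeneRecord]] = {}
    for i, r in enumerate(regions):
        out[i] = [
            g
            for g in genes
            if g.contig == r.contig
            and _span_distance(r.start, r.end, g.start, g.end) <= max_dist
        ]
    return out


def gene_min_distance(gene: GeneRecord, regions: list[SelectedRegion]) -> float:
    """Minimal span distance from a gene to any region (inf if none on its contig)."""
    ds = [
        _span_distance(r.start, r.end, gene.start, gene.end)
        for r in regions
        if r.contig == gene.contig
    ]
    return min(ds) if ds else float("inf")


def deg_proximity_enrichment(
    regions: list[SelectedRegion],
    genes: list[GeneRecord],
    deg_flags: dict[str, bool],
    dmin: int = 20_000,
    dmax: int = 250_000,
):
    """Are differentially expressed genes enriched at medium range from regions?

    A gene is "in zone" iff its minimal distance d to any listed region
    satisfies dmin <= d <= dmax. The 2x2 table (DEG vs non-DEG) x (in-zone vs
    not) is tested by Pearson chi-squared with 1 df, no continuity correction.
    Returns (count of DEGs in zone, chi2, p); chi2/p are NaN when a table
    margin is zero (degenerate).
    """
    missing = [g.gene_id for g in genes if g.gene_id not in deg_flags]
    if missing:
        raise ValueError(f"genes without a DEG flag: {missing[:5]}")
    in_zone = np.array(
        [dmin <= gene_min_distance(g, regions) <= dmax for g in genes], dtype=bool
    )
    is_deg = np.array([bool(deg_flags[g.gene_id]) for g in genes], dtype=bool)
    table = np.array(
        [
            [int((is_deg & in_zone).sum()), int((is_deg & ~in_zone).sum())],
            [int((~is_deg & in_zone).sum()), int((~is_deg & ~in_zone).sum())],
        ]
    )
    count_in_zone = int(table[0, 0])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return count_in_zone, float("nan"), float("nan")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return count_in_zone, float(chi2), float(p)


def regions_to_frame(regions: list[SelectedRegion]) -> pd.DataFrame:
    rows = []
    for r in regions:
        rows.append(
            {
                "contig": r.contig,
                "start": r.start,
                "end": r.end,
                "classification": r.classification,
                "zfst_chd_eud": r.zfst_chd_eud,
                "perm_p": r.perm_p,
                "h12_CHW": r.h12.get("CHW", np.nan),
                "h12_CHD": r.h12.get("CHD", np.nan),
                "h12_EUW": r.h12.get("EUW", np.nan),
                "h12_EUD": r.h12.get("EUD", np.nan),
                "is_ap_chd": r.is_ap_chd,
                "is_ap_euw": r.is_ap_euw,
                "ancient_call": r.ancient_call,
            }
        )
    return pd.DataFrame(rows)
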