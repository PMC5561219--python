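"""Identity scores, the ancient-genome introgression classifier, and nIBD.

The identity score between two groups at a site is IS = 1 - |F1 - F2| on
reference-allele frequencies, assessed only where at least half of each
group's individuals are fully called; window values average over assessed
sites. Comparing the ancient pre-introgression European domestic genome (AP)
against modern Chinese domestic pigs versus European wild boar separates
selection that predates Asian introgression from introgression-then-selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .io import GenotypeDataset, Window

AncientCallLabel = str  # one of the constants below

INTROGRESSION_THEN_SELECTION = "introgression_then_selection"
PRE_INTROGRESSION_SELECTION = "pre_introgression_selection"
AMBIGUOUS = "ambiguous"
NO_DATA = "no_data"
NOT_APPLICABLE = "not_applicable"


@dataclass
class IdentityScoreRow:
    window: Window
    pair: tuple[str, str]
    is_value: float  # NaN when no site assessed
    n_sites_assessed: int


@dataclass
class AncientCall:
    contig: str
    start: int
    end: int
    is_ap_chd: float
    is_ap_euw: float
    margin: float
    call: AncientCallLabel


def group_ref_freq(dataset: GenotypeDataset, group: str) -> np.ndarray:
    """Per-site reference-allele frequency among called alleles for *group*.

    A site is assessed only if the number of fully-called individuals is at
    least half the group size (ceil(n/2)); otherwise NaN. For a single-member
    group (the ancient sample) this means the site must be called in it.
    """
    idx = dataset.group_indices(group)
    g = dataset.genotypes[idx]
    called = (g >= 0).all(axis=2)
    n_called = called.sum(axis=0)
    alt = (np.where(called, g.clip(min=0).sum(axis=2), 0)).sum(axis=0)
    need = ceil(idx.size / 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = 1.0 - alt / (2.0 * n_called)
    freq[n_called < need] = np.nan
    return freq


def identity_score_window(
    dataset: GenotypeDataset,
    g1: str,
    g2: str,
    window: Window,
    _freq_cache: dict | None = None,
) -> IdentityScoreRow:
    """Mean per-site 1 - |F_g1 - F_g2| over the window's assessed sites."""
    cache = _freq_cache if _freq_cache is not None else {}
    for g in (g1, g2):
        if g not in cache:
            cache[g] = group_ref_freq(dataset, g)
    sl = dataset.window_variant_slice(window)
    f1 = cache[g1][sl]
    f2 = cache[g2][sl]
    ok = ~np.isnan(f1) & ~np.isnan(f2)
    n = int(ok.sum())
    value = float((1.0 - np.abs(f1[ok] - f2[ok])).mean()) if n else float("nan")
    return IdentityScoreRow(window, (g1, g2), value, n)


def identity_score_table(
    dataset: GenotypeDataset,
    pairs: list[tuple[str, str]],
    windows: list[Window],
) -> pd.DataFrame:
    """IS for several group pairs over a window grid (shared frequency cache)."""
    cache: dict[str, np.ndarray] = {}
    rows = []
    for g1, g2 in pairs:
        for w in windows:
            r = identity_score_window(dataset, g1, g2, w, _freq_cache=cache)
            rows.append((w.contig, w.start, w.end, g1, g2, r.is_value, r.n_sites_assessed))
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "group1", "group2", "is_value", "n_sites"]
    )


def region_identity_score(
    dataset: GenotypeDataset,
    g1: str,
    g2: str,
    member_windows: list[Window],
    _freq_cache: dict | None = None,
) -> float:
    """Region IS = unweighted mean of defined member-window IS values."""
    vals = [
        identity_score_window(dataset, g1, g2, w, _freq_cache=_freq_cache).is_value
        for w in member_windows
    ]
    vals = [v for v in vals if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def classify_ancient(
    is_ap_chd: float, is_ap_euw: float, margin: float = 0.1
) -> AncientCallLabel:
    """Classify a unidirectional region from ancient-genome identity scores.

    IS(AP, CHD) < IS(AP, EUW) + margin: the ancient genome resembles European
    wild boar more than Chinese domestic pigs, so the selected haplotype was
    not yet present — introgression-then-selection. The reverse strict
    inequality indicates selection predating introgression. Exactly at the
    margin the call is ambiguous; any undefined score yields no_data.
    """
    if np.isnan(is_ap_chd) or np.isnan(is_ap_euw):
        return NO_DATA
    if is_ap_chd < is_ap_euw + margin:
        return INTROGRESSION_THEN_SELECTION
    if is_ap_chd > is_ap_euw + margin:
        return PRE_INTROGRESSION_SELECTION
    return AMBIGUOUS


# ---------------------------------------------------------------------------
# IBD proxy and nIBD


@dataclass
class IBDSegment:
    sample1: str
    hap1: int  # 0 or 1
    sample2: str
    hap2: int
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("segment end must exceed start")


def detect_ibd_proxy(
    dataset: GenotypeDataset,
    sample_pair: tuple[str, str],
    bin_size: int = 20_000,
    identity_threshold: float = 0.99,
    min_shared_sites: int = 5,
) -> list[IBDSegment]:
    """Bin-wise haplotype identity as a simple IBD stand-in.

    For each of the four haplotype combinations of the sample pair, a bin is
    IBD when the fraction of identical calls among sites called in both
    haplotypes reaches ``identity_threshold``; runs of adjacent IBD bins are
    concatenated into segments. Bins with fewer than ``min_shared_sites``
    jointly-called sites are skipped. This binned identity criterion is not
    equivalent to an HMM-based IBD caller (e.g. Beagle fastIBD); externally
    produced segments can be supplied to :func:`nibd` instead.
    """
    s1, s2 = sample_pair
    i1 = dataset.samples.index(s1)
    i2 = dataset.samples.index(s2)
    segments: list[IBDSegment] = []
    for contig, length in dataset.contig_lengths.items():
        csl = dataset.contig_variant_slice(contig)
        pos0 = dataset.positions0(contig)
        n_bins = (length + bin_size - 1) // bin_size
        bin_of_site = pos0 // bin_size
        for h1 in (0, 1):
            for h2 in (0, 1):
                hap1 = dataset.genotypes[i1, csl, h1]
                hap2 = dataset.genotypes[i2, csl, h2]
                shared = (hap1 >= 0) & (hap2 >= 0)
                same = shared & (hap1 == hap2)
                n_shared = np.bincount(bin_of_site[shared], minlength=n_bins)
                n_same = np.bincount(bin_of_site[same], minlength=n_bins)
                with np.errstate(divide="ignore", invalid="ignore"):
                    frac = n_same / n_shared
                ibd = (n_shared >= min_shared_sites) & (frac >= identity_threshold)
                segments.extend(
                    IBDSegment(s1, h1, s2, h2, contig, int(b0 * bin_size),
                               int(min(b1 * bin_size, length)))
                    for b0, b1 in _runs(ibd)
                )
    return segments


def _runs(mask: np.ndarray):
    """Yield (start_bin, end_bin_exclusive) for maximal True runs."""
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    yield from zip(starts, ends)


def nibd(
    segments: list[IBDSegment],
    dataset: GenotypeDataset,
    group1: str,
    group2: str,
    bin_size: int = 20_000,
) -> pd.DataFrame:
    """Normalised IBD per bin: nIBD = cIBD / tIBD.

    cIBD counts cross-group haplotype pairs whose segments fully cover the
    bin; tIBD = (2 n1) * (2 n2) is the total number of cross-group haplotype
    comparisons.
    """
    n1 = dataset.group_indices(group1).size
    n2 = dataset.group_indices(group2).size
    tibd = (2 * n1) * (2 * n2)
    g1_samples = {dataset.samples[i] for i in dataset.group_indices(group1)}
    g2_samples = {dataset.samples[i] for i in dataset.group_indices(group2)}
    rows = []
    for contig, length in dataset.contig_lengths.items():
        n_bins = (length + bin_size - 1) // bin_size
        cibd = np.zeros(n_bins, dtype=np.int64)
        for seg in segments:
            if seg.contig != contig:
                continue
            cross = (seg.sample1 in g1_samples and seg.sample2 in g2_samples) or (
                seg.sample1 in g2_samples and seg.sample2 in g1_samples
            )
            if not cross:
                continue
            # a bin is covered only if the segment spans it entirely
            first = seg.start // bin_size + (0 if seg.start % bin_size == 0 else 1)
            last_end = min(seg.end, length)
            last = last_end // bin_size  # exclusive bin index
            if last_end == length and length % bin_size != 0:
                last = n_bins  # partial terminal bin counts if covered to contig end
            if last > first:
                cibd[first:last] += 1
        for b in range(n_bins):
            rows.append(
                (contig, b * bin_size, min((b + 1) * bin_size, length),
                 int(cibd[b]), cibd[b] / tibd)
            )
    return pd.DataFrame(rows, columns=["contig", "start", "end", "cibd", "nibd"])


def write_ibd_segments(segments: list[IBDSegment], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#sample1\thap1\tsample2\thap2\tcontig\tstart\tend\n")
        for s in segments:
            fh.write(
                f"{s.sample1}\t{s.hap1}\t{s.sample2}\t{s.hap2}\t{s.contig}\t{s.start}\t{s.end}\n"
            )


def read_ibd_segments(path: str) -> list[IBDSegment]:
    out: list[IBDSegment] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            s1, h1, s2, h2, contig, start, end = line.split("\t")[:7]
            out.append(IBDSegment(s1, int(h1), s2, int(h2), contig, int(start), int(end)))
    return out
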