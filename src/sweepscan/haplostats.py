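"""H12 haplotype-homozygosity scan.

H12 = (p1 + p2)^2 + sum_{i>2} p_i^2 over the sorted haplotype-frequency
spectrum of a fixed-size SNP window; pooling the two most frequent haplotypes
makes the statistic sensitive to soft as well as hard sweeps. Windows are
counted in SNPs (default 50) advancing by a fixed SNP step (default 10),
matching the SelectionHapStats scan convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeDataset


@dataclass
class HaplotypeSpectrum:
    """Sorted haplotype frequencies p1 >= p2 >= ... summing to 1."""

    frequencies: np.ndarray
    n_haplotypes: int

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=np.float64)
        if f.size == 0:
            raise ValueError("empty haplotype spectrum")
        if np.any(np.diff(f) > 1e-12):
            raise ValueError("spectrum must be sorted descending")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("spectrum must sum to 1")
        self.frequencies = f


def spectrum_from_haplotypes(haps: np.ndarray) -> HaplotypeSpectrum | None:
    """Build the spectrum from a (n_haps, n_snps) allele matrix.

    Haplotypes containing any missing call are dropped (haplotype identity is
    never imputed). Returns None when no complete haplotype remains.
    """
    complete = haps[(haps >= 0).all(axis=1)]
    if complete.shape[0] == 0:
        return None
    _, counts = np.unique(complete, axis=0, return_counts=True)
    counts = np.sort(counts)[::-1]
    return HaplotypeSpectrum(counts / counts.sum(), int(complete.shape[0]))


def h12(spectrum: HaplotypeSpectrum) -> float:
    """(p1 + p2)^2 + sum_{i>2} p_i^2, with p2 = 0 for a single class."""
    f = spectrum.frequencies
    p1 = f[0]
    p2 = f[1] if f.size > 1 else 0.0
    return float((p1 + p2) ** 2 + (f[2:] ** 2).sum())


def h12_scan(
    dataset: GenotypeDataset,
    group: str,
    window_snps: int = 50,
    step_snps: int = 10,
) -> pd.DataFrame:
    """Per-contig H12 over windows of ``window_snps`` SNPs stepping by ``step_snps``.

    Rows: contig, center_snp_index (within contig), center_pos (1-based bp),
    first_pos, last_pos, group, h12, n_haps. Contigs with fewer SNPs than one
    window produce no rows.
    """
    rows = []
    for contig in dataset.contig_lengths:
        csl = dataset.contig_variant_slice(contig)
        n = csl.stop - csl.start
        if n < window_snps:
            continue
        haps = dataset.haplotypes(group, csl)
        pos = dataset.variants["pos"].to_numpy()[csl]
        for start in range(0, n - window_snps + 1, step_snps):
            win = haps[:, start : start + window_snps]
            spec = spectrum_from_haplotypes(win)
            center = start + window_snps // 2
            rows.append(
                (
                    contig,
                    center,
                    int(pos[center]),
                    int(pos[start]),
                    int(pos[start + window_snps - 1]),
                    group,
                    h12(spec) if spec is not None else np.nan,
                    spec.n_haplotypes if spec is not None else 0,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "center_snp_index",
            "center_pos",
            "first_pos",
            "last_pos",
            "group",
            "h12",
            "n_haps",
        ],
    )


def h12_subsampled(
    dataset: GenotypeDataset,
    domestic_group: str,
    wild_group_size: int,
    reps: int = 10,
    seed: int = 0,
    window_snps: int = 50,
    step_snps: int = 10,
) -> pd.DataFrame:
    """Sample-size-matched H12 for a (larger) domestic group.

    Draws ``reps`` subsamples of ``wild_group_size`` individuals from the
    domestic group and returns the per-window arithmetic mean of the H12
    scans, removing the upward bias a larger sample would otherwise carry
    relative to its wild comparator.
    """
    idx = dataset.group_indices(domestic_group)
    if idx.size < wild_group_size:
        raise ValueError(
            f"domestic group {domestic_group!r} ({idx.size}) is smaller than the wild "
            f"group size ({wild_group_size}); swap the roles of the two groups"
        )
    rng = np.random.default_rng(seed)
    results = []
    for _ in range(reps):
        chosen = np.sort(rng.choice(idx, size=wild_group_size, replace=False))
        sub = _subset_samples(dataset, chosen)
        results.append(h12_scan(sub, domestic_group, window_snps, step_snps))
    out = results[0].copy()
    out["h12"] = np.nanmean(np.stack([r["h12"].to_numpy() for r in results]), axis=0)
    out["n_haps"] = np.stack([r["n_haps"].to_numpy() for r in results]).min(axis=0)
    return out


def _subset_samples(dataset: GenotypeDataset, sample_idx: np.ndarray) -> GenotypeDataset:
    samples = [dataset.samples[i] for i in sample_idx]
    return GenotypeDataset(
        variants=dataset.variants,
        genotypes=dataset.genotypes[sample_idx],
        samples=samples,
        group_of={s: dataset.group_of[s] for s in samples},
        contig_lengths=dataset.contig_lengths,
        phased=dataset.phased,
    )


def region_h12(rows: pd.DataFrame, contig: str, start: int, end: int) -> float:
    """Region summary: max H12 over scan windows centered inside [start, end).

    Centers are compared on the 0-based scale. Returns NaN ("no data") when no
    window center falls inside the region.
    """
    sub = rows[
        (rows["contig"] == contig)
        & (rows["center_pos"] - 1 >= start)
        & (rows["center_pos"] - 1 < end)
    ]
    vals = sub["h12"].dropna()
    if vals.empty:
        return float("nan")
    return float(vals.max())
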