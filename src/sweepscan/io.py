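"""Readers/writers for the formats the scan touches, and the sliding-window grid.

Internal coordinates are 0-based half-open everywhere; conversion to/from the
1-based conventions of VCF and GFF3 happens only at the file boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # allele code for a missing call

GROUPS_CORE = ("CHW", "CHD", "EUW", "EUD")


class ConfigurationError(ValueError):
    """Inconsistent inputs (sample/group bookkeeping, impossible parameters)."""


class FormatError(ValueError):
    """A file that does not conform to the supported dialect."""


@dataclass
class Window:
    """One genomic window, 0-based half-open."""

    contig: str
    start: int
    end: int
    n_variants: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"window end must exceed start: [{self.start}, {self.end})")


@dataclass
class GeneRecord:
    """A gene span (0-based half-open internally)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"


@dataclass
class GenotypeDataset:
    """Phased diploid genotypes with per-variant coordinates and group labels.

    ``genotypes`` has shape (n_samples, n_variants, 2) with allele codes
    0 (REF), 1 (ALT) and -1 (missing). ``variants`` holds columns
    ``contig``, ``pos`` (1-based, as in VCF), ``ref``, ``alt``.
    """

    variants: pd.DataFrame
    genotypes: np.ndarray
    samples: list[str]
    group_of: dict[str, str]
    contig_lengths: dict[str, int]
    phased: bool = True
    n_skipped_records: int = 0
    _group_idx: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.genotypes.shape != (len(self.samples), len(self.variants), 2):
            raise ConfigurationError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing = [s for s in self.samples if s not in self.group_of]
        if missing:
            raise ConfigurationError(f"samples absent from popmap: {missing[:5]}")
        for contig, sub in self.variants.groupby("contig", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise FormatError(f"positions not strictly increasing on {contig}")
        codes = np.unique(self.genotypes)
        bad = codes[(codes != MISSING) & (codes != 0) & (codes != 1)]
        if bad.size:
            raise FormatError(f"allele codes outside {{0,1,missing}}: {bad.tolist()}")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.group_of[s], None)
        return list(seen)

    def group_indices(self, group: str) -> np.ndarray:
        """Sample indices (row numbers in ``genotypes``) belonging to *group*."""
        if group not in self._group_idx:
            idx = np.array(
                [i for i, s in enumerate(self.samples) if self.group_of[s] == group],
                dtype=np.intp,
            )
            if idx.size == 0:
                raise ConfigurationError(f"group {group!r} has no samples")
            self._group_idx[group] = idx
        return self._group_idx[group]

    def contig_variant_slice(self, contig: str) -> slice:
        """Column slice of ``genotypes`` for *contig* (variants are contig-grouped)."""
        mask = (self.variants["contig"] == contig).to_numpy()
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            return slice(0, 0)
        if not np.all(np.diff(idx) == 1):
            raise FormatError(f"variants of contig {contig} are not contiguous")
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def positions0(self, contig: str) -> np.ndarray:
        """0-based positions of the contig's variants."""
        sl = self.contig_variant_slice(contig)
        return self.variants["pos"].to_numpy()[sl] - 1

    def window_variant_slice(self, window: Window) -> slice:
        """Columns (absolute indices) whose 0-based position falls in the window."""
        csl = self.contig_variant_slice(window.contig)
        pos0 = self.variants["pos"].to_numpy()[csl] - 1
        lo = int(np.searchsorted(pos0, window.start, side="left"))
        hi = int(np.searchsorted(pos0, window.end, side="left"))
        return slice(csl.start + lo, csl.start + hi)

    def haplotypes(self, group: str, variant_slice: slice | None = None) -> np.ndarray:
        """(2*n_samples, n_variants) haplotype matrix for *group*; requires phasing."""
        if not self.phased:
            raise ConfigurationError(
                "haplotype-level statistics require phased genotypes; "
                "phase the VCF (e.g. with Beagle) before running this stage"
            )
        idx = self.group_indices(group)
        g = self.genotypes[idx]
        if variant_slice is not None:
            g = g[:, variant_slice]
        # interleave the two haplotypes of each sample
        return g.transpose(0, 2, 1).reshape(2 * idx.size, -1)


# ---------------------------------------------------------------------------
# window grid


def make_windows(
    contig_lengths: dict[str, int], size: int = 20_000, step: int = 10_000
) -> list[Window]:
    """Sliding windows: 20-kb windows advancing in 10-kb steps by default.

    Starts are 0, step, 2*step, ... while start < contig length; the final
    (possibly partial) window is emitted with end clipped to the contig.
    """
    if size <= 0 or step <= 0:
        raise ValueError("window size and step must be positive")
    out: list[Window] = []
    for contig, length in contig_lengths.items():
        start = 0
        while start < length:
            out.append(Window(contig, start, min(start + size, length)))
            start += step
    return out


def count_window_variants(dataset: GenotypeDataset, windows: list[Window]) -> None:
    """Fill ``n_variants`` on each window in place."""
    for w in windows:
        sl = dataset.window_variant_slice(w)
        w.n_variants = sl.stop - sl.start


# ---------------------------------------------------------------------------
# VCF


def read_genotypes(vcf_path: str, popmap_path: str) -> GenotypeDataset:
    """Load a phased multi-sample VCF plus a sample→group map.

    Multiallelic and non-SNP records are skipped (counted, logged). Missing
    alleles are preserved as -1. Every VCF sample must appear in the popmap.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in popmap]
    if absent:
        raise ConfigurationError(
            f"VCF samples missing from popmap {popmap_path}: {absent[:5]}"
        )
    contig_lengths = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}

    rows = []
    genos = []
    phased = True
    n_skipped = 0
    last: dict[str, int] = {}
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise FormatError(f"unsorted VCF: {v.CHROM}:{v.POS} after {last[v.CHROM]}")
        last[v.CHROM] = v.POS
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        gt = np.asarray(v.genotypes, dtype=np.int64)  # (n, 3): a0, a1, phased
        genos.append(gt[:, :2])
        called = gt[:, :2] >= 0
        if np.any(called.all(axis=1) & (gt[:, 2] == 0)):
            phased = False
    if n_skipped:
        log.info("skipped %d multiallelic/non-SNP records", n_skipped)
    variants = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    if genos:
        g = np.stack(genos, axis=1).astype(np.int8)  # (n_samples, n_variants, 2)
        g[g < 0] = MISSING
    else:
        g = np.empty((len(samples), 0, 2), dtype=np.int8)
    if not contig_lengths:
        contig_lengths = {
            c: int(sub["pos"].max()) for c, sub in variants.groupby("contig", sort=False)
        }
    return GenotypeDataset(
        variants=variants,
        genotypes=g,
        samples=samples,
        group_of={s: popmap[s] for s in samples},
        contig_lengths=contig_lengths,
        phased=phased,
        n_skipped_records=n_skipped,
    )


def write_vcf(dataset: GenotypeDataset, path: str) -> None:
    """Emit the dataset as an uncompressed phased VCF 4.2 (biallelic SNPs)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig, length in dataset.contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.samples)
            + "\n"
        )
        sep = "|" if dataset.phased else "/"
        g = dataset.genotypes
        for j, (contig, pos, ref, alt) in enumerate(
            dataset.variants[["contig", "pos", "ref", "alt"]].itertuples(index=False)
        ):
            cols = []
            for i in range(g.shape[0]):
                a, b = int(g[i, j, 0]), int(g[i, j, 1])
                if a < 0 or b < 0:
                    cols.append("./.")
                else:
                    cols.append(f"{a}{sep}{b}")
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(cols) + "\n"
            )


# ---------------------------------------------------------------------------
# small TSV formats


def read_popmap(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: expected 'sample<TAB>group'")
            out[parts[0]] = parts[1]
    return out


def write_popmap(group_of: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tgroup\n")
        for s, g in group_of.items():
            fh.write(f"{s}\t{g}\n")


def read_contig_lengths(path: str) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, length = line.split("\t")[:2]
            out[contig] = int(length)
    return out


def write_contig_lengths(contig_lengths: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#contig\tlength\n")
        for c, n in contig_lengths.items():
            fh.write(f"{c}\t{n}\n")


def write_regions_bed(regions, path: str) -> None:
    """BED (0-based half-open); the name column carries the region class."""
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tclass\n")
        for r in regions:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{r.classification}\n")


def read_gene_annotation(gff_path: str) -> list[GeneRecord]:
    """'gene' features from a GFF3, converted to 0-based half-open spans."""
    genes: list[GeneRecord] = []
    with open(gff_path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{gff_path}:{ln}: expected 9 GFF3 columns, got {len(parts)}")
            contig, _, ftype, start, end, _, strand, _, attrs = parts
            if ftype != "gene":
                continue
            try:
                s1, e1 = int(start), int(end)
            except ValueError as exc:
                raise FormatError(f"{gff_path}:{ln}: non-integer coordinates") from exc
            if e1 < s1:
                raise FormatError(f"{gff_path}:{ln}: end < start")
            gene_id = "NA"
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            genes.append(GeneRecord(gene_id, contig, s1 - 1, e1, strand))
    return genes


def write_gene_annotation(genes: list[GeneRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.contig}\tsweepscan\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )
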