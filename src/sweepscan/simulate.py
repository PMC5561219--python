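"""Synthetic phased cohorts with known per-region selection scenarios.

The generative model is a founder-haplotype pool, not a coalescent: each
region (a 20-kb block) carries K founder haplotypes; ancestral founder
frequencies are drawn from a symmetric Dirichlet and drifted along the
population tree (ancestor → {CHW, EUW}; CHW → CHD; EUW → EUD) with a
Dirichlet analogue of the Balding–Nichols reparameterisation, so a branch
with drift θ produces child frequencies ~ Dirichlet(parent · (1−θ)/θ).
Sweeps raise a chosen founder haplotype to ``sweep_frequency`` in the swept
group(s). This directly induces the allele-frequency (Fst) and
haplotype-homozygosity (H12) signals the scan consumes:

- ``neutral``: domestic frequencies drift only.
- ``uni_introgression``: the founder most common in CHW is swept in BOTH CHD
  and EUD; the ancient sample (AP) draws its haplotypes from the EUW pool —
  the selected haplotype reached EUD by introgression after AP lived.
- ``uni_preintrogression``: the same sweep, but AP draws from the swept EUD
  pool — selection predates the ancient sample.
- ``bidirectional``: distinct founders are swept in CHD and in EUD; the wild
  groups stay intermediate.

AP genotypes are masked at ``ancient_missing_rate`` to emulate a
low-coverage ancient genome.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ConfigurationError,
    GenotypeDataset,
    GeneRecord,
    write_contig_lengths,
    write_gene_annotation,
    write_popmap,
    write_vcf,
)

SCENARIOS = ("neutral", "uni_introgression", "uni_preintrogression", "bidirectional")

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_contigs: int = 2
    contig_length: int = 2_000_000
    region_length: int = 20_000
    snp_density: float = 1.0 / 200.0
    n_regions_per_scenario: dict[str, int] = field(default_factory=dict)
    samples_per_group: dict[str, int] = field(
        default_factory=lambda: {"CHW": 30, "CHD": 30, "EUW": 30, "EUD": 30, "AP": 1}
    )
    founder_haplotypes: int = 8
    founder_concentration: float = 3.0  # Dirichlet α for ancestral founder freqs
    private_variant_rate: float = 0.005  # per-haplotype per-site allele flip
    wild_divergence: float = 0.2  # drift θ on ancestor → CHW / EUW branches
    domestic_divergence: float = 0.05  # drift θ on CHW → CHD / EUW → EUD branches
    sweep_frequency: float = 0.98
    ancient_missing_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs <= 0 or self.contig_length <= 0 or self.region_length <= 0:
            raise ConfigurationError("counts and lengths must be positive")
        if self.founder_haplotypes < 2:
            raise ConfigurationError("need at least 2 founder haplotypes")
        if not 0.0 <= self.wild_divergence < 1.0 or not 0.0 <= self.domestic_divergence < 1.0:
            raise ConfigurationError("divergence parameters must lie in [0, 1)")
        if not 0.8 < self.sweep_frequency <= 1.0:
            raise ConfigurationError("sweep_frequency must lie in (0.8, 1.0]")
        if not 0.0 <= self.ancient_missing_rate <= 1.0:
            raise ConfigurationError("ancient_missing_rate must lie in [0, 1]")
        if not 0.0 <= self.private_variant_rate < 0.5:
            raise ConfigurationError("private_variant_rate must lie in [0, 0.5)")
        unknown = set(self.n_regions_per_scenario) - set(SCENARIOS)
        if unknown:
            raise ConfigurationError(f"unknown scenarios: {sorted(unknown)}")
        for g in ("CHW", "CHD", "EUW", "EUD"):
            if self.samples_per_group.get(g, 0) <= 0:
                raise ConfigurationError(f"group {g} needs at least one sample")
        blocks = self.n_contigs * (self.contig_length // self.region_length)
        wanted = sum(self.n_regions_per_scenario.values())
        if wanted > blocks:
            raise ConfigurationError(
                f"{wanted} regions requested but only {blocks} blocks of "
                f"{self.region_length} bp fit on {self.n_contigs} contigs"
            )

    @property
    def snps_per_region(self) -> int:
        return max(1, round(self.region_length * self.snp_density))


def _drift(rng: np.random.Generator, parent: np.ndarray, theta: float) -> np.ndarray:
    if theta <= 0.0:
        return parent.copy()
    alpha = np.maximum(parent * (1.0 - theta) / theta, 1e-9)
    return rng.dirichlet(alpha)


def _sweep(freq: np.ndarray, fav: int, s: float) -> np.ndarray:
    out = freq.copy()
    rest = 1.0 - out[fav]
    if rest <= 0.0:
        out[:] = 0.0
        out[fav] = 1.0
        return out
    out *= (1.0 - s) / rest
    out[fav] = s
    return out


def simulate_cohort(config: SimulationConfig) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Generate a phased cohort plus its truth table.

    Contigs are tiled into region_length blocks; the requested scenario
    regions are placed on randomly chosen blocks (non-overlapping by
    construction) and all remaining blocks evolve neutrally as background.
    The truth table lists only the requested regions, with columns contig,
    start, end (0-based half-open), scenario, fav_chd, fav_eud (founder ids,
    -1 for none). Each block uses a sub-stream seeded by (seed, block index),
    so identical seed + config give identical output.
    """
    root = np.random.default_rng(config.seed)
    blocks_per_contig = config.contig_length // config.region_length
    n_blocks = config.n_contigs * blocks_per_contig
    contigs = [f"chr{i + 1}" for i in range(config.n_contigs)]
    contig_lengths = {c: config.contig_length for c in contigs}

    labels = np.array(["background"] * n_blocks, dtype=object)
    wanted = [
        (scen, count)
        for scen in SCENARIOS
        for count in [config.n_regions_per_scenario.get(scen, 0)]
        if count > 0
    ]
    total = sum(c for _, c in wanted)
    chosen = root.choice(n_blocks, size=total, replace=False)
    k = 0
    for scen, count in wanted:
        labels[chosen[k : k + count]] = scen
        k += count

    group_order = [g for g in ("CHW", "CHD", "EUW", "EUD", "AP") if config.samples_per_group.get(g, 0) > 0]
    n_of = {g: config.samples_per_group[g] for g in group_order}
    samples = [f"{g}_{i:03d}" for g in group_order for i in range(n_of[g])]
    group_of = {s: s.rsplit("_", 1)[0] for s in samples}

    var_rows = []
    geno_blocks = []
    truth_rows = []
    K = config.founder_haplotypes
    m = config.snps_per_region
    for b in range(n_blocks):
        contig = contigs[b // blocks_per_contig]
        block_start = (b % blocks_per_contig) * config.region_length
        rng = np.random.default_rng([config.seed, b])
        scen = labels[b]

        pos0 = np.sort(rng.choice(config.region_length, size=m, replace=False)) + block_start
        founders = rng.integers(0, 2, size=(K, m)).astype(np.int8)
        ref_idx = rng.integers(0, 4, size=m)
        alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4

        anc = rng.dirichlet(np.full(K, config.founder_concentration))
        chw = _drift(rng, anc, config.wild_divergence)
        euw = _drift(rng, anc, config.wild_divergence)
        chd = _drift(rng, chw, config.domestic_divergence)
        eud = _drift(rng, euw, config.domestic_divergence)

        fav_chd = fav_eud = -1
        ap_pool = euw
        if scen in ("uni_introgression", "uni_preintrogression"):
            # the favoured haplotype is a random draw from the Chinese wild
            # pool: the lineage early domestication happened to pick up
            fav = int(rng.choice(K, p=chw))
            chd = _sweep(chd, fav, config.sweep_frequency)
            eud = _sweep(eud, fav, config.sweep_frequency)
            fav_chd = fav_eud = fav
            ap_pool = eud if scen == "uni_preintrogression" else euw
        elif scen == "bidirectional":
            fav_chd = int(rng.choice(K, p=chd))
            eud_excl = eud.copy()
            eud_excl[fav_chd] = 0.0
            eud_excl /= eud_excl.sum()
            fav_eud = int(rng.choice(K, p=eud_excl))
            chd = _sweep(chd, fav_chd, config.sweep_frequency)
            eud = _sweep(eud, fav_eud, config.sweep_frequency)

        pools = {"CHW": chw, "CHD": chd, "EUW": euw, "EUD": eud, "AP": ap_pool}
        block_geno = np.empty((len(samples), m, 2), dtype=np.int8)
        row = 0
        for g in group_order:
            n = n_of[g]
            hap_idx = rng.choice(K, size=2 * n, p=pools[g])
            haps = founders[hap_idx]  # (2n, m)
            block_geno[row : row + n] = haps.reshape(n, 2, m).transpose(0, 2, 1)
            row += n
        if config.private_variant_rate > 0.0:
            # private singleton variation, as in any resequencing cohort;
            # keeps swept windows from collapsing to literal monomorphism
            flip = rng.random(block_geno.shape) < config.private_variant_rate
            block_geno = np.where(flip, 1 - block_geno, block_geno).astype(np.int8)
        if "AP" in group_order and config.ancient_missing_rate > 0.0:
            ap_row = samples.index(f"AP_{0:03d}")
            miss = rng.random(m) < config.ancient_missing_rate
            block_geno[ap_row, miss, :] = -1

        geno_blocks.append(block_geno)
        for j in range(m):
            var_rows.append(
                (contig, int(pos0[j]) + 1, _BASES[ref_idx[j]], _BASES[alt_idx[j]])
            )
        if scen != "background":
            truth_rows.append(
                (contig, block_start, block_start + config.region_length, scen, fav_chd, fav_eud)
            )

    dataset = GenotypeDataset(
        variants=pd.DataFrame(var_rows, columns=["contig", "pos", "ref", "alt"]),
        genotypes=np.concatenate(geno_blocks, axis=1),
        samples=samples,
        group_of=group_of,
        contig_lengths=contig_lengths,
        phased=True,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["contig", "start", "end", "scenario", "fav_chd", "fav_eud"]
    ).sort_values(["contig", "start"], ignore_index=True)
    return dataset, truth


def write_fixture(
    dataset: GenotypeDataset,
    truth: pd.DataFrame,
    out_dir: str,
    gene_offset: int = 0,
) -> dict[str, str]:
    """Write cohort.vcf, popmap.tsv, truth.tsv, contigs.tsv and genes.gff3.

    One toy gene per truth region is placed at ``gene_offset`` bp downstream
    of the region end (0 = overlapping the region end), for the gene-proximity
    annotation tests.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vcf": os.path.join(out_dir, "cohort.vcf"),
        "popmap": os.path.join(out_dir, "popmap.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "contigs": os.path.join(out_dir, "contigs.tsv"),
        "gff": os.path.join(out_dir, "genes.gff3"),
    }
    write_vcf(dataset, paths["vcf"])
    write_popmap(dataset.group_of, paths["popmap"])
    truth.to_csv(paths["truth"], sep="\t", index=False)
    write_contig_lengths(dataset.contig_lengths, paths["contigs"])
    genes = []
    for i, r in truth.iterrows():
        start = min(int(r["end"]) - 1 + gene_offset, dataset.contig_lengths[r["contig"]] - 1000)
        genes.append(
            GeneRecord(f"gene{i:04d}_{r['scenario']}", r["contig"], start, start + 1000, "+")
        )
    write_gene_annotation(genes, paths["gff"])
    return paths


def read_truth(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def score_against_truth(regions, truth: pd.DataFrame) -> pd.DataFrame:
    """For each truth region, the classification of overlapping called regions.

    Adds a ``called`` column: the most specific classification among regions
    overlapping the truth span ('none' when nothing overlaps).
    """
    rank = {"unidirectional": 3, "bidirectional": 3, "common": 2, "candidate": 1}
    called = []
    for r in truth.itertuples(index=False):
        best, best_rank = "none", 0
        for reg in regions:
            if reg.contig == r.contig and reg.start < r.end and r.start < reg.end:
                if rank.get(reg.classification, 0) > best_rank:
                    best, best_rank = reg.classification, rank[reg.classification]
        called.append(best)
    out = truth.copy()
    out["called"] = called
    return out
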