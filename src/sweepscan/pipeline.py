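"""End-to-end orchestration: scan → candidate regions → permutation filter →
H12 filter → uni/bi split → ancient-genome classification → annotation.

Every stage writes a self-describing TSV/BED artifact into the output
directory and the run ends with a JSON summary of class counts and
parameters. All randomness flows from the single configured seed.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .haplostats import h12_scan, h12_subsampled
from .identity import NOT_APPLICABLE, classify_ancient, region_identity_score
from .io import (
    GenotypeDataset,
    make_windows,
    read_contig_lengths,
    read_gene_annotation,
    read_genotypes,
    write_regions_bed,
)
from .regions import (
    BIDIRECTIONAL,
    COMMON,
    REJECTED,
    UNIDIRECTIONAL,
    SelectedRegion,
    annotate_genes,
    call_candidate_windows,
    deg_proximity_enrichment,
    intersect_common,
    merge_windows_to_regions,
    permutation_test,
    regions_to_frame,
    split_uni_bi,
)
from .windowstats import contrast_table

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained in outdir."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    vcf: str = ""
    popmap: str = ""
    contigs: str = ""
    gff: str | None = None
    deg_table: str | None = None
    outdir: str = "sweepscan_out"
    # which popmap labels play each role; AP may be None (no ancient sample)
    groups: dict[str, str | None] = field(
        default_factory=lambda: {"CHW": "CHW", "CHD": "CHD", "EUW": "EUW", "EUD": "EUD", "AP": "AP"}
    )
    window_size: int = 20_000
    window_step: int = 10_000
    min_snps: int = 10
    z_threshold: float = 2.0
    uni_threshold: float = -1.0
    bi_threshold: float = 2.0
    z_summary: str = "mean"
    n_perm: int = 1000
    perm_p_threshold: float = 0.01
    perm_rule: str = "max"
    h12_window_snps: int = 50
    h12_step_snps: int = 10
    h12_reps: int = 10
    ancient_margin: float = 0.1
    gene_dist: int = 20_000
    deg_dmin: int = 20_000
    deg_dmax: int = 250_000
    tajima: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key {k!r}")
            setattr(cfg, k, v)
        return cfg


@dataclass
class PipelineResult:
    summary: dict
    regions: list[SelectedRegion]
    tables: dict[str, pd.DataFrame]
    h12_by_group: dict[str, pd.DataFrame]


def _derived_seed(seed: int, *path: int) -> int:
    return int(np.random.SeedSequence([seed, *path]).generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig, dataset: GenotypeDataset | None = None) -> PipelineResult:
    """Run the full scan; writes artifacts and returns the result bundle."""
    stage = "setup"
    try:
        return _run(config, dataset)
    except StageError:
        raise
    except BaseException as exc:  # noqa: BLE001 - re-raise with stage context
        stage = getattr(exc, "_sweepscan_stage", stage)
        raise StageError(stage, exc) from exc


def _run(config: PipelineConfig, dataset: GenotypeDataset | None) -> PipelineResult:
    os.makedirs(config.outdir, exist_ok=True)
    stage = "load"
    try:
        if dataset is None:
            dataset = read_genotypes(config.vcf, config.popmap)
            if config.contigs:
                dataset.contig_lengths = read_contig_lengths(config.contigs)
        roles = {k: v for k, v in config.groups.items() if v}
        for role in ("CHW", "CHD", "EUW", "EUD"):
            if role not in roles:
                raise ValueError(f"group mapping must cover role {role}")

        stage = "scan"
        windows = make_windows(dataset.contig_lengths, config.window_size, config.window_step)
        chw, chd, euw, eud = (roles[r] for r in ("CHW", "CHD", "EUW", "EUD"))
        contrasts = {
            "CHD_vs_CHW": (chd, chw),
            "EUD_vs_EUW": (eud, euw),
            "CHD_vs_EUD": (chd, eud),
        }
        tables: dict[str, pd.DataFrame] = {}
        for name, pair in contrasts.items():
            tables[name] = contrast_table(
                dataset, pair, windows, min_snps=config.min_snps, tajima=config.tajima
            )
            tables[name].to_csv(
                os.path.join(config.outdir, f"fst_{name}.tsv"),
                sep="\t", index=False, float_format="%.6g",
            )

        stage = "call-regions"
        chd_cand = merge_windows_to_regions(
            call_candidate_windows(tables["CHD_vs_CHW"], config.z_threshold)
        )
        eud_cand = merge_windows_to_regions(
            call_candidate_windows(tables["EUD_vs_EUW"], config.z_threshold)
        )
        common = intersect_common(chd_cand, eud_cand)
        log.info("candidates: %d (CHD), %d (EUD); common: %d",
                 len(chd_cand), len(eud_cand), len(common))

        stage = "permutation"
        for i, region in enumerate(common):
            res = permutation_test(
                dataset, region, [(chd, chw), (eud, euw)],
                n_perm=config.n_perm,
                seed=_derived_seed(config.seed, 1, i),
                rule=config.perm_rule,
            )
            region.perm_p = res.p
            if res.p >= config.perm_p_threshold:
                region.classification = REJECTED
        passing = [r for r in common if r.classification == COMMON]
        log.info("permutation filter: %d of %d regions pass", len(passing), len(common))

        stage = "h12"
        wild_sizes = {g: dataset.group_indices(g).size for g in (chw, euw)}
        h12_by_group: dict[str, pd.DataFrame] = {
            wild: h12_scan(dataset, wild, config.h12_window_snps, config.h12_step_snps)
            for wild in (chw, euw)
        }
        for dom, wild in ((chd, chw), (eud, euw)):
            if dataset.group_indices(dom).size > wild_sizes[wild]:
                h12_by_group[dom] = h12_subsampled(
                    dataset, dom, wild_sizes[wild],
                    reps=config.h12_reps,
                    seed=_derived_seed(config.seed, 2),
                    window_snps=config.h12_window_snps,
                    step_snps=config.h12_step_snps,
                )
            else:
                h12_by_group[dom] = h12_scan(
                    dataset, dom, config.h12_window_snps, config.h12_step_snps
                )
        for label, rows in h12_by_group.items():
            rows.to_csv(os.path.join(config.outdir, f"h12_{label}.tsv"),
                        sep="\t", index=False, float_format="%.6g")

        stage = "classify"
        split_uni_bi(
            passing, tables["CHD_vs_EUD"], h12_by_group,
            uni_threshold=config.uni_threshold,
            bi_threshold=config.bi_threshold,
            z_summary=config.z_summary,
            roles={"CHW": chw, "CHD": chd, "EUW": euw, "EUD": eud},
        )

        stage = "ancient"
        ap = roles.get("AP")
        if ap is not None and ap in dataset.groups:
            freq_cache: dict[str, np.ndarray] = {}
            for region in passing:
                if region.classification != UNIDIRECTIONAL:
                    continue
                member = region.windows_in_extent()
                region.is_ap_chd = region_identity_score(dataset, ap, chd, member, freq_cache)
                region.is_ap_euw = region_identity_score(dataset, ap, euw, member, freq_cache)
                region.ancient_call = classify_ancient(
                    region.is_ap_chd, region.is_ap_euw, config.ancient_margin
                )
        else:
            for region in passing:
                region.ancient_call = NOT_APPLICABLE

        stage = "annotate"
        gene_hits: dict[str, list[str]] = {}
        enrichment = None
        if config.gff:
            genes = read_gene_annotation(config.gff)
            interesting = [
                r for r in passing if r.classification in (UNIDIRECTIONAL, BIDIRECTIONAL)
            ]
            hits = annotate_genes(interesting, genes, config.gene_dist)
            gene_hits = {
                f"{interesting[i].contig}:{interesting[i].start}-{interesting[i].end}":
                    [g.gene_id for g in gs]
                for i, gs in hits.items()
            }
            if config.deg_table:
                deg = pd.read_csv(config.deg_table, sep="\t", comment="#", header=None,
                                  names=["gene_id", "is_deg"])
                flags = dict(zip(deg["gene_id"], deg["is_deg"].astype(bool)))
                bi = [r for r in passing if r.classification == BIDIRECTIONAL]
                count, chi2, p = deg_proximity_enrichment(
                    bi, genes, flags, config.deg_dmin, config.deg_dmax
                )
                enrichment = {"deg_in_zone": count, "chi2": chi2, "p": p}

        stage = "report"
        frame = regions_to_frame(common)
        frame.to_csv(os.path.join(config.outdir, "regions.tsv"),
                     sep="\t", index=False, float_format="%.6g")
        write_regions_bed(common, os.path.join(config.outdir, "regions.bed"))
        counts = frame["classification"].value_counts().to_dict() if len(frame) else {}
        ancient_counts = (
            frame.loc[frame["classification"] == UNIDIRECTIONAL, "ancient_call"]
            .value_counts().to_dict()
            if len(frame) else {}
        )
        summary = {
            "version": __version__,
            "parameters": asdict(config),
            "n_windows": len(windows),
            "n_candidate_regions": {"CHD": len(chd_cand), "EUD": len(eud_cand)},
            "n_common_regions": len(common),
            "n_permutation_passing": len(passing),
            "class_counts": counts,
            "ancient_call_counts": ancient_counts,
            "gene_hits": gene_hits,
            "deg_enrichment": enrichment,
        }
        with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return PipelineResult(summary, common, tables, h12_by_group)
    except BaseException as exc:
        exc._sweepscan_stage = stage  # noqa: SLF001 - carried to run_pipeline's wrapper
        raise
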