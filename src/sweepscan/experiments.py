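"""Reproducible evaluation experiments on synthetic cohorts.

Two standard experiments back the package's validation story:

- :func:`permutation_calibration` checks that the region permutation test is
  calibrated: on a genome where domestic and wild groups are drawn from the
  same pool (exchangeable labels), the fraction of neutral regions reaching
  p < 0.01 should be compatible with the nominal level.
- :func:`recovery_experiment` runs the full scan on a genome with implanted
  unidirectional/bidirectional sweeps and scores the calls against the truth
  table, including the ancient-genome introgression calls.
"""

from __future__ import annotations

import tempfile

import numpy as np

from .pipeline import PipelineConfig, run_pipeline
from .regions import SelectedRegion, permutation_test
from .simulate import SimulationConfig, simulate_cohort

ANCIENT_EXPECTED = {
    "uni_introgression": "introgression_then_selection",
    "uni_preintrogression": "pre_introgression_selection",
}


def permutation_calibration(
    seed: int,
    n_regions: int = 200,
    n_perm: int = 1000,
    samples_per_group: int = 30,
) -> dict:
    """Permutation p-values on neutral regions with exchangeable labels.

    The cohort is simulated with zero domestic-branch drift so that each
    domestic group is statistically identical to its wild counterpart — the
    null hypothesis of the permutation test holds exactly.
    """
    cfg = SimulationConfig(
        n_contigs=2,
        contig_length=n_regions // 2 * 20_000,
        n_regions_per_scenario={"neutral": n_regions},
        samples_per_group={
            "CHW": samples_per_group,
            "CHD": samples_per_group,
            "EUW": samples_per_group,
            "EUD": samples_per_group,
            "AP": 1,
        },
        domestic_divergence=0.0,
        seed=seed,
    )
    dataset, truth = simulate_cohort(cfg)
    pvals = []
    for i, r in enumerate(truth.itertuples(index=False)):
        region = SelectedRegion(r.contig, int(r.start), int(r.end))
        res = permutation_test(
            dataset,
            region,
            [("CHD", "CHW"), ("EUD", "EUW")],
            n_perm=n_perm,
            seed=int(np.random.SeedSequence([seed, 91, i]).generate_state(1)[0] % (2**31)),
        )
        pvals.append(res.p)
    pvals = np.asarray(pvals)
    return {
        "pvals": pvals,
        "fraction_below_001": float((pvals < 0.01).mean()),
        "n_regions": int(n_regions),
    }


def recovery_config(seed: int) -> SimulationConfig:
    """The standard recovery scenario: 2x2 Mb, 30 samples/group, 30 sweeps."""
    return SimulationConfig(
        n_contigs=2,
        contig_length=2_000_000,
        n_regions_per_scenario={
            "uni_introgression": 10,
            "uni_preintrogression": 10,
            "bidirectional": 10,
            "neutral": 50,
        },
        samples_per_group={"CHW": 30, "CHD": 30, "EUW": 30, "EUD": 30, "AP": 1},
        sweep_frequency=0.98,
        ancient_missing_rate=0.3,
        seed=seed,
    )


def recovery_experiment(seeds, outdir: str | None = None, n_perm: int = 1000) -> dict:
    """Run the full pipeline on implanted sweeps and score against truth.

    Returns per-scenario recovery rates, the neutral false-call rate, and the
    accuracy of the ancient-genome calls among correctly-called
    unidirectional regions.
    """
    counts = {
        "uni": 0, "uni_n": 0, "bi": 0, "bi_n": 0, "neutral_false": 0, "neutral_n": 0,
        "ancient_ok": 0, "ancient_n": 0,
    }
    for seed in seeds:
        dataset, truth = simulate_cohort(recovery_config(seed))
        with tempfile.TemporaryDirectory() as tmp:
            cfg = PipelineConfig(outdir=outdir or tmp, n_perm=n_perm, seed=seed)
            result = run_pipeline(cfg, dataset=dataset)
        from .simulate import score_against_truth

        scored = score_against_truth(result.regions, truth)
        uni = scored["scenario"].str.startswith("uni")
        bi = scored["scenario"] == "bidirectional"
        neu = scored["scenario"] == "neutral"
        counts["uni"] += int((scored.loc[uni, "called"] == "unidirectional").sum())
        counts["uni_n"] += int(uni.sum())
        counts["bi"] += int((scored.loc[bi, "called"] == "bidirectional").sum())
        counts["bi_n"] += int(bi.sum())
        counts["neutral_false"] += int(
            scored.loc[neu, "called"].isin(["unidirectional", "bidirectional"]).sum()
        )
        counts["neutral_n"] += int(neu.sum())
        for region in result.regions:
            if region.classification != "unidirectional":
                continue
            hit = truth[
                (truth["contig"] == region.contig)
                & (truth["start"] < region.end)
                & (region.start < truth["end"])
                & truth["scenario"].str.startswith("uni")
            ]
            if hit.empty:
                continue
            counts["ancient_n"] += 1
            expected = ANCIENT_EXPECTED[hit["scenario"].iloc[0]]
            counts["ancient_ok"] += int(region.ancient_call == expected)
    return {
        "uni_recovery": counts["uni"] / counts["uni_n"],
        "bi_recovery": counts["bi"] / counts["bi_n"],
        "neutral_false_rate": counts["neutral_false"] / counts["neutral_n"],
        "ancient_call_accuracy": (
            counts["ancient_ok"] / counts["ancient_n"] if counts["ancient_n"] else float("nan")
        ),
        "counts": counts,
        "n_seeds": len(list(seeds)),
    }
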