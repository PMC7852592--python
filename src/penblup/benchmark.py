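"""End-to-end benchmark of the simulation study's headline quantities.

One call of :func:`run_study_benchmark` simulates replicates of the nucleus
population design and recomputes, from scratch:

* mean AI-REML additive variance of the group-recorded trait (pedigree,
  univariate, scenario S12_L2x3) at full population scale;
* mean Valid_R accuracies of univariate pedigree BLUP from group and
  individual records (S12_L2x3), and from group records under the S12_Lran
  and S24_L2x3 grouping scenarios;
* mean Valid_R / Valid_nR accuracies of the bivariate model combining
  trait-1 group records with trait-2 individual records, for generating
  genetic correlations 0.8 and 0.5;
* mean AI-REML pen covariance of the bivariate mixed-record model (with the
  cross-record residual covariance structurally excluded), run on a
  quarter-scale nucleus where the record-level covariance stays tractable --
  the pen-covariance inflation it measures is a structural artifact
  (approximately the residual covariance divided by the mean pen size) and
  does not depend on the nucleus size.

Genome simulation uses the QTL-only map: marker panels play no role in any
pedigree-based analysis.  One genome/pedigree simulation is shared by all
grouping scenarios and both genetic-correlation variants of a replicate;
pens, environmental effects and phenotypes are redrawn per scenario.
"""

from __future__ import annotations

import numpy as np

from .evaluation import fit_cell, score_results, validation_subsets
from .model import AnimalModel
from .simulate import (
    PopulationDesign,
    ScenarioConfig,
    assign_trait_architecture,
    build_dataset,
    simulate_genome,
)
from .varcomp import RemlOptions

BENCHMARK_KEYS = (
    "reml_group_additive_variance",
    "acc_group_S12_L2x3",
    "acc_individual_S12_L2x3",
    "acc_group_S12_Lran",
    "acc_group_S24_L2x3",
    "acc_bivariate_validR",
    "acc_bivariate_validnR",
    "reml_bivariate_pen_covariance",
    "acc_bivariate_rg05_validR",
)


def _reml_options() -> RemlOptions:
    # benchmark runs use looser tolerances and a hard iteration cap: the
    # reported components are stable to ~0.01 after a dozen AI iterations,
    # far below the replicate spread they are averaged over
    return RemlOptions(max_iter=25, tol_param=1e-5, tol_grad=1e-2)


def run_study_benchmark(
    seed: int,
    n_replicates: int = 10,
    reml_replicates: int | None = None,
    progress: bool = False,
) -> dict:
    """Recompute the study's headline numbers; returns
    ``{key: {"value": mean over replicates, "n": replicate count}}``."""
    reml_replicates = reml_replicates or n_replicates
    root = np.random.SeedSequence(seed)
    full_seqs = root.spawn(n_replicates)
    small_seqs = root.spawn(reml_replicates)
    design = PopulationDesign()
    acc = {k: [] for k in BENCHMARK_KEYS}
    uni_start = None  # REML warm starts carried across replicates
    biv_start = None

    for rep, seq in enumerate(full_seqs):
        rng = np.random.default_rng(seq)
        sim = simulate_genome(design, rng, genome="qtl_only")
        qtl_ref = sim.population.dosages()[sim.pedigree.generation == 0][
            :, sim.gmap.is_qtl
        ]
        arch08 = assign_trait_architecture(qtl_ref, 0.8, rng=rng)
        arch05 = assign_trait_architecture(qtl_ref, 0.5, rng=rng)

        cfg = ScenarioConfig(grouping="S12_L2x3", genetic_correlation=0.8, seed=0)
        ds = build_dataset(sim, cfg, rng, design=design, architecture=arch08)
        subs = validation_subsets(ds.phenotypes, ds.genotyped_30, 8)
        val = subs["All"]
        res, _ = fit_cell(ds, "uni_group")
        acc["acc_group_S12_L2x3"].append(score_results(res, ds.phenotypes, val, "y1")[0])
        res, _ = fit_cell(ds, "uni_individual")
        acc["acc_individual_S12_L2x3"].append(
            score_results(res, ds.phenotypes, val, "y1")[0]
        )
        res, _ = fit_cell(ds, "biv_group")
        acc["acc_bivariate_validR"].append(score_results(res, ds.phenotypes, val, "y1")[0])
        res, _ = fit_cell(ds, "biv_group", record_state="Valid_nR")
        acc["acc_bivariate_validnR"].append(
            score_results(res, ds.phenotypes, val, "y1")[0]
        )
        # univariate group-record AI-REML at full scale (V has ~1200 rows);
        # warm-started from the previous replicate's estimates (replicates
        # are exchangeable, so this only saves iterations)
        model = AnimalModel(
            ds.pedigree,
            ds.phenotypes,
            traits=("y1",),
            record_modes={"y1": "group"},
            groups=ds.groups,
        )
        fit = model.fit_reml(start=uni_start, options=_reml_options())
        uni_start = fit.components
        acc["reml_group_additive_variance"].append(fit.components.additive[0, 0])

        for grouping, key in (
            ("S12_Lran", "acc_group_S12_Lran"),
            ("S24_L2x3", "acc_group_S24_L2x3"),
        ):
            cfg_g = ScenarioConfig(grouping=grouping, genetic_correlation=0.8, seed=0)
            ds_g = build_dataset(sim, cfg_g, rng, design=design, architecture=arch08)
            subs_g = validation_subsets(ds_g.phenotypes, ds_g.genotyped_30, 8)
            res, _ = fit_cell(ds_g, "uni_group")
            acc[key].append(
                score_results(res, ds_g.phenotypes, subs_g["All"], "y1")[0]
            )

        cfg5 = ScenarioConfig(grouping="S12_L2x3", genetic_correlation=0.5, seed=0)
        ds5 = build_dataset(sim, cfg5, rng, design=design, architecture=arch05)
        subs5 = validation_subsets(ds5.phenotypes, ds5.genotyped_30, 8)
        res, _ = fit_cell(ds5, "biv_group")
        acc["acc_bivariate_rg05_validR"].append(
            score_results(res, ds5.phenotypes, subs5["All"], "y1")[0]
        )
        if progress:
            print(f"full-scale replicate {rep + 1}/{n_replicates} done")

    # quarter-scale replicates for the bivariate mixed-record AI-REML
    small_design = PopulationDesign.quarter_scale()
    for rep, seq in enumerate(small_seqs):
        rng = np.random.default_rng(seq)
        sim = simulate_genome(small_design, rng, genome="qtl_only")
        cfg = ScenarioConfig(grouping="S12_L2x3", genetic_correlation=0.8, seed=0)
        ds = build_dataset(sim, cfg, rng, design=small_design)
        model = AnimalModel(
            ds.pedigree,
            ds.phenotypes,
            traits=("y1", "y2"),
            record_modes={"y1": "group"},
            groups=ds.groups,
        )
        fit = model.fit_reml(start=biv_start, options=_reml_options())
        biv_start = fit.components
        acc["reml_bivariate_pen_covariance"].append(fit.components.pen[0, 1])
        if progress:
            print(f"quarter-scale REML replicate {rep + 1}/{reml_replicates} done")

    out = {}
    for k, vals in acc.items():
        out[k] = {"value": float(np.mean(vals)), "n": len(vals)}
    return out
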