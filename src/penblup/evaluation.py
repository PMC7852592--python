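"""Scoring of estimated against true breeding values and experiment driving.

Accuracy is the Pearson correlation between EBV and true BV over a validation
set; bias is the ordinary least-squares regression slope of true BV on EBV
(1 = dispersion-unbiased).  Validation uses the last generation, either with
its records kept in the data (Valid_R) or removed before fitting (Valid_nR),
and three animal subsets: all validation animals, those genotyped under the
30% genotyping design (Group I) and the rest (Group II).  Group membership is
frozen per replicate so every genotyping design scores identical animal sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import AnimalModel
from .simulate import (
    Dataset,
    PopulationDesign,
    ScenarioConfig,
    build_dataset,
    simulate_genome,
)

RECORD_STATES = ("Valid_R", "Valid_nR")
SUBSETS = ("All", "GroupI", "GroupII")

MODEL_CELLS = {
    # cell -> (traits, record modes)
    "uni_group": (("y1",), {"y1": "group"}),
    "uni_individual": (("y1",), {}),
    "uni_trait2": (("y2",), {}),
    "biv_group": (("y1", "y2"), {"y1": "group"}),
    "biv_individual": (("y1", "y2"), {}),
}

GENOTYPING_RELATIONSHIP = {0: "pedigree", 30: "single-step", 100: "genomic"}


def accuracy(ebv: np.ndarray, tbv: np.ndarray) -> float:
    """Pearson correlation of EBV with true BV; NaN (with a warning) when
    either vector is constant."""
    ebv = np.asarray(ebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if len(ebv) != len(tbv) or len(ebv) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(ebv) == 0 or np.std(tbv) == 0:
        warnings.warn("zero variance in EBV or TBV: accuracy undefined")
        return np.nan
    return float(np.corrcoef(ebv, tbv)[0, 1])


def bias_regression(tbv: np.ndarray, ebv: np.ndarray) -> float:
    """OLS slope of true BV on EBV."""
    ebv = np.asarray(ebv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    v = np.var(ebv, ddof=1)
    if v == 0:
        warnings.warn("zero variance in EBV: bias slope undefined")
        return np.nan
    return float(np.cov(tbv, ebv)[0, 1] / v)


@dataclass(frozen=True)
class ValidationPlan:
    """One scoring cell: record state x animal subset of the validation
    generation."""

    record_state: str  # Valid_R | Valid_nR
    subset: str  # All | GroupI | GroupII

    def __post_init__(self) -> None:
        if self.record_state not in RECORD_STATES:
            raise ValueError(f"unknown record state {self.record_state!r}")
        if self.subset not in SUBSETS:
            raise ValueError(f"unknown subset {self.subset!r}")


def validation_subsets(
    phenotypes: pd.DataFrame,
    genotyped_30: np.ndarray | None,
    validation_generation: int = 8,
) -> dict[str, np.ndarray]:
    """Ids per subset (All / GroupI / GroupII) among the post-attrition
    validation-generation animals."""
    val = phenotypes[
        phenotypes["has_record"]
        & (phenotypes["generation"] == validation_generation)
    ]["id"].to_numpy()
    if genotyped_30 is None:
        genotyped_30 = np.array([], dtype=val.dtype)
    g1 = np.intersect1d(val, genotyped_30)
    g2 = np.setdiff1d(val, g1)
    return {"All": np.sort(val), "GroupI": g1, "GroupII": g2}


def remove_validation_records(
    phenotypes: pd.DataFrame, validation_generation: int = 8
) -> pd.DataFrame:
    """Valid_nR data state: all records (both traits) of the validation
    generation are removed before fitting; the animals keep their pedigree
    links and still receive EBVs."""
    out = phenotypes.copy()
    out.loc[out["generation"] == validation_generation, "has_record"] = False
    return out


def score_results(
    results,
    phenotypes: pd.DataFrame,
    ids: np.ndarray,
    trait: str = "y1",
) -> tuple[float, float]:
    """(accuracy, bias slope) of ``results.ebv`` against the simulated true
    BVs for the given animals."""
    tbv_col = "tbv" + trait[-1]
    ph = phenotypes.set_index("id")
    ebv = results.ebv.set_index("id")[trait]
    common = np.asarray(ids)
    e = ebv.loc[common].to_numpy()
    t = ph.loc[common, tbv_col].to_numpy()
    return accuracy(e, t), bias_regression(t, e)


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------


def fit_cell(
    dataset: Dataset,
    cell: str,
    genotyping: int = 0,
    record_state: str = "Valid_R",
    validation_generation: int = 8,
):
    """Fit one model cell on one dataset and return its BLUPResults."""
    traits, modes = MODEL_CELLS[cell]
    pheno = dataset.phenotypes
    if record_state == "Valid_nR":
        pheno = remove_validation_records(pheno, validation_generation)
    trait_idx = [int(t[-1]) - 1 for t in traits]
    comps = (
        dataset.components
        if len(traits) == 2
        else dataset.components.subset(trait_idx)
    )
    relationship = GENOTYPING_RELATIONSHIP[genotyping]
    kwargs = {}
    if relationship != "pedigree":
        kwargs = {
            "genotyped_ids": dataset.genotyped,
            "dosages": dataset.marker_dosages,
        }
    model = AnimalModel(
        dataset.pedigree,
        pheno,
        traits=traits,
        record_modes=modes,
        groups=dataset.groups,
        relationship=relationship,
        **kwargs,
    )
    return model.fit(comps), comps


@dataclass
class ExperimentSummary:
    """Per-replicate scores and their aggregation over replicates."""

    scores: pd.DataFrame  # long format, one row per replicate x cell
    reml: pd.DataFrame | None = None

    def aggregate(self) -> pd.DataFrame:
        keys = ["cell", "genotyping", "record_state", "subset", "trait"]
        g = self.scores.groupby(keys)
        out = g.agg(
            accuracy_mean=("accuracy", "mean"),
            accuracy_sd=("accuracy", "std"),
            bias_mean=("bias", "mean"),
            bias_sd=("bias", "std"),
            n_replicates=("replicate", "nunique"),
        ).reset_index()
        single = out["n_replicates"] < 2
        out.loc[single, ["accuracy_sd", "bias_sd"]] = np.nan
        return out

    def to_tsv(self, path) -> None:
        self.aggregate().to_csv(path, sep="\t", index=False)


def run_experiment(
    config: ScenarioConfig,
    design: PopulationDesign | None = None,
    gmap=None,
    genome: str = "qtl_only",
    models=("uni_group", "uni_individual"),
    record_states=RECORD_STATES,
    subsets=("All",),
    reml_models=(),
    progress: bool = False,
) -> ExperimentSummary:
    """Simulate ``config.replicates`` replicates and score the requested
    model cells with the generating ("true") variance components.

    Identical seeds give bitwise-identical summaries.  Failed cells are
    recorded with NaN scores and counted in the output.
    """
    design = design or PopulationDesign()
    root = np.random.SeedSequence(config.seed)
    rows = []
    reml_rows = []
    for rep, seq in enumerate(root.spawn(config.replicates)):
        rng = np.random.default_rng(seq)
        sim = simulate_genome(design, rng, genome=genome, gmap=gmap)
        dataset = build_dataset(sim, config, rng, design=design)
        subsets_ids = validation_subsets(
            dataset.phenotypes, dataset.genotyped_30, design.validation_generation
        )
        for cell in models:
            for state in record_states:
                try:
                    res, _ = fit_cell(
                        dataset,
                        cell,
                        genotyping=config.genotyping,
                        record_state=state,
                        validation_generation=design.validation_generation,
                    )
                except Exception as exc:  # cell failure: log and continue
                    warnings.warn(f"cell {cell}/{state} failed in rep {rep}: {exc}")
                    res = None
                for subset in subsets:
                    ids = subsets_ids[subset]
                    for trait in MODEL_CELLS[cell][0]:
                        if res is None or len(ids) < 3:
                            acc = bias = np.nan
                        else:
                            acc, bias = score_results(
                                res, dataset.phenotypes, ids, trait
                            )
                        rows.append(
                            {
                                "replicate": rep,
                                "cell": cell,
                                "genotyping": config.genotyping,
                                "grouping": config.grouping,
                                "record_state": state,
                                "subset": subset,
                                "trait": trait,
                                "accuracy": acc,
                                "bias": bias,
                            }
                        )
        for cell in reml_models:
            traits, modes = MODEL_CELLS[cell]
            trait_idx = [int(t[-1]) - 1 for t in traits]
            model = AnimalModel(
                dataset.pedigree,
                dataset.phenotypes,
                traits=traits,
                record_modes=modes,
                groups=dataset.groups,
                relationship="pedigree",
            )
            fit = model.fit_reml()
            for (eff, i, j) in fit.params:
                reml_rows.append(
                    {
                        "replicate": rep,
                        "cell": cell,
                        "effect": eff,
                        "trait_i": i + 1,
                        "trait_j": j + 1,
                        "estimate": fit.components.block(eff)[i, j],
                        "se": fit.standard_errors.get((eff, i, j), np.nan),
                        "converged": fit.converged,
                    }
                )
        if progress:
            print(f"replicate {rep + 1}/{config.replicates} done")
    return ExperimentSummary(
        scores=pd.DataFrame(rows),
        reml=pd.DataFrame(reml_rows) if reml_rows else None,
    )
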