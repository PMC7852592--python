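"""Readers and writers for the plain-text interchange formats.

* Pedigree CSV: ``id, sire, dam, generation, sex, breeding_flag`` with 0 for
  an unknown parent (and an optional ``litter`` column).
* Genotype file: tab-separated ``id`` followed by per-marker 0/1/2 dosages.
* Phenotype CSV: ``id, litter, pen, y1, y2, tbv1, tbv2, has_record``.
* Group-record CSV: ``pen, group_size, y1_sum, member_ids``
  (semicolon-joined).
* Phased haplotypes: an HDF5 container (ids, alleles, map arrays) for
  internal reuse of simulated genomes.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .genome import GenomeMap, HaplotypePopulation
from .pedigree import Pedigree
from .simulate import GroupIncidence, ScenarioConfig


# -- pedigree ---------------------------------------------------------------


def write_pedigree(ped: Pedigree, path) -> None:
    ped.to_dataframe().to_csv(path, index=False)


def read_pedigree(path) -> Pedigree:
    return Pedigree.from_dataframe(pd.read_csv(path))


# -- genotypes --------------------------------------------------------------


def write_genotypes(ids, dosages: np.ndarray, path) -> None:
    df = pd.DataFrame(np.asarray(dosages, dtype=np.int8))
    df.insert(0, "id", np.asarray(ids))
    df.to_csv(path, sep="\t", index=False, header=False)


def read_genotypes(path) -> tuple[np.ndarray, np.ndarray]:
    """Returns (ids, dosage matrix)."""
    df = pd.read_csv(path, sep="\t", header=None)
    ids = df.iloc[:, 0].to_numpy()
    dosages = df.iloc[:, 1:].to_numpy(dtype=np.int8)
    if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
        raise ValueError("dosages must be coded 0/1/2")
    return ids, dosages


# -- phenotypes and group records ------------------------------------------


def write_phenotypes(phenotypes: pd.DataFrame, path) -> None:
    cols = [
        c
        for c in ("id", "generation", "litter", "pen", "y1", "y2", "tbv1", "tbv2", "has_record")
        if c in phenotypes.columns
    ]
    phenotypes[cols].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "has_record" not in df.columns:
        df["has_record"] = True
    df["has_record"] = df["has_record"].astype(bool)
    return df


def write_group_records(group_records: pd.DataFrame, path) -> None:
    group_records.to_csv(path, index=False)


def read_groups(phenotypes: pd.DataFrame) -> GroupIncidence:
    """Group incidence from the pen column of a phenotype table."""
    rec = phenotypes[phenotypes["pen"].notna()]
    return GroupIncidence(
        member_ids=rec["id"].to_numpy(), pen=rec["pen"].to_numpy()
    )


# -- haplotypes (HDF5) ------------------------------------------------------


def write_haplotypes(pop: HaplotypePopulation, gmap: GenomeMap, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("ids", data=np.asarray(pop.ids, dtype=np.int64))
        f.create_dataset(
            "haplotypes", data=pop.haplotypes, compression="gzip", compression_opts=4
        )
        f.create_dataset("sex", data=pop.sex)
        f.attrs["generation"] = pop.generation
        g = f.create_group("map")
        g.create_dataset("chromosome", data=gmap.chromosome)
        g.create_dataset("position", data=gmap.position)
        g.create_dataset("is_qtl", data=gmap.is_qtl)
        g.create_dataset("chromosome_length", data=gmap.chromosome_length)
        g.attrs["mutation_rate"] = gmap.mutation_rate


def read_haplotypes(path) -> tuple[HaplotypePopulation, GenomeMap]:
    with h5py.File(path, "r") as f:
        pop = HaplotypePopulation(
            ids=f["ids"][:],
            haplotypes=f["haplotypes"][:],
            generation=int(f.attrs["generation"]),
            sex=f["sex"][:],
        )
        g = f["map"]
        gmap = GenomeMap(
            chromosome=g["chromosome"][:],
            position=g["position"][:],
            is_qtl=g["is_qtl"][:],
            chromosome_length=g["chromosome_length"][:],
            mutation_rate=float(g.attrs["mutation_rate"]),
        )
    return pop, gmap


# -- relationship matrices --------------------------------------------------


def write_matrix_triplets(matrix, ids, path, threshold: float = 0.0) -> None:
    """Symmetric matrix as text triplets (i, j, value), upper triangle."""
    m = sp.coo_matrix(np.triu(np.asarray(matrix)))
    ids = np.asarray(ids)
    df = pd.DataFrame(
        {"i": ids[m.row], "j": ids[m.col], "value": m.data}
    )
    if threshold > 0:
        df = df[np.abs(df["value"]) >= threshold]
    df.to_csv(path, sep="\t", index=False)


# -- scenario configuration -------------------------------------------------


def read_scenario_config(path) -> ScenarioConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    return ScenarioConfig(**raw)


def write_scenario_config(config: ScenarioConfig, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(
            {
                "grouping": config.grouping,
                "attrition": config.attrition,
                "genotyping": config.genotyping,
                "genetic_correlation": config.genetic_correlation,
                "replicates": config.replicates,
                "seed": config.seed,
            },
            f,
        )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
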