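"""Forward simulation of a pig nucleus population with pen-grouped phenotypes.

The simulated design mirrors a closed nucleus: a drift/mutation historical
phase (see :mod:`penblup.genome`) seeds a base step in which 30 sires are
mated to 200 dams; 600 female and 30 male offspring become the generation-0
founders, and eight further non-overlapping generations each use 30 sires and
600 dams producing 600 litters of three males and three females (29,430
pedigree animals in total at the default sizes).

Two correlated traits are simulated from QTL effects drawn bivariate normal;
phenotypes for the last four generations are the sum of an overall mean,
litter, pen, additive and residual effects.  Pens are built within generation
under three grouping scenarios, 20% of the animals are culled (breeding
animals are always kept), and the group record of trait 1 is the pen sum of
the surviving members' records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .components import VarianceComponents
from .genome import (
    GenomeMap,
    HaplotypePopulation,
    apply_maf_filter,
    sample_gametes,
    simulate_historical,
)
from .pedigree import UNKNOWN, Pedigree

GROUPING_SCENARIOS = ("S12_L2x3", "S12_Lran", "S24_L2x3")


@dataclass
class PopulationDesign:
    """Sizes of the historical, base and nucleus phases."""

    n_historical: int = 400
    historical_generations: int = 300
    n_base_sires: int = 30
    n_base_dams: int = 200
    n_sires: int = 30
    n_litters: int = 600  # dams (= litters) per generation
    litter_size: int = 6  # 3 males + 3 females
    n_generations: int = 8
    recorded_generations: tuple = (5, 6, 7, 8)
    validation_generation: int = 8

    def __post_init__(self) -> None:
        if self.litter_size % 2:
            raise ValueError("litter size must be even (equal sex ratio)")
        base_females = self.n_base_dams * self.litter_size // 2
        if base_females < self.n_litters:
            raise ValueError("base step produces too few females for the nucleus")

    @property
    def offspring_per_generation(self) -> int:
        return self.n_litters * self.litter_size

    @property
    def n_pedigree(self) -> int:
        return self.n_sires + self.n_litters + self.n_generations * self.offspring_per_generation

    @classmethod
    def quarter_scale(cls) -> "PopulationDesign":
        """A 1/4-size nucleus (150 litters, 8 sires per generation) preserving
        litter structure, mating ratio and the 9-generation layout."""
        return cls(
            n_base_sires=8,
            n_base_dams=50,
            n_sires=8,
            n_litters=150,
        )


@dataclass
class ScenarioConfig:
    """One cell of the simulation study."""

    grouping: str = "S12_L2x3"
    attrition: float = 0.2
    genotyping: int = 0  # percent of data animals genotyped: 0 / 30 / 100
    genetic_correlation: float = 0.8
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grouping not in GROUPING_SCENARIOS:
            raise ValueError(f"unknown grouping scenario {self.grouping!r}")
        if self.genotyping not in (0, 30, 100):
            raise ValueError("genotyping design must be 0, 30 or 100 (percent)")
        if not 0 <= self.attrition < 1:
            raise ValueError("attrition fraction must be in [0, 1)")


# ---------------------------------------------------------------------------
# pedigree expansion
# ---------------------------------------------------------------------------


def expand_recent_population(
    founders: HaplotypePopulation,
    gmap: GenomeMap,
    design: PopulationDesign,
    rng: np.random.Generator,
) -> tuple[Pedigree, HaplotypePopulation]:
    """Base step plus ``n_generations`` non-overlapping nucleus generations.

    Returns the full pedigree (generation-0 founders have unknown parents)
    and the phased haplotypes of every pedigree animal.  Mutation is applied
    in the historical phase only; nucleus meioses are mutation-free.
    """
    if founders.n < 2:
        raise ValueError("insufficient founders")
    hist = founders.haplotypes
    males = np.flatnonzero(founders.sex == 0)
    females = np.flatnonzero(founders.sex == 1)
    if len(males) < design.n_base_sires or len(females) < design.n_base_dams:
        raise ValueError("insufficient founders of one sex for the base step")

    # --- base step: produce litters of size litter_size per base dam -------
    base_sires = rng.choice(males, design.n_base_sires, replace=False)
    base_dams = rng.choice(females, design.n_base_dams, replace=False)
    sire_of_dam = rng.choice(base_sires, design.n_base_dams)
    k = design.litter_size
    pat_rows = np.repeat(sire_of_dam, k)
    mat_rows = np.repeat(base_dams, k)
    paternal = sample_gametes(hist[pat_rows], gmap, rng, mutate=False)
    maternal = sample_gametes(hist[mat_rows], gmap, rng, mutate=False)
    base_haps = np.stack([paternal, maternal], axis=1)
    base_sex = np.tile(
        np.r_[np.zeros(k // 2, np.int8), np.ones(k // 2, np.int8)], design.n_base_dams
    )
    base_m = np.flatnonzero(base_sex == 0)
    base_f = np.flatnonzero(base_sex == 1)
    founder_sires = rng.choice(base_m, design.n_sires, replace=False)
    founder_dams = rng.choice(base_f, design.n_litters, replace=False)

    # --- allocate pedigree arrays ------------------------------------------
    n_total = design.n_pedigree
    n_loci = gmap.n_loci
    haps = np.empty((n_total, 2, n_loci), dtype=np.uint8)
    sire = np.full(n_total, UNKNOWN, dtype=np.int64)
    dam = np.full(n_total, UNKNOWN, dtype=np.int64)
    generation = np.empty(n_total, dtype=np.int32)
    sex = np.empty(n_total, dtype=np.int8)
    litter = np.zeros(n_total, dtype=np.int64)  # 0 = no litter label

    n0 = design.n_sires + design.n_litters
    haps[: design.n_sires] = base_haps[founder_sires]
    haps[design.n_sires : n0] = base_haps[founder_dams]
    generation[:n0] = 0
    sex[: design.n_sires] = 0
    sex[design.n_sires : n0] = 1

    nxt = n0
    litter_counter = 0
    prev = np.arange(n0)
    for g in range(1, design.n_generations + 1):
        prev_m = prev[sex[prev] == 0]
        prev_f = prev[sex[prev] == 1]
        sires_g = rng.choice(prev_m, design.n_sires, replace=False)
        dams_g = rng.choice(prev_f, design.n_litters, replace=False)
        # each sire serves an equal share of randomly permuted dams
        dams_g = rng.permutation(dams_g)
        sire_of_litter = np.repeat(
            sires_g, design.n_litters // design.n_sires
        )
        rem = design.n_litters - len(sire_of_litter)
        if rem:
            sire_of_litter = np.r_[sire_of_litter, rng.choice(sires_g, rem)]
        off = design.offspring_per_generation
        rows = slice(nxt, nxt + off)
        pat_rows = np.repeat(sire_of_litter, k)
        mat_rows = np.repeat(dams_g, k)
        paternal = sample_gametes(haps[pat_rows], gmap, rng, mutate=False)
        maternal = sample_gametes(haps[mat_rows], gmap, rng, mutate=False)
        haps[rows] = np.stack([paternal, maternal], axis=1)
        sire[rows] = pat_rows
        dam[rows] = mat_rows
        generation[rows] = g
        sex[rows] = np.tile(
            np.r_[np.zeros(k // 2, np.int8), np.ones(k // 2, np.int8)],
            design.n_litters,
        )
        litter[rows] = np.repeat(
            litter_counter + np.arange(design.n_litters) + 1, k
        )
        litter_counter += design.n_litters
        prev = np.arange(nxt, nxt + off)
        nxt += off

    ped = Pedigree(
        sire=sire,
        dam=dam,
        generation=generation,
        sex=sex,
        litter=litter,
        ids=np.arange(1, n_total + 1),
    )
    pop = HaplotypePopulation(
        ids=ped.ids, haplotypes=haps, generation=design.n_generations, sex=sex
    )
    return ped, pop


# ---------------------------------------------------------------------------
# trait architecture
# ---------------------------------------------------------------------------


@dataclass
class TraitArchitecture:
    """QTL allele-substitution effects for two traits plus the scaling that
    pins the reference-generation breeding-value variances to target values."""

    effects: np.ndarray  # (n_qtl, n_traits)
    scale: np.ndarray  # (n_traits,)
    offset: np.ndarray  # (n_traits,) mean of scaled raw BVs in the reference set
    genetic_correlation: float
    target_variances: tuple

    def breeding_values(self, qtl_dosages: np.ndarray) -> np.ndarray:
        """True breeding values ``(n, n_traits)`` from 0/1/2 QTL dosages."""
        raw = qtl_dosages.astype(float) @ self.effects
        return raw * self.scale[None, :] - self.offset[None, :]


def assign_trait_architecture(
    qtl_dosages_reference: np.ndarray,
    genetic_correlation: float = 0.8,
    target_variances: tuple = (30.0, 100.0),
    rng: np.random.Generator | None = None,
) -> TraitArchitecture:
    """Sample QTL effect pairs from a bivariate normal with the given
    correlation and scale each trait so the empirical BV variance in the
    reference genotypes equals its target."""
    rg = float(genetic_correlation)
    if abs(rg) > 1:
        raise ValueError("|genetic correlation| must be <= 1")
    rng = np.random.default_rng(rng)
    n_qtl = qtl_dosages_reference.shape[1]
    n_traits = len(target_variances)
    if n_traits == 2 and abs(rg) == 1.0:  # degenerate: perfectly shared effects
        z = rng.standard_normal((n_qtl, 1))
        effects = np.hstack([z, rg * z])
    else:
        corr = np.full((n_traits, n_traits), rg)
        np.fill_diagonal(corr, 1.0)
        effects = rng.standard_normal((n_qtl, n_traits)) @ np.linalg.cholesky(corr).T
    raw = qtl_dosages_reference.astype(float) @ effects
    var_raw = raw.var(axis=0)
    if np.any(var_raw == 0):
        raise ValueError("no segregating QTL: cannot scale breeding values")
    scale = np.sqrt(np.asarray(target_variances, dtype=float) / var_raw)
    offset = (raw * scale[None, :]).mean(axis=0)
    return TraitArchitecture(
        effects=effects,
        scale=scale,
        offset=offset,
        genetic_correlation=rg,
        target_variances=tuple(target_variances),
    )


# ---------------------------------------------------------------------------
# pens
# ---------------------------------------------------------------------------


@dataclass
class GroupIncidence:
    """Disjoint assignment of individuals to pens (groups)."""

    member_ids: np.ndarray
    pen: np.ndarray  # pen label per member

    def __post_init__(self) -> None:
        self.member_ids = np.asarray(self.member_ids)
        self.pen = np.asarray(self.pen)
        if len(self.member_ids) != len(self.pen):
            raise ValueError("member and pen arrays must align")
        if len(np.unique(self.member_ids)) != len(self.member_ids):
            raise ValueError("groups must be disjoint: duplicate member")
        self._pen_of = dict(zip(self.member_ids.tolist(), self.pen.tolist()))

    def pen_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._pen_of[int(i)] for i in np.atleast_1d(ids)])
        except KeyError as e:
            raise KeyError(f"individual {e} has no pen") from None

    def sizes(self, ids=None) -> pd.Series:
        pens = self.pen if ids is None else self.pen_of(ids)
        return pd.Series(pens).value_counts().sort_index()

    def matrix(self, record_ids) -> tuple[sp.csr_matrix, np.ndarray]:
        """Sparse group-incidence matrix T (one row per pen, one column per
        record, in the order of ``record_ids``) and the pen labels per row."""
        record_ids = np.atleast_1d(record_ids)
        pens = self.pen_of(record_ids)
        labels, rows = np.unique(pens, return_inverse=True)
        T = sp.csr_matrix(
            (np.ones(len(record_ids)), (rows, np.arange(len(record_ids)))),
            shape=(len(labels), len(record_ids)),
        )
        return T, labels


def _pack_sublitters(
    sub_litter: np.ndarray, per_pen: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign sublitters to pens of ``per_pen`` sublitters such that the two
    sublitters of one litter never share a pen.  Returns pen index per
    sublitter."""
    n_sub = len(sub_litter)
    if n_sub % per_pen:
        raise ValueError("sublitter count not divisible into equal pens")
    n_pens = n_sub // per_pen
    pen_members: list[list[int]] = [[] for _ in range(n_pens)]
    pen_litters: list[set] = [set() for _ in range(n_pens)]
    open_pens = set(range(n_pens))
    order = rng.permutation(n_sub)
    assign = np.empty(n_sub, dtype=np.int64)
    for it in order:
        lit = sub_litter[it]
        ok = [p for p in open_pens if lit not in pen_litters[p]]
        if ok:
            p = ok[rng.integers(len(ok))] if len(ok) > 1 else ok[0]
        else:
            # The only pen with space holds this litter's sibling sublitter.
            # Swap: move a compatible member out of a full pen q, place this
            # sublitter into q.  A suitable (q, m) always exists because a
            # full pen carries more distinct litters than the open pen.
            p_space = next(iter(open_pens))
            full = [
                q
                for q in range(n_pens)
                if q not in open_pens and lit not in pen_litters[q]
            ]
            q = full[rng.integers(len(full))]
            m = next(
                m
                for m in pen_members[q]
                if sub_litter[m] not in pen_litters[p_space]
            )
            pen_members[q].remove(m)
            pen_litters[q].discard(sub_litter[m])
            pen_members[p_space].append(m)
            pen_litters[p_space].add(sub_litter[m])
            assign[m] = p_space
            if len(pen_members[p_space]) == per_pen:
                open_pens.discard(p_space)
            p = q
            open_pens.add(q)
        pen_members[p].append(it)
        pen_litters[p].add(lit)
        assign[it] = p
        if len(pen_members[p]) == per_pen:
            open_pens.discard(p)
    return assign


def assign_pens(
    member_ids: np.ndarray,
    litters: np.ndarray,
    scenario: str,
    rng: np.random.Generator,
    pen_offset: int = 0,
) -> GroupIncidence:
    """Assign one generation's individuals to pens.

    ``S12_L2x3`` / ``S24_L2x3``: each litter of 6 is split randomly into two
    sublitters of 3; pens take 4 (respectively 8) sublitters from distinct
    litters, so full-sib trios stay together but the two halves of a litter
    never meet.  ``S12_Lran``: individuals are permuted into pens of up to 12.
    """
    member_ids = np.asarray(member_ids)
    litters = np.asarray(litters)
    if scenario == "S12_Lran":
        n = len(member_ids)
        perm = rng.permutation(n)
        pen_per_member = np.empty(n, dtype=np.int64)
        pen_per_member[perm] = np.arange(n) // 12  # last pen may hold < 12
        return GroupIncidence(member_ids=member_ids, pen=pen_offset + pen_per_member)
    if scenario not in ("S12_L2x3", "S24_L2x3"):
        raise ValueError(f"unknown grouping scenario {scenario!r}")
    per_pen = 4 if scenario == "S12_L2x3" else 8
    order = np.argsort(litters, kind="stable")
    ids_sorted = member_ids[order]
    lit_sorted = litters[order]
    uniq, start = np.unique(lit_sorted, return_index=True)
    counts = np.diff(np.r_[start, len(lit_sorted)])
    if np.any(counts != 6):
        raise ValueError("L2x3 scenarios require litters of exactly 6")
    # split each litter into two random sublitters of 3
    n_lit = len(uniq)
    sub_of_member = np.empty(len(ids_sorted), dtype=np.int64)
    for j, s in enumerate(start):
        half = rng.permutation(6) < 3
        sub_of_member[s : s + 6] = 2 * j + half
    sub_litter = np.repeat(np.arange(n_lit), 2)  # litter index per sublitter
    assign = _pack_sublitters(sub_litter, per_pen, rng)
    pen_per_member = pen_offset + assign[sub_of_member]
    return GroupIncidence(member_ids=ids_sorted, pen=pen_per_member)


def assign_pens_all_generations(
    ped: Pedigree,
    scenario: str,
    rng: np.random.Generator,
    generations=None,
) -> GroupIncidence:
    """Pens built within each recorded generation, with disjoint labels."""
    gens = generations if generations is not None else np.unique(ped.generation)
    members, pens = [], []
    offset = 0
    for g in gens:
        idx = np.flatnonzero(ped.generation == g)
        if idx.size == 0:
            continue
        gi = assign_pens(
            ped.ids[idx], ped.litter[idx], scenario, rng, pen_offset=offset
        )
        members.append(gi.member_ids)
        pens.append(gi.pen)
        offset = int(gi.pen.max()) + 1
    return GroupIncidence(
        member_ids=np.concatenate(members), pen=np.concatenate(pens)
    )


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def simulate_phenotypes(
    ped: Pedigree,
    breeding_values: np.ndarray,
    pens: GroupIncidence,
    components: VarianceComponents,
    rng: np.random.Generator,
    recorded_generations=(5, 6, 7, 8),
    mean: tuple = (0.0, 0.0),
) -> pd.DataFrame:
    """Two-trait records ``y = mu + litter + pen + additive + residual`` for
    the recorded generations.

    Litter, pen and residual effect pairs are drawn bivariate normal with the
    generating (co)variances; the additive part is the true breeding value
    from the QTL architecture.  Returns a phenotype table with the record
    values, the true BVs and the individual effect components (kept for
    diagnostics), plus a ``has_record`` flag.
    """
    t = components.n_traits
    mask = np.isin(ped.generation, np.asarray(recorded_generations))
    idx = np.flatnonzero(mask)
    ids = ped.ids[idx]
    litters = ped.litter[idx]
    if np.any(litters == 0):
        raise ValueError("recorded individual without litter label")
    pen_labels = pens.pen_of(ids)  # raises if a pen is missing

    def draw(block, labels):
        uniq, inv = np.unique(labels, return_inverse=True)
        chol = np.linalg.cholesky(block + 1e-14 * np.eye(t)) if np.any(block) else np.zeros((t, t))
        vals = rng.standard_normal((len(uniq), t)) @ chol.T
        return vals[inv]

    l_eff = draw(components.litter, litters)
    c_eff = draw(components.pen, pen_labels)
    chol_e = (
        np.linalg.cholesky(components.residual + 1e-14 * np.eye(t))
        if np.any(components.residual)
        else np.zeros((t, t))
    )
    e_eff = rng.standard_normal((len(ids), t)) @ chol_e.T
    a_eff = breeding_values[idx][:, :t]
    mu = np.asarray(mean, dtype=float)[:t]
    y = mu[None, :] + l_eff + c_eff + a_eff + e_eff

    data = {
        "id": ids,
        "generation": ped.generation[idx],
        "litter": litters,
        "pen": pen_labels,
        "has_record": np.ones(len(ids), dtype=bool),
    }
    for j in range(t):
        data[f"y{j+1}"] = y[:, j]
        data[f"tbv{j+1}"] = a_eff[:, j]
        data[f"l{j+1}"] = l_eff[:, j]
        data[f"c{j+1}"] = c_eff[:, j]
        data[f"e{j+1}"] = e_eff[:, j]
    return pd.DataFrame(data)


def apply_attrition(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    fraction: float = 0.2,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Randomly delete ``fraction`` of the recorded animals, never touching
    breeding animals (parents of a later generation).  Deleted animals lose
    their records (``has_record = False``) but stay in the pedigree."""
    rng = np.random.default_rng(rng)
    pheno = phenotypes.copy()
    recorded = pheno.index[pheno["has_record"]].to_numpy()
    n_delete = int(round(fraction * len(recorded)))
    if n_delete == 0:
        return pheno
    idx = ped.indices_of(pheno.loc[recorded, "id"].to_numpy())
    deletable = recorded[~ped.breeding[idx]]
    if n_delete > len(deletable):
        raise ValueError(
            "attrition fraction exceeds the proportion of non-breeding animals"
        )
    drop = rng.choice(deletable, n_delete, replace=False)
    pheno.loc[drop, "has_record"] = False
    return pheno


def select_genotyped(
    phenotypes: pd.DataFrame,
    ped: Pedigree,
    design: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Ids of genotyped animals under a 0/30/100-percent design.

    The 30% design genotypes every breeding animal in the data plus a random
    fill from the remaining recorded animals."""
    if design not in (0, 30, 100):
        raise ValueError("genotyping design must be 0, 30 or 100")
    rng = np.random.default_rng(rng)
    data_ids = phenotypes.loc[phenotypes["has_record"], "id"].to_numpy()
    if design == 0:
        return np.array([], dtype=data_ids.dtype)
    if design == 100:
        return np.sort(data_ids)
    idx = ped.indices_of(data_ids)
    breeders = data_ids[ped.breeding[idx]]
    target = int(round(0.30 * len(data_ids)))
    if len(breeders) > target:
        raise ValueError("breeding animals already exceed the 30% target")
    rest = np.setdiff1d(data_ids, breeders)
    fill = rng.choice(rest, target - len(breeders), replace=False)
    return np.sort(np.r_[breeders, fill])


def make_group_records(
    phenotypes: pd.DataFrame,
    pens: GroupIncidence,
    trait: str = "y1",
) -> pd.DataFrame:
    """One record per pen: the sum of the surviving members' trait records."""
    rec = phenotypes[phenotypes["has_record"]]
    pen_labels = pens.pen_of(rec["id"].to_numpy())
    df = pd.DataFrame({"pen": pen_labels, "y": rec[trait].to_numpy(), "id": rec["id"].to_numpy()})
    grouped = df.groupby("pen")
    out = grouped.agg(
        group_size=("y", "size"),
        y1_sum=("y", "sum"),
        member_ids=("id", lambda s: ";".join(map(str, s))),
    ).reset_index()
    return out


# ---------------------------------------------------------------------------
# one replicate end to end
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenome:
    """Genome + pedigree shared by the grouping scenarios of one replicate."""

    gmap: GenomeMap
    pedigree: Pedigree
    population: HaplotypePopulation
    n_markers_segregating: int
    n_qtl_segregating: int


@dataclass
class Dataset:
    """Everything one model run consumes."""

    pedigree: Pedigree
    phenotypes: pd.DataFrame
    groups: GroupIncidence
    components: VarianceComponents  # generating values (the "true" variances)
    genotyped: np.ndarray | None = None
    marker_dosages: np.ndarray | None = None  # aligned to `genotyped` ids
    architecture: TraitArchitecture | None = None
    genotyped_30: np.ndarray | None = None  # frozen Group I membership


def simulate_genome(
    design: PopulationDesign,
    rng: np.random.Generator,
    genome: str = "qtl_only",
    gmap: GenomeMap | None = None,
) -> SimulatedGenome:
    """Historical phase, MAF filter and nucleus expansion.

    ``genome='qtl_only'`` simulates only the QTL loci (sufficient for any
    pedigree-based analysis); ``'full'`` includes the marker panel."""
    if gmap is None:
        if genome == "qtl_only":
            gmap = GenomeMap.random(n_markers=0, n_qtl=50, rng=rng)
        elif genome == "full":
            gmap = GenomeMap.random(rng=rng)
        else:
            raise ValueError("genome must be 'qtl_only' or 'full'")
    hist = simulate_historical(
        gmap, n=design.n_historical, generations=design.historical_generations, rng=rng
    )
    hist, gmap_f = apply_maf_filter(hist, gmap, threshold=0.01)
    ped, pop = expand_recent_population(hist, gmap_f, design, rng)
    return SimulatedGenome(
        gmap=gmap_f,
        pedigree=ped,
        population=pop,
        n_markers_segregating=gmap_f.n_markers,
        n_qtl_segregating=gmap_f.n_qtl,
    )


def build_dataset(
    sim: SimulatedGenome,
    config: ScenarioConfig,
    rng: np.random.Generator,
    design: PopulationDesign | None = None,
    architecture: TraitArchitecture | None = None,
) -> Dataset:
    """Pens, phenotypes, attrition and genotyping for one scenario cell."""
    design = design or PopulationDesign()
    ped = sim.pedigree
    qtl_dos = sim.population.dosages()[:, sim.gmap.is_qtl]
    if architecture is None:
        ref = ped.generation == 0
        architecture = assign_trait_architecture(
            qtl_dos[ref],
            genetic_correlation=config.genetic_correlation,
            rng=rng,
        )
    bvs = architecture.breeding_values(qtl_dos)
    components = VarianceComponents.simulation_defaults(config.genetic_correlation)
    pens = assign_pens_all_generations(
        ped, config.grouping, rng, generations=design.recorded_generations
    )
    pheno = simulate_phenotypes(
        ped, bvs, pens, components, rng,
        recorded_generations=design.recorded_generations,
    )
    pheno = apply_attrition(pheno, ped, config.attrition, rng)
    # Group I membership is frozen from the 30% design for every genotyping
    # design so all designs score identical validation subsets.
    genotyped_30 = select_genotyped(pheno, ped, 30, rng)
    if config.genotyping == 30:
        genotyped = genotyped_30
    else:
        genotyped = select_genotyped(pheno, ped, config.genotyping, rng)
    marker_dos = None
    if len(genotyped) and sim.gmap.n_markers:
        gidx = ped.indices_of(genotyped)
        marker_dos = sim.population.dosages()[np.ix_(gidx, ~sim.gmap.is_qtl)]
    return Dataset(
        pedigree=ped,
        phenotypes=pheno,
        groups=pens,
        components=components,
        genotyped=genotyped if len(genotyped) else None,
        marker_dosages=marker_dos,
        architecture=architecture,
        genotyped_30=genotyped_30,
    )
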