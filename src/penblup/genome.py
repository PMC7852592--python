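"""Genome map, gamete sampling and historical-population simulation.

The genome is a set of biallelic loci (markers and QTL) on a linkage map.
Recombination follows the Haldane model: crossover counts per chromosome are
Poisson with mean equal to the map length in Morgans, placed uniformly and
without interference.  Recurrent mutation flips alleles (0 <-> 1) at a fixed
per-locus, per-meiosis rate.

A long random-mating "historical" phase at constant size builds up linkage
disequilibrium and an allele-frequency profile by drift/mutation balance;
the last historical generation seeds the pedigreed nucleus population
(see :mod:`penblup.simulate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenomeMap:
    """Positions (cM) and classes of biallelic loci on a multi-chromosome map."""

    chromosome: np.ndarray  # int, 0-based chromosome index per locus
    position: np.ndarray  # cM within chromosome, strictly increasing per chrom
    is_qtl: np.ndarray  # bool per locus
    chromosome_length: np.ndarray  # cM per chromosome
    mutation_rate: float = 2.5e-5  # per locus per meiosis

    def __post_init__(self) -> None:
        self.chromosome = np.asarray(self.chromosome, dtype=np.int32)
        self.position = np.asarray(self.position, dtype=float)
        self.is_qtl = np.asarray(self.is_qtl, dtype=bool)
        self.chromosome_length = np.atleast_1d(
            np.asarray(self.chromosome_length, dtype=float)
        )
        if not (
            len(self.chromosome) == len(self.position) == len(self.is_qtl)
        ):
            raise ValueError("per-locus arrays must have equal length")
        if np.any(np.diff(self.chromosome) < 0):
            raise ValueError("loci must be sorted by chromosome")
        for c in range(self.n_chromosomes):
            pos = self.position[self.chromosome == c]
            if pos.size and np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing on chromosome {c}"
                )
            if pos.size and (pos.min() < 0 or pos.max() > self.chromosome_length[c]):
                raise ValueError(f"locus position outside chromosome {c}")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")

    @property
    def n_loci(self) -> int:
        return len(self.position)

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_length)

    @property
    def n_markers(self) -> int:
        return int((~self.is_qtl).sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    def chromosome_slices(self):
        """Yield ``(chrom_index, slice)`` of the locus array per chromosome."""
        bounds = np.searchsorted(self.chromosome, np.arange(self.n_chromosomes + 1))
        for c in range(self.n_chromosomes):
            yield c, slice(bounds[c], bounds[c + 1])

    def subset(self, mask: np.ndarray) -> "GenomeMap":
        mask = np.asarray(mask, dtype=bool)
        return GenomeMap(
            chromosome=self.chromosome[mask],
            position=self.position[mask],
            is_qtl=self.is_qtl[mask],
            chromosome_length=self.chromosome_length.copy(),
            mutation_rate=self.mutation_rate,
        )

    @classmethod
    def random(
        cls,
        n_chromosomes: int = 18,
        chromosome_length: float = 100.0,
        n_markers: int = 3100,
        n_qtl: int = 50,
        mutation_rate: float = 2.5e-5,
        rng: np.random.Generator | None = None,
    ) -> "GenomeMap":
        """Random map: markers and QTL uniformly distributed on each chromosome.

        Defaults give the 18 x 100 cM genome with 3100 markers + 50 QTL per
        chromosome used in the simulation study.
        """
        rng = np.random.default_rng(rng)
        per_chrom = n_markers + n_qtl
        chrom, pos, qtl = [], [], []
        for c in range(n_chromosomes):
            p = np.sort(rng.uniform(0.0, chromosome_length, per_chrom))
            while np.any(np.diff(p) <= 0):  # ties are vanishingly rare
                p = np.sort(rng.uniform(0.0, chromosome_length, per_chrom))
            flags = np.zeros(per_chrom, dtype=bool)
            flags[rng.choice(per_chrom, n_qtl, replace=False)] = True
            chrom.append(np.full(per_chrom, c))
            pos.append(p)
            qtl.append(flags)
        return cls(
            chromosome=np.concatenate(chrom),
            position=np.concatenate(pos),
            is_qtl=np.concatenate(qtl),
            chromosome_length=np.full(n_chromosomes, float(chromosome_length)),
            mutation_rate=mutation_rate,
        )


@dataclass
class HaplotypePopulation:
    """Phased biallelic haplotypes for a set of individuals.

    ``haplotypes`` has shape ``(n_individuals, 2, n_loci)`` with values 0/1.
    """

    ids: np.ndarray
    haplotypes: np.ndarray
    generation: int = 0
    sex: np.ndarray | None = field(default=None)  # 0 = male, 1 = female

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 3 or self.haplotypes.shape[1] != 2:
            raise ValueError("haplotypes must have shape (n, 2, n_loci)")
        if self.haplotypes.shape[0] != len(self.ids):
            raise ValueError("ids and haplotypes disagree on population size")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("alleles must be 0/1")
        if self.sex is None:
            n = len(self.ids)
            self.sex = (np.arange(n) % 2).astype(np.int8)
        else:
            self.sex = np.asarray(self.sex, dtype=np.int8)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def dosages(self) -> np.ndarray:
        """0/1/2 allele-count matrix ``(n, n_loci)``."""
        return self.haplotypes.sum(axis=1, dtype=np.uint8)

    def allele_frequencies(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))


# ---------------------------------------------------------------------------
# gamete sampling
# ---------------------------------------------------------------------------


def sample_gametes(
    parent_haplotypes: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
    mutate: bool = True,
) -> np.ndarray:
    """Sample one gamete per parent from ``(k, 2, n_loci)`` parental haplotypes.

    Crossovers per chromosome ~ Poisson(length in Morgans), uniform positions,
    no interference; mutation flips each transmitted allele with probability
    ``gmap.mutation_rate``.
    """
    haps = np.asarray(parent_haplotypes, dtype=np.uint8)
    if haps.ndim == 2:
        haps = haps[None]
    k = haps.shape[0]
    out = np.empty((k, gmap.n_loci), dtype=np.uint8)
    for c, sl in gmap.chromosome_slices():
        pos = gmap.position[sl]
        nl = len(pos)
        if nl == 0:
            continue
        lam = gmap.chromosome_length[c] / 100.0  # Morgans
        n_xo = rng.poisson(lam, k)
        start = rng.integers(0, 2, k, dtype=np.int8)
        counts = np.zeros((k, nl), dtype=np.int16)
        kmax = int(n_xo.max()) if k else 0
        if kmax > 0:
            xo = rng.uniform(0.0, gmap.chromosome_length[c], (k, kmax))
            xo[np.arange(kmax)[None, :] >= n_xo[:, None]] = np.inf
            for j in range(kmax):
                counts += xo[:, j][:, None] < pos[None, :]
        choice = ((start[:, None] + counts) % 2).astype(np.uint8)
        block = haps[:, :, sl]
        out[:, sl] = np.take_along_axis(block, choice[:, None, :], axis=1)[:, 0]
    if mutate and gmap.mutation_rate > 0:
        # sample the (few) mutation events rather than a uniform per locus;
        # index collisions are vanishingly rare at realistic rates
        total = out.size
        n_mut = rng.binomial(total, gmap.mutation_rate)
        if n_mut:
            flat = rng.integers(0, total, n_mut)
            out.reshape(-1)[flat] ^= 1
    return out


def meiosis(
    parent_haplotypes: np.ndarray,
    gmap: GenomeMap,
    rng: np.random.Generator,
    mutate: bool = True,
) -> np.ndarray:
    """One gamete from a single parent's two phased haplotypes."""
    haps = np.asarray(parent_haplotypes, dtype=np.uint8)
    if haps.shape != (2, gmap.n_loci):
        raise ValueError("parent haplotypes must have shape (2, n_loci)")
    return sample_gametes(haps[None], gmap, rng, mutate=mutate)[0]


# ---------------------------------------------------------------------------
# historical population
# ---------------------------------------------------------------------------


def founder_population(
    gmap: GenomeMap,
    n: int,
    rng: np.random.Generator,
    allele_frequencies: np.ndarray | None = None,
) -> HaplotypePopulation:
    """Unrelated founders with per-locus allele frequencies drawn uniform(0, 1)
    unless given explicitly."""
    if allele_frequencies is None:
        allele_frequencies = rng.uniform(0.0, 1.0, gmap.n_loci)
    p = np.asarray(allele_frequencies, dtype=float)
    haps = (rng.random((n, 2, gmap.n_loci)) < p).astype(np.uint8)
    return HaplotypePopulation(ids=np.arange(n), haplotypes=haps, generation=0)


def simulate_historical(
    gmap: GenomeMap,
    n: int = 400,
    generations: int = 300,
    rng: np.random.Generator | int | None = None,
    founders: HaplotypePopulation | None = None,
) -> HaplotypePopulation:
    """Random mating at constant size ``n`` (equal sex ratio) for ``generations``
    generations with recurrent mutation; returns the final generation.

    ``generations=0`` returns the founders unchanged.
    """
    if n <= 0 or n % 2:
        raise ValueError("historical population size must be positive and even")
    if generations < 0:
        raise ValueError("generations must be >= 0")
    rng = np.random.default_rng(rng)
    pop = founders if founders is not None else founder_population(gmap, n, rng)
    if pop.n != n:
        raise ValueError("founder population size disagrees with n")
    if generations == 0:
        return pop
    haps = pop.haplotypes
    sex = pop.sex
    for g in range(1, generations + 1):
        males = rng.permutation(np.flatnonzero(sex == 0))
        females = rng.permutation(np.flatnonzero(sex == 1))
        # random monogamous pairs, each contributing one son and one
        # daughter: constant size with equal family sizes (Ne ~ 2N), the
        # regime that reproduces the reported marker/QTL segregation counts
        sires = np.repeat(males, 2)
        dams = np.repeat(females, 2)
        paternal = sample_gametes(haps[sires], gmap, rng)
        maternal = sample_gametes(haps[dams], gmap, rng)
        haps = np.stack([paternal, maternal], axis=1)
        sex = np.tile(np.array([0, 1], dtype=np.int8), n // 2)
    return HaplotypePopulation(
        ids=np.arange(n), haplotypes=haps, generation=generations, sex=sex
    )


def apply_maf_filter(
    pop: HaplotypePopulation,
    gmap: GenomeMap,
    threshold: float = 0.01,
) -> tuple[HaplotypePopulation, GenomeMap]:
    """Drop loci with minor allele frequency below ``threshold``.

    Returns the filtered population and map; surviving marker/QTL counts are
    available as ``gmap.n_markers`` / ``gmap.n_qtl`` on the returned map.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must be in [0, 0.5]")
    p = pop.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    keep = maf >= threshold
    newpop = HaplotypePopulation(
        ids=pop.ids,
        haplotypes=pop.haplotypes[:, :, keep],
        generation=pop.generation,
        sex=pop.sex,
    )
    return newpop, gmap.subset(keep)


# ---------------------------------------------------------------------------
# linkage disequilibrium
# ---------------------------------------------------------------------------


def _pairwise_r2(h: np.ndarray, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """r^2 between locus pairs from a (n_haplotypes, n_loci) 0/1 matrix."""
    x = h[:, i].astype(float)
    y = h[:, j].astype(float)
    x -= x.mean(axis=0)
    y -= y.mean(axis=0)
    vx = (x * x).mean(axis=0)
    vy = (y * y).mean(axis=0)
    cov = (x * y).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = cov * cov / (vx * vy)
    r2[(vx == 0) | (vy == 0)] = np.nan  # monomorphic pairs skipped
    return r2


def compute_ld_decay(
    pop: HaplotypePopulation,
    gmap: GenomeMap,
    bins: np.ndarray | None = None,
    max_pairs_per_bin: int = 2000,
    rng: np.random.Generator | int | None = None,
    markers_only: bool = True,
) -> pd.DataFrame:
    """Mean r^2 between marker pairs by map-distance bin.

    Pairs are sampled uniformly within each distance bin on each chromosome
    (up to ``max_pairs_per_bin`` per bin overall).  Monomorphic pairs are
    skipped.  Returns a DataFrame with columns
    ``bin_low, bin_high, mean_r2, n_pairs``.
    """
    rng = np.random.default_rng(rng)
    if bins is None:
        bins = np.array([0.0, 0.5, 1, 2, 5, 10, 20, 50, 100.0])
    bins = np.asarray(bins, dtype=float)
    h = pop.haplotypes.reshape(pop.n * 2, pop.n_loci)
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        ii, jj = [], []
        for c, sl in gmap.chromosome_slices():
            idx = np.arange(sl.start, sl.stop)
            if markers_only:
                idx = idx[~gmap.is_qtl[sl]]
            if len(idx) < 2:
                continue
            pos = gmap.position[idx]
            # sample left members, then a partner within [lo, hi)
            n_draw = max_pairs_per_bin
            left = rng.integers(0, len(idx), n_draw)
            lo_i = np.searchsorted(pos, pos[left] + lo, side="left")
            lo_i = np.maximum(lo_i, left + 1)  # partner strictly to the right
            hi_i = np.searchsorted(pos, pos[left] + hi, side="left")
            ok = hi_i > lo_i
            if not ok.any():
                continue
            left = left[ok]
            lo_i, hi_i = lo_i[ok], hi_i[ok]
            right = lo_i + (rng.random(len(left)) * (hi_i - lo_i)).astype(int)
            ii.append(idx[left])
            jj.append(idx[right])
        if not ii:
            rows.append((lo, hi, np.nan, 0))
            continue
        ii = np.concatenate(ii)
        jj = np.concatenate(jj)
        if len(ii) > max_pairs_per_bin:
            sel = rng.choice(len(ii), max_pairs_per_bin, replace=False)
            ii, jj = ii[sel], jj[sel]
        r2 = _pairwise_r2(h, ii, jj)
        r2 = r2[np.isfinite(r2)]
        rows.append((lo, hi, r2.mean() if r2.size else np.nan, int(r2.size)))
    return pd.DataFrame(rows, columns=["bin_low", "bin_high", "mean_r2", "n_pairs"])


def adjacent_marker_r2(pop: HaplotypePopulation, gmap: GenomeMap) -> float:
    """Mean r^2 between physically adjacent marker pairs (all chromosomes)."""
    h = pop.haplotypes.reshape(pop.n * 2, pop.n_loci)
    vals = []
    for c, sl in gmap.chromosome_slices():
        idx = np.arange(sl.start, sl.stop)[~gmap.is_qtl[sl]]
        if len(idx) < 2:
            continue
        r2 = _pairwise_r2(h, idx[:-1], idx[1:])
        vals.append(r2[np.isfinite(r2)])
    if not vals:
        return np.nan
    return float(np.concatenate(vals).mean())


def plot_ld_decay(decay: pd.DataFrame, ax=None):
    """Plot the binned LD-decay curve produced by :func:`compute_ld_decay`."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    mid = 0.5 * (decay["bin_low"] + decay["bin_high"])
    ax.plot(mid, decay["mean_r2"], marker="o")
    ax.set_xlabel("marker distance (cM)")
    ax.set_ylabel("mean $r^2$")
    ax.set_xscale("log")
    return ax
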