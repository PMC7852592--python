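"""Nucleus expansion, trait architecture, pens, attrition and group records."""

import numpy as np
import pandas as pd
import pytest

import penblup as pb
from penblup.components import VarianceComponents
from penblup.simulate import (
    PopulationDesign,
    ScenarioConfig,
    apply_attrition,
    assign_pens,
    assign_pens_all_generations,
    assign_trait_architecture,
    build_dataset,
    expand_recent_population,
    make_group_records,
    select_genotyped,
    simulate_genome,
    simulate_phenotypes,
)


@pytest.fixture(scope="module")
def full_pedigree():
    """Full-size pedigree expansion with a minimal genome (the pedigree
    structure is what is under test)."""
    rng = np.random.default_rng(42)
    gmap = pb.GenomeMap.random(n_chromosomes=1, n_markers=0, n_qtl=4, rng=rng)
    hist = pb.simulate_historical(gmap, n=400, generations=2, rng=rng)
    ped, pop = expand_recent_population(hist, gmap, PopulationDesign(), rng)
    return ped


class TestExpansion:
    def test_total_and_per_generation_counts(self, full_pedigree):
        ped = full_pedigree
        assert ped.n == 29430
        gens, counts = np.unique(ped.generation, return_counts=True)
        assert counts[0] == 630
        assert np.all(counts[1:] == 3600)
        # generations 5-8 hold 14,400 individuals
        assert np.isin(ped.generation, (5, 6, 7, 8)).sum() == 14400

    def test_mating_design(self, full_pedigree):
        ped = full_pedigree
        df = ped.to_dataframe()
        late = df[df.generation == 6]
        litters = late.groupby("litter")
        # every litter: 6 members, 3 males + 3 females, one sire and one dam
        assert (litters.size() == 6).all()
        assert (litters["sex"].sum() == 3).all()
        assert (litters["sire"].nunique() == 1).all()
        assert (litters["dam"].nunique() == 1).all()
        # each dam has exactly one litter per generation; 30 sires serve 600 litters
        per_litter = late.drop_duplicates("litter")
        assert per_litter["dam"].is_unique
        assert per_litter["sire"].nunique() == 30

    def test_generation_monotone_parents(self, full_pedigree):
        ped = full_pedigree
        known = ped.sire >= 0
        assert np.all(
            ped.generation[ped.sire[known]] == ped.generation[known] - 1
        )


class TestTraitArchitecture:
    def test_scaled_variances_hit_targets_exactly(self, tiny_sim):
        ped = tiny_sim.pedigree
        qtl = tiny_sim.population.dosages()[:, tiny_sim.gmap.is_qtl]
        ref = qtl[ped.generation == 0]
        arch = assign_trait_architecture(ref, 0.8, rng=np.random.default_rng(0))
        bv = arch.breeding_values(ref)
        assert bv[:, 0].var() == pytest.approx(30.0, abs=1e-8)
        assert bv[:, 1].var() == pytest.approx(100.0, abs=1e-8)

    def test_perfect_correlation_gives_proportional_bvs(self, tiny_sim):
        ped = tiny_sim.pedigree
        qtl = tiny_sim.population.dosages()[:, tiny_sim.gmap.is_qtl]
        ref = qtl[ped.generation == 0]
        arch = assign_trait_architecture(ref, 1.0, rng=np.random.default_rng(1))
        bv = arch.breeding_values(ref)
        k = np.sqrt(100.0 / 30.0)
        assert np.allclose(bv[:, 1], k * bv[:, 0], atol=1e-8)

    def test_effect_correlation_recovered_over_replicates(self, tiny_sim):
        ped = tiny_sim.pedigree
        qtl = tiny_sim.population.dosages()[:, tiny_sim.gmap.is_qtl]
        ref = qtl[ped.generation == 0]
        rng = np.random.default_rng(2)
        cors = [
            np.corrcoef(arch.effects[:, 0], arch.effects[:, 1])[0, 1]
            for arch in (
                assign_trait_architecture(ref, 0.8, rng=rng) for _ in range(25)
            )
        ]
        assert np.mean(cors) == pytest.approx(0.8, abs=0.05)

    def test_invalid_correlation(self, tiny_sim):
        qtl = tiny_sim.population.dosages()[:, tiny_sim.gmap.is_qtl]
        with pytest.raises(ValueError):
            assign_trait_architecture(qtl[:5], 1.5, rng=np.random.default_rng(0))


class TestPens:
    def test_S12_structure(self):
        rng = np.random.default_rng(3)
        litters = np.repeat(np.arange(600), 6)
        gi = assign_pens(np.arange(3600), litters, "S12_L2x3", rng)
        df = pd.DataFrame({"pen": gi.pen, "litter": litters[gi.member_ids]})
        sizes = df.groupby("pen").size()
        assert len(sizes) == 300 and (sizes == 12).all()
        assert (df.groupby("pen")["litter"].nunique() == 4).all()
        per = df.groupby(["litter", "pen"]).size()
        assert (per == 3).all()  # sublitters of 3
        assert (per.groupby("litter").size() == 2).all()  # two pens per litter

    def test_S24_structure(self):
        rng = np.random.default_rng(4)
        litters = np.repeat(np.arange(600), 6)
        gi = assign_pens(np.arange(3600), litters, "S24_L2x3", rng)
        df = pd.DataFrame({"pen": gi.pen, "litter": litters[gi.member_ids]})
        sizes = df.groupby("pen").size()
        assert len(sizes) == 150 and (sizes == 24).all()
        assert (df.groupby("pen")["litter"].nunique() == 8).all()

    def test_random_pens_fullsib_pairs_match_hypergeometric(self):
        # E[within-pen full-sib pairs] = C(12,2) * 5/(N-1) per pen
        rng = np.random.default_rng(5)
        n_lit, n = 50, 300
        litters = np.repeat(np.arange(n_lit), 6)
        expected_per_pen = 66 * 5 / (n - 1)
        counts = []
        for _ in range(300):
            gi = assign_pens(np.arange(n), litters, "S12_Lran", rng)
            df = pd.DataFrame({"pen": gi.pen, "litter": litters[gi.member_ids]})
            pairs = (
                df.groupby(["pen", "litter"]).size().map(lambda k: k * (k - 1) / 2).sum()
            )
            counts.append(pairs / df["pen"].nunique())
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected_per_pen) < 4 * se

    def test_sublitter_packing_never_reunites_a_litter(self):
        # property: for any admissible litter count and pen capacity, the two
        # sublitters of one litter never share a pen and pens are exactly full
        from hypothesis import given, settings
        from hypothesis import strategies as st

        from penblup.simulate import _pack_sublitters

        @settings(max_examples=40, deadline=None, derandomize=True)
        @given(
            n_groups=st.integers(2, 40),
            per_pen=st.sampled_from([2, 4, 8]),
            seed=st.integers(0, 1000),
        )
        def check(n_groups, per_pen, seed):
            n_lit = n_groups * per_pen // 2
            sub_litter = np.repeat(np.arange(n_lit), 2)
            assign = _pack_sublitters(sub_litter, per_pen,
                                      np.random.default_rng(seed))
            df = pd.DataFrame({"pen": assign, "litter": sub_litter})
            assert (df.groupby("pen").size() == per_pen).all()
            assert (df.groupby("pen")["litter"].nunique() == per_pen).all()

        check()

    def test_wrong_litter_size_rejected(self):
        rng = np.random.default_rng(6)
        with pytest.raises(ValueError, match="litters of exactly 6"):
            assign_pens(np.arange(10), np.repeat([0, 1], 5), "S12_L2x3", rng)


class TestPhenotypes:
    def test_zero_variances_leave_only_mean_and_bv(self, tiny_design, tiny_sim):
        ped = tiny_sim.pedigree
        qtl = tiny_sim.population.dosages()[:, tiny_sim.gmap.is_qtl]
        arch = assign_trait_architecture(
            qtl[ped.generation == 0], 0.8, rng=np.random.default_rng(0)
        )
        bv = arch.breeding_values(qtl)
        rng = np.random.default_rng(1)
        pens = assign_pens_all_generations(
            ped, "S12_L2x3", rng, generations=tiny_design.recorded_generations
        )
        zero = VarianceComponents(
            pen=np.zeros((2, 2)), litter=np.zeros((2, 2)),
            additive=np.eye(2), residual=np.zeros((2, 2)),
        )
        ph = simulate_phenotypes(ped, bv, pens, zero, rng,
                                 recorded_generations=tiny_design.recorded_generations,
                                 mean=(5.0, -2.0))
        assert np.allclose(ph["y1"], 5.0 + ph["tbv1"])
        assert np.allclose(ph["y2"], -2.0 + ph["tbv2"])

    def test_generating_variances_recovered_empirically(self, tiny_design, tiny_sim):
        # each simulated effect class matches its generating variance
        ped = tiny_sim.pedigree
        qtl = tiny_sim.population.dosages()[:, tiny_sim.gmap.is_qtl]
        arch = assign_trait_architecture(
            qtl[ped.generation == 0], 0.8, rng=np.random.default_rng(0)
        )
        bv = arch.breeding_values(qtl)
        rng = np.random.default_rng(7)
        comps = VarianceComponents.simulation_defaults(0.8)
        pens = assign_pens_all_generations(
            ped, "S12_L2x3", rng, generations=tiny_design.recorded_generations
        )
        ph = simulate_phenotypes(ped, bv, pens, comps, rng,
                                 recorded_generations=tiny_design.recorded_generations)
        # residual pair correlation ~ 0.5 within sampling error
        r = np.corrcoef(ph["e1"], ph["e2"])[0, 1]
        assert r == pytest.approx(0.5, abs=3 / np.sqrt(len(ph)))
        lit = ph.drop_duplicates("litter")
        for col, var in (("l1", 10.0), ("c1", 10.0), ("e1", 50.0)):
            vals = ph.drop_duplicates("pen")[col] if col == "c1" else (
                lit[col] if col == "l1" else ph[col]
            )
            se = var * np.sqrt(2.0 / len(vals))
            assert abs(np.var(vals) - var) < 3.5 * se

    def test_implied_heritabilities(self):
        c = VarianceComponents.simulation_defaults(0.8)
        tot = c.pen + c.litter + c.additive + c.residual
        h2 = np.diag(c.additive) / np.diag(tot)
        assert h2[0] == pytest.approx(0.30)
        assert h2[1] == pytest.approx(0.25)


class TestAttritionAndGenotyping:
    def test_zero_fraction_identity(self, tiny_dataset, tiny_design):
        ph = tiny_dataset.phenotypes.copy()
        ph["has_record"] = True
        out = apply_attrition(ph, tiny_dataset.pedigree, 0.0, np.random.default_rng(0))
        assert out["has_record"].all()

    def test_exact_fraction_and_breeders_kept(self, tiny_dataset):
        ped = tiny_dataset.pedigree
        ph = tiny_dataset.phenotypes
        n_rec = int(ph["has_record"].sum())
        n_all = len(ph)
        assert n_rec == round(0.8 * n_all)
        dropped = ph.loc[~ph["has_record"], "id"].to_numpy()
        assert not ped.breeding[ped.indices_of(dropped)].any()

    def test_mean_pen_size_after_attrition(self, tiny_dataset):
        rec = tiny_dataset.phenotypes[tiny_dataset.phenotypes.has_record]
        sizes = rec.groupby("pen").size()
        assert sizes.mean() == pytest.approx(9.6, abs=0.45)
        assert sizes.min() >= 4 - 2  # binomial tail at tiny scale
        assert sizes.max() <= 12

    def test_excessive_fraction_rejected(self, tiny_dataset):
        ph = tiny_dataset.phenotypes.copy()
        ph["has_record"] = True
        with pytest.raises(ValueError, match="attrition"):
            apply_attrition(ph, tiny_dataset.pedigree, 0.95, np.random.default_rng(0))

    @pytest.mark.parametrize("design", [0, 30, 100])
    def test_genotyping_designs(self, tiny_dataset, design):
        ped = tiny_dataset.pedigree
        ph = tiny_dataset.phenotypes
        ids = select_genotyped(ph, ped, design, np.random.default_rng(1))
        data_ids = ph.loc[ph.has_record, "id"].to_numpy()
        if design == 0:
            assert len(ids) == 0
        elif design == 100:
            assert np.array_equal(ids, np.sort(data_ids))
        else:
            assert len(ids) == round(0.3 * len(data_ids))
            breeders = data_ids[ped.breeding[ped.indices_of(data_ids)]]
            assert np.isin(breeders, ids).all()


class TestGroupRecords:
    def test_sum_conservation_and_singletons(self, tiny_dataset):
        ph = tiny_dataset.phenotypes
        gr = make_group_records(ph, tiny_dataset.groups)
        rec = ph[ph.has_record]
        assert gr["y1_sum"].sum() == pytest.approx(rec["y1"].sum())
        assert gr["group_size"].sum() == len(rec)
        # singleton group equals the individual's record
        one = pb.GroupIncidence(member_ids=rec["id"].to_numpy()[:3],
                                pen=np.arange(3))
        gr1 = make_group_records(ph[ph["id"].isin(one.member_ids)], one)
        assert np.allclose(
            np.sort(gr1["y1_sum"]), np.sort(rec["y1"].to_numpy()[:3])
        )

    def test_arithmetic(self):
        ph = pd.DataFrame(
            {
                "id": [1, 2, 3],
                "y1": [3.0, 4.5, -1.5],
                "has_record": [True, True, True],
            }
        )
        gi = pb.GroupIncidence(member_ids=[1, 2, 3], pen=[7, 7, 7])
        gr = make_group_records(ph, gi)
        assert gr["y1_sum"].iloc[0] == pytest.approx(6.0)
        assert gr["group_size"].iloc[0] == 3
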