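"""Mixed-model equations: design construction, residual structure, BLUP
solutions and their oracle equivalences."""

import numpy as np
import pytest
import scipy.sparse as sp

import penblup as pb
from penblup.components import VarianceComponents
from penblup.model import AnimalModel
from penblup.varcomp import MarginalStructures


@pytest.fixture(scope="module")
def group_model(tiny_dataset):
    return AnimalModel(
        tiny_dataset.pedigree,
        tiny_dataset.phenotypes,
        traits=("y1",),
        record_modes={"y1": "group"},
        groups=tiny_dataset.groups,
    )


def dense_gls_ebv(model, vc):
    """Oracle: direct GLS on the record-level covariance."""
    ms = MarginalStructures(model)
    V = ms.build_V(ms.components_to_theta(vc))
    Vi = np.linalg.inv(V)
    X, y = ms.X, ms.y
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = Vi @ (y - X @ beta)
    _, Z = model.design_blocks()
    T = len(model.traits)
    q = len(model.additive_ids)
    A = model.K_dense()
    Sa = vc.additive
    out = []
    for i_t in range(T):
        ah = np.zeros(q)
        for j_t in range(T):
            Zj = Z["additive"][ms.slices[j_t], j_t * q : (j_t + 1) * q]
            ah += Sa[i_t, j_t] * (A @ (Zj.T @ resid[ms.slices[j_t]]))
        out.append(ah)
    return beta, np.column_stack(out)


class TestDesign:
    def test_group_design_counts_members(self, group_model, tiny_dataset):
        X, Z = group_model.design_blocks()
        # T1 equals the group-size vector
        sizes = group_model._rec[0]["weights"]
        assert np.allclose(np.asarray(X.todense()).ravel(), sizes)
        # row sums of the litter design equal group sizes as well
        assert np.allclose(np.asarray(Z["litter"].sum(axis=1)).ravel(), sizes)

    def test_group_mode_requires_groups(self, tiny_dataset):
        with pytest.raises(ValueError, match="GroupIncidence"):
            AnimalModel(
                tiny_dataset.pedigree,
                tiny_dataset.phenotypes,
                traits=("y1",),
                record_modes={"y1": "group"},
            )

    def test_residual_structure_group_scaling(self, group_model, tiny_dataset):
        vc = tiny_dataset.components.subset([0])
        Rinv = group_model.residual_rinv(vc).diagonal()
        sizes = group_model._rec[0]["weights"]
        assert np.allclose(Rinv, 1.0 / (sizes * vc.residual[0, 0]))

    def test_bivariate_individual_residual_covariance(self, tiny_dataset):
        m = AnimalModel(
            tiny_dataset.pedigree,
            tiny_dataset.phenotypes,
            traits=("y1", "y2"),
            groups=tiny_dataset.groups,
        )
        vc = tiny_dataset.components
        # generating residual covariance 0.5*sqrt(50*220) = 52.44
        assert vc.residual[0, 1] == pytest.approx(52.44, abs=0.005)
        Rinv = m.residual_rinv(vc)
        n1 = m.n_records[0]
        R = np.linalg.inv(Rinv.toarray())
        assert R[0, 0] == pytest.approx(50.0)
        assert R[0, n1] == pytest.approx(vc.residual[0, 1])

    def test_mixed_mode_residual_structurally_diagonal(self, tiny_dataset):
        m = AnimalModel(
            tiny_dataset.pedigree,
            tiny_dataset.phenotypes,
            traits=("y1", "y2"),
            record_modes={"y1": "group"},
            groups=tiny_dataset.groups,
        )
        assert m.mixed_mode
        Rinv = m.residual_rinv(tiny_dataset.components)
        off = Rinv - sp.diags(Rinv.diagonal())
        assert abs(off).sum() == 0.0


class TestBlupSolutions:
    def test_single_record_shrinkage_closed_form(self):
        # one animal, one record, additive + residual only:
        # EBV = h^2 (y - mu_hat); with a single record mu_hat = y, EBV = 0;
        # add a second unrelated animal to identify the mean
        import pandas as pd

        from penblup.pedigree import Pedigree

        ped = Pedigree.from_dataframe(
            pd.DataFrame({"id": [1, 2], "sire": [0, 0], "dam": [0, 0]})
        )
        ph = pd.DataFrame(
            {"id": [1, 2], "litter": [1, 2], "pen": [1, 2],
             "y1": [10.0, 6.0], "has_record": [True, True]}
        )
        vc = VarianceComponents(pen=[[0.0]], litter=[[0.0]],
                                additive=[[30.0]], residual=[[70.0]])
        m = AnimalModel(ped, ph, traits=("y1",), random_effects=("additive",))
        res = m.fit(vc)
        mu = res.fixed_effects["y1"]
        # symmetric pair: mu_hat = 8, EBV_i = h2/(...) * shrinkage of (y - mu)
        # exact GLS: EBV = 30/(30+70+30) * (y_i - y_j) adjusted; check against oracle
        beta, ebv = dense_gls_ebv(m, vc)
        assert mu == pytest.approx(beta[0], abs=1e-9)
        assert np.allclose(res.ebv["y1"].to_numpy(), ebv[:, 0], atol=1e-9)
        # and against the explicit closed form EBV = h^2 (y - mu_hat)
        h2 = 30.0 / (30.0 + 70.0)
        assert res.ebv["y1"].iloc[0] == pytest.approx(h2 * (10.0 - 8.0), abs=1e-8)

    def test_zero_phenotypes_zero_solutions(self, tiny_dataset):
        ph = tiny_dataset.phenotypes.copy()
        ph["y1"] = 0.0
        m = AnimalModel(tiny_dataset.pedigree, ph, traits=("y1",),
                        record_modes={"y1": "group"}, groups=tiny_dataset.groups)
        res = m.fit(tiny_dataset.components.subset([0]))
        assert np.allclose(res.ebv["y1"], 0.0, atol=1e-12)
        assert res.fixed_effects["y1"] == pytest.approx(0.0)

    def test_location_equivariance(self, tiny_dataset):
        vc = tiny_dataset.components.subset([0])
        m1 = AnimalModel(tiny_dataset.pedigree, tiny_dataset.phenotypes,
                         traits=("y1",), groups=tiny_dataset.groups)
        r1 = m1.fit(vc)
        ph = tiny_dataset.phenotypes.copy()
        ph["y1"] = ph["y1"] + 7.0
        m2 = AnimalModel(tiny_dataset.pedigree, ph, traits=("y1",),
                         groups=tiny_dataset.groups)
        r2 = m2.fit(vc)
        assert r2.fixed_effects["y1"] - r1.fixed_effects["y1"] == pytest.approx(7.0, abs=1e-8)
        assert np.allclose(r1.ebv["y1"], r2.ebv["y1"], atol=1e-8)

    @pytest.mark.parametrize(
        "traits,modes",
        [
            (("y1",), {"y1": "group"}),
            (("y1",), {}),
            (("y1", "y2"), {"y1": "group"}),
            (("y1", "y2"), {}),
        ],
    )
    def test_mme_equals_dense_gls(self, tiny_dataset, traits, modes):
        m = AnimalModel(tiny_dataset.pedigree, tiny_dataset.phenotypes,
                        traits=traits, record_modes=modes,
                        groups=tiny_dataset.groups)
        vc = (tiny_dataset.components if len(traits) == 2
              else tiny_dataset.components.subset([0]))
        res = m.fit(vc)
        beta, ebv = dense_gls_ebv(m, vc)
        assert np.allclose(res.fixed_effects.to_numpy(), beta, atol=1e-8)
        for j, t in enumerate(m.traits):
            assert np.allclose(res.ebv[t.name].to_numpy(), ebv[:, j], atol=1e-8)

    def test_singleton_groups_reproduce_individual_model(self, tiny_dataset):
        rec = tiny_dataset.phenotypes[tiny_dataset.phenotypes.has_record]
        singles = pb.GroupIncidence(member_ids=rec["id"].to_numpy(),
                                    pen=np.arange(len(rec)))
        vc = tiny_dataset.components.subset([0])
        mg = AnimalModel(tiny_dataset.pedigree, tiny_dataset.phenotypes,
                         traits=("y1",), record_modes={"y1": "group"},
                         groups=singles)
        mi = AnimalModel(tiny_dataset.pedigree, tiny_dataset.phenotypes,
                         traits=("y1",), groups=singles)
        rg = mg.fit(vc)
        ri = mi.fit(vc)
        assert np.allclose(rg.ebv["y1"], ri.ebv["y1"], atol=1e-8)

    def test_bivariate_decouples_with_zero_covariances(self, tiny_dataset):
        vc = tiny_dataset.components.copy()
        for eff in ("pen", "litter", "additive", "residual"):
            blk = vc.block(eff)
            blk[0, 1] = blk[1, 0] = 0.0
        m2 = AnimalModel(tiny_dataset.pedigree, tiny_dataset.phenotypes,
                         traits=("y1", "y2"), record_modes={"y1": "group"},
                         groups=tiny_dataset.groups)
        r2 = m2.fit(vc)
        m1 = AnimalModel(tiny_dataset.pedigree, tiny_dataset.phenotypes,
                         traits=("y1",), record_modes={"y1": "group"},
                         groups=tiny_dataset.groups)
        r1 = m1.fit(vc.subset([0]))
        assert np.allclose(r2.ebv["y1"], r1.ebv["y1"], atol=1e-7)

    def test_fullsibs_same_sublitter_same_pen_identical_ebv(self, tiny_dataset):
        # pedigree-based group records cannot distinguish full sibs that share
        # litter and pen
        ph = tiny_dataset.phenotypes
        rec = ph[ph.has_record]
        vc = tiny_dataset.components.subset([0])
        m = AnimalModel(tiny_dataset.pedigree, ph, traits=("y1",),
                        record_modes={"y1": "group"}, groups=tiny_dataset.groups)
        res = m.fit(vc)
        ebv = res.ebv.set_index("id")["y1"]
        # restrict to last-generation animals: earlier-generation sibs can be
        # parents and then differ through their progeny's records
        last = rec[rec["generation"] == rec["generation"].max()]
        found = 0
        for (lit, pen), members in last.groupby(["litter", "pen"]):
            if len(members) >= 2:
                vals = ebv.loc[members["id"]].to_numpy()
                assert np.allclose(vals, vals[0], atol=1e-8)
                found += 1
        assert found > 10


class TestGenomicModels:
    def test_ssgblup_with_all_genotyped_matches_gblup(self, tiny_dataset, tiny_sim):
        ped = tiny_dataset.pedigree
        ph = tiny_dataset.phenotypes
        data_ids = np.sort(ph.loc[ph.has_record, "id"].to_numpy())
        idx = ped.indices_of(data_ids)
        dos = tiny_sim.population.dosages()[np.ix_(idx, ~tiny_sim.gmap.is_qtl)]
        vc = tiny_dataset.components.subset([0])
        kwargs = dict(
            traits=("y1",), record_modes={"y1": "group"}, groups=tiny_dataset.groups,
            genotyped_ids=data_ids, dosages=dos,
        )
        mss = AnimalModel(ped, ph, relationship="single-step", **kwargs)
        mg = AnimalModel(ped, ph, relationship="genomic", **kwargs)
        rss = mss.fit(vc)
        rg = mg.fit(vc)
        ss = rss.ebv.set_index("id").loc[data_ids, "y1"].to_numpy()
        gg = rg.ebv.set_index("id").loc[data_ids, "y1"].to_numpy()
        # identical for genotyped animals when everyone is genotyped
        assert np.corrcoef(ss, gg)[0, 1] > 0.9999

    def test_ssgblup_with_pedigree_prior_reduces_to_pblup(self, tiny_dataset):
        # Gw = A11 makes H = A exactly
        ped = tiny_dataset.pedigree
        ids = tiny_dataset.genotyped_30
        A11 = ped.additive_matrix(ped.indices_of(ids), ped.indices_of(ids))
        vc = tiny_dataset.components.subset([0])
        m = AnimalModel(ped, tiny_dataset.phenotypes, traits=("y1",),
                        record_modes={"y1": "group"}, groups=tiny_dataset.groups,
                        relationship="single-step", genotyped_ids=ids,
                        dosages=np.zeros((len(ids), 3)))
        m._Gw = pb.RelationshipMatrix(ids=ids, values=A11, kind="Gw")
        res = m.fit(vc)
        mp = AnimalModel(ped, tiny_dataset.phenotypes, traits=("y1",),
                         record_modes={"y1": "group"}, groups=tiny_dataset.groups)
        rp = mp.fit(vc)
        assert np.allclose(res.ebv["y1"], rp.ebv["y1"], atol=1e-6)
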