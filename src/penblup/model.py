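"""Henderson mixed-model equations for individually and group-recorded traits.

The univariate individual-record animal model is

    y = 1 mu + Z_l l + Z_c c + Z_a a + e,

with litter l ~ N(0, I sigma_l^2), pen c ~ N(0, I sigma_c^2), additive
a ~ N(0, Omega sigma_a^2) and residual e ~ N(0, I sigma_e^2), where Omega is
A (pedigree), Gw (genomic) or H (single-step).  Premultiplying by the group
incidence matrix T turns it into the group-record model

    T y = T1 mu + T Z_l l + T Z_c c + T Z_a a + T e,

whose records are pen sums, whose design columns count pen members per effect
level (T1 is the vector of group sizes) and whose residual covariance is
diagonal with entries group_size * sigma_e^2 (groups are disjoint).

The bivariate model stacks two traits with 2x2 covariance blocks Kronecker
the effect structure.  When one trait has group records and the other
individual records, the cross-trait residual covariance is structurally
excluded from the model (the parameter simply does not exist in this
formulation); for two individually recorded traits it applies to animals
recorded on both.

``AnimalModel.fit`` solves the sparse MME directly (SuperLU) with iterative
refinement to a relative residual below the solver tolerance and returns a
:class:`BLUPResults`; ``AnimalModel.fit_reml`` estimates the (co)variance
components by AI-REML (see :mod:`penblup.varcomp`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .components import VarianceComponents
from .kinship import RelationshipMatrix, assemble_H, genomic_matrix, h_inverse
from .pedigree import Pedigree
from .simulate import GroupIncidence

RELATIONSHIPS = ("pedigree", "genomic", "single-step")


@dataclass
class TraitSpec:
    name: str  # phenotype column
    mode: str  # "individual" | "group"


class AnimalModel:
    """Mixed animal model with an overall mean per trait and (by default)
    litter + pen + additive random effects.

    Parameters
    ----------
    pedigree : Pedigree
    phenotypes : DataFrame with columns id, has_record, the trait columns and
        litter / pen where those effects are modeled.
    traits : sequence of trait column names (1 or 2).
    record_modes : mapping trait -> "individual" | "group"
        (default: individual).
    groups : GroupIncidence, required when any trait uses group records.
    relationship : "pedigree" (A), "genomic" (Gw over the genotyped animals)
        or "single-step" (H over the whole pedigree).
    genotyped_ids, dosages : genotyped animals and their 0/1/2 marker matrix
        (required for genomic / single-step).
    random_effects : which random effects to fit; "additive" is mandatory.
    """

    def __init__(
        self,
        pedigree: Pedigree,
        phenotypes: pd.DataFrame,
        traits=("y1",),
        record_modes: dict | None = None,
        groups: GroupIncidence | None = None,
        relationship: str = "pedigree",
        genotyped_ids=None,
        dosages: np.ndarray | None = None,
        blend_weight: float = 0.05,
        random_effects=("litter", "pen", "additive"),
    ) -> None:
        if relationship not in RELATIONSHIPS:
            raise ValueError(f"relationship must be one of {RELATIONSHIPS}")
        record_modes = record_modes or {}
        self.traits = [
            TraitSpec(t, record_modes.get(t, "individual"))
            for t in np.atleast_1d(traits)
        ]
        if not 1 <= len(self.traits) <= 2:
            raise ValueError("one or two traits are supported")
        for t in self.traits:
            if t.mode not in ("individual", "group"):
                raise ValueError(f"unknown record mode {t.mode!r}")
        if any(t.mode == "group" for t in self.traits) and groups is None:
            raise ValueError("group-recorded trait requires a GroupIncidence")
        if "additive" not in random_effects:
            raise ValueError("the additive effect cannot be dropped")
        self.random_effect_names = tuple(
            e for e in ("litter", "pen", "additive") if e in random_effects
        )
        self.pedigree = pedigree
        self.phenotypes = phenotypes
        self.groups = groups
        self.relationship = relationship
        self.blend_weight = blend_weight
        self.genotyped_ids = (
            np.atleast_1d(genotyped_ids) if genotyped_ids is not None else None
        )
        self.dosages = dosages
        if relationship in ("genomic", "single-step"):
            if self.genotyped_ids is None or dosages is None:
                raise ValueError(
                    f"{relationship} model requires genotyped_ids and dosages"
                )
        self._Gw: RelationshipMatrix | None = None
        self._build_records()
        self._build_designs()

    # ------------------------------------------------------------------
    # record and design construction
    # ------------------------------------------------------------------

    @property
    def mixed_mode(self) -> bool:
        """True when the traits mix group and individual records (the
        cross-trait residual covariance then has no parameter)."""
        modes = {t.mode for t in self.traits}
        return len(self.traits) == 2 and modes == {"group", "individual"}

    def _build_records(self) -> None:
        ph = self.phenotypes
        self._rec: list[dict] = []
        for t in self.traits:
            rows = ph[ph["has_record"] & ph[t.name].notna()]
            ids = rows["id"].to_numpy()
            y_ind = rows[t.name].to_numpy(dtype=float)
            entry = {"ids": ids, "y_individual": y_ind}
            if "litter" in self.random_effect_names:
                entry["litter"] = rows["litter"].to_numpy()
            if "pen" in self.random_effect_names:
                entry["pen"] = (
                    self.groups.pen_of(ids)
                    if self.groups is not None
                    else rows["pen"].to_numpy()
                )
            if t.mode == "group":
                T, pen_labels = self.groups.matrix(ids)
                entry["T"] = T
                entry["y"] = T @ y_ind
                entry["weights"] = np.asarray(T.sum(axis=1)).ravel()  # sizes
                entry["group_pens"] = pen_labels
            else:
                entry["y"] = y_ind
                entry["weights"] = np.ones(len(ids))
            self._rec.append(entry)
        self.n_records = [len(r["y"]) for r in self._rec]

    def _build_designs(self) -> None:
        self.effect_levels: dict[str, np.ndarray] = {}
        for eff in ("litter", "pen"):
            if eff in self.random_effect_names:
                self.effect_levels[eff] = np.unique(
                    np.concatenate([r[eff] for r in self._rec])
                )
        self.additive_ids = (
            self.genotyped_ids if self.relationship == "genomic" else self.pedigree.ids
        )
        self.effect_levels["additive"] = self.additive_ids
        anim_pos = {int(i): k for k, i in enumerate(self.additive_ids)}

        def incidence(labels, levels):
            col = np.searchsorted(levels, labels)
            if np.any(col >= len(levels)) or np.any(levels[col] != labels):
                raise ValueError("label outside level set")
            return sp.csr_matrix(
                (np.ones(len(labels)), (np.arange(len(labels)), col)),
                shape=(len(labels), len(levels)),
            )

        self._design: list[dict] = []
        for t, r in zip(self.traits, self._rec):
            d = {}
            for eff in ("litter", "pen"):
                if eff in self.random_effect_names:
                    d[eff] = incidence(r[eff], self.effect_levels[eff])
            try:
                acol = np.array([anim_pos[int(i)] for i in r["ids"]])
            except KeyError as e:
                raise ValueError(
                    f"recorded animal {e} is not an additive-effect level "
                    "(not genotyped under the genomic model?)"
                ) from None
            d["additive"] = sp.csr_matrix(
                (np.ones(len(r["ids"])), (np.arange(len(r["ids"])), acol)),
                shape=(len(r["ids"]), len(self.additive_ids)),
            )
            d["X"] = sp.csr_matrix(np.ones((len(r["ids"]), 1)))
            if t.mode == "group":
                T = r["T"]
                d = {k: T @ v for k, v in d.items()}
            self._design.append(d)

    # ------------------------------------------------------------------
    # covariance structures
    # ------------------------------------------------------------------

    def Gw(self) -> RelationshipMatrix:
        if self._Gw is None:
            self._Gw = genomic_matrix(
                self.dosages, self.genotyped_ids, self.pedigree, w=self.blend_weight
            )
        return self._Gw

    def K_inverse(self) -> sp.csr_matrix:
        """Sparse inverse of the additive relationship structure Omega."""
        if self.relationship == "pedigree":
            return self.pedigree.a_inverse()
        if self.relationship == "genomic":
            return sp.csr_matrix(np.linalg.inv(self.Gw().values))
        return h_inverse(self.pedigree, self.Gw())

    def K_dense(self) -> np.ndarray:
        """Dense Omega for small problems (test oracles, REML structures)."""
        if self.relationship == "pedigree":
            return self.pedigree.additive_matrix()
        if self.relationship == "genomic":
            return self.Gw().values
        return assemble_H(self.pedigree, self.Gw()).values

    def log_det_K(self) -> float:
        if self.relationship == "pedigree":
            return self.pedigree.log_det_A()
        return float(np.linalg.slogdet(self.K_dense())[1])

    def residual_rinv(self, components: VarianceComponents) -> sp.csr_matrix:
        """Sparse R^-1 over the stacked records.

        Individual records: 1/sigma_e^2; group records: 1/(size sigma_e^2);
        a cross-trait residual covariance applies only to animals with
        individual records on both traits."""
        Re = components.residual
        n_tot = sum(self.n_records)
        offs = np.r_[0, np.cumsum(self.n_records)]
        diag = np.concatenate(
            [r["weights"] * Re[j, j] for j, r in enumerate(self._rec)]
        )
        cross = (
            len(self.traits) == 2
            and all(t.mode == "individual" for t in self.traits)
            and Re[0, 1] != 0.0
        )
        if not cross:
            return sp.diags(1.0 / diag, format="csr")
        ids0, ids1 = self._rec[0]["ids"], self._rec[1]["ids"]
        common, i0, i1 = np.intersect1d(ids0, ids1, return_indices=True)
        det = Re[0, 0] * Re[1, 1] - Re[0, 1] ** 2
        if det <= 0:
            raise ValueError("singular residual covariance block; drop the covariance")
        rinv = np.empty(n_tot)
        rinv[offs[0] : offs[1]] = 1.0 / Re[0, 0]
        rinv[offs[1] : offs[2]] = 1.0 / Re[1, 1]
        rinv[offs[0] + i0] = Re[1, 1] / det
        rinv[offs[1] + i1] = Re[0, 0] / det
        rows = np.r_[offs[0] + i0, offs[1] + i1]
        cols = np.r_[offs[1] + i1, offs[0] + i0]
        vals = np.full(2 * len(common), -Re[0, 1] / det)
        off_diag = sp.coo_matrix((vals, (rows, cols)), shape=(n_tot, n_tot))
        return (sp.diags(rinv) + off_diag).tocsr()

    def log_det_R(self, components: VarianceComponents) -> float:
        Re = components.residual
        total = 0.0
        cross = (
            len(self.traits) == 2
            and all(t.mode == "individual" for t in self.traits)
            and Re[0, 1] != 0.0
        )
        if cross:
            ids0, ids1 = self._rec[0]["ids"], self._rec[1]["ids"]
            common, _, _ = np.intersect1d(ids0, ids1, return_indices=True)
            n_pair = len(common)
            det = Re[0, 0] * Re[1, 1] - Re[0, 1] ** 2
            total += n_pair * np.log(det)
            total += (len(ids0) - n_pair) * np.log(Re[0, 0])
            total += (len(ids1) - n_pair) * np.log(Re[1, 1])
            return total
        for j, r in enumerate(self._rec):
            total += float(np.log(r["weights"] * Re[j, j]).sum())
        return total

    # ------------------------------------------------------------------
    # MME assembly and solving
    # ------------------------------------------------------------------

    def _check_components(self, components: VarianceComponents) -> VarianceComponents:
        if components.n_traits != len(self.traits):
            raise ValueError("components trait dimension does not match the model")
        for eff in self.random_effect_names:
            blk = components.block(eff)
            if np.linalg.det(blk) <= 0:
                raise ValueError(
                    f"singular {eff} covariance block; set the covariance to "
                    "zero to decouple the traits or drop the effect"
                )
        return components

    def stacked_y(self) -> np.ndarray:
        return np.concatenate([r["y"] for r in self._rec])

    def design_blocks(self):
        """(X, {effect: Z}) as sparse matrices over the stacked records with
        trait-major effect columns."""
        X = sp.block_diag([d["X"] for d in self._design], format="csr")
        Z = {
            eff: sp.block_diag([d[eff] for d in self._design], format="csr")
            for eff in self.random_effect_names
        }
        return X, Z

    def build_mme(self, components: VarianceComponents):
        """Assemble the sparse MME coefficient matrix, right-hand side and the
        equation layout {effect: (offset, n_levels)}."""
        components = self._check_components(components)
        T = len(self.traits)
        X, Z = self.design_blocks()
        W = sp.hstack([X] + [Z[e] for e in self.random_effect_names], format="csr")
        y = self.stacked_y()
        Rinv = self.residual_rinv(components)
        C = (W.T @ Rinv @ W).tocsr()
        rhs = W.T @ (Rinv @ y)
        layout = {"p": T, "n_eq": C.shape[0]}
        off = T
        prior_rows, prior_cols, prior_vals = [], [], []
        for eff in self.random_effect_names:
            q = len(self.effect_levels[eff])
            layout[eff] = (off, q)
            Sig = components.block(eff)
            Sinv = (
                np.linalg.inv(Sig) if Sig.shape[0] > 1 else np.array([[1.0 / Sig[0, 0]]])
            )
            Kinv = (
                self.K_inverse() if eff == "additive" else sp.identity(q, format="coo")
            )
            kron = sp.kron(sp.csr_matrix(Sinv), Kinv, format="coo")
            prior_rows.append(kron.row + off)
            prior_cols.append(kron.col + off)
            prior_vals.append(kron.data)
            off += Sinv.shape[0] * q
        prior = sp.coo_matrix(
            (
                np.concatenate(prior_vals),
                (np.concatenate(prior_rows), np.concatenate(prior_cols)),
            ),
            shape=C.shape,
        )
        return (C + prior.tocsr()).tocsc(), rhs, layout

    def fit(
        self,
        components: VarianceComponents,
        tol: float = 1e-10,
        solver: str = "auto",
        max_refinements: int = 10,
    ) -> "BLUPResults":
        """Solve the MME (BLUP with the given variance components).

        Small systems use a direct sparse LU factorization with iterative
        refinement; large animal-model systems use Jacobi-preconditioned
        conjugate gradients (the standard choice for MMEs at this scale).
        Either way the solution must reach a relative residual of ``tol``.
        """
        C, rhs, layout = self.build_mme(components)
        rhs_norm = np.linalg.norm(rhs)
        if rhs_norm == 0:
            sol = np.zeros(C.shape[0])
            return BLUPResults(self, components, sol, layout, residual=0.0)
        if solver == "auto":
            solver = "direct" if C.shape[0] <= 6000 else "pcg"
        if solver == "direct":
            lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
            sol = lu.solve(rhs)
            rel = np.inf
            for _ in range(max_refinements):
                resid = rhs - C @ sol
                rel = np.linalg.norm(resid) / rhs_norm
                if rel <= tol:
                    break
                sol = sol + lu.solve(resid)
        elif solver == "pcg":
            M = sp.diags(1.0 / C.diagonal())
            sol = np.zeros(C.shape[0])
            rel = np.inf
            for max_it in (3000, 20000):
                sol, info = spla.cg(
                    C, rhs, x0=sol, M=M, rtol=0.01 * tol, maxiter=max_it
                )
                rel = np.linalg.norm(rhs - C @ sol) / rhs_norm
                if rel <= tol:
                    break
        else:
            raise ValueError("solver must be 'auto', 'direct' or 'pcg'")
        if rel > tol:
            raise RuntimeError(
                f"MME {solver} solve did not reach relative residual {tol:.0e} "
                f"(achieved {rel:.2e}); the system may be ill-conditioned"
            )
        return BLUPResults(self, components, sol, layout, residual=float(rel))

    def fit_reml(self, start=None, options=None):
        """Estimate (co)variance components by AI-REML; see penblup.varcomp."""
        from .varcomp import reml_estimate

        return reml_estimate(self, start=start, options=options)


class BLUPResults:
    """Solutions of the mixed-model equations.

    Attributes
    ----------
    fixed_effects : pd.Series, the overall mean per trait.
    ebv : DataFrame (id + one column per trait) of estimated breeding values
        for every additive-effect level (all pedigree animals, or the
        genotyped set under the pure genomic model).
    """

    def __init__(self, model, components, solution, layout, residual=0.0):
        self.model = model
        self.components = components
        self.solution = solution
        self.layout = layout
        self.solve_residual = residual
        self.fixed_effects = pd.Series(
            solution[: layout["p"]], index=[t.name for t in model.traits], name="mean"
        )
        self.random_effects = {}
        for eff in model.random_effect_names:
            off, q = layout[eff]
            levels = model.effect_levels[eff]
            cols = {
                t.name: solution[off + j * q : off + (j + 1) * q]
                for j, t in enumerate(model.traits)
            }
            self.random_effects[eff] = pd.DataFrame({"level": levels, **cols})
        self.ebv = self.random_effects["additive"].rename(columns={"level": "id"})

    def ebv_table(self, tag: str = "") -> pd.DataFrame:
        """Long-format (id, trait, ebv, model) table."""
        return pd.concat(
            [
                pd.DataFrame(
                    {
                        "id": self.ebv["id"],
                        "trait": t.name,
                        "ebv": self.ebv[t.name],
                        "model": tag,
                    }
                )
                for t in self.model.traits
            ],
            ignore_index=True,
        )

    def summary(self) -> str:
        lines = ["Mixed-model (BLUP) solution", "=" * 29]
        modes = ", ".join(f"{t.name}[{t.mode}]" for t in self.model.traits)
        lines.append(f"traits:        {modes}")
        lines.append(f"relationship:  {self.model.relationship}")
        lines.append(f"records:       {self.model.n_records}")
        lines.append(f"equations:     {self.layout['n_eq']}")
        lines.append(f"solve rel.res: {self.solve_residual:.2e}")
        lines.append("")
        lines.append("fixed effects (overall mean):")
        for name, val in self.fixed_effects.items():
            lines.append(f"  {name:>8s}  {val: .4f}")
        for eff in self.model.random_effect_names:
            df = self.random_effects[eff]
            sds = ", ".join(
                f"{c}: {df[c].std():.3f}" for c in df.columns if c != "level"
            )
            lines.append(f"{eff:>9s} solutions ({len(df)} levels)  sd {sds}")
        return "\n".join(lines)
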