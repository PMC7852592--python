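"""Restricted maximum likelihood with average-information (AI) updates.

The REML objective is evaluated on the marginal (record-level) covariance

    V(theta) = sum_k theta_k F_k,

which is linear in the (co)variance parameters: every random effect
contributes F = Z_i K Z_j' blocks (K = I for litter and pen, K = A / Gw / H
for the additive effect) and the residual contributes diagonal blocks
(group records: the group sizes) plus, for two individually recorded traits,
an alignment block for animals recorded on both.  Group-record data keep V
small (one row per pen), which is what makes this route practical even for
large pedigrees: the pedigree only enters through quadratic forms Q A Q'
computed from the sparse Cholesky-like factorization of A.

Updates are Newton steps with the average-information matrix

    AI_kl = 1/2 y' P F_k P F_l P y,      grad_k = -1/2 [tr(P F_k) - y' P F_k P y],

safeguarded by step halving (with a Levenberg ridge when the AI matrix is
not positive definite) so the restricted log-likelihood never decreases;
variances are floored at 1e-8 rather than removed.  For mixed group +
individual record models the cross-trait residual covariance is not a
parameter at all (structural exclusion).

``restricted_loglik`` offers two routes — the dense-V formula and the
MME-factorization identity  -2 logL = log|R| + log|G| + log|C| + y'Py —
which agree to numerical precision and are both exercised by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .components import EFFECTS, VarianceComponents

LOG2PI = np.log(2.0 * np.pi)


def _sym_inverse_from_chol(cf) -> np.ndarray:
    """Full symmetric inverse from a scipy cho_factor (LAPACK dpotri)."""
    c, lower = cf
    inv, info = la.lapack.dpotri(c, lower=lower)
    if info != 0:
        raise la.LinAlgError(f"dpotri failed with info={info}")
    # dpotri fills only one triangle
    inv = np.tril(inv) + np.tril(inv, -1).T if lower else np.triu(inv) + np.triu(inv, 1).T
    return inv


@dataclass
class RemlOptions:
    """Iteration controls for AI-REML."""

    max_iter: int = 200
    tol_param: float = 1e-8  # relative parameter change
    tol_grad: float = 1e-6  # gradient infinity norm
    variance_floor: float = 1e-8
    max_halvings: int = 30
    verbose: bool = False

    def __post_init__(self) -> None:
        if self.tol_param <= 0 or self.tol_grad <= 0:
            raise ValueError("convergence thresholds must be positive")


class MarginalStructures:
    """Dense V(theta) = sum theta_k F_k structures for a fitted model."""

    def __init__(self, model) -> None:
        self.model = model
        self.y = model.stacked_y()
        X, _ = model.design_blocks()
        self.X = np.asarray(X.todense())
        self.n = len(self.y)
        self.p = self.X.shape[1]
        n_rec = model.n_records
        self.slices = []
        off = 0
        for n_t in n_rec:
            self.slices.append(slice(off, off + n_t))
            off += n_t
        T = len(model.traits)
        self.blocks: dict = {}
        _, Z = model.design_blocks()
        for eff in model.random_effect_names:
            q = len(model.effect_levels[eff])
            Zt = [
                Z[eff][self.slices[j], j * q : (j + 1) * q] for j in range(T)
            ]
            if eff == "additive" and model.relationship == "pedigree":
                Q = sp.vstack(Zt, format="csr")
                M = model.pedigree.relationship_product(Q)
            else:
                if eff == "additive":
                    K = model.K_dense()
                    Q = sp.vstack(Zt, format="csr")
                    M = np.asarray((Q @ K @ Q.T))
                else:
                    Q = sp.vstack(Zt, format="csr")
                    M = np.asarray((Q @ Q.T).todense())
            offs = np.r_[0, np.cumsum(n_rec)]
            for i in range(T):
                for j in range(i, T):
                    self.blocks[(eff, i, j)] = M[
                        offs[i] : offs[i + 1], offs[j] : offs[j + 1]
                    ]
        # residual structures: diagonal per trait, alignment across traits
        self.resid_diag = [r["weights"] for r in model._rec]
        self.resid_cross = None
        if (
            T == 2
            and all(t.mode == "individual" for t in model.traits)
        ):
            ids0, ids1 = model._rec[0]["ids"], model._rec[1]["ids"]
            common, i0, i1 = np.intersect1d(ids0, ids1, return_indices=True)
            if len(common):
                E = sp.coo_matrix(
                    (np.ones(len(common)), (i0, i1)),
                    shape=(len(ids0), len(ids1)),
                ).toarray()
                self.resid_cross = E
        self.params = self._parameter_list()

    def _parameter_list(self):
        T = len(self.model.traits)
        params = []
        for eff in (*self.model.random_effect_names, "residual"):
            for i in range(T):
                params.append((eff, i, i))
            if T == 2:
                if eff == "residual" and self.resid_cross is None:
                    continue  # structural zero (mixed record modes)
                params.append((eff, 0, 1))
        return params

    # -- V assembly ------------------------------------------------------

    def components_to_theta(self, vc: VarianceComponents) -> np.ndarray:
        return np.array([vc.block(e)[i, j] for e, i, j in self.params])

    def theta_to_components(self, theta: np.ndarray) -> VarianceComponents:
        T = len(self.model.traits)
        blocks = {e: np.zeros((T, T)) for e in EFFECTS}
        for val, (e, i, j) in zip(theta, self.params):
            blocks[e][i, j] = val
            blocks[e][j, i] = val
        return VarianceComponents(**blocks)

    def build_V(self, theta: np.ndarray) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        for val, (eff, i, j) in zip(theta, self.params):
            self._add_F(V, eff, i, j, val)
        return V

    def _add_F(self, V, eff, i, j, scale=1.0):
        si, sj = self.slices[min(i, j)], self.slices[max(i, j)]
        if eff == "residual":
            if i == j:
                idx = np.arange(si.start, si.stop)
                V[idx, idx] += scale * self.resid_diag[i]
            else:
                V[si, sj] += scale * self.resid_cross
                V[sj, si] += scale * self.resid_cross.T
            return
        M = self.blocks[(eff, min(i, j), max(i, j))]
        if i == j:
            V[si, sj] += scale * M
        else:
            V[si, sj] += scale * M
            V[sj, si] += scale * M.T

    def F_matvec(self, eff, i, j, v: np.ndarray) -> np.ndarray:
        """F_k @ v for parameter (eff, i, j)."""
        out = np.zeros_like(v)
        si, sj = self.slices[min(i, j)], self.slices[max(i, j)]
        if eff == "residual":
            if i == j:
                d = self.resid_diag[i]
                out[si] = d[:, None] * v[si] if v.ndim > 1 else d * v[si]
            else:
                out[si] += self.resid_cross @ v[sj]
                out[sj] += self.resid_cross.T @ v[si]
            return out
        M = self.blocks[(eff, min(i, j), max(i, j))]
        if i == j:
            out[si] = M @ v[si]
        else:
            out[si] += M @ v[sj]
            out[sj] += M.T @ v[si]
        return out

    def trace_inner(self, S: np.ndarray, eff, i, j) -> float:
        """tr(S F_k) for symmetric S."""
        si, sj = self.slices[min(i, j)], self.slices[max(i, j)]
        if eff == "residual":
            if i == j:
                d = np.arange(si.start, si.stop)
                return float((S[d, d] * self.resid_diag[i]).sum())
            return 2.0 * float((S[si, sj] * self.resid_cross).sum())
        M = self.blocks[(eff, min(i, j), max(i, j))]
        if i == j:
            return float((S[si, sj] * M).sum())
        return 2.0 * float((S[si, sj] * M).sum())

    def quad_inner(self, v: np.ndarray, eff, i, j) -> float:
        """v' F_k v."""
        return float(v @ self.F_matvec(eff, i, j, v))


# ---------------------------------------------------------------------------
# restricted log-likelihood (two routes)
# ---------------------------------------------------------------------------


def restricted_loglik(model, components: VarianceComponents, method: str = "dense") -> float:
    """REML log-likelihood of the model's records under the given components.

    ``method='dense'`` works on the record-level covariance V;
    ``method='mme'`` uses the sparse MME factorization identity.  The two
    agree to numerical precision.
    """
    if method == "dense":
        ms = MarginalStructures(model)
        theta = ms.components_to_theta(components)
        return _loglik_dense(ms, theta)[0]
    if method == "mme":
        return _loglik_mme(model, components)
    raise ValueError("method must be 'dense' or 'mme'")


def _loglik_dense(ms: MarginalStructures, theta: np.ndarray):
    V = ms.build_V(theta)
    try:
        cf = la.cho_factor(V, lower=True, check_finite=False)
    except la.LinAlgError:
        return -np.inf, None
    logdetV = 2.0 * np.log(np.diag(cf[0])).sum()
    ViX = la.cho_solve(cf, ms.X, check_finite=False)
    XtViX = ms.X.T @ ViX
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf, None
    Viy = la.cho_solve(cf, ms.y, check_finite=False)
    beta = la.solve(XtViX, ViX.T @ ms.y, assume_a="pos")
    Py = Viy - ViX @ beta
    yPy = float(ms.y @ Py)
    ll = -0.5 * (
        logdetV + logdetXtViX + yPy + (ms.n - ms.p) * LOG2PI
    )
    return ll, {"cf": cf, "ViX": ViX, "XtViX": XtViX, "Py": Py, "beta": beta}


def _loglik_mme(model, components: VarianceComponents) -> float:
    C, rhs, layout = model.build_mme(components)
    if C.shape[0] > 20000:
        raise ValueError(
            "the MME factorization route is for moderate systems; "
            "use method='dense' (record-level covariance) at scale"
        )
    y = model.stacked_y()
    Rinv = model.residual_rinv(components)
    lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
    sol = lu.solve(rhs)
    yPy = float(y @ (Rinv @ y) - sol @ rhs)
    logdetC = float(np.log(np.abs(lu.U.diagonal())).sum())
    logdetR = model.log_det_R(components)
    logdetG = 0.0
    T = len(model.traits)
    for eff in model.random_effect_names:
        q = len(model.effect_levels[eff])
        Sig = components.block(eff)
        sign, ld = np.linalg.slogdet(Sig)
        logdetG += q * ld
        if eff == "additive":
            logdetG += T * model.log_det_K()
    n, p = len(y), layout["p"]
    return -0.5 * (logdetR + logdetG + logdetC + yPy + (n - p) * LOG2PI)


# ---------------------------------------------------------------------------
# AI-REML
# ---------------------------------------------------------------------------


@dataclass
class REMLResults:
    """Point estimates, standard errors and convergence diagnostics."""

    components: VarianceComponents
    standard_errors: dict
    loglik_path: list
    converged: bool
    n_iter: int
    message: str
    params: list = field(default_factory=list)
    ai_matrix: np.ndarray | None = None

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1] if self.loglik_path else np.nan

    def summary(self) -> str:
        lines = ["AI-REML variance components", "=" * 29]
        lines.append(
            f"converged: {self.converged}  iterations: {self.n_iter}  "
            f"logL: {self.loglik:.4f}"
        )
        lines.append(f"{'parameter':>22s} {'estimate':>12s} {'SE':>10s}")
        for (eff, i, j) in self.params:
            est = self.components.block(eff)[i, j]
            se = self.standard_errors.get((eff, i, j), np.nan)
            name = f"{eff}[{i+1},{j+1}]" if i != j else f"{eff}[{i+1}]"
            lines.append(f"{name:>22s} {est:>12.4f} {se:>10.4f}")
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)


def _default_start(ms: MarginalStructures) -> np.ndarray:
    """40% of the phenotypic variance to the residual, the rest split evenly
    over the remaining components; covariances start at zero."""
    model = ms.model
    v_p = []
    for r, t in zip(model._rec, model.traits):
        y = np.asarray(r["y"], dtype=float)
        w = np.asarray(r["weights"], dtype=float)
        # individual-scale variance proxy; for group records remove the
        # pure-size trend by scaling each record to a per-member mean
        v = float(np.var(y / w) * np.mean(w)) if t.mode == "group" else float(np.var(y))
        v_p.append(max(v, 1e-6))
    n_var_effects = len(model.random_effect_names)
    theta = np.zeros(len(ms.params))
    for k, (eff, i, j) in enumerate(ms.params):
        if i != j:
            continue
        if eff == "residual":
            theta[k] = 0.4 * v_p[i]
        else:
            theta[k] = 0.6 * v_p[i] / n_var_effects
    return theta


class _CholeskyParam:
    """Cholesky parameterization of the (co)variance parameter vector.

    Each effect's 2x2 trait block Sigma = L L' is driven by (l11, l21, l22),
    a univariate block by l11 alone.  Positive semi-definiteness is automatic
    and the PSD boundary (l22 = 0) is an ordinary point of the search space,
    which is what lets the iteration slide along it instead of stalling
    (the boundary binds in mixed record-mode models, where the excluded
    cross-record residual covariance is absorbed by the pen block)."""

    def __init__(self, ms: MarginalStructures, floor: float) -> None:
        self.floor = floor
        pos = {key: k for k, key in enumerate(ms.params)}
        self.blocks = []  # (theta indices [v1, v2, c] or [v], x offset)
        off = 0
        for eff in (*ms.model.random_effect_names, "residual"):
            ks = [key for key in ms.params if key[0] == eff]
            if not ks:
                continue
            if any(i != j for (_, i, j) in ks):
                idx = [pos[(eff, 0, 0)], pos[(eff, 1, 1)], pos[(eff, 0, 1)]]
                self.blocks.append((idx, off, 3))
                off += 3
            else:
                for _, i, _ in ks:
                    self.blocks.append(([pos[(eff, i, i)]], off, 1))
                    off += 1
        self.n_x = off
        self.n_theta = len(ms.params)

    def x_from_theta(self, theta: np.ndarray) -> np.ndarray:
        x = np.zeros(self.n_x)
        for idx, off, sz in self.blocks:
            if sz == 1:
                x[off] = np.sqrt(max(theta[idx[0]], self.floor))
            else:
                v1, v2, c = theta[idx[0]], theta[idx[1]], theta[idx[2]]
                l11 = np.sqrt(max(v1, self.floor))
                l21 = c / l11
                l22 = np.sqrt(max(v2 - l21 * l21, self.floor))
                x[off : off + 3] = (l11, l21, l22)
        return x

    def theta(self, x: np.ndarray) -> np.ndarray:
        th = np.zeros(self.n_theta)
        for idx, off, sz in self.blocks:
            if sz == 1:
                th[idx[0]] = x[off] ** 2
            else:
                l11, l21, l22 = x[off : off + 3]
                th[idx[0]] = l11 * l11
                th[idx[1]] = l21 * l21 + l22 * l22
                th[idx[2]] = l11 * l21
        return th

    def clamp(self, x: np.ndarray) -> np.ndarray:
        out = x.copy()
        root = np.sqrt(self.floor)
        for idx, off, sz in self.blocks:
            if sz == 1:
                out[off] = max(abs(out[off]), root)
            else:
                out[off] = max(abs(out[off]), root)
                out[off + 2] = max(abs(out[off + 2]), root)
        return out

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """d theta / d x."""
        J = np.zeros((self.n_theta, self.n_x))
        for idx, off, sz in self.blocks:
            if sz == 1:
                J[idx[0], off] = 2.0 * x[off]
            else:
                l11, l21, l22 = x[off : off + 3]
                J[idx[0], off] = 2.0 * l11
                J[idx[1], off + 1] = 2.0 * l21
                J[idx[1], off + 2] = 2.0 * l22
                J[idx[2], off] = l21
                J[idx[2], off + 1] = l11
        return J


def _theta_valid(ms: MarginalStructures, theta: np.ndarray, floor: float) -> bool:
    T = len(ms.model.traits)
    for eff in (*ms.model.random_effect_names, "residual"):
        block = np.zeros((T, T))
        present = False
        for val, (e, i, j) in zip(theta, ms.params):
            if e == eff:
                block[i, j] = block[j, i] = val
                present = True
        if not present:
            continue
        if np.any(np.diag(block) < floor * 0.999):
            return False
        if T == 2 and np.linalg.det(block) < -1e-12 * max(1.0, block.max() ** 2):
            return False
    return True


def reml_estimate(model, start=None, options: RemlOptions | None = None) -> REMLResults:
    """AI-REML estimation of all (co)variance components of ``model``.

    ``start`` may be a VarianceComponents or a parameter vector; the default
    start assigns 40% of the phenotypic variance to the residual and splits
    the rest evenly, with zero covariances.
    """
    opts = options or RemlOptions()
    ms = MarginalStructures(model)
    if start is None:
        theta = _default_start(ms)
    elif isinstance(start, VarianceComponents):
        theta = ms.components_to_theta(start)
    else:
        theta = np.asarray(start, dtype=float).copy()
    if not np.all(np.isfinite(theta)):
        raise ValueError("invalid starting values")
    chol = _CholeskyParam(ms, opts.variance_floor)
    # the Cholesky transform also projects a start that sits marginally
    # outside the PSD cone back onto it
    x = chol.x_from_theta(theta)
    theta = chol.theta(x)
    if not _theta_valid(ms, theta, opts.variance_floor * 0.5):
        raise ValueError("invalid starting values")

    ll, aux = _loglik_dense(ms, theta)
    if not np.isfinite(ll):
        raise ValueError("starting values give a singular covariance")
    path = [ll]
    converged = False
    message = ""
    grad = np.zeros_like(theta)
    AI = np.eye(len(theta))
    it = 0
    lam = 0.0  # Levenberg-Marquardt damping, adapted across iterations
    for it in range(1, opts.max_iter + 1):
        cf, ViX, XtViX, Py = aux["cf"], aux["ViX"], aux["XtViX"], aux["Py"]
        Vinv = _sym_inverse_from_chol(cf)
        XtViX_inv = la.inv(XtViX)
        # gradient
        for k, (eff, i, j) in enumerate(ms.params):
            trPF = ms.trace_inner(Vinv, eff, i, j) - float(
                np.trace(XtViX_inv @ (ViX.T @ ms.F_matvec(eff, i, j, ViX)))
            )
            grad[k] = -0.5 * (trPF - ms.quad_inner(Py, eff, i, j))
        # average information
        U = np.column_stack(
            [ms.F_matvec(eff, i, j, Py) for (eff, i, j) in ms.params]
        )
        PU = la.cho_solve(cf, U, check_finite=False) - ViX @ (
            XtViX_inv @ (ViX.T @ U)
        )
        AI = 0.5 * (U.T @ PU)
        AI = 0.5 * (AI + AI.T)
        if np.max(np.abs(grad)) < opts.tol_grad and it > 1:
            converged = True
            break
        # Newton/AI step in the Cholesky parameterization with adaptive
        # Levenberg-Marquardt damping: when the AI curvature misleads, the
        # damping grows toward a scaled gradient step, so the iteration
        # cannot stall while the gradient is nonzero
        J = chol.jacobian(x)
        grad_x = J.T @ grad
        AI_x = J.T @ AI @ J
        scale = np.mean(np.abs(np.diag(AI_x))) or 1.0
        accepted = False
        while lam <= 1e14:
            try:
                step = la.solve(
                    AI_x + lam * scale * np.eye(chol.n_x), grad_x, assume_a="sym"
                )
            except la.LinAlgError:
                lam = max(lam * 10, 1e-8)
                continue
            x_prop = chol.clamp(x + step)
            prop = chol.theta(x_prop)
            ll_new, aux_new = _loglik_dense(ms, prop)
            if np.isfinite(ll_new) and ll_new > ll:
                predicted = 0.5 * float(step @ grad_x)
                good = (ll_new - ll) > 0.1 * max(predicted, 0.0)
                lam = lam / 5 if good else max(lam * 5, 1e-8)
                accepted = True
                break
            lam = max(lam * 10, 1e-8)
        if not accepted:
            # the (transformed) gradient cannot be followed uphill any more:
            # numerically at the optimum (possibly on the PSD boundary)
            converged = np.max(np.abs(grad_x)) < np.sqrt(opts.tol_grad)
            if not converged:
                message = (
                    "no admissible uphill step found; stopped at last iterate"
                )
            break
        rel_change = np.max(
            np.abs(prop - theta) / np.maximum(np.abs(theta), 1.0)
        )
        theta, x, ll, aux = prop, x_prop, ll_new, aux_new
        path.append(ll)
        if opts.verbose:
            print(
                f"iter {it:3d}  logL {ll:.6f}  max|grad| {np.max(np.abs(grad)):.3e}"
                f"  lam {lam:.1e}"
            )
        # gradient criterion in the Cholesky space: at a PSD-boundary optimum
        # only the transformed gradient vanishes
        if rel_change < opts.tol_param and np.max(np.abs(grad_x)) < opts.tol_grad:
            converged = True
            break
    if not converged and not message:
        message = f"not converged in {opts.max_iter} iterations"

    # standard errors from the inverse AI matrix at the final iterate
    se = {}
    try:
        AI_inv = la.inv(AI)
        for k, key in enumerate(ms.params):
            se[key] = float(np.sqrt(max(AI_inv[k, k], 0.0)))
    except la.LinAlgError:
        se = {key: np.nan for key in ms.params}
    return REMLResults(
        components=ms.theta_to_components(theta),
        standard_errors=se,
        loglik_path=path,
        converged=converged,
        n_iter=it,
        message=message,
        params=list(ms.params),
        ai_matrix=AI,
    )
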