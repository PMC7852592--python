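"""Variance-component containers shared by the simulator and the mixed models.

The generating values used throughout follow the bivariate pig-trait setting
this package was written for (a group-recorded trait such as total pen feed
intake, and an individually recorded correlated trait such as daily gain):

========== ======= ======= ===========
component  trait 1 trait 2 correlation
========== ======= ======= ===========
pen        10      40      0.3
litter     10      40      0.3
additive   30      100     0.8
residual   50      220     0.5
========== ======= ======= ===========

which imply narrow-sense heritabilities of 0.30 and 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EFFECTS = ("pen", "litter", "additive", "residual")


def _as_cov_block(x) -> np.ndarray:
    m = np.atleast_2d(np.asarray(x, dtype=float))
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"covariance block must be square, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ValueError("covariance block must be symmetric")
    return m


@dataclass
class VarianceComponents:
    """Per-effect (co)variance blocks for one or two traits.

    Each block is a ``t x t`` symmetric matrix where ``t`` is the number of
    traits; univariate components are stored as ``1 x 1`` matrices.
    """

    pen: np.ndarray
    litter: np.ndarray
    additive: np.ndarray
    residual: np.ndarray
    standard_errors: dict | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pen = _as_cov_block(self.pen)
        self.litter = _as_cov_block(self.litter)
        self.additive = _as_cov_block(self.additive)
        self.residual = _as_cov_block(self.residual)
        t = self.pen.shape[0]
        for name in EFFECTS:
            blk = getattr(self, name)
            if blk.shape != (t, t):
                raise ValueError("all effect blocks must have the same size")
            if np.any(np.diag(blk) < 0):
                raise ValueError(f"negative variance in {name} block")
            # PSD within numerical tolerance
            if np.linalg.eigvalsh(blk).min() < -1e-8 * max(1.0, blk.max()):
                raise ValueError(f"{name} block is not positive semi-definite")

    @property
    def n_traits(self) -> int:
        return self.pen.shape[0]

    def block(self, effect: str) -> np.ndarray:
        if effect not in EFFECTS:
            raise KeyError(effect)
        return getattr(self, effect)

    def subset(self, traits) -> "VarianceComponents":
        """Marginal components for a subset of traits (by index)."""
        idx = np.atleast_1d(np.asarray(traits, dtype=int))
        return VarianceComponents(
            **{e: self.block(e)[np.ix_(idx, idx)] for e in EFFECTS}
        )

    def copy(self) -> "VarianceComponents":
        return VarianceComponents(
            pen=self.pen.copy(),
            litter=self.litter.copy(),
            additive=self.additive.copy(),
            residual=self.residual.copy(),
        )

    @classmethod
    def simulation_defaults(cls, genetic_correlation: float = 0.8) -> "VarianceComponents":
        """The generating bivariate components of the simulation study.

        ``genetic_correlation`` rescales only the additive covariance
        (0.8 by default; 0.5 is the reduced-correlation variant).
        """
        rg = float(genetic_correlation)
        if not -1.0 <= rg <= 1.0:
            raise ValueError("genetic correlation must be in [-1, 1]")

        def cov(v1, v2, r):
            c = r * np.sqrt(v1 * v2)
            return np.array([[v1, c], [c, v2]])

        return cls(
            pen=cov(10.0, 40.0, 0.3),
            litter=cov(10.0, 40.0, 0.3),
            additive=cov(30.0, 100.0, rg),
            residual=cov(50.0, 220.0, 0.5),
        )
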