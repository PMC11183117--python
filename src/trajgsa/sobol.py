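"""Variance-based Sobol' sensitivity indices, two ways.

The first-order index ``S_i = V[E(Y|X_i)] / V[Y]`` measures the share of
output variance removed by fixing parameter ``i`` alone; the total-order
index ``S_Ti = E[V(Y|X_~i)] / V[Y]`` measures the share that remains through
``i`` and all its interactions.

Two estimators are provided:

* analytic, from a fitted PCE surrogate: squared coefficients of the
  orthonormal basis are partial variances, so indices follow exactly from
  sums over multi-index subsets (vector-valued over the g output columns);
* Monte Carlo, using the Saltelli design of ``N_base * (d + 2)`` model
  evaluations with pick-freeze product estimators (the Jansen difference
  estimators are available behind a flag) and percentile bootstrap
  confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .exceptions import (
    ConfigurationError,
    DegenerateVarianceError,
    DimensionError,
    InvalidInputError,
)
from .pce import PCESurrogate

__all__ = [
    "SensitivityResult",
    "SaltelliDesign",
    "pce_sobol_indices",
    "subset_sobol_index",
    "saltelli_design",
    "mc_sobol_estimates",
    "bootstrap_ci",
]


@dataclass
class SensitivityResult:
    """First-/total-order indices per parameter and output component.

    ``first_order`` and ``total_order`` have shape (k, g) — for the Monte
    Carlo baseline applied per time step, g is the number of output
    components.  ``dispersion`` holds matching-shape bootstrap CI bounds or
    across-repeat variances, keyed by name.  PCE-path indices satisfy
    ``0 <= S_i <= S_Ti <= 1`` and ``sum_i S_i <= 1`` by construction; MC
    estimates may transiently violate these bounds at small N and are
    reported as-is.
    """

    first_order: np.ndarray
    total_order: np.ndarray
    method: str
    parameter_names: tuple[str, ...] = ()
    dispersion: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.first_order = np.atleast_2d(np.asarray(self.first_order, float).T).T
        self.total_order = np.atleast_2d(np.asarray(self.total_order, float).T).T
        if not self.parameter_names:
            self.parameter_names = tuple(
                f"x{i+1}" for i in range(self.first_order.shape[0])
            )

    @property
    def k(self) -> int:
        return self.first_order.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (parameter, output component)."""
        rows = []
        k, g = self.first_order.shape
        for i in range(k):
            for j in range(g):
                row = {
                    "method": self.method,
                    "parameter": self.parameter_names[i],
                    "output_dim": j,
                    "S1": self.first_order[i, j],
                    "ST": self.total_order[i, j],
                }
                for key in ("S1_lo", "S1_hi", "ST_lo", "ST_hi"):
                    if key in self.dispersion:
                        row[key] = np.asarray(self.dispersion[key])[i, j]
                rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None) -> str:
        import json

        doc = {
            "method": self.method,
            "parameter_names": list(self.parameter_names),
            "first_order": self.first_order.tolist(),
            "total_order": self.total_order.tolist(),
            "dispersion": {k: np.asarray(v).tolist()
                           for k, v in self.dispersion.items()},
            "metadata": {k: v for k, v in self.metadata.items()
                         if isinstance(v, (int, float, str, bool, list))},
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------------------
# Analytic indices from PCE coefficients
# ---------------------------------------------------------------------------

def _partial_variance_masks(indices, k):
    arr = np.array(indices)  # (P, k)
    nonzero = arr != 0
    first = [nonzero[:, i] & (nonzero.sum(axis=1) == 1) for i in range(k)]
    total = [nonzero[:, i] for i in range(k)]
    return first, total


def pce_sobol_indices(
    surrogate: PCESurrogate,
    parameter_names: Sequence[str] | None = None,
) -> SensitivityResult:
    """Analytic first- and total-order indices from PCE coefficients.

    ``S_i`` sums squared coefficients over multi-indices active in parameter
    ``i`` only; ``S_Ti`` over all multi-indices with ``s_i != 0``; both are
    normalized by the total variance (all non-constant squared coefficients),
    componentwise over the g output dimensions.
    """
    sq = surrogate.coefficients**2
    zero = surrogate.zero_index
    denom = sq.sum(axis=0) - sq[zero]
    if np.any(denom <= 0):
        raise DegenerateVarianceError(
            "all non-constant PCE coefficients are zero for some output"
        )
    k = surrogate.basis.k
    first_masks, total_masks = _partial_variance_masks(surrogate.basis.indices, k)
    S = np.stack([sq[mask].sum(axis=0) / denom for mask in first_masks])
    ST = np.stack([sq[mask].sum(axis=0) / denom for mask in total_masks])
    names = tuple(parameter_names) if parameter_names else tuple(
        m.name or f"x{i+1}" for i, m in enumerate(surrogate.marginals)
    )
    return SensitivityResult(
        first_order=S, total_order=ST, method="pce",
        parameter_names=names,
        metadata={"basis_size": len(surrogate.basis), "g": surrogate.g},
    )


def subset_sobol_index(surrogate: PCESurrogate, u: Sequence[int]) -> np.ndarray:
    """Closed Sobol' index ``S_u`` for an exact interaction subset ``u``.

    ``u`` holds 0-based parameter positions; the index sums squared
    coefficients over multi-indices active in exactly the parameters of
    ``u``.  Summed over all nonempty subsets, these reconstruct 1.
    """
    u = frozenset(int(i) for i in u)
    if not u:
        raise InvalidInputError("subset u must be nonempty")
    sq = surrogate.coefficients**2
    zero = surrogate.zero_index
    denom = sq.sum(axis=0) - sq[zero]
    arr = np.array(surrogate.basis.indices) != 0
    mask = np.array([frozenset(np.flatnonzero(row)) == u for row in arr])
    return sq[mask].sum(axis=0) / denom


# ---------------------------------------------------------------------------
# Saltelli Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SaltelliDesign:
    """Unit-hypercube Saltelli design of ``N_base * (d + 2)`` rows.

    Row blocks in order: the base block X, the resample block X', then d
    mixed blocks in which column i is taken from X and all other columns
    from X'.
    """

    X: np.ndarray
    N_base: int
    d: int
    sampler: str
    seed: int | None

    @property
    def n_rows(self) -> int:
        return self.N_base * (self.d + 2)

    def blocks(self, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Split aligned model evaluations into (f_A, f_B, f_AB[d])."""
        v = np.asarray(values, dtype=float)
        if v.shape[0] != self.n_rows:
            raise DimensionError(
                f"expected {self.n_rows} evaluations, got {v.shape[0]}"
            )
        N, d = self.N_base, self.d
        fA = v[:N]
        fB = v[N:2 * N]
        fAB = np.stack([v[(2 + i) * N:(3 + i) * N] for i in range(d)])
        return fA, fB, fAB


def saltelli_design(
    N_base: int,
    d: int,
    sampler: str = "sobol_sequence",
    seed: int | None = None,
) -> SaltelliDesign:
    """Build the Saltelli pick-freeze design on the unit hypercube."""
    if N_base < 2 or d < 1:
        raise InvalidInputError(f"need N_base >= 2 and d >= 1, got {N_base}, {d}")
    if sampler == "sobol_sequence":
        engine = qmc.Sobol(d=2 * d, scramble=True, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            base = engine.random(N_base)
    elif sampler == "pseudorandom":
        rng = np.random.default_rng(seed)
        base = rng.random((N_base, 2 * d))
    else:
        raise ConfigurationError(f"unknown sampler {sampler!r}")
    A, B = base[:, :d], base[:, d:]
    blocks = [A, B]
    for i in range(d):
        AB = B.copy()
        AB[:, i] = A[:, i]
        blocks.append(AB)
    return SaltelliDesign(
        X=np.vstack(blocks), N_base=N_base, d=d, sampler=sampler, seed=seed
    )


def _indices_from_blocks(fA, fB, fAB, estimator: str):
    # fA, fB: (N, T); fAB: (d, N, T)
    M0 = fA.mean(axis=0)
    D = (fA**2).mean(axis=0) - M0**2
    if np.any(D <= 0):
        raise DegenerateVarianceError("total variance estimate is <= 0")
    if estimator == "product":
        Di = (fA[None] * fAB).mean(axis=1) - M0[None] ** 2
        Dnoti = (fAB * fB[None]).mean(axis=1) - M0[None] ** 2
        S = Di / D[None]
        ST = 1.0 - Dnoti / D[None]
    elif estimator == "jansen":
        S = 1.0 - ((fA[None] - fAB) ** 2).mean(axis=1) / (2.0 * D[None])
        ST = ((fB[None] - fAB) ** 2).mean(axis=1) / (2.0 * D[None])
    else:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    return S, ST


def mc_sobol_estimates(
    model_values: np.ndarray,
    design: SaltelliDesign,
    estimator: str = "product",
    parameter_names: Sequence[str] | None = None,
) -> SensitivityResult:
    """Saltelli Monte-Carlo first- and total-order index estimates.

    ``model_values`` holds one scalar (or a vector of output components,
    e.g. time steps) per design row, aligned with the design's block
    structure.  The default ``"product"`` estimator is the pick-freeze
    product form (sample mean of paired products minus the squared mean
    estimate); ``"jansen"`` uses squared-difference estimators.  Negative
    estimates are reported as-is with a warning.
    """
    v = np.asarray(model_values, dtype=float)
    squeeze = v.ndim == 1
    v = np.atleast_2d(v.T).T
    fA, fB, fAB = design.blocks(v)
    S, ST = _indices_from_blocks(fA, fB, fAB, estimator)
    if np.any(S < 0) or np.any(ST < 0):
        warnings.warn(
            "negative Sobol' index estimate(s); reported unclipped",
            RuntimeWarning,
            stacklevel=2,
        )
    if squeeze:
        S, ST = S[:, :1], ST[:, :1]
    return SensitivityResult(
        first_order=S, total_order=ST, method="saltelli",
        parameter_names=tuple(parameter_names) if parameter_names else (),
        metadata={"N_base": design.N_base, "estimator": estimator,
                  "sampler": design.sampler, "seed": design.seed},
    )


def bootstrap_ci(
    model_values: np.ndarray,
    design: SaltelliDesign,
    B: int = 500,
    level: float = 0.95,
    seed: int | None = None,
    estimator: str = "product",
) -> dict[str, np.ndarray]:
    """Percentile bootstrap confidence intervals for the MC indices.

    Entire aligned rows (one base-sample index across all d+2 blocks) are
    resampled ``B`` times; interval bounds are percentiles of the resampled
    index estimates at the requested level.  Deterministic under ``seed``.
    """
    if B < 100:
        raise InvalidInputError(f"need B >= 100 bootstrap resamples, got {B}")
    v = np.atleast_2d(np.asarray(model_values, dtype=float).T).T
    fA, fB, fAB = design.blocks(v)
    rng = np.random.default_rng(seed)
    N = design.N_base
    Ss, STs = [], []
    for _ in range(B):
        idx = rng.integers(0, N, size=N)
        S, ST = _indices_from_blocks(fA[idx], fB[idx], fAB[:, idx], estimator)
        Ss.append(S)
        STs.append(ST)
    Ss = np.stack(Ss)
    STs = np.stack(STs)
    alpha = (1.0 - level) / 2.0
    return {
        "S1_lo": np.quantile(Ss, alpha, axis=0),
        "S1_hi": np.quantile(Ss, 1.0 - alpha, axis=0),
        "ST_lo": np.quantile(STs, alpha, axis=0),
        "ST_hi": np.quantile(STs, 1.0 - alpha, axis=0),
        "level": level,
    }
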