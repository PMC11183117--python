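"""Polynomial chaos expansion surrogates on the diffusion manifold.

A PCE represents the map from the ``k`` input parameters to the ``g``
retained diffusion coordinates as a sum of multivariate polynomials
orthonormal with respect to the input distributions: shifted/scaled Legendre
polynomials for uniform marginals and normalized probabilists' Hermite
polynomials for Gaussian marginals.  The basis is a total-degree multi-index
set (``||s||_1 <= s_max``, cardinality ``(k + s_max)! / (k! s_max!)``).

Coefficients are fit either by ordinary least squares on the full basis or by
the hybrid least-angle-regression procedure: LAR produces a nested sequence of
active sets, each re-fit by OLS, and the sparsity level with the smallest
leave-one-out error is kept (with an early stop at a target error and a
three-consecutive-increase overfitting rule).  Because squared coefficients
of an orthonormal basis are partial variances, Sobol' indices follow
analytically from a fitted surrogate (see :mod:`trajgsa.sobol`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.linear_model import lars_path

from .exceptions import (
    ConfigurationError,
    DegenerateResponseError,
    DimensionError,
    IllConditionedProblemError,
    InvalidInputError,
)

__all__ = [
    "Marginal",
    "MultiIndexSet",
    "PCESurrogate",
    "total_degree_multiindices",
    "evaluate_basis",
    "ols_fit",
    "loo_error",
    "hybrid_lar_fit",
    "fit_surrogate",
    "validation_metrics",
]


@dataclass(frozen=True)
class Marginal:
    """Marginal distribution of one input parameter.

    Supported families: ``"uniform"`` with bounds ``(a, b)`` and
    ``"normal"`` with ``(mu, sigma)``.
    """

    family: str
    a: float = 0.0
    b: float = 1.0
    name: str = ""

    @classmethod
    def uniform(cls, a: float, b: float, name: str = "") -> "Marginal":
        if not b > a:
            raise ConfigurationError(f"uniform bounds require b > a, got ({a}, {b})")
        return cls(family="uniform", a=a, b=b, name=name)

    @classmethod
    def normal(cls, mu: float, sigma: float, name: str = "") -> "Marginal":
        if sigma <= 0:
            raise ConfigurationError(f"normal sigma must be > 0, got {sigma}")
        return cls(family="normal", a=mu, b=sigma, name=name)

    def ppf(self, u: np.ndarray) -> np.ndarray:
        """Map standard-uniform samples to this marginal."""
        if self.family == "uniform":
            return self.a + (self.b - self.a) * u
        if self.family == "normal":
            return stats.norm.ppf(u, loc=self.a, scale=self.b)
        raise ConfigurationError(f"unsupported marginal family {self.family!r}")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        """Affine map to the family's reference domain ([-1, 1] or N(0,1))."""
        if self.family == "uniform":
            return 2.0 * (x - self.a) / (self.b - self.a) - 1.0
        if self.family == "normal":
            return (x - self.a) / self.b
        raise ConfigurationError(f"unsupported marginal family {self.family!r}")

    def to_dict(self) -> dict:
        return {"family": self.family, "a": self.a, "b": self.b, "name": self.name}

    @classmethod
    def from_dict(cls, d: dict) -> "Marginal":
        return cls(**d)


@dataclass(frozen=True)
class MultiIndexSet:
    """Total-degree multi-index set in graded-lexicographic order."""

    indices: tuple[tuple[int, ...], ...]
    k: int
    s_max: int

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def position(self, s: tuple[int, ...]) -> int:
        return self.indices.index(tuple(s))


def _compositions(total: int, k: int):
    # All k-tuples of nonnegative integers summing to `total`, lexicographic
    # descending on the first coordinate: (total,0,..), ..., (0,..,total).
    if k == 1:
        yield (total,)
        return
    for first in range(total, -1, -1):
        for rest in _compositions(total - first, k - 1):
            yield (first,) + rest


def total_degree_multiindices(k: int, s_max: int) -> MultiIndexSet:
    """Full total-degree set ``{s : ||s||_1 <= s_max}``, graded-lex ordered."""
    if k < 1 or s_max < 0:
        raise ConfigurationError(f"need k >= 1 and s_max >= 0, got k={k}, s_max={s_max}")
    indices = tuple(
        s for degree in range(s_max + 1) for s in _compositions(degree, k)
    )
    expected = math.comb(k + s_max, k)
    assert len(indices) == expected
    return MultiIndexSet(indices=indices, k=k, s_max=s_max)


def _legendre_orthonormal(z: np.ndarray, max_degree: int) -> np.ndarray:
    """Orthonormal Legendre family w.r.t. U(-1, 1); shape (N, max_degree+1)."""
    N = z.shape[0]
    P = np.empty((N, max_degree + 1))
    P[:, 0] = 1.0
    if max_degree >= 1:
        P[:, 1] = z
    for n in range(1, max_degree):
        P[:, n + 1] = ((2 * n + 1) * z * P[:, n] - n * P[:, n - 1]) / (n + 1)
    norms = np.sqrt(2.0 * np.arange(max_degree + 1) + 1.0)
    return P * norms


def _hermite_orthonormal(z: np.ndarray, max_degree: int) -> np.ndarray:
    """Normalized probabilists' Hermite family w.r.t. N(0, 1)."""
    N = z.shape[0]
    H = np.empty((N, max_degree + 1))
    H[:, 0] = 1.0
    if max_degree >= 1:
        H[:, 1] = z
    for n in range(1, max_degree):
        H[:, n + 1] = z * H[:, n] - n * H[:, n - 1]
    norms = np.array([math.sqrt(math.factorial(n)) for n in range(max_degree + 1)])
    return H / norms


def evaluate_basis(
    X: np.ndarray,
    basis: MultiIndexSet,
    marginals: Sequence[Marginal],
) -> np.ndarray:
    """Design matrix of multivariate orthonormal polynomials at ``X``.

    Inputs are standardized per marginal (uniform -> [-1, 1], Gaussian ->
    N(0, 1)), univariate families are evaluated by recurrence, and tuple
    products assembled per multi-index.  The zero-tuple column is identically
    one.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != basis.k:
        raise DimensionError(f"X has {X.shape[1]} columns, basis expects {basis.k}")
    if len(marginals) != basis.k:
        raise DimensionError("one marginal required per input dimension")
    max_deg = [max(s[i] for s in basis.indices) for i in range(basis.k)]
    uni = []
    for i, marg in enumerate(marginals):
        z = marg.standardize(X[:, i])
        if marg.family == "uniform":
            uni.append(_legendre_orthonormal(z, max_deg[i]))
        elif marg.family == "normal":
            uni.append(_hermite_orthonormal(z, max_deg[i]))
        else:
            raise ConfigurationError(f"unsupported marginal family {marg.family!r}")
    Phi = np.ones((X.shape[0], len(basis)))
    for col, s in enumerate(basis.indices):
        for i, si in enumerate(s):
            if si:
                Phi[:, col] *= uni[i][:, si]
    return Phi


def _hat_diagonal(Phi: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(Phi, mode="reduced")
    return np.sum(Q * Q, axis=1)


def _loo_from_residuals(
    resid: np.ndarray, h: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Eq.-style closed-form LOO error per response column."""
    y = np.atleast_2d(y.T).T
    resid = np.atleast_2d(resid.T).T
    var = np.var(y, axis=0, ddof=1)
    if np.any(var <= 0):
        raise DegenerateResponseError("response variance is zero")
    unstable = h >= 1.0 - 1e-12
    if np.any(unstable):
        warnings.warn(
            f"{int(unstable.sum())} leverage value(s) ~1; excluding those "
            "terms from the LOO error",
            RuntimeWarning,
            stacklevel=3,
        )
    keep = ~unstable
    scaled = resid[keep] / (1.0 - h[keep])[:, None]
    return np.mean(scaled**2, axis=0) / var


def ols_fit(design: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients for all response columns, plus LOO error.

    Returns ``(coef, eps_loo)`` with ``coef`` of shape (P, g) and
    ``eps_loo`` of shape (g,).  Requires ``N >= P``; a rank-deficient design
    warns and falls back to the minimum-norm solution.
    """
    Phi = np.asarray(design, dtype=float)
    Y = np.asarray(y, dtype=float)
    squeeze = Y.ndim == 1
    Y = np.atleast_2d(Y.T).T
    N, P = Phi.shape
    if N < P:
        raise IllConditionedProblemError(
            f"N={N} samples < P={P} basis functions; OLS is ill-conditioned"
        )
    coef, _, rank, _ = np.linalg.lstsq(Phi, Y, rcond=None)
    if rank < P:
        warnings.warn(
            f"design matrix rank {rank} < {P}; minimum-norm solution used",
            RuntimeWarning,
            stacklevel=2,
        )
    resid = Y - Phi @ coef
    h = _hat_diagonal(Phi)
    eps = _loo_from_residuals(resid, h, Y)
    if squeeze:
        return coef[:, 0], eps
    return coef, eps


def loo_error(design: np.ndarray, y: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """Leave-one-out error ``E[(Delta_i/(1-h_i))^2] / V[Y]`` per column."""
    Phi = np.asarray(design, dtype=float)
    Y = np.atleast_2d(np.asarray(y, dtype=float).T).T
    C = np.atleast_2d(np.asarray(coefficients, dtype=float).T).T
    resid = Y - Phi @ C
    return _loo_from_residuals(resid, _hat_diagonal(Phi), Y)


def hybrid_lar_fit(
    design: np.ndarray,
    y: np.ndarray,
    constant_index: int = 0,
    eps_target: float = 1e-8,
    max_increase_steps: int = 3,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Sparse fit of one scalar response by hybrid least-angle regression.

    LAR (on centered, unit-norm regressors, the constant column excluded) is
    run once to obtain the nested active-set sequence
    ``L_1 c L_2 c ... c L_m`` with ``m = min(P, N)``.  Each prefix, plus the
    always-active constant, is re-fit by OLS on the *original* columns and
    scored by the closed-form leave-one-out error; the minimizer is returned.
    Iteration stops early once the error drops to ``eps_target`` or after
    ``max_increase_steps`` consecutive steps above the best error seen
    (overfitting rule).

    Returns ``(active_columns, coefficients, eps_loo_path)``; coefficients
    are a full-length vector with zeros outside the selected set.
    """
    Phi = np.asarray(design, dtype=float)
    yv = np.asarray(y, dtype=float).ravel()
    N, P = Phi.shape
    if N < 2:
        raise IllConditionedProblemError("hybrid LAR requires N >= 2")
    if np.var(yv, ddof=1) <= 0:
        raise DegenerateResponseError("response is constant")
    others = [j for j in range(P) if j != constant_index]
    Xc = Phi[:, others] - Phi[:, others].mean(axis=0)
    norms = np.linalg.norm(Xc, axis=0)
    nonzero = norms > 0
    Xc = Xc[:, nonzero] / np.where(norms[nonzero] > 0, norms[nonzero], 1.0)
    candidates = [others[j] for j in np.flatnonzero(nonzero)]
    yc = yv - yv.mean()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, active_order, _ = lars_path(Xc, yc, method="lar", verbose=False)
    m = min(len(active_order), N - 1)

    best_eps = np.inf
    best_cols: list[int] | None = None
    best_coef: np.ndarray | None = None
    path: list[float] = []
    increases = 0
    for i in range(1, m + 1):
        cols = [constant_index] + [candidates[j] for j in active_order[:i]]
        if len(cols) > N:
            break
        sub = Phi[:, cols]
        coef_sub, _, _, _ = np.linalg.lstsq(sub, yv, rcond=None)
        resid = yv - sub @ coef_sub
        eps = float(_loo_from_residuals(resid, _hat_diagonal(sub), yv)[0])
        path.append(eps)
        if eps < best_eps:
            best_eps = eps
            best_cols = cols
            best_coef = coef_sub
            increases = 0
        else:
            increases += 1
        if best_eps <= eps_target or increases >= max_increase_steps:
            break
    if best_cols is None:  # pragma: no cover - defensive
        best_cols = [constant_index]
        best_coef = np.array([yv.mean()])
        best_eps = 1.0
    coef = np.zeros(P)
    coef[best_cols] = best_coef
    return np.array(best_cols), coef, path


@dataclass
class PCESurrogate:
    """Fitted PCE surrogate from inputs to the g diffusion coordinates.

    ``coefficients`` always has one row per basis function (zeros outside a
    sparse active set) and one column per output dimension; ``active_sets``
    records, per output, the multi-indices LAR kept (``None`` for OLS fits).
    """

    basis: MultiIndexSet
    coefficients: np.ndarray
    marginals: tuple[Marginal, ...]
    errors: dict = field(default_factory=dict)
    active_sets: tuple[tuple[tuple[int, ...], ...], ...] | None = None
    method: str = "ols"

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(
            np.asarray(self.coefficients, dtype=float).T
        ).T
        if self.coefficients.shape[0] != len(self.basis):
            raise DimensionError(
                "coefficient rows must equal basis cardinality "
                f"({self.coefficients.shape[0]} vs {len(self.basis)})"
            )
        self.marginals = tuple(self.marginals)

    @property
    def g(self) -> int:
        return self.coefficients.shape[1]

    @property
    def zero_index(self) -> int:
        return self.basis.position((0,) * self.basis.k)

    @property
    def mean(self) -> np.ndarray:
        """Surrogate mean per output dimension (the zero-tuple coefficient)."""
        return self.coefficients[self.zero_index].copy()

    @property
    def variance(self) -> np.ndarray:
        """Surrogate variance: sum of squared non-constant coefficients."""
        sq = self.coefficients**2
        return sq.sum(axis=0) - sq[self.zero_index]

    def predict(self, X: np.ndarray) -> np.ndarray:
        Phi = evaluate_basis(X, self.basis, self.marginals)
        return Phi @ self.coefficients

    def to_json(self, path=None) -> str:
        doc = {
            "k": self.basis.k,
            "s_max": self.basis.s_max,
            "indices": [list(s) for s in self.basis.indices],
            "coefficients": self.coefficients.tolist(),
            "marginals": [m.to_dict() for m in self.marginals],
            "errors": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in self.errors.items()},
            "active_sets": (
                None if self.active_sets is None
                else [[list(s) for s in aset] for aset in self.active_sets]
            ),
            "method": self.method,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PCESurrogate":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        basis = MultiIndexSet(
            indices=tuple(tuple(s) for s in doc["indices"]),
            k=doc["k"],
            s_max=doc["s_max"],
        )
        return cls(
            basis=basis,
            coefficients=np.array(doc["coefficients"], dtype=float),
            marginals=tuple(Marginal.from_dict(d) for d in doc["marginals"]),
            errors={k: (np.array(v) if isinstance(v, list) else v)
                    for k, v in doc["errors"].items()},
            active_sets=(
                None if doc["active_sets"] is None
                else tuple(tuple(tuple(s) for s in aset)
                           for aset in doc["active_sets"])
            ),
            method=doc["method"],
        )


def fit_surrogate(
    X: np.ndarray,
    Theta: np.ndarray,
    marginals: Sequence[Marginal],
    s_max: int,
    method: str = "lar",
    eps_target: float = 1e-8,
) -> PCESurrogate:
    """Fit a PCE surrogate for all output columns.

    OLS solves all ``g`` columns at once on the full total-degree basis;
    LAR loops over output columns, selecting a possibly different sparse
    active set for each.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Theta = np.atleast_2d(np.asarray(Theta, dtype=float).T).T
    basis = total_degree_multiindices(X.shape[1], s_max)
    Phi = evaluate_basis(X, basis, marginals)
    if method == "ols":
        coef, eps = ols_fit(Phi, Theta)
        return PCESurrogate(
            basis=basis, coefficients=coef, marginals=marginals,
            errors={"eps_loo": eps}, method="ols",
        )
    if method != "lar":
        raise ConfigurationError(f"unknown fit method {method!r}")
    zero = basis.position((0,) * basis.k)
    g = Theta.shape[1]
    coef = np.zeros((len(basis), g))
    eps = np.empty(g)
    active_sets = []
    for j in range(g):
        cols, cj, path = hybrid_lar_fit(
            Phi, Theta[:, j], constant_index=zero, eps_target=eps_target
        )
        coef[:, j] = cj
        eps[j] = min(path) if path else 1.0
        active_sets.append(tuple(basis.indices[c] for c in cols))
    return PCESurrogate(
        basis=basis, coefficients=coef, marginals=marginals,
        errors={"eps_loo": eps}, active_sets=tuple(active_sets), method="lar",
    )


def validation_metrics(
    surrogate: PCESurrogate,
    X_test: np.ndarray,
    Theta_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Relative validation error and mean absolute error on a held-out set.

    ``eps_val = sum_i (Theta*_i - pred_i)^2 / sum_i (Theta*_i - mean)^2`` and
    ``MAE = mean_i |Theta*_i - pred_i|``, computed per output dimension.
    """
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    T = np.atleast_2d(np.asarray(Theta_test, dtype=float).T).T
    if X_test.shape[0] == 0:
        raise InvalidInputError("empty test set")
    pred = surrogate.predict(X_test)
    if pred.shape != T.shape:
        raise DimensionError(
            f"prediction shape {pred.shape} does not match test {T.shape}"
        )
    denom = np.sum((T - T.mean(axis=0)) ** 2, axis=0)
    if np.any(denom <= 0):
        raise DegenerateResponseError("zero test-set variance")
    eps_val = np.sum((T - pred) ** 2, axis=0) / denom
    mae = np.mean(np.abs(T - pred), axis=0)
    return eps_val, mae
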