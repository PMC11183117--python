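"""Pointwise linear dimension reduction on the Grassmann manifold.

Each model-output trajectory, reshaped to an ``n x m`` real matrix ``Y``, is
projected onto the Grassmannians ``G(p, n)`` and ``G(p, m)`` through its thin
singular value decomposition ``Y = U diag(S) V^T``: the spans of the first
``p`` left and right singular vectors are the subspace representatives of the
trajectory.  Pairwise subspace similarity is measured with the projection
kernel ``k_pr(A, B) = ||A^T B||_F^2``, which depends only on the spans (it is
invariant under right-multiplication by orthogonal matrices), is bounded by
``p``, and attains ``p`` exactly when the spans coincide.  The left and right
kernel matrices are composed entrywise (Hadamard product by default, sum as an
alternative) into the single N x N kernel consumed by the diffusion-maps
stage.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .exceptions import DimensionError, InvalidInputError

__all__ = [
    "GrassmannPoint",
    "RankProfile",
    "KernelMatrix",
    "project_to_grassmann",
    "numerical_rank",
    "rank_profile",
    "projection_kernel",
    "build_kernel_matrices",
]

#: Default relative singular-value cutoff for numerical rank decisions.
DEFAULT_RANK_TOLERANCE = 1e-10


@dataclass(frozen=True)
class GrassmannPoint:
    """Truncated thin SVD of one trajectory matrix.

    Attributes
    ----------
    U : (n, p) ndarray
        Orthonormal left subspace basis (a representative of a point on
        ``G(p, n)``).
    S : (p,) ndarray
        Leading singular values, sorted descending, all nonnegative.
    V : (m, p) ndarray
        Orthonormal right subspace basis (a point on ``G(p, m)``).
    p : int
        Subspace dimension.
    """

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray
    p: int

    def __post_init__(self) -> None:
        if self.U.shape[1] != self.p or self.V.shape[1] != self.p:
            raise DimensionError(
                f"basis column counts {self.U.shape[1]}/{self.V.shape[1]} "
                f"do not match p={self.p}"
            )
        if self.S.shape != (self.p,):
            raise DimensionError("singular value count does not match p")

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def m(self) -> int:
        return self.V.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Rank-``p`` reconstruction ``U diag(S) V^T``."""
        return (self.U * self.S) @ self.V.T


@dataclass(frozen=True)
class RankProfile:
    """Distribution of numerical ranks over an ensemble and the chosen p."""

    counts: Mapping[int, int]
    threshold: float
    selected_p: int


@dataclass
class KernelMatrix:
    """An N x N Grassmannian kernel matrix.

    ``kind`` records whether the matrix was built from left bases (``U``),
    right bases (``V``) or their composition; ``composition`` records how the
    two one-sided kernels were combined.  For a one-sided projection-kernel
    matrix every diagonal entry equals ``p``.
    """

    K: np.ndarray
    kind: str = "composed"
    composition: str = "none"
    left: "KernelMatrix | None" = field(default=None, repr=False)
    right: "KernelMatrix | None" = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.K.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        """Check symmetry and positive semi-definiteness."""
        K = self.K
        if not np.allclose(K, K.T, atol=atol):
            raise InvalidInputError("kernel matrix is not symmetric")
        evals = np.linalg.eigvalsh((K + K.T) / 2.0)
        if evals[0] < -1e-8 * max(evals[-1], 1.0):
            raise InvalidInputError(
                f"kernel matrix is not PSD (lambda_min={evals[0]:.3e})"
            )

    def to_csv(self, path) -> None:
        np.savetxt(path, self.K, delimiter=",")


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Deterministic sign convention: largest-magnitude entry of each U column
    # positive; the paired V column is flipped with it so U diag(S) V^T is
    # unchanged.  Spans are unaffected.
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def project_to_grassmann(Y: np.ndarray, p: int) -> GrassmannPoint:
    """Project a trajectory matrix onto ``G(p, n) x G(p, m)`` via thin SVD.

    Parameters
    ----------
    Y : (n, m) array_like
        Finite real matrix.
    p : int
        Subspace dimension, ``1 <= p <= min(n, m)``.  If the numerical rank
        of ``Y`` is below ``p`` a warning is emitted (one fixed ``p`` per
        ensemble is used even when individual ranks vary) but the projection
        still returns ``p`` columns.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise DimensionError(f"expected a 2-D matrix, got shape {Y.shape}")
    if not np.all(np.isfinite(Y)):
        raise InvalidInputError("trajectory matrix contains non-finite entries")
    n, m = Y.shape
    if not (1 <= p <= min(n, m)):
        raise DimensionError(f"p={p} outside [1, min(n, m)={min(n, m)}]")
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    if numerical_rank(s) < p:
        warnings.warn(
            f"numerical rank {numerical_rank(s)} < requested p={p}; "
            "projecting with p columns anyway",
            RuntimeWarning,
            stacklevel=2,
        )
    U, V = _fix_signs(U[:, :p], Vt[:p].T)
    return GrassmannPoint(U=U, S=s[:p].copy(), V=V, p=p)


def numerical_rank(
    singular_values_or_matrix: np.ndarray,
    tolerance: float = DEFAULT_RANK_TOLERANCE,
) -> int:
    """Number of singular values exceeding ``tolerance * sigma_1``."""
    a = np.asarray(singular_values_or_matrix, dtype=float)
    s = np.linalg.svd(a, compute_uv=False) if a.ndim == 2 else a
    if s.size == 0 or s[0] <= 0:
        return 0
    return int(np.count_nonzero(s > tolerance * s[0]))


def rank_profile(
    matrices: Iterable[np.ndarray],
    tolerance: float = DEFAULT_RANK_TOLERANCE,
    threshold: float | None = None,
) -> RankProfile:
    """Tabulate numerical ranks across an ensemble and select the dimension p.

    By default ``selected_p`` is the modal (most frequently occurring) rank,
    ties broken toward the smaller rank.  With ``threshold`` in ``(0, 1]``,
    ranks are accumulated in descending order of occurrence count until the
    cumulative frequency reaches the threshold, and the smallest rank among
    those accumulated is selected.
    """
    ranks = [numerical_rank(np.asarray(Y, dtype=float), tolerance) for Y in matrices]
    if not ranks:
        raise InvalidInputError("rank_profile requires a nonempty ensemble")
    counts = Counter(ranks)
    if threshold is None:
        best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
        selected = best[0]
        threshold_used = 1.0
    else:
        if not (0.0 < threshold <= 1.0):
            raise InvalidInputError(f"threshold {threshold} outside (0, 1]")
        total = sum(counts.values())
        ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        cum = 0
        included: list[int] = []
        for rank, c in ordered:
            included.append(rank)
            cum += c
            if cum / total >= threshold:
                break
        selected = min(included)
        threshold_used = threshold
    return RankProfile(counts=dict(sorted(counts.items())),
                       threshold=threshold_used, selected_p=selected)


def projection_kernel(A: np.ndarray, B: np.ndarray) -> float:
    """Projection kernel ``||A^T B||_F^2`` between two orthonormal bases.

    Equals ``sum_i cos^2(phi_i)`` over the principal angles between the
    spans, hence lies in ``[0, p]`` with ``p`` iff the spans coincide.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise DimensionError(f"basis shapes differ: {A.shape} vs {B.shape}")
    return float(np.sum((A.T @ B) ** 2))


def _kernel_matrix(bases: np.ndarray) -> np.ndarray:
    # bases: (N, n, p).  k_ij = ||B_i^T B_j||_F^2 = tr(P_i P_j) with the
    # projectors P = B B^T, so K = F F^T for F the flattened projectors.
    N, n, _ = bases.shape
    if N * n * n * 8 <= 512 * 2 ** 20:  # projector route, <= 512 MB scratch
        F = np.einsum("inp,imp->inm", bases, bases).reshape(N, n * n)
        K = F @ F.T
    else:
        K = np.empty((N, N))
        for i in range(N):
            C = np.einsum("np,jnq->jpq", bases[i], bases)
            K[i] = np.sum(C * C, axis=(1, 2))
    return (K + K.T) / 2.0


def build_kernel_matrices(
    points: Sequence[GrassmannPoint],
    composition: str = "hadamard",
) -> KernelMatrix:
    """Assemble the left/right projection-kernel matrices and compose them.

    ``composition`` is ``"hadamard"`` (entrywise product, the default) or
    ``"sum"``.  The returned composed :class:`KernelMatrix` carries the
    one-sided matrices in its ``left`` and ``right`` fields.
    """
    if not points:
        raise InvalidInputError("build_kernel_matrices requires >= 1 point")
    p = points[0].p
    n, m = points[0].n, points[0].m
    for pt in points:
        if (pt.p, pt.n, pt.m) != (p, n, m):
            raise DimensionError(
                "all Grassmann points must share (p, n, m); got "
                f"({pt.p}, {pt.n}, {pt.m}) vs ({p}, {n}, {m})"
            )
    KU = _kernel_matrix(np.stack([pt.U for pt in points]))
    KV = _kernel_matrix(np.stack([pt.V for pt in points]))
    if composition == "hadamard":
        K = KU * KV
    elif composition == "sum":
        K = KU + KV
    else:
        raise InvalidInputError(f"unknown composition {composition!r}")
    return KernelMatrix(
        K=K,
        kind="composed",
        composition=composition,
        left=KernelMatrix(K=KU, kind="left"),
        right=KernelMatrix(K=KV, kind="right"),
    )
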