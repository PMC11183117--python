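"""Diffusion maps on the composed Grassmannian kernel.

The composed kernel defines a random walk over the ensemble: degrees
``D_ii = sum_j k_ij``, symmetric normalization
``kappa_ij = k_ij / sqrt(D_ii D_jj)``, and the row-stochastic transition
matrix ``P`` obtained by row-normalizing ``kappa`` (the standard
diffusion-maps construction; see :func:`transition_matrix` for the literal
alternative).  Single-step diffusion coordinates are
``Theta_{l,j} = lambda_j * xi_{l,j}`` over ``g`` retained nontrivial
eigenpairs of ``P``.  Retention is either by eigenvalue rank or
"parsimonious": eigenvectors that are well predicted by a local linear
regression on earlier ones ("repeated eigendirections", higher-order
harmonics) are skipped in favour of eigenvectors carrying new directions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .exceptions import (
    DegenerateKernelError,
    DimensionError,
    InvalidInputError,
    NumericalError,
)
from .grassmann import KernelMatrix

__all__ = [
    "TransitionMatrix",
    "DiffusionEmbedding",
    "transition_matrix",
    "diffusion_eigendecomposition",
    "parsimonious_select",
    "select_coordinates",
    "embedding_to_csv",
    "embedding_from_csv",
]


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition matrix of the kernel-induced random walk.

    ``D`` are the raw kernel degrees, ``kappa`` the symmetrically normalized
    kernel, and ``pi`` the degree-based distribution ``D_ii / sum_k D_kk``
    (the stationary distribution of the unnormalized walk ``D^{-1} K``; it is
    reported alongside but not asserted stationary for ``P`` itself).
    """

    P: np.ndarray
    D: np.ndarray
    kappa: np.ndarray
    pi: np.ndarray


@dataclass(frozen=True)
class DiffusionEmbedding:
    """Eigenstructure of the diffusion walk and retained coordinates.

    ``eigenvalues``/``eigenvectors`` hold all computed eigenpairs sorted by
    eigenvalue descending (index 0 is the trivial pair with ``lambda_0 = 1``
    and a near-constant eigenvector).  ``coordinates`` is the N x g matrix
    with columns ``lambda_j * xi_j`` over ``retained_indices`` (which never
    include index 0); both are ``None`` until selection has been applied.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    stationary: np.ndarray
    coordinates: np.ndarray | None = None
    retained_indices: tuple[int, ...] | None = None
    selection_mode: str | None = None

    @property
    def g(self) -> int | None:
        return None if self.retained_indices is None else len(self.retained_indices)


def transition_matrix(K, numerator: str = "kappa") -> TransitionMatrix:
    """Build the random-walk transition matrix from a kernel matrix.

    Parameters
    ----------
    K : KernelMatrix or (N, N) array_like
        Symmetric nonnegative-degree kernel.
    numerator : {"kappa", "raw"}
        ``"kappa"`` (default) row-normalizes the symmetrically normalized
        kernel, ``P_ij = kappa_ij / sum_k kappa_ik``, which makes ``P``
        similar to a symmetric matrix with spectrum in [-1, 1].  ``"raw"``
        uses the raw kernel in the numerator over the kappa row sums; kept
        only for comparison, as it loses the usual spectral properties.
    """
    Kmat = K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)
    if Kmat.ndim != 2 or Kmat.shape[0] != Kmat.shape[1]:
        raise DimensionError(f"kernel must be square, got {Kmat.shape}")
    if not np.allclose(Kmat, Kmat.T, atol=1e-10):
        raise InvalidInputError("kernel matrix must be symmetric")
    D = Kmat.sum(axis=1)
    bad = np.flatnonzero(D <= 0)
    if bad.size:
        raise DegenerateKernelError(
            f"zero kernel degree for sample(s) {bad.tolist()}"
        )
    kappa = Kmat / np.sqrt(np.outer(D, D))
    if numerator == "kappa":
        P = kappa / kappa.sum(axis=1, keepdims=True)
    elif numerator == "raw":
        P = Kmat / kappa.sum(axis=1, keepdims=True)
    else:
        raise InvalidInputError(f"unknown numerator {numerator!r}")
    pi = D / D.sum()
    return TransitionMatrix(P=P, D=D, kappa=kappa, pi=pi)


def _fix_vector_signs(V: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(V), axis=0)
    signs = np.sign(V[idx, np.arange(V.shape[1])])
    signs[signs == 0] = 1.0
    return V * signs


def diffusion_eigendecomposition(
    T: TransitionMatrix, g_max: int
) -> DiffusionEmbedding:
    """Eigendecompose the transition matrix; coordinates not yet selected.

    ``P`` is similar to the symmetric matrix
    ``A = Dk^{1/2} P Dk^{-1/2}`` (``Dk`` the kappa row sums), so a dense
    symmetric solver is used and right eigenvectors of ``P`` are recovered as
    ``xi = Dk^{-1/2} phi``.  Eigenpairs are sorted by eigenvalue descending,
    eigenvectors unit-normalized with a deterministic sign (largest-magnitude
    entry positive); ties in eigenvalue keep original index order.  The
    ``g_max + 1`` leading pairs (trivial pair included) are stored.
    """
    P = T.P
    N = P.shape[0]
    if not (0 < g_max < N):
        raise DimensionError(f"g_max={g_max} must be in (0, N={N})")
    dk = T.kappa.sum(axis=1)
    sq = np.sqrt(dk)
    A = (sq[:, None] * P) / sq[None, :]
    A = (A + A.T) / 2.0
    try:
        evals, evecs = np.linalg.eigh(A)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare
        raise NumericalError(f"symmetric eigensolver failed: {exc}") from exc
    order = np.argsort(-evals, kind="stable")
    evals = evals[order]
    xi = evecs[:, order] / sq[:, None]
    xi /= np.linalg.norm(xi, axis=0, keepdims=True)
    xi = _fix_vector_signs(xi)
    keep = g_max + 1
    evals, xi = evals[:keep], xi[:, :keep]
    resid = np.max(np.abs(P @ xi - xi * evals[None, :]))
    if resid > 1e-8:
        raise NumericalError(
            f"eigenpair residual {resid:.3e} exceeds 1e-8 "
            f"(N={N}, g_max={g_max})"
        )
    return DiffusionEmbedding(eigenvalues=evals, eigenvectors=xi,
                              stationary=T.pi)


def _local_linear_residual(
    Phi: np.ndarray, target: np.ndarray, bandwidth_scale: float
) -> float:
    """Leave-one-out local-linear-regression residual of ``target`` on ``Phi``.

    For each sample i, a Gaussian-weighted linear fit on all other samples
    predicts ``target[i]``; the normalized residual norm lies in [0, 1]-ish,
    with small values flagging ``target`` as a harmonic of earlier
    eigendirections.
    """
    N = Phi.shape[0]
    d2 = np.sum((Phi[:, None, :] - Phi[None, :, :]) ** 2, axis=-1)
    pair = np.sqrt(d2[np.triu_indices(N, k=1)])
    med = np.median(pair)
    if med <= 0:
        return 0.0
    eps = (bandwidth_scale * med) ** 2
    W = np.exp(-d2 / eps)
    X = np.column_stack([np.ones(N), Phi])
    preds = np.empty(N)
    for i in range(N):
        w = W[i].copy()
        w[i] = 0.0
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], target * sw, rcond=None)
        preds[i] = X[i] @ coef
    denom = np.linalg.norm(target)
    return float(np.linalg.norm(target - preds) / denom) if denom > 0 else 0.0


def parsimonious_select(
    eigenvectors: np.ndarray,
    eigenvalues: np.ndarray,
    g: int,
    bandwidth_scale: float = 3.0,
) -> tuple[tuple[int, ...], np.ndarray]:
    """Select ``g`` eigenvectors that introduce new directions.

    ``eigenvectors`` holds the *nontrivial* eigenvectors as columns, in
    eigenvalue order.  Scanning in that order, each candidate is regressed
    (local linear regression, Gaussian weights with bandwidth
    ``bandwidth_scale * median pairwise distance``) on all previous
    candidates; the residual score ``r_k`` is ~1 for genuinely new directions
    and ~0 for repeated eigendirections.  The first candidate always has
    ``r_1 = 1``.  The ``g`` largest-residual eigenvectors are retained (ties
    broken toward lower eigenvalue-rank), returned with their scores.

    Returns ``(retained_positions, residuals)`` where positions index into
    the nontrivial eigenvector columns (0-based), sorted ascending.
    """
    K = eigenvectors.shape[1]
    if g > K:
        raise DimensionError(f"g={g} exceeds available nontrivial pairs {K}")
    if len(eigenvalues) != K:
        raise DimensionError("eigenvalue/eigenvector count mismatch")
    residuals = np.empty(K)
    residuals[0] = 1.0
    for k in range(1, K):
        residuals[k] = _local_linear_residual(
            eigenvectors[:, :k], eigenvectors[:, k], bandwidth_scale
        )
    order = np.argsort(-residuals, kind="stable")
    retained = tuple(sorted(int(i) for i in order[:g]))
    return retained, residuals


def select_coordinates(
    embedding: DiffusionEmbedding,
    g: int,
    mode: str = "parsimonious",
    bandwidth_scale: float = 3.0,
) -> DiffusionEmbedding:
    """Retain ``g`` nontrivial diffusion coordinates ``lambda_j xi_j``."""
    evals = embedding.eigenvalues
    xi = embedding.eigenvectors
    n_nontrivial = len(evals) - 1
    if g > n_nontrivial:
        raise DimensionError(
            f"g={g} exceeds available nontrivial eigenpairs {n_nontrivial}"
        )
    if mode == "top_eigenvalues":
        positions = tuple(range(g))
    elif mode == "parsimonious":
        positions, _ = parsimonious_select(
            xi[:, 1:], evals[1:], g, bandwidth_scale
        )
    else:
        raise InvalidInputError(f"unknown selection mode {mode!r}")
    retained = tuple(p + 1 for p in positions)  # shift past trivial index 0
    coords = xi[:, retained] * evals[list(retained)][None, :]
    return replace(
        embedding,
        coordinates=coords,
        retained_indices=retained,
        selection_mode=mode,
    )


def embedding_to_csv(embedding: DiffusionEmbedding, path) -> None:
    """Write retained coordinates to CSV, bit-exactly reloadable.

    Header row carries the retained eigenvalue index and value per column.
    """
    if embedding.coordinates is None:
        raise InvalidInputError("embedding has no selected coordinates")
    header = ",".join(
        f"theta_{j}={float(embedding.eigenvalues[j])!r}"
        for j in embedding.retained_indices
    )
    np.savetxt(path, embedding.coordinates, delimiter=",", header=header,
               comments="", fmt="%.17g")


def embedding_from_csv(path) -> tuple[np.ndarray, tuple[int, ...], np.ndarray]:
    """Reload ``(coordinates, retained_indices, eigenvalues)`` from CSV."""
    with open(path) as fh:
        header = fh.readline().strip()
    cols = header.split(",")
    indices = tuple(int(c.split("=")[0].split("_")[1]) for c in cols)
    evals = np.array([float(c.split("=")[1]) for c in cols])
    coords = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return coords, indices, evals
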