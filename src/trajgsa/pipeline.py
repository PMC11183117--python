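"""End-to-end orchestration of trajectory-based sensitivity analysis.

The full procedure: sample an experimental design from declared marginals,
evaluate the model to obtain one trajectory record per design point, reshape
each record to an ``n x m`` matrix, project the ensemble onto the Grassmann
manifold, build and compose projection-kernel matrices, embed with diffusion
maps, retain ``g`` diffusion coordinates, fit a PCE surrogate from inputs to
coordinates on a train split, and read first-/total-order Sobol' indices off
the surrogate coefficients; held-out validation metrics quantify surrogate
quality.  Multi-level outputs (agent / community / population) are supported
through :func:`aggregate_levels`.  Every stochastic stage consumes an
explicit seed derived from the config seed, so a run is a pure function of
its configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from . import diffusion, grassmann, pce, sobol
from .exceptions import (
    AggregationError,
    ConfigurationError,
    DimensionError,
    InvalidInputError,
    ShapeError,
)
from .pce import Marginal, PCESurrogate, fit_surrogate, validation_metrics
from .sobol import SensitivityResult, pce_sobol_indices

__all__ = [
    "ExperimentalDesign",
    "TrajectoryEnsemble",
    "GSAConfig",
    "GSAResult",
    "RepeatSummary",
    "sample_design",
    "reshape_trajectory",
    "aggregate_levels",
    "run_gsa",
    "repeat_statistics",
    "load_ensemble",
    "save_ensemble",
]


@dataclass(frozen=True)
class ExperimentalDesign:
    """N x k table of sampled inputs with declared marginals."""

    X: np.ndarray
    marginals: tuple[Marginal, ...]
    sampler: str = "sobol_sequence"
    seed: int | None = None

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "marginals", tuple(self.marginals))
        if X.shape[1] != len(self.marginals):
            raise ConfigurationError(
                f"{X.shape[1]} design columns vs {len(self.marginals)} marginals"
            )
        names = [m.name for m in self.marginals if m.name]
        if len(names) != len(set(names)):
            raise ConfigurationError("parameter names must be unique")
        for j, m in enumerate(self.marginals):
            if m.family == "uniform":
                col = X[:, j]
                if col.min() < m.a - 1e-12 or col.max() > m.b + 1e-12:
                    raise ConfigurationError(
                        f"column {j} outside declared uniform bounds "
                        f"[{m.a}, {m.b}]"
                    )

    @property
    def N(self) -> int:
        return self.X.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name or f"x{j+1}" for j, m in enumerate(self.marginals))

    def to_csv(self, path) -> None:
        header = ",".join(self.names)
        np.savetxt(path, self.X, delimiter=",", header=header, comments="",
                   fmt="%.17g")

    @classmethod
    def from_csv(cls, path, marginals: Sequence[Marginal]) -> "ExperimentalDesign":
        X = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(X=X, marginals=tuple(marginals), sampler="file", seed=None)


def sample_design(
    marginals: Sequence[Marginal],
    N: int,
    sampler: str = "sobol_sequence",
    seed: int | None = None,
) -> ExperimentalDesign:
    """Draw an experimental design from the declared marginals.

    ``"sobol_sequence"`` uses a scrambled low-discrepancy sequence,
    ``"pseudorandom"`` plain iid uniforms; both are mapped through the
    marginal quantile functions.
    """
    k = len(marginals)
    if sampler == "sobol_sequence":
        engine = qmc.Sobol(d=k, scramble=True, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            U = engine.random(N)
    elif sampler == "pseudorandom":
        U = np.random.default_rng(seed).random((N, k))
    else:
        raise ConfigurationError(f"unknown sampler {sampler!r}")
    X = np.column_stack([m.ppf(U[:, j]) for j, m in enumerate(marginals)])
    return ExperimentalDesign(X=X, marginals=tuple(marginals),
                              sampler=sampler, seed=seed)


@dataclass
class TrajectoryEnsemble:
    """N reshaped trajectory matrices plus level metadata."""

    matrices: np.ndarray  # (N, n, m)
    level: str = "macro"
    reshape_spec: str = "auto_square"

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3:
            raise DimensionError(
                f"expected (N, n, m) array, got shape {self.matrices.shape}"
            )

    @property
    def N(self) -> int:
        return self.matrices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrices.shape[1:]

    @classmethod
    def from_records(
        cls, records: Sequence[np.ndarray], target="auto_square",
        level: str = "macro",
    ) -> "TrajectoryEnsemble":
        mats = np.stack([reshape_trajectory(r, target) for r in records])
        return cls(matrices=mats, level=level,
                   reshape_spec=str(target))


def reshape_trajectory(record: np.ndarray, target="auto_square") -> np.ndarray:
    """Reshape one trajectory record to an ``n x m`` matrix.

    The record is flattened row-major: response channels concatenated in
    declared order, time fastest within each channel.  ``"auto_square"``
    requires the flattened length to be a perfect square; an explicit
    ``(n, m)`` must satisfy ``n * m == L``.
    """
    flat = np.asarray(record, dtype=float).ravel(order="C")
    L = flat.size
    if L < 1:
        raise ShapeError("empty trajectory record")
    if isinstance(target, str):
        if target != "auto_square":
            raise ConfigurationError(f"unknown reshape target {target!r}")
        side = int(round(np.sqrt(L)))
        if side * side != L:
            nearest = side * side if side * side < L else (side - 1) ** 2
            raise ShapeError(
                f"length {L} is not a perfect square; nearest valid "
                f"truncation is {nearest}"
            )
        return flat.reshape(side, side)
    n, m = target
    if n * m != L:
        raise ShapeError(f"target {n}x{m} != flattened length {L}")
    return flat.reshape(n, m)


def aggregate_levels(
    micro: np.ndarray,
    community_labels: np.ndarray,
    duplicates: int = 8,
    drop_last: int = 6,
    macro_drop_last: int = 1,
    seed: int | None = None,
    meso_target="auto_square",
    macro_target="auto_square",
    n_communities: int | None = None,
) -> tuple[TrajectoryEnsemble, TrajectoryEnsemble]:
    """Aggregate agent-level trajectories to community and population levels.

    ``micro`` is (N, agents, T).  A community trajectory is the mean of its
    agents' trajectories; ``duplicates`` randomly chosen community rows
    (seeded) are appended and the last ``drop_last`` steps removed before the
    square reshape.  The macro trajectory is the mean over all agents, with
    its own ``macro_drop_last`` trailing steps removed.
    """
    micro = np.asarray(micro, dtype=float)
    if micro.ndim != 3:
        raise DimensionError(f"micro must be (N, agents, T), got {micro.shape}")
    N, A, T = micro.shape
    labels = np.asarray(community_labels)
    if labels.shape != (A,):
        raise AggregationError("labels must cover every agent exactly once")
    if duplicates < 0 or drop_last >= T or macro_drop_last >= T:
        raise ConfigurationError("invalid duplicates/drop settings")
    if n_communities is None:
        communities = np.unique(labels)
    else:
        communities = np.arange(n_communities)
    groups = []
    for c in communities:
        members = np.flatnonzero(labels == c)
        if members.size == 0:
            raise AggregationError(f"community {c} is empty")
        groups.append(members)
    meso = np.stack(
        [micro[:, g, :].mean(axis=1) for g in groups], axis=1
    )  # (N, C, T)
    if duplicates:
        rng = np.random.default_rng(seed)
        extra = rng.choice(len(communities), size=duplicates, replace=True)
        meso = np.concatenate([meso, meso[:, extra, :]], axis=1)
    if drop_last:
        meso = meso[:, :, :T - drop_last]
    macro = micro.mean(axis=1)
    if macro_drop_last:
        macro = macro[:, :T - macro_drop_last]
    meso_ens = TrajectoryEnsemble.from_records(
        list(meso), target=meso_target, level="meso"
    )
    macro_ens = TrajectoryEnsemble.from_records(
        list(macro), target=macro_target, level="macro"
    )
    return meso_ens, macro_ens


@dataclass
class GSAConfig:
    """All knobs of one pipeline run; validated before any compute."""

    marginals: tuple[Marginal, ...] = ()
    N: int = 600
    sampler: str = "sobol_sequence"
    seed: int = 0
    p: int | str = "auto"
    rank_tolerance: float = grassmann.DEFAULT_RANK_TOLERANCE
    rank_threshold: float | None = None
    g: int = 3
    selection_mode: str = "parsimonious"
    composition: str = "hadamard"
    s_max: int = 6
    fit_method: str = "lar"
    eps_target: float = 1e-8
    test_fraction: float = 1.0 / 3.0
    split: str = "tail"
    reshape_target: object = "auto_square"
    repeats: int = 1
    bootstrap_B: int = 500

    def validate(self) -> None:
        if not self.marginals:
            raise ConfigurationError("config declares no input marginals")
        if self.N < 4:
            raise ConfigurationError("N must be >= 4")
        if isinstance(self.p, str) and self.p != "auto":
            raise ConfigurationError(f"p must be an integer or 'auto', got {self.p!r}")
        if self.g < 1:
            raise ConfigurationError("g must be >= 1")
        if self.selection_mode not in ("parsimonious", "top_eigenvalues"):
            raise ConfigurationError(f"bad selection_mode {self.selection_mode!r}")
        if self.composition not in ("hadamard", "sum"):
            raise ConfigurationError(f"bad composition {self.composition!r}")
        if self.fit_method not in ("ols", "lar"):
            raise ConfigurationError(f"bad fit_method {self.fit_method!r}")
        if not (0.0 < self.test_fraction < 1.0):
            raise ConfigurationError("test_fraction must be in (0, 1)")
        if self.split not in ("tail", "random"):
            raise ConfigurationError(f"bad split {self.split!r}")

    def hash(self) -> str:
        payload = {k: (v if isinstance(v, (int, float, str, bool)) else str(v))
                   for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class GSAResult:
    """Everything one pipeline run produces."""

    sensitivity: SensitivityResult
    embedding: diffusion.DiffusionEmbedding
    surrogate: PCESurrogate
    errors: dict
    design: ExperimentalDesign
    rank_profile: grassmann.RankProfile | None
    metadata: dict = field(default_factory=dict)


def _derive_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def run_gsa(
    config: GSAConfig,
    model: Callable[[np.ndarray], np.ndarray],
    design: ExperimentalDesign | None = None,
    ensemble: TrajectoryEnsemble | None = None,
) -> GSAResult:
    """Run the full trajectory-based GSA pipeline.

    ``model`` maps one design row to a trajectory record; a precomputed
    ``design`` and/or ``ensemble`` can be supplied instead of sampling and
    simulating.  Stages: sample -> evaluate -> reshape -> Grassmann
    projection (``p`` from config or the ensemble rank profile) -> composed
    kernel -> diffusion embedding -> train/test split -> surrogate fit ->
    analytic Sobol' indices -> validation metrics.
    """
    config.validate()
    if design is None:
        design = sample_design(
            config.marginals, config.N, config.sampler,
            seed=_derive_seed(config.seed, "design"),
        )
    if ensemble is None:
        if model is None:
            raise ConfigurationError("need a model callable or an ensemble")
        records = [model(x) for x in design.X]
        ensemble = TrajectoryEnsemble.from_records(
            records, target=config.reshape_target
        )
    if ensemble.N != design.N:
        raise DimensionError(
            f"ensemble size {ensemble.N} != design size {design.N}"
        )

    profile = None
    if config.p == "auto":
        profile = grassmann.rank_profile(
            ensemble.matrices, tolerance=config.rank_tolerance,
            threshold=config.rank_threshold,
        )
        p = profile.selected_p
    else:
        p = int(config.p)  # a user-specified p always wins
    points = [grassmann.project_to_grassmann(Y, p) for Y in ensemble.matrices]
    kernel = grassmann.build_kernel_matrices(points, config.composition)
    walk = diffusion.transition_matrix(kernel)
    g_max = min(max(4 * config.g, config.g + 5), design.N - 1)
    emb = diffusion.diffusion_eigendecomposition(walk, g_max=g_max)
    emb = diffusion.select_coordinates(emb, config.g, config.selection_mode)
    Theta = emb.coordinates

    n_test = int(np.floor(design.N * config.test_fraction))
    if config.split == "tail":
        test_idx = np.arange(design.N - n_test, design.N)
    else:
        rng = np.random.default_rng(_derive_seed(config.seed, "split"))
        test_idx = rng.choice(design.N, size=n_test, replace=False)
    train_mask = np.ones(design.N, dtype=bool)
    train_mask[test_idx] = False

    surrogate = fit_surrogate(
        design.X[train_mask], Theta[train_mask], design.marginals,
        s_max=config.s_max, method=config.fit_method,
        eps_target=config.eps_target,
    )
    errors = {"eps_loo": surrogate.errors["eps_loo"]}
    if n_test:
        eps_val, mae = validation_metrics(
            surrogate, design.X[test_idx], Theta[test_idx]
        )
        errors["eps_val"] = eps_val
        errors["mae"] = mae
    surrogate.errors.update(errors)

    sens = pce_sobol_indices(surrogate, parameter_names=design.names)
    sens.metadata.update(
        N=design.N, seed=config.seed, p=p, g=config.g,
        selection_mode=config.selection_mode,
        retained_indices=list(emb.retained_indices),
        config_hash=config.hash(),
    )
    return GSAResult(
        sensitivity=sens, embedding=emb, surrogate=surrogate, errors=errors,
        design=design, rank_profile=profile,
        metadata={"p": p, "config_hash": config.hash(), "seed": config.seed},
    )


@dataclass
class RepeatSummary:
    """Across-repeat mean and variance of the sensitivity indices."""

    mean_first_order: np.ndarray
    mean_total_order: np.ndarray
    var_first_order: np.ndarray
    var_total_order: np.ndarray
    retained_sets: tuple[tuple[int, ...], ...]
    repeats: int
    mode: str
    results: tuple[GSAResult, ...] = ()


def repeat_statistics(
    config: GSAConfig,
    model_factory: Callable[[int], Callable[[np.ndarray], np.ndarray]],
    repeats: int,
    mode: str = "resample_inputs",
    keep_results: bool = False,
) -> RepeatSummary:
    """Mean and variance of indices over independent pipeline repeats.

    ``mode="resample_inputs"`` redraws the experimental design each repeat
    (same model seed); ``mode="reseed_model"`` keeps the design fixed and
    reseeds the model.  Indices are averaged by retained-coordinate slot
    (first/second/third kept coordinate), since parsimonious selection may
    retain different eigenvector indices per repeat.
    """
    if repeats < 2:
        raise ConfigurationError("repeats must be >= 2")
    if mode not in ("resample_inputs", "reseed_model"):
        raise ConfigurationError(f"unknown repeat mode {mode!r}")
    S_list, ST_list, retained, results = [], [], [], []
    for r in range(repeats):
        cfg = GSAConfig(**{**asdict(config),
                           "marginals": config.marginals})
        if mode == "resample_inputs":
            cfg.seed = _derive_seed(config.seed, f"repeat{r}")
            model = model_factory(config.seed)
        else:
            cfg.seed = config.seed
            model = model_factory(_derive_seed(config.seed, f"model{r}"))
        res = run_gsa(cfg, model)
        S_list.append(res.sensitivity.first_order)
        ST_list.append(res.sensitivity.total_order)
        retained.append(tuple(res.embedding.retained_indices))
        if keep_results:
            results.append(res)
    S = np.stack(S_list)
    ST = np.stack(ST_list)
    return RepeatSummary(
        mean_first_order=S.mean(axis=0),
        mean_total_order=ST.mean(axis=0),
        var_first_order=S.var(axis=0),
        var_total_order=ST.var(axis=0),
        retained_sets=tuple(retained),
        repeats=repeats,
        mode=mode,
        results=tuple(results),
    )


# ---------------------------------------------------------------------------
# Ensemble I/O
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: TrajectoryEnsemble, path) -> None:
    """Save to ``.npy`` or HDF5 (by extension) as an (N, n, m) array."""
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, ensemble.matrices)
    elif path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("trajectories", data=ensemble.matrices)
            ds.attrs["level"] = ensemble.level
    else:
        raise ConfigurationError(f"unsupported ensemble format {path.suffix!r}")


def load_ensemble(path, target="auto_square", level: str = "macro") -> TrajectoryEnsemble:
    """Load an ensemble from a directory of CSV matrices, ``.npy`` or HDF5."""
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.csv"))
        if not files:
            raise InvalidInputError(f"no CSV matrices found in {path}")
        mats = [np.loadtxt(f, delimiter=",", ndmin=2) for f in files]
        return TrajectoryEnsemble(matrices=np.stack(mats), level=level)
    if path.suffix == ".npy":
        arr = np.load(path)
    elif path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            arr = fh["trajectories"][...]
    else:
        raise ConfigurationError(f"unsupported ensemble format {path.suffix!r}")
    if arr.ndim == 2:  # N flat records
        return TrajectoryEnsemble.from_records(list(arr), target=target, level=level)
    return TrajectoryEnsemble(matrices=arr, level=level)
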