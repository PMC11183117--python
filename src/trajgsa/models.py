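"""Bundled desk-scale data generators.

Three simulators exercise the sensitivity-analysis pipeline end to end:

* a Lotka-Volterra predator-prey ODE solver (``du/dt = alpha*u - beta*u*v``,
  ``dv/dt = delta*u*v - gamma*v``), with uncertain growth rate ``alpha`` and
  predation rate ``beta``;
* a toy stochastic epidemic agent simulator whose per-contact transmission
  probability is ``P = 1 - exp(-lambda)`` with a hazard proportional to a
  gamma infectivity-profile window integral, modulated by age-dependent
  susceptibility, stage-dependent infectiousness, and network-type duration
  scalars, each multiplied by an uncertain general scale factor;
* a synthetic multi-level wealth-trajectory generator with planted,
  analytically known first-order variance shares, emulating the structure of
  an economic agent-based model's micro/meso/macro outputs (it does NOT
  simulate the underlying economy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp

from . import constants
from .exceptions import (
    ConfigurationError,
    InvalidInputError,
    NumericalError,
)
from .pce import Marginal

__all__ = [
    "LVParams",
    "EpidemicParams",
    "WealthGenParams",
    "solve_lotka_volterra",
    "infection_probability",
    "simulate_toy_epidemic",
    "generate_multilevel_wealth",
    "get_model",
    "LOTKA_VOLTERRA_MARGINALS",
    "EPIDEMIC_MARGINALS",
    "POVERTY_TRAP_MARGINALS",
]

#: Uncertain-parameter marginals for the Lotka-Volterra demonstration.
LOTKA_VOLTERRA_MARGINALS = (
    Marginal.uniform(0.90, 1.05, "alpha"),
    Marginal.uniform(0.10, 0.18, "beta"),
)

#: Uncertain-parameter marginals for the epidemic demonstration
#: (overall infection rate R and four general multiplicative scalars).
EPIDEMIC_MARGINALS = (
    Marginal.uniform(1.9, 6.5, "R"),
    Marginal.uniform(0.5, 1.5, "S_F"),
    Marginal.uniform(0.5, 1.5, "A_F"),
    Marginal.uniform(0.7, 1.3, "B_F"),
    Marginal.uniform(0.7, 1.3, "Gamma_F"),
)

#: Nominal marginals for the six wealth-model inputs.
POVERTY_TRAP_MARGINALS = (
    Marginal.uniform(0.01, 2.0, "COST"),
    Marginal.uniform(0.7, 0.8, "beta"),
    Marginal.uniform(0.30, 0.45, "ell"),
    Marginal.uniform(1.7, 2.3, "G_upper"),
    Marginal.uniform(0.01, 0.15, "sigma_w"),
    Marginal.uniform(8.0, 20.0, "lambda"),
)


# ---------------------------------------------------------------------------
# Lotka-Volterra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LVParams:
    """Lotka-Volterra rates, initial populations and time grid."""

    alpha: float = 0.975
    beta: float = 0.14
    gamma: float = 1.5
    delta: float = 0.75
    u0: float = 10.0
    v0: float = 5.0
    T: float = 25.0
    n: int = 512

    def __post_init__(self) -> None:
        # zero interaction rates (beta, delta) decouple the system and are
        # allowed; growth/death rates must be positive
        if self.alpha <= 0 or self.gamma <= 0 or self.beta < 0 or self.delta < 0:
            raise ConfigurationError("Lotka-Volterra rates must be positive "
                                     "(interaction rates may be zero)")
        if self.u0 < 0 or self.v0 < 0:
            raise ConfigurationError("initial populations must be >= 0")
        if self.n < 2:
            raise ConfigurationError("need at least 2 time points")


def solve_lotka_volterra(params: LVParams) -> np.ndarray:
    """Integrate the predator-prey system on a uniform ``n``-point grid.

    Returns a (2, n) array ``[u; v]``; adaptive high-order integration with
    relative tolerance 1e-9.
    """
    p = params

    def rhs(_t, y):
        u, v = y
        return (p.alpha * u - p.beta * u * v, p.delta * u * v - p.gamma * v)

    t_eval = np.linspace(0.0, p.T, p.n)
    sol = solve_ivp(
        rhs, (0.0, p.T), (p.u0, p.v0), t_eval=t_eval,
        method="DOP853", rtol=1e-9, atol=1e-11,
    )
    if not sol.success:
        raise NumericalError(
            f"ODE solver failed for params {p}: {sol.message}"
        )
    return sol.y


# ---------------------------------------------------------------------------
# Toy epidemic
# ---------------------------------------------------------------------------

# Reduced stage machine (desk-scale stand-in for the 11-stage original).
SUSCEPTIBLE, PRESYMPTOMATIC, SYMPTOMATIC, HOSPITALIZED, RECOVERED, DEAD = range(6)

# Map reduced stages to rows of the canonical infectiousness table.
_PRESYMP_A_INDEX = constants.DISEASE_STAGES.index("presymptomatic_mild")
_MILD_A_INDEX = constants.DISEASE_STAGES.index("mild_symptomatic")
_SEVERE_A_INDEX = constants.DISEASE_STAGES.index("severe_symptomatic")


@dataclass(frozen=True)
class EpidemicParams:
    """Uncertain scalars, base tables and desk-scale simulation settings.

    ``R`` is the overall infection-rate scalar; ``S_F``, ``A_F``, ``B_F`` and
    ``Gamma_F`` multiply the age-susceptibility table, the stage
    infectiousness table, the network-duration scalars, and the gamma
    infectivity-profile parameters respectively.  Network degrees determine
    the mean number of daily interactions ``I_bar``.
    """

    R: float = 4.2
    S_F: float = 1.0
    A_F: float = 1.0
    B_F: float = 1.0
    Gamma_F: float = 1.0
    n_agents: int = 2000
    horizon: int = 180
    initial_infected: int = 10
    degrees: dict = field(
        default_factory=lambda: {"household": 3, "occupation": 8, "random": 2}
    )
    severe_fraction: float = 0.2
    death_prob_hospitalized: float = 0.3
    mean_presymptomatic_days: float = 2.0
    mean_symptomatic_days: float = 5.0
    mean_hospitalized_days: float = 8.0
    gamma_scale_mode: str = "both"  # Gamma_F scales both mu and sigma^2

    def __post_init__(self) -> None:
        if self.n_agents > 10**4:
            raise ConfigurationError(
                "desk-scale simulator limited to 10^4 agents"
            )
        if self.Gamma_F <= 0:
            raise ConfigurationError("Gamma_F must be > 0")

    @property
    def mean_daily_interactions(self) -> float:
        return float(sum(self.degrees.values()))

    def gamma_profile(self) -> tuple[float, float]:
        """Scaled (mean, variance) of the gamma infectivity profile."""
        if self.gamma_scale_mode == "both":
            return (constants.GAMMA_MEAN * self.Gamma_F,
                    constants.GAMMA_VARIANCE * self.Gamma_F)
        if self.gamma_scale_mode == "mean":
            return (constants.GAMMA_MEAN * self.Gamma_F,
                    constants.GAMMA_VARIANCE)
        raise ConfigurationError(
            f"unknown gamma_scale_mode {self.gamma_scale_mode!r}"
        )


def _gamma_window(t: np.ndarray, mean: float, variance: float) -> np.ndarray:
    """Integral of the gamma infectivity PDF over the window [t-1, t]."""
    shape = mean**2 / variance
    scale = variance / mean
    t = np.asarray(t, dtype=float)
    return (stats.gamma.cdf(t, a=shape, scale=scale)
            - stats.gamma.cdf(t - 1.0, a=shape, scale=scale))


def infection_probability(
    t: int,
    s_i: int,
    a_s: int,
    n_net: str,
    params: EpidemicParams,
) -> float:
    """Per-contact transmission probability ``P = 1 - exp(-lambda)``.

    ``t`` is whole days since the infector's infection (t >= 1), ``s_i``
    indexes the canonical disease-stage infectiousness table, ``a_s`` the
    age group of the susceptible agent, and ``n_net`` names the interaction
    network.  The hazard multiplies the overall rate ``R``, the (scaled)
    susceptibility, infectiousness and network scalars, divided by the mean
    daily interactions, times the gamma-profile window integral.
    """
    if t < 1:
        raise InvalidInputError(f"t must be >= 1, got {t}")
    try:
        S_a = constants.AGE_SUSCEPTIBILITY[a_s]
        A_s = constants.STAGE_INFECTIOUSNESS[s_i]
        B_n = constants.NETWORK_SCALARS[n_net]
    except (IndexError, KeyError) as exc:
        raise IndexError(f"invalid category: {exc}") from exc
    mean, variance = params.gamma_profile()
    lam = (
        params.R * (params.S_F * S_a) * (params.A_F * A_s) * (params.B_F * B_n)
        / params.mean_daily_interactions
        * float(_gamma_window(np.array([t]), mean, variance)[0])
    )
    return float(1.0 - np.exp(-lam))


def _regular_network(n: int, d: int, seed: int) -> np.ndarray:
    """(n, d) neighbor table of a random d-regular graph."""
    G = nx.random_regular_graph(d, n, seed=seed)
    nbr = np.empty((n, d), dtype=np.int64)
    for i in range(n):
        nbr[i] = sorted(G.neighbors(i))
    return nbr


def simulate_toy_epidemic(params: EpidemicParams, seed: int) -> np.ndarray:
    """Discrete-time stochastic epidemic on three static contact networks.

    Index cases are seeded as mild infections at day 0.  Each day every
    infectious agent exposes its neighbors on the household, occupation and
    random networks with the hazard of :func:`infection_probability`; disease
    course follows the reduced stage machine (presymptomatic -> symptomatic,
    severe cases -> hospitalized -> dead or recovered, mild -> recovered)
    with seeded integer stage durations.

    Returns a (horizon, 5) integer array of daily counts:
    susceptible, hospitalized, dead, recovered, active.
    """
    p = params
    ss = np.random.SeedSequence(seed)
    net_seeds, rng_seed = ss.spawn(2)
    rng = np.random.default_rng(rng_seed)
    net_children = net_seeds.spawn(len(p.degrees))
    networks = {
        name: _regular_network(p.n_agents, d,
                               int(child.generate_state(1)[0] % (2**31)))
        for (name, d), child in zip(p.degrees.items(), net_children)
    }
    ages = rng.integers(0, len(constants.AGE_SUSCEPTIBILITY), size=p.n_agents)

    stage = np.full(p.n_agents, SUSCEPTIBLE, dtype=np.int64)
    infection_day = np.full(p.n_agents, -1, dtype=np.int64)
    severe = np.zeros(p.n_agents, dtype=bool)
    dies = np.zeros(p.n_agents, dtype=bool)
    stage_until = np.zeros(p.n_agents, dtype=np.int64)
    dur_symp = np.zeros(p.n_agents, dtype=np.int64)
    dur_hosp = np.zeros(p.n_agents, dtype=np.int64)

    def infect(agents: np.ndarray, day: int, index_case: bool = False) -> None:
        stage[agents] = PRESYMPTOMATIC
        infection_day[agents] = day
        if not index_case:
            severe[agents] = rng.random(agents.size) < p.severe_fraction
        dies[agents] = severe[agents] & (
            rng.random(agents.size) < p.death_prob_hospitalized
        )
        stage_until[agents] = day + 1 + rng.poisson(
            max(p.mean_presymptomatic_days - 1, 0), agents.size
        )
        dur_symp[agents] = 1 + rng.poisson(
            max(p.mean_symptomatic_days - 1, 0), agents.size
        )
        dur_hosp[agents] = 1 + rng.poisson(
            max(p.mean_hospitalized_days - 1, 0), agents.size
        )

    seeds0 = rng.choice(p.n_agents, size=p.initial_infected, replace=False)
    infect(seeds0, day=0, index_case=True)

    mean, variance = p.gamma_profile()
    window = np.concatenate(
        [[0.0], _gamma_window(np.arange(1, p.horizon + 2), mean, variance)]
    )
    sus_scaled = p.S_F * np.asarray(constants.AGE_SUSCEPTIBILITY)[ages]
    base = p.R * p.A_F * p.B_F / p.mean_daily_interactions

    counts = np.zeros((p.horizon, 5), dtype=np.int64)
    for day in range(1, p.horizon + 1):
        # -- transmission
        infectious = np.flatnonzero(
            (stage == PRESYMPTOMATIC) | (stage == SYMPTOMATIC)
        )
        if infectious.size:
            A_src = np.where(
                stage[infectious] == PRESYMPTOMATIC,
                constants.STAGE_INFECTIOUSNESS[_PRESYMP_A_INDEX],
                np.where(severe[infectious],
                         constants.STAGE_INFECTIOUSNESS[_SEVERE_A_INDEX],
                         constants.STAGE_INFECTIOUSNESS[_MILD_A_INDEX]),
            )
            w_src = window[np.clip(day - infection_day[infectious], 1, p.horizon + 1)]
            newly: list[np.ndarray] = []
            for name in networks:
                nbr = networks[name]
                d = nbr.shape[1]
                tgt = nbr[infectious].ravel()
                lam = (
                    base * constants.NETWORK_SCALARS[name]
                    * np.repeat(A_src * w_src, d) * sus_scaled[tgt]
                )
                hit = (stage[tgt] == SUSCEPTIBLE) & (
                    rng.random(tgt.size) < 1.0 - np.exp(-lam)
                )
                if np.any(hit):
                    newly.append(tgt[hit])
            if newly:
                infect(np.unique(np.concatenate(newly)), day=day)
        # -- progression (reverse stage order so nobody advances twice a day)
        done = stage_until == day
        move = np.flatnonzero(done & (stage == HOSPITALIZED))
        if move.size:
            stage[move[dies[move]]] = DEAD
            stage[move[~dies[move]]] = RECOVERED
        move = np.flatnonzero(done & (stage == SYMPTOMATIC))
        if move.size:
            sev = move[severe[move]]
            mild = move[~severe[move]]
            stage[mild] = RECOVERED
            stage[sev] = HOSPITALIZED
            stage_until[sev] = day + dur_hosp[sev]
        move = np.flatnonzero(done & (stage == PRESYMPTOMATIC)
                              & (infection_day < day))
        if move.size:
            stage[move] = SYMPTOMATIC
            stage_until[move] = day + dur_symp[move]
        counts[day - 1] = (
            np.sum(stage == SUSCEPTIBLE),
            np.sum(stage == HOSPITALIZED),
            np.sum(stage == DEAD),
            np.sum(stage == RECOVERED),
            np.sum((stage == PRESYMPTOMATIC) | (stage == SYMPTOMATIC)
                   | (stage == HOSPITALIZED)),
        )
    return counts


# ---------------------------------------------------------------------------
# Synthetic multi-level wealth generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WealthGenParams:
    """Planted-effect settings for the synthetic wealth generator.

    ``shares`` are the target first-order variance shares of the named
    inputs on the population-level trajectory; they enter through a single
    additive linear score of degree-1 orthonormal polynomials that
    modulates the trajectory shape, so the ground-truth Sobol' indices are
    ``shares / sum(shares)`` (no interactions are planted).  Community
    offsets and agent-level noise are seeded independently of the
    experimental design.
    """

    n_agents: int = 1250
    n_communities: int = 267
    n_steps: int = 50
    shares: tuple[float, ...] = (0.6, 0.3, 0.1, 0.0, 0.0, 0.0)
    noise_scale: float = 0.01
    community_offset_scale: float = 0.05
    decay_rate: float = 1.5
    decay_gain: float = 0.4
    wave_amplitude: float = 0.3
    wave_frequency: float = 1.0
    frequency_gain: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.shares):
            raise ConfigurationError("planted shares must be >= 0")
        if sum(self.shares) <= 0:
            raise ConfigurationError("at least one planted share must be > 0")
        if self.n_communities > self.n_agents:
            raise ConfigurationError("more communities than agents")

    def ground_truth_shares(self) -> np.ndarray:
        v = np.asarray(self.shares, dtype=float)
        return v / v.sum()


def generate_multilevel_wealth(
    params: WealthGenParams, design
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate agent-level wealth trajectories with known sensitivities.

    The planted inputs act through the single linear score
    ``L_i = sum_j sqrt(share_j) psi_1(z_ij)`` (``psi_1`` the degree-1
    orthonormal Legendre polynomial of the standardized input), which
    modulates both the wealth decay rate and the frequency of an
    oscillatory component:

    ``s_i(t) = exp(-(r0 + ra L_i) t) + cw cos(2 pi (f0 + fa L_i) t)``.

    Both modulations rotate the subspaces of the reshaped trajectory
    matrices (a purely additive planted effect would leave the spans, and
    hence the Grassmannian kernel, unchanged).  An agent's trajectory
    multiplies its community's offset factor and adds seeded Gaussian
    noise; since every trajectory is a deterministic function of the scalar
    ``L_i``, the first-order variance shares of any smooth monotone summary
    of the trajectory are ``shares / sum(shares)`` up to the warp's mild
    nonlinearity.

    Parameters
    ----------
    params : WealthGenParams
    design : object with ``X`` (N, k) and ``marginals`` attributes
        Typically a :class:`trajgsa.pipeline.ExperimentalDesign`.

    Returns
    -------
    micro : (N, n_agents, n_steps) ndarray
    labels : (n_agents,) int ndarray of community memberships
    truth : (k,) ndarray of ground-truth first-order variance shares
    """
    X = np.asarray(design.X, dtype=float)
    marginals = design.marginals
    k = len(params.shares)
    if X.shape[1] != k or len(marginals) != k:
        raise ConfigurationError(
            f"design has {X.shape[1]} inputs; planted effects declare {k}"
        )
    rng = np.random.default_rng(params.seed)
    labels = np.arange(params.n_agents) % params.n_communities
    offsets = params.community_offset_scale * rng.standard_normal(
        params.n_communities
    )

    Z = np.column_stack(
        [m.standardize(X[:, j]) for j, m in enumerate(marginals)]
    )
    weights = np.sqrt(np.asarray(params.shares, dtype=float))
    L = (np.sqrt(3.0) * Z) @ weights  # psi_1(z) = sqrt(3) z, orthonormal

    tn = np.linspace(0.0, 1.0, params.n_steps)
    shape = np.exp(
        -(params.decay_rate + params.decay_gain * L[:, None]) * tn[None, :]
    ) + params.wave_amplitude * np.cos(
        2.0 * np.pi
        * (params.wave_frequency + params.frequency_gain * L[:, None])
        * tn[None, :]
    )
    micro = shape[:, None, :] * (1.0 + offsets[labels])[None, :, None]
    if params.noise_scale > 0:
        micro = micro + params.noise_scale * rng.standard_normal(micro.shape)
    return micro, labels, params.ground_truth_shares()


# ---------------------------------------------------------------------------
# Model registry
# ---------------------------------------------------------------------------

def get_model(name: str, seed: int | None = None, **kwargs):
    """Return ``(callable, marginals)`` for a bundled model.

    The callable maps one design row to a trajectory record (a 2-D
    responses-by-time array).  Stochastic models consume one child seed per
    call from a stream derived from ``seed``, so a fresh factory replays the
    same realizations.
    """
    if name == "lotka_volterra":
        fixed = {"gamma": 1.5, "delta": 0.75}
        fixed.update(kwargs)

        def lv(x):
            params = LVParams(alpha=float(x[0]), beta=float(x[1]), **fixed)
            return solve_lotka_volterra(params)

        return lv, LOTKA_VOLTERRA_MARGINALS

    if name == "epidemic":
        ss = np.random.SeedSequence(0 if seed is None else seed)

        def epi(x):
            params = EpidemicParams(
                R=float(x[0]), S_F=float(x[1]), A_F=float(x[2]),
                B_F=float(x[3]), Gamma_F=float(x[4]), **kwargs,
            )
            child = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            return simulate_toy_epidemic(params, seed=child).T

        return epi, EPIDEMIC_MARGINALS

    raise ConfigurationError(f"unknown model {name!r}")
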