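"""Consumer-resource model of plant-pollinator dynamics.

State: plant densities p_i, animal densities a_j, floral rewards R_i, and
per-capita foraging efforts alpha_ij restricted to the network's incidence
support. Governing rates:

    dp_i/dt     = gamma_i * e_i * sum_j sigma_ij V_ij  -  muP_i p_i
    da_j/dt     = c_j * sum_i V_ij b_j R_i / p_i       -  muA_j a_j
    dR_i/dt     = beta_i p_i - phi_i R_i - sum_j V_ij b_j R_i / p_i
    dalpha_ij/dt = G_j alpha_ij (c_j tau_j b_j R_i
                                 - sum_k alpha_kj c_j tau_j b_j R_k)   [adaptive]

with V_ij = alpha_ij tau_j a_j p_i, sigma_ij = V_ij / sum_k V_kj, and
gamma_i = g_i (1 - sum_{l != i} u_l p_l - w_i p_i) clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .netgen import BipartiteNetwork

__all__ = [
    "DEFAULT_MEANS",
    "ModelParams",
    "SystemState",
    "load_means",
    "save_means",
    "sample_params",
    "initial_state",
    "visitation_rates",
    "visit_quality",
    "recruitment_fraction",
    "derivatives",
]

#: Mean parameter values. Plant parameters are drawn uniformly within +-10%
#: of these means; animal parameters are used exactly.
DEFAULT_MEANS = {
    "tau": 1.0,    # animal visitation efficiency
    "e": 0.8,      # seeds per pollination event
    "mu_p": 0.001, # plant mortality
    "c": 0.2,      # rewards -> births conversion
    "mu_a": 0.001, # animal mortality
    "b": 0.4,      # rewards extraction efficiency per visit
    "g": 0.4,      # max fraction of seeds recruiting
    "u": 0.06,     # inter-specific plant competition
    "w": 1.2,      # intra-specific plant competition
    "beta": 0.2,   # rewards production rate
    "phi": 0.04,   # rewards self-limitation
    "G": 2.0,      # foraging adaptation rate
}

_PLANT_KEYS = ("e", "mu_p", "g", "u", "w", "beta", "phi")
_ANIMAL_KEYS = ("tau", "c", "mu_a", "b", "G")


def load_means(path) -> dict:
    """Read a key = value parameter-means file (one mean per line, '#' comments)."""
    means = dict(DEFAULT_MEANS)
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key = key.strip()
        if key not in DEFAULT_MEANS:
            raise KeyError(f"unknown parameter mean: {key!r}")
        means[key] = float(val)
    return means


def save_means(means: dict, path) -> None:
    Path(path).write_text("".join(f"{k} = {v}\n" for k, v in means.items()))


@dataclass(frozen=True)
class ModelParams:
    """Per-species model parameters (arrays indexed like the incidence matrix)."""

    # per-plant
    e: np.ndarray
    mu_p: np.ndarray
    g: np.ndarray
    u: np.ndarray
    w: np.ndarray
    beta: np.ndarray
    phi: np.ndarray
    # per-animal
    tau: np.ndarray
    c: np.ndarray
    mu_a: np.ndarray
    b: np.ndarray
    G: np.ndarray

    def __post_init__(self):
        for name in _PLANT_KEYS + _ANIMAL_KEYS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if (arr < 0).any():
                raise ValueError(f"parameter {name} must be non-negative")
            object.__setattr__(self, name, arr)
        for name in ("e", "g", "b", "c"):
            if (getattr(self, name) > 1).any():
                raise ValueError(f"parameter {name} must lie in [0, 1]")
        if (self.phi <= 0).any():
            raise ValueError("phi must be strictly positive")

    @property
    def n_plants(self) -> int:
        return self.e.size

    @property
    def n_animals(self) -> int:
        return self.tau.size


@dataclass
class SystemState:
    """Densities, rewards, and foraging efforts at one time point."""

    p: np.ndarray
    a: np.ndarray
    R: np.ndarray
    alpha: np.ndarray  # (P, A), zero off the incidence support

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)

    def validate(self, net: BipartiteNetwork, atol: float = 1e-8) -> None:
        if (self.p < 0).any() or (self.a < 0).any() or (self.R < 0).any():
            raise ValueError("densities and rewards must be non-negative")
        if (self.alpha[net.incidence == 0] != 0).any():
            raise ValueError("foraging effort present off the incidence support")
        col = self.alpha.sum(axis=0)
        live = col > 0  # animals with an empty (extinct) diet carry all-zero efforts
        if not np.allclose(col[live], 1.0, atol=atol):
            raise ValueError("foraging efforts of an animal must sum to 1")

    def copy(self) -> "SystemState":
        return SystemState(self.p.copy(), self.a.copy(), self.R.copy(), self.alpha.copy())


def sample_params(
    net: BipartiteNetwork,
    rng: np.random.Generator | None = None,
    means: dict | None = None,
) -> ModelParams:
    """Draw per-species parameters.

    Plant parameters ~ Uniform[0.9 * mean, 1.1 * mean] independently per
    species and parameter; animal parameters equal their means exactly.
    """
    rng = np.random.default_rng(rng)
    means = dict(DEFAULT_MEANS if means is None else means)
    P, A = net.n_plants, net.n_animals
    kw = {}
    for key in _PLANT_KEYS:
        m = means[key]
        kw[key] = rng.uniform(0.9 * m, 1.1 * m, size=P)
    for key in _ANIMAL_KEYS:
        kw[key] = np.full(A, float(means[key]))
    return ModelParams(**kw)


def initial_state(net: BipartiteNetwork) -> SystemState:
    """All densities and rewards at 0.5; efforts uniform over each diet."""
    P, A = net.n_plants, net.n_animals
    M = net.incidence.astype(float)
    alpha = M / M.sum(axis=0, keepdims=True)
    return SystemState(np.full(P, 0.5), np.full(A, 0.5), np.full(P, 0.5), alpha)


def visitation_rates(state: SystemState, params: ModelParams, net: BipartiteNetwork) -> np.ndarray:
    """V_ij = alpha_ij * tau_j * a_j * p_i (zero off-support)."""
    return state.alpha * (params.tau * state.a)[None, :] * state.p[:, None]


def visit_quality(state: SystemState, params: ModelParams, net: BipartiteNetwork) -> np.ndarray:
    """sigma_ij = V_ij / sum_k V_kj; all-zero column where an animal has no visits."""
    V = visitation_rates(state, params, net)
    tot = V.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma = np.where(tot > 0, V / tot, 0.0)
    return sigma


def recruitment_fraction(state: SystemState, params: ModelParams) -> np.ndarray:
    """gamma_i = g_i (1 - sum_{l != i} u_l p_l - w_i p_i), clamped at 0."""
    up = params.u * state.p
    crowding = up.sum() - up + params.w * state.p
    return np.maximum(params.g * (1.0 - crowding), 0.0)


def derivatives(
    state: SystemState,
    params: ModelParams,
    net: BipartiteNetwork,
    adaptive: bool,
    af_percapita_rewards: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Time derivatives (dp, da, dR, dalpha) of the full system.

    ``adaptive=False`` freezes efforts (dalpha = 0). R_i / p_i is defined as
    0 where p_i = 0. ``af_percapita_rewards`` switches the effort dynamics
    from total rewards R_i to per-plant-individual rewards R_i / p_i.
    """
    p, a, R, alpha = state.p, state.a, state.R, state.alpha
    if (
        np.isnan(p).any() or np.isnan(a).any() or np.isnan(R).any() or np.isnan(alpha).any()
        or (p < 0).any() or (a < 0).any() or (R < 0).any()
    ):
        raise ValueError("invalid state: NaN or negative densities")
    V = visitation_rates(state, params, net)
    sigma = visit_quality(state, params, net)
    gamma = recruitment_fraction(state, params)

    deposition_total = (sigma * V).sum(axis=1)  # per plant species
    dp = gamma * params.e * deposition_total - params.mu_p * p

    with np.errstate(divide="ignore", invalid="ignore"):
        rewards_per_capita = np.where(p > 0, R / p, 0.0)
    consumption = V * params.b[None, :] * rewards_per_capita[:, None]
    da = params.c * consumption.sum(axis=0) - params.mu_a * a
    dR = params.beta * p - params.phi * R - consumption.sum(axis=1)

    if adaptive:
        reward_signal = rewards_per_capita if af_percapita_rewards else R
        intake = (params.c * params.tau * params.b)[None, :] * reward_signal[:, None]
        mean_intake = (alpha * intake).sum(axis=0, keepdims=True)
        dalpha = params.G[None, :] * alpha * (intake - mean_intake)
        dalpha = np.where(net.incidence == 1, dalpha, 0.0)
    else:
        dalpha = np.zeros_like(alpha)
    return dp, da, dR, dalpha
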