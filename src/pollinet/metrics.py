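"""Pollination-service metrics: conspecific pollen deposition rates and
structure-function summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import ModelParams, SystemState, visit_quality, visitation_rates
from .netgen import (
    BipartiteNetwork,
    connectance,
    count_specialist_pollinators,
    degree_summary,
    nodf,
)

__all__ = [
    "per_plant_deposition",
    "per_pollinator_deposition",
    "deposition_vs_degree",
    "effort_specialization_profile",
    "metrics_table",
]


def _deposition_matrix(state: SystemState, params: ModelParams, net: BipartiteNetwork) -> np.ndarray:
    """sigma_ij * V_ij / p_i per (plant, animal) pair; 0 where p_i = 0."""
    V = visitation_rates(state, params, net)
    sigma = visit_quality(state, params, net)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_p = np.where(state.p > 0, 1.0 / state.p, 0.0)
    return sigma * V * inv_p[:, None]


def per_plant_deposition(state: SystemState, params: ModelParams, net: BipartiteNetwork) -> np.ndarray:
    """Total per-plant pollen deposition rate, sum_j sigma_ij V_ij / p_i."""
    return _deposition_matrix(state, params, net).sum(axis=1)


def per_pollinator_deposition(
    state: SystemState, params: ModelParams, net: BipartiteNetwork
) -> np.ndarray:
    """Total per-plant deposition contributed by each animal species,
    sum_i sigma_ij V_ij / p_i."""
    return _deposition_matrix(state, params, net).sum(axis=0)


def deposition_vs_degree(
    deposition: np.ndarray, degrees: np.ndarray, alive: np.ndarray | None = None
) -> float:
    """Spearman rank correlation between degree and deposition (ties
    mid-ranked). Extinct species are excluded via ``alive``. Returns NaN when
    all degrees are equal (correlation undefined)."""
    deposition = np.asarray(deposition, dtype=float)
    degrees = np.asarray(degrees, dtype=float)
    if alive is not None:
        deposition = deposition[alive]
        degrees = degrees[alive]
    if deposition.size < 3:
        raise ValueError("need at least 3 species with positive density")
    if np.unique(degrees).size == 1:
        return float("nan")
    rho, _ = stats.spearmanr(degrees, deposition)
    return float(rho)


def effort_specialization_profile(state: SystemState, net: BipartiteNetwork) -> pd.DataFrame:
    """Tidy table of (plant, animal, alpha, plant_degree, animal_degree) rows
    over the incidence support."""
    rows_i, cols_j = np.nonzero(net.incidence)
    pdeg = net.plant_degrees()
    adeg = net.animal_degrees()
    return pd.DataFrame(
        {
            "plant": [net.plant_ids[i] for i in rows_i],
            "animal": [net.animal_ids[j] for j in cols_j],
            "alpha": state.alpha[rows_i, cols_j],
            "plant_degree": pdeg[rows_i],
            "animal_degree": adeg[cols_j],
        }
    )


def metrics_table(state: SystemState, params: ModelParams, net: BipartiteNetwork) -> dict:
    """All per-species and per-network metrics for one simulated state.

    Returns a dict with 'plants' and 'animals' DataFrames plus a 'network'
    dict of structural descriptors.
    """
    plant_dep = per_plant_deposition(state, params, net)
    animal_dep = per_pollinator_deposition(state, params, net)
    summ = degree_summary(net)
    plants = pd.DataFrame(
        {
            "species": list(net.plant_ids),
            "degree": summ["plants"]["degrees"],
            "density": state.p,
            "rewards": state.R,
            "deposition": plant_dep,
        }
    )
    animals = pd.DataFrame(
        {
            "species": list(net.animal_ids),
            "degree": summ["animals"]["degrees"],
            "density": state.a,
            "deposition": animal_dep,
        }
    )
    network = {
        "n_plants": net.n_plants,
        "n_animals": net.n_animals,
        "richness": net.richness,
        "connectance": connectance(net),
        "nodf": nodf(net),
        "specialist_pollinators": count_specialist_pollinators(net),
        "plant_degree_summary": {k: v for k, v in summ["plants"].items() if k != "degrees"},
        "animal_degree_summary": {k: v for k, v in summ["animals"].items() if k != "degrees"},
    }
    return {"plants": plants, "animals": animals, "network": network}
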