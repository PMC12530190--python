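"""Orchestration of the structure x foraging study.

Each treatment cell (richness x connectance x nestedness) is run for an
ensemble of networks; every network is simulated twice — fixed and adaptive
foragers — from identical initial conditions and parameter draws (paired
design).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .model_core import initial_state, sample_params
from .netgen import GenTarget, GenerationError, generate_network
from .simulate import SimConfig, SimulationError, run_simulation

__all__ = [
    "TreatmentConfig",
    "RunResult",
    "all_treatments",
    "run_experiment",
    "run_study",
    "summarize_ensemble",
    "compare_treatments",
]

RICHNESS_LEVELS = (90, 200)
CONNECTANCE_LEVELS = (0.15, 0.30)
NESTEDNESS_LEVELS = (False, True)


@dataclass(frozen=True)
class TreatmentConfig:
    """One structure cell of the study plus run controls."""

    S_target: int
    C_target: float
    nested: bool
    n_networks: int = 10
    master_seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    n_null: int = 200
    retry_cap: int = 5

    def __post_init__(self):
        if self.n_networks < 1:
            raise ValueError("n_networks must be >= 1")

    @property
    def label(self) -> str:
        nest = "nested" if self.nested else "non-nested"
        return f"S{self.S_target}_C{self.C_target:g}_{nest}"


@dataclass
class RunResult:
    """Raw per-species rows plus per-network rows for one or more treatments."""

    species: pd.DataFrame   # one row per species per network per AF condition
    networks: pd.DataFrame  # one row per network per AF condition
    failures: list = field(default_factory=list)


def all_treatments(
    n_networks: int = 10, master_seed: int = 0, sim: SimConfig | None = None
) -> list[TreatmentConfig]:
    """The 8 structure cells: 2 richness x 2 connectance x 2 nestedness."""
    sim = sim or SimConfig()
    cells = itertools.product(RICHNESS_LEVELS, CONNECTANCE_LEVELS, NESTEDNESS_LEVELS)
    return [
        TreatmentConfig(S, C, nested, n_networks=n_networks, master_seed=master_seed, sim=sim)
        for S, C, nested in cells
    ]


def _network_rows(config, net_idx, adaptive, net, state, params, sim_result):
    tab = metrics_mod.metrics_table(state, params, net)
    alive_p = state.p > 0
    alive_a = state.a > 0
    try:
        rho_plants = metrics_mod.deposition_vs_degree(
            tab["plants"]["deposition"].to_numpy(),
            tab["plants"]["degree"].to_numpy(),
            alive=alive_p,
        )
    except ValueError:
        rho_plants = float("nan")
    netinfo = tab["network"]
    network_row = {
        "treatment": config.label,
        "S_target": config.S_target,
        "C_target": config.C_target,
        "nested": config.nested,
        "network": net_idx,
        "adaptive": adaptive,
        "richness": netinfo["richness"],
        "n_plants": netinfo["n_plants"],
        "n_animals": netinfo["n_animals"],
        "connectance": netinfo["connectance"],
        "nodf": netinfo["nodf"],
        "specialist_pollinators": netinfo["specialist_pollinators"],
        "median_plant_deposition": float(
            np.median(tab["plants"].loc[alive_p, "deposition"]) if alive_p.any() else np.nan
        ),
        "spearman_plant_degree_deposition": rho_plants,
        "reached_steady": sim_result.reached_steady,
        "n_extinct_plants": len(sim_result.extinct_plants),
        "n_extinct_animals": len(sim_result.extinct_animals),
    }
    species_rows = []
    for side, df in (("plant", tab["plants"]), ("animal", tab["animals"])):
        for _, row in df.iterrows():
            species_rows.append(
                {
                    "treatment": config.label,
                    "network": net_idx,
                    "adaptive": adaptive,
                    "side": side,
                    "species": row["species"],
                    "degree": int(row["degree"]),
                    "density": float(row["density"]),
                    "deposition": float(row["deposition"]),
                }
            )
    return network_row, species_rows


def run_experiment(config: TreatmentConfig) -> RunResult:
    """Run one treatment: generate each network, parameterize it, simulate
    with fixed and adaptive foragers from identical initial conditions, and
    extract metrics. Substream seeds derive deterministically from the
    master seed; failed networks are resampled up to the retry cap."""
    seed_seq = np.random.SeedSequence(
        (config.master_seed, config.S_target, int(config.C_target * 100), int(config.nested))
    )
    net_seeds = seed_seq.spawn(config.n_networks)
    network_rows: list[dict] = []
    species_rows: list[dict] = []
    failures: list[str] = []
    for idx, sub in enumerate(net_seeds):
        attempt_streams = sub.spawn(config.retry_cap)
        done = False
        for attempt, stream in enumerate(attempt_streams):
            rng = np.random.default_rng(stream)
            try:
                target = GenTarget(
                    config.S_target, config.C_target, config.nested, n_null=config.n_null
                )
                net = generate_network(target, rng=rng)
                params = sample_params(net, rng=rng)
                state0 = initial_state(net)
                for adaptive in (False, True):
                    sim = replace(config.sim, adaptive=adaptive)
                    result = run_simulation(net, params, sim, state0=state0.copy())
                    nrow, srows = _network_rows(
                        config, idx, adaptive, net, result.final_state, params, result
                    )
                    network_rows.append(nrow)
                    species_rows.extend(srows)
                done = True
                break
            except (GenerationError, SimulationError) as exc:
                failures.append(f"{config.label} net {idx} attempt {attempt}: {exc}")
        if not done:
            raise RuntimeError(
                f"treatment {config.label}: network {idx} failed after "
                f"{config.retry_cap} attempts; log: {failures[-config.retry_cap:]}"
            )
    return RunResult(pd.DataFrame(species_rows), pd.DataFrame(network_rows), failures)


def run_study(treatments: list[TreatmentConfig]) -> RunResult:
    """Run several treatments and concatenate their results."""
    results = [run_experiment(t) for t in treatments]
    return RunResult(
        species=pd.concat([r.species for r in results], ignore_index=True),
        networks=pd.concat([r.networks for r in results], ignore_index=True),
        failures=sum((r.failures for r in results), []),
    )


def summarize_ensemble(result: RunResult, metric: str) -> pd.DataFrame:
    """Boxplot statistics (median, quartiles, 1.5*IQR whiskers, outliers) of a
    per-network metric, per treatment x AF condition."""
    if metric not in result.networks.columns:
        available = sorted(
            c for c in result.networks.columns if result.networks[c].dtype.kind in "fi"
        )
        raise KeyError(f"unknown metric {metric!r}; available: {available}")
    rows = []
    for (treatment, adaptive), grp in result.networks.groupby(["treatment", "adaptive"]):
        x = grp[metric].dropna().to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        inlier = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
        outliers = x[(x < q1 - 1.5 * iqr) | (x > q3 + 1.5 * iqr)]
        rows.append(
            {
                "treatment": treatment,
                "adaptive": adaptive,
                "metric": metric,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": inlier.min() if inlier.size else np.nan,
                "whisker_high": inlier.max() if inlier.size else np.nan,
                "n_outliers": int(outliers.size),
                "outliers": list(outliers),
                "n": int(x.size),
            }
        )
    return pd.DataFrame(rows)


def compare_treatments(result: RunResult) -> pd.DataFrame:
    """Treatments ranked by median per-plant deposition, with the AF
    contrast per treatment."""
    summ = summarize_ensemble(result, "median_plant_deposition")
    wide = summ.pivot(index="treatment", columns="adaptive", values="median")
    wide.columns = ["median_fixed" if not c else "median_adaptive" for c in wide.columns]
    pooled = (
        result.networks.groupby(["treatment", "adaptive"])["median_plant_deposition"]
        .median()
        .groupby("treatment")
        .max()
    )
    out = wide.assign(best_median=pooled).sort_values("best_median", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index()
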