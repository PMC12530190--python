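"""Reader and structural analysis for empirical incidence matrices
(web-of-life CSV layout), plus the connectance-richness regression used to
classify generated networks as empirically connected."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .netgen import BipartiteNetwork, connectance, count_specialist_pollinators

__all__ = [
    "EmpiricalNetworkRecord",
    "read_incidence_csv",
    "write_incidence_csv",
    "record_from_network",
    "SCRegression",
    "sc_prediction_interval",
]


@dataclass(frozen=True)
class EmpiricalNetworkRecord:
    network_id: str
    network: BipartiteNetwork
    S: int
    C: float
    specialist_pollinators: int


def read_incidence_csv(path) -> BipartiteNetwork:
    """Read a plant x animal incidence CSV (first row = animal labels, first
    column = plant labels). Any cell value > 0 is binarized to 1."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")[1:]
    if len(set(header)) != len(header):
        dupes = sorted({h for h in header if header.count(h) > 1})
        raise ValueError(f"{path}: duplicate animal labels {dupes}")
    df = pd.read_csv(path, index_col=0)
    if df.empty or df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty incidence matrix")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"{path}: duplicate plant labels {dupes}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed numeric cell ({exc})") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing or non-numeric cells")
    M = (values > 0).astype(np.int8)
    empty_rows = [str(df.index[i]) for i in np.flatnonzero(M.sum(axis=1) == 0)]
    if empty_rows:
        raise ValueError(f"{path}: plant species with no interactions: {empty_rows}")
    empty_cols = [str(df.columns[j]) for j in np.flatnonzero(M.sum(axis=0) == 0)]
    if empty_cols:
        raise ValueError(f"{path}: animal species with no interactions: {empty_cols}")
    return BipartiteNetwork(tuple(map(str, df.index)), tuple(map(str, df.columns)), M)


def write_incidence_csv(net: BipartiteNetwork, path) -> None:
    df = pd.DataFrame(net.incidence, index=list(net.plant_ids), columns=list(net.animal_ids))
    df.to_csv(path)


def record_from_network(network_id: str, net: BipartiteNetwork) -> EmpiricalNetworkRecord:
    return EmpiricalNetworkRecord(
        network_id=network_id,
        network=net,
        S=net.richness,
        C=connectance(net),
        specialist_pollinators=count_specialist_pollinators(net),
    )


@dataclass(frozen=True)
class SCRegression:
    """OLS fit of log10(C) on log10(S) with a 95% prediction interval."""

    intercept: float
    slope: float
    _fit: object

    def predict_interval(self, S, alpha: float = 0.05):
        """(C_hat, C_lo, C_hi) on the original connectance scale."""
        S = np.atleast_1d(np.asarray(S, dtype=float))
        if (S <= 0).any():
            raise ValueError("S must be positive")
        X = sm.add_constant(np.log10(S), has_constant="add")
        pred = self._fit.get_prediction(X)
        frame = pred.summary_frame(alpha=alpha)
        return (
            10 ** frame["mean"].to_numpy(),
            10 ** frame["obs_ci_lower"].to_numpy(),
            10 ** frame["obs_ci_upper"].to_numpy(),
        )

    def is_empirically_connected(self, S: float, C: float, alpha: float = 0.05) -> bool:
        """True iff (S, C) falls inside the prediction interval. Nestedness is
        checked separately by the caller."""
        if S <= 0 or C <= 0:
            raise ValueError("S and C must be positive")
        _, lo, hi = self.predict_interval([S], alpha=alpha)
        return bool(lo[0] <= C <= hi[0])


def sc_prediction_interval(
    records: list[EmpiricalNetworkRecord],
    size_band: tuple[int, int] = (15, 500),
) -> SCRegression:
    """Fit the connectance-richness relation on log-log scale over records
    inside the size band."""
    kept = [r for r in records if size_band[0] <= r.S <= size_band[1]]
    if len(kept) < 10:
        raise ValueError(f"need at least 10 records inside the size band, got {len(kept)}")
    S = np.array([r.S for r in kept], dtype=float)
    C = np.array([r.C for r in kept], dtype=float)
    if (S <= 0).any() or (C <= 0).any():
        raise ValueError("S and C must be positive")
    X = sm.add_constant(np.log10(S))
    fit = sm.OLS(np.log10(C), X).fit()
    return SCRegression(intercept=float(fit.params[0]), slope=float(fit.params[1]), _fit=fit)
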