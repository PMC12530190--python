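"""Generation and structural analysis of bipartite plant-pollinator networks.

Networks are binary incidence matrices (rows = plants, columns = animals).
The generator targets a total species richness, a connectance band, and a
nestedness label (nested / non-nested, operationalised as a NODF z-score
against a connectance-preserving null), using accept/reject sampling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BipartiteNetwork",
    "GenTarget",
    "GenerationError",
    "sample_richness_split",
    "generate_network",
    "connectance",
    "nodf",
    "nestedness_zscore",
    "degree_summary",
    "count_specialist_pollinators",
]


class GenerationError(RuntimeError):
    """Raised when accept/reject sampling exhausts its attempt budget."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BipartiteNetwork:
    """Binary plant x animal incidence structure.

    ``incidence[i, j] == 1`` iff animal ``j`` visits plant ``i``. Every row
    and column must contain at least one interaction.
    """

    plant_ids: tuple
    animal_ids: tuple
    incidence: np.ndarray

    def __post_init__(self):
        M = np.asarray(self.incidence)
        if M.ndim != 2:
            raise ValueError("incidence must be a 2-D matrix")
        if not np.isin(M, (0, 1)).all():
            raise ValueError("incidence must be binary")
        P, A = M.shape
        if len(self.plant_ids) != P or len(self.animal_ids) != A:
            raise ValueError("label lengths do not match incidence shape")
        if P < 2 or A < 2:
            raise ValueError("need at least 2 plants and 2 animals")
        if (M.sum(axis=1) == 0).any():
            raise ValueError("unconnected plant species present")
        if (M.sum(axis=0) == 0).any():
            raise ValueError("unconnected animal species present")
        object.__setattr__(self, "incidence", M.astype(np.int8))
        object.__setattr__(self, "plant_ids", tuple(self.plant_ids))
        object.__setattr__(self, "animal_ids", tuple(self.animal_ids))

    @property
    def n_plants(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_animals(self) -> int:
        return self.incidence.shape[1]

    @property
    def richness(self) -> int:
        return self.n_plants + self.n_animals

    @property
    def n_links(self) -> int:
        return int(self.incidence.sum())

    def plant_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=1)

    def animal_degrees(self) -> np.ndarray:
        return self.incidence.sum(axis=0)

    @classmethod
    def from_matrix(cls, M, plant_ids=None, animal_ids=None) -> "BipartiteNetwork":
        M = np.asarray(M)
        P, A = M.shape
        if plant_ids is None:
            plant_ids = tuple(f"P{i}" for i in range(P))
        if animal_ids is None:
            animal_ids = tuple(f"A{j}" for j in range(A))
        return cls(tuple(plant_ids), tuple(animal_ids), M)


@dataclass(frozen=True)
class GenTarget:
    """Target richness / connectance / nestedness cell for the generator."""

    S_target: int
    C_target: float
    nested: bool
    rng_seed: int = 0
    max_attempts: int = 1000
    n_null: int = 200
    skew: float = field(default=1.15)  # plant-rank Zipf exponent for nested fill

    def __post_init__(self):
        if self.S_target < 10:
            raise ValueError("S_target must be at least 10")
        if not 0.0 < self.C_target < 1.0:
            raise ValueError("C_target must lie in (0, 1)")


# --------------------------------------------------------------------------
# tolerance bands (accept/reject constraints of the generator)
# --------------------------------------------------------------------------

#: Realized-richness bands for the two published richness labels.
RICHNESS_BANDS = {90: (87, 91), 200: (198, 201)}

#: Realized-connectance bands for the two published connectance labels.
CONNECTANCE_BANDS = {0.15: (0.14, 0.16), 0.30: (0.25, 0.35)}

#: Plant-count band and ensemble-median target for S = 90, extrapolated
#: proportionally to other richness levels.
_PLANT_BAND_90 = (20, 36)
_PLANT_REF_S = 89  # midpoint of the S = 90 realized band

#: Mode of the triangular animal:plant ratio distribution, calibrated so the
#: S = 90 ensemble plant-count median is 23 (see tests/test_netgen.py).
RATIO_TRIANGULAR = (1.5, 3.38, 3.5)


def richness_band(S_target: int) -> tuple[int, int]:
    if S_target in RICHNESS_BANDS:
        return RICHNESS_BANDS[S_target]
    return (S_target - 3, S_target + 1)


def connectance_band(C_target: float) -> tuple[float, float]:
    for label, band in CONNECTANCE_BANDS.items():
        if math.isclose(C_target, label, rel_tol=1e-9):
            return band
    return (C_target * 0.93, C_target * 1.07)


# --------------------------------------------------------------------------
# richness split
# --------------------------------------------------------------------------


def sample_richness_split(S_target: int, rng: np.random.Generator) -> tuple[int, int]:
    """Sample plant and animal counts (P, A) for a target total richness.

    Realized richness P + A is drawn uniformly inside the label's band; the
    animal:plant ratio follows a triangular law calibrated so that S = 90
    ensembles have plant counts in [20, 36] with median 23.

    Raises
    ------
    ValueError
        If ``S_target`` is too small to allow P >= 2 and A >= 2.
    """
    if S_target < 10:
        raise ValueError(f"S_target={S_target} too small: need P >= 2 and A >= 2")
    lo, hi = richness_band(S_target)
    S_real = int(rng.integers(lo, hi + 1))
    p_lo = max(2, round(_PLANT_BAND_90[0] * S_real / _PLANT_REF_S))
    p_hi = min(S_real - 2, round(_PLANT_BAND_90[1] * S_real / _PLANT_REF_S))
    a, c, b = RATIO_TRIANGULAR
    ratio = rng.triangular(a, c, b)
    P = int(np.clip(round(S_real / (1.0 + ratio)), p_lo, p_hi))
    A = S_real - P
    return P, A


# --------------------------------------------------------------------------
# degree-sequence sampling
# --------------------------------------------------------------------------

#: Specialist-fraction calibration: fraction of degree-1 animals in nested
#: networks decays exponentially with the mean animal degree. Anchored at the
#: empirically connected cell (mean degree ~3.45 -> ~19.5% specialists).
NESTED_SPECIALIST_ANCHOR = (3.45, 0.2075)
NESTED_SPECIALIST_DECAY = 0.40


def _nested_specialist_fraction(mean_degree: float) -> float:
    m0, s0 = NESTED_SPECIALIST_ANCHOR
    return float(np.clip(s0 * math.exp(-NESTED_SPECIALIST_DECAY * (mean_degree - m0)), 0.0, 0.9))


def _sample_degrees_nested(A: int, P: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """Long-tailed animal degree sequence: a degree-1 atom plus a shifted
    geometric tail, truncated at P, with mean L / A."""
    m = L / A
    s = _nested_specialist_fraction(m)
    # mean of the k >= 2 branch needed to hit the overall mean
    tail_mean = (m - s) / (1.0 - s)
    tail_mean = max(tail_mean, 2.0 + 1e-9)
    ratio = (tail_mean - 2.0) / (tail_mean - 1.0)  # Geom0 mean r/(1-r) = tail_mean - 2
    k = np.where(
        rng.random(A) < s,
        1,
        2 + rng.geometric(1.0 - ratio, size=A) - 1,
    )
    return np.minimum(k, P).astype(np.int64)


def _sample_degrees_random(A: int, P: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """Binomial animal degree sequence conditioned on k >= 1 (Erdos-Renyi-like)."""
    C = L / (P * A)
    k = rng.binomial(P, C, size=A)
    zero = k == 0
    while zero.any():
        k[zero] = rng.binomial(P, C, size=int(zero.sum()))
        k = np.maximum(k, 0)
        zero = k == 0
    return np.minimum(k, P).astype(np.int64)


def _adjust_degree_sum(k: np.ndarray, L: int, P: int, rng: np.random.Generator) -> np.ndarray:
    """Nudge the degree sequence so it sums to L without touching degree-1
    animals (their count carries the specialist statistics)."""
    k = k.copy()
    guard = 0
    while k.sum() != L:
        guard += 1
        if guard > 100000:
            raise GenerationError("could not adjust degree sequence to target link count")
        if k.sum() > L:
            cand = np.flatnonzero(k >= 3)
            if cand.size == 0:
                cand = np.flatnonzero(k >= 2)
            k[rng.choice(cand)] -= 1
        else:
            cand = np.flatnonzero((k >= 2) & (k < P))
            if cand.size == 0:
                cand = np.flatnonzero(k < P)
            k[rng.choice(cand)] += 1
    return k


def _fill_incidence(
    k: np.ndarray, P: int, nested: bool, skew: float, rng: np.random.Generator
) -> np.ndarray:
    """Assign each animal's links to plants.

    nested=True: plants are sampled without replacement with Zipf-decaying
    rank weights, concentrating links on top-ranked plants; nested=False:
    uniform sampling.
    """
    A = k.size
    M = np.zeros((P, A), dtype=np.int8)
    if nested:
        w = (np.arange(1, P + 1, dtype=float)) ** (-skew)
    else:
        w = np.ones(P)
    w = w / w.sum()
    for j in range(A):
        rows = rng.choice(P, size=int(k[j]), replace=False, p=w)
        M[rows, j] = 1
    return M


def _repair_empty_plants(M: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Move links from the busiest plants onto unconnected ones.

    Donor cells are chosen so the donating animal keeps degree >= 2 and the
    donating plant keeps degree >= 1.
    """
    M = M.copy()
    empty = np.flatnonzero(M.sum(axis=1) == 0)
    for i in empty:
        col_deg = M.sum(axis=0)
        row_deg = M.sum(axis=1)
        donors = (M == 1) & (col_deg[None, :] >= 2) & (row_deg[:, None] >= 2)
        rows, cols = np.nonzero(donors)
        if rows.size == 0:
            raise GenerationError("cannot repair unconnected plant: no donor link")
        # prefer donating from the highest-degree plant
        best = rows == row_deg.max()
        if best.any():
            rows, cols = rows[best], cols[best]
        pick = rng.integers(rows.size)
        M[rows[pick], cols[pick]] = 0
        M[i, cols[pick]] = 1
    return M


# --------------------------------------------------------------------------
# structural descriptors
# --------------------------------------------------------------------------


def connectance(net: BipartiteNetwork) -> float:
    """Fraction of possible plant x animal interactions that are realized."""
    return net.n_links / (net.n_plants * net.n_animals)


def _nodf_axis(M: np.ndarray) -> tuple[float, int]:
    """Summed paired-overlap contributions over all row pairs of M."""
    deg = M.sum(axis=1).astype(float)
    n = M.shape[0]
    if n < 2:
        return 0.0, 0
    overlap = (M @ M.T).astype(float)
    di = deg[:, None]
    dj = deg[None, :]
    lesser = np.minimum(di, dj)
    with np.errstate(divide="ignore", invalid="ignore"):
        paired = np.where((di != dj) & (lesser > 0), 100.0 * overlap / lesser, 0.0)
    iu = np.triu_indices(n, k=1)
    return float(paired[iu].sum()), len(iu[0])


def nodf(net: BipartiteNetwork) -> float:
    """NODF nestedness score in [0, 100].

    Paired overlap with the decreasing-fill rule (pairs of equal marginal
    totals contribute zero), averaged over all row pairs and column pairs.
    """
    M = net.incidence.astype(float)
    rs, rn = _nodf_axis(M)
    cs, cn = _nodf_axis(M.T)
    if rn + cn == 0:
        return 0.0
    return (rs + cs) / (rn + cn)


def _null_matrix(P: int, A: int, L: int, rng: np.random.Generator) -> np.ndarray:
    """Connectance-preserving null draw: L cells uniform at random, repaired
    so every species keeps at least one link."""
    for _ in range(100):
        cells = rng.choice(P * A, size=L, replace=False)
        M = np.zeros(P * A, dtype=np.int8)
        M[cells] = 1
        M = M.reshape(P, A)
        # repair empty rows/cols by moving links from the fullest lines
        ok = True
        for axis in (1, 0):
            deg = M.sum(axis=axis)
            for idx in np.flatnonzero(deg == 0):
                other_deg = M.sum(axis=1 - axis)
                if axis == 1:  # empty plant row
                    donors = (M == 1) & (M.sum(axis=0)[None, :] >= 2) & (M.sum(axis=1)[:, None] >= 2)
                else:  # empty animal column
                    donors = (M == 1) & (M.sum(axis=1)[:, None] >= 2) & (M.sum(axis=0)[None, :] >= 2)
                r, c = np.nonzero(donors)
                if r.size == 0:
                    ok = False
                    break
                pick = rng.integers(r.size)
                if axis == 1:
                    M[r[pick], c[pick]] = 0
                    M[idx, c[pick]] = 1
                else:
                    M[r[pick], c[pick]] = 0
                    M[r[pick], idx] = 1
            if not ok:
                break
        if ok and (M.sum(axis=0) > 0).all() and (M.sum(axis=1) > 0).all():
            return M
    raise GenerationError("null-model repair failed")


def nestedness_zscore(
    net: BipartiteNetwork, n_null: int = 200, rng: np.random.Generator | None = None
) -> float:
    """NODF z-score of ``net`` against a connectance-preserving null ensemble.

    Null draws share the network's dimensions and link count, with all
    species connected. Returns signed infinity (with a warning) if the null
    standard deviation is zero.
    """
    if n_null < 100:
        raise ValueError("n_null must be at least 100")
    rng = np.random.default_rng(rng)
    P, A, L = net.n_plants, net.n_animals, net.n_links
    obs = nodf(net)
    scores = np.empty(n_null)
    for t in range(n_null):
        scores[t] = nodf(BipartiteNetwork.from_matrix(_null_matrix(P, A, L, rng)))
    sd = scores.std(ddof=1)
    if sd == 0:
        warnings.warn("null NODF ensemble has zero variance; returning signed infinity")
        diff = obs - scores.mean()
        return math.copysign(math.inf, diff) if diff != 0 else 0.0
    return float((obs - scores.mean()) / sd)


def degree_summary(net: BipartiteNetwork) -> dict:
    """Per-side interaction counts and five-number summaries.

    Quartiles use linear interpolation between order statistics.
    """
    out = {}
    for side, deg in (("plants", net.plant_degrees()), ("animals", net.animal_degrees())):
        q1, med, q3 = np.percentile(deg, [25, 50, 75])
        out[side] = {
            "degrees": deg.astype(int),
            "min": int(deg.min()),
            "q1": float(q1),
            "median": float(med),
            "q3": float(q3),
            "max": int(deg.max()),
        }
    return out


def count_specialist_pollinators(net: BipartiteNetwork) -> int:
    """Number of animal species visiting exactly one plant species."""
    return int((net.animal_degrees() == 1).sum())


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------


def generate_network(target: GenTarget, rng: np.random.Generator | None = None) -> BipartiteNetwork:
    """Generate one bipartite network satisfying the target's bands.

    Accept/reject sampling: richness split, link count inside the
    connectance band, degree-sequence fill (nested or uniform), connectivity
    repair, then a NODF z-score gate (z >= 2 for nested, |z| < 2 for
    non-nested). Deterministic for a fixed ``target.rng_seed`` when no
    external ``rng`` is supplied.
    """
    if rng is None:
        rng = np.random.default_rng(target.rng_seed)
    c_lo, c_hi = connectance_band(target.C_target)
    s_lo, s_hi = richness_band(target.S_target)
    last_violation = "no attempt made"
    for _ in range(target.max_attempts):
        P, A = sample_richness_split(target.S_target, rng)
        # aim inside the band with margin so integer rounding cannot escape it
        margin = 0.1 * (c_hi - c_lo)
        C_real = rng.uniform(c_lo + margin, c_hi - margin)
        L = int(round(C_real * P * A))
        L = max(L, max(P, A))  # connectivity lower bound
        if not (c_lo <= L / (P * A) <= c_hi):
            last_violation = f"link count {L} escapes connectance band"
            continue
        if target.nested:
            k = _sample_degrees_nested(A, P, L, rng)
        else:
            k = _sample_degrees_random(A, P, L, rng)
        try:
            k = _adjust_degree_sum(k, L, P, rng)
            M = _fill_incidence(k, P, target.nested, target.skew, rng)
            M = _repair_empty_plants(M, rng)
        except GenerationError as exc:
            last_violation = str(exc)
            continue
        net = BipartiteNetwork.from_matrix(M)
        C_net = connectance(net)
        if not (c_lo <= C_net <= c_hi):
            last_violation = f"realized connectance {C_net:.4f} outside [{c_lo}, {c_hi}]"
            continue
        if not (s_lo <= net.richness <= s_hi):
            last_violation = f"realized richness {net.richness} outside [{s_lo}, {s_hi}]"
            continue
        z = nestedness_zscore(net, n_null=target.n_null, rng=rng)
        if target.nested and z < 2.0:
            last_violation = f"nested network has z = {z:.2f} < 2"
            continue
        if not target.nested and not (-2.0 < z < 2.0):
            last_violation = f"non-nested network has |z| = {abs(z):.2f} >= 2"
            continue
        return net
    raise GenerationError(
        f"failed to generate network within {target.max_attempts} attempts; "
        f"last violated constraint: {last_violation}"
    )
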