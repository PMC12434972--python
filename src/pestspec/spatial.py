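"""Spatial autocorrelation of damage levels: Moran's I, LISA and Gi*.

Damage levels are treated as ordinal values 1–4 on the tree points.
Global Moran's I measures stand-wide autocorrelation,

    I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2,    E[I] = -1/(n-1),

with permutation inference.  Anselin's local Moran's I decomposes it
per tree,

    I_i = z_i * sum_j w_ij z_j / (sum_k z_k^2 / n),

with conditional-permutation pseudo-p values; significant trees are
categorised HH/HL/LH/LL by the signs of z_i and its spatial lag, and
those categories map onto pest-distribution types: HH -> spread
(an advancing infestation front), HL -> saltatory (isolated severe
trees ahead of the front), LH -> latent (still-green trees inside the
outbreak), LL -> healthy area; non-significant trees are unclassified.
Getis-Ord Gi* (self-inclusive weights) adds hot/cold-spot z-scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DISTRIBUTION_MAP = {
    "HH": "spread",
    "HL": "saltatory",
    "LH": "latent",
    "LL": "healthy",
    "ns": "unclassified",
}


@dataclass
class SpatialWeights:
    """Neighbour graph over tree points.

    ``neighbors[i]`` / ``weights[i]`` are aligned arrays (no
    self-neighbours).  ``scheme`` records the construction; isolated
    points (distance-band graphs only) carry empty neighbour lists and
    are flagged.
    """

    neighbors: list[np.ndarray]
    weights: list[np.ndarray]
    scheme: str
    standardization: str  # "row" | "binary"

    @property
    def n(self) -> int:
        return len(self.neighbors)

    @property
    def cardinalities(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors])

    @property
    def isolated(self) -> np.ndarray:
        return self.cardinalities == 0

    @property
    def s0(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def _padded(self):
        """(nb_pad, w_pad): fixed-width neighbour/weight arrays, padded with
        a sentinel index ``n`` carrying weight 0 — enables vectorised lags."""
        if not hasattr(self, "_pad_cache"):
            kmax = max(int(self.cardinalities.max()), 1)
            nb_pad = np.full((self.n, kmax), self.n, dtype=int)
            w_pad = np.zeros((self.n, kmax))
            for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
                nb_pad[i, : len(nb)] = nb
                w_pad[i, : len(nb)] = w
            self._pad_cache = (nb_pad, w_pad)
        return self._pad_cache

    def lag(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        nb_pad, w_pad = self._padded()
        ext = np.append(values, 0.0)
        return (w_pad * ext[nb_pad]).sum(axis=1)

    def dense(self) -> np.ndarray:
        W = np.zeros((self.n, self.n))
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            W[i, nb] = w
        return W


def build_weights(
    points: np.ndarray,
    scheme: str = "knn",
    k: int = 8,
    band: float | None = None,
    standardization: str = "row",
) -> SpatialWeights:
    """k-nearest-neighbour or distance-band weights over planar points.

    knn ties break toward the lowest point index for determinism.
    Distance-band graphs are symmetric before standardization.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2 or len(np.unique(pts, axis=0)) < 2:
        raise ValueError("need at least 2 distinct points")
    d = np.hypot(
        pts[:, 0][:, None] - pts[:, 0][None, :],
        pts[:, 1][:, None] - pts[:, 1][None, :],
    )
    neighbors: list[np.ndarray] = []
    if scheme == "knn":
        if not 1 <= k < n:
            raise ValueError("knn requires 1 <= k < n")
        ids = np.arange(n)
        for i in range(n):
            order = np.lexsort((ids, d[i]))
            order = order[order != i]
            neighbors.append(np.sort(order[:k]))
        label = f"knn({k})"
    elif scheme == "distance_band":
        if band is None or band <= 0:
            raise ValueError("distance_band requires a positive band")
        for i in range(n):
            nb = np.flatnonzero((d[i] <= band))
            neighbors.append(nb[nb != i])
        if all(len(nb) == 0 for nb in neighbors):
            raise ValueError("band excludes all pairs")
        label = f"distance_band({band})"
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    weights = []
    for nb in neighbors:
        w = np.ones(len(nb))
        if standardization == "row" and len(nb):
            w /= w.sum()
        elif standardization not in ("row", "binary"):
            raise ValueError(f"unknown standardization {standardization!r}")
        weights.append(w)
    return SpatialWeights(neighbors, weights, label, standardization)


@dataclass
class GlobalMoranResult:
    I: float
    expected: float
    z_sim: float
    p_sim: float
    permutations: int

    def to_dict(self) -> dict:
        return {
            "morans_i": self.I,
            "expected_i": self.expected,
            "z_sim": self.z_sim,
            "p_sim": self.p_sim,
            "permutations": self.permutations,
        }


def _moran_stat(z: np.ndarray, W: SpatialWeights) -> float:
    n = len(z)
    return n / W.s0 * float(z @ W.lag(z)) / float(z @ z)


def global_morans_i(
    values,
    W: SpatialWeights,
    permutations: int = 999,
    seed: int = 0,
) -> GlobalMoranResult:
    """Global Moran's I with a full-permutation null."""
    v = np.asarray(values, dtype=float)
    if np.all(v == v[0]):
        raise ValueError("Moran's I undefined for constant values")
    if permutations < 99:
        raise ValueError("use at least 99 permutations")
    z = v - v.mean()
    n = len(v)
    obs = _moran_stat(z, W)
    rng = np.random.default_rng(seed % (2**31))
    sims = np.empty(permutations)
    for s in range(permutations):
        sims[s] = _moran_stat(rng.permutation(z), W)
    spread = sims.std(ddof=1)
    z_sim = (obs - sims.mean()) / spread if spread > 0 else np.nan
    if obs >= sims.mean():
        extreme = int((sims >= obs).sum())
    else:
        extreme = int((sims <= obs).sum())
    p_sim = (extreme + 1) / (permutations + 1)
    return GlobalMoranResult(obs, -1.0 / (n - 1), z_sim, p_sim, permutations)


@dataclass
class LocalMoranResult:
    local_i: np.ndarray
    lag: np.ndarray
    p_sim: np.ndarray
    category: np.ndarray  # HH / HL / LH / LL / ns
    alpha: float
    permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "local_i": self.local_i,
                "lag": self.lag,
                "p_sim": self.p_sim,
                "category": self.category,
            }
        )


def local_morans_i(
    values,
    W: SpatialWeights,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> LocalMoranResult:
    """Anselin local Moran's I with conditional-permutation inference.

    For each tree the values of all *other* trees are permuted among its
    neighbour slots; the pseudo-p is one-sided in the direction of the
    observed local statistic.  Significant trees are categorised by the
    quadrant of (z_i, spatial lag of z_i).
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if np.all(v == v[0]):
        raise ValueError("local Moran undefined for constant values")
    z = v - v.mean()
    m2 = float(z @ z) / n
    lag = W.lag(z)
    local = z * lag / m2
    rng = np.random.default_rng(seed % (2**31))
    # shared permutation table: each row is a permutation of n-1 "other" slots
    kmax = int(W.cardinalities.max()) if n else 0
    perm_rows = np.empty((permutations, kmax), dtype=int)
    for s in range(permutations):
        perm_rows[s] = rng.permutation(n - 1)[:kmax]
    p_sim = np.ones(n)
    others_template = np.arange(n - 1)
    for i in range(n):
        nb = W.neighbors[i]
        ki = len(nb)
        if ki == 0:
            p_sim[i] = np.nan
            continue
        others = others_template.copy()
        others[i:] += 1  # indices of all points except i
        draws = others[perm_rows[:, :ki]]  # (permutations, ki)
        wz = z[draws] @ W.weights[i]
        sims = z[i] * wz / m2
        if local[i] >= 0:
            extreme = int((sims >= local[i]).sum())
        else:
            extreme = int((sims <= local[i]).sum())
        p_sim[i] = (extreme + 1) / (permutations + 1)
    category = np.full(n, "ns", dtype=object)
    sig = p_sim <= alpha
    category[sig & (z > 0) & (lag > 0)] = "HH"
    category[sig & (z > 0) & (lag <= 0)] = "HL"
    category[sig & (z <= 0) & (lag > 0)] = "LH"
    category[sig & (z <= 0) & (lag <= 0)] = "LL"
    return LocalMoranResult(local, lag, p_sim, category, alpha, permutations)


def classify_distribution(categories) -> np.ndarray:
    """Map LISA categories to pest-distribution types.

    HH -> spread, HL -> saltatory, LH -> latent, LL -> healthy,
    not-significant -> unclassified.
    """
    return np.array([DISTRIBUTION_MAP[c] for c in np.asarray(categories, dtype=object)])


@dataclass
class GiStarResult:
    z_scores: np.ndarray
    hotspot_class: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gi_z": self.z_scores, "hotspot": self.hotspot_class})


def getis_ord_gi_star(
    values,
    W: SpatialWeights,
    z_extreme: float = 2.575829,  # two-sided 0.01
    z_significant: float = 1.959964,  # two-sided 0.05
) -> GiStarResult:
    """Getis-Ord Gi* hot/cold-spot z-scores with self-inclusive weights.

    Uses binary (unstandardized) weights plus the self term, and the
    standard analytical moments:

        z_i = (sum_j w_ij x_j - xbar W_i)
              / (s * sqrt((n S1_i - W_i^2) / (n - 1)))

    Classes: ``hot_p01`` (extremely significant hotspot), ``hot_p05``
    (significant hotspot), ``cold`` (|z| beyond the significant
    threshold on the low side), else ``ns``.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if np.all(x == x[0]):
        raise ValueError("Gi* undefined for constant values")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    zs = np.empty(n)
    for i in range(n):
        nb = W.neighbors[i]
        wsum = x[nb].sum() + x[i]  # binary weights, self-inclusive
        Wi = len(nb) + 1
        S1 = Wi  # binary weights: sum of squares equals the count
        denom = s * np.sqrt((n * S1 - Wi**2) / (n - 1))
        zs[i] = (wsum - xbar * Wi) / denom
    cls = np.full(n, "ns", dtype=object)
    cls[zs >= z_significant] = "hot_p05"
    cls[zs >= z_extreme] = "hot_p01"
    cls[zs <= -z_significant] = "cold"
    return GiStarResult(zs, cls)


@dataclass
class SpatialAnalysis:
    """Bundle of global + local autocorrelation results for one stand."""

    weights: SpatialWeights
    global_moran: GlobalMoranResult
    local_moran: LocalMoranResult
    gi_star: GiStarResult
    distribution_type: np.ndarray = field(default=None)

    def to_frame(self, index=None) -> pd.DataFrame:
        df = pd.concat([self.local_moran.to_frame(), self.gi_star.to_frame()], axis=1)
        df["distribution_type"] = self.distribution_type
        if index is not None:
            df.index = index
        return df


def analyze_spatial(
    points,
    values,
    scheme: str = "knn",
    k: int = 8,
    band: float | None = None,
    permutations: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> SpatialAnalysis:
    """Run the full spatial battery on tree points and damage values."""
    W = build_weights(points, scheme=scheme, k=k, band=band, standardization="row")
    gm = global_morans_i(values, W, permutations=permutations, seed=seed)
    lm = local_morans_i(
        values, W, permutations=permutations, alpha=alpha, seed=seed + 1
    )
    gi = getis_ord_gi_star(values, W)
    return SpatialAnalysis(
        weights=W,
        global_moran=gm,
        local_moran=lm,
        gi_star=gi,
        distribution_type=classify_distribution(lm.category),
    )
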