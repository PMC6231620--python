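"""Copula-based Cramér–von Mises dissimilarity between stationary time series.

The dependence pattern of a strictly stationary series ``X`` at lag ``h`` is
summarised by the copula of the pair ``(X_t, X_{t+h})``.  Two series are close
when these lag-h copulas are close in squared L2 distance over the unit square:

    D_h(i, i') = ∫∫ (C_{i,h}(u, v) − C_{i',h}(u, v))^2 du dv.

Each copula is estimated by the empirical copula of rescaled ranks
(pseudo-observations), which makes the distance fully nonparametric and
invariant under strictly increasing transformations of either series.  Because
the empirical copulas are piecewise-constant, the double integral has an exact
closed form in terms of the L-statistic

    L_{a,b} = (1 / (T_a−h)(T_b−h)) Σ_t Σ_t' (1−max(U_at, U_bt'))(1−max(V_at, V_bt'))

via D̂_h(a, b) = L_{a,a} − 2 L_{a,b} + L_{b,b}; no numerical quadrature is ever
needed (``cvm_grid_oracle`` exists only as an independent check).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "TimeSeries",
    "Panel",
    "PseudoPairs",
    "WeightScheme",
    "DistanceMatrix",
    "pseudo_pairs",
    "empirical_copula",
    "l_statistic",
    "lag_distance",
    "weighted_distance",
    "distance_matrix",
    "cvm_grid_oracle",
]


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class InvalidLagError(InvalidInputError):
    """Raised when a lag (or maximum lag K) is too large for a series."""


@dataclass(frozen=True)
class TimeSeries:
    """A single univariate series with a unique string label.

    Values must be finite reals; the length is whatever the data provides
    (series in one panel may have different lengths).
    """

    id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise InvalidInputError(f"series {self.id!r}: values must be a non-empty 1-d array")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError(f"series {self.id!r}: values must be finite")
        object.__setattr__(self, "values", arr)

    @property
    def length(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class Panel:
    """An ordered collection of time series with unique ids."""

    series: tuple[TimeSeries, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "series", tuple(self.series))
        ids = [s.id for s in self.series]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("panel ids must be unique")

    @property
    def n(self) -> int:
        return len(self.series)

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.series]

    def __iter__(self):
        return iter(self.series)

    def __getitem__(self, key: int | str) -> TimeSeries:
        if isinstance(key, str):
            for s in self.series:
                if s.id == key:
                    return s
            raise KeyError(key)
        return self.series[key]


@dataclass(frozen=True)
class PseudoPairs:
    """Lag-h rank pairs (U_t, V_t) of one series.

    U_t = T/(T+1) · F̂(X_t) and V_t = T/(T+1) · F̂(X_{t+h}) for t = 1..T−h,
    where F̂ is the empirical CDF of the *full* series.  All values are
    multiples of 1/(T+1) strictly inside (0, 1).
    """

    h: int
    U: np.ndarray
    V: np.ndarray
    T: int

    def __len__(self) -> int:
        return self.U.size


@dataclass(frozen=True)
class WeightScheme:
    """Weights ω_1..ω_K for the multi-lag distance D = Σ_h ω_h D_h.

    The default everywhere is K = 1 with unit weight: serial dependence is
    typically strongest at lag one and a single lag keeps the cost linear in K.
    """

    K: int = 1
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        w = tuple(float(x) for x in self.weights)
        if self.K < 1 or len(w) != self.K:
            raise InvalidInputError("weights must have length K >= 1")
        if any(x < 0 for x in w) or not any(x > 0 for x in w):
            raise InvalidInputError("weights must be nonnegative with at least one positive")
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, K: int) -> "WeightScheme":
        """Unit weight ω_h = 1 at every lag (a plain sum of D_h)."""
        return cls(K=K, weights=(1.0,) * K)


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise copula distances."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        arr = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if arr.shape != (n, n):
            raise InvalidInputError("matrix shape must match number of ids")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("distance entries must be finite")
        if not np.allclose(arr, arr.T, rtol=0.0, atol=1e-9):
            raise InvalidInputError("distance matrix must be symmetric")
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return len(self.ids)


# ---------------------------------------------------------------------------
# Pseudo-observations and the empirical copula
# ---------------------------------------------------------------------------

def pseudo_pairs(series: TimeSeries, h: int, ties: str = "max") -> PseudoPairs:
    """Rescaled-rank pairs feeding the empirical lag-h copula of one series.

    The empirical CDF is evaluated on the full series, F̂(x) = #{s: X_s ≤ x}/T,
    which for distinct values is the ordinary rank divided by T.  ``ties="max"``
    realises exactly this count-of-≤ definition (the margins are assumed
    continuous, so ties are measure-zero in theory); ``ties="average"`` is
    available for heavily tied data.
    """
    if h < 1:
        raise InvalidLagError(f"lag must be >= 1, got {h}")
    T = series.length
    if h >= T:
        raise InvalidLagError(f"lag {h} must be smaller than series length {T}")
    if ties not in ("max", "average"):
        raise InvalidInputError(f"unknown tie method {ties!r}")
    scaled = rankdata(series.values, method=ties) / (T + 1)
    return PseudoPairs(h=h, U=scaled[: T - h], V=scaled[h:], T=T)


def empirical_copula(pairs: PseudoPairs, u, v):
    """Empirical copula Ĉ_h(u, v) = mean_t I(U_t ≤ u) I(V_t ≤ v).

    ``u`` and ``v`` broadcast, so a grid evaluation is a single call.
    """
    if len(pairs) == 0:
        raise InvalidInputError("pseudo-pairs are empty")
    u_b, v_b = np.broadcast_arrays(np.asarray(u, dtype=float),
                                   np.asarray(v, dtype=float))
    ind = (pairs.U[:, None] <= u_b.ravel()) & (pairs.V[:, None] <= v_b.ravel())
    out = ind.mean(axis=0).reshape(u_b.shape)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Closed-form Cramér–von Mises distance
# ---------------------------------------------------------------------------

def l_statistic(a: PseudoPairs, b: PseudoPairs) -> float:
    """The bilinear form L_{a,b} = ∫∫ Ĉ_a Ĉ_b du dv, evaluated exactly.

    Direct O(T_a·T_b) double sum over all index pairs; symmetric in its
    arguments and always in [0, 1].
    """
    if a.h != b.h:
        raise InvalidInputError(f"lag mismatch: {a.h} vs {b.h}")
    if len(a) == 0 or len(b) == 0:
        raise InvalidInputError("pseudo-pairs are empty")
    # canonical argument order makes the summation order, and hence the
    # floating-point result, exactly symmetric
    if (len(b), b.U.tobytes(), b.V.tobytes()) < (len(a), a.U.tobytes(), a.V.tobytes()):
        a, b = b, a
    mu = np.maximum.outer(a.U, b.U)
    mv = np.maximum.outer(a.V, b.V)
    return float(np.mean((1.0 - mu) * (1.0 - mv)))


_CLAMP = 1e-12  # |negative| below this is floating-point cancellation noise


def lag_distance(a: TimeSeries, b: TimeSeries, h: int, ties: str = "max") -> float:
    """Estimated lag-h copula distance D̂_h(a, b) = L_aa − 2 L_ab + L_bb."""
    pa = pseudo_pairs(a, h, ties=ties)
    pb = pseudo_pairs(b, h, ties=ties)
    return _distance_from_l(l_statistic(pa, pa), l_statistic(pa, pb), l_statistic(pb, pb))


def _distance_from_l(laa: float, lab: float, lbb: float) -> float:
    d = laa - 2.0 * lab + lbb
    if d < 0.0:
        if d < -_CLAMP:
            raise ArithmeticError(f"distance {d} negative beyond cancellation tolerance")
        d = 0.0
    return d


def weighted_distance(a: TimeSeries, b: TimeSeries, scheme: WeightScheme,
                      ties: str = "max") -> float:
    """Weighted multi-lag distance D(a, b) = Σ_{h=1}^{K} ω_h D̂_h(a, b)."""
    if scheme.K >= min(a.length, b.length):
        raise InvalidLagError(
            f"K={scheme.K} too large for series lengths {a.length}, {b.length}")
    return sum(w * lag_distance(a, b, h, ties=ties)
               for h, w in enumerate(scheme.weights, start=1) if w != 0.0)


def distance_matrix(panel: Panel, scheme: WeightScheme | None = None,
                    ties: str = "max") -> DistanceMatrix:
    """Full pairwise matrix of weighted copula distances for a panel.

    Each unordered pair is computed once; per-series quantities (pseudo-pairs
    and the diagonal statistics L_ii) are cached across pairs, so the cost is
    one L-statistic per pair per active lag.
    """
    if scheme is None:
        scheme = WeightScheme()
    if panel.n < 2:
        raise InvalidInputError("need at least 2 series for a distance matrix")
    for s in panel:
        if s.length <= scheme.K:
            raise InvalidLagError(f"series {s.id!r} has length {s.length} <= K={scheme.K}")

    active = [(h, w) for h, w in enumerate(scheme.weights, start=1) if w != 0.0]
    pairs = {(i, h): pseudo_pairs(s, h, ties=ties)
             for i, s in enumerate(panel) for h, _ in active}
    diag = {(i, h): l_statistic(pairs[i, h], pairs[i, h])
            for i in range(panel.n) for h, _ in active}

    D = np.zeros((panel.n, panel.n))
    for i in range(panel.n):
        for j in range(i + 1, panel.n):
            d = sum(w * _distance_from_l(diag[i, h],
                                         l_statistic(pairs[i, h], pairs[j, h]),
                                         diag[j, h])
                    for h, w in active)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(ids=tuple(panel.ids), values=D)


# ---------------------------------------------------------------------------
# Quadrature oracle (testing aid, not the production path)
# ---------------------------------------------------------------------------

def cvm_grid_oracle(a: PseudoPairs, b: PseudoPairs, m: int = 2000) -> float:
    """Midpoint Riemann sum of ∫∫ (Ĉ_a − Ĉ_b)² du dv on an m×m grid.

    Converges to :func:`lag_distance` as m → ∞; kept as an independent check
    of the closed form.  Each copula is evaluated on the grid by a 2-d
    histogram of the pseudo-pairs followed by cumulative sums.
    """
    if m < 10:
        raise InvalidInputError("grid size m must be >= 10")
    if a.h != b.h:
        raise InvalidInputError(f"lag mismatch: {a.h} vs {b.h}")
    mid = (np.arange(m) + 0.5) / m

    def copula_on_grid(p: PseudoPairs) -> np.ndarray:
        edges = np.concatenate(([0.0], mid, [1.0]))
        hist, _, _ = np.histogram2d(p.U, p.V, bins=(edges, edges))
        # cell (k, l) of the cumulative histogram counts pairs with
        # U <= mid[k] and V <= mid[l]
        return hist.cumsum(axis=0).cumsum(axis=1)[:-1, :-1] / len(p)

    diff = copula_on_grid(a) - copula_on_grid(b)
    return float(np.mean(diff * diff))
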