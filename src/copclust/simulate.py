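"""Seeded generators for the nonlinear benchmark models used in the studies.

Seven stationary families driven by i.i.d. N(0, 1) innovations ε_t:

* ``TAR``    X_t = 0.5 X_{t−1} I(X_{t−1} ≤ 0) − b1 X_{t−1} I(X_{t−1} > 0) + ε_t
* ``EXPAR``  X_t = (a2 − b2 exp(−X²_{t−1})) X_{t−1} + ε_t
* ``MA``     X_t = ε_t − 0.4 ε_{t−1}
* ``NLMA``   X_t = ε_t − a4 ε_{t−1} + b4 ε²_{t−1}
* ``STAR``   X_t = 0.5 X_{t−1} − 2.5 X_{t−1} (1 + exp(−X_{t−1}))^{−1} + ε_t
* ``STMA``   X_t = ε_t − 0.4 ε_{t−1} + 0.8 ε_{t−1}(1 − exp(−X²_{t−1})) + ε_t
* ``AR``     X_t = φ X_{t−1} + ε_t

The STMA equation is implemented exactly as displayed in its source, with the
ε_t term appearing twice (so the shock enters with coefficient 2); this is
very likely a typographical duplication, and ``single_noise=True`` drops the
second ε_t.  The default keeps the printed form so results are comparable.

Panel builders reproduce the three benchmark designs: four series from each of
four families (n = 16).  A strength dial α ∈ [0, 1] interpolates the third
design between the fully nonlinear models (α = 1, coefficients (b1, b2, b4) =
(2, 10, 0.8)) and a purely linear AR/MA quartet (α = 0, (−0.5, 0, 0)) via
(b1, b2, b4) = (2.5α − 0.5, 10α, 0.8α).

Reproducibility: one master seed spawns an independent child stream per
series, so a panel is bitwise reproducible and individual series do not
depend on the order in which they are generated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .distance import InvalidInputError, Panel, TimeSeries

__all__ = [
    "ModelSpec",
    "Partition",
    "LabeledPanel",
    "FAMILIES",
    "ALPHA_GRID",
    "alpha_coefficients",
    "simulate_series",
    "example1_panel",
    "example2_panel",
    "example3_panel",
    "two_cluster_panel",
]

FAMILIES = ("TAR", "EXPAR", "MA", "NLMA", "STAR", "STMA", "AR")

#: Six uniformly spaced nonlinearity strengths used in the third design.
ALPHA_GRID = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)

# Families whose recursion consumes one pre-sample innovation ε_0.
_MA_TYPE = frozenset({"MA", "NLMA", "STMA"})


@dataclass(frozen=True)
class Partition:
    """Disjoint non-empty groups of series ids (a flat clustering)."""

    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        gs = tuple(frozenset(g) for g in self.groups)
        if any(not g for g in gs):
            raise InvalidInputError("groups must be non-empty")
        all_ids = [i for g in gs for i in g]
        if len(all_ids) != len(set(all_ids)):
            raise InvalidInputError("groups must be disjoint")
        object.__setattr__(self, "groups", gs)

    @property
    def J0(self) -> int:
        return len(self.groups)

    @property
    def ids(self) -> frozenset[str]:
        return frozenset(i for g in self.groups for i in g)

    @classmethod
    def from_labels(cls, labels: dict[str, object]) -> "Partition":
        by_group: dict[object, set[str]] = {}
        for sid, g in labels.items():
            by_group.setdefault(g, set()).add(sid)
        return cls(groups=tuple(frozenset(v) for _, v in sorted(
            by_group.items(), key=lambda kv: str(kv[0]))))


@dataclass(frozen=True)
class LabeledPanel:
    """A simulated panel together with its ground-truth grouping."""

    panel: Panel
    truth: Partition

    def __post_init__(self) -> None:
        if self.truth.ids != frozenset(self.panel.ids):
            raise InvalidInputError("truth must cover exactly the panel ids")


@dataclass(frozen=True)
class ModelSpec:
    """One data-generating model: a family name plus its coefficients.

    ``single_noise`` affects only the STMA family (see module docstring).
    """

    family: str
    params: dict = field(default_factory=dict)
    single_noise: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise InvalidInputError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family == "TAR":
            # stationarity of the two-regime model with zero intercepts and
            # threshold: coefficients (0.5, −b1) must satisfy a < 1, b < 1, ab < 1
            b1 = float(self.params.get("b1", 2.0))
            a, b = 0.5, -b1
            if not (a < 1 and b < 1 and a * b < 1):
                warnings.warn(
                    f"TAR coefficients (0.5, {b:g}) violate the stationarity "
                    "condition a < 1, b < 1, ab < 1", stacklevel=2)


def _innovations(n: int, seed, noise_override) -> np.ndarray:
    if noise_override is not None:
        eps = np.asarray(noise_override, dtype=float)
        if eps.size != n:
            raise InvalidInputError(f"noise_override must have length {n}, got {eps.size}")
        return eps
    return np.random.default_rng(seed).standard_normal(n)


def simulate_series(spec: ModelSpec, T: int, burn: int = 200, seed=None,
                    noise_override=None, id: str = "sim") -> TimeSeries:
    """Run one family's recursion and return T post-burn-in observations.

    The state starts at X_0 = 0; moving-average families additionally consume
    one pre-sample innovation, so they draw ``burn + T + 1`` innovations where
    autoregressive families draw ``burn + T``.  ``noise_override`` substitutes
    an explicit innovation sequence of exactly that length (for deterministic
    checks); otherwise innovations are N(0, 1) from ``seed``.
    """
    if T < 10 and noise_override is None:
        raise InvalidInputError(f"series length T={T} must be >= 10")
    if burn < 0:
        raise InvalidInputError("burn-in must be nonnegative")
    total = burn + T + (1 if spec.family in _MA_TYPE else 0)
    eps = _innovations(total, seed, noise_override)
    p = spec.params
    fam = spec.family
    x = np.empty(burn + T)
    prev = 0.0

    if fam in _MA_TYPE:
        a4 = float(p.get("a4", 0.5))
        b4 = float(p.get("b4", 0.8))
        for t in range(burn + T):
            e, e1 = eps[t + 1], eps[t]
            if fam == "MA":
                x[t] = e - 0.4 * e1
            elif fam == "NLMA":
                x[t] = e - a4 * e1 + b4 * e1 * e1
            else:  # STMA
                val = e - 0.4 * e1 + 0.8 * e1 * (1.0 - np.exp(-prev * prev))
                if not spec.single_noise:
                    val += e  # the displayed equation carries ε_t twice
                x[t] = val
                prev = x[t]
    else:
        b1 = float(p.get("b1", 2.0))
        a2 = float(p.get("a2", 0.3))
        b2 = float(p.get("b2", 10.0))
        phi = float(p.get("phi", 0.5))
        for t in range(burn + T):
            if fam == "TAR":
                mean = 0.5 * prev if prev <= 0 else -b1 * prev
            elif fam == "EXPAR":
                mean = (a2 - b2 * np.exp(-prev * prev)) * prev
            elif fam == "STAR":
                mean = 0.5 * prev - 2.5 * prev / (1.0 + np.exp(-prev))
            else:  # AR
                mean = phi * prev
            x[t] = mean + eps[t]
            prev = x[t]

    return TimeSeries(id=id, values=x[burn:])


def _spawn(seed, n: int) -> list[np.random.SeedSequence]:
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return ss.spawn(n)


def _build_panel(specs: list[tuple[str, ModelSpec]], T: int, burn: int, seed) -> LabeledPanel:
    children = _spawn(seed, len(specs))
    series, labels = [], {}
    for (sid, spec), child in zip(specs, children):
        series.append(simulate_series(spec, T=T, burn=burn, seed=child, id=sid))
        labels[sid] = spec.family
    return LabeledPanel(panel=Panel(series=tuple(series)),
                        truth=Partition.from_labels(labels))


def example1_panel(T: int = 200, seed=None, burn: int = 200) -> LabeledPanel:
    """Four series each from TAR(b1=2), EXPAR(0.3, 10), MA and NLMA(0.5, 0.8)."""
    if T < 50:
        raise InvalidInputError("panel series length must be >= 50")
    fams = [ModelSpec("TAR", {"b1": 2.0}),
            ModelSpec("EXPAR", {"a2": 0.3, "b2": 10.0}),
            ModelSpec("MA"),
            ModelSpec("NLMA", {"a4": 0.5, "b4": 0.8})]
    specs = [(f"{m.family}-{r}", m) for m in fams for r in range(1, 5)]
    return _build_panel(specs, T, burn, seed)


def example2_panel(T: int = 200, seed=None, burn: int = 200) -> LabeledPanel:
    """Heterogeneous variant: STAR, EXPAR and NLMA with per-series random
    coefficients (a2 ~ U(0.2, 0.6), b2 ~ U(6, 12); a4 ~ U(0.3, 0.7),
    b4 ~ U(0.2, 0.9)), and STMA in place of the linear MA."""
    if T < 50:
        raise InvalidInputError("panel series length must be >= 50")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    coef_child, panel_child = ss.spawn(2)
    rng = np.random.default_rng(coef_child)
    specs: list[tuple[str, ModelSpec]] = []
    for r in range(1, 5):
        specs.append((f"STAR-{r}", ModelSpec("STAR")))
    for r in range(1, 5):
        specs.append((f"EXPAR-{r}", ModelSpec("EXPAR", {
            "a2": rng.uniform(0.2, 0.6), "b2": rng.uniform(6.0, 12.0)})))
    for r in range(1, 5):
        specs.append((f"STMA-{r}", ModelSpec("STMA")))
    for r in range(1, 5):
        specs.append((f"NLMA-{r}", ModelSpec("NLMA", {
            "a4": rng.uniform(0.3, 0.7), "b4": rng.uniform(0.2, 0.9)})))
    return _build_panel(specs, T, burn, panel_child)


def alpha_coefficients(alpha: float) -> tuple[float, float, float]:
    """Nonlinearity-strength mapping (b1, b2, b4) = (2.5α − 0.5, 10α, 0.8α)."""
    if not 0.0 <= alpha <= 1.0:
        raise InvalidInputError(f"alpha must lie in [0, 1], got {alpha}")
    return 2.5 * alpha - 0.5, 10.0 * alpha, 0.8 * alpha


def example3_panel(alpha: float, T: int = 200, seed=None, burn: int = 200) -> LabeledPanel:
    """Strength-dial design: TAR(b1), EXPAR(0.3, b2), MA, NLMA(0.5, b4) with
    (b1, b2, b4) = alpha_coefficients(alpha).  α = 1 reproduces the first
    design; α = 0 degenerates every model to a linear AR/MA form."""
    if T < 50:
        raise InvalidInputError("panel series length must be >= 50")
    b1, b2, b4 = alpha_coefficients(alpha)
    fams = [ModelSpec("TAR", {"b1": b1}),
            ModelSpec("EXPAR", {"a2": 0.3, "b2": b2}),
            ModelSpec("MA"),
            ModelSpec("NLMA", {"a4": 0.5, "b4": b4})]
    specs = [(f"{m.family}-{r}", m) for m in fams for r in range(1, 5)]
    return _build_panel(specs, T, burn, seed)


def two_cluster_panel(T: int = 200, seed=None, n_per: int = 5,
                      burn: int = 200) -> LabeledPanel:
    """Two well-separated dependence clusters: n_per series of AR(1) with
    φ = 0.8 against n_per of NLMA(a4=0.5, b4=0.8).  Used for cluster-number
    selection and nesting-consistency checks."""
    specs = ([(f"AR-{r}", ModelSpec("AR", {"phi": 0.8})) for r in range(1, n_per + 1)]
             + [(f"NLMA-{r}", ModelSpec("NLMA", {"a4": 0.5, "b4": 0.8}))
                for r in range(1, n_per + 1)])
    return _build_panel(specs, T, burn, seed)
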