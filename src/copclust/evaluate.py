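"""Partition scoring and the simulation-replication harness.

The quality of an estimated clustering A against a ground truth G is the
Dice-style similarity index

    Sim(G, A) = (1/J0) Σ_i max_j 2|G_i ∩ A_j| / (|G_i| + |A_j|),

which is 1 exactly when every true group appears verbatim in A.  The formula
is applied literally: if A has more groups than G the max simply ranges over
all of them, and if it has fewer, each true group scores its best partial
match with no extra penalty.

``run_experiment`` replays a benchmark design end to end — simulate a
labeled panel, compute the copula distance matrix, agglomerate, cut at the
true number of clusters, score — for a number of independent replicates, and
also records the silhouette-selected cluster count per replicate as a
diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distance import InvalidInputError, WeightScheme, distance_matrix
from .hclust import agglomerate, cut_tree, select_n_clusters
from .simulate import (LabeledPanel, Partition, example1_panel, example2_panel,
                       example3_panel)

__all__ = [
    "ExperimentReport",
    "pair_similarity",
    "similarity_index",
    "labels_to_partition",
    "run_experiment",
]


def pair_similarity(Gi: set, Aj: set) -> float:
    """Dice overlap 2|Gi ∩ Aj| / (|Gi| + |Aj|) of two id sets, in [0, 1]."""
    Gi, Aj = set(Gi), set(Aj)
    if not Gi or not Aj:
        raise InvalidInputError("similarity of an empty set is undefined")
    return 2.0 * len(Gi & Aj) / (len(Gi) + len(Aj))


def similarity_index(G: Partition, A: Partition) -> float:
    """Average over true groups of the best-matching Dice overlap with A."""
    if G.ids != A.ids:
        raise InvalidInputError("partitions must cover the same ids")
    return float(np.mean([max(pair_similarity(Gi, Aj) for Aj in A.groups)
                          for Gi in G.groups]))


def labels_to_partition(labels) -> Partition:
    """Convert a ClusterLabels (or any id→group mapping) to a Partition."""
    mapping = labels.labels if hasattr(labels, "labels") else dict(labels)
    return Partition.from_labels(mapping)


@dataclass(frozen=True)
class ExperimentReport:
    """Per-replicate similarity indices for one design, with summaries."""

    example: int
    replicates: int
    indices: tuple[float, ...]
    selected_J: tuple[int, ...]          # silhouette-selected cluster counts
    settings: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.indices))

    @property
    def median(self) -> float:
        return float(np.median(self.indices))

    @property
    def quartiles(self) -> tuple[float, float]:
        q1, q3 = np.percentile(self.indices, [25, 75])
        return float(q1), float(q3)

    def summary(self) -> dict:
        q1, q3 = self.quartiles
        return {"example": self.example, "replicates": self.replicates,
                "mean": self.mean, "median": self.median, "q1": q1, "q3": q3,
                "indices": list(self.indices),
                "selected_J": list(self.selected_J),
                "settings": dict(self.settings)}


_BUILDERS = {1: example1_panel, 2: example2_panel}


def _build(example: int, T: int, alpha: float | None, seed) -> LabeledPanel:
    if example == 3:
        if alpha is None:
            raise InvalidInputError("example 3 requires alpha")
        return example3_panel(alpha, T=T, seed=seed)
    if example not in _BUILDERS:
        raise InvalidInputError(f"unknown example {example}; choose 1, 2 or 3")
    return _BUILDERS[example](T=T, seed=seed)


def run_experiment(example: int, reps: int = 20, T: int = 200,
                   scheme: WeightScheme | None = None, linkage: str = "ward",
                   J_cut: int = 4, seed=0, alpha: float | None = None
                   ) -> ExperimentReport:
    """Replicate one simulation design and score recovery of the true groups.

    Each replicate gets an independent child stream of ``seed``.  The tree is
    cut at ``J_cut`` (the true group count, 4, in all three designs) for the
    similarity index; the silhouette-selected J is recorded alongside.
    """
    if reps < 1:
        raise InvalidInputError("need at least one replicate")
    if scheme is None:
        scheme = WeightScheme()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(reps)
    indices, selected = [], []
    for child in children:
        lp = _build(example, T, alpha, child)
        D = distance_matrix(lp.panel, scheme)
        tree = agglomerate(D, linkage=linkage)
        est = labels_to_partition(cut_tree(tree, J_cut, D.ids))
        indices.append(similarity_index(lp.truth, est))
        selected.append(select_n_clusters(D, tree)[0])
    settings = {"T": T, "K": scheme.K, "weights": list(scheme.weights),
                "linkage": linkage, "J_cut": J_cut,
                "seed": ss.entropy}
    if alpha is not None:
        settings["alpha"] = alpha
    return ExperimentReport(example=example, replicates=reps,
                            indices=tuple(indices), selected_J=tuple(selected),
                            settings=settings)
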