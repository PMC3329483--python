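"""Feature-subset search, clustering score and per-feature CCDF analysis.

The discriminability of a feature subset is scored on the flat clusters
obtained by cutting the dendrogram: every cluster contributes the product of
the number of networks it holds from a reference group (protein interaction
networks by default) and from a comparison group (the duplication-model
networks).  A score of zero means the two groups never share a cluster; the
normalizer (total group-A count times total group-B count) makes 1 the
everything-in-one-cluster worst case.

Enumerating all subsets obtained by eliminating up to ``max_eliminate``
features and scoring each yields a score table; the empirical CCDF of the
scores observed *without* a given feature measures how much that feature's
absence degrades separation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .netclust import cluster_networks, cut_dendrogram

__all__ = [
    "GROUP_A_DEFAULT",
    "GROUP_B_DEFAULT",
    "ClusteringScore",
    "clustering_score",
    "score_dendrogram",
    "enumerate_subsets",
    "subset_scan",
    "EmpiricalDistribution",
    "feature_ccdf",
    "feature_correlation_report",
]

#: the two groups whose mixing the score quantifies; SCN/OTHER are bystanders
GROUP_A_DEFAULT = frozenset({"PPI"})
GROUP_B_DEFAULT = frozenset({"NGD", "DMC"})

NETWORK_CLASSES = {"SCN": 1, "PPI": 2, "OTHER": 3, "NGD": 4, "DMC": 5}


class ClusteringScore(NamedTuple):
    raw: int
    normalized: float


def clustering_score(
    assignment: dict,
    classes: dict,
    group_a=GROUP_A_DEFAULT,
    group_b=GROUP_B_DEFAULT,
) -> ClusteringScore:
    """Mixing score of a flat cluster assignment.

    ``raw = sum_clusters (#group_a in cluster) * (#group_b in cluster)``;
    ``normalized`` divides by (total group-a) * (total group-b).  Labels whose
    class belongs to neither group contribute nothing.  When either group is
    absent the normalizer is undefined: the raw score is still returned, with
    ``normalized = nan``.
    """
    if set(assignment) != set(classes):
        raise ValueError("assignment and classes must share the same labels")
    group_a = frozenset(group_a)
    group_b = frozenset(group_b)
    if group_a & group_b:
        raise ValueError("groups must be disjoint")
    counts: dict[int, list[int]] = {}
    total_a = total_b = 0
    for label, cluster in assignment.items():
        cls = classes[label]
        pair = counts.setdefault(cluster, [0, 0])
        if cls in group_a:
            pair[0] += 1
            total_a += 1
        elif cls in group_b:
            pair[1] += 1
            total_b += 1
    raw = sum(a * b for a, b in counts.values())
    if total_a == 0 or total_b == 0:
        return ClusteringScore(raw=raw, normalized=math.nan)
    return ClusteringScore(raw=raw, normalized=raw / (total_a * total_b))


def score_dendrogram(
    dend,
    classes: dict,
    k_cut: int,
    group_a=GROUP_A_DEFAULT,
    group_b=GROUP_B_DEFAULT,
    monochrome_subtrees: bool = False,
) -> ClusteringScore:
    """Score a dendrogram, by default on its ``k_cut`` flat clusters.

    ``monochrome_subtrees=True`` switches to the alternative branch reading:
    clusters are the maximal subtrees whose leaves are pure in one group
    (group-a-only, group-b-only or bystander-only), with mixed leaves falling
    back to the flat cut.  The flat-cut reading is the default because the
    root of any tree mixes everything, which would forbid a perfect score.
    """
    if monochrome_subtrees:
        assignment = _monochrome_assignment(dend, classes, group_a, group_b)
    else:
        assignment = cut_dendrogram(dend, k_cut)
    return clustering_score(assignment, classes, group_a=group_a, group_b=group_b)


def _monochrome_assignment(dend, classes, group_a, group_b) -> dict:
    def colour(label):
        cls = classes[label]
        if cls in group_a:
            return "a"
        if cls in group_b:
            return "b"
        return "other"

    n = dend.n
    members: dict[int, list] = {i: [dend.leaves[i]] for i in range(n)}
    colours: dict[int, str | None] = {i: colour(dend.leaves[i]) for i in range(n)}
    roots = set(range(n))
    maximal: list[list] = []
    for t, (a, b, _h, _s) in enumerate(dend.merges):
        new = n + t
        merged = members[a] + members[b]
        if colours[a] == colours[b] and colours[a] is not None:
            colours[new] = colours[a]
        else:
            colours[new] = None
            for child in (a, b):
                if colours[child] is not None:
                    maximal.append(members[child])
        members[new] = merged
        roots.discard(a)
        roots.discard(b)
        roots.add(new)
    for r in roots:
        if colours[r] is not None:
            maximal.append(members[r])
    assignment = {}
    for idx, group in enumerate(sorted(maximal, key=lambda g: min(str(x) for x in g)), start=1):
        for label in group:
            assignment[label] = idx
    return assignment


def enumerate_subsets(feature_names, max_eliminate: int) -> list[tuple]:
    """All subsets reachable by eliminating 0..max_eliminate features.

    Ordered by number of eliminated features, then lexicographically by the
    eliminated combination, so subset indices are reproducible.  The count is
    ``sum_{k=0..max_eliminate} C(F, k)``.
    """
    names = tuple(feature_names)
    if not 0 <= max_eliminate < len(names):
        raise ValueError(
            f"max_eliminate must be in 0..{len(names) - 1}, got {max_eliminate}"
        )
    subsets = []
    for n_out in range(max_eliminate + 1):
        for out in itertools.combinations(sorted(names), n_out):
            removed = set(out)
            subsets.append(tuple(f for f in names if f not in removed))
    return subsets


def subset_scan(
    features,
    k_cut: int | None = None,
    max_eliminate: int = 2,
    feature_names=None,
    group_a=GROUP_A_DEFAULT,
    group_b=GROUP_B_DEFAULT,
    monochrome_subtrees: bool = False,
) -> pd.DataFrame:
    """Cluster and score every enumerated feature subset.

    ``features`` is a sequence of feature vectors with ``name`` and
    ``class_label``; ``k_cut`` defaults to the number of distinct class
    labels present.  Returns a DataFrame with one row per subset (enumeration
    order) and columns ``subset``, ``raw``, ``normalized``, ``size``.
    """
    classes = {fv.name: fv.class_label for fv in features}
    present_a = {c for c in classes.values() if c in group_a}
    present_b = {c for c in classes.values() if c in group_b}
    if not present_a or not present_b:
        raise ValueError(
            f"need networks from both score groups ({set(group_a)} and {set(group_b)})"
        )
    if k_cut is None:
        k_cut = len(set(classes.values()))
    if feature_names is None:
        feature_names = features[0].feature_names
    rows = []
    for subset in enumerate_subsets(feature_names, max_eliminate):
        dend, _ = cluster_networks(features, subset)
        score = score_dendrogram(
            dend, classes, k_cut, group_a=group_a, group_b=group_b,
            monochrome_subtrees=monochrome_subtrees,
        )
        rows.append(
            {
                "subset": "+".join(subset),
                "raw": score.raw,
                "normalized": score.normalized,
                "size": len(subset),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Empirical step-function CDF/CCDF over observed scores."""

    scores: np.ndarray  # sorted

    def cdf(self, x: float) -> float:
        """P(score <= x)."""
        return float(np.searchsorted(self.scores, x, side="right")) / len(self.scores)

    def ccdf(self, x: float) -> float:
        """P(score > x)."""
        return 1.0 - self.cdf(x)

    def support(self) -> np.ndarray:
        return np.unique(self.scores)


def feature_ccdf(table: pd.DataFrame, feature: str, feature_names=None) -> EmpiricalDistribution:
    """Score distribution over the subsets that do *not* contain ``feature``.

    A feature whose absence shifts this distribution toward high scores is
    important for the separation.  ``feature_names`` (defaulting to all
    features appearing in the table) guards against typos.
    """
    if table.empty:
        raise ValueError("score table is empty")
    known = set(feature_names) if feature_names is not None else {
        f for subset in table["subset"] for f in subset.split("+")
    }
    if feature not in known:
        raise KeyError(f"unknown feature {feature!r}; known: {sorted(known)}")
    mask = table["subset"].map(lambda s: feature not in s.split("+"))
    scores = np.sort(table.loc[mask, "normalized"].to_numpy(dtype=float))
    if scores.size == 0:
        raise ValueError(f"feature {feature!r} is present in every enumerated subset")
    return EmpiricalDistribution(scores=scores)


def feature_correlation_report(features, by_class: bool = True) -> dict:
    """Pearson correlations between features, per network class.

    Returns ``class -> DataFrame``; with ``by_class=False`` a single entry
    ``"all"`` pools every network.  Classes with fewer than 3 networks are
    skipped with a warning; zero-variance features yield NaN entries.
    """
    frame = pd.DataFrame([fv.as_dict() for fv in features])
    frame["class"] = [fv.class_label for fv in features]
    out = {}
    groups = frame.groupby("class") if by_class else [("all", frame)]
    for cls, sub in groups:
        if len(sub) < 3:
            warnings.warn(
                f"class {cls!r} has only {len(sub)} networks; skipping correlations",
                stacklevel=2,
            )
            continue
        out[cls] = sub.drop(columns="class").corr(method="pearson")
    return out
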