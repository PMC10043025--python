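"""Trees from model dissimilarities and feature (THP) regressions.

Two downstream analyses build on the pairwise similarity machinery:

* hierarchical clustering of models by UPGMA on a dissimilarity matrix
  (sensitivity distance ``D = 1 - |S_M|`` or Jaccard distance
  ``1 - J_M``), producing ultrametric trees serializable as Newick;
* linear regressions of normalized similarities on binary
  taxonomy/habitat/physiology (THP) feature vectors, restricted to model
  pairs with identical, fully specified features, with F-tests against the
  constant model and two-sided t-tests per coefficient.  Per-feature
  coefficients can themselves be clustered into a tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import statsmodels.api as sm_api

from .model import MetabolicModel
from .sensitivity import SensitivityMatrix, sensitivity_matrix
from .similarity import model_similarity
from .repertoire import jaccard_models

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "FeatureTable",
    "RegressionFit",
    "dissimilarity_matrix",
    "upgma",
    "parse_newick",
    "feature_pairs",
    "thp_regression",
    "coefficient_tree",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def dissimilarity_matrix(
    models: list[MetabolicModel],
    method: str = "sensitivity",
    correlation: str = "pearson",
    sensitivities: dict[str, SensitivityMatrix] | None = None,
) -> DistanceMatrix:
    """Pairwise model dissimilarities.

    ``method='sensitivity'`` uses D(l, m) = 1 - |S_M(l, m)| on sensitivity
    correlations (precomputed matrices can be passed to avoid recomputation);
    ``method='jaccard'`` uses 1 - J_M(l, m) on reaction repertoires.
    """
    labels = [m.id for m in models]
    n = len(models)
    D = np.zeros((n, n))
    if method == "sensitivity":
        sens = sensitivities or {}
        for model in models:
            if model.id not in sens:
                sens[model.id] = sensitivity_matrix(model)
        for i, j in combinations(range(n), 2):
            ms = model_similarity(sens[labels[i]], sens[labels[j]], correlation)
            D[i, j] = D[j, i] = ms.D
    elif method == "jaccard":
        for i, j in combinations(range(n), 2):
            D[i, j] = D[j, i] = 1.0 - jaccard_models(models[i], models[j])
    else:
        raise ValueError(f"unknown method {method!r}")
    return DistanceMatrix(labels=labels, values=D)


@dataclass
class TreeNode:
    """Node of a rooted ultrametric dendrogram.

    ``height`` is the distance from this node down to any of its leaves
    (0 for leaves); Newick branch lengths are parent-child height
    differences.
    """

    name: str | None = None
    height: float = 0.0
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_depth(self, name: str) -> float:
        """Root-to-leaf path length (equals root height for ultrametric)."""
        if self.is_leaf:
            return 0.0 if self.name == name else float("nan")
        for c in self.children:
            if name in c.leaves():
                return (self.height - c.height) + c.leaf_depth(name)
        return float("nan")

    def cophenetic(self, a: str, b: str) -> float:
        """Height of the lowest common ancestor of leaves a and b, doubled
        (the tree-implied distance between them)."""
        node = self
        while True:
            nxt = None
            for c in node.children:
                lv = set(c.leaves())
                if a in lv and b in lv:
                    nxt = c
                    break
            if nxt is None:
                return 2.0 * node.height
            node = nxt

    def to_newick(self) -> str:
        return self._newick_part() + ";"

    def _newick_part(self, parent_height: float | None = None) -> str:
        if self.is_leaf:
            label = self.name or ""
        else:
            inner = ",".join(c._newick_part(self.height) for c in self.children)
            label = f"({inner})"
        if parent_height is None:
            return label
        return f"{label}:{parent_height - self.height:.10g}"


def upgma(dist: DistanceMatrix) -> TreeNode:
    """Unweighted pair-group average-linkage clustering.

    Cluster pairs at minimal distance merge at height d/2; the distance of
    the merged cluster to others is the size-weighted average.  Ties break
    deterministically on the lexicographically smallest pair of cluster
    labels (a cluster is labelled by its smallest leaf).
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least two leaves")
    if not np.all(np.isfinite(dist.values)):
        raise ValueError("distance matrix has non-finite entries")
    clusters: dict[str, TreeNode] = {
        lab: TreeNode(name=lab) for lab in dist.labels
    }
    sizes = {lab: 1 for lab in dist.labels}
    d = {
        frozenset((a, b)): dist.get(a, b)
        for a, b in combinations(dist.labels, 2)
    }
    while len(clusters) > 1:
        best = min(
            (pair for pair in d if pair <= set(clusters)),
            key=lambda p: (d[p], tuple(sorted(p))),
        )
        a, b = sorted(best)
        height = d[best] / 2.0
        merged = TreeNode(
            name=None, height=height, children=[clusters[a], clusters[b]]
        )
        size_a, size_b = sizes[a], sizes[b]
        for other in list(clusters):
            if other in (a, b):
                continue
            da = d[frozenset((a, other))]
            db = d[frozenset((b, other))]
            d[frozenset((a, other))] = (size_a * da + size_b * db) / (
                size_a + size_b
            )
        del clusters[b], sizes[b]
        clusters[a] = merged
        sizes[a] = size_a + size_b
    return next(iter(clusters.values()))


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string produced by :meth:`TreeNode.to_newick`."""
    text = text.strip().rstrip(";")
    pos = 0

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = []
            while True:
                child, length = parse_node()
                child_pair = (child, length)
                children.append(child_pair)
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
            node = TreeNode(name=None, children=[c for c, _ in children])
            # heights from the first child's branch length
            node.height = children[0][0].height + children[0][1]
        else:
            start = pos
            while pos < len(text) and text[pos] not in ":,()":
                pos += 1
            node = TreeNode(name=text[start:pos] or None)
        length = 0.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",()":
                pos += 1
            length = float(text[start:pos])
        return node, length

    root, _ = parse_node()
    return root


@dataclass
class FeatureTable:
    """Binary THP features per model: 1 = has, 0 = lacks, -1 = undefined."""

    model_ids: list[str]
    feature_names: list[str]
    values: np.ndarray  # (n_models, n_features) of {0, 1, -1}
    classes: dict[str, str] = field(default_factory=dict)  # feature -> class

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=int)
        if v.shape != (len(self.model_ids), len(self.feature_names)):
            raise ValueError("feature table shape mismatch")
        if not np.isin(v, (-1, 0, 1)).all():
            raise ValueError("feature values must be in {0, 1, -1}")
        self.values = v

    def row(self, model_id: str) -> np.ndarray:
        return self.values[self.model_ids.index(model_id)]


def feature_pairs(features: FeatureTable) -> list[tuple[str, str]]:
    """P_F: unordered model pairs with identical, fully specified features.

    Any model with an undefined (-1) entry is excluded from all pairs.
    """
    defined = [
        (mid, tuple(row))
        for mid, row in zip(features.model_ids, features.values)
        if -1 not in row
    ]
    pairs = [
        (a, b)
        for (a, fa), (b, fb) in combinations(defined, 2)
        if fa == fb
    ]
    if not pairs:
        raise ValueError(
            "no model pairs with identical fully-specified feature vectors; "
            "consider coarsening the feature classes"
        )
    return pairs


@dataclass
class RegressionFit:
    feature_names: list[str]  # after dropping aliased columns
    coefficients: dict[str, float]  # includes 'intercept'
    t_pvalues: dict[str, float]
    conf_int: dict[str, tuple[float, float]]  # 95% per-coefficient CI
    f_pvalue: float
    n_pairs: int
    alpha: float
    dropped: list[str] = field(default_factory=list)

    def significant(self, name: str) -> bool:
        """A coefficient counts as significant only when the regression
        itself beats the constant model (F-test) and its t-test rejects."""
        return self.f_pvalue < self.alpha and self.t_pvalues[name] < self.alpha


def thp_regression(
    pairs: list[tuple[str, str]],
    responses: dict[tuple[str, str], float],
    features: FeatureTable,
    alpha: float = 0.05,
) -> RegressionFit:
    """OLS of normalized similarities on feature vectors over P_F pairs.

    Design rows are ``[1, F_l]`` (the two models of a pair share F).  The
    response for a pair is its normalized similarity (global, or restricted
    to one subsystem's reactions upstream).  Aliased (collinear) feature
    columns are dropped with a warning — e.g. a feature nested inside
    another class.  No multiple-testing correction is applied.
    """
    rows, y = [], []
    for pair in pairs:
        key = pair if pair in responses else (pair[1], pair[0])
        if key not in responses:
            continue
        rows.append(features.row(pair[0]).astype(float))
        y.append(responses[key])
    if len(rows) <= len(features.feature_names) + 1:
        raise ValueError(
            f"{len(rows)} usable pairs cannot identify "
            f"{len(features.feature_names)} features"
        )
    F = np.asarray(rows)
    y = np.asarray(y, dtype=float)

    keep: list[int] = []
    dropped: list[str] = []
    X = np.ones((F.shape[0], 1))
    for j in range(F.shape[1]):
        cand = np.hstack([X, F[:, [j]]])
        if np.linalg.matrix_rank(cand) > np.linalg.matrix_rank(X):
            X = cand
            keep.append(j)
        else:
            dropped.append(features.feature_names[j])
    if dropped:
        warnings.warn(
            f"dropped aliased feature columns: {dropped}", stacklevel=2
        )
    names = ["intercept"] + [features.feature_names[j] for j in keep]
    fit = sm_api.OLS(y, X).fit()
    f_p = float(fit.f_pvalue) if X.shape[1] > 1 else 1.0
    if np.isnan(f_p):
        f_p = 1.0
    ci = fit.conf_int(alpha=0.05)
    return RegressionFit(
        feature_names=names[1:],
        coefficients=dict(zip(names, map(float, fit.params))),
        t_pvalues=dict(zip(names, map(float, fit.pvalues))),
        conf_int={
            name: (float(lo), float(hi))
            for name, (lo, hi) in zip(names, np.asarray(ci))
        },
        f_pvalue=f_p,
        n_pairs=len(y),
        alpha=alpha,
        dropped=dropped,
    )


def coefficient_tree(coefficients: dict[str, float]) -> TreeNode:
    """UPGMA on absolute differences between per-feature coefficients."""
    names = sorted(coefficients)
    if len(names) < 2:
        raise ValueError("need at least two coefficients")
    n = len(names)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        D[i, j] = D[j, i] = abs(coefficients[names[i]] - coefficients[names[j]])
    return upgma(DistanceMatrix(labels=names, values=D))
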