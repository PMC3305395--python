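"""Global structure diagnostics: array clustering and sources of variation.

Hierarchical clustering of the sample profiles shows which design factor
dominates expression variation (lineage, in a well-sorted gonad time
course, with sex and stage secondary).  The complementary quantitative view
is a per-gene main-effects ANOVA over the design factors, aggregated to a
mean and median F ratio per factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .study import ExpressionStudy, StudyError

__all__ = [
    "Dendrogram",
    "VariationReport",
    "cluster_arrays",
    "sources_of_variation",
]

_LINKAGES = ("ward", "average", "complete")
_METRICS = ("squared_euclidean", "euclidean", "pearson_dissimilarity")


@dataclass
class Dendrogram:
    """Sample dendrogram: scipy linkage matrix plus leaf labels."""

    linkage: np.ndarray
    labels: tuple
    method: str
    metric: str

    def cut(self, k: int) -> dict:
        """Assignment of each sample to one of *k* flat clusters."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in flat)))

    def to_newick(self) -> str:
        """Newick string with merge-height differences as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return f"({render(tree.left, tree.dist)},{render(tree.right, tree.dist)});"


def cluster_arrays(
    study: ExpressionStudy,
    linkage: str = "ward",
    metric: str = "squared_euclidean",
) -> Dendrogram:
    """Cluster the sample profiles hierarchically.

    The default, Ward linkage on (squared) Euclidean distances, is Ward's
    minimum-variance criterion.  Alternates: average linkage with Euclidean
    distance, complete linkage with Pearson's dissimilarity (1 - r across
    genes, invariant to per-sample affine rescaling).
    """
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}, got {metric!r}")
    if study.matrix.shape[1] < 2:
        raise StudyError("need at least 2 samples to cluster")

    profiles = study.matrix.to_numpy(float).T  # samples x genes
    if metric == "pearson_dissimilarity":
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(profiles)
        corr = np.nan_to_num(corr, nan=0.0)  # constant profiles: r undefined -> 0
        np.fill_diagonal(corr, 1.0)
        dist = squareform(1.0 - corr, checks=False)
        dist = np.clip(dist, 0.0, None)
    else:
        dist = pdist(profiles, metric="euclidean")
        if metric == "squared_euclidean" and linkage != "ward":
            dist = dist**2
        # For Ward, scipy expects plain Euclidean distances and minimises the
        # within-cluster sum of squares — the classic squared-Euclidean Ward.
    if np.all(dist == 0.0):
        warnings.warn("constant expression matrix: all pairwise distances are zero")
    Z = hierarchy.linkage(dist, method=linkage)
    return Dendrogram(
        linkage=Z, labels=tuple(study.matrix.columns), method=linkage, metric=metric
    )


@dataclass
class VariationReport:
    """Per-factor aggregates of per-gene ANOVA F ratios, ordered by mean F."""

    table: pd.DataFrame        # index factor, columns mean_F, median_F, df1, df2
    f_values: pd.DataFrame     # genes x factors

    @property
    def ranking(self) -> tuple:
        return tuple(self.table.index)


def _dummies(series: pd.Series) -> np.ndarray:
    return pd.get_dummies(series, drop_first=True).to_numpy(float)


def _sse(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid**2).sum(axis=0)


def sources_of_variation(
    study: ExpressionStudy,
    factors: Sequence[str] = ("lineage", "sex", "stage"),
) -> VariationReport:
    """Main-effects ANOVA per gene; report mean and median F per factor.

    For each factor the F ratio compares the fit of the full main-effects
    model with the model omitting that factor (all other factors retained)
    against the full model's residual variance.
    """
    samples = study.samples.loc[list(study.matrix.columns)]
    blocks = {}
    for f in factors:
        if f not in samples.columns:
            raise StudyError(f"unknown design factor {f!r}")
        levels = samples[f].nunique()
        if levels < 2:
            raise StudyError(f"factor {f!r} has {levels} level(s); need >= 2")
        blocks[f] = _dummies(samples[f])

    n = len(samples)
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [blocks[f] for f in factors])
    rank_full = np.linalg.matrix_rank(X_full)
    df2 = n - rank_full
    if df2 <= 0:
        raise StudyError(
            "design leaves no residual degrees of freedom; replication "
            "within factor combinations is required"
        )

    Y = study.matrix.to_numpy(float).T  # samples x genes
    sse_full = _sse(X_full, Y)
    sse_full = np.maximum(sse_full, 0.0)

    rows = {}
    f_cols = {}
    for f in factors:
        X_red = np.hstack([intercept] + [blocks[g] for g in factors if g != f])
        df1 = rank_full - np.linalg.matrix_rank(X_red)
        sse_red = _sse(X_red, Y)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ((sse_red - sse_full) / df1) / (sse_full / df2)
        F = np.clip(np.nan_to_num(F, nan=0.0, posinf=np.inf), 0.0, None)
        f_cols[f] = F
        rows[f] = {
            "mean_F": float(F[np.isfinite(F)].mean()),
            "median_F": float(np.median(F[np.isfinite(F)])),
            "df1": int(df1),
            "df2": int(df2),
        }

    table = pd.DataFrame(rows).T.sort_values("mean_F", ascending=False)
    table[["df1", "df2"]] = table[["df1", "df2"]].astype(int)
    f_values = pd.DataFrame(f_cols, index=study.matrix.index)
    return VariationReport(table=table, f_values=f_values)
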