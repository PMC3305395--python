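"""List-level false discovery rate by sample-label permutation.

The per-cluster p-values feeding a list recipe are deliberately left
uncorrected; error control happens on the composed list itself.  The arrays
participating in a recipe's comparisons are randomly reassigned to the
recipe's groups (group sizes preserved), the full series of comparison
steps is re-evaluated on the relabelled columns, and the resulting list
size recorded.  Repeating this ``n_permutations`` times gives a null
distribution of list sizes; the FDR is the mean permuted count divided by
the observed count.  Set-difference removal steps (e.g. subtracting the
deduced Leydig list from an endothelial list) are ignored during the
permutation runs.

Counts are tracked both at transcript-cluster and at deduplicated gene
level; the FDR reported uses gene-level counts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .signatures import Recipe, evaluate_recipe
from .study import ExpressionStudy, ThresholdConfig

__all__ = ["FdrResult", "permutation_fdr", "recipe_seed"]


@dataclass
class FdrResult:
    list_name: str
    observed_clusters: int
    observed_genes: int
    permuted_cluster_counts: np.ndarray
    permuted_gene_counts: np.ndarray
    seed: int

    @property
    def mean_permuted(self) -> float:
        return float(self.permuted_gene_counts.mean())

    @property
    def median_permuted(self) -> float:
        return float(np.median(self.permuted_gene_counts))

    @property
    def mean_permuted_clusters(self) -> float:
        return float(self.permuted_cluster_counts.mean())

    @property
    def median_permuted_clusters(self) -> float:
        return float(np.median(self.permuted_cluster_counts))

    @property
    def fdr(self) -> float | None:
        """Mean permuted gene count over observed gene count (None if 0 observed)."""
        if self.observed_genes == 0:
            return None
        return self.mean_permuted / self.observed_genes

    def acceptable(self, cfg: ThresholdConfig) -> bool:
        return self.fdr is not None and self.fdr <= cfg.fdr_acceptable

    def summary_row(self, cfg: ThresholdConfig) -> dict:
        """One row of the FDR summary table (observed/permuted, both levels)."""
        return {
            "list": self.list_name,
            "observed_clusters": self.observed_clusters,
            "observed_genes": self.observed_genes,
            "mean_permuted_clusters": self.mean_permuted_clusters,
            "median_permuted_clusters": self.median_permuted_clusters,
            "mean_permuted_genes": self.mean_permuted,
            "median_permuted_genes": self.median_permuted,
            "fdr_percent": None if self.fdr is None else 100.0 * self.fdr,
            "acceptable": self.acceptable(cfg),
        }


def recipe_seed(seed: int, name: str) -> int:
    """Derive an independent, stable sub-seed per named recipe.

    Adding or reordering recipes in an analysis must not reshuffle the
    permutations of existing ones, so each recipe's stream depends only on
    the run seed and its own name.
    """
    return int(
        np.random.SeedSequence([seed, zlib.crc32(name.encode())]).generate_state(1)[0]
        % (2**31)
    )


def permutation_fdr(
    study: ExpressionStudy,
    recipe: Recipe,
    cfg: ThresholdConfig,
    seed: int = 0,
) -> FdrResult:
    """Estimate the FDR of *recipe* on *study* by label permutation.

    Only the samples referenced by the recipe's comparison steps
    participate; their assignment to groups is permuted uniformly with
    group sizes preserved, sampling with replacement from the permutation
    space.  A fixed seed reproduces counts bit-exactly.
    """
    groups = sorted(recipe.groups())
    columns: dict = {g: study.group_samples(g) for g in groups}
    pool = [c for g in groups for c in columns[g]]
    sizes = [len(columns[g]) for g in groups]

    observed = evaluate_recipe(study, recipe, cfg)
    observed_genes = len(study.symbols_of(observed))

    derived = recipe_seed(seed, recipe.name)
    rng = np.random.default_rng(derived)
    cluster_counts = np.empty(cfg.n_permutations, dtype=int)
    gene_counts = np.empty(cfg.n_permutations, dtype=int)
    for i in range(cfg.n_permutations):
        shuffled = list(rng.permutation(pool))
        column_map = {}
        offset = 0
        for g, size in zip(groups, sizes):
            column_map[g] = shuffled[offset : offset + size]
            offset += size
        ids = evaluate_recipe(
            study, recipe, cfg, column_map=column_map, skip_removals=True
        )
        cluster_counts[i] = len(ids)
        gene_counts[i] = len(study.symbols_of(ids))

    return FdrResult(
        list_name=recipe.name,
        observed_clusters=len(observed),
        observed_genes=observed_genes,
        permuted_cluster_counts=cluster_counts,
        permuted_gene_counts=gene_counts,
        seed=derived,
    )
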