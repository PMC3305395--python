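"""List algebra: recipes composing pairwise comparisons into gene lists.

A :class:`Recipe` is the declarative form of the prose rules used to define
lineage signatures: an ordered collection of comparison steps (intersection
of the clusters with a wanted call), exclusion steps (comparison-based
removal, re-evaluated under label permutation), and removal steps (set
difference against a previously computed list, skipped under permutation).
Encoding the rules as data means the observed list and its permutation-FDR
re-runs are guaranteed to evaluate the same series of operations.

The recipes implemented here:

* sex-specific lineage enrichment/depletion — the focal population differs
  from its opposite-sex counterpart and from every other same-sex lineage;
* sex-independent lineage enrichment/depletion — lineage-specific within
  both sexes and identically expressed between XX and XY of the focal
  lineage (the sexually undifferentiated progenitor signature);
* steroidogenic (Leydig) contaminant deduction — genes over/under-expressed
  in both the XY interstitium and the XY endothelial fraction, reflecting
  ectopic reporter expression that co-sorts Leydig cells with endothelium;
* single-comparison sexual dimorphism per lineage with cross-lineage
  overlap counting.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import pairwise
from .study import LINEAGES, ExpressionStudy, Group, StudyError, ThresholdConfig

__all__ = [
    "Comparison",
    "Exclusion",
    "Removal",
    "Recipe",
    "GeneList",
    "make_gene_list",
    "evaluate_recipe",
    "enriched_recipe",
    "depleted_recipe",
    "lineage_enriched",
    "lineage_depleted",
    "leydig_recipe",
    "leydig_genes",
    "subtract_list",
    "dimorphic_recipe",
    "dimorphic_overlaps",
    "shared_pair_list",
]


# ------------------------------------------------------------------ recipe IR
@dataclass(frozen=True)
class Comparison:
    """Keep clusters whose call for (a vs b) equals ``wanted``."""

    a: Group
    b: Group
    wanted: str  # "higher" | "lower" | "identical"


@dataclass(frozen=True)
class Exclusion:
    """Drop clusters whose call for (a vs b) equals ``call``.

    Re-evaluated during permutation runs (it is part of the comparison
    series, e.g. the differential-repression elimination step of the
    priming recipes).
    """

    a: Group
    b: Group
    call: str


@dataclass(frozen=True)
class Removal:
    """Set difference against a fixed, separately computed list.

    Ignored during permutation runs, mirroring how list subtractions (such
    as removing deduced Leydig genes from endothelial lists) are excluded
    from FDR estimation.
    """

    list_name: str
    cluster_ids: frozenset


@dataclass(frozen=True)
class Recipe:
    name: str
    steps: tuple = ()

    def __post_init__(self) -> None:
        if not any(isinstance(s, Comparison) for s in self.steps):
            raise ValueError(f"recipe {self.name!r} has no comparison step")

    @property
    def comparisons(self) -> tuple:
        return tuple(s for s in self.steps if isinstance(s, (Comparison, Exclusion)))

    @property
    def removals(self) -> tuple:
        return tuple(s for s in self.steps if isinstance(s, Removal))

    def groups(self) -> set[Group]:
        """Groups participating in comparison/exclusion steps."""
        out: set[Group] = set()
        for s in self.comparisons:
            out.add(s.a)
            out.add(s.b)
        return out

    def with_removal(self, removal: "GeneList") -> "Recipe":
        step = Removal(removal.name, frozenset(removal.cluster_ids))
        return Recipe(self.name, self.steps + (step,))


# ------------------------------------------------------------------ gene list
@dataclass(frozen=True)
class GeneList:
    """A named set of transcript clusters with gene-level deduplication."""

    name: str
    cluster_ids: frozenset
    symbols: frozenset
    recipe: Recipe | None = None

    @property
    def gene_level_count(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.cluster_ids)

    def __contains__(self, cluster_id: str) -> bool:
        return cluster_id in self.cluster_ids

    def table(self, study: ExpressionStudy) -> pd.DataFrame:
        """Per-cluster table (cluster id, gene symbol), symbol-sorted."""
        ids = sorted(self.cluster_ids)
        return (
            pd.DataFrame(
                {
                    "cluster_id": ids,
                    "gene_symbol": study.clusters.loc[ids, "gene_symbol"].to_numpy(),
                }
            )
            .sort_values(["gene_symbol", "cluster_id"])
            .reset_index(drop=True)
        )


def make_gene_list(
    study: ExpressionStudy,
    name: str,
    cluster_ids: Iterable[str],
    recipe: Recipe | None = None,
) -> GeneList:
    ids = frozenset(cluster_ids)
    return GeneList(
        name=name,
        cluster_ids=ids,
        symbols=frozenset(study.symbols_of(ids)),
        recipe=recipe,
    )


# --------------------------------------------------------------- evaluation
def evaluate_recipe(
    study: ExpressionStudy,
    recipe: Recipe,
    cfg: ThresholdConfig,
    column_map: Mapping[Group, Sequence[str]] | None = None,
    skip_removals: bool = False,
    _cache: dict | None = None,
) -> frozenset:
    """Evaluate a recipe to the set of retained cluster ids.

    ``column_map`` overrides the group -> sample-column resolution (used by
    the permutation engine to re-run the same series of operations on
    relabelled arrays).  Intersection steps commute; removal steps apply
    last and are skipped when ``skip_removals`` is set.
    """
    cache: dict = {} if _cache is None else _cache

    def calls_for(a: Group, b: Group) -> pd.DataFrame:
        key = (a, b)
        if key not in cache:
            if column_map is None:
                cache[key] = pairwise.compare_groups(study, a, b, cfg)
            else:
                cache[key] = pairwise.compare_columns(
                    study, list(column_map[a]), list(column_map[b]), cfg
                )
        return cache[key]

    kept: frozenset | None = None
    for step in recipe.steps:
        if isinstance(step, Comparison):
            ids = pairwise.call_ids(calls_for(step.a, step.b), step.wanted)
            kept = ids if kept is None else kept & ids
    if kept is None:  # pragma: no cover - guarded by Recipe.__post_init__
        raise ValueError("recipe without comparisons")
    for step in recipe.steps:
        if isinstance(step, Exclusion):
            kept -= pairwise.call_ids(calls_for(step.a, step.b), step.call)
    if not skip_removals:
        for step in recipe.removals:
            kept -= step.cluster_ids
    return frozenset(kept)


def _check_groups(study: ExpressionStudy, recipe: Recipe) -> None:
    missing = [g for g in recipe.groups() if len(study.group_samples(g)) == 0]
    if missing:
        raise StudyError(
            f"recipe {recipe.name!r}: missing sample groups "
            + ", ".join(str(g) for g in sorted(missing))
        )


def _other_lineages(focal: str, lineages: Sequence[str] = LINEAGES) -> list[str]:
    return [lin for lin in lineages if lin != focal]


def _other_sex(sex: str) -> str:
    return {"XX": "XY", "XY": "XX"}[sex]


# ------------------------------------------------------------ recipe builders
def enriched_recipe(
    lineage: str,
    sex: str,
    stage: str,
    mode: str = "sex_specific",
    lineages: Sequence[str] = LINEAGES,
) -> Recipe:
    """Lineage-enrichment recipe for one focal population.

    ``sex_specific``: higher than the opposite-sex focal lineage and higher
    than every other same-sex lineage at the stage.  ``sex_independent``:
    higher than every other lineage within each sex separately, and
    identical between XX and XY of the focal lineage.
    """
    return _signature_recipe(lineage, sex, stage, mode, "higher", lineages)


def depleted_recipe(
    lineage: str,
    sex: str,
    stage: str,
    mode: str = "sex_specific",
    lineages: Sequence[str] = LINEAGES,
) -> Recipe:
    """As :func:`enriched_recipe` with every direction reversed: the focal
    population is lower than the opposite-sex counterpart (sex-specific) and
    lower than every other lineage."""
    return _signature_recipe(lineage, sex, stage, mode, "lower", lineages)


def _signature_recipe(lineage, sex, stage, mode, direction, lineages) -> Recipe:
    focal = Group(lineage, sex, stage)
    kind = "enriched" if direction == "higher" else "depleted"
    steps: list = []
    if mode == "sex_specific":
        steps.append(Comparison(focal, Group(lineage, _other_sex(sex), stage), direction))
        for other in _other_lineages(lineage, lineages):
            steps.append(Comparison(focal, Group(other, sex, stage), direction))
    elif mode == "sex_independent":
        for s in ("XY", "XX"):
            own = Group(lineage, s, stage)
            for other in _other_lineages(lineage, lineages):
                steps.append(Comparison(own, Group(other, s, stage), direction))
        steps.append(
            Comparison(Group(lineage, "XX", stage), Group(lineage, "XY", stage), "identical")
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    name = f"{kind}_{mode}_{lineage}_{sex if mode == 'sex_specific' else 'both'}_{stage}"
    return Recipe(name, tuple(steps))


def lineage_enriched(
    study: ExpressionStudy,
    lineage: str,
    sex: str,
    stage: str,
    cfg: ThresholdConfig,
    mode: str = "sex_specific",
) -> GeneList:
    recipe = enriched_recipe(lineage, sex, stage, mode)
    _check_groups(study, recipe)
    ids = evaluate_recipe(study, recipe, cfg)
    return make_gene_list(study, recipe.name, ids, recipe)


def lineage_depleted(
    study: ExpressionStudy,
    lineage: str,
    sex: str,
    stage: str,
    cfg: ThresholdConfig,
    mode: str = "sex_specific",
) -> GeneList:
    recipe = depleted_recipe(lineage, sex, stage, mode)
    _check_groups(study, recipe)
    ids = evaluate_recipe(study, recipe, cfg)
    return make_gene_list(study, recipe.name, ids, recipe)


# ----------------------------------------------------------------- Leydig
def leydig_recipe(stage: str, direction: str = "enriched") -> Recipe:
    """Deduce steroidogenic-contaminant genes shared by the XY interstitium
    and the XY "endothelial" fraction at a late stage.

    Enriched variant: higher in XY interstitium than XY supporting and germ
    cells; higher in XY endothelium than XY supporting and germ cells;
    higher in XY interstitium than XX stroma; higher in XY endothelium than
    XX endothelium.  The depleted variant reverses every direction.
    """
    call = "higher" if direction == "enriched" else "lower"
    inter = Group("interstitial_stromal", "XY", stage)
    endo = Group("endothelial", "XY", stage)
    steps = (
        Comparison(inter, Group("supporting", "XY", stage), call),
        Comparison(inter, Group("germ", "XY", stage), call),
        Comparison(endo, Group("supporting", "XY", stage), call),
        Comparison(endo, Group("germ", "XY", stage), call),
        Comparison(inter, Group("interstitial_stromal", "XX", stage), call),
        Comparison(endo, Group("endothelial", "XX", stage), call),
    )
    return Recipe(f"leydig_{direction}_{stage}", steps)


def leydig_genes(
    study: ExpressionStudy,
    stage: str,
    cfg: ThresholdConfig,
    direction: str = "enriched",
) -> GeneList:
    recipe = leydig_recipe(stage, direction)
    _check_groups(study, recipe)
    ids = evaluate_recipe(study, recipe, cfg)
    return make_gene_list(study, recipe.name, ids, recipe)


def subtract_list(study: ExpressionStudy, target: GeneList, removal: GeneList) -> GeneList:
    """Set difference on cluster ids, recorded as a removal step.

    The removal is flagged in the recipe so permutation-FDR re-runs skip it.
    """
    recipe = target.recipe.with_removal(removal) if target.recipe else None
    return make_gene_list(
        study,
        f"{target.name}_minus_{removal.name}",
        target.cluster_ids - removal.cluster_ids,
        recipe,
    )


# ------------------------------------------------- single-comparison dimorphism
def dimorphic_recipe(lineage: str, stage: str, sex: str) -> Recipe:
    """Single pairwise comparison: higher in *sex* than the opposite sex."""
    focal = Group(lineage, sex, stage)
    other = Group(lineage, _other_sex(sex), stage)
    return Recipe(f"dimorphic_{lineage}_{sex}_{stage}", (Comparison(focal, other, "higher"),))


@dataclass
class OverlapResult:
    """Cross-lineage overlap of single-comparison sexually dimorphic genes.

    ``assignment[sex]`` maps each gene symbol to the frozenset of lineages
    it is counted in; ``table[sex]`` counts genes per lineage combination.
    When a gene's transcript clusters disagree, the gene is counted in the
    highest-overlap category (the cluster covering the most lineages; ties
    broken deterministically by sorted lineage tuple).
    """

    lists: dict
    assignment: dict
    table: dict

    def count(self, sex: str, lineages: Iterable[str]) -> int:
        return self.table[sex].get(frozenset(lineages), 0)


def dimorphic_overlaps(
    study: ExpressionStudy,
    stage: str,
    cfg: ThresholdConfig,
    lineages: Sequence[str] | None = None,
) -> OverlapResult:
    lineages = tuple(lineages) if lineages is not None else study.lineages
    lists: dict = {}
    # cluster -> set of lineages in which it is dimorphic, per over-expressing sex
    cluster_hits: dict = {"XX": {}, "XY": {}}
    for lineage in lineages:
        calls = pairwise.compare_groups(
            study, Group(lineage, "XY", stage), Group(lineage, "XX", stage), cfg
        )
        for sex, wanted in (("XY", "higher"), ("XX", "lower")):
            ids = pairwise.call_ids(calls, wanted)
            recipe = dimorphic_recipe(lineage, stage, sex)
            lists[(lineage, sex)] = make_gene_list(study, recipe.name, ids, recipe)
            for cid in ids:
                cluster_hits[sex].setdefault(cid, set()).add(lineage)

    assignment: dict = {}
    table: dict = {}
    for sex in ("XX", "XY"):
        per_gene: dict = {}
        for cid, lins in cluster_hits[sex].items():
            sym = study.clusters.at[cid, "gene_symbol"]
            if not isinstance(sym, str) or not sym:
                continue
            per_gene.setdefault(sym, []).append(frozenset(lins))
        chosen = {
            sym: max(sets, key=lambda s: (len(s), tuple(sorted(s, reverse=True))))
            for sym, sets in per_gene.items()
        }
        assignment[sex] = chosen
        table[sex] = dict(Counter(chosen.values()))
    return OverlapResult(lists=lists, assignment=assignment, table=table)


def shared_pair_list(
    study: ExpressionStudy,
    lineage_pair: tuple[str, str],
    sex: str,
    stage: str,
    cfg: ThresholdConfig,
) -> GeneList:
    """Genes dimorphic in exactly two lineages with convergent expression:
    identical between the two focal lineages (within *sex*) and higher in
    both than each of the remaining lineages."""
    a, b = lineage_pair
    steps: list = [
        Comparison(Group(a, sex, stage), Group(a, _other_sex(sex), stage), "higher"),
        Comparison(Group(b, sex, stage), Group(b, _other_sex(sex), stage), "higher"),
        Comparison(Group(a, sex, stage), Group(b, sex, stage), "identical"),
    ]
    for other in LINEAGES:
        if other in lineage_pair:
            continue
        steps.append(Comparison(Group(a, sex, stage), Group(other, sex, stage), "higher"))
        steps.append(Comparison(Group(b, sex, stage), Group(other, sex, stage), "higher"))
    recipe = Recipe(f"shared_{a}_{b}_{sex}_{stage}", tuple(steps))
    _check_groups(study, recipe)
    ids = evaluate_recipe(study, recipe, cfg)
    return make_gene_list(study, recipe.name, ids, recipe)
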