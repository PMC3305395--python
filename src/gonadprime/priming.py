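"""Lineage-priming classification.

A gene is *primed* when the sexually undifferentiated XX and XY progenitors
of a lineage express it identically, and during differentiation one sex
represses it while the other maintains or activates it.  Three methods of
increasing stringency are implemented:

``all``
    Priming pattern alone: identical between the sexes at the start stage,
    higher in the retaining sex at the end stage, repressed between start
    and end in the other sex, and not also repressed in the retaining sex
    (differential repression required).
``enriched``
    Additionally lineage-specifically enriched at the start stage in both
    sexes and at the end stage in the retaining sex.
``depleted``
    The mirror pattern for specifically repressed genes: identical at the
    start and lineage-specifically depleted in both sexes, activated by one
    sex while the other remains lineage- and sex-specifically depleted, with
    differential activation required.

Each primed gene is further tagged by the progenitor's expression level
relative to the differentiated cells: *similar* (identical between start
and end in the retaining sex) or *intermediate* (between the two sexes'
final levels).  Counts are reported gene-level deduplicated; a symbol whose
transcript clusters land in both categories is counted as *other*, while a
symbol with one categorised cluster and one uncategorised cluster keeps the
categorised tag.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import pairwise
from .signatures import (
    Comparison,
    Exclusion,
    GeneList,
    Recipe,
    _check_groups,
    _other_lineages,
    evaluate_recipe,
    make_gene_list,
)
from .study import ExpressionStudy, Group, ThresholdConfig

__all__ = [
    "METHODS",
    "PrimingResult",
    "primed_recipe",
    "find_primed",
    "marker_recipe",
    "marker_denominator",
    "classify_level",
    "gene_level_tags",
    "priming_analysis",
]

METHODS = ("all", "enriched", "depleted")
_RETAINING = {"male": "XY", "female": "XX"}


def _sexes(sex_for: str) -> tuple[str, str]:
    try:
        retaining = _RETAINING[sex_for]
    except KeyError:
        raise ValueError(f"sex_for must be 'male' or 'female', got {sex_for!r}")
    other = "XX" if retaining == "XY" else "XY"
    return retaining, other


def primed_recipe(
    lineage: str,
    start_stage: str,
    end_stage: str,
    sex_for: str,
    method: str = "all",
    relaxed_start: bool = False,
) -> Recipe:
    """Recipe identifying *sex_for*-primed genes of a lineage.

    ``relaxed_start`` replaces the start-stage identity requirement with
    "higher in the retaining sex" — the prior-priming signature used when
    cross-referencing a data set whose progenitors have already begun
    diverging.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    rsex, osex = _sexes(sex_for)
    r_start, r_end = Group(lineage, rsex, start_stage), Group(lineage, rsex, end_stage)
    o_start, o_end = Group(lineage, osex, start_stage), Group(lineage, osex, end_stage)
    others = _other_lineages(lineage)

    steps: list = []
    if relaxed_start:
        steps.append(Comparison(r_start, o_start, "higher"))
    else:
        steps.append(Comparison(o_start, r_start, "identical"))

    if method in ("all", "enriched"):
        steps.append(Comparison(r_end, o_end, "higher"))          # retained in R
        steps.append(Comparison(o_start, o_end, "higher"))        # repressed in O
        if method == "enriched":
            for other in others:                                  # enriched at start
                steps.append(Comparison(r_start, Group(other, rsex, start_stage), "higher"))
            for other in others:
                steps.append(Comparison(o_start, Group(other, osex, start_stage), "higher"))
            for other in others:                                  # enriched at end in R
                steps.append(Comparison(r_end, Group(other, rsex, end_stage), "higher"))
        steps.append(Exclusion(r_start, r_end, "higher"))         # differential repression
    else:  # depleted
        for other in others:                                      # depleted at start
            steps.append(Comparison(r_start, Group(other, rsex, start_stage), "lower"))
        for other in others:
            steps.append(Comparison(o_start, Group(other, osex, start_stage), "lower"))
        steps.append(Comparison(r_end, o_end, "lower"))           # stays repressed in R
        for other in others:                                      # depleted at end in R
            steps.append(Comparison(r_end, Group(other, rsex, end_stage), "lower"))
        steps.append(Comparison(o_end, o_start, "higher"))        # activated in O
        steps.append(Exclusion(r_end, r_start, "higher"))         # differential activation

    suffix = "_relaxed" if relaxed_start else ""
    name = f"primed_{method}_{sex_for}_{lineage}_{start_stage}_to_{end_stage}{suffix}"
    return Recipe(name, tuple(steps))


def find_primed(
    study: ExpressionStudy,
    lineage: str,
    start_stage: str,
    end_stage: str,
    sex_for: str,
    cfg: ThresholdConfig,
    method: str = "all",
    relaxed_start: bool = False,
) -> GeneList:
    recipe = primed_recipe(lineage, start_stage, end_stage, sex_for, method, relaxed_start)
    _check_groups(study, recipe)
    ids = evaluate_recipe(study, recipe, cfg)
    return make_gene_list(study, recipe.name, ids, recipe)


# ------------------------------------------------------------- denominators
def marker_recipe(
    lineage: str, end_stage: str, sex_for: str, method: str = "all"
) -> Recipe:
    """The marker-list denominator matching a priming method.

    ``all``: every gene sexually dimorphic toward *sex_for* at the end
    stage.  ``enriched``: additionally lineage-specifically enriched in the
    retaining sex at the end stage.  ``depleted``: dimorphic toward the
    *other* sex at the end stage and lineage-specifically depleted in the
    retaining sex (the activated-elsewhere, repressed-here marker set).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    rsex, osex = _sexes(sex_for)
    r_end = Group(lineage, rsex, end_stage)
    o_end = Group(lineage, osex, end_stage)
    others = _other_lineages(lineage)

    steps: list = []
    if method in ("all", "enriched"):
        steps.append(Comparison(r_end, o_end, "higher"))
        if method == "enriched":
            for other in others:
                steps.append(Comparison(r_end, Group(other, rsex, end_stage), "higher"))
    else:
        steps.append(Comparison(r_end, o_end, "lower"))
        for other in others:
            steps.append(Comparison(r_end, Group(other, rsex, end_stage), "lower"))
    return Recipe(f"markers_{method}_{sex_for}_{lineage}_{end_stage}", tuple(steps))


def marker_denominator(
    study: ExpressionStudy,
    lineage: str,
    end_stage: str,
    sex_for: str,
    cfg: ThresholdConfig,
    method: str = "all",
) -> GeneList:
    recipe = marker_recipe(lineage, end_stage, sex_for, method)
    _check_groups(study, recipe)
    ids = evaluate_recipe(study, recipe, cfg)
    return make_gene_list(study, recipe.name, ids, recipe)


# ------------------------------------------------------------------- levels
def classify_level(
    study: ExpressionStudy,
    primed: GeneList,
    lineage: str,
    sex_for: str,
    start_stage: str,
    end_stage: str,
    cfg: ThresholdConfig,
    direction: str = "enriched",
) -> dict:
    """Tag each primed cluster similar / intermediate / other.

    *similar*: identically expressed in the retaining sex at start and end.
    *intermediate*: higher at the end than the start for maintained genes,
    higher at the start for depleted-primed genes (the progenitor sat
    between the two sexes' final levels).
    """
    if direction not in ("enriched", "depleted"):
        raise ValueError(f"direction must be enriched/depleted, got {direction!r}")
    rsex, _ = _sexes(sex_for)
    calls = pairwise.compare_groups(
        study, Group(lineage, rsex, end_stage), Group(lineage, rsex, start_stage), cfg
    )
    intermediate_call = "higher" if direction == "enriched" else "lower"
    tags = {}
    for cid in primed.cluster_ids:
        call = calls.at[cid, "call"]
        if call == "identical":
            tags[cid] = "similar"
        elif call == intermediate_call:
            tags[cid] = "intermediate"
        else:
            tags[cid] = "other"
    return tags


def gene_level_tags(study: ExpressionStudy, cluster_tags: dict) -> dict:
    """Collapse cluster tags to per-symbol tags.

    Clusters of one symbol falling into both the similar and intermediate
    categories make the gene *other*; a symbol with one categorised and one
    uncategorised cluster keeps the categorised tag.
    """
    per_symbol: dict = {}
    for cid, tag in cluster_tags.items():
        sym = study.clusters.at[cid, "gene_symbol"]
        if isinstance(sym, str) and sym:
            per_symbol.setdefault(sym, set()).add(tag)
    out = {}
    for sym, tags in per_symbol.items():
        defined = tags & {"similar", "intermediate"}
        if len(defined) == 1:
            out[sym] = next(iter(defined))
        else:
            out[sym] = "other"
    return out


# ------------------------------------------------------------------- bundle
@dataclass
class PrimingResult:
    """Primed gene lists for both sexes with level tags and denominators."""

    method: str
    lineage: str
    start_stage: str
    end_stage: str
    male_primed: GeneList
    female_primed: GeneList
    level_tags: dict       # sex_for -> {cluster_id: tag}
    gene_tags: dict        # sex_for -> {symbol: tag}
    male_markers: GeneList
    female_markers: GeneList

    def primed(self, sex_for: str) -> GeneList:
        return self.male_primed if sex_for == "male" else self.female_primed

    def markers(self, sex_for: str) -> GeneList:
        return self.male_markers if sex_for == "male" else self.female_markers

    def tag_counts(self, sex_for: str) -> dict:
        counts = {"similar": 0, "intermediate": 0, "other": 0}
        for tag in self.gene_tags[sex_for].values():
            counts[tag] += 1
        return counts


def priming_analysis(
    study: ExpressionStudy,
    lineage: str,
    start_stage: str,
    end_stage: str,
    cfg: ThresholdConfig,
    method: str = "all",
) -> PrimingResult:
    """Run one priming method for both sexes and assemble the result."""
    direction = "depleted" if method == "depleted" else "enriched"
    primed = {}
    markers = {}
    level_tags = {}
    gene_tags = {}
    for sex_for in ("male", "female"):
        primed[sex_for] = find_primed(
            study, lineage, start_stage, end_stage, sex_for, cfg, method
        )
        markers[sex_for] = marker_denominator(
            study, lineage, end_stage, sex_for, cfg, method
        )
        level_tags[sex_for] = classify_level(
            study, primed[sex_for], lineage, sex_for, start_stage, end_stage, cfg, direction
        )
        gene_tags[sex_for] = gene_level_tags(study, level_tags[sex_for])
    return PrimingResult(
        method=method,
        lineage=lineage,
        start_stage=start_stage,
        end_stage=end_stage,
        male_primed=primed["male"],
        female_primed=primed["female"],
        level_tags=level_tags,
        gene_tags=gene_tags,
        male_markers=markers["male"],
        female_markers=markers["female"],
    )
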