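"""Symbol-based integration of a second expression study.

A mixed-population time course (e.g. sorted Sf1-EGFP urogenital-ridge
cells, which contain supporting and interstitial/stromal lineages) can
reach earlier stages than lineage-pure sorts, but its primed genes must be
restricted to the lineage of interest before interpretation.  Because the
two studies use different array platforms, transcript-cluster ids are never
compared across studies; the integration is membership-only, keyed on
normalised gene symbols.

Two restriction methods are provided: retain only primed genes whose
symbol also appears in the reference study's lineage-enriched lists
(rigorous), or remove genes attributable to the interstitial/stromal
population via a three-step subtraction (permissive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

from . import pairwise
from .signatures import GeneList, Group, make_gene_list
from .study import ExpressionStudy, ThresholdConfig

__all__ = [
    "normalize_symbol",
    "symbol_map",
    "restrict_by_enrichment",
    "interstromal_removal_set",
    "restrict_by_removal",
    "primed_overlap_report",
    "start_point_stability",
]

logger = logging.getLogger(__name__)


def normalize_symbol(symbol: str) -> str:
    """Canonical mouse-style capitalisation (first letter upper, rest lower)."""
    s = str(symbol).strip()
    if not s:
        return ""
    return s[0].upper() + s[1:].lower()


def _norm_set(symbols: Iterable[str]) -> frozenset:
    out = set()
    dropped = 0
    for s in symbols:
        n = normalize_symbol(s)
        if n:
            out.add(n)
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d empty/ambiguous symbols during normalisation", dropped)
    return frozenset(out)


def symbol_map(study: ExpressionStudy) -> dict:
    """Normalised symbol -> set of cluster ids carrying it in *study*."""
    out: dict = {}
    for cid, sym in study.clusters["gene_symbol"].items():
        n = normalize_symbol(sym) if isinstance(sym, str) else ""
        if n:
            out.setdefault(n, set()).add(cid)
    return out


def restrict_by_enrichment(
    study_b: ExpressionStudy, primed_b: GeneList, enriched_a: GeneList
) -> GeneList:
    """Keep primed_b members whose symbol appears in the reference
    lineage-enriched list from study A."""
    keep_symbols = _norm_set(enriched_a.symbols)
    ids = {
        cid
        for cid in primed_b.cluster_ids
        if normalize_symbol(study_b.clusters.at[cid, "gene_symbol"]) in keep_symbols
    }
    return make_gene_list(
        study_b, f"{primed_b.name}_in_{enriched_a.name}", ids, primed_b.recipe
    )


def interstromal_removal_set(
    study_a: ExpressionStudy, stage: str, sex: str, cfg: ThresholdConfig
) -> GeneList:
    """Genes attributable to the interstitial/stromal population, by the
    three-step subtraction on the reference (lineage-sorted) study.

    1. Genes higher in the *sex* interstitium/stroma than the same-sex
       supporting cells at *stage*.
    2. Genes dimorphic in both the supporting cells and the
       interstitium/stroma (higher in *sex* in each), minus step 1.
    3. All genes dimorphic in the interstitium/stroma (higher in *sex*),
       minus the step-2 remainder.

    The result contains genes sexually dimorphic in the interstitial/stromal
    cells and not the supporting cells, plus genes dimorphic in both if
    their expression is higher in the interstitial/stromal cells.
    """
    other = {"XX": "XY", "XY": "XX"}[sex]
    inter = Group("interstitial_stromal", sex, stage)
    inter_o = Group("interstitial_stromal", other, stage)
    supp = Group("supporting", sex, stage)
    supp_o = Group("supporting", other, stage)

    int_over_supp = pairwise.call_ids(
        pairwise.compare_groups(study_a, inter, supp, cfg), "higher"
    )
    supp_dimorphic = pairwise.call_ids(
        pairwise.compare_groups(study_a, supp, supp_o, cfg), "higher"
    )
    int_dimorphic = pairwise.call_ids(
        pairwise.compare_groups(study_a, inter, inter_o, cfg), "higher"
    )

    step1 = int_over_supp
    step2 = (supp_dimorphic & int_dimorphic) - step1
    step3 = int_dimorphic - step2
    return make_gene_list(study_a, f"interstromal_removal_{sex}_{stage}", step3)


def restrict_by_removal(
    study_b: ExpressionStudy, primed_b: GeneList, removal_a: GeneList
) -> GeneList:
    """Drop primed_b members whose symbol is in the removal set from study A."""
    drop = _norm_set(removal_a.symbols)
    ids = {
        cid
        for cid in primed_b.cluster_ids
        if normalize_symbol(study_b.clusters.at[cid, "gene_symbol"]) not in drop
    }
    return make_gene_list(
        study_b, f"{primed_b.name}_minus_{removal_a.name}", ids, primed_b.recipe
    )


def primed_overlap_report(
    primed_a: GeneList,
    primed_b: GeneList,
    dimorphic_a_at_start: GeneList,
    signature_a: GeneList | None = None,
) -> dict:
    """Partition study-B primed symbols by their status in study A.

    Categories (mutually exclusive, in priority order; counts sum to the
    number of study-B primed symbols):

    - ``primed_in_both``: also primed in study A;
    - ``dimorphic_with_signature``: already sexually dimorphic at study A's
      start stage but matching the relaxed prior-priming pattern (the primed
      sex already higher at the start);
    - ``dimorphic_without_signature``: dimorphic at study A's start with no
      priming signature;
    - ``not_detected``: absent from study A's primed/dimorphic sets.
    """
    b_symbols = _norm_set(primed_b.symbols)
    a_primed = _norm_set(primed_a.symbols)
    a_dimorphic = _norm_set(dimorphic_a_at_start.symbols)
    a_signature = _norm_set(signature_a.symbols) if signature_a is not None else frozenset()

    categories = {
        "primed_in_both": set(),
        "dimorphic_with_signature": set(),
        "dimorphic_without_signature": set(),
        "not_detected": set(),
    }
    for sym in b_symbols:
        if sym in a_primed:
            categories["primed_in_both"].add(sym)
        elif sym in a_dimorphic and sym in a_signature:
            categories["dimorphic_with_signature"].add(sym)
        elif sym in a_dimorphic:
            categories["dimorphic_without_signature"].add(sym)
        else:
            categories["not_detected"].add(sym)
    return {
        "symbols": {k: frozenset(v) for k, v in categories.items()},
        "counts": {k: len(v) for k, v in categories.items()},
        "total": len(b_symbols),
    }


def start_point_stability(
    study: ExpressionStudy,
    lineage: str,
    earlier_stage: str,
    later_stage: str,
    end_stage: str,
    cfg: ThresholdConfig,
) -> dict:
    """Compare two candidate start points for the priming analysis.

    For the primed genes called from the *earlier* start, reports the
    fraction still identically expressed between the sexes at both candidate
    starts, and — among those — the fraction undergoing a concordant,
    significant shift in the same direction in both sexes between the two
    starts.  A high concordant-shift fraction indicates the progenitor
    transcriptome is still moving, confounding a start at the earlier stage.
    """
    from .priming import find_primed  # local import to avoid a cycle

    primed_ids: set = set()
    for sex_for in ("male", "female"):
        primed_ids |= find_primed(
            study, lineage, earlier_stage, end_stage, sex_for, cfg, "all"
        ).cluster_ids
    if not primed_ids:
        return {
            "n_primed": 0,
            "fraction_identical_both_starts": None,
            "fraction_concordant_shift": None,
        }

    identical_at = {}
    for stage in (earlier_stage, later_stage):
        calls = pairwise.compare_groups(
            study, Group(lineage, "XX", stage), Group(lineage, "XY", stage), cfg
        )
        identical_at[stage] = pairwise.call_ids(calls, "identical")
    stable = primed_ids & identical_at[earlier_stage] & identical_at[later_stage]

    concordant: set = set()
    calls_by_sex = {
        sex: pairwise.compare_groups(
            study,
            Group(lineage, sex, later_stage),
            Group(lineage, sex, earlier_stage),
            cfg,
        )
        for sex in ("XX", "XY")
    }
    for cid in stable:
        cx = calls_by_sex["XX"].at[cid, "call"]
        cy = calls_by_sex["XY"].at[cid, "call"]
        if cx == cy and cx in ("higher", "lower"):
            concordant.add(cid)

    return {
        "n_primed": len(primed_ids),
        "fraction_identical_both_starts": len(stable) / len(primed_ids),
        "fraction_concordant_shift": (len(concordant) / len(stable)) if stable else None,
    }
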