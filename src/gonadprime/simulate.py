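"""Synthetic sorted-cell expression studies with known ground truth.

The generator emulates the design of a lineage-sorted gonad time course:
four lineages x two sexes x three stages x three biological replicates
(72 arrays), log2 intensities with a per-gene baseline plus Gaussian
replicate noise, and planted genes following the expression templates the
pipeline is built to detect — lineage-specific enrichment and depletion
(sex-specific and sex-independent), sexual dimorphism in one or several
lineages, a steroidogenic contaminant shared by the XY interstitium and
the XY endothelial fraction at late stages, and primed genes of both sexes
with progenitor expression at the retained level (*similar*) or between
the two final levels (*intermediate*).

Because every planted gene's true group means are stored, the expected
membership of any list recipe can be computed by evaluating the recipe on
the noiseless means — an oracle sharing the list algebra but none of the
statistics — and recovery can be scored against it.

Run ``python -m gonadprime.simulate --out DIR --seed S`` to write the three
standard input files plus a ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .signatures import Comparison, Exclusion, GeneList, Recipe, Removal
from .study import LINEAGES, ExpressionStudy, Group, ThresholdConfig

__all__ = [
    "PATTERNS",
    "SimulationSpec",
    "GroundTruth",
    "RecoveryScore",
    "simulate_study",
    "score_recovery",
    "score_lists",
]

#: Planted expression patterns.  Primed templates live on the germ lineage
#: (start = first stage, end = last stage); signature templates on the
#: supporting lineage; dimorphism templates on the interstitium at the last
#: stage; the contaminant on XY interstitium + endothelium at late stages.
PATTERNS = (
    "enriched_sex_specific",
    "enriched_sex_independent",
    "depleted_sex_specific",
    "depleted_sex_independent",
    "dimorphic",
    "dimorphic_multilineage",
    "male_primed_similar",
    "male_primed_intermediate",
    "female_primed_similar",
    "female_primed_intermediate",
    "depleted_primed_male",
    "depleted_primed_female",
    "leydig_contaminant",
)


@dataclass(frozen=True)
class SimulationSpec:
    """Study design and plant roster for one synthetic data set.

    The defaults are the desk-scale emulation of the sorted-cell study
    design: 5,000 genes over 4 lineages x 2 sexes x 3 stages x 3
    replicates, planted effects of 2 log2 units against replicate noise of
    0.25 log2 units, and roughly 2% of genes planted per pattern.
    """

    n_genes: int = 5000
    lineages: tuple = LINEAGES
    sexes: tuple = ("XX", "XY")
    stages: tuple = ("E11.5", "E12.5", "E13.5")
    n_replicates: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.25
    delta: float = 2.0
    pattern_counts: Mapping[str, int] | None = None
    plants_per_pattern: int = 100
    duplicate_cluster_rate: float = 0.10
    lineage_effect_sd: float = 0.0
    sex_effect_sd: float = 0.0
    stage_effect_sd: float = 0.0
    unannotated_fraction: float = 0.01
    poor_quality_fraction: float = 0.02
    seed: int = 0

    def counts(self) -> dict:
        if self.pattern_counts is not None:
            unknown = set(self.pattern_counts) - set(PATTERNS)
            if unknown:
                raise ValueError(f"unknown patterns in roster: {sorted(unknown)}")
            return dict(self.pattern_counts)
        return {p: self.plants_per_pattern for p in PATTERNS}

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not math.isfinite(self.delta):
            raise ValueError("delta must be finite")
        if sum(self.counts().values()) > self.n_genes:
            raise ValueError("plant roster larger than the gene universe")
        if len(self.stages) < 2:
            raise ValueError("need at least two stages")


def _template_offsets(pattern: str, spec: SimulationSpec) -> dict:
    """Per-group offsets (in units of delta) for one planted pattern."""
    start, end = spec.stages[0], spec.stages[-1]
    mids = spec.stages[1:-1]
    off: dict = {}

    def put(lineage, sex, stage, value):
        off[Group(lineage, sex, stage)] = value

    if pattern == "enriched_sex_specific":
        put("supporting", "XY", spec.stages[1], 1.0)
    elif pattern == "enriched_sex_independent":
        for sex in spec.sexes:
            put("supporting", sex, start, 1.0)
    elif pattern == "depleted_sex_specific":
        put("supporting", "XY", spec.stages[1], -1.0)
    elif pattern == "depleted_sex_independent":
        for sex in spec.sexes:
            put("supporting", sex, start, -1.0)
    elif pattern == "dimorphic":
        put("interstitial_stromal", "XY", end, 1.0)
    elif pattern == "dimorphic_multilineage":
        put("supporting", "XY", end, 1.0)
        put("interstitial_stromal", "XY", end, 1.0)
    elif pattern in ("male_primed_similar", "female_primed_similar",
                     "male_primed_intermediate", "female_primed_intermediate"):
        retaining = "XY" if pattern.startswith("male") else "XX"
        other = "XX" if retaining == "XY" else "XY"
        # progenitors sit delta above the repressed level; for the
        # intermediate template the retaining sex activates a further delta,
        # so every planted contrast carries the full effect size
        top = 1.0 if pattern.endswith("similar") else 2.0
        put("germ", retaining, start, 1.0)
        put("germ", other, start, 1.0)
        put("germ", retaining, end, top)
        # other sex falls to baseline at the end; mid stages interpolate
        for i, mid in enumerate(mids, start=1):
            frac = i / (len(mids) + 1)
            put("germ", retaining, mid, 1.0 + (top - 1.0) * frac)
            put("germ", other, mid, 1.0 - frac)
    elif pattern in ("depleted_primed_male", "depleted_primed_female"):
        retaining = "XY" if pattern.endswith("_male") else "XX"
        other = "XX" if retaining == "XY" else "XY"
        put("germ", retaining, start, -1.0)
        put("germ", other, start, -1.0)
        put("germ", retaining, end, -1.0)
        for i, mid in enumerate(mids, start=1):
            frac = i / (len(mids) + 1)
            put("germ", retaining, mid, -1.0)
            put("germ", other, mid, -(1.0 - frac))
    elif pattern == "leydig_contaminant":
        for stage in spec.stages[1:]:
            put("interstitial_stromal", "XY", stage, 1.0)
            put("endothelial", "XY", stage, 1.0)
    else:  # pragma: no cover
        raise ValueError(f"unknown pattern {pattern!r}")
    return off


@dataclass
class RecoveryScore:
    name: str
    n_expected: int
    n_detected: int
    true_positives: int
    false_positives: int
    sensitivity: float | None
    fpr: float | None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class GroundTruth:
    """True pattern labels, group means, and expected list memberships."""

    spec: SimulationSpec
    genes: pd.DataFrame          # index symbol, column "pattern"
    group_means: pd.DataFrame    # genes x groups (columns: Group objects)
    clusters: pd.DataFrame       # index cluster_id, column "gene"

    def pattern_genes(self, *patterns: str) -> frozenset:
        mask = self.genes["pattern"].isin(patterns)
        return frozenset(self.genes.index[mask])

    @property
    def symbols(self) -> frozenset:
        return frozenset(self.genes.index)

    def _expected_call(self, a: Group, b: Group, cfg: ThresholdConfig) -> pd.Series:
        delta = self.group_means[a] - self.group_means[b]
        cut = math.log2(cfg.fc_cutoff)
        return pd.Series(
            np.select(
                [delta >= cut, delta <= -cut, delta == 0.0],
                ["higher", "lower", "identical"],
                default="neither",
            ),
            index=self.group_means.index,
        )

    def expected_members(self, recipe: Recipe, cfg: ThresholdConfig) -> frozenset:
        """Gene symbols a recipe should return, judged on the noiseless means.

        A difference call requires a true log2 offset of at least
        log2(fc_cutoff); an identity call requires a true offset of exactly
        zero.  Removal steps subtract the symbols of their stored clusters.
        """
        kept: pd.Series | None = None
        for step in recipe.steps:
            if isinstance(step, Comparison):
                hit = self._expected_call(step.a, step.b, cfg) == step.wanted
                kept = hit if kept is None else (kept & hit)
        if kept is None:
            raise ValueError("recipe without comparisons")
        for step in recipe.steps:
            if isinstance(step, Exclusion):
                kept &= self._expected_call(step.a, step.b, cfg) != step.call
        members = set(self.group_means.index[kept])
        for step in recipe.steps:
            if isinstance(step, Removal):
                removed = {
                    self.clusters.at[cid, "gene"]
                    for cid in step.cluster_ids
                    if cid in self.clusters.index
                }
                members -= removed
        return frozenset(members)


def simulate_study(spec: SimulationSpec) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate one study and its ground truth, deterministic under the seed."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.counts()
    groups = [
        Group(lin, sex, stage)
        for lin in spec.lineages
        for sex in spec.sexes
        for stage in spec.stages
    ]

    symbols = [f"G{i:05d}" for i in range(spec.n_genes)]
    patterns = []
    for p in PATTERNS:
        patterns.extend([p] * counts.get(p, 0))
    patterns.extend(["null"] * (spec.n_genes - len(patterns)))
    # plants occupy a random subset of the gene universe
    order = rng.permutation(spec.n_genes)
    pattern_by_gene = np.empty(spec.n_genes, dtype=object)
    pattern_by_gene[order] = patterns
    planted_mask = pattern_by_gene != "null"

    baselines = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    # planted templates describe expressed genes: keep their baselines
    # clear of the expression floor so the inclusion filter never hides them
    floor = 6.5
    low = planted_mask & (baselines < floor)
    while low.any():
        baselines[low] = rng.normal(spec.baseline_mean, spec.baseline_sd, low.sum())
        low = planted_mask & (baselines < floor)

    means = np.tile(baselines[:, None], (1, len(groups)))

    factor_sds = {
        "lineage": spec.lineage_effect_sd,
        "sex": spec.sex_effect_sd,
        "stage": spec.stage_effect_sd,
    }
    for factor, sd in factor_sds.items():
        if sd <= 0:
            continue
        levels = sorted({getattr(g, factor) for g in groups})
        effects = {lv: rng.normal(0.0, sd, spec.n_genes) for lv in levels}
        for j, g in enumerate(groups):
            means[:, j] += effects[getattr(g, factor)]

    template_cache = {p: _template_offsets(p, spec) for p in PATTERNS}
    col_of = {g: j for j, g in enumerate(groups)}
    for i in np.nonzero(planted_mask)[0]:
        for g, mult in template_cache[pattern_by_gene[i]].items():
            means[i, col_of[g]] += mult * spec.delta

    # transcript clusters: every gene one cluster; a random fraction of
    # genes carries a duplicate cluster with independent noise
    n_dup = int(round(spec.duplicate_cluster_rate * spec.n_genes))
    dup_genes = rng.choice(spec.n_genes, size=n_dup, replace=False)
    cluster_gene_idx = list(range(spec.n_genes)) + list(dup_genes)
    cluster_ids = [f"TC{k:06d}" for k in range(len(cluster_gene_idx))]

    # annotation defects on a fraction of null genes exercise the filter
    null_idx = np.nonzero(~planted_mask)[0]
    n_unannot = int(round(spec.unannotated_fraction * spec.n_genes))
    n_poor = int(round(spec.poor_quality_fraction * spec.n_genes))
    defect = rng.choice(null_idx, size=min(n_unannot + n_poor, len(null_idx)), replace=False)
    unannotated = set(defect[:n_unannot].tolist())
    poor_quality = set(defect[n_unannot:].tolist())

    sample_ids, sample_rows, sample_group = [], [], []
    for g in groups:
        for r in range(1, spec.n_replicates + 1):
            sample_ids.append(f"{g.lineage}_{g.sex}_{g.stage}_r{r}")
            sample_rows.append(
                {"lineage": g.lineage, "sex": g.sex, "stage": g.stage, "replicate": r}
            )
            sample_group.append(col_of[g])

    cluster_means = means[cluster_gene_idx][:, sample_group]
    noise = (
        rng.normal(0.0, spec.noise_sd, cluster_means.shape)
        if spec.noise_sd > 0
        else np.zeros_like(cluster_means)
    )
    matrix = pd.DataFrame(cluster_means + noise, index=cluster_ids, columns=sample_ids)

    samples = pd.DataFrame(sample_rows, index=pd.Index(sample_ids, name="sample_id"))
    gene_of_cluster = [symbols[i] for i in cluster_gene_idx]
    clusters = pd.DataFrame(
        {
            "gene_symbol": [
                "" if i in unannotated else symbols[i] for i in cluster_gene_idx
            ],
            "annotation_quality": [
                "other" if i in poor_quality else "best" for i in cluster_gene_idx
            ],
            "is_control": False,
        },
        index=pd.Index(cluster_ids, name="cluster_id"),
    )

    study = ExpressionStudy(matrix=matrix, samples=samples, clusters=clusters)
    truth = GroundTruth(
        spec=spec,
        genes=pd.DataFrame({"pattern": pattern_by_gene}, index=pd.Index(symbols, name="gene")),
        group_means=pd.DataFrame(means, index=symbols, columns=groups),
        clusters=pd.DataFrame(
            {"gene": gene_of_cluster}, index=pd.Index(cluster_ids, name="cluster_id")
        ),
    )
    return study, truth


# ------------------------------------------------------------------- scoring
def score_recovery(
    truth: GroundTruth,
    detected: Iterable[str],
    expected: Iterable[str],
    name: str = "",
    universe: Iterable[str] | None = None,
) -> RecoveryScore:
    """Confusion counts of a detected symbol set against an expected set.

    The false-positive rate denominator is the gene universe minus the
    expected genes (all simulated genes by default).
    """
    detected = set(detected)
    expected = set(expected)
    universe = set(universe) if universe is not None else set(truth.symbols)
    tp = len(detected & expected)
    fp = len(detected - expected)
    negatives = len(universe - expected)
    return RecoveryScore(
        name=name,
        n_expected=len(expected),
        n_detected=len(detected),
        true_positives=tp,
        false_positives=fp,
        sensitivity=(tp / len(expected)) if expected else None,
        fpr=(fp / negatives) if negatives else None,
    )


def score_lists(
    truth: GroundTruth,
    lists: Mapping[str, GeneList],
    cfg: ThresholdConfig,
) -> pd.DataFrame:
    """Score each recipe-backed gene list against its noiseless expectation."""
    rows = []
    for name, gl in lists.items():
        if gl.recipe is None:
            raise ValueError(f"list {name!r} carries no recipe to derive truth from")
        expected = truth.expected_members(gl.recipe, cfg)
        rows.append(score_recovery(truth, gl.symbols, expected, name=name).to_dict())
    return pd.DataFrame(rows).set_index("name")


# ----------------------------------------------------------------------- CLI
def _main(argv=None) -> None:  # pragma: no cover - thin wrapper
    import argparse

    from .study import write_study

    ap = argparse.ArgumentParser(description="regenerate synthetic study fixtures")
    ap.add_argument("--out", required=True, help="output directory")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-genes", type=int, default=SimulationSpec.n_genes)
    args = ap.parse_args(argv)

    # keep the default ~2%-per-pattern roster when the universe is scaled
    spec = SimulationSpec(
        n_genes=args.n_genes,
        plants_per_pattern=max(1, args.n_genes // 50),
        seed=args.seed,
    )
    study, truth = simulate_study(spec)
    paths = write_study(study, args.out)
    truth_path = f"{args.out}/truth.tsv"
    truth.genes.to_csv(truth_path, sep="\t")
    print(f"wrote {paths['matrix']}, {paths['samples']}, {paths['annotation']}, {truth_path}")


if __name__ == "__main__":  # pragma: no cover
    _main()
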