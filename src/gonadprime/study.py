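"""Containers, file I/O, and the inclusion filter for sorted-cell expression studies.

An :class:`ExpressionStudy` bundles a log2 intensity matrix (transcript
clusters x samples) with two annotation tables: a sample sheet describing
the sorting design (lineage, sex, stage, replicate) and a transcript-cluster
annotation (gene symbol, annotation quality).  All downstream analysis —
pairwise comparisons, list recipes, priming classification — operates on a
study that has passed :func:`filter_clusters`, which applies the study-wide
inclusion criteria: best annotation quality, a non-empty gene symbol, and
expression above a log2 floor in enough replicates of at least one sample
group.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LINEAGES",
    "SEXES",
    "Group",
    "ThresholdConfig",
    "ExpressionStudy",
    "StudyError",
    "ConfigError",
    "load_study",
    "write_study",
    "filter_clusters",
]

#: Canonical lineage labels.  "interstitial_stromal" covers the XY
#: interstitium and the XX stroma: one lineage with sex-dependent naming.
LINEAGES = ("supporting", "interstitial_stromal", "germ", "endothelial")
SEXES = ("XX", "XY")

_LINEAGE_ALIASES = {
    "interstitial": "interstitial_stromal",
    "interstitium": "interstitial_stromal",
    "stroma": "interstitial_stromal",
    "stromal": "interstitial_stromal",
    "interstitial/stromal": "interstitial_stromal",
}

#: Annotation values mapped to the "best" quality tier: cross-hybridization
#: category 1 (perfect match) on Gene ST arrays, annotation grades A/B on
#: 430 2.0 arrays.
_BEST_QUALITY = {"1", "A", "B", "best"}


class StudyError(ValueError):
    """Malformed study inputs (duplicate/missing ids, non-numeric cells)."""


class ConfigError(ValueError):
    """Threshold configuration incompatible with the study design."""


@dataclass(frozen=True, order=True)
class Group:
    """A sample group: one sorted population of one sex at one stage."""

    lineage: str
    sex: str
    stage: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.sex} {self.lineage} @ {self.stage}"


@dataclass(frozen=True)
class ThresholdConfig:
    """Thresholds shared by every list-building operation.

    Parameters
    ----------
    p_cutoff
        Per-comparison p-value cutoff for "different" calls; "identical"
        requires p strictly above it.
    fc_cutoff
        Linear-scale fold-change cutoff (signed convention, magnitude >= 1);
        "identical" requires |FC| strictly inside (-fc_cutoff, fc_cutoff).
    expression_floor
        log2 intensity a cluster must strictly exceed to count as expressed.
    min_replicates_over_floor
        Replicates (out of 3) that must exceed the floor in at least one
        sample group.  For designs with n != 3 replicates the proportion is
        preserved as ceil(n * min_replicates_over_floor / 3).
    n_permutations
        Label permutations per list-level FDR estimate.
    fdr_acceptable
        Largest permutation FDR still considered acceptable for a list.
    model_extreme_fraction
        Fraction of primed genes the extreme (all-female / all-male) models
        predict for their favoured sex.
    alpha_model
        Exclusion threshold for the differentiation-model tests.
    equal_variance
        Pooled-variance t-test when True (default), Welch otherwise.
    """

    p_cutoff: float = 0.05
    fc_cutoff: float = 1.5
    expression_floor: float = 6.0
    min_replicates_over_floor: int = 2
    n_permutations: int = 200
    fdr_acceptable: float = 0.20
    model_extreme_fraction: float = 0.90
    alpha_model: float = 0.05
    equal_variance: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff < 1.0:
            raise ConfigError(f"p_cutoff must be in (0,1), got {self.p_cutoff}")
        if not 0.0 < self.alpha_model < 1.0:
            raise ConfigError(f"alpha_model must be in (0,1), got {self.alpha_model}")
        if not self.fc_cutoff > 1.0:
            raise ConfigError(f"fc_cutoff must exceed 1, got {self.fc_cutoff}")
        if not 0.0 < self.fdr_acceptable <= 1.0:
            raise ConfigError(
                f"fdr_acceptable must be in (0,1], got {self.fdr_acceptable}"
            )
        if not 0.5 < self.model_extreme_fraction < 1.0:
            raise ConfigError(
                "model_extreme_fraction must be in (0.5,1), "
                f"got {self.model_extreme_fraction}"
            )
        if self.min_replicates_over_floor < 1:
            raise ConfigError("min_replicates_over_floor must be positive")

    def replicates_required(self, n_replicates: int) -> int:
        """Replicates over the floor required for a group of size *n_replicates*."""
        if n_replicates == 3:
            required = self.min_replicates_over_floor
        else:
            required = math.ceil(n_replicates * self.min_replicates_over_floor / 3)
        if required > n_replicates:
            raise ConfigError(
                f"group with {n_replicates} replicates cannot satisfy "
                f"min_replicates_over_floor={self.min_replicates_over_floor}"
            )
        return required


def _stage_key(stage: str):
    """Sort key giving the natural embryonic-day ordering (E10.5 < E11.0 < ...)."""
    text = str(stage)
    digits = "".join(ch for ch in text if ch.isdigit() or ch == ".")
    try:
        return (0, float(digits))
    except ValueError:
        return (1, text)


@dataclass
class ExpressionStudy:
    """A log2 expression matrix plus sample and transcript-cluster annotation.

    Attributes
    ----------
    matrix
        DataFrame of log2 intensities, index = cluster ids, columns = sample ids.
    samples
        DataFrame indexed by sample id with columns lineage, sex, stage,
        replicate.
    clusters
        DataFrame indexed by cluster id with columns gene_symbol,
        annotation_quality and is_control.
    """

    matrix: pd.DataFrame
    samples: pd.DataFrame
    clusters: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------ checks
    def validate(self) -> None:
        dup_samples = self.samples.index[self.samples.index.duplicated()].tolist()
        if dup_samples:
            raise StudyError(f"duplicate sample ids: {sorted(set(dup_samples))}")
        dup_clusters = self.clusters.index[self.clusters.index.duplicated()].tolist()
        if dup_clusters:
            raise StudyError(f"duplicate cluster ids: {sorted(set(dup_clusters))}")
        dup_rows = self.matrix.index[self.matrix.index.duplicated()].tolist()
        if dup_rows:
            raise StudyError(f"duplicate matrix rows: {sorted(set(dup_rows))}")

        missing_cols = [c for c in self.matrix.columns if c not in self.samples.index]
        if missing_cols:
            raise StudyError(
                f"matrix columns absent from sample sheet: {missing_cols}"
            )
        extra = [s for s in self.samples.index if s not in set(self.matrix.columns)]
        if extra:
            raise StudyError(f"sample sheet rows absent from matrix: {extra}")
        unannotated = [r for r in self.matrix.index if r not in self.clusters.index]
        if unannotated:
            raise StudyError(
                f"matrix rows missing from annotation: {unannotated[:10]}"
                + ("..." if len(unannotated) > 10 else "")
            )

        combos = self.samples[["lineage", "sex", "stage", "replicate"]]
        dup = combos[combos.duplicated()]
        if not dup.empty:
            raise StudyError(
                "duplicate (lineage, sex, stage, replicate) combinations: "
                f"{dup.to_dict('records')}"
            )
        if not np.issubdtype(self.matrix.values.dtype, np.number):
            raise StudyError("matrix contains non-numeric values")

    # -------------------------------------------------------------- accessors
    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(sorted(self.samples["stage"].unique(), key=_stage_key))

    @property
    def lineages(self) -> tuple[str, ...]:
        present = set(self.samples["lineage"].unique())
        ordered = [lin for lin in LINEAGES if lin in present]
        ordered += sorted(present - set(LINEAGES))
        return tuple(ordered)

    def group_samples(self, group: Group) -> list[str]:
        """Sample ids belonging to one (lineage, sex, stage) group."""
        mask = (
            (self.samples["lineage"] == group.lineage)
            & (self.samples["sex"] == group.sex)
            & (self.samples["stage"] == group.stage)
        )
        return list(self.samples.index[mask])

    def groups(self) -> Iterator[Group]:
        seen = self.samples[["lineage", "sex", "stage"]].drop_duplicates()
        for row in seen.itertuples(index=False):
            yield Group(row.lineage, row.sex, row.stage)

    def symbols_of(self, cluster_ids: Iterable[str]) -> set[str]:
        """Distinct non-empty gene symbols carried by *cluster_ids*."""
        ids = list(cluster_ids)
        syms = self.clusters.loc[ids, "gene_symbol"]
        return {s for s in syms if isinstance(s, str) and s}

    def subset_clusters(self, cluster_ids: Sequence[str]) -> "ExpressionStudy":
        wanted = set(cluster_ids)
        ids = [c for c in self.matrix.index if c in wanted]
        return ExpressionStudy(
            matrix=self.matrix.loc[ids],
            samples=self.samples.copy(),
            clusters=self.clusters.loc[ids],
        )

    def with_sexes_swapped(self) -> "ExpressionStudy":
        """Relabel XX<->XY everywhere (used for symmetry checks)."""
        samples = self.samples.copy()
        samples["sex"] = samples["sex"].map({"XX": "XY", "XY": "XX"})
        return ExpressionStudy(self.matrix.copy(), samples, self.clusters.copy())


# ---------------------------------------------------------------------- I/O
def _normalise_lineage(value: str) -> str:
    v = str(value).strip().lower()
    return _LINEAGE_ALIASES.get(v, v)


def _normalise_quality(value) -> str:
    v = str(value).strip()
    return "best" if v in _BEST_QUALITY else "other"


def load_study(
    matrix_file: str | Path,
    sample_sheet: str | Path,
    annotation_file: str | Path,
    sep: str = "\t",
) -> ExpressionStudy:
    """Read the three standard delimited files into a validated study.

    The matrix file has cluster ids in the first column and sample ids in the
    header; the sample sheet has columns sample_id, lineage, sex, stage,
    replicate; the annotation has cluster_id, gene_symbol,
    annotation_quality and optionally is_control (absent column: no
    controls assumed).
    """
    raw = pd.read_csv(matrix_file, sep=sep, index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        where = [
            f"({raw.index[r]}, {raw.columns[c]})={raw.iat[r, c]!r}"
            for r, c in list(zip(rows, cols))[:5]
        ]
        raise StudyError(f"non-numeric matrix cells at {', '.join(where)}")
    matrix = numeric.astype(float)
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    matrix.index.name = None
    matrix.columns.name = None

    samples = pd.read_csv(sample_sheet, sep=sep, dtype=str)
    required = {"sample_id", "lineage", "sex", "stage", "replicate"}
    if missing := required - set(samples.columns):
        raise StudyError(f"sample sheet missing columns: {sorted(missing)}")
    samples["lineage"] = samples["lineage"].map(_normalise_lineage)
    samples["replicate"] = samples["replicate"].astype(int)
    samples = samples.set_index("sample_id")

    clusters = pd.read_csv(annotation_file, sep=sep, dtype=str)
    if missing := {"cluster_id", "gene_symbol", "annotation_quality"} - set(
        clusters.columns
    ):
        raise StudyError(f"annotation missing columns: {sorted(missing)}")
    clusters["gene_symbol"] = clusters["gene_symbol"].fillna("")
    clusters["annotation_quality"] = clusters["annotation_quality"].map(
        _normalise_quality
    )
    if "is_control" in clusters.columns:
        clusters["is_control"] = (
            clusters["is_control"].fillna("false").str.strip().str.lower()
            .isin({"1", "true", "yes"})
        )
    else:
        clusters["is_control"] = False
    clusters = clusters.set_index("cluster_id")

    return ExpressionStudy(matrix=matrix, samples=samples, clusters=clusters)


def write_study(study: ExpressionStudy, out_dir: str | Path, sep: str = "\t") -> dict:
    """Write the three standard files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.tsv",
        "samples": out / "samples.tsv",
        "annotation": out / "annotation.tsv",
    }
    study.matrix.to_csv(paths["matrix"], sep=sep, index_label="cluster_id")
    study.samples.to_csv(paths["samples"], sep=sep, index_label="sample_id")
    study.clusters.to_csv(paths["annotation"], sep=sep, index_label="cluster_id")
    return paths


# -------------------------------------------------------------------- filter
def filter_clusters(
    study: ExpressionStudy, cfg: ThresholdConfig | None = None
) -> ExpressionStudy:
    """Apply the study-wide transcript-cluster inclusion criteria.

    Retains exactly the clusters that (a) carry the best annotation quality,
    (b) have a non-empty gene symbol, (c) are not control probes, and
    (d) strictly exceed ``cfg.expression_floor`` in at least
    ``cfg.min_replicates_over_floor`` replicates of at least one
    (lineage, sex, stage) group.  Intensity values are never altered, so the
    operation is idempotent.
    """
    cfg = cfg or ThresholdConfig()
    keep = (
        (study.clusters["annotation_quality"] == "best")
        & (study.clusters["gene_symbol"].astype(str) != "")
        & (~study.clusters["is_control"])
    )
    keep = keep.reindex(study.matrix.index, fill_value=False)

    expressed = pd.Series(False, index=study.matrix.index)
    for group in study.groups():
        cols = study.group_samples(group)
        required = cfg.replicates_required(len(cols))
        over = (study.matrix[cols] > cfg.expression_floor).sum(axis=1)
        expressed |= over >= required
    keep &= expressed

    kept_ids = study.matrix.index[keep.to_numpy()]
    return study.subset_clusters(list(kept_ids))
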