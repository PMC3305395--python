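"""The atomic pairwise comparison between two sample groups.

Every list recipe in the pipeline composes exactly one primitive: compare
the log2 replicate values of two (lineage, sex, stage) groups for every
transcript cluster and call each cluster ``higher``, ``lower``,
``identical`` or ``neither``.

A "different" call requires p < p_cutoff and a signed linear fold change of
magnitude >= fc_cutoff; an "identical" call requires p > p_cutoff and a fold
change strictly between -fc_cutoff and +fc_cutoff.  Fold changes follow the
signed convention of array-analysis suites: ``2**d`` for a log2 difference
d >= 0 and ``-2**(-d)`` otherwise, so magnitudes never fall inside (-1, 1)
and the identity window reads literally.

The per-cluster test is a two-sided two-sample t-test on the log2 replicate
values (pooled variance by default, Welch optionally).  P-values are left
uncorrected: error control happens at the list level by permutation.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .study import ExpressionStudy, Group, StudyError, ThresholdConfig

__all__ = ["CALLS", "compare_groups", "compare_columns", "call_ids", "calls_table"]

CALLS = ("higher", "lower", "identical", "neither")


def _as_group(g) -> Group:
    if isinstance(g, Group):
        return g
    return Group(*g)


def compare_columns(
    study: ExpressionStudy,
    cols_a: Sequence[str],
    cols_b: Sequence[str],
    cfg: ThresholdConfig,
) -> pd.DataFrame:
    """Compare two explicit sets of sample columns (vectorised over clusters).

    Returns a DataFrame indexed by cluster id with columns ``mean_a``,
    ``mean_b``, ``fold_change``, ``p_value`` and ``call``.
    """
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise StudyError(
            f"each group needs >=2 replicates (got {len(cols_a)} and {len(cols_b)})"
        )
    a = study.matrix[list(cols_a)].to_numpy(float)
    b = study.matrix[list(cols_b)].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    delta = mean_a - mean_b

    if cfg.equal_variance:
        pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
        se2 = pooled * (1.0 / na + 1.0 / nb)
        df = np.full_like(se2, na + nb - 2)
    else:
        se2 = var_a / na + var_b / nb
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2**2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )

    with np.errstate(divide="ignore", invalid="ignore"):
        t = delta / np.sqrt(se2)
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # Degenerate zero-variance limits of the t statistic: equal constant
    # replicates are perfectly identical (p=1); distinct constants differ
    # with certainty (p=0, the call then decided by the fold change alone).
    degenerate = se2 == 0.0
    p = np.where(degenerate & (delta == 0.0), 1.0, p)
    p = np.where(degenerate & (delta != 0.0), 0.0, p)

    fold = np.where(delta >= 0.0, np.exp2(delta), -np.exp2(-delta))

    different = p < cfg.p_cutoff
    call = np.select(
        [
            different & (fold >= cfg.fc_cutoff),
            different & (fold <= -cfg.fc_cutoff),
            (p > cfg.p_cutoff) & (np.abs(fold) < cfg.fc_cutoff),
        ],
        ["higher", "lower", "identical"],
        default="neither",
    )
    return pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "fold_change": fold,
            "p_value": p,
            "call": call,
        },
        index=study.matrix.index,
    )


def compare_groups(
    study: ExpressionStudy,
    group_a: Group | tuple,
    group_b: Group | tuple,
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """One :class:`ComparisonCall` row per retained cluster for a group pair."""
    cfg = cfg or ThresholdConfig()
    ga, gb = _as_group(group_a), _as_group(group_b)
    cols_a = study.group_samples(ga)
    cols_b = study.group_samples(gb)
    if len(cols_a) < 2:
        raise StudyError(f"group {ga} resolves to {len(cols_a)} samples (<2)")
    if len(cols_b) < 2:
        raise StudyError(f"group {gb} resolves to {len(cols_b)} samples (<2)")
    out = compare_columns(study, cols_a, cols_b, cfg)
    out.attrs["group_a"] = ga
    out.attrs["group_b"] = gb
    return out


def call_ids(calls: pd.DataFrame, wanted: str) -> frozenset[str]:
    """Cluster ids whose call equals *wanted* (one of CALLS)."""
    if wanted not in CALLS:
        raise ValueError(f"unknown call {wanted!r}; expected one of {CALLS}")
    return frozenset(calls.index[calls["call"] == wanted])


def calls_table(calls: pd.DataFrame, study: ExpressionStudy) -> pd.DataFrame:
    """Comparison table with gene symbols attached, ready to write as TSV."""
    out = calls.copy()
    out.insert(0, "gene_symbol", study.clusters.loc[out.index, "gene_symbol"])
    return out
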