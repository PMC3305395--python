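from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gonadprime import SimulationSpec, ThresholdConfig, filter_clusters, simulate_study
from gonadprime.study import ExpressionStudy


def build_study(
    rows: dict,
    symbols: dict | None = None,
    quality: dict | None = None,
    controls: set | None = None,
) -> ExpressionStudy:
    """Construct a study from explicit replicate values.

    ``rows`` maps cluster_id -> {(lineage, sex, stage): [replicate values]};
    every cluster must define the same groups with the same replicate counts.
    """
    symbols = symbols or {}
    quality = quality or {}
    controls = controls or set()
    first = next(iter(rows.values()))
    groups = list(first.keys())

    sample_ids, meta = [], []
    for (lineage, sex, stage) in groups:
        n = len(first[(lineage, sex, stage)])
        for r in range(1, n + 1):
            sample_ids.append(f"{lineage}_{sex}_{stage}_r{r}")
            meta.append(
                {"lineage": lineage, "sex": sex, "stage": stage, "replicate": r}
            )

    data = {}
    for cid, values in rows.items():
        flat = []
        for g in groups:
            flat.extend(values[g])
        data[cid] = flat
    matrix = pd.DataFrame(data, index=sample_ids).T.astype(float)

    clusters = pd.DataFrame(
        {
            "gene_symbol": [symbols.get(c, c.upper()) for c in matrix.index],
            "annotation_quality": [quality.get(c, "best") for c in matrix.index],
            "is_control": [c in controls for c in matrix.index],
        },
        index=matrix.index,
    )
    samples = pd.DataFrame(meta, index=pd.Index(sample_ids, name="sample_id"))
    return ExpressionStudy(matrix=matrix, samples=samples, clusters=clusters)


@pytest.fixture(scope="session")
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture(scope="session")
def sim_small(cfg):
    """Small planted study shared by recovery-style unit tests."""
    spec = SimulationSpec(n_genes=800, plants_per_pattern=12, seed=7)
    study, truth = simulate_study(spec)
    return study, truth, filter_clusters(study, cfg)


@pytest.fixture()
def study_factory():
    return build_study
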