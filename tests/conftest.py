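import numpy as np
import pandas as pd
import pytest

import dosagenet as d
from dosagenet.containers import ExpressionMatrix


@pytest.fixture(scope="session")
def small_study():
    """Default-design study at a small genome scale."""
    return d.generate_study(n_genes=120, genes_per_df=4, seed=3)


@pytest.fixture(scope="session")
def small_analysis(small_study):
    from dosagenet.pipeline import analyze_sex

    return analyze_sex(
        small_study.expression, small_study.deficiencies, "female", n_perm=1000, seed=7
    )


def make_matrix(
    gene_values: np.ndarray,
    lines: list[str],
    n_replicates: int = 3,
    sex: str = "female",
    control_values: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
) -> ExpressionMatrix:
    """Hand-built single-sex ExpressionMatrix for unit tests.

    ``gene_values``: (n_genes, n_lines * n_replicates) log2 values, sample
    columns grouped by line.
    """
    gene_values = np.asarray(gene_values, dtype=float)
    n_genes = gene_values.shape[0]
    sample_ids, meta = [], []
    for line in lines:
        for r in range(n_replicates):
            sample_ids.append(f"{line}_{sex}_{r + 1}")
            meta.append((line, sex, r + 1))
    if control_values is None:
        rng = np.random.default_rng(0)
        control_values = rng.normal(4.0, 0.3, (10, len(sample_ids)))
    gene_ids = gene_ids or [f"g{i:03d}" for i in range(n_genes)]
    ctrl_ids = [f"ctrl{i:02d}" for i in range(control_values.shape[0])]
    values = pd.DataFrame(
        np.vstack([gene_values, control_values]),
        index=gene_ids + ctrl_ids,
        columns=sample_ids,
    )
    samples = pd.DataFrame(meta, columns=["line", "sex", "replicate"], index=sample_ids)
    features = pd.DataFrame(
        {
            "probe_class": ["gene"] * n_genes + ["control"] * len(ctrl_ids),
            "spike_subset": None,
            "expected_log2_ratio": np.nan,
        },
        index=values.index,
    )
    return ExpressionMatrix(values, samples, features)
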