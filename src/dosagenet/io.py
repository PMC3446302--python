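"""Flat-file interchange: annotation, deficiency, expression and truth
tables. Interval files are written both as BED (0-based half-open) and as
1-based inclusive TSV; expression matrices round-trip through a single
TSV carrying probe-class flags and sample names ``line_sex_rep``."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import DeficiencyLine, ExpressionMatrix, PlantedTruth, to_internal


def write_annotation_bed(annotation: pd.DataFrame, path) -> None:
    rows = []
    for r in annotation.itertuples():
        start, end = to_internal(r.first, r.last)
        rows.append((r.chrom, start, end, r.gene, 0, getattr(r, "strand", "+")))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def write_deficiencies_tsv(deficiencies: list[DeficiencyLine], path) -> None:
    pd.DataFrame(
        [
            {
                "Deficiency": d.name,
                "Chromosome": d.chrom,
                "First missing base": d.first,
                "Last missing base": d.last,
                "Genes removed": len(d.one_dose_genes),
                "One-dose genes": ",".join(d.one_dose_genes),
            }
            for d in deficiencies
        ]
    ).to_csv(path, sep="\t", index=False)


def read_deficiencies_tsv(path) -> list[DeficiencyLine]:
    tab = pd.read_csv(path, sep="\t")
    return [
        DeficiencyLine(
            name=r["Deficiency"],
            chrom=r["Chromosome"],
            first=int(r["First missing base"]),
            last=int(r["Last missing base"]),
            one_dose_genes=tuple(
                str(r["One-dose genes"]).split(",") if pd.notna(r["One-dose genes"]) else ()
            ),
        )
        for _, r in tab.iterrows()
    ]


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.features.join(matrix.values)
    out.index.name = "feature"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a gene-level log2 expression TSV.

    Sample columns must be named ``line_sex_rep`` (e.g. ``w1118_female_1``);
    missing values are rejected with a clear error rather than imputed.
    """
    tab = pd.read_csv(path, sep="\t", index_col="feature")
    feat_cols = [c for c in ("probe_class", "spike_subset", "expected_log2_ratio") if c in tab]
    features = tab[feat_cols].copy()
    if "probe_class" not in features:
        features["probe_class"] = "gene"
    values = tab.drop(columns=feat_cols).astype(float)
    if values.isna().any().any():
        bad = values.columns[values.isna().any()].tolist()
        raise ValueError(
            f"expression matrix contains missing values (columns {bad}); "
            "missing data are not supported"
        )
    meta = []
    for c in values.columns:
        parts = c.rsplit("_", 2)
        if len(parts) != 3 or parts[1] not in ("female", "male"):
            raise ValueError(f"sample column {c!r} is not of the form line_sex_rep")
        meta.append((parts[0], parts[1], int(parts[2])))
    samples = pd.DataFrame(
        meta,
        columns=["line", "sex", "replicate"],
        index=pd.Index(values.columns, name="sample"),
    )
    if "spike_subset" in features:
        features["spike_subset"] = features["spike_subset"].where(
            features["spike_subset"].notna(), None
        )
    return ExpressionMatrix(values, samples, features)


def write_truth_tsv(truth: PlantedTruth, path) -> None:
    out = pd.DataFrame(
        {
            "class": truth.gene_class,
            "true_lfc": truth.true_lfc,
            "sex_bias": truth.sex_bias,
        }
    )
    if truth.true_lfc_by_sex is not None:
        out["true_lfc_female"] = truth.true_lfc_by_sex["female"]
        out["true_lfc_male"] = truth.true_lfc_by_sex["male"]
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    out = calls.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
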