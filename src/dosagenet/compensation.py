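"""Five-class dosage-compensation calling and related analyses.

The classifier is two-step. Step 1 tests, per one-dose gene, the null that
expression dropped two-fold (log2 fold change = -1) with a moderated
t-test; genes whose null is not rejected (BH q >= alpha) are
*non-compensated*, rejected genes below -1 are *anti-compensated*. Step 2
stratifies the remaining rejected genes (LFC > -1): their LFC values are
bootstrapped, a normal-theory 2.5%/97.5% band (mean +/- 1.96 SD) is
computed and re-centered at zero ("no change" vs the reference), and genes
inside the band are *fully*, above it *over-*, below it *partially*
compensated.

Also here: contiguous-block resampling of two-dose genes (a size-matched
null for the one-dose LFC distribution), distribution-shape tests,
variance comparisons, compensation-vs-expression-level association,
between-sex concordance by sex-bias group, and cross-deficiency
consistency for genes uncovered by more than one deletion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DeficiencyLine, ExpressionMatrix
from .expression import (
    ModeratedTestResult,
    bh_fdr,
    fit_variance_prior,
    log_ratios,
    moderated_t_from_stats,
    squeeze_variances,
)


@dataclass(frozen=True)
class ClassCutoffs:
    """Centered step-2 band: lower < 0 < upper (log2 units)."""

    lower: float
    upper: float
    boot_mean: float
    boot_sd: float
    n_boot: int


# ---------------------------------------------------------------------------
# per-gene one-dose statistics


def one_dose_stats(
    matrix: ExpressionMatrix,
    deficiencies: list[DeficiencyLine],
    reference: pd.Series,
    sex: str,
    detected: pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Pooled replicate log-ratio statistics for one-dose genes.

    A gene one-dose in several lines pools the replicate log-ratios of all
    those lines. Returns (stats table with lfc/s2/df/n, Series gene ->
    comma-joined line names).
    """
    gene_lines: dict[str, list[str]] = {}
    for d in deficiencies:
        for g in d.one_dose_genes:
            gene_lines.setdefault(g, []).append(d.name)
    genes = [g for g in matrix.gene_ids if g in gene_lines]
    if detected is not None:
        genes = [g for g in genes if bool(detected.get(g, False))]
    rows = []
    for g in genes:
        vals = []
        for line in gene_lines[g]:
            ids = matrix.line_samples(line, sex)
            vals.append(matrix.values.loc[g, ids].to_numpy() - reference[g])
        v = np.concatenate(vals)
        rows.append((g, v.mean(), v.var(ddof=1), len(v) - 1.0, float(len(v))))
    table = pd.DataFrame(rows, columns=["gene", "lfc", "s2", "df", "n"]).set_index("gene")
    lines = pd.Series({g: ",".join(gene_lines[g]) for g in table.index}, name="lines")
    return table, lines


def one_dose_moderated_test(
    matrix: ExpressionMatrix,
    deficiencies: list[DeficiencyLine],
    reference: pd.Series,
    sex: str,
    detected: pd.Series | None = None,
    null_lfc: float = -1.0,
) -> tuple[ModeratedTestResult, pd.Series]:
    """Moderated t of one-dose genes against the two-fold-reduction null."""
    tab, lines = one_dose_stats(matrix, deficiencies, reference, sex, detected)
    res = moderated_t_from_stats(tab["lfc"], tab["s2"], tab["df"], tab["n"], null_lfc)
    return res, lines


# ---------------------------------------------------------------------------
# classifier


def classify_compensation(
    result: ModeratedTestResult,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    lines: pd.Series | None = None,
    sex: str = "",
) -> tuple[pd.DataFrame, ClassCutoffs]:
    """Assign each tested one-dose gene exactly one of five classes.

    ``result`` must have been computed against null_lfc = -1.
    """
    if result.null_lfc != -1.0:
        raise ValueError("classification requires the two-fold-reduction null (null_lfc = -1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tab = result.table
    lfc = tab["lfc"].to_numpy()
    q = tab["q"].to_numpy()
    cls = np.empty(len(tab), dtype=object)
    cls[q >= alpha] = "non"
    cls[(q < alpha) & (lfc < -1.0)] = "anti"
    cls[(q < alpha) & (lfc == -1.0)] = "non"  # defensive; rejection at -1 exactly
    step2 = (q < alpha) & (lfc > -1.0)

    step2_lfc = lfc[step2]
    if step2.sum() >= 10:
        boot = rng.choice(step2_lfc, size=n_boot, replace=True)
        m, sd = float(boot.mean()), float(boot.std(ddof=1))
        cut = ClassCutoffs(-1.96 * sd, 1.96 * sd, m, sd, n_boot)
        sub = np.where(
            step2_lfc > cut.upper, "over", np.where(step2_lfc < cut.lower, "partial", "full")
        )
    else:
        warnings.warn(
            "fewer than 10 genes entered step 2; classifying them all as "
            "partial (conservative)"
        )
        cut = ClassCutoffs(np.nan, np.nan, np.nan, np.nan, 0)
        sub = np.full(int(step2.sum()), "partial", dtype=object)
    cls[step2] = sub

    calls = pd.DataFrame(
        {
            "sex": sex,
            "lines": lines.reindex(tab.index) if lines is not None else "",
            "lfc": tab["lfc"],
            "p": tab["p"],
            "q": tab["q"],
            "class": cls,
        },
        index=tab.index,
    )
    return calls, cut


# ---------------------------------------------------------------------------
# contiguous-block resampling of two-dose genes


def block_resample(
    values: pd.Series,
    eligible: pd.Series,
    block_size: int,
    n_draws: int = 2000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Resample contiguous blocks of eligible genes in genome order.

    ``values`` must be ordered by genomic position; a valid block is
    ``block_size`` consecutive genes, all eligible (ineligible genes break
    contiguity). Returns one row per draw with the block mean and variance.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    v = values.to_numpy()
    ok = eligible.reindex(values.index).fillna(False).to_numpy(dtype=bool)
    run_ok = np.convolve(ok.astype(int), np.ones(block_size), mode="valid") == block_size
    starts = np.flatnonzero(run_ok)
    if len(starts) == 0:
        raise ValueError(f"no contiguous run of {block_size} eligible genes")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picks = rng.choice(starts, size=n_draws, replace=True)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csum2 = np.concatenate([[0.0], np.cumsum(v**2)])
    s = csum[picks + block_size] - csum[picks]
    s2 = csum2[picks + block_size] - csum2[picks]
    mean = s / block_size
    var = (s2 - block_size * mean**2) / max(block_size - 1, 1)
    return pd.DataFrame({"start": picks, "mean": mean, "var": var})


def block_resample_two_dose(
    lfc_in_genome_order: pd.Series,
    two_dose_detected: pd.Series,
    df: DeficiencyLine,
    n_draws: int = 2000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Blocks gene-count-matched to one deficiency's one-dose set."""
    return block_resample(
        lfc_in_genome_order,
        two_dose_detected,
        block_size=len(df.one_dose_genes),
        n_draws=n_draws,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# distribution shape and variance


def distribution_tests(one_dose_lfc, resampled_two_dose_lfc) -> dict:
    """Jarque-Bera normality of the one-dose LFCs, two-sample KS between
    one-dose and resampled two-dose LFCs, and the mean fold reduction
    2^(-mean LFC)."""
    x = np.asarray(one_dose_lfc, dtype=float)
    y = np.asarray(resampled_two_dose_lfc, dtype=float)
    if len(x) < 20 or len(y) < 20:
        raise ValueError("need >= 20 values per sample")
    jb = stats.jarque_bera(x)
    ks = stats.ks_2samp(x, y)
    return {
        "jarque_bera_stat": float(jb.statistic),
        "jarque_bera_p": float(jb.pvalue),
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "mean_one_dose_lfc": float(x.mean()),
        "mean_two_dose_lfc": float(y.mean()),
        "mean_fold_reduction": float(2.0 ** (-x.mean())),
    }


def _notched_summary(draws: np.ndarray) -> dict:
    q1, med, q3 = np.percentile(draws, [25, 50, 75])
    notch = 1.57 * (q3 - q1) / np.sqrt(len(draws))
    return {
        "median": float(med),
        "ci_low": float(med - notch),
        "ci_high": float(med + notch),
        "q1": float(q1),
        "q3": float(q3),
    }


def variance_comparison(
    one_dose_lfc: pd.Series,
    matched_two_dose_lfc: pd.Series,
    n_draws: int = 2000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Bootstrap distributions of fold-difference variance in both states.

    Both inputs are indexed by gene (the same genes measured one-dose and
    two-dose). Each draw resamples the gene set and computes the variance
    of the fold differences (2^lfc), giving paired sampling distributions
    summarized as for a notched boxplot.
    """
    common = one_dose_lfc.index.intersection(matched_two_dose_lfc.index)
    if len(common) < 2:
        raise ValueError("need >= 2 genes measurable in both states")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f1 = 2.0 ** one_dose_lfc.loc[common].to_numpy()
    f2 = 2.0 ** matched_two_dose_lfc.loc[common].to_numpy()
    idx = rng.integers(0, len(common), size=(n_draws, len(common)))
    v1 = f1[idx].var(axis=1, ddof=1)
    v2 = f2[idx].var(axis=1, ddof=1)
    return {
        "one_dose": _notched_summary(v1),
        "two_dose": _notched_summary(v2),
        "median_difference": float(np.median(v1 - v2)),
        "difference_ci": _notched_summary(v1 - v2),
        "draws_one_dose": v1,
        "draws_two_dose": v2,
    }


# ---------------------------------------------------------------------------
# associations


def compensation_vs_expression(
    lfc: pd.Series, two_dose_level: pd.Series, n_bins: int = 10
) -> dict:
    """Spearman association of two-dose expression level with the
    compensation ratio (LFC), plus an MA-style binned trend."""
    common = lfc.index.intersection(two_dose_level.index)
    if len(common) < 10:
        raise ValueError("need >= 10 genes")
    x = two_dose_level.loc[common]
    y = lfc.loc[common]
    if x.nunique() < 2:
        return {"rho": np.nan, "p": np.nan, "trend": None, "degenerate": True}
    rho, p = stats.spearmanr(x, y)
    bins = pd.qcut(x.rank(method="first"), q=min(n_bins, len(common)), labels=False)
    trend = pd.DataFrame({"level": x, "lfc": y, "bin": bins}).groupby("bin").agg(
        level_mean=("level", "mean"), lfc_mean=("lfc", "mean"), n=("lfc", "size")
    )
    return {"rho": float(rho), "p": float(p), "trend": trend, "degenerate": False}


def sex_concordance(
    lfc_female: pd.Series, lfc_male: pd.Series, bias_labels: pd.Series
) -> pd.DataFrame:
    """Spearman rho of female vs male compensation ratios per bias group."""
    common = lfc_female.index.intersection(lfc_male.index)
    rows = []
    for group in ("female", "male", "none"):
        genes = [g for g in common if bias_labels.get(g) == group]
        if len(genes) < 5:
            rows.append({"bias": group, "n": len(genes), "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(lfc_female.loc[genes], lfc_male.loc[genes])
        rows.append({"bias": group, "n": len(genes), "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("bias")


def cross_df_consistency(
    matrix: ExpressionMatrix,
    deficiencies: list[DeficiencyLine],
    reference: pd.Series,
    sex: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated equality test of a gene's LFC across deficiencies.

    For each gene one-dose in >= 2 lines, a moderated one-way F compares
    the per-line mean log-ratios, with per-line residual variances shrunk
    toward a common prior fit over all (gene, line) cells.
    """
    gene_lines: dict[str, list[str]] = {}
    for d in deficiencies:
        for g in d.one_dose_genes:
            gene_lines.setdefault(g, []).append(d.name)
    shared = {g: ls for g, ls in gene_lines.items() if len(ls) >= 2}
    if not shared:
        return pd.DataFrame(columns=["n_lines", "F", "df1", "df2", "p", "q", "significant"])

    cells = []  # (gene, line, mean, s2, n)
    for g, ls in shared.items():
        for line in ls:
            ids = matrix.line_samples(line, sex)
            v = matrix.values.loc[g, ids].to_numpy() - reference[g]
            cells.append((g, line, v.mean(), v.var(ddof=1), len(v)))
    cell_df = pd.DataFrame(cells, columns=["gene", "line", "mean", "s2", "n"])
    d0, s0 = fit_variance_prior(
        cell_df["s2"].to_numpy(), (cell_df["n"] - 1).to_numpy(dtype=float)
    )
    rows = []
    for g, grp in cell_df.groupby("gene"):
        k = len(grp)
        n = grp["n"].to_numpy(dtype=float)
        m = grp["mean"].to_numpy()
        grand = np.average(m, weights=n)
        ms_between = float(np.sum(n * (m - grand) ** 2) / (k - 1))
        df_resid = float(np.sum(n - 1))
        s2_pooled = float(np.sum((n - 1) * grp["s2"].to_numpy()) / df_resid)
        s2t = float(squeeze_variances(np.array([s2_pooled]), np.array([df_resid]), d0, s0)[0])
        df2 = df_resid if np.isinf(d0) else d0 + df_resid
        f = ms_between / s2t
        p = float(stats.f.sf(f, k - 1, df2))
        rows.append({"gene": g, "n_lines": k, "F": f, "df1": k - 1.0, "df2": df2, "p": p})
    out = pd.DataFrame(rows).set_index("gene")
    out["q"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


def extent_position_association(
    calls: pd.DataFrame, deficiencies: list[DeficiencyLine]
) -> pd.DataFrame:
    """Spearman association of per-Df class proportions with deletion
    extent (bp), gene count, and chromosomal midpoint."""
    if len(deficiencies) < 5:
        raise ValueError("need >= 5 deficiencies")
    per_df = []
    for d in deficiencies:
        genes = [g for g in d.one_dose_genes if g in calls.index]
        if not genes:
            continue
        cc = calls.loc[genes, "class"].value_counts(normalize=True)
        per_df.append(
            {
                "df": d.name,
                "extent_bp": d.extent_bp,
                "n_genes": len(d.one_dose_genes),
                "midpoint": d.midpoint,
                **{f"prop_{c}": cc.get(c, 0.0) for c in ("anti", "non", "partial", "full", "over")},
            }
        )
    tab = pd.DataFrame(per_df).set_index("df")
    rows = []
    for cls in ("anti", "non", "partial", "full", "over"):
        for covariate in ("extent_bp", "n_genes", "midpoint"):
            x, y = tab[covariate], tab[f"prop_{cls}"]
            if y.nunique() < 2 or x.nunique() < 2:
                rho, p = np.nan, np.nan
            else:
                rho, p = stats.spearmanr(x, y)
            rows.append({"class": cls, "covariate": covariate, "rho": rho, "p": p})
    return pd.DataFrame(rows)
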