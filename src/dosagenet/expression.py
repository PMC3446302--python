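"""Expression-matrix statistics: replicate QC, detection filtering,
reference construction, empirical-Bayes moderated t-tests with FDR
control, RPKM, and spike-in calibration.

The moderated t-test shrinks each gene's residual variance toward a prior
estimated from the whole ensemble under a scaled-inverse-chi-square
hierarchy: if s_g^2 has d_g degrees of freedom and the prior is (s0^2, d0),
the posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

and (lfc - null) / (s~_g / sqrt(n)) follows a t distribution with
d0 + d_g degrees of freedom. (d0, s0^2) are fit by moment-matching the
log residual variances against the implied scaled-F distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats, special
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# replicate QC


def qc_replicates(
    matrix: ExpressionMatrix, min_rank_correlation: float = 0.8
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop replicates that do not rank-correlate with their group.

    Within each (line, sex) group, replicates whose median pairwise
    Spearman correlation with the other replicates falls below
    ``min_rank_correlation`` are removed worst-first, recomputing after
    each removal (so one corrupt replicate does not drag down its intact
    partners); the boundary value is retained. Returns the filtered matrix
    and a per-sample report.
    """
    gene_vals = matrix.gene_values()
    rows = []
    keep: list[str] = []
    for (line, sex), grp in matrix.samples.groupby(["line", "sex"], sort=False):
        ids = list(grp.index)
        if len(ids) < 2:
            raise ValueError(f"group ({line}, {sex}) has fewer than 2 replicates")
        active = list(ids)
        final_med: dict[str, float] = {}
        while len(active) >= 2:
            sub = gene_vals[active].to_numpy()
            if len(active) == 2:
                r = stats.spearmanr(sub[:, 0], sub[:, 1]).statistic
                rho = np.array([[1.0, r], [r, 1.0]])
            else:
                rho = np.asarray(stats.spearmanr(sub).statistic)
            med = {
                sid: float(np.median(np.delete(rho[i], i)))
                for i, sid in enumerate(active)
            }
            worst = min(active, key=lambda s: med[s])
            # boundary is inclusive; tolerate float error in rank correlations
            if med[worst] >= min_rank_correlation - 1e-9:
                final_med.update(med)
                break
            final_med[worst] = med[worst]
            active.remove(worst)
        for sid in ids:
            ok = sid in active
            rows.append({"sample": sid, "line": line, "sex": sex,
                         "median_rank_correlation": final_med.get(sid, np.nan),
                         "retained": ok})
            if ok:
                keep.append(sid)
    report = pd.DataFrame(rows).set_index("sample")
    dropped = report.index[~report["retained"]]
    if len(dropped):
        logger.info("qc_replicates dropped samples: %s", list(dropped))
    for (line, sex), grp in report[report["retained"]].groupby(["line", "sex"]):
        if len(grp) < 2:
            warnings.warn(f"group ({line}, {sex}) left with <2 replicates after QC")
    return matrix.subset_samples([s for s in matrix.samples.index if s in set(keep)]), report


# ---------------------------------------------------------------------------
# detection


def detection_mask(matrix: ExpressionMatrix, sd_factor: float = 2.0) -> pd.DataFrame:
    """Per-sex detection mask: detected in *all* lines of that sex.

    The per-sample detection threshold is mean + ``sd_factor`` * SD of the
    control-probe intensities in that sample; a gene counts as detected in
    a line when its replicate-mean expression exceeds the replicate-mean
    threshold (strictly greater).
    """
    ctrl = matrix.control_values()
    if len(ctrl) < 2:
        raise ValueError("need >= 2 control-probe rows for detection thresholds")
    thr = ctrl.mean(axis=0) + sd_factor * ctrl.std(axis=0, ddof=1)  # per sample
    genes = matrix.gene_values()
    out = {}
    for sex in matrix.samples["sex"].unique():
        detected_all = pd.Series(True, index=genes.index)
        for line in matrix.lines(sex):
            ids = matrix.line_samples(line, sex)
            detected_all &= genes[ids].mean(axis=1) > thr[ids].mean()
        out[sex] = detected_all
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# references


def build_reference(
    matrix: ExpressionMatrix,
    mode: str,
    sex: str,
    parental_line: str = "w1118",
) -> pd.Series:
    """Per-gene reference: 'parental' = median over the parental line's
    replicates of that sex; 'composite' = median over all Df/+ samples of
    that sex (the parental line excluded)."""
    if mode == "parental":
        ids = matrix.line_samples(parental_line, sex)
        if len(ids) == 0:
            raise ValueError(f"no parental ({parental_line}) samples for sex={sex}")
    elif mode == "composite":
        keep = (matrix.samples["sex"] == sex) & (matrix.samples["line"] != parental_line)
        ids = matrix.samples.index[keep]
        if len(ids) == 0:
            raise ValueError(f"no Df/+ samples for sex={sex}")
    else:
        raise ValueError("mode must be 'parental' or 'composite'")
    return matrix.values[ids].median(axis=1)


def log_ratios(matrix: ExpressionMatrix, reference: pd.Series, sample_ids) -> pd.DataFrame:
    """Per-replicate log2 ratios to the reference (gene rows only)."""
    genes = matrix.gene_values()
    return genes[list(sample_ids)].sub(reference.loc[genes.index], axis=0)


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the monotone branch)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df) -> tuple[float, float]:
    """Moment-match (d0, s0^2) of the scaled-inverse-chi-square prior.

    Works on log variances: under the hierarchy, log s_g^2 is a shifted
    log-F variable whose mean and variance involve digamma/trigamma of the
    degrees of freedom; equating the observed moments of log s_g^2 yields
    d0 and s0^2. Degenerate ensembles (no excess spread in the log
    variances) fall back to d0 = inf, i.e. a fully pooled variance.
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.any(s2 < 0):
        raise ValueError("variances must be non-negative")
    s2 = np.maximum(s2, 1e-10 * max(np.median(s2), 1e-300))
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        logger.info("degenerate variance ensemble: falling back to pooled variance")
        d0 = np.inf
        s0 = float(np.exp(emean))
    return float(d0), float(s0)


def squeeze_variances(s2: np.ndarray, df, d0: float, s0_sq: float) -> np.ndarray:
    """Posterior variances s~^2 = (d0 s0^2 + d s^2) / (d0 + d)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if np.isinf(d0):
        return np.full_like(s2, s0_sq)
    return (d0 * s0_sq + df * s2) / (d0 + df)


@dataclass
class ModeratedTestResult:
    """Per-gene table plus the fitted prior.

    table columns: lfc, s2, df, s2_tilde, t, df_total, p, q.
    """

    table: pd.DataFrame
    d0: float
    s0_sq: float
    null_lfc: float


def moderated_t_from_stats(
    lfc: pd.Series,
    s2: pd.Series,
    df: pd.Series,
    n: pd.Series,
    null_lfc: float = 0.0,
) -> ModeratedTestResult:
    """Moderated one-sample t from per-gene summary statistics.

    ``n`` is the number of replicate log-ratios averaged into ``lfc``;
    the standard error of the moderated statistic is s~ / sqrt(n).
    """
    idx = lfc.index
    d0, s0 = fit_variance_prior(s2.to_numpy(), df.to_numpy())
    s2t = squeeze_variances(s2.to_numpy(), df.to_numpy(), d0, s0)
    se = np.sqrt(s2t / n.to_numpy())
    t = (lfc.to_numpy() - null_lfc) / se
    df_total = d0 + df.to_numpy()
    if np.isinf(d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "s2": s2,
            "df": df,
            "s2_tilde": s2t,
            "t": t,
            "df_total": df_total,
            "p": p,
            "q": bh_fdr(p),
        },
        index=idx,
    )
    return ModeratedTestResult(table, d0, s0, null_lfc)


def moderated_t(
    ratios: pd.DataFrame, null_lfc: float = 0.0
) -> ModeratedTestResult:
    """Moderated one-sample t on per-replicate log-ratios (genes x reps)."""
    n = ratios.shape[1]
    if n < 2:
        raise ValueError("need >= 2 replicates for a residual variance")
    lfc = ratios.mean(axis=1)
    s2 = ratios.var(axis=1, ddof=1)
    df = pd.Series(float(n - 1), index=ratios.index)
    return moderated_t_from_stats(lfc, s2, df, pd.Series(float(n), index=ratios.index), null_lfc)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sequencing normalization


def rpkm(counts, gene_length_bp, total_mapped) -> np.ndarray:
    """Reads per kilobase per million mapped: counts * 1e9 / (L * N)."""
    counts = np.asarray(counts, dtype=float)
    length = np.asarray(gene_length_bp, dtype=float)
    if np.any(length <= 0) or total_mapped <= 0:
        raise ValueError("gene length and total mapped reads must be positive")
    return counts * 1e9 / (length * total_mapped)


# ---------------------------------------------------------------------------
# spike-in calibration


def spikein_calibration(matrix: ExpressionMatrix, parental_line: str = "w1118") -> dict:
    """Observed vs expected log2 ratios for the spike-in subsets.

    One external mix is added to the parental mRNA, the other to the Df/+
    mRNAs, so the observed per-spike log2 ratio is mean(Df samples) -
    mean(parental samples). Reports the per-subset mean observed ratio,
    its deviation from the design ratio, and the observed-vs-expected
    regression slope across all spikes.
    """
    spikes = matrix.spike_features()
    if len(spikes) == 0 or spikes["spike_subset"].isna().any():
        raise ValueError("spike rows must carry subset annotation")
    vals = matrix.values.loc[spikes.index]
    is_df = (matrix.samples["line"] != parental_line).to_numpy()
    obs = vals.loc[:, is_df].mean(axis=1) - vals.loc[:, ~is_df].mean(axis=1)
    expected = spikes["expected_log2_ratio"].astype(float)
    per_subset = (
        pd.DataFrame({"subset": spikes["spike_subset"], "observed": obs, "expected": expected})
        .groupby("subset")
        .agg(n=("observed", "size"), observed_mean=("observed", "mean"),
             observed_sem=("observed", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
             expected=("expected", "first"))
    )
    per_subset["deviation"] = per_subset["observed_mean"] - per_subset["expected"]
    if expected.nunique() > 1:
        fit = stats.linregress(expected, obs)
        slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        slope, intercept = np.nan, np.nan
    return {"per_subset": per_subset, "slope": slope, "intercept": intercept}
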