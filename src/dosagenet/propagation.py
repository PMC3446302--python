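"""Propagation of one-dose perturbations into the two-dose genome.

Per-line differential expression against the composite reference defines,
for every deficiency line, the set of two-dose genes that changed and in
which direction. Projected onto a co-expression network, the unique
first-degree two-dose neighbors of each one-dose gene are scored for
change probability and direction, stratified by the hub's compensation
class; protein complexes are scored for coherent co-change with a joint
hypergeometric-enrichment x direction-uniformity probability.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import DeficiencyLine, ExpressionMatrix
from .expression import log_ratios, moderated_t

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# per-line differential expression (one-versus-everyone)


def per_line_de(
    matrix: ExpressionMatrix,
    composite_reference: pd.Series,
    sex: str,
    alpha: float = 0.05,
    parental_line: str = "w1118",
    genes: pd.Index | None = None,
) -> dict[str, pd.DataFrame]:
    """Moderated t (null LFC = 0) of each Df/+ line vs the composite.

    Returns, per line, a gene table with lfc, p, q, ``changed`` (q <
    alpha) and ``sign``. BH correction is applied within each (line, sex)
    family. Lines with < 2 replicates are skipped with a warning.
    """
    out: dict[str, pd.DataFrame] = {}
    for line in matrix.lines(sex):
        if line == parental_line:
            continue
        ids = matrix.line_samples(line, sex)
        if len(ids) < 2:
            logger.warning("line %s (%s): <2 replicates, skipped", line, sex)
            continue
        ratios = log_ratios(matrix, composite_reference, ids)
        if genes is not None:
            ratios = ratios.loc[[g for g in genes if g in ratios.index]]
        res = moderated_t(ratios, null_lfc=0.0)
        tab = res.table[["lfc", "p", "q"]].copy()
        tab["changed"] = tab["q"] < alpha
        tab["sign"] = np.sign(tab["lfc"]).astype(int)
        out[line] = tab
    return out


# ---------------------------------------------------------------------------
# first-degree neighbors


def first_degree_neighbors(
    net: nx.Graph, one_dose_genes
) -> dict[str, set[str]]:
    """Unique two-dose first-degree neighbors of each one-dose gene.

    Neighbors that are themselves one-dose genes of the same line are
    excluded. One-dose genes absent from the network get an empty set.
    """
    od = set(one_dose_genes)
    out: dict[str, set[str]] = {}
    for g in one_dose_genes:
        if g in net:
            out[g] = set(net.neighbors(g)) - od
        else:
            out[g] = set()
    return out


def _rate_test(n_hit: int, n_total: int, p0: float) -> tuple[float, str]:
    """Goodness-of-fit vs a global rate: 1-df chi-square when all expected
    cells are >= 5, exact binomial otherwise."""
    if n_total == 0 or not (0.0 < p0 < 1.0):
        return np.nan, "none"
    expected = np.array([n_total * p0, n_total * (1 - p0)])
    if expected.min() >= 5:
        chi2 = ((n_hit - expected[0]) ** 2) / expected[0] + (
            (n_total - n_hit - expected[1]) ** 2
        ) / expected[1]
        return float(stats.chi2.sf(chi2, df=1)), "chi2"
    return float(stats.binomtest(n_hit, n_total, p0).pvalue), "binomial"


def _neighbor_pairs(
    deficiencies: list[DeficiencyLine],
    net: nx.Graph,
    calls: pd.DataFrame,
    changed: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """One row per (line, one-dose hub, neighbor) with hub class and the
    neighbor's change status/sign in that line."""
    rows = []
    for d in deficiencies:
        if d.name not in changed:
            continue
        tab = changed[d.name]
        nbrs = first_degree_neighbors(net, [g for g in d.one_dose_genes if g in calls.index])
        for hub, nset in nbrs.items():
            cls = calls.loc[hub, "class"]
            for nb in nset:
                if nb not in tab.index:
                    continue
                rows.append(
                    (d.name, hub, cls, nb, bool(tab.loc[nb, "changed"]), int(tab.loc[nb, "sign"]))
                )
    return pd.DataFrame(
        rows, columns=["line", "hub", "class", "neighbor", "changed", "sign"]
    )


def global_change_rates(
    net: nx.Graph,
    changed: dict[str, pd.DataFrame],
    deficiencies: list[DeficiencyLine],
    measured_genes: pd.Index,
) -> dict:
    """Pooled global change probability and positive-direction proportion.

    The primary denominator is network nodes two-dose in each line (the
    null neighbors are drawn from those); the all-measured-genes
    denominator is reported alongside.
    """
    one_dose = {d.name: set(d.one_dose_genes) for d in deficiencies}
    n_net = c_net = n_all = c_all = pos = chg = 0
    for line, tab in changed.items():
        od = one_dose.get(line, set())
        two_dose = tab.index.difference(od)
        sub = tab.loc[two_dose]
        netmask = sub.index.isin(net.nodes())
        n_net += int(netmask.sum())
        c_net += int(sub.loc[netmask, "changed"].sum())
        n_all += len(sub)
        c_all += int(sub["changed"].sum())
        ch = sub[sub["changed"]]
        chg += len(ch)
        pos += int((ch["sign"] > 0).sum())
    return {
        "p_change_network_nodes": c_net / n_net if n_net else np.nan,
        "p_change_all_measured": c_all / n_all if n_all else np.nan,
        "p_positive_given_changed": pos / chg if chg else np.nan,
        "n_network_nodes": n_net,
        "n_all_measured": n_all,
    }


def neighbor_change_by_class(
    deficiencies: list[DeficiencyLine],
    net: nx.Graph,
    calls: pd.DataFrame,
    changed: dict[str, pd.DataFrame],
    measured_genes: pd.Index,
    mode: str = "pair",
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Probability of first-degree-neighbor change per compensation class.

    ``mode='pair'`` (default): every (one-dose gene -> neighbor) pair
    counts once, so a neighbor shared by two hubs of a class counts twice.
    ``mode='unique'``: each neighbor counts once per class and line.
    The per-class probability is tested against the pooled global change
    probability over two-dose network nodes (1-df chi-square, exact
    binomial when expected counts are small).
    """
    pairs = _neighbor_pairs(deficiencies, net, calls, changed)
    rates = global_change_rates(net, changed, deficiencies, measured_genes)
    p0 = rates["p_change_network_nodes"]
    rows = []
    for cls in ("anti", "non", "partial", "full", "over"):
        sub = pairs[pairs["class"] == cls]
        if mode == "unique":
            sub = sub.drop_duplicates(subset=["line", "neighbor"])
        n = len(sub)
        if n == 0:
            rows.append({"class": cls, "n_hubs": 0, "n_neighbors": 0,
                         "p_change": np.nan, "p_vs_global": np.nan, "test": "none"})
            continue
        k = int(sub["changed"].sum())
        p, which = _rate_test(k, n, p0)
        rows.append(
            {
                "class": cls,
                "n_hubs": sub["hub"].nunique(),
                "n_neighbors": n,
                "n_changed": k,
                "p_change": k / n,
                "p_vs_global": p,
                "significant": (p < alpha) if np.isfinite(p) else False,
                "test": which,
            }
        )
    return pd.DataFrame(rows).set_index("class"), rates


def neighbor_direction_by_class(
    deficiencies: list[DeficiencyLine],
    net: nx.Graph,
    calls: pd.DataFrame,
    changed: dict[str, pd.DataFrame],
    measured_genes: pd.Index,
    mode: str = "pair",
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, dict]:
    """Proportion of changed neighbors with increased expression, per hub
    class, tested against the global positive proportion among changed
    two-dose genes."""
    pairs = _neighbor_pairs(deficiencies, net, calls, changed)
    rates = global_change_rates(net, changed, deficiencies, measured_genes)
    p0 = rates["p_positive_given_changed"]
    rows = []
    for cls in ("anti", "non", "partial", "full", "over"):
        sub = pairs[(pairs["class"] == cls) & pairs["changed"]]
        if mode == "unique":
            sub = sub.drop_duplicates(subset=["line", "neighbor"])
        n = len(sub)
        if n == 0:
            rows.append({"class": cls, "n_changed_neighbors": 0,
                         "p_positive": np.nan, "p_vs_global": np.nan, "test": "none"})
            continue
        k = int((sub["sign"] > 0).sum())
        p, which = _rate_test(k, n, p0)
        rows.append(
            {
                "class": cls,
                "n_changed_neighbors": n,
                "n_positive": k,
                "p_positive": k / n,
                "p_vs_global": p,
                "significant": (p < alpha) if np.isfinite(p) else False,
                "test": which,
            }
        )
    return pd.DataFrame(rows).set_index("class"), rates


# ---------------------------------------------------------------------------
# protein-complex coherence


def complex_coherence(
    changed: dict[tuple[str, str], pd.DataFrame] | dict[str, dict[str, pd.DataFrame]],
    complexes: pd.DataFrame,
    deficiencies: list[DeficiencyLine],
    measured_genes: dict[str, pd.Index],
    min_members: int = 10,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Joint change-enrichment and direction-uniformity per
    (complex, line, sex) cell.

    For each cell: the universe is the measured two-dose genes of that
    line and sex; enrichment p is the upper-tail hypergeometric of the
    number of changed members; direction p is a two-sided binomial of the
    positive count among changed members at the global positive rate of
    that sex; the joint p is their product, flagged at < ``alpha``. The
    pure enrichment p is reported alongside. Complexes are filtered once
    per sex — fewer than ``min_members`` members among that sex's
    measured genes excludes the complex (logged) — so the retained
    complexes enumerate a complete complex x line matrix per sex.
    """
    if changed and isinstance(next(iter(changed.values())), dict):
        flat = {(line, sex): tab for sex, d in changed.items() for line, tab in d.items()}
    else:
        flat = dict(changed)  # type: ignore[arg-type]
    one_dose = {d.name: set(d.one_dose_genes) for d in deficiencies}
    members = {c: set(grp["gene"]) for c, grp in complexes.groupby("complex_id")}

    # global positive-direction rate per sex (pooled over lines)
    pos_rate: dict[str, float] = {}
    for sex in {s for _, s in flat}:
        pos = tot = 0
        for (line, s), tab in flat.items():
            if s != sex:
                continue
            ch = tab[tab["changed"] & ~tab.index.isin(one_dose.get(line, set()))]
            pos += int((ch["sign"] > 0).sum())
            tot += len(ch)
        pos_rate[sex] = pos / tot if tot else 0.5

    # select complexes once per sex, on that sex's measured gene set
    kept: dict[str, list[str]] = {}
    for sex in {s for _, s in flat}:
        measured = measured_genes.get(sex, pd.Index([]))
        kept[sex] = []
        for cid, mem in sorted(members.items()):
            n_meas = sum(g in measured for g in mem)
            if n_meas >= min_members:
                kept[sex].append(cid)
            else:
                logger.info("complex %s (%s): %d measured members < %d, excluded",
                            cid, sex, n_meas, min_members)

    rows = []
    for (line, sex), tab in sorted(flat.items()):
        universe = tab.index.difference(one_dose.get(line, set()))
        if sex in measured_genes:
            universe = universe.intersection(measured_genes[sex])
        sub = tab.loc[universe]
        n_universe = len(sub)
        n_changed_universe = int(sub["changed"].sum())
        for cid in kept[sex]:
            measured = [g for g in members[cid] if g in sub.index]
            msub = sub.loc[measured]
            k = int(msub["changed"].sum())
            p_enrich = float(
                stats.hypergeom.sf(k - 1, n_universe, n_changed_universe, len(measured))
            )
            ch = msub[msub["changed"]]
            if len(ch):
                k_pos = int((ch["sign"] > 0).sum())
                p_dir = float(stats.binomtest(k_pos, len(ch), pos_rate[sex]).pvalue)
                dominant = max(k_pos, len(ch) - k_pos)
            else:
                k_pos, p_dir, dominant = 0, 1.0, 0
            p_joint = p_enrich * p_dir
            rows.append(
                {
                    "complex_id": cid,
                    "line": line,
                    "sex": sex,
                    "members_measured": len(measured),
                    "members_changed": k,
                    "n_positive": k_pos,
                    "dominant_direction_count": dominant,
                    "p_enrichment": p_enrich,
                    "p_direction": p_dir,
                    "p_joint": p_joint,
                    "significant": p_joint < alpha,
                }
            )
    return pd.DataFrame(rows)


def coherence_matrix(results: pd.DataFrame, sex: str, scale: str = "inverse_log") -> pd.DataFrame:
    """Complex x line matrix of joint p (default -log10) for heat maps."""
    sub = results[results["sex"] == sex]
    mat = sub.pivot(index="complex_id", columns="line", values="p_joint")
    if scale == "inverse_log":
        mat = -np.log10(mat)
    return mat
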