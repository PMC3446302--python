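"""Sex-specific mutual-information co-expression networks.

Profiles are z-scored per gene across all lines and replicates of one sex,
pairwise MI is estimated with a Gaussian-kernel plug-in (bandwidth h,
diagonal bandwidth in the bivariate term):

    MI = (1/n) * sum_i log[ f_XY(x_i, y_i) / (f_X(x_i) * f_Y(y_i)) ]

in nats. Edge significance uses a pooled permutation null: after
z-scoring, the null MI distribution depends only on n and h, so one null
sample (MI of independently permuted profile pairs) serves all pairs —
per-pair permutation across all O(G^2) pairs at alpha = 0.005 would be
intractable. Topology statistics and a degree-preserving double-edge-swap
null model (swap endpoints, reject self-loops and already-existing edges)
support the downstream propagation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .containers import ExpressionMatrix


def standardize(
    matrix: ExpressionMatrix, sex: str, genes: pd.Index | None = None
) -> pd.DataFrame:
    """Per-gene z-scores over one sex's samples; zero-SD genes excluded."""
    ids = matrix.sex_samples(sex)
    vals = matrix.gene_values()[ids]
    if genes is not None:
        vals = vals.loc[[g for g in genes if g in vals.index]]
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    zero = sd == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} zero-variance genes from standardization")
        vals, mu, sd = vals[~zero], mu[~zero], sd[~zero]
    return vals.sub(mu, axis=0).div(sd, axis=0)


def kernel_mi(x: np.ndarray, y: np.ndarray, h: float = 0.3) -> float:
    """Plug-in kernel MI (nats) between two equal-length profiles.

    Gaussian kernels of width ``h`` for the marginals and diagonal
    bandwidth h*I for the joint; normalization constants cancel in the
    ratio. Symmetric in its arguments by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D profiles")
    if len(x) < 8:
        raise ValueError("need n >= 8 samples")
    kx = np.exp(-0.5 * ((x[:, None] - x[None, :]) / h) ** 2)
    ky = np.exp(-0.5 * ((y[:, None] - y[None, :]) / h) ** 2)
    joint = (kx * ky).mean(axis=1)
    fx = kx.mean(axis=1)
    fy = ky.mean(axis=1)
    return float(np.mean(np.log(joint / (fx * fy))))


def _kernel_tensor(z: np.ndarray, h: float) -> np.ndarray:
    """(G, n, n) Gaussian kernel values between samples, per gene."""
    d = z[:, :, None] - z[:, None, :]
    return np.exp(-0.5 * (d / h) ** 2)


def mi_matrix(z: pd.DataFrame, h: float = 0.3) -> pd.DataFrame:
    """All-pairs kernel MI for a z-scored genes x samples frame."""
    a = _kernel_tensor(z.to_numpy(), h)
    g, n, _ = a.shape
    marg = a.mean(axis=2)  # (G, n) marginal density at each sample point
    out = np.zeros((g, g))
    for i in range(n):
        m = np.ascontiguousarray(a[:, i, :])  # (G, n)
        joint = (m @ m.T) / n
        out += np.log(joint / (marg[:, i][:, None] * marg[:, i][None, :]))
    out /= n
    np.fill_diagonal(out, np.nan)  # self-information is not an edge score
    return pd.DataFrame(out, index=z.index, columns=z.index)


def pair_mi(
    z: pd.DataFrame, pairs: list[tuple[str, str]], h: float = 0.3, chunk: int = 512
) -> np.ndarray:
    """Kernel MI for an explicit list of gene pairs (batched)."""
    zi = {g: k for k, g in enumerate(z.index)}
    arr = z.to_numpy()
    ix = np.array([zi[a] for a, _ in pairs])
    iy = np.array([zi[b] for _, b in pairs])
    out = np.empty(len(pairs))
    for s in range(0, len(pairs), chunk):
        e = min(s + chunk, len(pairs))
        kx = _kernel_tensor(arr[ix[s:e]], h)
        ky = _kernel_tensor(arr[iy[s:e]], h)
        joint = (kx * ky).mean(axis=2)
        fx = kx.mean(axis=2)
        fy = ky.mean(axis=2)
        out[s:e] = np.log(joint / (fx * fy)).mean(axis=1)
    return out


def null_mi_sample(
    z: pd.DataFrame, h: float = 0.3, n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Pooled permutation null: MI of independently permuted profile pairs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = z.to_numpy()
    g, n = arr.shape
    xs = arr[rng.integers(0, g, n_perm)]
    ys = arr[rng.integers(0, g, n_perm)]
    perm = np.argsort(rng.random((n_perm, n)), axis=1)
    ys = np.take_along_axis(ys, perm, axis=1)
    out = np.empty(n_perm)
    chunk = 512
    for s in range(0, n_perm, chunk):
        e = min(s + chunk, n_perm)
        kx = _kernel_tensor(xs[s:e], h)
        ky = _kernel_tensor(ys[s:e], h)
        joint = (kx * ky).mean(axis=2)
        out[s:e] = np.log(joint / (kx.mean(axis=2) * ky.mean(axis=2))).mean(axis=1)
    return out


def edge_significance(
    z: pd.DataFrame,
    h: float = 0.3,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.005,
) -> pd.DataFrame:
    """MI and pooled-permutation p for every unordered gene pair.

    p = (1 + #{null >= observed}) / (1 + n_perm), so p is in (0, 1];
    ``n_perm`` must be at least 2/alpha for the requested significance
    level to be attainable.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    if n_perm < 2.0 / alpha:
        raise ValueError(f"n_perm={n_perm} too small for alpha={alpha} (need >= {2/alpha:.0f})")
    mim = mi_matrix(z, h)
    null = np.sort(null_mi_sample(z, h, n_perm, seed))
    genes = list(z.index)
    iu = np.triu_indices(len(genes), k=1)
    mi = mim.to_numpy()[iu]
    p = (1.0 + (len(null) - np.searchsorted(null, mi, side="left"))) / (1.0 + len(null))
    return pd.DataFrame(
        {
            "gene_a": np.asarray(genes, dtype=object)[iu[0]],
            "gene_b": np.asarray(genes, dtype=object)[iu[1]],
            "mi": mi,
            "p": p,
        }
    )


def build_network(
    edges: pd.DataFrame, alpha: float = 0.005, nodes=None
) -> nx.Graph:
    """Simple graph with edges at p < alpha; isolated measured genes are
    kept as nodes so one-dose genes without edges remain queryable."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    else:
        g.add_nodes_from(pd.unique(edges[["gene_a", "gene_b"]].to_numpy().ravel()))
    sig = edges[edges["p"] < alpha]
    g.add_edges_from(
        (a, b, {"mi": m, "p": p})
        for a, b, m, p in sig[["gene_a", "gene_b", "mi", "p"]].itertuples(index=False)
    )
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


# ---------------------------------------------------------------------------
# topology


def fit_power_law_exponent(degrees) -> float:
    """Least-squares slope of log frequency vs log degree (degree >= 1)."""
    deg = np.asarray([d for d in degrees if d >= 1])
    if len(deg) == 0:
        return np.nan
    ks, counts = np.unique(deg, return_counts=True)
    if len(ks) < 2:
        return np.nan
    slope = np.polyfit(np.log(ks), np.log(counts / counts.sum()), 1)[0]
    return float(slope)


@dataclass(frozen=True)
class TopologyStats:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    average_neighbors: float
    density: float
    power_law_exponent: float


def topology_stats(g: nx.Graph) -> TopologyStats:
    """Average local clustering, mean degree, density and power-law slope."""
    n = g.number_of_nodes()
    if n < 3:
        raise ValueError("need >= 3 nodes")
    e = g.number_of_edges()
    clustering = nx.average_clustering(g) if e else 0.0
    return TopologyStats(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=float(clustering),
        average_neighbors=2.0 * e / n,
        density=float(nx.density(g)),
        power_law_exponent=fit_power_law_exponent([d for _, d in g.degree()]) if e else np.nan,
    )


# ---------------------------------------------------------------------------
# degree-preserving null model


def _double_edge_swap(g: nx.Graph, n_attempts: int, rng: np.random.Generator) -> int:
    """In-place double-edge swaps; returns the number of successful swaps."""
    edges = list(g.edges())
    n_done = 0
    m = len(edges)
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if len({a, b, c, d}) < 4:
            continue
        if g.has_edge(a, d) or g.has_edge(c, b):
            continue
        g.remove_edge(a, b)
        g.remove_edge(c, d)
        g.add_edge(a, d)
        g.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
        n_done += 1
    return n_done


def randomized_graphs(
    g: nx.Graph,
    n_randomizations: int = 100,
    n_swaps_factor: int = 10,
    seed: int | np.random.Generator = 0,
):
    """Yield degree-preserving randomizations of ``g``.

    Each randomization attempts ``n_swaps_factor * |E|`` double-edge swaps
    (endpoints exchanged; swaps creating self-loops or already-existing
    edges are rejected), which preserves every node's degree exactly. A
    graph admitting no legal swap (e.g. a complete graph or K3) is yielded
    unchanged with a warning.
    """
    if g.number_of_edges() < 2:
        raise ValueError("need >= 2 edges")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    warned = False
    for _ in range(n_randomizations):
        h = g.copy()
        done = _double_edge_swap(h, n_swaps_factor * g.number_of_edges(), rng)
        if done == 0 and not warned:
            warnings.warn("graph admits no legal double-edge swap; returning it unchanged")
            warned = True
        yield h


def degree_preserving_shuffle(
    g: nx.Graph,
    statistic,
    n_randomizations: int = 100,
    n_swaps_factor: int = 10,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Empirical null of ``statistic`` under degree-preserving shuffling.

    Returns observed value, the null sample, and add-one empirical
    p-values for the observed being high (``p_greater``) or low
    (``p_less``).
    """
    observed = statistic(g)
    null = np.array(
        [statistic(h) for h in randomized_graphs(g, n_randomizations, n_swaps_factor, seed)]
    )
    r = len(null)
    return {
        "observed": float(observed),
        "null": null,
        "p_greater": float((1 + np.sum(null >= observed)) / (1 + r)),
        "p_less": float((1 + np.sum(null <= observed)) / (1 + r)),
    }


def subnetwork_clustering_by_bias(
    g: nx.Graph,
    bias_labels: pd.Series,
    n_randomizations: int = 100,
    n_swaps_factor: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Induced-subgraph clustering per sex-bias group with shuffle p.

    For each group, the clustering coefficient of the induced subgraph is
    compared with its distribution over degree-preserving randomizations
    of the *full* network (group membership fixed).
    """
    groups = [grp for grp in pd.unique(bias_labels.reindex(g.nodes()).dropna())]
    members = {
        grp: [v for v in g.nodes() if bias_labels.get(v) == grp] for grp in groups
    }

    def group_clustering(net: nx.Graph, grp: str) -> float:
        nodes = members[grp]
        if len(nodes) < 3:
            return np.nan
        return nx.average_clustering(net.subgraph(nodes))

    observed = {grp: group_clustering(g, grp) for grp in groups}
    null: dict[str, list[float]] = {grp: [] for grp in groups}
    for h in randomized_graphs(g, n_randomizations, n_swaps_factor, seed):
        for grp in groups:
            null[grp].append(group_clustering(h, grp))
    rows = []
    for grp in groups:
        obs = observed[grp]
        arr = np.array(null[grp])
        if np.isnan(obs):
            rows.append({"bias": grp, "n_nodes": len(members[grp]), "clustering": np.nan,
                         "p_greater": np.nan})
            continue
        p = float((1 + np.sum(arr >= obs)) / (1 + len(arr)))
        rows.append({"bias": grp, "n_nodes": len(members[grp]), "clustering": float(obs),
                     "p_greater": p})
    return pd.DataFrame(rows).set_index("bias")


def write_edge_list(edges: pd.DataFrame, path, alpha: float = 0.005) -> None:
    """TSV edge list (gene_a, gene_b, mi, p) of significant edges."""
    edges[edges["p"] < alpha].to_csv(path, sep="\t", index=False)


def write_sif(g: nx.Graph, path, interaction: str = "mi") -> None:
    """SIF export for interchange with graph viewers."""
    with open(path, "w") as fh:
        seen = set()
        for a, b in g.edges():
            fh.write(f"{a}\t{interaction}\t{b}\n")
            seen.update((a, b))
        for v in g.nodes():
            if v not in seen:
                fh.write(f"{v}\n")
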