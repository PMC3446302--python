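"""Synthetic study generator with planted ground truth.

Emulates the design of a deficiency-heterozygote dosage study in
*Drosophila*: a parental line plus 21 Df/+ lines, two sexes, biological
triplicates, gene-level log2 expression with control probes and external
spike-ins, and binned DNA-seq coverage in which deleted regions have half
the read depth. Ground truth is planted for every verifiable downstream
stage: per-gene compensation classes and true dose responses, a scale-free
co-expression network, per-class first-degree-neighbor responses, sex-bias
groups, and the deleted intervals themselves.

All randomness derives from a single master seed; each component draws from
its own deterministic child stream, so a fixed seed reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    COMPENSATION_CLASSES,
    PROBE_CONTROL,
    PROBE_GENE,
    PROBE_SPIKE,
    CoverageTrack,
    DeficiencyLine,
    ExpressionMatrix,
    PlantedTruth,
)

PARENTAL_LINE = "w1118"
SEXES = ("female", "male")

# log2 ratios of the three spike-in subsets (Df mix vs parental mix):
# 1:1, 1.5:1, 1:1.5
SPIKE_SUBSET_LOG2 = {"1:1": 0.0, "1.5:1": np.log2(1.5), "1:1.5": -np.log2(1.5)}


class InvalidConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic generator.

    Defaults emulate the real study's design (21 Df/+ lines + parental,
    two sexes, triplicates) at a computationally tractable genome scale;
    per-class effect ranges are exposed because the source study reports
    only the qualitative class structure, not effect-size distributions.
    """

    n_genes: int = 500
    n_lines: int = 21
    n_replicates: int = 3  # per sex
    chrom_length: int | None = None  # default: 8 kb per gene
    chrom: str = "2L"
    #: mean number of contiguous genes removed per deficiency
    genes_per_df: int = 2
    #: proportions over (anti, non, partial, full, over)
    class_mixture: tuple[float, ...] = (0.05, 0.40, 0.30, 0.20, 0.05)
    #: per-class uniform ranges for the true log2 one-dose response
    class_effects: dict = field(
        default_factory=lambda: {
            "anti": (-1.9, -1.3),
            "non": (-1.0, -0.95),
            "partial": (-0.65, -0.35),
            "full": (-0.06, 0.06),
            "over": (0.35, 0.65),
        }
    )
    #: planted log2 shift of first-degree neighbors, per hub class
    neighbor_shift: dict = field(
        default_factory=lambda: {
            "anti": -0.9,
            "non": -0.6,
            "partial": 0.6,
            "full": 0.6,
            "over": 0.7,
        }
    )
    #: target exponent of the planted degree distribution
    network_degree_exponent: float = 2.5
    #: cap on planted degrees (keeps per-edge correlation from vanishing
    #: at the largest hubs)
    network_max_degree: int = 20
    #: weight of per-edge latent co-expression factors
    coexpression_weight: float = 0.12
    #: 'line' draws one factor per (line, sex) — biological line-level
    #: covariation; 'sample' draws per sample (iid co-expression)
    coexpression_per: str = "line"
    noise_sd: float = 0.25  # log2 units, replicate-level
    #: SD of the sex-shared gene-specific wobble is folded into class_effects;
    #: sex-specific deviation SDs by bias group:
    sex_effect_sd_biased: float = 0.25
    sex_effect_sd_unbiased: float = 0.05
    sex_bias_fractions: tuple[float, float, float] = (0.2, 0.2, 0.6)  # f, m, none
    sex_bias_magnitude: float = 1.5  # log2 offset between sexes for biased genes
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    baseline_min: float = 6.5
    n_controls: int = 50
    control_mean: float = 4.0
    control_sd: float = 0.3
    n_spikes_per_subset: int = 32
    spike_ratios: tuple[str, ...] = ("1:1", "1.5:1", "1:1.5")
    coverage_depth: float = 100.0  # mean reads per bin (two-dose regions)
    bin_size: int = 1000
    n_complexes: int = 23
    complex_size_range: tuple[int, int] = (12, 20)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_lines, self.n_replicates) < 1:
            raise InvalidConfigError("all counts must be >= 1")
        if abs(sum(self.class_mixture) - 1.0) > 1e-9 or len(self.class_mixture) != 5:
            raise InvalidConfigError("class_mixture must be 5 proportions summing to 1")
        if self.coverage_depth <= 0:
            raise InvalidConfigError("coverage_depth must be > 0")
        if self.length // self.n_genes < 200:
            raise InvalidConfigError(
                "chromosome too short: need >= 200 bp per gene"
            )

    @property
    def length(self) -> int:
        return self.chrom_length if self.chrom_length is not None else 8000 * self.n_genes

    def rng(self, *stream: int) -> np.random.Generator:
        """Deterministic child stream of the master seed."""
        return np.random.default_rng([self.seed, *stream])


# component stream ids
_S_ANNOT, _S_DF, _S_TRUTH, _S_EXPR, _S_COV, _S_COMPLEX = range(1, 7)


def generate_annotation(config: SyntheticConfig) -> pd.DataFrame:
    """Non-overlapping gene intervals in genome order, 1-based inclusive."""
    rng = config.rng(_S_ANNOT)
    g, total = config.n_genes, config.length
    max_len = max(201, int(0.5 * total / g))
    lengths = rng.integers(200, max_len + 1, size=g)
    slack = total - int(lengths.sum())
    if slack < 0:  # cannot happen with max_len <= total/(2g), kept defensive
        raise GenerationError("gene lengths exceed chromosome")
    gaps = rng.multinomial(slack, np.full(g + 1, 1.0 / (g + 1)))
    first = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])]) + 1
    last = first + lengths - 1
    return pd.DataFrame(
        {
            "gene": [f"g{i:05d}" for i in range(g)],
            "chrom": config.chrom,
            "first": first.astype(int),
            "last": last.astype(int),
            "strand": "+",
        }
    )


def _one_dose_genes(annotation: pd.DataFrame, first: int, last: int) -> tuple[str, ...]:
    """Genes overlapping [first, last] (1-based inclusive) by >= 1 bp."""
    hit = (annotation["first"] <= last) & (annotation["last"] >= first)
    return tuple(annotation.loc[hit, "gene"])


def generate_deficiencies(
    config: SyntheticConfig, annotation: pd.DataFrame
) -> list[DeficiencyLine]:
    """Place ``n_lines`` deletions; at least two pairs of lines overlap.

    Each deletion removes ``genes_per_df`` contiguous genes in full or part.
    Overlapping pairs are placed deliberately so that some one-dose genes
    recur in multiple deficiencies.
    """
    rng = config.rng(_S_DF)
    g, n, k = config.n_genes, config.n_lines, max(1, config.genes_per_df)
    if n > g // 2:
        raise InvalidConfigError("n_lines must be <= n_genes / 2")
    if n * k > g:
        raise GenerationError("cannot place deficiencies: too many genes requested")
    # evenly spaced starts with jitter, then force two overlapping pairs
    spacing = g / n
    starts = np.minimum(
        (np.arange(n) * spacing).astype(int)
        + rng.integers(0, max(1, int(spacing - k)), size=n),
        g - k,
    )
    if n >= 2:
        starts[1] = starts[0] + (k // 2)  # first overlapping pair
    if n >= 4:
        starts[n // 2 + 1] = starts[n // 2] + (k // 2)  # second overlapping pair
    starts = np.minimum(starts, g - k)

    firsts = annotation["first"].to_numpy()
    lasts = annotation["last"].to_numpy()
    lines = []
    for i, s in enumerate(starts):
        lo, hi = int(firsts[s]), int(lasts[s + k - 1])
        # jitter breakpoints into flanking intergenic space without touching
        # the neighboring genes, so the one-dose set is exactly genes [s, s+k)
        left_gap = firsts[s] - (lasts[s - 1] + 1) if s > 0 else firsts[s] - 1
        right_gap = (
            firsts[s + k] - 1 - lasts[s + k - 1] if s + k < g else config.length - lasts[s + k - 1]
        )
        lo -= int(rng.integers(0, max(1, left_gap // 2)))
        hi += int(rng.integers(0, max(1, right_gap // 2)))
        lines.append(
            DeficiencyLine(
                name=f"Df_{i + 1:02d}",
                chrom=config.chrom,
                first=max(1, lo),
                last=min(config.length, hi),
                one_dose_genes=_one_dose_genes(annotation, max(1, lo), min(config.length, hi)),
            )
        )
    n_overlap_pairs = sum(
        lines[i].overlaps(lines[j]) for i in range(n) for j in range(i + 1, n)
    )
    if n >= 4 and n_overlap_pairs < 2:
        raise GenerationError("failed to place two overlapping deficiency pairs")
    return lines


def _planted_network(config: SyntheticConfig, genes: list[str]) -> list[tuple[str, str]]:
    """Simple scale-free graph from a power-law degree sequence."""
    rng = config.rng(_S_TRUTH, 1)
    n = len(genes)
    w = nx.utils.powerlaw_sequence(n, exponent=config.network_degree_exponent, seed=int(rng.integers(2**31)))
    deg = np.maximum(1, np.round(w).astype(int))
    deg = np.minimum(deg, min(n - 1, config.network_max_degree))
    if deg.sum() % 2:
        deg[int(np.argmax(deg))] += 1
    g = nx.configuration_model(list(deg), seed=int(rng.integers(2**31)))
    g = nx.Graph(g)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    return [(genes[a], genes[b]) for a, b in g.edges()]


def generate_truth(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    deficiencies: list[DeficiencyLine],
) -> PlantedTruth:
    """Plant classes, true responses, sex-bias labels and the network."""
    rng = config.rng(_S_TRUTH)
    genes = list(annotation["gene"])
    classes = pd.Series(
        rng.choice(COMPENSATION_CLASSES, size=len(genes), p=config.class_mixture),
        index=genes,
        name="class",
    )
    base = np.empty(len(genes))
    for cls, (lo, hi) in config.class_effects.items():
        m = classes.to_numpy() == cls
        base[m] = rng.uniform(lo, hi, size=int(m.sum()))
    true_lfc = pd.Series(base, index=genes, name="true_lfc")

    bias = pd.Series(
        rng.choice(["female", "male", "none"], size=len(genes), p=config.sex_bias_fractions),
        index=genes,
        name="sex_bias",
    )
    sd = np.where(
        bias.to_numpy() == "none",
        config.sex_effect_sd_unbiased,
        config.sex_effect_sd_biased,
    )
    by_sex = pd.DataFrame(
        {
            "female": base + rng.normal(0, sd),
            "male": base + rng.normal(0, sd),
        },
        index=genes,
    )
    return PlantedTruth(
        gene_class=classes,
        true_lfc=true_lfc,
        edges=_planted_network(config, genes),
        sex_bias=bias,
        deleted={d.name: (d.first, d.last) for d in deficiencies},
        neighbor_shift=pd.Series(config.neighbor_shift),
        true_lfc_by_sex=by_sex,
    )


def simulate_coverage(
    config: SyntheticConfig,
    deficiencies: list[DeficiencyLine],
    sex: str,
) -> dict[str, CoverageTrack]:
    """Poisson binned DNA-seq tracks per line (plus the parental line).

    Expected depth is ``coverage_depth`` per bin outside deletions and half
    that inside; boundary bins are pro-rated by deleted fraction.
    """
    n_bins = -(-config.length // config.bin_size)
    bin_lo = np.arange(n_bins) * config.bin_size  # 0-based half-open bins
    bin_hi = np.minimum(bin_lo + config.bin_size, config.length)
    widths = (bin_hi - bin_lo).astype(float)
    tracks: dict[str, CoverageTrack] = {}
    sex_i = SEXES.index(sex)
    for li, line in enumerate([None] + deficiencies):
        rng = config.rng(_S_COV, sex_i, li)
        lam = np.full(n_bins, config.coverage_depth) * widths / config.bin_size
        if line is not None:
            start, end = line.first - 1, line.last  # internal half-open
            frac = (
                np.clip(np.minimum(bin_hi, end) - np.maximum(bin_lo, start), 0, None)
                / widths
            )
            lam *= 1.0 - 0.5 * frac
        name = PARENTAL_LINE if line is None else line.name
        tracks[name] = CoverageTrack(
            chrom=config.chrom,
            bin_size=config.bin_size,
            counts=rng.poisson(lam).astype(float),
            chrom_length=config.length,
        )
    return tracks


def _sample_table(config: SyntheticConfig, deficiencies: list[DeficiencyLine]) -> pd.DataFrame:
    lines = [PARENTAL_LINE] + [d.name for d in deficiencies]
    rows = [
        (f"{line}_{sex}_{r + 1}", line, sex, r + 1)
        for sex in SEXES
        for line in lines
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(
        rows, columns=["sample", "line", "sex", "replicate"]
    ).set_index("sample")


def simulate_expression(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    deficiencies: list[DeficiencyLine],
    truth: PlantedTruth | None = None,
) -> tuple[ExpressionMatrix, PlantedTruth]:
    """log2 expression for all samples, with planted structure.

    Per gene and sample the value is
    baseline + sex-bias offset + dose response (if one-dose in that line)
    + planted neighbor shift (if first-degree neighbor of a one-dose gene)
    + per-edge co-expression factors (drawn per line and sex)
    + iid Gaussian noise.  Control probes and spike-ins are appended.
    """
    if truth is None:
        truth = generate_truth(config, annotation, deficiencies)
    rng = config.rng(_S_EXPR)
    genes = list(annotation["gene"])
    gi = {g: i for i, g in enumerate(genes)}
    samples = _sample_table(config, deficiencies)
    n_s = len(samples)

    baseline = np.maximum(
        rng.normal(config.baseline_mean, config.baseline_sd, len(genes)),
        config.baseline_min,
    )
    half_bias = 0.5 * config.sex_bias_magnitude
    bias_vec = truth.sex_bias.to_numpy()
    sex_offset = {
        "female": np.where(bias_vec == "female", half_bias, np.where(bias_vec == "male", -half_bias, 0.0)),
        "male": np.where(bias_vec == "male", half_bias, np.where(bias_vec == "female", -half_bias, 0.0)),
    }

    one_dose = {d.name: set(d.one_dose_genes) for d in deficiencies}
    neighbors: dict[str, list[str]] = {g: [] for g in genes}
    for a, b in truth.edges:
        neighbors[a].append(b)
        neighbors[b].append(a)

    # per-line-and-sex mean surface (line effects shared by replicates)
    line_mean: dict[tuple[str, str], np.ndarray] = {}
    edge_index = {e: k for k, e in enumerate(truth.edges)}
    w = config.coexpression_weight
    for sex in SEXES:
        for line in [PARENTAL_LINE] + [d.name for d in deficiencies]:
            line_mean[(line, sex)] = baseline + sex_offset[sex]

    # co-expression factors: per-edge latent variables, one draw per
    # (line, sex) by default (line-level biological covariation) or per
    # sample (iid covariation; used when within-line variance must not
    # carry the network signal)
    incidence = np.zeros((len(genes), len(truth.edges)))
    for (a, b), k in edge_index.items():
        incidence[gi[a], k] = 1.0
        incidence[gi[b], k] = 1.0
    sample_coexpr = np.zeros((len(genes), n_s))
    if w > 0 and truth.edges:
        if config.coexpression_per == "line":
            for si, sex in enumerate(SEXES):
                zrng = config.rng(_S_EXPR, 11, si)
                lines = [PARENTAL_LINE] + [d.name for d in deficiencies]
                z = zrng.normal(0.0, 1.0, size=(len(lines), len(truth.edges)))
                for li, line in enumerate(lines):
                    line_mean[(line, sex)] += w * (incidence @ z[li])
        elif config.coexpression_per == "sample":
            zrng = config.rng(_S_EXPR, 12)
            z = zrng.normal(0.0, 1.0, size=(len(truth.edges), n_s))
            sample_coexpr = w * (incidence @ z)
        else:
            raise InvalidConfigError("coexpression_per must be 'line' or 'sample'")

    # dose responses and neighbor shifts
    shift_by = truth.neighbor_shift
    for d in deficiencies:
        od = one_dose[d.name]
        for sex in SEXES:
            mu = line_mean[(d.name, sex)]
            for g in od:
                mu[gi[g]] += truth.true_lfc_by_sex.loc[g, sex]
                for nb in neighbors[g]:
                    if nb not in od:
                        mu[gi[nb]] += shift_by[truth.gene_class[g]]

    # assemble gene values
    values = np.empty((len(genes), n_s))
    for j, (sid, row) in enumerate(samples.iterrows()):
        values[:, j] = line_mean[(row["line"], row["sex"])]
    values += sample_coexpr
    values += rng.normal(0.0, config.noise_sd, size=values.shape)

    # control probes
    ctrl = rng.normal(config.control_mean, config.control_sd, (config.n_controls, n_s))
    ctrl_ids = [f"ctrl{i:03d}" for i in range(config.n_controls)]

    # spike-ins: mix 1 in the parental samples, mix 2 in Df/+ samples
    spike_ids, spike_subsets, spike_expected, spike_rows = [], [], [], []
    is_df = (samples["line"] != PARENTAL_LINE).to_numpy()
    k = 0
    for subset in config.spike_ratios:
        lr = SPIKE_SUBSET_LOG2[subset]
        for _ in range(config.n_spikes_per_subset):
            base = rng.uniform(2.0, 22.0)  # 2^20 dynamic range
            row = np.full(n_s, base) + np.where(is_df, lr, 0.0)
            spike_rows.append(row)
            spike_ids.append(f"spike{k:03d}")
            spike_subsets.append(subset)
            spike_expected.append(lr)
            k += 1
    spikes = np.array(spike_rows) + rng.normal(
        0.0, config.noise_sd, (len(spike_rows), n_s)
    )

    all_values = pd.DataFrame(
        np.vstack([values, ctrl, spikes]),
        index=genes + ctrl_ids + spike_ids,
        columns=samples.index,
    )
    features = pd.DataFrame(
        {
            "probe_class": [PROBE_GENE] * len(genes)
            + [PROBE_CONTROL] * len(ctrl_ids)
            + [PROBE_SPIKE] * len(spike_ids),
            "spike_subset": [None] * (len(genes) + len(ctrl_ids)) + spike_subsets,
            "expected_log2_ratio": [np.nan] * (len(genes) + len(ctrl_ids))
            + spike_expected,
        },
        index=all_values.index,
    )
    return ExpressionMatrix(all_values, samples, features), truth


def generate_complexes(
    config: SyntheticConfig,
    annotation: pd.DataFrame,
    truth: PlantedTruth,
) -> pd.DataFrame:
    """Synthetic protein-complex membership table (complex_id, gene).

    About a third of complexes are drawn from planted-network neighborhoods
    (members share co-expression factors, so their expression co-changes);
    the rest are random gene sets. Stand-in for a curated complex catalog.
    """
    rng = config.rng(_S_COMPLEX)
    genes = list(annotation["gene"])
    adj: dict[str, set[str]] = {g: set() for g in genes}
    for a, b in truth.edges:
        adj[a].add(b)
        adj[b].add(a)
    rows = []
    for c in range(config.n_complexes):
        size = int(rng.integers(config.complex_size_range[0], config.complex_size_range[1] + 1))
        if c % 3 == 0:
            seed_gene = genes[int(rng.integers(len(genes)))]
            members, frontier = [seed_gene], [seed_gene]
            seen = {seed_gene}
            while frontier and len(members) < size:
                nxt = frontier.pop(0)
                for nb in sorted(adj[nxt]):
                    if nb not in seen:
                        seen.add(nb)
                        members.append(nb)
                        frontier.append(nb)
                        if len(members) >= size:
                            break
            while len(members) < size:  # top up sparse neighborhoods
                cand = genes[int(rng.integers(len(genes)))]
                if cand not in seen:
                    seen.add(cand)
                    members.append(cand)
        else:
            members = list(rng.choice(genes, size=size, replace=False))
        rows += [(f"cpx{c + 1:02d}", g) for g in members]
    return pd.DataFrame(rows, columns=["complex_id", "gene"])


@dataclass
class SyntheticStudy:
    """Bundle of everything one synthetic run produces."""

    config: SyntheticConfig
    annotation: pd.DataFrame
    deficiencies: list[DeficiencyLine]
    truth: PlantedTruth
    expression: ExpressionMatrix
    complexes: pd.DataFrame


def generate_study(config: SyntheticConfig | None = None, **overrides) -> SyntheticStudy:
    """One-call generator for the full synthetic study."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    annotation = generate_annotation(config)
    deficiencies = generate_deficiencies(config, annotation)
    truth = generate_truth(config, annotation, deficiencies)
    expression, truth = simulate_expression(config, annotation, deficiencies, truth)
    complexes = generate_complexes(config, annotation, truth)
    return SyntheticStudy(config, annotation, deficiencies, truth, expression, complexes)
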