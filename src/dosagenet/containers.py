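"""Core data containers shared across the pipeline.

Coordinate convention: genomic intervals are 1-based inclusive at every
public surface (matching deficiency breakpoint tables, "first missing
base"/"last missing base"); internal arithmetic uses 0-based half-open
offsets. :func:`to_internal` / :func:`to_external` are the only crossing
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_GENE = "gene"
PROBE_CONTROL = "control"
PROBE_SPIKE = "spike"

COMPENSATION_CLASSES = ("anti", "non", "partial", "full", "over")


def to_internal(first: int, last: int) -> tuple[int, int]:
    """1-based inclusive [first, last] -> 0-based half-open [start, end)."""
    if first < 1 or last < first:
        raise ValueError(f"invalid 1-based interval [{first}, {last}]")
    return first - 1, last


def to_external(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive [first, last]."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid 0-based interval [{start}, {end})")
    return start + 1, end


@dataclass(frozen=True)
class DeficiencyLine:
    """A named heterozygous deletion and the genes it reduces to one dose.

    ``first``/``last`` are 1-based inclusive deleted positions. A gene is
    one-dose if its interval overlaps the deletion by >= 1 bp (genes removed
    in full or in part).
    """

    name: str
    chrom: str
    first: int
    last: int
    one_dose_genes: tuple[str, ...] = ()

    @property
    def extent_bp(self) -> int:
        return self.last - self.first + 1

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.first + self.last)

    def overlaps(self, other: "DeficiencyLine") -> bool:
        return (
            self.chrom == other.chrom
            and self.first <= other.last
            and other.first <= self.last
        )


@dataclass
class CoverageTrack:
    """Binned read counts tiling one chromosome.

    ``counts[i]`` covers 0-based half-open [i*bin_size, (i+1)*bin_size),
    clipped at ``chrom_length``. ``total_reads`` is the library size used
    for RPM normalization (defaults to the track sum).
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    chrom_length: int
    total_reads: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("coverage counts must be non-negative")
        n_bins = -(-self.chrom_length // self.bin_size)
        if len(self.counts) != n_bins:
            raise ValueError(
                f"{len(self.counts)} bins do not tile chromosome of length "
                f"{self.chrom_length} at bin size {self.bin_size}"
            )
        if self.total_reads is None:
            self.total_reads = float(self.counts.sum())

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class ExpressionMatrix:
    """log2 expression with sample and feature annotation.

    values   : DataFrame, rows = features (genes + control probes + spike-ins),
               columns = sample ids.
    samples  : DataFrame indexed by sample id with columns
               ``line``, ``sex`` ('female'|'male'), ``replicate``.
    features : DataFrame indexed by feature id with column ``probe_class``
               in {gene, control, spike}; spike rows also carry
               ``spike_subset`` and ``expected_log2_ratio``.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("values columns must match samples index")
        if not self.values.index.equals(self.features.index):
            raise ValueError("values index must match features index")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite (no NA)")
        missing = {"line", "sex", "replicate"} - set(self.samples.columns)
        if missing:
            raise ValueError(f"sample metadata lacks columns: {sorted(missing)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.features.index[self.features["probe_class"] == PROBE_GENE]

    def gene_values(self) -> pd.DataFrame:
        return self.values.loc[self.gene_ids]

    def control_values(self) -> pd.DataFrame:
        ctrl = self.features.index[self.features["probe_class"] == PROBE_CONTROL]
        return self.values.loc[ctrl]

    def spike_features(self) -> pd.DataFrame:
        return self.features[self.features["probe_class"] == PROBE_SPIKE]

    def sex_samples(self, sex: str) -> pd.Index:
        return self.samples.index[self.samples["sex"] == sex]

    def line_samples(self, line: str, sex: str | None = None) -> pd.Index:
        keep = self.samples["line"] == line
        if sex is not None:
            keep &= self.samples["sex"] == sex
        return self.samples.index[keep]

    def lines(self, sex: str | None = None) -> list[str]:
        meta = self.samples if sex is None else self.samples[self.samples["sex"] == sex]
        return list(dict.fromkeys(meta["line"]))

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = pd.Index(sample_ids)
        return ExpressionMatrix(
            self.values[sample_ids], self.samples.loc[sample_ids], self.features
        )


@dataclass
class PlantedTruth:
    """Ground truth planted by the synthetic generator.

    gene_class      : Series gene -> compensation class (one-dose genes).
    true_lfc        : Series gene -> true log2 response to the one-dose state.
    edges           : planted co-expression edges (unordered gene pairs).
    sex_bias        : Series gene -> 'female' | 'male' | 'none'.
    deleted         : dict line -> (first, last) 1-based inclusive.
    neighbor_shift  : Series class -> planted log2 shift applied to
                      first-degree neighbors of a one-dose gene of that class.
    """

    gene_class: pd.Series
    true_lfc: pd.Series
    edges: list[tuple[str, str]]
    sex_bias: pd.Series
    deleted: dict[str, tuple[int, int]]
    neighbor_shift: pd.Series = field(default=None)  # type: ignore[assignment]
    #: per-sex true responses (columns 'female', 'male'); the sex-shared part
    #: is ``true_lfc``
    true_lfc_by_sex: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        bad = set(self.gene_class.unique()) - set(COMPENSATION_CLASSES)
        if bad:
            raise ValueError(f"unknown compensation classes: {sorted(bad)}")
        genes = set(self.true_lfc.index)
        for a, b in self.edges:
            if a not in genes or b not in genes:
                raise ValueError(f"planted edge ({a}, {b}) references unknown gene")
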