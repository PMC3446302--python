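"""End-to-end orchestration: from an expression study to compensation
calls, sex-specific MI networks, and propagation summaries.

Each stage is available separately in its own module; this wrapper wires
them together with the study's two-reference scheme (parental reference
for one-dose compensation calls, composite reference for per-line
differential expression of the two-dose genome).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from . import compensation, expression, network, propagation
from .containers import DeficiencyLine, ExpressionMatrix
from .synthetic import PARENTAL_LINE


@dataclass
class SexAnalysis:
    sex: str
    detected: pd.Series
    parental_reference: pd.Series
    composite_reference: pd.Series
    one_dose_result: expression.ModeratedTestResult
    calls: pd.DataFrame
    cutoffs: compensation.ClassCutoffs
    edges: pd.DataFrame
    net: nx.Graph
    topology: network.TopologyStats
    per_line: dict[str, pd.DataFrame]
    neighbor_change: pd.DataFrame
    neighbor_direction: pd.DataFrame
    global_rates: dict


def analyze_sex(
    matrix: ExpressionMatrix,
    deficiencies: list[DeficiencyLine],
    sex: str,
    parental_line: str = PARENTAL_LINE,
    alpha: float = 0.05,
    mi_h: float = 0.3,
    mi_alpha: float = 0.005,
    n_perm: int = 2000,
    n_boot: int = 1000,
    de_alpha: float = 0.05,
    neighbor_alpha: float = 0.01,
    seed: int = 0,
    calls_override: pd.DataFrame | None = None,
) -> SexAnalysis:
    """Run the full single-sex analysis.

    ``calls_override`` substitutes an external class assignment (e.g.
    planted ground truth) for the classifier output in the neighbor
    analyses; everything else is computed identically.
    """
    mask = expression.detection_mask(matrix)
    detected = mask[sex]
    parental_ref = expression.build_reference(matrix, "parental", sex, parental_line)
    composite_ref = expression.build_reference(matrix, "composite", sex, parental_line)

    one_dose_res, lines = compensation.one_dose_moderated_test(
        matrix, deficiencies, parental_ref, sex, detected
    )
    calls, cutoffs = compensation.classify_compensation(
        one_dose_res, alpha=alpha, n_boot=n_boot, seed=seed, lines=lines, sex=sex
    )

    genes_for_net = detected.index[detected]
    z = network.standardize(matrix, sex, genes=genes_for_net)
    edges = network.edge_significance(z, h=mi_h, n_perm=n_perm, seed=seed + 1, alpha=mi_alpha)
    net = network.build_network(edges, alpha=mi_alpha, nodes=z.index)
    topo = network.topology_stats(net)

    per_line = propagation.per_line_de(
        matrix, composite_ref, sex, alpha=de_alpha, parental_line=parental_line,
        genes=genes_for_net,
    )
    use_calls = calls if calls_override is None else calls_override
    nb_change, rates = propagation.neighbor_change_by_class(
        deficiencies, net, use_calls, per_line, genes_for_net, alpha=neighbor_alpha
    )
    nb_dir, _ = propagation.neighbor_direction_by_class(
        deficiencies, net, use_calls, per_line, genes_for_net, alpha=neighbor_alpha
    )
    return SexAnalysis(
        sex=sex,
        detected=detected,
        parental_reference=parental_ref,
        composite_reference=composite_ref,
        one_dose_result=one_dose_res,
        calls=calls,
        cutoffs=cutoffs,
        edges=edges,
        net=net,
        topology=topo,
        per_line=per_line,
        neighbor_change=nb_change,
        neighbor_direction=nb_dir,
        global_rates=rates,
    )
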