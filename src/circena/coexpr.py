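"""Gene co-expression networks: significant Pearson pairs, hubs, W-cores.

Builds an unweighted graph whose edges are significantly correlated
feature pairs (two-sided t test on Pearson r, df = n - 2), on
log2(normalized count + 1) expression.  Provides degree centrality,
W-core decomposition (the graph-theoretic k-core: the maximal
subnetwork in which every node keeps at least W neighbours), core
regulators ranked by between-class degree difference, and the
correlated-partner query used to shortlist candidate circRNAs for a
target mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io import CountMatrix
from .diffexpr import normalized_counts

__all__ = [
    "CoexprNetwork",
    "log_expression",
    "pearson_network",
    "degree_centrality",
    "w_core",
    "core_regulators",
    "correlated_partners",
]


@dataclass
class CoexprNetwork:
    """Feature co-expression graph with per-edge correlation statistics."""

    graph: nx.Graph
    n_samples: int
    dropped_zero_variance: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, float]]:
        return [
            (a, b, d["r"], d["p"]) for a, b, d in self.graph.edges(data=True)
        ]

    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, d["r"], d["p"]) for a, b, d in self.graph.edges(data=True)],
            columns=["node_a", "node_b", "r", "p"],
        )


def log_expression(matrix: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """log2(normalized count + 1): Pearson on raw NB counts is mean-driven."""
    if isinstance(matrix, CountMatrix):
        frame = normalized_counts(matrix)
    else:
        frame = matrix
    return np.log2(frame + 1.0)


def _pearson_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p (t reference, df = n - 2)."""
    n = values.shape[1]
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return r, p


def pearson_network(
    expr: CountMatrix | pd.DataFrame,
    config: PipelineConfig | None = None,
    p_threshold: float | None = None,
    r_threshold: float | None = None,
) -> CoexprNetwork:
    """Graph of significantly correlated feature pairs.

    An edge joins two features when the two-sided correlation p-value is
    below ``correlation_p_threshold`` AND |r| >= ``correlation_r_threshold``
    (signed r is stored on the edge).  Small cohorts make a p-only rule
    weak, hence the combined rule; both knobs live in the config.
    Zero-variance features cannot carry a correlation and are dropped,
    with their names recorded on the returned network.
    """
    config = config or PipelineConfig()
    if p_threshold is None:
        p_threshold = config.correlation_p_threshold
    if r_threshold is None:
        r_threshold = config.correlation_r_threshold
    frame = log_expression(expr)
    if frame.shape[1] < 3:
        raise ValueError("Pearson p-values require at least 3 samples")
    variances = frame.var(axis=1)
    dropped = list(frame.index[variances == 0])
    frame = frame.loc[variances > 0]
    graph = nx.Graph()
    graph.add_nodes_from(frame.index)
    if len(frame) >= 2:
        r, p = _pearson_matrix(frame.to_numpy())
        ids = list(frame.index)
        iu, ju = np.triu_indices(len(ids), k=1)
        keep = (p[iu, ju] < p_threshold) & (np.abs(r[iu, ju]) >= r_threshold)
        for i, j in zip(iu[keep], ju[keep]):
            graph.add_edge(ids[i], ids[j], r=float(r[i, j]), p=float(p[i, j]))
    return CoexprNetwork(graph, n_samples=frame.shape[1],
                         dropped_zero_variance=dropped)


def degree_centrality(network: CoexprNetwork | nx.Graph) -> dict[str, int]:
    """Exact incident-edge count per node (the published definition)."""
    graph = network.graph if isinstance(network, CoexprNetwork) else network
    return dict(graph.degree())


def w_core(network: CoexprNetwork | nx.Graph, w: int) -> nx.Graph:
    """Maximal subnetwork in which every node has >= w neighbours inside it.

    Computed by iterative removal of nodes with degree < w until a
    fixpoint; the result is unique regardless of removal order (this is
    the graph-theoretic k-core).
    """
    if w < 0:
        raise ValueError("W must be >= 0")
    graph = network.graph if isinstance(network, CoexprNetwork) else network
    stripped = graph.copy()
    stripped.remove_edges_from(nx.selfloop_edges(stripped))
    return nx.k_core(stripped, k=w)


def core_regulators(
    expr: CountMatrix,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Nodes ranked by between-class degree difference.

    Builds one network per sample class with identical thresholds and
    ranks nodes by |degree_A - degree_B| descending (the class-switching
    hubs), ties broken by larger total degree, then node id.  With
    3-sample classes, correlation p-values rest on a single degree of
    freedom; the output flags such networks as exploratory.
    """
    config = config or PipelineConfig()
    groups = expr.groups_array()
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"exactly two classes required, got {labels}")
    frame = log_expression(expr)
    degrees = {}
    for lab in labels:
        cols = [s for s, g in zip(expr.sample_ids, groups) if g == lab]
        if len(cols) < 3:
            raise ValueError(
                f"class {lab!r} has {len(cols)} samples; Pearson p-values "
                "require at least 3 per class"
            )
        net = pearson_network(frame[cols], config)
        degrees[lab] = degree_centrality(net)
    a, b = labels
    rows = []
    for node in frame.index:
        da = degrees[a].get(node, 0)
        db = degrees[b].get(node, 0)
        rows.append((node, da, db, abs(da - db)))
    df = pd.DataFrame(rows, columns=["node", f"degree_{a}", f"degree_{b}",
                                     "degree_difference"])
    df["_total"] = df[f"degree_{a}"] + df[f"degree_{b}"]
    df = df.sort_values(
        ["degree_difference", "_total", "node"], ascending=[False, False, True]
    ).drop(columns="_total").reset_index(drop=True)
    df.attrs["exploratory"] = any(
        np.sum(groups == lab) <= 3 for lab in labels
    )
    return df


def correlated_partners(
    expr: CountMatrix | pd.DataFrame,
    target_id: str,
    candidate_ids: list[str],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Candidates significantly correlated with a target feature.

    Returns (candidate, r, p) for candidates passing the network edge
    rule against the target, sorted by |r| descending.  The expression
    matrix may mix feature types (e.g. mRNA genes and circRNAs) so
    circRNA candidates can be screened against a target mRNA.
    """
    config = config or PipelineConfig()
    frame = log_expression(expr)
    if target_id not in frame.index:
        raise KeyError(f"target {target_id!r} not in the expression matrix")
    missing = [c for c in candidate_ids if c not in frame.index]
    if missing:
        raise KeyError(f"candidates not in the expression matrix: {missing[:5]}")
    target = frame.loc[target_id].to_numpy()
    n = len(target)
    if n < 3:
        raise ValueError("Pearson p-values require at least 3 samples")
    rows = []
    for cand in candidate_ids:
        if cand == target_id:
            continue
        x = frame.loc[cand].to_numpy()
        if np.std(x) == 0 or np.std(target) == 0:
            continue
        r, p = stats.pearsonr(x, target)
        if p < config.correlation_p_threshold and abs(r) >= config.correlation_r_threshold:
            rows.append((cand, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["candidate", "r", "p"])
    return df.reindex(df["r"].abs().sort_values(ascending=False).index).reset_index(
        drop=True
    )
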