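"""Condition-specific Pearson co-expression networks and hub nomination.

For every unordered gene pair within one condition, the Pearson correlation
r is tested via ``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of
freedom (two-sided); Benjamini-Hochberg adjustment runs over all tested
pairs of that condition and edges with ``q < edge_fdr_alpha`` are kept.

Downstream statistics: degree centrality (incident edge count), k-core
numbers (iterative peeling), the degree difference between two conditions
("dif degree", absolute by default with the signed value reported), and
strict-threshold hub selection intersected across perturbations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .enrich import bh_fdr
from .errors import InputError, StatisticsError
from .expression import ExpressionMatrix

__all__ = [
    "Edge",
    "CoexpressionNetwork",
    "HubSelection",
    "build_network",
    "degree_centrality",
    "k_core_decomposition",
    "dif_degree",
    "select_hubs",
]

POSITIVE = "positive"
NEGATIVE = "negative"


class Edge(NamedTuple):
    gene_a: str
    gene_b: str
    r: float
    p_value: float
    q_value: float
    sign: str


@dataclass(frozen=True)
class CoexpressionNetwork:
    condition_label: str
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    n_samples: int

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        for e in self.edges:
            if e.gene_a == e.gene_b:
                raise InputError(f"self-edge on {e.gene_a!r}")
            if e.gene_a > e.gene_b:
                raise InputError("edges must be stored with gene_a < gene_b")
            if e.gene_a not in node_set or e.gene_b not in node_set:
                raise InputError(f"edge endpoint missing from node set: {e}")

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.gene_a, e.gene_b, r=e.r, p_value=e.p_value, q_value=e.q_value, sign=e.sign)
        return g


@dataclass(frozen=True)
class HubSelection:
    threshold: int
    selected: Mapping[str, tuple[str, ...]]  # perturbation label -> sorted genes
    core_regulators: tuple[str, ...]


def build_network(
    matrix: ExpressionMatrix,
    genes: Iterable[str],
    condition_label: str,
    edge_fdr_alpha: float = 0.05,
    log_transform: bool = True,
) -> CoexpressionNetwork:
    """Pearson co-expression network over one condition's samples.

    By default correlations are computed on ``log2(value + pseudocount)``
    (pseudocount = 1e-6 of the submatrix mean): expression values are
    heavy-tailed on the linear scale, where the t-transform p-values of the
    correlation test are badly anti-conservative; the log scale restores
    their calibration.  Pass ``log_transform=False`` to correlate raw values.

    Zero-variance genes stay in the node set but contribute no edges
    (a warning is emitted).  Requires at least 4 samples and 2 genes.
    """
    if not 0.0 < edge_fdr_alpha <= 1.0:
        raise InputError(f"edge_fdr_alpha must be in (0, 1], got {edge_fdr_alpha}")
    nodes = tuple(sorted(set(genes)))
    if len(nodes) < 2:
        raise InputError(f"need at least 2 genes, got {len(nodes)}")
    samples = matrix.samples_for(condition_label)
    n = len(samples)
    if n < 4:
        raise StatisticsError(
            f"need at least 4 samples for correlation testing, got {n}"
        )
    X = matrix.submatrix(nodes)[samples].to_numpy(dtype=float)
    if log_transform:
        mean = float(X.mean())
        pc = 1e-6 * mean if mean > 0 else 1e-6
        X = np.log2(X + pc)
    sd = X.std(axis=1)
    valid = sd > 0
    if not valid.all():
        isolated = [g for g, ok in zip(nodes, valid) if not ok]
        warnings.warn(
            f"zero-variance genes isolated in {condition_label!r} network: {isolated}",
            stacklevel=2,
        )
    vidx = np.flatnonzero(valid)
    edges: tuple[Edge, ...] = ()
    if vidx.size >= 2:
        R = np.corrcoef(X[vidx])
        iu, ju = np.triu_indices(vidx.size, k=1)
        r = np.clip(R[iu, ju], -1.0, 1.0)
        # snap float-rounded collinear pairs to exactly +/-1
        r[1.0 - np.abs(r) < 1e-12] = np.sign(r[1.0 - np.abs(r) < 1e-12])
        denom = 1.0 - r * r
        t = np.zeros_like(r)
        np.divide(r * np.sqrt(n - 2), np.sqrt(denom), out=t, where=denom > 0)
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p[denom <= 0] = 0.0  # |r| = 1 by convention
        q = bh_fdr(p)
        keep = q < edge_fdr_alpha
        out = []
        for idx in np.flatnonzero(keep):
            a = nodes[vidx[iu[idx]]]
            b = nodes[vidx[ju[idx]]]
            out.append(
                Edge(
                    gene_a=a,
                    gene_b=b,
                    r=float(r[idx]),
                    p_value=float(p[idx]),
                    q_value=float(q[idx]),
                    sign=POSITIVE if r[idx] >= 0 else NEGATIVE,
                )
            )
        edges = tuple(out)
    return CoexpressionNetwork(
        condition_label=condition_label, nodes=nodes, edges=edges, n_samples=n
    )


def degree_centrality(network: CoexpressionNetwork) -> dict[str, int]:
    """Incident-edge count per node; isolated nodes map to 0."""
    deg = {g: 0 for g in network.nodes}
    for e in network.edges:
        deg[e.gene_a] += 1
        deg[e.gene_b] += 1
    return deg


def k_core_decomposition(network: CoexpressionNetwork) -> dict[str, int]:
    """Core number per node via iterative peeling (networkx backend)."""
    return {g: int(c) for g, c in nx.core_number(network.to_networkx()).items()}


def dif_degree(
    control_net: CoexpressionNetwork, perturbed_net: CoexpressionNetwork
) -> pd.DataFrame:
    """Per-gene degree table across two conditions.

    The node union is taken; a gene absent from one network counts degree 0
    there.  Columns: degree_control, degree_perturbed, dif_degree (absolute
    difference) and signed_dif (control minus perturbed).
    """
    dc = degree_centrality(control_net)
    dp = degree_centrality(perturbed_net)
    genes = sorted(set(dc) | set(dp))
    deg_c = np.array([dc.get(g, 0) for g in genes], dtype=int)
    deg_p = np.array([dp.get(g, 0) for g in genes], dtype=int)
    table = pd.DataFrame(
        {
            "degree_control": deg_c,
            "degree_perturbed": deg_p,
            "dif_degree": np.abs(deg_c - deg_p),
            "signed_dif": deg_c - deg_p,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return table


def select_hubs(
    tables: Mapping[str, pd.DataFrame], threshold: int = 8
) -> HubSelection:
    """Strictly-above-threshold hub genes per table, intersected across tables.

    `tables` maps perturbation label to a :func:`dif_degree` frame; genes with
    ``dif_degree > threshold`` are selected (boundary value excluded).
    """
    if not tables:
        raise InputError("at least one degree table is required")
    if threshold < 0:
        raise InputError(f"threshold must be >= 0, got {threshold}")
    selected: dict[str, tuple[str, ...]] = {}
    for label, table in tables.items():
        if "dif_degree" not in table.columns:
            raise InputError(f"table for {label!r} lacks a dif_degree column")
        picked = table.index[table["dif_degree"] > threshold]
        selected[label] = tuple(sorted(picked))
    sets = [set(v) for v in selected.values()]
    core = set.intersection(*sets) if sets else set()
    return HubSelection(
        threshold=threshold, selected=selected, core_regulators=tuple(sorted(core))
    )
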