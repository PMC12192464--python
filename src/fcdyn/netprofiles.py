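"""Region-level networks and seven-metric connectivity profiles.

Channel-level FC is mapped to brain regions by taking, for each directed
region pair, the maximum weight among all channel links connecting them.
On the resulting region graph, seven centrality metrics describe each
region's role: weighted in-/out-degree, closeness-in/out, betweenness and
Katz-in/out.  Path-based metrics convert edge weights w in (0, 1] to
lengths 1/w (stronger link = shorter path).  Each metric is bounded in
[0, 1], so per-(region, task) profile distributions need no further
rescaling for radar-style comparison.

Closeness and betweenness are delegated to networkx (Dijkstra-based);
Katz solves its defining linear system directly so the result is exact to
solver precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .dynamics import MIXED_LABEL, WindowedFC

__all__ = [
    "RegionAtlasMap", "RegionGraph",
    "to_region_graph", "degree_centrality", "closeness_centrality",
    "betweenness_centrality", "katz_centrality",
    "region_metrics", "build_profiles", "region_windowed_fc",
    "PROFILE_METRICS",
]

logger = logging.getLogger(__name__)

PROFILE_METRICS = ("in_degree", "out_degree", "closeness_in", "closeness_out",
                   "betweenness", "katz_in", "katz_out")


@dataclass
class RegionAtlasMap:
    """Channel -> (region, hemisphere) lookup."""

    rows: list[tuple[str, str, str]]   # (channel_label, region_name, hemisphere)

    def __post_init__(self) -> None:
        chans = [r[0] for r in self.rows]
        if len(set(chans)) != len(chans):
            raise ValueError("duplicate channel labels in atlas map")
        self._region_of = {c: r for c, r, _ in self.rows}

    def region_of(self, channel: str) -> str:
        return self._region_of[channel]

    @property
    def regions(self) -> list[str]:
        seen: list[str] = []
        for _, r, _ in self.rows:
            if r not in seen:
                seen.append(r)
        return seen

    @classmethod
    def from_tsv(cls, path) -> "RegionAtlasMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        cols = list(df.columns[:3])
        return cls([tuple(r) for r in df[cols].itertuples(index=False)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.rows, columns=["channel", "region", "hemisphere"]
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class RegionGraph:
    """Directed weighted region network; values in [0, 1], zero diagonal."""

    regions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.regions), len(self.regions)):
            raise ValueError("values shape must match region count")
        self.values = v

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def to_networkx(self, lengths: bool = False) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_regions))
        n = self.n_regions
        for i in range(n):
            for j in range(n):
                w = self.values[i, j]
                if i != j and w > 0:
                    attrs = {"weight": w}
                    if lengths:
                        attrs["length"] = 1.0 / w
                    g.add_edge(i, j, **attrs)
        return g


def to_region_graph(fc_values: np.ndarray, channel_labels: list[str],
                    atlas: RegionAtlasMap) -> RegionGraph:
    """Max-weight aggregation of channel FC to the region level.

    Entry (a, b) is the maximum FC weight over all channel pairs
    (i in a, j in b); within-region links are discarded (zero diagonal).
    """
    unmapped = [c for c in channel_labels if c not in atlas._region_of]
    if unmapped:
        raise ValueError(f"unmapped channel(s): {unmapped}")
    regions = atlas.regions
    reg_idx = {r: k for k, r in enumerate(regions)}
    memb = np.array([reg_idx[atlas.region_of(c)] for c in channel_labels])
    R = len(regions)
    values = np.zeros((R, R))
    fc = np.asarray(fc_values)
    for a in range(R):
        rows = memb == a
        for b in range(R):
            if a == b:
                continue
            cols = memb == b
            if rows.any() and cols.any():
                values[a, b] = fc[np.ix_(rows, cols)].max()
    return RegionGraph(regions, values)


def degree_centrality(g: RegionGraph) -> tuple[np.ndarray, np.ndarray]:
    """Weighted (in_degree, out_degree), each normalized by R - 1.

    With weights in [0, 1] the normalized strength is in [0, 1] and equals
    binary degree centrality on a 0/1 graph.
    """
    if g.n_regions < 2:
        raise ValueError("need at least 2 regions")
    denom = g.n_regions - 1
    return g.values.sum(axis=0) / denom, g.values.sum(axis=1) / denom


def closeness_centrality(g: RegionGraph, direction: str = "in") -> np.ndarray:
    """Shortest-path closeness with reachable-fraction scaling.

    cC(v) = ((r - 1) / sum of d) * ((r - 1) / (n - 1)) with r the number of
    nodes reaching v ("in") or reached from v ("out"), d the 1/weight path
    lengths.  Unreachable-only nodes score 0; values lie in [0, 1] because
    every length is >= 1.
    """
    gx = g.to_networkx(lengths=True)
    if direction == "out":
        gx = gx.reverse()
    elif direction != "in":
        raise ValueError("direction must be 'in' or 'out'")
    cc = nx.closeness_centrality(gx, distance="length", wf_improved=True)
    return np.array([cc[i] for i in range(g.n_regions)])


def betweenness_centrality(g: RegionGraph) -> np.ndarray:
    """Directed weighted betweenness, normalized by (n-1)(n-2)."""
    gx = g.to_networkx(lengths=True)
    bc = nx.betweenness_centrality(gx, weight="length", normalized=True)
    return np.array([bc[i] for i in range(g.n_regions)])


def katz_centrality(g: RegionGraph, direction: str = "in",
                    alpha_frac: float = 0.9, beta: float = 1.0) -> np.ndarray:
    """Katz centrality by direct linear solve, rescaled to max = 1.

    Solves x = alpha * M x + beta * 1 with M = A^T for incoming walks
    ("in") or A for outgoing ("out"); alpha = alpha_frac / lambda_max(A)
    guarantees convergence of the underlying walk series.  An empty graph
    yields the uniform vector (pure beta).
    """
    if not 0 < alpha_frac < 1:
        raise ValueError("alpha_frac must be in (0, 1)")
    A = g.values
    n = g.n_regions
    if not A.any():
        return np.ones(n)
    lam = float(np.max(np.abs(np.linalg.eigvals(A))))
    # nilpotent (acyclic) adjacency: the walk series terminates for any
    # alpha, so the attenuation fraction is used directly
    alpha = alpha_frac / lam if lam > 1e-12 else alpha_frac
    M = A.T if direction == "in" else A
    if direction not in ("in", "out"):
        raise ValueError("direction must be 'in' or 'out'")
    x = np.linalg.solve(np.eye(n) - alpha * M, beta * np.ones(n))
    return x / x.max()


def region_metrics(g: RegionGraph) -> dict[str, np.ndarray]:
    """All seven profile metrics of a region graph, each in [0, 1]."""
    in_d, out_d = degree_centrality(g)
    return {
        "in_degree": in_d,
        "out_degree": out_d,
        "closeness_in": closeness_centrality(g, "in"),
        "closeness_out": closeness_centrality(g, "out"),
        "betweenness": betweenness_centrality(g),
        "katz_in": katz_centrality(g, "in"),
        "katz_out": katz_centrality(g, "out"),
    }


def region_windowed_fc(wfc: WindowedFC, atlas: RegionAtlasMap) -> WindowedFC:
    """Map every window's channel FC to the region level (max aggregation)."""
    mats = np.array([
        to_region_graph(m, wfc.channel_labels, atlas).values
        for m in wfc.matrices
    ])
    regions = atlas.regions
    return WindowedFC(list(wfc.windows), mats, list(wfc.task_labels), regions)


def build_profiles(wfc: WindowedFC, atlas: RegionAtlasMap) -> pd.DataFrame:
    """Per-(region, task, metric) profile distribution summaries.

    Each non-mixed window's FC becomes a region graph whose seven metrics
    are pooled per task; the long-format table reports median and the
    25th/75th percentiles.  Regions are never imputed: a region without
    coverage in a task is simply absent from that task's rows.
    """
    sub = wfc.non_mixed()
    if sub.n_windows == 0:
        raise ValueError("no non-mixed windows to profile")
    records: dict[tuple[str, str, str], list[float]] = {}
    for w in range(sub.n_windows):
        task = sub.task_labels[w]
        rg = to_region_graph(sub.matrices[w], sub.channel_labels, atlas) \
            if sub.channel_labels != atlas.regions else RegionGraph(
                atlas.regions, sub.matrices[w])
        metrics = region_metrics(rg)
        for metric, vec in metrics.items():
            for r, region in enumerate(rg.regions):
                records.setdefault((region, task, metric), []).append(vec[r])
    rows = []
    for (region, task, metric), vals in sorted(records.items()):
        arr = np.array(vals)
        rows.append({
            "region": region, "task": task, "metric": metric,
            "median": float(np.median(arr)),
            "q25": float(np.percentile(arr, 25)),
            "q75": float(np.percentile(arr, 75)),
            "n_windows": len(vals),
        })
    return pd.DataFrame(rows)
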