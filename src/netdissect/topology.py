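"""Topological characterisation of the integrated network.

Per-node degree, betweenness centrality (BC) and topological coefficient
(TC) follow the NetworkAnalyzer conventions: BC uses exact shortest-path
counting normalized by (n-1)(n-2)/2 with disconnected pairs contributing
zero, and TC is the average shared-neighbour ratio J(n,m)/k_n over all
nodes m sharing at least one neighbour with n (J counts common
neighbours, plus one when n and m are themselves adjacent).

Degree distributions are summarised by a least-squares line on the
log-log frequency plot (slope and R^2), the scale-free signature; node
groups are compared by two-sided Mann-Whitney U tests; hubs are the top-k
nodes by degree (k = 50 by convention) and hub lncRNAs are profiled by
the disease-type mix of their ceRNA partners.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedFitError, ValidationError
from .graph import TypedGraph


# -- per-node metrics --------------------------------------------------


def compute_degree(g: TypedGraph) -> dict[str, int]:
    """Incident-edge count, ppi and cerna edges alike."""
    return g.degrees()


def compute_betweenness(g: TypedGraph) -> dict[str, float]:
    """Normalized betweenness centrality (Brandes accumulation).

    For each node v, the sum over unordered pairs {s,t} (s,t != v) of the
    fraction of shortest s-t paths through v, divided by (n-1)(n-2)/2.
    Graphs with fewer than 3 nodes have all-zero BC.
    """
    simple = g.simple_graph()
    n = simple.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in simple.nodes}
    return nx.betweenness_centrality(simple, normalized=True)


def compute_topological_coefficient(g: TypedGraph) -> dict[str, float]:
    """Shared-neighbour topological coefficient in [0, 1].

    TC(n) = mean_m J(n,m) / k_n over nodes m != n sharing >= 1 neighbour
    with n, where J(n,m) = |N(n) & N(m)| + [n ~ m]; zero for nodes of
    degree <= 1 or with no qualifying partner.
    """
    simple = g.simple_graph()
    neigh = {v: set(simple.neighbors(v)) for v in simple.nodes}
    out: dict[str, float] = {}
    for v in simple.nodes:
        k = len(neigh[v])
        if k <= 1:
            out[v] = 0.0
            continue
        partners = set()
        for u in neigh[v]:
            partners.update(neigh[u])
        partners.discard(v)
        ratios = []
        for m in partners:
            shared = len(neigh[v] & neigh[m])
            if shared == 0:
                continue
            ratios.append((shared + (1 if m in neigh[v] else 0)) / k)
        out[v] = float(np.mean(ratios)) if ratios else 0.0
    return out


def compute_node_metrics(g: TypedGraph) -> pd.DataFrame:
    """DataFrame indexed by node: type, degree, bc, tc."""
    deg = compute_degree(g)
    bc = compute_betweenness(g)
    tc = compute_topological_coefficient(g)
    types = g.node_types()
    nodes = sorted(deg)
    return pd.DataFrame(
        {
            "type": [types[n] for n in nodes],
            "degree": [deg[n] for n in nodes],
            "bc": [bc[n] for n in nodes],
            "tc": [tc[n] for n in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


# -- power-law fit -----------------------------------------------------


@dataclass(frozen=True)
class PowerLawFit:
    slope: float
    r2: float
    points_used: int


def fit_power_law(degrees) -> PowerLawFit:
    """Least-squares line on (log k, log N(k)) over observed degrees k >= 1.

    N(k) is the frequency (count) of nodes with degree k; zero-frequency
    degrees are absent by construction and degree 0 is excluded.  Requires
    at least 3 distinct positive degree values.
    """
    degrees = [int(d) for d in degrees if d > 0]
    counts: dict[int, int] = {}
    for d in degrees:
        counts[d] = counts.get(d, 0) + 1
    if len(counts) < 3:
        raise UndefinedFitError(
            f"power-law fit needs >=3 distinct positive degrees, "
            f"got {len(counts)}"
        )
    ks = sorted(counts)
    x = np.log10(ks)
    y = np.log10([counts[k] for k in ks])
    res = stats.linregress(x, y)
    return PowerLawFit(float(res.slope), float(res.rvalue**2), len(ks))


# -- group comparisons -------------------------------------------------


@dataclass(frozen=True)
class GroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_stat: float
    p: float
    method: str


def mann_whitney(x, y) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U.

    Exact null distribution when both groups have <= 8 observations and
    there are no ties; otherwise the normal approximation with mid-rank
    tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(set(x) | set(y)) < len(x) + len(y)
    exact = len(x) <= 8 and len(y) <= 8 and not ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def compare_metric_by_type(
    metrics: pd.DataFrame, metric: str, types: list[str] | None = None
) -> list[GroupComparison]:
    """Pairwise Mann-Whitney comparisons of one metric across node types.

    Groups with fewer than 2 members are skipped with a warning.
    """
    if metric not in metrics.columns:
        raise ValidationError(f"unknown metric {metric!r}")
    if types is None:
        types = sorted(metrics["type"].unique())
    out = []
    for a, b in itertools.combinations(types, 2):
        xa = metrics.loc[metrics["type"] == a, metric].to_numpy()
        xb = metrics.loc[metrics["type"] == b, metric].to_numpy()
        if len(xa) < 2 or len(xb) < 2:
            warnings.warn(
                f"skipping {metric} comparison {a} vs {b}: group too small"
            )
            continue
        u, p, method = mann_whitney(xa, xb)
        out.append(GroupComparison(metric, a, b, len(xa), len(xb), u, p, method))
    return out


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


# -- hubs and regulating proportions -----------------------------------


def select_hubs(
    metrics: pd.DataFrame, k: int = 50, node_filter=None
) -> list[str]:
    """Top-k node ids by degree (descending), ties broken by id ascending."""
    if k < 1:
        raise ValidationError("hub count k must be >= 1")
    frame = metrics
    if node_filter is not None:
        frame = frame[[node_filter(n) for n in frame.index]]
    ranked = sorted(frame.index, key=lambda n: (-frame.at[n, "degree"], n))
    return ranked[:k]


def regulating_proportions(
    g: TypedGraph, hub_lncrnas: list[str]
) -> pd.DataFrame:
    """Disease-type mix of each hub lncRNA's ceRNA partners.

    Proportions are over disease-typed partners only (diabetes, DR,
    common, summing to 1); partners typed "other" are reported as a
    separate count.  A lncRNA with no disease-typed partner gets NaN
    proportions.
    """
    rows = []
    for lnc in hub_lncrnas:
        if g.node_type(lnc) != "lncRNA":
            raise ValidationError(f"{lnc!r} is not an lncRNA node")
        counts = {"diabetes": 0, "DR": 0, "common": 0, "other": 0}
        for partner in g.neighbors(lnc, kind="cerna"):
            t = g.node_type(partner)
            counts[t if t in counts else "other"] += 1
        typed = counts["diabetes"] + counts["DR"] + counts["common"]
        if typed:
            props = [counts[t] / typed for t in ("diabetes", "DR", "common")]
        else:
            props = [math.nan] * 3
        rows.append((lnc, *props, counts["other"], typed))
    return pd.DataFrame(
        rows,
        columns=["lncrna", "p_diabetes", "p_dr", "p_common",
                 "n_other", "n_typed"],
    ).set_index("lncrna")
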