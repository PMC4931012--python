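"""Spearman correlations, co-occurrence networks and environment heatmaps.

Networks follow the study's edge rule: only pairs with an absolute Spearman
rank correlation strictly above 0.3 and a p-value strictly below 0.05 become
edges, computed among bacterial families whose mean abundance within the
analysed sample subset is strictly above 1%.  Environment variables (pH,
organic acids, oligosaccharides, cell counts) may join the network as nodes
but never participate in the abundance filter.

p-values use the t-approximation t = rho*sqrt((n-2)/(1-rho^2)); this is
approximate for n < 10 and flagged as such on each result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .profiles import AbundanceTable, EnvironmentTable, filter_prevalent

__all__ = [
    "CorrelationResult",
    "spearman",
    "build_network",
    "correlation_heatmap_table",
    "export_graph",
    "read_edge_tsv",
]


@dataclass
class CorrelationResult:
    var1: str
    var2: str
    rho: float
    p: float
    n: int
    testable: bool = True
    approximate: bool = False  # t-approximation on n < 10


def spearman(
    x: Sequence[float], y: Sequence[float], var1: str = "x", var2: str = "y"
) -> CorrelationResult:
    """Spearman rank correlation with pairwise missing-value removal.

    Constant inputs (zero rank variance) yield an untestable result with
    rho = NaN, ineligible for network edges.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3:
        return CorrelationResult(var1, var2, math.nan, math.nan, n, testable=False)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(var1, var2, math.nan, math.nan, n, testable=False)
    rho, p = sps.spearmanr(x, y)
    if abs(rho) >= 1.0 - 1e-14:
        p = 0.0
    return CorrelationResult(var1, var2, float(rho), float(p), n, approximate=n < 10)


def _joined_frame(
    table: AbundanceTable,
    env: EnvironmentTable | None,
    sample_ids: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    taxa = table.data.loc[list(sample_ids)]
    env_df = None
    if env is not None:
        env_df = env.data.set_index("sample_id").loc[list(sample_ids)]
    return taxa, env_df


def build_network(
    table: AbundanceTable,
    sample_ids: Sequence[str] | None = None,
    env: EnvironmentTable | None = None,
    rho_min: float = 0.3,
    p_max: float = 0.05,
    min_mean: float = 0.01,
) -> nx.Graph:
    """Thresholded Spearman co-occurrence network.

    Taxa are filtered to those with mean abundance strictly above
    ``min_mean`` within the subset; edges require |rho| > rho_min *and*
    p < p_max (both strict).  Nodes carry their mean abundance (taxa) or
    variable class; edges carry rho, p and sign.
    """
    ids = list(sample_ids) if sample_ids is not None else table.sample_ids
    if len(ids) < 3:
        raise ValueError("need at least 3 samples")
    filtered, kept = filter_prevalent(table, min_mean=min_mean, sample_ids=ids)
    taxa_df = filtered.data
    columns: list[tuple[str, pd.Series, str]] = [
        (t, taxa_df[t], "taxon") for t in kept
    ]
    if env is not None:
        env_df = env.data.set_index("sample_id").loc[ids]
        columns += [(v, env_df[v], "environment") for v in env.variables]

    g = nx.Graph()
    if len(columns) < 2:
        return g  # empty network with a warning left to the caller
    for name, series, kind in columns:
        attrs = {"kind": kind}
        if kind == "taxon":
            attrs["mean_abundance"] = float(series.mean())
        g.add_node(name, **attrs)
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            n1, s1, _ = columns[i]
            n2, s2, _ = columns[j]
            res = spearman(s1.to_numpy(), s2.to_numpy(), n1, n2)
            if not res.testable:
                continue
            if abs(res.rho) > rho_min and res.p < p_max:
                g.add_edge(
                    n1, n2,
                    rho=res.rho, p=res.p, n=res.n,
                    sign="+" if res.rho > 0 else "-",
                    weight=abs(res.rho),
                )
    return g


def correlation_heatmap_table(
    table: AbundanceTable,
    env: EnvironmentTable,
    sample_ids: Sequence[str] | None = None,
    min_mean: float | None = None,
) -> pd.DataFrame:
    """Families × environment-variable Spearman matrix, tidy long format.

    One row per (family, variable) cell with rho, p and the per-cell n after
    pairwise missing-value removal; cells with n < 3 or a constant input are
    marked untestable.  ``min_mean`` optionally restricts the families shown.
    """
    ids = list(sample_ids) if sample_ids is not None else table.sample_ids
    families = table.taxon_ids
    if min_mean is not None:
        _, families = filter_prevalent(table, min_mean=min_mean, sample_ids=ids)
    taxa_df, env_df = _joined_frame(table, env, ids)
    rows = []
    for fam in families:
        for var in env.variables:
            res = spearman(
                taxa_df[fam].to_numpy(), env_df[var].to_numpy(), fam, var
            )
            rows.append(
                {
                    "family": fam,
                    "variable": var,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                    "testable": res.testable,
                }
            )
    return pd.DataFrame(rows)


def export_graph(network: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network as GraphML or a 5-column edge TSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(network, path)
    elif format == "edge-tsv":
        rows = [
            {
                "from": u,
                "to": v,
                "rho": data["rho"],
                "p": data["p"],
                "sign": data["sign"],
            }
            for u, v, data in network.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["from", "to", "rho", "p", "sign"]).to_csv(
            path, sep="\t", index=False, float_format="%.12g"
        )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = ["from", "to", "rho", "p", "sign"]
    if list(df.columns) != expected:
        raise ValueError(f"edge TSV columns {list(df.columns)} != {expected}")
    return df
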