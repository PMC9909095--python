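"""Order-level Spearman co-occurrence networks.

Taxa are aggregated to taxonomic orders on relative abundances, orders with
mean relative abundance below 1% are removed, and an undirected edge joins
two orders when |Spearman rho| > 0.4 and p < 0.05 (two-sided, t-distribution
transform). No multiple-testing correction is applied by default — the raw
p < 0.05 gate is the convention this pipeline follows; a Benjamini-Hochberg
option is available for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .core_io import AbundanceTable, CountTable, ParameterError, TaxonomyMap
from .diversity import EmptyResultError, relative_abundance


@dataclass(frozen=True)
class EdgeList:
    """Thresholded co-occurrence network.

    ``edges``: one row per undirected edge (source, target, rho, p, sign);
    ``nodes``: one row per order passing the abundance filter (mean relative
    abundance, guild when known), isolated nodes included.
    """

    edges: pd.DataFrame
    nodes: pd.DataFrame

    def degree(self) -> pd.Series:
        deg = pd.Series(0, index=self.nodes.index, dtype=int)
        for col in ("source", "target"):
            counts = self.edges[col].value_counts()
            deg = deg.add(counts, fill_value=0)
        return deg.astype(int)


def aggregate_to_order(
    table: CountTable | AbundanceTable, taxonomy: TaxonomyMap
) -> AbundanceTable:
    """Sum relative abundances of member taxa per order; column sums stay 1."""
    unmapped = taxonomy.covers(table.data.index)
    if unmapped:
        raise ParameterError(f"taxa missing from taxonomy: {unmapped[:10]}")
    rel = table if isinstance(table, AbundanceTable) and table.kind == "relative" else relative_abundance(table)
    orders = taxonomy.order_of().loc[rel.data.index]
    grouped = rel.data.groupby(orders.to_numpy()).sum()
    grouped.index.name = "order"
    return AbundanceTable(grouped, kind="relative")


def filter_mean_relabund(
    table: AbundanceTable, threshold: float = 0.01
) -> AbundanceTable:
    """Keep rows whose mean relative abundance across samples is >= threshold.

    Strictly-below-threshold rows are removed ("less than 1%" convention:
    a mean of exactly 1% is retained).
    """
    means = table.data.mean(axis=1)
    kept = table.data.loc[means >= threshold]
    if kept.empty:
        raise EmptyResultError(f"no rows with mean relative abundance >= {threshold}")
    return AbundanceTable(kept, kind="raw")


def spearman_matrix(table: AbundanceTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p between rows.

    Average ranks on ties; p from the t-distribution transform of rho.
    Zero-variance rows yield NaN rho/p for their pairs (never an edge).
    """
    df = table.data
    n = df.shape[1]
    if n < 3:
        raise ParameterError("Spearman matrix needs >= 3 samples")
    X = df.to_numpy(dtype=float)
    ranks = np.apply_along_axis(scipy.stats.rankdata, 1, X)
    constant = ranks.std(axis=1) == 0
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centred**2).sum(axis=1))
    norm[norm == 0] = np.nan
    rho = (centred @ centred.T) / np.outer(norm, norm)
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * scipy.stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, 0.0)
    p[np.diag_indices_from(p)] = np.where(constant, np.nan, 0.0)
    idx = df.index
    return (
        pd.DataFrame(rho, index=idx, columns=idx),
        pd.DataFrame(p, index=idx, columns=idx),
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    rho_threshold: float = 0.4,
    alpha: float = 0.05,
    node_abundance: pd.Series | None = None,
    guilds: pd.Series | None = None,
    fdr: bool = False,
) -> EdgeList:
    """Edge iff |rho| > rho_threshold AND p < alpha; isolated nodes kept.

    ``fdr=True`` replaces raw p-values with Benjamini-Hochberg adjusted ones
    before gating (off by default).
    """
    if not 0 < rho_threshold < 1:
        raise ParameterError("rho_threshold must be in (0, 1)")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ParameterError("rho and p matrices must share labels")
    labels = list(rho.index)
    iu = np.triu_indices(len(labels), k=1)
    rho_v = rho.to_numpy()[iu]
    p_v = p.to_numpy()[iu].copy()
    if fdr:
        finite = np.isfinite(p_v)
        p_v[finite] = scipy.stats.false_discovery_control(p_v[finite], method="bh")
    keep = np.isfinite(rho_v) & np.isfinite(p_v) & (np.abs(rho_v) > rho_threshold) & (p_v < alpha)
    edges = pd.DataFrame(
        {
            "source": np.asarray(labels)[iu[0][keep]],
            "target": np.asarray(labels)[iu[1][keep]],
            "rho": rho_v[keep],
            "p": p_v[keep],
        }
    )
    edges["sign"] = np.where(edges["rho"] > 0, "positive", "negative")
    nodes = pd.DataFrame(index=pd.Index(labels, name="order"))
    if node_abundance is not None:
        nodes["mean_abundance"] = node_abundance.reindex(labels)
    if guilds is not None:
        nodes["guild"] = guilds.reindex(labels)
    return EdgeList(edges=edges, nodes=nodes)


def order_network(
    table: CountTable,
    taxonomy: TaxonomyMap,
    rho_threshold: float = 0.4,
    alpha: float = 0.05,
    abundance_threshold: float = 0.01,
    fdr: bool = False,
) -> EdgeList:
    """Full network stage: aggregate -> 1% filter -> Spearman -> threshold gate."""
    orders = aggregate_to_order(table, taxonomy)
    filtered = filter_mean_relabund(orders, abundance_threshold)
    rho, p = spearman_matrix(filtered)
    guilds = None
    if "guild" in taxonomy.data.columns:
        guilds = (
            taxonomy.data.groupby("order")["guild"]
            .agg(lambda g: g.mode().iat[0])
            .reindex(filtered.data.index)
        )
    return build_network(
        rho,
        p,
        rho_threshold=rho_threshold,
        alpha=alpha,
        node_abundance=filtered.data.mean(axis=1),
        guilds=guilds,
        fdr=fdr,
    )


def network_summary(edge_list: EdgeList) -> dict:
    """Edge/sign/guild tallies and per-node degree."""
    edges = edge_list.edges
    n_pos = int((edges["sign"] == "positive").sum())
    n_neg = int((edges["sign"] == "negative").sum())
    summary = {
        "n_nodes": int(len(edge_list.nodes)),
        "n_edges": int(len(edges)),
        "n_positive": n_pos,
        "n_negative": n_neg,
        "degree": edge_list.degree(),
    }
    if "guild" in edge_list.nodes.columns and len(edges):
        guild = edge_list.nodes["guild"]
        same = (guild.reindex(edges["source"]).to_numpy() == guild.reindex(edges["target"]).to_numpy())
        summary["n_within_guild"] = int(same.sum())
        summary["n_cross_guild"] = int((~same).sum())
    elif "guild" in edge_list.nodes.columns:
        summary["n_within_guild"] = 0
        summary["n_cross_guild"] = 0
    return summary
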