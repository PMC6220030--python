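"""Collapse probe statistics to genes and build the signed genome-wide ranking.

When several probes map to one gene, the probe with the lowest p-value
represents the gene.  Genes are then ordered from the most significantly
region-specific (positive effect, small p) to the most significantly
depleted (negative effect, small p); the signed score
``sign(t) * (-log10 p)`` encodes that order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["collapse_probes_to_genes", "signed_ranking", "P_FLOOR"]

# floor before the log so that underflowing p-values keep a finite score
P_FLOOR = 1e-300


def collapse_probes_to_genes(moderated: pd.DataFrame, probe_annot: pd.Series) -> pd.DataFrame:
    """One representative record per gene: minimal p, then larger |t|, then
    lexicographically smaller probe id.

    Parameters
    ----------
    moderated : DataFrame indexed by probe id with at least ``beta``,
        ``t_tilde``, ``p``, ``q`` columns.
    probe_annot : Series mapping probe id -> gene symbol.
    """
    missing = moderated.index.difference(probe_annot.index)
    if len(missing) > 0:
        raise KeyError(f"probes without gene annotation: {list(missing[:5])}")
    df = moderated.copy()
    df["gene_symbol"] = probe_annot.loc[df.index].to_numpy()
    df["probe_id"] = df.index.astype(str)
    df.index = pd.RangeIndex(len(df))
    df["_negabs_t"] = -df["t_tilde"].abs()
    df = df.sort_values(["p", "_negabs_t", "probe_id"], kind="mergesort")
    rep = df.groupby("gene_symbol", sort=True).head(1).drop(columns="_negabs_t")
    rep = rep.set_index("gene_symbol").sort_index()
    return rep[["probe_id", "beta", "t_tilde", "p", "q"]]


def signed_ranking(gene_stats: pd.DataFrame) -> pd.DataFrame:
    """Total order over genes, best (most specifically expressed) first.

    Sort key: descending ``sign(t) * (-log10 p)``; residual ties broken by
    |t| descending then gene symbol ascending, so the order is a
    deterministic total order.  Returns a DataFrame indexed by gene symbol
    in rank order with a 1-based ``rank`` column and ``signed_score``.
    """
    if len(gene_stats) == 0:
        raise ValueError("gene statistics are empty")
    t = gene_stats["t_tilde"].to_numpy(float)
    p = np.maximum(gene_stats["p"].to_numpy(float), P_FLOOR)
    score = np.sign(t) * (-np.log10(p))
    out = gene_stats.copy()
    out["signed_score"] = score
    out["_negabs_t"] = -np.abs(t)
    out["_gene"] = out.index
    out = out.sort_values(
        ["signed_score", "_negabs_t", "_gene"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns=["_negabs_t", "_gene"])
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
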