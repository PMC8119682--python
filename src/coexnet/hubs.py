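"""Connectivity-based gene hierarchy: HHub / iHub / eHub taxonomy.

kTotal_i is a gene's summed adjacency over the whole network; kWithin_i
its summed adjacency to genes of its own module. A gene is a "high
kTotal" gene when kTotal reaches the q_high quantile of kTotal over all
module-assigned genes (a global property), and a "high kWithin" gene when
kWithin reaches the q_high quantile within its own module (a local
property; module sizes vary widely). HHub = high in both; eHub = high
kTotal only; iHub = high kWithin only. Per-trait expression direction is
read off the gene-significance sign: hyper (GS > 0, P < alpha), hypo
(GS < 0, P < alpha) or NS.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .network import GREY
from .traitcorr import GeneTraitStats

__all__ = ["connectivities", "classify_hubs", "expression_direction"]


def connectivities(adj: pd.DataFrame, colors: pd.Series) -> pd.DataFrame:
    """Per-gene kTotal and kWithin given the adjacency and module colors.

    The adjacency diagonal is ignored (treated as 0).
    """
    colors = colors.reindex(adj.index)
    if colors.isna().any():
        raise ValueError("module colors must cover all genes in the adjacency")
    a = adj.to_numpy(float).copy()
    np.fill_diagonal(a, 0.0)
    k_total = a.sum(axis=1)
    k_within = np.zeros_like(k_total)
    codes = colors.to_numpy()
    for color in pd.unique(codes):
        members = np.flatnonzero(codes == color)
        k_within[members] = a[np.ix_(members, members)].sum(axis=1)
    return pd.DataFrame(
        {"module": colors.to_numpy(), "k_total": k_total, "k_within": k_within},
        index=adj.index,
    )


def classify_hubs(records: pd.DataFrame, q_high: float = 0.90) -> pd.DataFrame:
    """Attach hub_class (HHub/iHub/eHub/none) to connectivity records.

    Quantiles use linear interpolation (numpy default). Grey genes are
    never hubs. Modules with fewer than 5 genes get a warning (their
    within-module quantile is unstable); an all-equal connectivity vector
    degenerates to everything "high" and is flagged with a warning.
    """
    if not 0 < q_high < 1:
        raise ValueError("q_high must be in (0, 1)")
    out = records.copy()
    non_grey = out["module"] != GREY
    if non_grey.sum() < 10:
        raise ValueError("need at least 10 module-assigned genes")
    kt = out.loc[non_grey, "k_total"].to_numpy()
    kt_thresh = np.quantile(kt, q_high)
    if np.ptp(kt) == 0:
        warnings.warn("all kTotal values equal: hub classification degenerate")
    high_total = (out["k_total"] >= kt_thresh) & non_grey

    high_within = pd.Series(False, index=out.index)
    for color, grp in out[non_grey].groupby("module"):
        if len(grp) < 5:
            warnings.warn(
                f"module {color!r} has {len(grp)} genes; within-module quantile unstable"
            )
        kw_thresh = np.quantile(grp["k_within"].to_numpy(), q_high)
        high_within[grp.index] = grp["k_within"] >= kw_thresh

    cls = np.where(
        high_total & high_within, "HHub",
        np.where(high_total, "eHub", np.where(high_within, "iHub", "none")),
    )
    out["hub_class"] = np.where(non_grey, cls, "none")
    return out


def expression_direction(
    gts: GeneTraitStats, traits: list[str] | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene, per-trait direction: hyper / hypo / NS.

    hyper when GS > 0 with P < alpha; hypo when GS < 0 with P < alpha;
    NS otherwise (including P exactly equal to alpha).
    """
    if traits is None:
        traits = list(gts.gs.columns)
    missing = [t for t in traits if t not in gts.gs.columns]
    if missing:
        raise ValueError(f"no gene-significance statistics for trait(s) {missing}")
    gs = gts.gs[traits]
    p = gts.p[traits]
    out = pd.DataFrame("NS", index=gs.index, columns=traits)
    out[(gs > 0) & (p < alpha)] = "hyper"
    out[(gs < 0) & (p < alpha)] = "hypo"
    return out
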