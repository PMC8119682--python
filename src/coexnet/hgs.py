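"""Module membership (kME) and high-gene-significance (HGS) selection.

Module membership MM(i, m) -- also called eigengene-based connectivity
kME -- is the Pearson correlation between gene i's expression profile and
module m's eigengene. A gene is an HGS gene for a trait when it combines
high gene significance for that trait (|GS| >= gs_min, P < alpha) with
high membership in its own module (|MM| >= mm_min, P < alpha): a
candidate biomarker that is both trait-associated and representative of
its module. The MM-vs-GS scatter coordinates are always emitted so the
selection can also be made visually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GREY, EigengeneSet
from .traitcorr import GeneTraitStats, _profile_trait_corr

__all__ = ["MembershipStats", "module_membership", "select_hgs"]


@dataclass
class MembershipStats:
    """Gene x module membership correlations (kME) with p-values."""

    mm: pd.DataFrame
    p_mm: pd.DataFrame

    def own_module(self, colors: pd.Series) -> pd.DataFrame:
        """MM and p for each gene's own module (NaN for grey genes)."""
        colors = colors.reindex(self.mm.index)
        mm_own = np.full(len(self.mm), np.nan)
        p_own = np.full(len(self.mm), np.nan)
        for j, color in enumerate(self.mm.columns):
            members = (colors == color).to_numpy()
            mm_own[members] = self.mm.iloc[:, j].to_numpy()[members]
            p_own[members] = self.p_mm.iloc[:, j].to_numpy()[members]
        return pd.DataFrame(
            {"module": colors, "mm": mm_own, "p_mm": p_own}, index=self.mm.index
        )


def module_membership(
    expr: pd.DataFrame, eigengenes: EigengeneSet | pd.DataFrame
) -> MembershipStats:
    """MM = Pearson cor(gene profile, module eigengene), all gene x module."""
    eig = eigengenes.eigengenes if isinstance(eigengenes, EigengeneSet) else eigengenes
    sd = expr.to_numpy(float).std(axis=1)
    if (sd == 0).any():
        bad = list(expr.index[np.flatnonzero(sd == 0)[:5]])
        raise ValueError(f"constant gene(s): {bad}")
    stats = _profile_trait_corr(expr, eig.T)
    return MembershipStats(mm=stats.gs, p_mm=stats.p)


def select_hgs(
    gts: GeneTraitStats,
    membership: MembershipStats,
    colors: pd.Series,
    gs_min: float = 0.5,
    mm_min: float = 0.8,
    alpha: float = 0.05,
    hub_classes: pd.Series | None = None,
) -> pd.DataFrame:
    """Flag HGS genes per trait; long-format table with scatter coordinates.

    One row per (gene, trait) with GS, p_GS, own-module MM, p_MM, the
    ``hgs`` flag, a ``top_hgs`` flag marking the flagged gene with the
    largest |GS| + |MM| per (module, trait), and -- when hub classes are
    supplied -- an ``also_hh`` flag for HGS genes that are also HHubs.
    Grey genes are never selected (they have no own-module membership).
    """
    own = membership.own_module(colors)
    recs = []
    for trait in gts.gs.columns:
        gs = gts.gs[trait]
        p_gs = gts.p[trait]
        ok = (
            (gs.abs() >= gs_min)
            & (p_gs < alpha)
            & (own["mm"].abs() >= mm_min)
            & (own["p_mm"] < alpha)
            & (own["module"] != GREY)
        )
        df = pd.DataFrame(
            {
                "gene": gts.gs.index,
                "trait": trait,
                "module": own["module"].to_numpy(),
                "gs": gs.to_numpy(),
                "p_gs": p_gs.to_numpy(),
                "mm": own["mm"].to_numpy(),
                "p_mm": own["p_mm"].to_numpy(),
                "hgs": ok.fillna(False).to_numpy(),
            }
        )
        recs.append(df)
    out = pd.concat(recs, ignore_index=True)
    out["top_hgs"] = False
    flagged = out[out["hgs"]]
    if len(flagged):
        score = flagged["gs"].abs() + flagged["mm"].abs()
        top_idx = score.groupby(
            [flagged["module"], flagged["trait"]], observed=True
        ).idxmax()
        out.loc[top_idx.to_numpy(), "top_hgs"] = True
    if hub_classes is not None:
        hh = hub_classes.reindex(out["gene"]).to_numpy()
        out["also_hh"] = out["hgs"] & (hh == "HHub")
    return out
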