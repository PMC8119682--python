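"""Gene significance, module significance and module-trait correlations.

Gene significance (GS) is the Pearson correlation between a gene's
expression profile and a sample trait; module significance (MS) is the
module-average |GS|. Module-trait association correlates each module
eigengene with each trait; modules with |r| >= 0.50 and P < 0.05 for a
trait are flagged as selected. P-values come from the two-sided Student t
test with df = n - 2, t = r * sqrt(n - 2) / sqrt(1 - r^2). Binary and
ordinal traits enter the correlation as numeric codes (point-biserial /
grade scores); missing trait values are handled pairwise-complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneTraitStats",
    "ModuleTraitMatrix",
    "corr_pvalue",
    "gene_significance",
    "module_significance",
    "module_trait_correlations",
    "stratified_run",
]


def corr_pvalue(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided Student-t p-value for a Pearson correlation, df = n - 2."""
    r = np.asarray(r, float)
    n = np.asarray(n, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(np.maximum(n - 2, 0)) / np.sqrt(1 - r**2)
        p = 2 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))
    p = np.where(np.abs(r) >= 1, 0.0, p)
    p = np.where(n < 3, np.nan, p)
    return p


@dataclass
class GeneTraitStats:
    """Per-gene, per-trait correlation (GS), p-value and pair count."""

    gs: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame


def _profile_trait_corr(x: pd.DataFrame, traits: pd.DataFrame) -> GeneTraitStats:
    """Pairwise-complete Pearson correlation of each row of ``x`` (indexed
    profiles x samples) against each trait column."""
    common = [s for s in x.columns if s in traits.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 samples shared between expression and traits")
    xv = x[common].to_numpy(float)
    gs = np.empty((x.shape[0], traits.shape[1]))
    pv = np.empty_like(gs)
    ns = np.empty_like(gs, dtype=int)
    for j, trait in enumerate(traits.columns):
        tvals = traits.loc[common, trait].to_numpy(float)
        ok = ~np.isnan(tvals)
        n = int(ok.sum())
        if n < 3:
            raise ValueError(f"trait {trait!r}: fewer than 3 complete observations")
        t = tvals[ok]
        if t.std() == 0:
            raise ValueError(f"trait {trait!r} is constant on the analyzed samples")
        sub = xv[:, ok]
        sub_c = sub - sub.mean(axis=1, keepdims=True)
        t_c = t - t.mean()
        denom = np.sqrt((sub_c**2).sum(axis=1) * (t_c**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (sub_c @ t_c) / denom
        r = np.clip(r, -1.0, 1.0)
        gs[:, j] = r
        pv[:, j] = corr_pvalue(r, np.full(len(r), n))
        ns[:, j] = n
    idx, cols = x.index, traits.columns
    return GeneTraitStats(
        gs=pd.DataFrame(gs, index=idx, columns=cols),
        p=pd.DataFrame(pv, index=idx, columns=cols),
        n_used=pd.DataFrame(ns, index=idx, columns=cols),
    )


def gene_significance(expr: pd.DataFrame, traits: pd.DataFrame) -> GeneTraitStats:
    """GS = pairwise-complete Pearson r(gene expression, trait)."""
    return _profile_trait_corr(expr, traits)


def module_significance(
    gts: GeneTraitStats, colors: pd.Series, signed: bool = False
) -> pd.DataFrame:
    """Module-average gene significance per trait.

    By default the mean of |GS| (association strength); ``signed=True``
    averages the raw GS values instead.
    """
    colors = colors.reindex(gts.gs.index)
    rows = {}
    for color in colors.unique():
        members = gts.gs.loc[colors == color]
        if members.empty:
            warnings.warn(f"module {color!r} is empty; skipped")
            continue
        rows[color] = members.mean() if signed else members.abs().mean()
    return pd.DataFrame(rows).T


@dataclass
class ModuleTraitMatrix:
    """Module-eigengene x trait correlations with the selection mask."""

    r: pd.DataFrame
    p: pd.DataFrame
    n_used: pd.DataFrame
    selected: pd.DataFrame
    r_min: float = 0.50
    p_max: float = 0.05
    low_n: bool = False

    def selection_report(self) -> pd.DataFrame:
        recs = [
            {"module": m, "trait": t,
             "r": self.r.loc[m, t], "p": self.p.loc[m, t], "n": int(self.n_used.loc[m, t])}
            for m in self.r.index for t in self.r.columns
            if self.selected.loc[m, t]
        ]
        return pd.DataFrame(recs, columns=["module", "trait", "r", "p", "n"])


def module_trait_correlations(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    r_min: float = 0.50,
    p_max: float = 0.05,
) -> ModuleTraitMatrix:
    """Pearson r(ME, trait) with Student-t p and |r|>=r_min & p<p_max mask."""
    stats_ = _profile_trait_corr(eigengenes, traits)
    selected = (stats_.gs.abs() >= r_min) & (stats_.p < p_max)
    return ModuleTraitMatrix(
        r=stats_.gs, p=stats_.p, n_used=stats_.n_used, selected=selected,
        r_min=r_min, p_max=p_max,
    )


def stratified_run(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    strata: pd.Series,
    r_min: float = 0.50,
    p_max: float = 0.05,
) -> dict[str, ModuleTraitMatrix]:
    """Module-trait statistics per stratum of samples.

    Modules and eigengenes come from the full network; only the
    correlation statistics are recomputed on each stratum's samples.
    Strata with fewer than 4 samples are flagged ``low_n``.
    """
    out: dict[str, ModuleTraitMatrix] = {}
    for name in strata.dropna().unique():
        samples = strata.index[strata == name]
        cols = [s for s in eigengenes.columns if s in samples]
        res = module_trait_correlations(
            eigengenes[cols], traits.loc[traits.index.isin(cols)],
            r_min=r_min, p_max=p_max,
        )
        if len(cols) < 4:
            warnings.warn(f"stratum {name!r} has {len(cols)} samples; statistics low-n")
            res.low_n = True
        out[str(name)] = res
    return out
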