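"""Clinicopathological statistics: Spearman screens and frequency tables.

Pairwise Spearman rank correlations (midrank ties; p from the t
approximation) between declared pairs of demographic, clinical and
histological variables, run separately per stratum (all patients, left-HS,
right-HS). Frequency summaries report per-level counts and percentages of
the non-missing total, rounded to one decimal half away from zero.
No multiplicity correction is applied to the screen (raw P < 0.05 flags);
a BH column is added for information.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["spearman", "correlation_screen", "frequency_summary", "round_half_away"]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (5 always rounds outward)."""
    f = 10.0**decimals
    return float(np.sign(x) * np.floor(np.abs(x) * f + 0.5) / f)


def spearman(x, y) -> tuple[float, float, int]:
    """Midrank-tied Spearman rho with t-approximation p; complete pairs only.

    Returns (rho, p, n). Requires >= 4 complete pairs and non-constant
    vectors.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), n


def correlation_screen(
    table: pd.DataFrame,
    pairs: list[tuple[str, str]],
    strata: pd.Series | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen over declared variable pairs, per stratum.

    ``strata`` maps patient id -> stratum label; None runs a single
    "all" stratum. Pairs with fewer than 4 complete observations in a
    stratum are skipped with a warning. Output columns: stratum, var1,
    var2, rho, p, n, significant (raw p < alpha), q (BH, informative).
    """
    missing = {v for pair in pairs for v in pair} - set(table.columns)
    if missing:
        raise ValueError(f"unknown variable(s): {sorted(missing)}")
    if strata is None:
        strata = pd.Series("all", index=table.index)
    rows = []
    for name in strata.dropna().unique():
        ids = strata.index[strata == name]
        sub = table.loc[table.index.isin(ids)]
        if sub.empty:
            warnings.warn(f"stratum {name!r} is empty; skipped")
            continue
        for v1, v2 in pairs:
            try:
                rho, p, n = spearman(sub[v1], sub[v2])
            except ValueError as err:
                warnings.warn(f"{name}/{v1}~{v2}: {err}; skipped")
                continue
            rows.append(
                {"stratum": name, "var1": v1, "var2": v2,
                 "rho": rho, "p": p, "n": n, "significant": p < alpha}
            )
    out = pd.DataFrame(
        rows, columns=["stratum", "var1", "var2", "rho", "p", "n", "significant"]
    )
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def frequency_summary(
    table: pd.DataFrame, categorical: list[str] | None = None
) -> pd.DataFrame:
    """Counts and percentages per level of each categorical variable.

    The percentage denominator is the variable's non-missing count;
    values are rounded to one decimal, half away from zero.
    """
    if categorical is None:
        categorical = [
            c for c in table.columns
            if not np.issubdtype(table[c].dtype, np.floating)
            or table[c].dropna().nunique() <= 10
        ]
    rows = []
    for var in categorical:
        col = table[var].dropna()
        denom = len(col)
        counts = col.value_counts().sort_index()
        for level, count in counts.items():
            pct = round_half_away(100.0 * count / denom) if denom else 0.0
            rows.append(
                {"variable": var, "level": level, "count": int(count),
                 "n_nonmissing": denom, "percent": pct}
            )
    return pd.DataFrame(
        rows, columns=["variable", "level", "count", "n_nonmissing", "percent"]
    )
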