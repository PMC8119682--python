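"""GO-term over-representation of module gene lists.

One-sided Fisher exact test (hypergeometric upper tail) of each gene set
against the analyzed-gene background:

    p = sum_{x >= k} C(K, x) C(N - K, n - x) / C(N, n)

with k = |module ∩ term|, K = |term ∩ background|, n = |module|,
N = |background|. Benjamini-Hochberg q-values are computed across terms
within a module. The background is the set of genes that survived
preprocessing, not the whole genome.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .prep import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = ["enrich_module", "enriched_gene_fraction", "categorize_terms"]


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero."""
    return float(np.sign(x) * np.floor(np.abs(x) * 10 + 0.5) / 10)


def enrich_module(
    module_genes: set[str] | list[str],
    background: set[str] | list[str],
    gene_sets: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of every gene set in a module gene list.

    Gene sets are intersected with the background; the module must be a
    subset of the background. Results are sorted by p (stable ties) with
    columns term, name, k, K, n, N, p, q, genes.
    """
    background = {g.upper() for g in background}
    if not background:
        raise ValueError("empty background")
    module = {g.upper() for g in module_genes}
    if not module <= background:
        extra = sorted(module - background)[:5]
        raise ValueError(f"module genes outside the background: {extra}")
    N, n = len(background), len(module)
    rows = []
    for term, members in gene_sets.sets.items():
        members_bg = members & background
        if not members_bg:
            continue
        K = len(members_bg)
        overlap = sorted(members_bg & module)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "term": term,
                "name": gene_sets.names.get(term, ""),
                "k": k, "K": K, "n": n, "N": N,
                "p": min(p, 1.0),
                "genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows, columns=["term", "name", "k", "K", "n", "N", "p", "genes"])
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["q"] = np.maximum(out["q"], out["p"])
        out = out.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        out["q"] = pd.Series(dtype=float)
    out["significant"] = out["p"] < alpha
    return out


def enriched_gene_fraction(
    module_genes: set[str] | list[str],
    results: pd.DataFrame,
    alpha: float = 0.05,
    use_adjusted: bool = False,
) -> float:
    """Percentage of module genes in >= 1 significant term, one decimal.

    Significance uses the raw p by default (the selection criterion is
    P < alpha); set ``use_adjusted`` to apply the BH q instead.
    """
    module = {g.upper() for g in module_genes}
    if not module:
        return 0.0
    col = "q" if use_adjusted else "p"
    hit: set[str] = set()
    for _, row in results[results[col] < alpha].iterrows():
        if row["genes"]:
            hit |= set(row["genes"].split(","))
    return _round1(100.0 * len(hit & module) / len(module))


def categorize_terms(
    results: pd.DataFrame, keyword_config: dict[str, list[str]]
) -> pd.DataFrame:
    """Assign each term to the first keyword category it matches.

    ``keyword_config`` maps category name -> list of keywords, matched
    case-insensitively against the term name (falling back to the term
    id). Unmatched terms go to "other". A keyword appearing in several
    categories is resolved in favour of the first-listed category and the
    collision is logged.
    """
    out = results.copy()
    if not keyword_config:
        import warnings

        warnings.warn("empty keyword config: all terms categorized as 'other'")
        out["category"] = "other"
        return out
    seen: dict[str, str] = {}
    for cat, words in keyword_config.items():
        for w in words:
            wl = w.lower()
            if wl in seen:
                log.warning(
                    "keyword %r in categories %r and %r; keeping %r",
                    w, seen[wl], cat, seen[wl],
                )
            else:
                seen[wl] = cat
    def categorize(row) -> str:
        text = (row["name"] or row["term"]).lower()
        for cat, words in keyword_config.items():
            if any(w.lower() in text for w in words):
                return cat
        return "other"

    out["category"] = out.apply(categorize, axis=1)
    return out
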