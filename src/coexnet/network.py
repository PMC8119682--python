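"""Weighted co-expression network construction.

Pipeline: Pearson correlation -> soft-threshold scan with scale-free fit
-> adjacency |r|^beta -> topological overlap matrix (TOM) -> average
linkage clustering of 1-TOM -> dynamic tree cut module detection ->
module eigengenes -> eigengene network with meta-modules.

The TOM between genes i and j combines their direct adjacency with the
adjacency they share through common neighbours:

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij   = sum_{u != i,j} a_iu * a_uj,

with TOM_ii = 1; the clustering dissimilarity is 1 - TOM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.stats import linregress

__all__ = [
    "SoftThresholdScan",
    "ModuleAssignment",
    "EigengeneSet",
    "MetaModules",
    "NetworkModel",
    "MODULE_COLORS",
    "correlation_matrix",
    "scan_soft_thresholds",
    "pick_power",
    "adjacency",
    "topological_overlap",
    "tom_dissimilarity",
    "cluster_genes",
    "dynamic_tree_cut",
    "labels_to_colors",
    "module_eigengenes",
    "eigengene_network",
    "build_network",
]

# WGCNA-style color sequence, assigned to modules by decreasing size.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]
GREY = "grey"

# deep_split -> (max core scatter, min gap), on the normalized height scale.
_DEEP_SPLIT = {
    0: (0.64, 0.27),
    1: (0.73, 0.2025),
    2: (0.82, 0.135),
    3: (0.91, 0.0675),
    4: (0.95, 0.0375),
}


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Gene x gene Pearson correlations of a gene x sample matrix."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    x = expr.to_numpy(float)
    sd = x.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if len(zero):
        raise ValueError(f"zero-variance gene(s): {list(expr.index[zero[:5]])}")
    r = np.corrcoef(x)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def adjacency(cor: pd.DataFrame | np.ndarray, beta: int, kind: str = "unsigned"):
    """Soft-thresholded adjacency.

    unsigned: |r|^beta; signed: ((1+r)/2)^beta; signed hybrid: r^beta for
    r>0 else 0. The diagonal is set to 0 so that row sums are node
    connectivities.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = np.asarray(cor, float) if not isinstance(cor, pd.DataFrame) else cor.to_numpy()
    if kind == "unsigned":
        a = np.abs(r) ** beta
    elif kind == "signed":
        a = ((1 + r) / 2) ** beta
    elif kind == "signed hybrid":
        a = np.where(r > 0, r, 0.0) ** beta
    else:
        raise ValueError(f"unknown network kind {kind!r}")
    np.fill_diagonal(a, 0.0)
    if isinstance(cor, pd.DataFrame):
        return pd.DataFrame(a, index=cor.index, columns=cor.columns)
    return a


@dataclass
class SoftThresholdScan:
    """Scale-free fit index and mean connectivity per candidate power."""

    table: pd.DataFrame  # columns: power, r2_signed, slope, mean_k

    @property
    def powers(self) -> list[int]:
        return self.table["power"].tolist()


def _scale_free_fit(k: np.ndarray, n_bins: int) -> tuple[float, float]:
    """Signed R^2 of the log-log degree-distribution regression.

    Connectivities are binned into ``n_bins`` equal-width bins; the
    frequency p(k) of non-empty bins is regressed on the bin-mean k, both
    on log10 scale. Returns (r2 * -sign(slope), slope); (nan, nan) when
    the fit is undefined (fewer than 3 usable bins).
    """
    if np.ptp(k) == 0:
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        members = k[which == b]
        if len(members) == 0:
            continue
        mean_k = members.mean()
        freq = len(members) / len(k)
        if mean_k <= 0:
            continue
        xs.append(np.log10(mean_k))
        ys.append(np.log10(freq))
    if len(xs) < 3:
        return float("nan"), float("nan")
    fit = linregress(xs, ys)
    return float(fit.rvalue**2 * -np.sign(fit.slope)), float(fit.slope)


def scan_soft_thresholds(
    cor: pd.DataFrame | np.ndarray,
    powers: list[int] | range = range(1, 21),
    n_bins: int = 10,
    kind: str = "unsigned",
) -> SoftThresholdScan:
    rows = []
    for beta in powers:
        a = np.asarray(adjacency(cor, beta, kind=kind))
        k = a.sum(axis=0)
        r2, slope = _scale_free_fit(k, n_bins)
        rows.append((int(beta), r2, slope, float(k.mean())))
    return SoftThresholdScan(
        table=pd.DataFrame(rows, columns=["power", "r2_signed", "slope", "mean_k"])
    )


def pick_power(scan: SoftThresholdScan, r2_min: float = 0.90) -> int:
    """Smallest power whose signed scale-free R^2 reaches ``r2_min``.

    Falls back to the argmax power (with a warning) when no power reaches
    the criterion.
    """
    t = scan.table
    if t.empty:
        raise ValueError("empty soft-threshold scan")
    ok = t[t["r2_signed"] >= r2_min]
    if len(ok):
        return int(ok.iloc[0]["power"])
    if t["r2_signed"].isna().all():
        raise ValueError("scale-free fit undefined at every power")
    best = t.loc[t["r2_signed"].idxmax()]
    warnings.warn(
        f"no power reaches R^2 >= {r2_min}; using argmax power {int(best['power'])} "
        f"(R^2 = {best['r2_signed']:.3f})"
    )
    return int(best["power"])


def topological_overlap(adj: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap matrix of a symmetric [0,1] adjacency."""
    a = adj.to_numpy(float) if isinstance(adj, pd.DataFrame) else np.asarray(adj, float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    l = a @ a  # with zero diagonal, (A^2)_ij = sum_{u != i,j} a_iu a_uj
    k = a.sum(axis=0)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore"):
        tom = (l + a) / denom
    tom = np.clip(np.nan_to_num(tom), 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    if isinstance(adj, pd.DataFrame):
        return pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return tom


def tom_dissimilarity(adj: pd.DataFrame | np.ndarray):
    tom = topological_overlap(adj)
    return 1.0 - tom


def cluster_genes(diss: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Average-linkage (UPGMA) merge tree of a dissimilarity matrix.

    Returns a scipy linkage matrix. Deterministic given input order;
    among equal-distance merge candidates scipy's nearest-neighbour chain
    picks the lowest-index pair first.
    """
    d = diss.to_numpy(float) if isinstance(diss, pd.DataFrame) else np.asarray(diss, float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be square and symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity diagonal must be zero")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    return linkage(d[iu], method="average")


@dataclass
class ModuleAssignment:
    """Result of module detection.

    ``labels`` are integers (0 = unassigned); ``colors`` maps each gene to
    a color name ('grey' = unassigned), ordered so the largest module gets
    the first color of :data:`MODULE_COLORS`.
    """

    labels: np.ndarray
    colors: pd.Series
    degenerate: bool = False

    @property
    def module_colors(self) -> list[str]:
        sizes = self.colors[self.colors != GREY].value_counts()
        return list(sizes.index)


def dynamic_tree_cut(
    dendrogram: np.ndarray,
    diss: pd.DataFrame | np.ndarray,
    min_module_size: int = 30,
    deep_split: int = 2,
    pam_stage: bool = True,
    static_cut_frac: float = 0.99,
) -> ModuleAssignment:
    """Adaptive branch decomposition of a dendrogram into modules.

    A dynamic-hybrid style procedure:

    1. Static pre-cut at ``static_cut_frac * max(height)`` splits off the
       tree's top joins (where heights are compressed and uninformative)
       into candidate components.
    2. Each component of size >= ``min_module_size`` is analyzed
       recursively on the height scale normalized to [0, 1] between the
       5th percentile of merge heights (reference) and the maximum:
       when both children of a branch point hold >= ``min_module_size``
       objects and the gap between the branch point and the children's
       own root heights is at least the ``deep_split``-dependent minimum,
       the branch is split and both sides are analyzed in turn; otherwise
       the branch is declared one module provided its core scatter -- the
       mean of its ``min_module_size - 1`` lowest internal merge heights
       -- does not exceed the ``deep_split``-dependent ceiling. Branches
       failing the core test (loose, noise-like) are descended further
       where possible. Larger ``deep_split`` values relax both criteria
       and produce more, smaller modules.
    3. Everything else is left unassigned, then a PAM-like rescue
       (``pam_stage``) assigns each unassigned object to the module with
       the smallest average dissimilarity, provided that distance does
       not exceed the module's own radius (the largest member-to-module
       average dissimilarity); otherwise it stays grey.

    Degenerate input (all merge heights equal) yields a single module
    (or all grey when fewer than ``min_module_size`` objects) with
    ``degenerate=True``.
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    if deep_split not in _DEEP_SPLIT:
        raise ValueError("deep_split must be in 0..4")
    d = diss.to_numpy(float) if isinstance(diss, pd.DataFrame) else np.asarray(diss, float)
    index = diss.index if isinstance(diss, pd.DataFrame) else pd.RangeIndex(d.shape[0])
    n = d.shape[0]
    Z = np.asarray(dendrogram, float)
    if Z.shape[0] != n - 1:
        raise ValueError("dendrogram does not match dissimilarity size")

    heights = Z[:, 2]
    hmax = heights.max()
    ref = np.percentile(heights, 5)
    scale = hmax - ref
    if scale <= 1e-12:
        warnings.warn("degenerate dendrogram: all merge heights equal")
        labels = np.zeros(n, dtype=int)
        if n >= min_module_size:
            labels[:] = 1
        return ModuleAssignment(
            labels=labels, colors=labels_to_colors(labels, index), degenerate=True
        )

    def norm(h):
        return float(np.clip((h - ref) / scale, 0.0, 1.0))

    max_core, min_gap = _DEEP_SPLIT[deep_split]

    # node ids: 0..n-1 leaves, n+i = cluster created by merge i
    def node_size(node: int) -> int:
        return 1 if node < n else int(Z[node - n, 3])

    def node_height(node: int) -> float:
        return 0.0 if node < n else float(Z[node - n, 2])

    def children(node: int) -> tuple[int, int]:
        return int(Z[node - n, 0]), int(Z[node - n, 1])

    def subtree(node: int) -> tuple[list[int], list[float]]:
        """Leaf members and internal merge heights of a subtree."""
        members, hs, stack = [], [], [node]
        while stack:
            v = stack.pop()
            if v < n:
                members.append(v)
            else:
                hs.append(node_height(v))
                stack.extend(children(v))
        return members, hs

    def core_scatter(hs: list[float]) -> float:
        lows = np.sort(np.asarray(hs))[: min_module_size - 1]
        return norm(lows.mean())

    def trunk(node: int) -> list[int]:
        """Members of a candidate module after tail trimming.

        Loosely attached tails (noise chained onto a coherent branch) are
        separated from the trunk by the largest gap in the branch's own
        merge-height profile: when that gap reaches ``min_gap``, only the
        largest sub-branch below it is kept (the PAM stage re-attaches
        trimmed objects that genuinely belong).
        """
        members, hs = subtree(node)
        hs_sorted = np.sort(np.asarray(hs))
        if len(hs_sorted) < 2:
            return members
        gaps = np.diff(hs_sorted) / scale
        gi = int(np.argmax(gaps))
        if gaps[gi] < min_gap:
            return members
        thresh = (hs_sorted[gi] + hs_sorted[gi + 1]) / 2
        # largest maximal sub-subtree whose root is below the gap
        best: list[int] = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < n:
                continue
            if node_height(v) <= thresh:
                if node_size(v) > len(best):
                    best = subtree(v)[0]
            else:
                stack.extend(children(v))
        if len(best) >= min_module_size:
            return best
        return members

    # stage 1: component roots under the static pre-cut
    cut = static_cut_frac * hmax
    merged_away = set()
    for i in range(n - 1):
        if Z[i, 2] <= cut:
            merged_away.add(int(Z[i, 0]))
            merged_away.add(int(Z[i, 1]))
    roots = [
        node for node in range(2 * n - 1)
        if node not in merged_away and (node < n or node_height(node) <= cut)
    ]

    # stage 2: recursive branch analysis
    modules: list[list[int]] = []
    stack = [r for r in roots if node_size(r) >= min_module_size]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        left, right = children(node)
        sl, sr = node_size(left), node_size(right)
        gap = norm(node_height(node)) - norm(max(node_height(left), node_height(right)))
        if sl >= min_module_size and sr >= min_module_size and gap >= min_gap:
            stack.extend((left, right))
            continue
        _, hs = subtree(node)
        if core_scatter(hs) <= max_core:
            modules.append(trunk(node))
            continue
        if sl >= min_module_size:
            stack.append(left)
        if sr >= min_module_size:
            stack.append(right)

    labels = np.zeros(n, dtype=int)
    for mid, members in enumerate(modules, start=1):
        labels[members] = mid

    if pam_stage and modules:
        unassigned = np.flatnonzero(labels == 0)
        if len(unassigned):
            n_mod = len(modules)
            dist_to = np.empty((n, n_mod))
            radius = np.empty(n_mod)
            for m, members in enumerate(modules):
                cols = np.asarray(members)
                dist_to[:, m] = d[:, cols].mean(axis=1)
                s = len(cols)
                # member-to-own-module mean excluding the self-distance 0
                within = dist_to[cols, m] * s / max(s - 1, 1)
                radius[m] = within.max()
            nearest = dist_to[unassigned].argmin(axis=1)
            dmin = dist_to[unassigned, nearest]
            rescue = dmin <= radius[nearest]
            labels[unassigned[rescue]] = nearest[rescue] + 1

    return ModuleAssignment(labels=labels, colors=labels_to_colors(labels, index))


def labels_to_colors(labels: np.ndarray, index=None) -> pd.Series:
    """Map integer labels to color names, largest module first; 0 -> grey."""
    labels = np.asarray(labels)
    sizes = pd.Series(labels[labels != 0]).value_counts()
    mapping = {0: GREY}
    for rank, lab in enumerate(sizes.index):
        mapping[int(lab)] = (
            MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module_{rank + 1}"
        )
    out = pd.Series([mapping[int(l)] for l in labels], index=index, name="module")
    return out


@dataclass
class EigengeneSet:
    """Module eigengenes (first PCs of standardized module expression)."""

    eigengenes: pd.DataFrame  # module x sample, unit sample variance
    variance_explained: pd.Series


def module_eigengenes(expr: pd.DataFrame, colors: pd.Series) -> EigengeneSet:
    """First principal component per module, oriented and standardized.

    Genes are standardized across samples; the eigengene is the first
    right singular vector of the module's standardized matrix, rescaled to
    unit sample variance and sign-oriented so that its correlation with
    the module's mean standardized profile is non-negative.
    """
    colors = colors.reindex(expr.index)
    mes, varexp = {}, {}
    for color in colors[colors != GREY].unique():
        sub = expr.loc[colors == color].to_numpy(float)
        if sub.shape[0] < 2:
            raise ValueError(f"module {color!r} has fewer than 2 genes")
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).all():
            raise ValueError(f"module {color!r} contains only constant genes")
        if (sd == 0).any():
            sub = sub[sd > 0]
            sd = sd[sd > 0]
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        mean_profile = z.mean(axis=0)
        if np.corrcoef(me, mean_profile)[0, 1] < 0:
            me = -me
        me = (me - me.mean()) / me.std(ddof=1)
        mes[color] = me
        varexp[color] = float(s[0] ** 2 / (s**2).sum())
    eig = pd.DataFrame(mes, index=expr.columns).T
    order = [c for c in colors.unique() if c in mes]
    return EigengeneSet(
        eigengenes=eig.loc[order],
        variance_explained=pd.Series(varexp).loc[order],
    )


@dataclass
class MetaModules:
    """Eigengene network: ME dendrogram, adjacency and meta-module labels."""

    dendrogram: np.ndarray | None
    adjacency: pd.DataFrame  # (1 + cor) / 2
    meta_module_of: pd.Series
    cut_height: float | None = None


def eigengene_network(
    eigengenes: EigengeneSet | pd.DataFrame,
    cut_height: float = 0.25,
    method: str = "height",
) -> MetaModules:
    """Cluster module eigengenes into meta-modules.

    Dissimilarity is 1 - cor(ME_a, ME_b), clustered by average linkage.
    ``method="height"`` cuts statically at ``cut_height``;
    ``method="gap"`` cuts at the largest gap between consecutive merge
    heights -- the automated analogue of reading meta-modules off the
    dendrogram by eye, which adapts to the overall correlation level
    among eigengenes.
    """
    eig = eigengenes.eigengenes if isinstance(eigengenes, EigengeneSet) else eigengenes
    modules = list(eig.index)
    cor = np.corrcoef(eig.to_numpy(float))
    cor = np.atleast_2d(cor)
    adj = pd.DataFrame((1 + cor) / 2, index=modules, columns=modules)
    if len(modules) < 2:
        return MetaModules(
            dendrogram=None,
            adjacency=adj,
            meta_module_of=pd.Series([1] * len(modules), index=modules, name="meta"),
            cut_height=None,
        )
    diss = 1.0 - cor
    np.fill_diagonal(diss, 0.0)
    iu = np.triu_indices(len(modules), k=1)
    Z = linkage(diss[iu], method="average")
    heights = Z[:, 2]
    if method == "height":
        cut = cut_height
    elif method == "gap":
        if len(heights) == 1:
            # single merge: split only if the two MEs are far apart
            cut = cut_height if heights[0] > cut_height else heights[0] + 1e-9
        else:
            hs = np.sort(heights)
            gaps = np.diff(hs)
            gi = int(np.argmax(gaps))
            cut = float((hs[gi] + hs[gi + 1]) / 2)
    else:
        raise ValueError(f"unknown meta-module method {method!r}")
    from scipy.cluster.hierarchy import fcluster

    flat = fcluster(Z, t=cut, criterion="distance")
    return MetaModules(
        dendrogram=Z,
        adjacency=adj,
        meta_module_of=pd.Series(flat, index=modules, name="meta"),
        cut_height=float(cut),
    )


@dataclass
class NetworkModel:
    """Full co-expression network: power, adjacency, TOM, tree, modules."""

    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    dendrogram: np.ndarray
    assignment: ModuleAssignment
    eigengenes: EigengeneSet
    meta: MetaModules
    scan: SoftThresholdScan | None = None

    @property
    def module_of_gene(self) -> pd.Series:
        return self.assignment.colors


def build_network(
    expr: pd.DataFrame,
    beta: int | None = None,
    r2_min: float = 0.90,
    powers: list[int] | range = range(1, 21),
    kind: str = "unsigned",
    min_module_size: int = 30,
    deep_split: int = 2,
    pam_stage: bool = True,
    meta_cut_height: float = 0.25,
    meta_method: str = "gap",
) -> NetworkModel:
    """End-to-end network construction from a preprocessed matrix."""
    cor = correlation_matrix(expr)
    scan = None
    if beta is None:
        scan = scan_soft_thresholds(cor, powers=powers, kind=kind)
        beta = pick_power(scan, r2_min=r2_min)
    adj = adjacency(cor, beta, kind=kind)
    tom = topological_overlap(adj)
    diss = 1.0 - tom
    dd = diss.to_numpy()
    np.fill_diagonal(dd, 0.0)
    diss = pd.DataFrame(dd, index=diss.index, columns=diss.columns)
    Z = cluster_genes(diss)
    assignment = dynamic_tree_cut(
        Z, diss, min_module_size=min_module_size, deep_split=deep_split,
        pam_stage=pam_stage,
    )
    eig = module_eigengenes(expr, assignment.colors)
    meta = eigengene_network(eig, cut_height=meta_cut_height, method=meta_method)
    return NetworkModel(
        beta=int(beta), adjacency=adj, tom=tom, dendrogram=Z,
        assignment=assignment, eigengenes=eig, meta=meta, scan=scan,
    )
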