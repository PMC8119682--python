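# Methods

This note documents the models, numerical choices and limitations behind
`coexnet`, in the order of the analysis chain.

## Synthetic data model

Each simulated gene in module *m* follows a single-latent-factor model

    x_i = λ_i f_m + sqrt(1 − λ_i²) ε,      ε ~ N(0, 1) i.i.d.
    f_m = sqrt(1 − w²) e_m + w g_{G(m)}

with module factor `e_m ~ N(0, 1)` over samples, an optional super-group
factor `g` shared by all modules of a meta-group, and super-factor weight
`w ∈ [0, 1)`. Loadings λ are drawn uniformly from `loading_range`
(default 0.7–0.95, giving within-module gene–gene correlations of
≈ 0.5–0.9, typical of strong co-expression modules). Background genes are
pure N(0, 1) noise. All population variances are 1, so the moment of any
gene is checkable analytically. Two modules of the same meta-group have
factor correlation `w²`; the default benchmark `w = 0.6` yields ≈ 0.36,
i.e. clearly related but far from collinear eigengenes.

Traits are planted on the *module factor* `e_m`:
`t = ρ e_m + sqrt(1 − ρ²) η`. Binary and ordinal traits threshold that
latent at empirical quantiles (equal-probability cuts by default), which
mirrors semiquantitative histology grading relative to the cohort and
makes realized level counts exact. Cognitive tests draw controls from
N(μ, σ) and shift patients by the deficit δ toward the impaired side of
the test's direction. Flag counts are Binomial(3, rate) per spot.

One master seed drives everything; per-component generators (expression,
traits, cognitive, flags, gene sets) are spawned from it with fixed
offsets, so outputs are bit-reproducible and independent across
components.

**What the generator does not emulate:** probe-level intensity physics
(dye bias, background, saturation), batch effects, correlated noise,
non-Gaussian expression marginals, missing trait patterns that depend on
outcomes, and realistic GO term overlap structure. Passing recovery tests
therefore demonstrates correctness of the algorithms under the stated
factor model, not robustness to microarray artifacts.

## Preprocessing

Fixed order: flag-mask → complete-case probe exclusion → log2 → quantile
normalization → annotation filter. A spot with two or more quality flags
is treated as missing; any probe with ≥ 1 missing value is excluded
before transformation, so downstream matrices are complete by
construction. Normalization is between-array quantile normalization (the
standard single-channel choice): each column's sorted values are replaced
by across-column means of order statistics, with tie blocks receiving the
mean of their rank range. On tie-free data the operation is idempotent
and forces identical column distributions; with ties the tied column's
block means deviate slightly, which is inherent to rank-block averaging.
Multi-probe genes collapse to the probe with the highest mean expression.
Histology grades can be expanded one-hot (e.g. GCL0-1 / GCL2 / GCL3) and
age-type variables dichotomized at ≤ 5 years via `one_hot`/`binarize`.

## Network construction

Unsigned adjacency `|r|^β` is the default (signed and signed-hybrid
variants are available). The soft-threshold scan bins connectivities into
10 equal-width bins and regresses log10 frequency on log10 mean
connectivity; the fit index is R² signed by the negative of the slope
sign, and `pick_power` takes the first power reaching R² ≥ 0.90, falling
back to the argmax with a warning. On data dominated by a few strong
planted modules the scale-free criterion is genuinely uninformative — the
degree distribution is a mixture, R² hovers near the threshold and the
selected power can swing widely. The recovery benchmarks therefore fix
β = 6, the conventional default for unsigned networks at these sample
sizes; the auto scan remains the pipeline default for data-driven use.

TOM is computed by matrix multiplication (`ℓ = A²` with zero diagonal)
and clipped to [0, 1] against floating-point drift; `TOM_ii = 1`.
Clustering is average-linkage (UPGMA) on `1 − TOM` via scipy's
nearest-neighbour chain, which is deterministic for a given input order
and merges the lowest-index pair among exact ties.

### Dynamic tree cut

Module detection is a dynamic-hybrid style procedure authored here:

1. **Static pre-cut** at `0.99 · max(height)` splits off the compressed
   top of the dendrogram into candidate components.
2. **Recursive branch analysis** on heights normalized to [0, 1] between
   the 5th-percentile reference and the maximum. At a branch point whose
   two children both hold ≥ `min_module_size` objects, the branch is
   split when the gap between the branch point and the children's own
   root heights reaches the `deep_split`-dependent minimum gap;
   otherwise the branch is declared one module if its *core scatter* —
   the mean of its `min_module_size − 1` lowest internal merge heights —
   is below the `deep_split`-dependent ceiling. Loose (noise-like)
   branches failing the core test are descended further. A declared
   module is *tail-trimmed*: if the branch's own merge-height profile
   contains a gap ≥ the minimum gap, only the largest sub-branch below
   that gap is kept, which strips noise chains that attached just under
   the static cut.
3. **PAM-like rescue**: each unassigned object joins the module with the
   smallest average dissimilarity, provided that distance does not exceed
   the module's radius (its largest member-to-module average
   dissimilarity). Background objects fail the radius gate and stay grey.

`deep_split ∈ 0..4` maps to (max core scatter, min gap) pairs
(0.64, 0.27) … (0.95, 0.0375), with (0.82, 0.135) at the default 2 —
larger values split more aggressively. Degenerate input (all merge
heights equal) returns a single module (or all grey below
`min_module_size`) and is flagged. Known limitation: a perfectly
homogeneous single cluster with internal height jitter can be split into
two modules, since the top-level gap test has no parent context at the
root; the PAM stage reunites members only up to labels, not module
count.

Modules are named by the WGCNA color convention, largest module first
(turquoise, blue, brown, …), `grey` = unassigned.

### Eigengenes and meta-modules

The module eigengene is the first right singular vector of the module's
gene-standardized matrix, rescaled to unit sample variance and oriented
so its correlation with the module's mean standardized profile is ≥ 0.
The eigengene network uses dissimilarity `1 − cor(ME_a, ME_b)` under
average linkage; adjacency is reported as `(1 + cor)/2`. Meta-modules can
be cut statically (default height 0.25, i.e. ME correlation ≥ 0.75) or —
the pipeline default — at the **largest gap** between consecutive merge
heights, the automated analogue of reading meta-modules off the
dendrogram by eye. The gap method is scale-adaptive: with a super-factor
weight of 0.6 the within-group ME correlation is only ≈ 0.36, far below
any fixed 0.25-height cut, yet the gap between within-group and
between-group merges identifies the two meta-modules exactly.

## Module-trait statistics

GS, kME and eigengene-trait correlations are all Pearson correlations
with two-sided Student-t p-values (`t = r·sqrt(n−2)/sqrt(1−r²)`,
df = n − 2), computed pairwise-complete with the per-pair n recorded.
Binary and ordinal traits enter as numeric codes (point-biserial / grade
scores). Module significance is the module mean of |GS| (the signed mean
is also available — the absolute convention measures association
strength regardless of direction). Selection uses raw `|r| ≥ 0.50` and
`P < 0.05` with no multiplicity correction, matching the study design
this reimplements; BH q-values are emitted alongside for information.
Stratified runs recompute statistics on each stratum's samples against
the *full-network* modules and eigengenes (the network is never refit per
stratum); strata under 4 samples are flagged low-n.

## Hub taxonomy and HGS selection

kTotal is the row sum of the adjacency (zero diagonal); kWithin restricts
the sum to the gene's module. "High kTotal" is assessed against the 0.90
quantile (linear interpolation) over all module-assigned genes — a global
property — while "high kWithin" uses the 0.90 quantile *within the
gene's module*, because module sizes differ several-fold and intramodular
hubness is local. HHub = high in both, eHub = kTotal only, iHub =
kWithin only. The quantile replaces the visual threshold choice made on
kTotal-vs-kWithin scatter plots in practice; the scatter coordinates are
emitted so the plot can be redrawn. HGS selection requires
`|GS| ≥ 0.5` and own-module `|kME| ≥ 0.8`, both with p < 0.05 — the
community-conventional operationalization of "high GS and high MM" — and
additionally emits a `top_hgs` flag (largest |GS| + |kME| per
module-trait pair) and the HGS ∩ HHub overlap.

## Enrichment

One-sided Fisher exact (hypergeometric upper tail) per term, with the
background fixed to the genes surviving preprocessing, never the whole
genome. BH correction is applied across terms within a module;
`enriched_gene_fraction` counts module genes in ≥ 1 term with raw
p < 0.05 (the reported selection criterion), one decimal, with an
adjusted-p variant available. The two-category functional grouping is
deliberately user-configured keyword matching (first-listed category
wins on collisions), since any such grouping is a curation choice.

## Cognitive scoring

Per-test cut-offs maximize Youden J over midpoints between adjacent
distinct pooled scores, ties broken toward higher specificity; the
test's direction decides which side is impaired. Degenerate all/none
thresholds are not candidates. Mann-Whitney is two-sided; exact by
enumeration when both groups have ≤ 8 observations without ties,
otherwise normal approximation with tie-corrected variance and
continuity correction (an exactly central U reports p = 1). Impairment
scores count, per domain, the discriminative tests (Mann-Whitney
P < 0.05 by default, configurable to all tests) on whose impaired side
the patient falls; missing scores are logged and not counted. Severity
splits at the cohort mean of totals: strictly greater ⇒ severe. The
laterality association is a two-sided Fisher exact test on the
side × severity 2×2 table.

## Clinicopathological statistics

Spearman rho uses midranks and the t approximation for p, requiring ≥ 4
complete pairs; the screen runs declared variable pairs per stratum with
raw-p flags (BH informative). Frequency summaries use the variable's
non-missing count as denominator and round percentages to one decimal,
half away from zero — the convention that reproduces printed cohort
tables from their integer counts.

## Benchmark problem sizes

The recovery benchmarks use 3 000 genes (five modules of 400/300/200/
150/100 plus 1 850 background genes) at 100 and 200 samples, a
four-module / two-super-group dataset of 1 000 genes for meta-module
recovery, 200-replicate null simulations for type-I checks, and a
1 000 × 20 matrix at flag rate 0.1 for the preprocessing contract —
sizes chosen to exercise every code path at full statistical strength
while keeping a complete run in the minutes range on one CPU.
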