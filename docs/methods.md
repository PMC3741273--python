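# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, the numerical conventions, and what the synthetic studies do
and do not establish.

## Expression preprocessing

Input matrices are probe-set × sample tables of log2-scale intensities, as
public repositories serve them for single-color arrays. "RMA-style"
preprocessing is represented by its quantile-normalization step on the
already-summarized matrix (every column is forced onto the mean
order-statistic distribution; ties receive the mean of the quantile values
their rank span covers). Background correction and median-polish
summarization operate on raw probe-level data, which is out of scope; a
config flag (`input_scale: linear`) applies the log2 transform when inputs
are linear.

Row standardization uses the population (n) standard deviation. Because
standardization only rescales rows, every downstream correlation-based
quantity is identical under either denominator convention; the choice is
documented purely for reproducibility. Rows with standard deviation below
1e-12 cannot be standardized and are zeroed and flagged; constant profiles
are rejected by the correlation distance with the offending feature named,
so flagged rows must be filtered before clustering.

For cross-species integration each species block is row-standardized
*separately* (making the platforms' scales comparable), the blocks are
concatenated mouse-then-human, and values are clipped to [−3, 3]. Clipping
follows integration; the order is configurable in spirit but the default is
standardize → integrate → clip.

## SAM differential expression

Two-class unpaired statistic:

    d_i = (mean_B − mean_A) / (s_i + s0)
    s_i = sqrt((1/n_A + 1/n_B) (SS_A + SS_B) / (n_A + n_B − 2))

`s0` is tuned by the coefficient-of-variation rule: candidates are the
{0, 5, …, 95} percentiles of the scatter distribution; for each candidate
the features are split into scatter-quantile windows (100 windows at ≥500
features, n/25 below that) and the candidate minimizing the CV of the
windowed MAD of `d` wins, ties toward the smallest candidate. Below 50
features the windowed estimate is too unstable and the median scatter is
returned.

Permutations are balanced label reassignments of the pooled samples: all
C(n, n_A) distinct assignments when they fit in `n_perm` (20 for the 3v3
design), otherwise `n_perm` seeded draws. `d̄_(i)` is the mean permuted
i-th order statistic. For a threshold δ the called set is the asymmetric
exceedance {i : d_(i) − d̄_(i) > δ or < −δ}; the FDR estimate is
π0 × (median permuted exceedance count) / (observed called count), with π0
fixed at 1 (conservative; configurable). The δ grid is the observed
exceedance magnitudes plus zero, and the smallest δ meeting the FDR target
is chosen — the most permissive set that still satisfies control. When no
permuted feature exceeds at the chosen δ the estimate is 0; when the called
set itself is empty the FDR is vacuously 0. The fold-change gate
(FC ≥ c or ≤ 1/c on the linear scale) is applied *after* δ selection, so
the gate never influences the threshold. Consequences worth knowing:

- the strict `>` rule excludes a feature whose exceedance equals δ exactly
  (the grid is made of observed exceedances, so this happens at the
  boundary of the called set);
- the significant set is monotone in the fold-change cutoff (the gate at
  FC ≥ 3 selects a subset of the gate at FC ≥ 2), mirroring the two
  cutoff regimes (3 within species, 2 for cross-species work);
- order-statistic ties are broken by feature id for bit-reproducibility,
  and a fixed seed makes the whole procedure deterministic.

The union stage pools significant features over the four pairwise group
comparisons of the 2×2 design, recording per-feature provenance (which
comparisons selected it, and the direction).

## Hierarchical clustering and the consensus cluster count

Distance is 1 − Pearson correlation (range [0, 2]); linkage is average:
the distance between clusters is the mean over all cross-cluster pairs.
Cluster-pair distances are recomputed from the raw distance matrix at
every merge using exactly rounded summation (`math.fsum`), so heights are
independent of merge history and bit-identical to a definition-based
re-implementation; merge ties resolve toward the lexicographically
smallest node-id pair. Flat cuts undo the last k−1 merges and label
clusters 1..k in order of first leaf appearance. Dendrograms export to
Newick with the ultrametric convention (children of a node merged at
height h sit h/2 below it).

Three quality indices vote on the number of clusters:

- **Silhouette**: s(i) = (b−a)/max(a,b), singletons scoring 0; nominee is
  the argmax over k.
- **Homogeneity − separation**: H is the mean Pearson similarity of items
  to their cluster centroid, S the pair-count (n_i·n_j) weighted mean
  similarity between centroids; nominee is the argmax of H − S. Items of a
  zero-variance centroid contribute similarity 0.
- **Inter/intra ratio**: pair-count-weighted mean inter-cluster distance
  over mean intra-cluster distance. The raw ratio increases monotonically
  in k, so its nominee is the elbow: the interior k maximizing
  2f(k) − f(k−1) − f(k+1) (the largest drop in marginal gain), ties to the
  smallest k, falling back to the argmax when the grid has fewer than three
  points. The "weighted ratio" and knee formulas are design choices; the
  index family is only loosely specified in the clustering literature.

The consensus is the majority nomination; if all three differ, the median;
ties resolve toward the silhouette nominee. The default search range is
k = 2..15. Gene clustering runs on the standardized *group-mean* profiles
(4 coordinates for the four-group design) of the SAM union set, not on
per-sample profiles.

## Ortholog mapping and integration

The mapping contract is a closed form composed of two rules: a probe
linked to m genes contributes value/m to each (`split_mode: divide`,
default; `replicate` assigns the full value instead), and a gene averages
its incoming contributions. The closed form is order-independent — a
literal sequential sweep over probes would depend on probe order and be
irreproducible — and conserves contribution mass: per sample, the split
parts of every mapped probe sum to the probe's value. The split is applied
to log2-scale values as the procedure is conventionally described; the
per-species standardization that follows absorbs the scale distortion.
Probes with no link are excluded; a probe linked twice to the same gene
counts once (the table is deduplicated on read). Gene symbols are matched
case-insensitively (trimmed, upper-cased) with no alias resolution, and
the intersection of the two species' mapped gene sets defines the shared
ortholog panel.

## Concordance

Per-gene tumor-vs-normal log2 fold change is the difference of group means
(mouse: knockout tumors vs age-matched wild type; human: T1 ∪ T3 pooled vs
normal by default, with per-stage fold changes also reported — the exact
human pooling behind the published comparison is not recoverable, so it is
a documented config choice). Concordance is direction (sign) agreement;
genes with exactly zero fold change in either species count as
non-concordant and are flagged. A stricter mode
(`concordance_mode: sign_and_magnitude`) additionally requires
|log2FC| ≥ log2(2) in both species.

The report carries the raw rate, the raw percent, and a displayed integer
percent computed by rounding the percentage *up* at half-percent
resolution before half-up integer rounding. This display convention makes
117/151 (raw 77.48%) display as 78 — matching how such rates are
conventionally quoted — while plain half-up rounding would give 77; both
numbers are always emitted so the difference stays visible.

Sample-dimension clustering of the integrated matrix uses the same
1 − Pearson / average-linkage machinery; the co-clustering report lists,
for each mouse tumor sample, the human samples sharing its flat cluster at
k (default 2) with their disease-stage labels.

## ΔΔCt qPCR

Housekeeping aggregation is the arithmetic mean of Ct values (equivalent
to the geometric mean of linear quantities); all five panel housekeeping
genes (Gusb, Hprt1, Hsp90ab1, Gapdh, Actb) are used. The group test is
Welch's two-sided t on per-sample ΔCt values; when both groups have zero
variance the p-value degenerates to 0 (any shift) or 1 (no shift).
Selection requires FC ≥ cutoff or ≤ 1/cutoff *and* p < p_max (defaults 3
and 0.05). Undetermined wells are encoded at a Ct ceiling of 40
(configurable). Adding a constant to every Ct of a sample (a loading
offset) leaves ΔCt unchanged, and swapping test/reference groups flips
ΔΔCt's sign and reciprocates FC.

## Synthetic studies

Generators draw log2 intensities as gene-level signal plus Gaussian noise
(sd 0.25 by default — typical replicate scatter for normalized arrays) on
a baseline of N(8, 2²). The dual-species study plants tumor effects with
|log2FC| uniform on [1.6, 4.4] (3- to 21-fold, the magnitude range of the
strongest reported markers) on 160 of 400 shared genes, applied to the
mouse knockout tumor group and to the human tumor stages (full effect in
T3, half in T1, emulating progression); the cross-species direction agrees
with probability 0.78. Each platform has 1200 probes: one dedicated probe
per gene plus extra probes that are unlinked (5%) or random-linked, with a
15% chance of a probe mapping to two genes. Double-linked probes pair
genes within the same regulation stratum (a planted gene with a planted
gene, a flat gene with a flat gene), the way cross-hybridizing probe sets
hit homologous co-regulated families; pairing arbitrary genes would leak
planted effects into flat genes and contaminate the surviving ortholog set
with chance-concordant members. With these defaults roughly 155–160 genes
survive both species' FC ≥ 2 / FDR ≤ 0.05 filters and the intersection,
matching the scale of the published shared-ortholog panel.

The four-group generator plants group-mean archetype patterns (knockout-
tumor-high, age-up, knockout-down-with-age, …) scaled by the same effect
range, for cluster-count recovery tests. The qPCR generator emulates an
84-gene pathway panel plus the 5 housekeeping genes, shifting planted
genes by −log2FC cycles in the test group with 0.2-cycle Ct noise and a
per-sample loading offset that housekeeping normalization must remove.

Every generator writes a truth ledger (JSON) of planted effects, wirings
and agreement flags; recovery tests read truth only from the ledger. One
global seed drives everything through `numpy.random.SeedSequence.spawn`,
so outputs are byte-reproducible and per-stream regenerable.

**What the synthetic studies do not show.** Noise is homoscedastic
Gaussian on the log2 scale with no probe-affinity effects, batch
structure, array spatial artifacts, or intensity-dependent variance; human
cohorts have no clinical covariates or etiology-driven heterogeneity; the
ortholog table has no alias ambiguity. Passing recovery tests therefore
demonstrates correctness of the procedures under the assumed model, not
robustness to real-array pathologies.

## Problem sizes and numerical conventions

Statistical checks run at desk scale: 5000 features for null error
control, 1000 features with 200 planted eightfold changes for power, 25
seeded studies for cluster-count and co-clustering recovery, 100 for
concordance recovery, with 3v3 designs enumerating all 20 balanced
permutations. Tabular IO is strict TSV (decimal point, no NA in
expression matrices) with floats written in shortest round-trip (repr)
form; JSON reports are UTF-8 with sorted keys; Newick labels containing
metacharacters are single-quoted. The displayed-percent rule, the strict
exceedance boundary, the average-linkage tie rule, and the singleton
silhouette convention are the deliberate tie-break/degenerate-input
choices; each is asserted by a dedicated test.
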