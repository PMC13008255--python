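# Methods

This note documents the models and procedures implemented in `singist`,
the choices made where the design was genuinely open, and what the test
suite does and does not establish about behaviour on real data.

## Pseudobulk construction

Counts are summed per (sample, cell type), each summed profile is
library-size normalized to a fixed target (default 1e4 counts) over the
full measured gene space, and transformed to log2(1 + x). The pathway
restriction happens after normalization, so library size never depends on
the pathway under analysis. Cell types with fewer than `min_cells` cells
(default 10) in *any* sample are dropped dataset-wide: a cell type that is
reliable in some samples only would otherwise contribute blocks whose
per-sample precision varies wildly. The threshold is a config value because
it is a property of dataset scale, not of the method. Pathway genes that
were not measured are dropped rather than zero-filled — a constant column
carries no class information but would still receive centering/scaling
treatment and could absorb spurious weight under permutation.

Sum-then-normalize (rather than per-cell normalize-then-average) is the
package's pseudobulk convention; it weights cells by their library size,
which is the standard aggregate most differential-expression pipelines
assume. It is configurable only through `norm_target`; the alternative
ordering was deliberately not implemented to keep one well-tested path.

## asmbPLS-DA

The human reference classifier is a multi-block PLS with per-block adaptive
sparsity, fitted on centered and scaled blocks against the centered and
scaled 0/1 response (base class = 0). Per component j:

1. block weight wᵦ = Zᵦᵀf (f = current response residual), soft-thresholded
   at τ = the λⱼᵦ-quantile of |wᵦ|: entries with |w| ≤ τ are zeroed,
   survivors shrink by τ, then the vector is renormalized to unit norm;
2. block scores tᵦ = Zᵦwᵦ/√pᵦ — the 1/√pᵦ factor stops wide blocks from
   dominating the super level merely by having more genes;
3. super weights from regressing f on the block-score matrix, normalized to
   unit norm; super score t; response loading qⱼ = fᵀt/tᵀt;
4. deflation of every block and of f by the super score.

λ = 0 is special-cased to "no threshold" (τ = 0). Taking the 0-quantile
literally would equal min|w| and shrink every entry, and the single-block,
single-component, λ = 0 case would then no longer reduce to classical PLS1
(weights ∝ Xᵀy) — that reduction is a unit-tested anchor of the
implementation. λ = 1 zeroes a block for that component. Soft vs. hard
thresholding is a config switch (`threshold_mode`); soft is the default and
both satisfy the λ ∈ {0, 1} limit cases.

Because every step is linear in the scaled inputs, the fitted predictor has
an exact accumulated per-gene coefficient (computed by propagating the
deflation operators, vⱼ = aⱼ − Σ_{k<j} vₖ(pₖᵀaⱼ)). Prediction is affine in
the inputs, and the score decomposes exactly:
ŷᵢ − ȳ = Σᵦ γ̂ᵢᵦ = Σᵦ Σ_g δ̂ᵢgᵦ with δ̂ᵢgᵦ = y_sd · βgᵦ · zᵢgᵦ. The
response mean is reported as a separate intercept rather than apportioned
across genes: every downstream quantity (Ω̂, Γ̂ᵦ, Ω̂′, Γ̂ᵦ′) is a
difference of scores, so the intercept cancels identically and any
apportionment convention would be untestable decoration.

Numerical edge cases: zero-variance gene columns get unit scale and are
exactly zero after centering, hence can never acquire weight; a component
whose super weight vector has norm < 1e-12 truncates J with a warning;
a fit with no usable component is a hard error. Identical inputs produce
bitwise-identical models — there is no randomness in fitting.

### Tuning

J* and the per-block λ are selected by leave-one-out CV: fit on n−1
samples, predict the held-out sample, classify at ŷ ≥ 0.5 (on the 0/1
response scale), score F1 with the target class as positive (F1 = 0 when
the positive class is never predicted), minimize 1 − F1 over the candidate
grid. Ties break toward the smallest J, then the largest Σλ: among equally
predictive models, prefer the simplest and sparsest. The default grid is
λ ∈ {0, 0.25, 0.5, 0.75, 0.9, 0.95, 0.99, 1} per block (shared across
components) and J ∈ {1, 2, 3}; per-block combinations grow as |grid|^B, so
runs with many cell types may prefer `per_block=False` (one λ shared by all
blocks).

## Fold changes and treatment

The disease-model fold change per gene and cell type is the difference of
mean log2(count + 1) between target and base cells — the log2 ratio of
geometric means of counts + 1. Significance is a two-sided Wilcoxon
rank-sum test on the per-cell log values, BH-adjusted within each cell
type; the fold change is gated to zero when adjusted p > 0.05 (threshold
configurable). Cell types with fewer than 3 cells per class are fully gated
with a reason code. A precomputed fold-change table (cell_type, model_gene,
log2FC, adj_p) is accepted as an alternative input.

Treatment adds the gated fold change to the human base-class pseudobulk on
the log scale — x′ = x + r — exactly when the cell type is mapped and the
gene has an observed one-to-one ortholog; everything else is a no-op with a
recorded reason (unmapped cell type, no one-to-one ortholog, not sequenced
in the model, non-significant). No back-transform to counts and no
shrinkage beyond the significance gate are applied.

Because treatment adds a per-gene constant and prediction is affine, the
per-gene increment Δ̂gᵦ = δ̂′ᵢgᵦ − δ̂ᵢgᵦ is identical across samples (the
implementation verifies max−min < 1e-10 and warns otherwise), medians are
equivariant under the constant shift, and the recapitulation limits are
exact: matching fold changes give Ω̂f = 100, negated ones give −100.

Degenerate references (|Ω̂| or |Γ̂ᵦ| < 1e-8) make the corresponding
fractions undefined (NaN, never ±inf) and flag the report; a pathway that
does not separate the human classes has no meaningful recapitulation scale,
and the permutation gate is the proper guard against interpreting it.

## Permutation validity test

The observed statistic is the LOOCV F1 error at the tuned hyperparameters.
Each permutation shuffles Y, holds one uniformly chosen sample out of
fitting (guarding against trivially overfit nulls), predicts all samples
and scores F1 against the *true* labels. The p-value is the plus-one
estimator (k+1)/(n_perm+1) of the fraction of null errors at least as small
as observed. A model passes when the BH-adjusted p (across superpathways)
is at or below FDR = 0.1 *and* the observed error lies below the α/2
empirical quantile of the null errors (α = 0.05) — i.e. outside the
two-sided CI(1−α) on the favourable side.

A structural property of scoring the null against the true labels: when the
blocks separate the classes strongly, a permutation whose per-class
majority aligns with the truth can classify every sample correctly under
H0, so the null distribution keeps mass at zero error and the attainable
p-value is bounded away from 1/(n_perm+1) at small n. This makes the test
conservative for strong signals at n ≈ 10; it does not affect type-I
control, which the acceptance suite verifies empirically (pass rate on null
data within 3 binomial SEs of the nominal level over 100 simulations).
Default n_perm is 1000 (the test suite uses 200 for runtime).

## CIP / GIP

Component importance qⱼ is the share of response sum-of-squares captured by
component j (qⱼ²·tᵀt, normalized) — the standard weighting of
variable-importance-in-projection measures. Then

- CIPᵦ = Σⱼ qⱼ (ωᵦⱼ_super)² / Σⱼ qⱼ, with super weight vectors unit-norm
  per component, so Σᵦ CIPᵦ = 1;
- GIPgᵦ = Σⱼ qⱼ (ωgⱼᵦ)² / Σⱼ qⱼ‖ωⱼᵦ‖², i.e. the q-weighting restricted to
  components where block b is active.

The restriction in GIP is the one place the implementation departs from the
plain formula: a block zeroed by λ = 1 in some component has ‖ωⱼᵦ‖ = 0
there, and without the restriction the within-block GIP sum would fall
short of one — the printed unit-sum identity could not hold. Under the
restricted weighting, Σ_g GIPgᵦ = 1 for every block active in at least one
component; a block active in none has GIP ≡ 0 and is flagged
uninformative. Signs are sign(Σⱼ qⱼ ω): the q-weighted direction of the
raw weights.

GIP significance compares each gene's jackknife distribution (leave-one-
sample-out refits at fixed hyperparameters, n values) against a null built
by refitting on data whose entries are permuted jointly over samples and
genes *within* each block — never across blocks, where scale and sparsity
differences break exchangeability. The null GIP values are pooled across
the genes of the block (gene positions are exchangeable within a block
under this null), giving n_perm × pᵦ null values per block. The test is a
one-sided Mann-Whitney U (jackknife greater), with scipy's automatic
exact/normal-approximation switch handling ties and sample size. The
Bonferroni factor is the lower bound on true nulls per block,
m0ᵦ = max(1, ⌊Πⱼ λⱼᵦ · pᵦ⌋): heavy sparsity across all components implies
many presumed-null genes, so the correction adapts to the tuned λ.

## Synthetic data

`simulate_human` draws negative-binomial counts (NB size parameter
`dispersion`, default 2 — typical scRNA-seq overdispersion; larger is
quieter) around lognormal per-gene base means, and multiplies the mean of
each signal gene by 2^shift in target-class cells of its cell type. The
default scene is 2 × 5 samples, 3 cell types, 60 cells per sample-cell
type, a 50-gene pathway with 10 signal genes per cell type shifted 2 log2
units, plus 950 background genes. The background matters: signal genes must
be a small fraction of each cell's library, or library-size normalization
redistributes the injected shift across all genes. Even so the realized
pseudobulk shift is biased slightly low — the log2(1 + x) pseudocount
offset at moderate normalized magnitudes plus residual library coupling —
which is exactly why the recapitulation *exactness* tests use
`simulate_exact_shift`: base-class pseudobulk drawn Gaussian on the log
scale and each target sample an exact copy of one base sample plus the
shift. The identities Ω̂f = ±100 are defined at the pseudobulk stage, and
that is where the generator injects them.

`simulate_model` derives the disease-model fold changes from the human
truth under four concordance modes (perfect, sign-flipped, partial with
attenuation ρ and noise, null), an exact orthology-coverage fraction
(covered genes are a prefix of one seeded permutation, so coverage levels
are nested and lowering coverage only removes orthologs — this is what
makes recapitulation provably monotone in coverage in the location-shift
scenario), unmapped cell types, and a configurable fraction of significant
fold changes.

What the generators do *not* emulate: batch effects, cell-type proportion
shifts between classes, gene-gene correlation beyond the shared library,
ambient RNA, or dropout beyond what the NB marginal implies. Passing tests
therefore establish the algebraic and statistical correctness of the
pipeline under its own assumptions — not robustness to the full mess of
real single-cell data, where upstream correction is assumed done.

## Problem sizes in tests

The test and acceptance runs use the generator defaults (10 samples, 3
blocks, 50-gene pathway) and n_perm = 200 for permutation-based
procedures; the type-I acceptance check runs 100 null simulations. These
sizes were chosen as the smallest at which every property under test is
informative (medians need ≥ 3 samples per class; the permutation p
resolution at 200 permutations is 1/201).

## Known limitations

- Treatment assumes homogeneous fold-change effects across base-class
  samples; cell-type proportion changes between classes are not modelled.
- The permutation test is conservative for strongly separable data at
  small n (see above).
- LOOCV with per-block λ grids is combinatorial in the number of blocks.
- One response column, two classes only; no multi-class or continuous
  phenotypes.
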