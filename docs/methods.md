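# Methods

## Model

Each tumor sample *t* has a linear regulatory model
**w**<sub>t</sub> ∈ ℝ<sup>d</sup> mapping gene-level TF motif features
**X** ∈ ℝ<sup>N×d</sup> to its expression profile
**y**<sub>t</sub> ∈ ℝ<sup>N</sup> (N genes, d TF motifs). The models are
coupled through a latent-program factorization **W = LS**:
**L** ∈ ℝ<sup>d×K</sup> holds K latent regulatory programs,
**S** ∈ ℝ<sup>K×T</sup> the per-sample program weights. The joint cost is

    min_{L,S}  Σ_t (1/N) ‖y_t − X L s_t‖² + μ‖S‖₁ + λ‖L‖²_F

The ℓ₁ penalty μ sparsifies **S**, so tumors form soft, overlapping groups
by which programs they use; λ bounds the programs' ℓ₂ size. The (1/N) loss
scaling is kept explicit so that closed forms and penalty magnitudes are
unambiguous.

Assumptions worth stating: expression is modeled as a *linear* function of
motif features; regulation that is combinatorial, repressive in a
context-dependent way, or driven by TFs with no informative motif is
absorbed into the residual. A TF's "activity" here is a regression
coefficient — the inferred global contribution of its motif features to a
sample's expression — not a direct biochemical measurement. Tumor purity
and stromal admixture are not modeled.

## Optimization

Alternating minimization, each step an exact (or converged) solve of its
convex sub-problem, so the objective trace is non-increasing by
construction:

- **S-step.** For fixed **L** the tasks decouple:
  s_t = argmin (1/N)‖y_t − (XL)s‖² + μ‖s‖₁, a lasso on the K-column design
  XL, solved by cyclic coordinate descent (scikit-learn `Lasso` with
  α = μ/2, which maps its (1/2N)-scaled loss onto this cost) at tolerance
  1e-12. μ = 0 falls back to least squares.
- **L-step.** For fixed **S** the stationarity condition is the
  Sylvester-type system G L M + λL = B with G = XᵀX/N, M = SSᵀ,
  B = XᵀYSᵀ/N — the same linear system as the Kronecker-form normal
  equations [M ⊗ G + λI] vec(L) = vec(B). It is solved exactly through the
  eigendecomposition of M: one d×d ridge solve per latent program, which
  scales to any dK without an iterative fallback.
- **Initialization.** Single-task ridge coefficients W_stl are computed in
  closed form, then the rank-K SVD W_stl ≈ UΣVᵀ gives
  L₀ = U_K Σ_K^{1/2}, S₀ = Σ_K^{1/2} V_Kᵀ (the best rank-K start by
  Eckart–Young). A seeded random initialization exists for robustness
  checks.
- **Convergence.** Stop when the relative objective change < 1e-6 or after
  200 outer iterations (both configurable). An objective increase beyond
  1e-8 relative, twice, raises an error — each step is an exact minimizer,
  so an increase signals a solver bug, not a modeling condition.

The factorization is identifiable only up to permutation, sign, and (at
small penalties) rotation of the programs; all recovery diagnostics
therefore compare **W = LS** directly, or match programs by
maximum-|correlation| bipartite assignment before comparing **L** columns.

## Parameters

| parameter | default | meaning |
|---|---|---|
| K | 7 (config), 4 in the standard synthetic cohort | number of latent programs; selected in practice by scanning K against held-out-gene ρ and subtype separation |
| μ | 1e-3 | ℓ₁ penalty on S (unitless; scales with the (1/N)-normalized loss of unit-norm expression columns, which is ≤ 1/N per task) |
| λ | 1e-3 | Frobenius penalty on L |
| λ_ridge | 0.01 | single-task ridge penalty, same (1/N) loss convention |
| flank | 100 kb | regulatory window either side of the transcription unit |
| merge overlap | 0.75 of the shorter interval | peak-merging threshold |
| promoter window | ±2 kb around the TSS | promoter-only ablation filter |
| expressed threshold / fraction | > 0 in ≥ 50% of one group | TF expression filter |
| Jaccard threshold | 0.5 | target-set redundancy filter |
| pseudocount | 1.0 | added before log10 in expression normalization |

Defaults for μ and λ were chosen by held-out-gene grid search on the
standard synthetic cohort (a `grid_search_hyperparams` helper implements
the nested selection); because expression columns are unit-normalized, the
data-fit term is small (≈ (1−R²)·T/N) and both penalties must sit well
below 1 to avoid over-shrinking. Feature columns of X are z-scored before
regression by default (training-fold statistics inside cross-validation):
the penalties are scale-sensitive and raw motif-score columns have very
unequal variances. Zero-variance columns are dropped with a warning.

Expression normalization follows the convention for log-scale RNA-seq
matrices: log10(x + pseudocount) for linear-scale input (skipped via
`log_input` for already-log data), then each sample column scaled to unit
Euclidean norm. "Unit-normalized" is read as unit ℓ₂ norm; z-scoring is
the plausible alternative and callers can pre-transform if they prefer it.

## Feature construction choices

- **Merging** unions any pair of peaks overlapping by more than 75% of the
  *shorter* interval, repeated to fixpoint, first qualifying pair in
  coordinate order each round (deterministic); a reciprocal mode demands
  the fraction of both.
- **Assignment** windows are strand-symmetric (transcription unit
  ± flank): the upstream-of-TSS and downstream-of-3′ flanks jointly cover
  both sides, so strand only matters through the TSS used for the
  nearest-gene distance (peak midpoint to TSS; ties to the smaller gene
  id).
- **Aggregation** takes the per-gene maximum motif score; default score
  semantics is −log10 of the motif-hit p-value, raw match scores are
  accepted.
- **KS enrichment** compares member-peak log2 fold changes against the
  full differential table *including* the members (a disjoint-background
  mode exists). The top-k occurrence effect size is
  log2(((fg+0.5)/k)/((bg+0.5)/N)) — a pseudocounted log2 frequency ratio,
  chosen so that a motif exactly filling the top-k set scores
  log2(N/k). Exact small-sample KS below 30 members, asymptotic above.
- **Statistics.** Welch (unequal-variance) t-tests for group associations
  with Benjamini–Hochberg FDR across TFs; average linkage on
  (1 − Pearson) distance for activity clustering; Spearman with
  average-rank ties everywhere; the Wilcoxon signed-rank comparison uses
  the exact distribution up to n = 25 (enumerating sign flips directly
  when tied ranks invalidate the tabulated distribution) and the normal
  approximation with continuity correction beyond.

## Synthetic data

`simulate_regulatory_genome` emulates the *statistical* shape of an
ATAC-derived feature build: genes on synthetic chromosomes with
non-overlapping transcription units, Poisson per-gene peak counts placed
uniformly in each gene's ±100 kb window, a configurable fraction of decoy
peaks on a gene-free chromosome (hence outside every window), and
Bernoulli motif hits with scores 5 + Exp(1) (mimicking −log10 p-values of
scanner hits below 1e-5).

`simulate_cohort` plants the model the method assumes: unit-norm program
columns L₀, group-structured supports (program 0 shared by every group,
the others assigned round-robin — with K = 4 and five groups, fully
private programs are impossible, so groups share their specific programs
pairwise), per-sample weights with a group-coherent sign pattern and iid
magnitudes Uniform(0.3, 1.7) (tumors of a type use their programs in a
shared direction with varying strength — this within-group variation is
also what makes the basis identifiable), Gaussian noise, then per-sample
unit normalization in the same order as the real pipeline. Noise is either
a fixed σ or calibrated per task to a target oracle R²
(σ_t = sd(signal_t)·√((1−R²)/R²)).

The standard cohort mirrors a five-tumor-type design at desk scale:
T = 60 samples with group sizes proportional to (92, 255, 57, 272, 47),
N = 1000 genes, d = 100 motifs, K_true = 4, R² ≈ 0.5. Problem sizes were
chosen so the full pipeline (features → fit → 10-fold CV for four feature
sets → statistics) completes in minutes on one CPU.

What passing tests on these fixtures do **not** show: real tumor data has
correlated motif features (TF families share motifs), non-Gaussian noise,
batch structure, purity gradients, and regulatory signal that is not
max-of-motif-scores linear; the generator makes none of these. The
synthetic results validate the *machinery* — solver exactness, monotone
convergence, recovery when the model is true, the multitask advantage when
sharing exists, calibration of the test statistics — not biological
performance.

## Numerical and degenerate-input choices

- Constant predicted vectors in CV score ρ = 0 with a warning (Spearman is
  undefined there).
- A TF with zero variance in both comparison groups records p = 1 and a
  `degenerate` flag rather than NaN.
- Correlation-distance clustering refuses constant sample vectors and
  advises the euclidean mode.
- Regulatory-complexity tertile boundaries sit at the 33rd/66th count
  percentiles; boundary ties fall to the lower class, so highly tied count
  distributions produce unequal classes by design.
- Jaccard of an empty target set with anything is 0; redundancy-filter
  ties (equal mean Jaccard) remove the lexicographically smaller motif id.
- K is clipped to min(d, T) with a warning; K beyond the rank of the STL
  solution pads zero programs.
- All random draws flow from seeded `numpy` generators; every seeded entry
  point run twice is bit-identical.

## Known limitations

- Hyperparameter selection inside cross-validation uses fixed values by
  default; the nested grid search is available but multiplies runtime.
- The permutation/sign matching in recovery reports can flatter a model
  whose K exceeds the true K (extra programs are simply unmatched).
- The promoter-only ablation at synthetic scale removes most peaks
  (uniform peak placement puts few peaks within ±2 kb of a TSS), so its
  performance drop is starker than on real atlases, where promoters are
  strongly enriched for peaks.
- The enrichment module consumes externally computed log2 fold changes;
  it does not model count noise in differential accessibility.
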