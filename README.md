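# psionic

**Patient-specific transcription-factor activity inference by multitask
regression of tumor expression on ATAC-derived motif features.**

Tumor gene expression is shaped by which transcription factors (TFs) are
active, and TF activity leaves a footprint in chromatin: accessible
regulatory regions (ATAC-seq peaks) carrying a TF's binding motif mark its
candidate target genes. `psionic` turns that footprint into a quantitative
model. For each gene *i* and TF *j*, a feature matrix **X** holds the
strongest motif-hit score of TF *j* across the accessible regions assigned
to gene *i* (transcription unit ± 100 kb, nearest gene by TSS distance).
For each tumor sample *t*, the expression profile **y**<sub>t</sub>
(log-transformed, unit-normalized per sample) is regressed on **X**, and the
regression coefficients **w**<sub>t</sub> are read as the inferred
regulatory activities of the TFs in that sample.

Rather than fitting every sample independently, the per-sample models are
tied through a shared factorization — multitask learning with grouping and
overlap (GO-MTL). With *K* latent regulatory programs (columns of **L**, a
TF × K matrix) and per-sample program weights **s**<sub>t</sub>, each model
is **w**<sub>t</sub> = **L s**<sub>t</sub>, i.e. **W = LS**, fitted by

```
min_{L,S}  Σ_t (1/N) ‖y_t − X L s_t‖² + μ‖S‖₁ + λ‖L‖²_F
```

The ℓ₁ penalty μ makes each sample use a sparse combination of programs
(soft, overlapping groups of tumors); the Frobenius penalty λ keeps the
programs themselves small. The problem is solved by alternating exact
minimizations: the S-step is T independent lasso problems (cyclic
coordinate descent), the L-step a closed-form ridge system. A per-sample
ridge baseline (single-task learning, STL) and two randomization controls
(shuffled motif identities, shuffled peak locations) quantify what the
sharing and the features contribute.

The package also includes the surrounding pipeline: peak-atlas merging,
peak→gene assignment, per-gene motif-score aggregation, TF expression and
Jaccard-redundancy filters, regulatory-complexity tertiles, held-out-gene
cross-validation, per-TF tumor-type association tests (Welch t + BH-FDR),
activity clustering and phenotype correlations, KS-based motif enrichment
on differential accessibility, and a seeded synthetic-data generator that
plants a known (**L**, **S**) ground truth so everything is testable
without external downloads.

## Worked example

```python
from psionic import features as feat, mtl, simulate as sim

# synthetic regulatory genome: gene models, peak atlas, sparse motif hits
genes, atlas, hits = sim.simulate_regulatory_genome(n_genes=300, n_tfs=40, seed=1)
assignment = feat.assign_peaks_to_genes(atlas, genes)
X = feat.aggregate_motif_scores(assignment, hits,
                                motif_ids=sorted(hits["motif_id"].unique()))

# plant a K=3 latent-program model and generate noisy expression
cohort = sim.simulate_cohort(X, K_true=3, T=20, n_groups=3, target_r2=0.5, seed=2)

model = mtl.fit_psionic(cohort.X, cohort.Y, K=3, mu=1e-3, lam=1e-3, seed=0)
report = sim.recovery_report(model, cohort)
print(f"converged in {model.n_iter} iterations, "
      f"objective {model.final_objective:.6f}")
print(f"mean per-sample activity correlation with truth: "
      f"{report['mean_activity_corr']:.3f}")
print(f"mean matched-program correlation: {report['mean_program_corr']:.3f}")
```

prints

```
converged in 200 iterations, objective 0.034308
mean per-sample activity correlation with truth: 0.987
mean matched-program correlation: 0.807
```

The activity correlation says the fitted **W = LS** tracks the planted
per-sample TF activities almost perfectly at a signal-to-noise level of
R² ≈ 0.5; the matched-program correlation compares the latent programs
themselves after resolving the factorization's permutation/sign ambiguity.
The scripts in `examples/` walk through each capability (feature
construction, fitting, cross-validation with controls, TF-activity
statistics, accessibility enrichment) with printed, annotated output.

A thin CLI mirrors the pipeline stages:

```bash
psionic simulate --out fixtures/ --seed 0
psionic features --atlas fixtures/atlas.bed --genes fixtures/genes.tsv \
                 --hits fixtures/hits.tsv --out X.tsv
psionic fit --x X.tsv --y fixtures/Y.tsv --out model.zip
psionic cv  --x X.tsv --y fixtures/Y.tsv --out rho.tsv
psionic activities --model model.zip --out W.tsv
psionic associate --activities W.tsv --labels fixtures/labels.tsv --out assoc.tsv
```

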