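"""Downstream statistics on inferred TF activities.

Per-TF Welch t-tests of each tumor type against the rest (BH-FDR
corrected), hierarchical clustering of samples in activity space, and
Spearman correlation of one TF's activity with a numeric phenotype.
"""

import numpy as np

from psionic import mtl
from psionic import simulate as sim
from psionic import tf_activity as tfa

cohort, _ = sim.default_cohort(seed=3, n_genes=300, n_tfs=40, T=24)
model = mtl.fit_psionic(cohort.X, cohort.Y, K=4, seed=0)
W = model.activities()

tables, heat = tfa.onevsrest_scan(W, cohort.labels, top_k=5)
first = sorted(tables)[0]
print(f"type {first} vs rest, top TFs by |effect size|:")
print(tables[first].reindex(tables[first]["effect"].abs()
                            .sort_values(ascending=False).index)
      .head(5).round(4).to_string())
print(f"\nheatmap table: union of top-5 TFs per comparison -> "
      f"{heat.shape[0]} TFs x {heat.shape[1]} types")

Z, order = tfa.cluster_activities(W)
print(f"\nclustered sample order: {order[:8]} ...")

# phenotype association for the TF with the largest overall effect
tf = heat.abs().max(axis=1).idxmax()
rng = np.random.default_rng(0)
act = W.loc[tf].to_numpy()
act_z = (act - act.mean()) / act.std()
phenotype = act_z + 0.5 * rng.standard_normal(W.shape[1])
res = tfa.activity_phenotype_correlation(act, phenotype, seed=0)
print(f"\n{tf} activity vs phenotype: rho = {res['rho']:.3f}, "
      f"permutation p = {res['p_permutation']:.4f}")
# A small permutation p says the rank association is unlikely under
# random pairing of samples and phenotype values.
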