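"""Genomic prediction with BayesR, BayesRC and GBLUP.

Fits the four-component mixture model on a reference set, predicts
genomic breeding values (GBV) for validation individuals, and evaluates
accuracy (r / sqrt(h2)) and dispersion bias (slope of phenotype on GBV;
1.0 = unbiased).
"""

import numpy as np
import pandas as pd

from heatgp import (
    McmcConfig,
    build_grm,
    dispersion_bias,
    fit_bayesr,
    fit_bayesrc,
    fit_gblup,
    predict_gbv,
    prediction_accuracy,
)
from heatgp import simulate_genotypes

n_ref, n_val, m, h2 = 500, 300, 1200, 0.5
geno = simulate_genotypes({"A": n_ref + n_val},
                          {"n_chrom": 2, "chrom_length_bp": 3_000_000,
                           "n_array_snps": 200, "n_sequence_snps": m}, seed=9)
rng = np.random.default_rng(10)
eff = np.zeros(m)
qtl = rng.choice(60, 25, replace=False)      # QTL live in the first 60 SNPs
eff[qtl] = rng.normal(0, 1, 25)
tbv = geno.centered() @ eff
tbv *= np.sqrt(h2) / tbv.std()
y_all = tbv + rng.normal(0, np.sqrt(1 - h2), n_ref + n_val)

ref = geno.subset_individuals(geno.individual_ids[:n_ref])
val = geno.subset_individuals(geno.individual_ids[n_ref:])
y_ref, y_val = y_all[:n_ref], y_all[n_ref:]
mcmc = McmcConfig(n_chains=2, n_iter=2000, burn_in=1000, seed=11)

annot = np.zeros(m, dtype=int)
annot[:60] = 1                               # 'top SNPs' annotation class II

for name, post in (
        ("BayesR ", fit_bayesr(y_ref, ref, mcmc=mcmc)),
        ("BayesRC", fit_bayesrc(y_ref, ref, classes=annot, mcmc=mcmc))):
    gbv = predict_gbv(post, val)
    acc = prediction_accuracy(gbv, y_val, h2)
    bias = dispersion_bias(y_val, gbv)
    print(f"{name}: accuracy = {acc:.2f}, dispersion bias = {bias:.2f}")

gbv, comps = fit_gblup(pd.Series(y_ref, index=ref.individual_ids),
                       grms=build_grm(geno))
acc = prediction_accuracy(gbv.loc[val.individual_ids], y_val, h2)
print(f"GBLUP  : accuracy = {acc:.2f}, "
      f"h2 estimate = {comps[0].h2:.2f} (simulated {h2})")
print("BayesRC gains over BayesR when the annotated class is QTL-enriched;")
print("bias near 1.0 means predictions are neither inflated nor deflated")
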