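"""Derive heat-tolerance phenotypes from test-day records.

Fits the reaction-norm model (random intercept + slope per cow on the
thresholded, rescaled THI) after adjusting yields for herd-test-day and
parity, then averages daughter trait deviations into bull records with
daughter-count weights.
"""

import numpy as np
import pandas as pd

from heatgp import (
    bull_dtd,
    fit_reaction_norm,
    simulate_effects,
    simulate_genotypes,
    simulate_test_days,
)
from heatgp.simdata import sigma_v2_for_target_variance

geno = simulate_genotypes({"A": 600},
                          {"n_chrom": 1, "chrom_length_bp": 2_000_000,
                           "n_array_snps": 100, "n_sequence_snps": 500}, seed=4)
pi = (0.9, 0.05, 0.03, 0.02)
sv2 = sigma_v2_for_target_variance(geno, pi, 1.0)
model = simulate_effects(geno, pi, sv2, seed=5)
records = simulate_test_days(model, design={"records_per_cow": 10}, seed=6)

tds = fit_reaction_norm(records)
truth = pd.Series(model.tbv_slope, index=model.individual_ids)
merged = tds.set_index("cow_id").join(truth.rename("true_slope")).dropna()
r = np.corrcoef(merged.slope_td, merged.true_slope)[0, 1]
print(f"trait deviations for {len(tds)} cows; "
      f"corr(slope TD, true breeding value) = {r:.2f}")
print("(the gap from 1 is cow-level environmental slope + estimation noise)")

# pretend cows are daughters of 30 bulls
links = pd.DataFrame({"cow_id": tds.cow_id,
                      "sire_id": [f"bull{int(i) % 30}" for i in range(len(tds))]})
bulls = bull_dtd(tds, links, h2=0.25)
print(bulls.head(3).to_string(index=False))
print("w is the residual weight (1-h2)/(c h2 + (4-h2)/p) used in prediction")
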