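"""Null-normalized topology metrics of a modular covariance network.

A cohort with 4 latent modules (within-module correlation 0.6, between
0.15) yields a segregated covariance network. Its clustering (Cp) and
path length (Lp) are normalized by 100 distribution-matched random
covariance networks (HQS construction): gamma = Cp/Crand, lambda =
Lp/Lrand, sigma = gamma/lambda. A small-world network has gamma > 1,
lambda ~ 1 and sigma > 1.
"""

from morphnet import (CohortConfig, build_covariance_network, generate_cohort,
                      normalized_metrics)

cfg = CohortConfig(n_subjects_per_cell=40, seed=1, n_modules=4,
                   within_module_corr={"HC": 0.6, "MS": 0.6},
                   between_module_corr={"HC": 0.15, "MS": 0.15})
net = build_covariance_network(generate_cohort(cfg).table("CT", "HC", "3T"))

rec = normalized_metrics(net, n_null=100, seed=2)
print(rec[["density", "Q", "Cp", "Lp", "gamma", "lambda", "sigma"]]
      .round(3).to_string(index=False))
print(f"\nmin gamma = {rec['gamma'].min():.3f}, "
      f"min sigma = {rec['sigma'].min():.3f}  (> 1 at every density:")
print("high clustering at random-level path length — small-world topology).")
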