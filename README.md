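# morphnet

Structural covariance network analysis of cortical gray-matter
morphometry — for neuroimaging researchers comparing patient groups
and/or MRI field strengths at the level of network topology rather than
single regional measures.

Cortical thinning and gray-white boundary blurring in neurodegenerative
disease (the motivating case is early relapsing-remitting multiple
sclerosis studied at 3T and 7T) do not occur region-by-region in
isolation: regions degenerate in covarying patterns. `morphnet` models
this with *structural covariance networks*: for each group, the 68
regions of the Desikan-Killiany atlas become nodes, and the edge weight
between regions i and j is the Pearson correlation of a morphometric
measure — cortical thickness (CT, mm) or gray-white percent contrast
(GWc, %) — across the group's subjects. Thresholded to binary graphs
over a grid of edge densities (0.50–0.69 in 1 % steps by default), each
network is summarized by

* modularity **Q** (segregation into communities),
* mean clustering coefficient **Cp** and characteristic path length **Lp**,
* their null-normalized forms **γ = Cp/C<sub>rand</sub>**,
  **λ = Lp/L<sub>rand</sub>** and small-worldness **σ = γ/λ**, where the
  null means come from 100 random covariance matrices that match the
  observed off-diagonal mean and variance (the Hirschberger–Qi–Steuer
  construction). A small-world network has γ > 1, λ ≈ 1, σ > 1.

Around the core, the package provides the tissue-contrast formulas
(CNR, surface CNR, GWc = 100(W−G)/(0.5(W+G)), SNR, MP2RAGE background
masking), regional aggregation of vertex data, a GLM statistics layer
(per-region ANCOVA with age/sex/scanner covariates, Tukey–Kramer post
hocs, Benjamini–Hochberg FDR, 3T↔7T correspondence regression,
network-metric ANOVA, demographics tests), and a seeded synthetic cohort
generator whose latent factor model produces modular covariance
structure with configurable within/between-module correlations — so the
entire pipeline is testable without any scan data. See
[docs/methods.md](docs/methods.md) for the model details and design
choices.

## Worked example

A cohort with four latent modules (within-module correlation 0.6,
between 0.15, 40 subjects) yields a segregated CT covariance network;
normalizing against 100 distribution-matched nulls shows small-world
topology at every density (`examples/04_small_world_metrics.py`):

```text
 density     Q    Cp    Lp  gamma  lambda  sigma
    0.50 0.278 0.764 1.508  1.100   1.000  1.100
    0.51 0.268 0.757 1.496  1.090   1.000  1.091
     ...
    0.69 0.132 0.808 1.310  1.029   1.000  1.030

min gamma = 1.029, min sigma = 1.030
```

γ > 1 at random-level λ means the network keeps high local clustering
without losing global integration — exactly the regime expected from a
modular covariance structure, and the property the null model is built
to test. The other scripts in `examples/` walk through cohort
generation (`01`), the contrast formulas (`02`, e.g. CNR = 1.418 on a
20 000-sample fixture vs. the 1.414 closed form), network construction
and the connectivity floor (`03`), and the full statistics layer (`05`).

The same stages are scriptable from the shell:

```bash
morphnet simulate --seed 3 -o cohort/
morphnet network cohort/morphometry_long.tsv -o networks/
morphnet metrics networks/cov_CT_HC_3T.tsv --n-null 100 -o metrics.tsv
morphnet run-all -c config.yaml          # everything + report
```

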