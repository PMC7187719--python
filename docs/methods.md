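# Methods

`morphnet` analyzes cortical gray-matter organization through *structural
covariance networks*: graphs whose nodes are the 68 regions of the
bilateral Desikan-Killiany parcellation and whose edges reflect how
strongly a morphometric measure co-varies between regions across the
subjects of a group. The package covers the full chain — tissue-contrast
measures, covariance-network construction, null-normalized graph
topology, and the group-comparison statistics — together with a
synthetic cohort generator that supplies data with the statistical
structure the analysis assumes.

## Morphometric measures and tissue contrast

Two regional measures are consumed (not estimated from images):

* **Cortical thickness (CT, mm)** — distance between the white and pial
  surfaces, averaged per region; a proxy for neuronal loss.
* **Gray-white contrast (GWc, percent)** — `GWc = 100 (W − G) / (0.5 (W + G))`,
  with the WM intensity `W` sampled 1 mm below the white surface and the
  GM intensity `G` at 30 % cortical depth; a proxy for myelin/boundary
  integrity. Positive when WM is brighter; scale-invariant under a
  common positive intensity rescaling, but *not* under an additive
  offset (the denominator shifts).

Image-quality statistics from labeled intensity samples:

* **CNR** `= |mW − mG| / sqrt(Wvar + Gvar)` with tissue means `mG, mW`
  and variances `Gvar, Wvar`. The variance convention is the standard
  one consistent with "divided by the standard deviation of the
  signals"; a sum-of-SDs denominator is exposed via
  `compute_cnr(..., denominator="sd")` since the convention is not
  universal. The absolute value makes the statistic orientation-free.
  CNR is invariant under global intensity offset and positive rescaling.
* **sCNR** — the same formula restricted to surface-mapped samples.
* **SNR** — mean brain-tissue intensity over the background-noise SD.
  This is a convention choice of the package (no closed form is
  standard); it is reported only descriptively.

The 1-mm / 30 %-depth sampling rules are honored through the fixture
generator's labeling contract; no surface geometry is handled. Regional
aggregation is the arithmetic mean of vertex values, excluding
medial-wall vertices labeled `unknown`; the vertex-count-weighted mean
of regional values equals the mean over included vertices exactly.
MP2RAGE background masking multiplies the T1 map by a PD-weighted image
and zeroes voxels whose product falls at or below a threshold.

## Covariance networks and density thresholding

For one group cell and measure, the network entry (i, j) is the Pearson
correlation of regions i and j across subjects (`n ≥ 3`, every region
with nonzero variance). Binarization keeps the top
`floor(d · N(N−1)/2)` region pairs ranked by **signed** correlation
(negative correlations are the weakest links — the structural-covariance
convention; ranking by absolute value is a config switch). Ties break
lexicographically, so edge sets are deterministic and *nested* across
densities — which makes the minimum fully-connected density well defined
and lets it be found with a union-find over the ranked pairs.

The default analysis grid is **20 densities in 1 % steps ascending from
the minimum density threshold 0.50** (0.50–0.69). Both the start and the
step are configurable; the grid must sit at or above the minimum
fully-connected density, which the pipeline verifies and reports.

## Topology metrics and the distribution-matched null model

Per density: modularity **Q** (Newman-Girvan quality, optimized by
seeded Louvain with 20 restarts plus one greedy-agglomerative candidate,
each polished by a single-node-move sweep; best Q kept — a heuristic
that can, on rare tiny graphs, land below the global optimum), mean
clustering coefficient **Cp** (nodes of degree < 2 contribute 0), and
characteristic path length **Lp** (mean BFS distance over all pairs;
disconnected observed graphs are a hard error).

Cp and Lp are normalized by their means over **100 null networks**
generated with the Hirschberger–Qi–Steuer (HQS) construction: draw an
`N × m` factor matrix `X` with i.i.d. `N(μ, s²)` entries and use
`S = X Xᵀ`. With `μ² = e/m` and `s²` solving `m(s⁴ + 2μ²s²) = v`, the
off-diagonal entries of `S` match the observed off-diagonal mean `e` and
variance `v` exactly in expectation; `m = ceil((d̄² − e²)/v)` (floor 1,
capped at 10⁴) places the diagonal mean at the observed `d̄`. `S` is PSD
by construction. The diagonal is deliberately *not* renormalized to 1:
rescaling by `sqrt(S_ii S_jj)` would inject a Jensen-type bias of
several percent into the off-diagonal moments, and thresholding consumes
only off-diagonal ranks, so the diagonal never enters the analysis. The
construction requires `e ≥ 0` (an error otherwise); a degree-preserving
rewiring null (`maslov_sneppen_null`) is included as a labeled
alternative.

Null graphs thresholded at a given density can come out disconnected;
their Lp is computed on the largest connected component and the event is
counted in `n_null_disconnected` (dropping whole nulls would bias the
null path length downward). The normalized metrics are
`γ = Cp/Crand`, `λ = Lp/Lrand`, `σ = γ/λ` (exact identity in every
record); a small-world network satisfies `γ > 1`, `λ ≈ 1`, `σ > 1`.
Q is reported raw (group comparisons use Q itself, not a null-normalized
form).

Lp is non-increasing in density on the nested graphs (more edges can
only shorten paths) and this is property-tested. Cp usually rises with
density but is **not** monotone — an added edge between low-degree nodes
dilutes the average — so no such invariant is asserted.

## Group statistics

* **Regional ANCOVA** — per region, OLS of
  `value ~ group + age + sex + scanner` over pooled subject-sessions;
  the group factor is tested by the extra-sum-of-squares F test of the
  full vs. group-free model (identical to the Type-III test here since
  the model has no interactions). Rank-deficient designs (e.g. scanner
  perfectly confounded with group) raise an error naming the aliased
  terms.
* **Tukey–Kramer post hocs** — on covariate-adjusted group means, using
  the studentized-range distribution with `q = |Δ| / sqrt(var(Δ)/2)`;
  the unequal-n (Kramer) form arises naturally from the coefficient
  covariance. For k = 2 this reproduces the unadjusted t test.
* **FDR** — Benjamini–Hochberg step-up at q = 0.05 ("FDR at 95 %
  confidence"), applied across regions, or across the metric × measure
  family for network metrics. Post hocs are computed within factor and
  FDR across units.
* **Network-metric ANOVA** — one-way across the four group cells with
  per-density metric values as replicates (the only reading compatible
  with F(3, ~88)-scale degrees of freedom for four group-level
  networks); the per-density values are serially dependent, so the
  nominal dfs overstate the effective replication — a caveat inherited
  by design.
* **Field correspondence** — OLS/Pearson regression of 7T on 3T regional
  values. Default pooling is one point per subject × region (the only
  pooling that can produce the very small p values such regressions
  report); per-region group means (68 points) are the alternative and
  the automatic fallback when the two tables hold different subjects.
* **Demographics** — chi-square test of independence for sex × group
  (no continuity correction, expected counts attached, warnings for
  small or empty cells); t test (2 groups) or one-way ANOVA otherwise
  for age, lesion volume and brain parenchymal volume. Zero-variance
  identical samples are reported as a null result (statistic 0, p 1)
  rather than NaN.

## Synthetic cohort generator

The generator emulates the study conditions the analysis targets: a 2×2
cohort (HC/MS × 3T/7T) with default cell sizes 37/47/7/7 (controls
at 3T/7T, patients per field), 68 regions, and per-region baselines
around CT ≈ 2.5 mm and GWc ≈ 20 % with a fixed, seed-independent
regional spread (±0.4 mm / ±3 %) so that regional profiles — and hence
the 3T↔7T correspondence regression — are meaningful. Default effects:
7T shifts CT by −0.20 mm and GWc by +2.0 %; the MS-like group shifts CT
by −0.12 mm and GWc by +1.0 %, reproducing the orderings
HC 3T > MS 3T > HC 7T > MS 7T (CT) and the reverse (GWc).

Inter-regional structure comes from a latent factor model: with a
shared factor `g`, one factor per module `f_m` and idiosyncratic noise,
`z_r = sqrt(b)·g + sqrt(w−b)·f_m(r) + sqrt(1−w)·ε_r` has unit variance,
correlation `w` within modules and `b` between — PSD by construction for
any `0 ≤ b ≤ w < 1` (negative between-module correlation is not
representable in this one-shared-factor form and is rejected at config
time). Defaults: 4 modules as contiguous blocks, within/between
correlation 0.60/0.15 for the MS-like group and 0.45/0.15 for controls,
making the MS-like networks more segregated. Subject values are
`baseline + effects + sd·z` with total SDs 0.15 mm (CT) and 1.5 % (GWc);
CT and GWc draw independent latents. Ages are uniform on 19–60, sex
Bernoulli(0.5), and lesion-volume / brain-volume columns are
group-shifted Gaussians purely so the demographics tests have inputs.

What the generator does **not** emulate: spatial autocorrelation and
hemispheric symmetry of real cortical maps, the paired design (the same
patients scanned at both fields — cells are independent draws),
non-Gaussian tails, lesion geometry, and any image content. Passing
tests therefore demonstrate correctness of the pipeline's statistics and
graph machinery under its stated model, not robustness to real-scan
artifacts.

## Numerical and scale choices

Determinism everywhere: every stochastic step takes an explicit seed
(cohorts, Louvain restarts, HQS draws, pipeline stages derive
per-network seeds from the config seed via a seed sequence), and reruns
of a pipeline config are byte-identical. Correlations are clipped to
[−1, 1] and symmetrized against floating drift. Degenerate inputs fail
loudly: zero-variance regions, zero contrast denominators, edgeless
graphs, disconnected observed graphs, rank-deficient designs.

Verification problem sizes are chosen at desk scale: oracle equivalence
of Cp/Lp/Q uses exhaustive enumeration on graphs of ≤ 8 nodes (Bell-number
search); small-world and null-moment checks use a 40-subject modular
cohort with 100 nulls on the default grid; the modularity
group-ordering recovery uses 100 replicates of 16-subject cells with 3
optimizer restarts; type-I error control uses 500 zero-effect cohorts of
6 subjects per cell over 8 regions. These sizes are the package's own
verification design and are configurable at the API level.

## Known limitations

* Group-level networks only — no individual-subject networks, weighted
  or signed-graph analysis, or sparse inverse-covariance estimation.
* The modularity optimizer is a heuristic; on small graphs it can stop
  at a local optimum slightly below the exhaustive maximum (observed on
  ~1 % of random ≤ 8-node graphs).
* The HQS null matches first and second off-diagonal moments, not the
  full dependence structure; being a low-rank factor product it is
  itself substantially clustered, so γ against it is conservative —
  at the high default densities (≥ 0.50) the clustering margin of a
  moderately modular 40-subject network over the HQS null is only a few
  percent and single cohort draws can dip below 1, even when the same
  networks show γ of 1.04–1.3 against degree-preserving rewiring nulls.
  The rewiring null (`maslov_sneppen_null`) is the complementary check.
* Treating per-density metric values as ANOVA replicates folds the
  strong metric-vs-density trend into the error term, which deflates F
  and the Tukey statistics; group effects must be large relative to the
  trend's spread over the grid to reach significance under this design,
  and enlarging the cohorts does not help (the trend is not sampling
  noise). A narrower density window or a density-adjusted model would
  be more powerful, but the replicate design is retained as specified.
* ANCOVA treats subject-sessions as independent observations; the
  paired patients-at-both-fields design of a real study would warrant a
  mixed model, which is out of scope here.
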