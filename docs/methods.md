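# Methods

## Mixture model and adjustment

Saliva DNA is treated as a two-cell-type mixture of buccal epithelium
and leukocytes. For sample *i* with buccal fraction `p_i`, the observed
β at CpG *j* is

    β_ij = p_i β_A,j + (1 − p_i) β_B,j + ε_ij,

with additive Gaussian noise ε on the β scale, truncated to [0,1]. Two
consequences drive everything downstream: (i) at any CpG, β is linear
in `p`; (ii) therefore β at any composition-driven CpG is linear in β
at any *other* composition-driven CpG. A marker CpG that is near-binary
between the cell types (large reference separation) is thus both a
quantitative readout of `p` — by inverting the convex combination,
`p̂ = (β_obs − β_B)/(β_A − β_B)`, clipped to [0,1] — and a regression
covariate that absorbs the composition component of every other CpG.

Adjustment is *selective*: each non-marker CpG is regressed (OLS) on the
marker β across samples; only CpGs whose regression F-test P falls below
the `affected` threshold are corrected by subtracting
`slope · (marker − anchor)`. Unaffected CpGs are passed through
bit-identical — biological signal uncorrelated with composition is never
touched. The multi-marker variant (e.g. additional leukocyte-subtype
markers) is the same computation with a multiple-regression design
matrix; collinear later markers are dropped in input order with a
warning.

Key numerical facts:

* **Orthogonality.** OLS residuals are exactly orthogonal to the
  regressor in-sample, so an adjusted CpG's correlation with the marker
  is zero to machine precision — *except* where the final truncation to
  [0,1] clips a value. Truncation events are counted and reported
  (`n_truncated`); in confounded simulations a handful of clipped
  values can leave residual |r| of up to ~0.1 at an affected CpG. This
  is the sole deviation from exact orthogonality and is inherent to
  keeping β values interpretable as fractions.
* **Idempotence.** Re-fitting on an adjusted matrix yields slopes ≈ 0;
  re-adjusting changes nothing beyond the truncation artifact.
* **Anchor.** Adjusted values are pinned at the cohort-mean marker
  value, keeping them on the β scale near observed levels. Any anchor
  in [0,1] is accepted; the choice shifts all adjusted values of a CpG
  by a constant and cancels in paired differences, so it does not
  affect the association results.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `affected_p` | 0.01 | per-CpG marker-regression P below which a CpG is adjusted; unadjusted for multiplicity, matching the analysis' general nominal-significance convention |
| `min_separation` | 0.3 | minimum reference β separation for a marker to be invertible into a proportion |
| `n_mad` | 3.0 | composition-outlier rule: marker β outside median ± 3·MAD flags a sample, and its whole pair is excluded |
| `p_threshold`, `d_threshold` | 0.01, 0.05 | MVP calling: P below threshold in every analysis *and* \|mean Δβ\| above threshold |

The outlier rule targets *individually* extreme pairs (e.g. one pair
with ~pure buccal saliva) whose leverage distorts every regression
slope. It is intentionally not applied in the deliberately confounded
demonstration scenario, where *all* heavy co-twins are shifted — a
global shift is the signal under study there, not an outlier.

## Exact statistics

**Wilcoxon signed rank.** The test statistic is the positive-rank sum
W⁺ of the paired differences. The exact null is built by dynamic
programming over all 2ⁿ sign assignments; ranks are doubled so that
midranks (ties) stay integral, which keeps the enumeration exact in the
presence of ties (the tied null is data-dependent and recomputed per
input). Zero differences are discarded before ranking (classical
treatment; Pratt's variant — rank zeros, then drop their ranks from the
statistic — is available). The two-sided P doubles the smaller tail,
`min(1, 2·min(P(W≤w), P(W≥w)))`, which yields the familiar floor
2·2⁻ⁿ for n untied same-sign pairs (3.05 × 10⁻⁵ at n = 16). Exact
enumeration is used up to 25 nonzero pairs (mode `auto`); beyond that a
tie-corrected normal approximation takes over. The epigenome-wide
driver vectorizes the common case — no zeros, no ties — against a
cached null distribution, and falls back to the general routine row by
row otherwise.

**Freeman–Halton r×c test.** Depth-first enumeration of all tables with
the observed margins; a table contributes when its conditional
(multivariate hypergeometric) probability does not exceed the observed
table's, with a 10⁻⁹ log-scale guard against floating-point ties.
Log-factorials keep the products stable. Intended for totals up to a
few hundred; the study-scale tables (n ≈ 32) enumerate instantly.

**Power.** For the paired design the exact power of the two-sided
paired t-test is computed from the noncentral t distribution with
df = n − 1 and noncentrality δ√n/σ_d. Deep-tail terms that underflow to
NaN in the noncentral-t CDF are treated as zero. At 16 pairs,
δ = 0.05, σ_d = 0.025 and α = 0.01 the power exceeds 0.99 — the basis
for reading a negative EWAS as informative rather than underpowered.
The Wilcoxon test's power is bounded by this parametric envelope
(asymptotic relative efficiency 3/π under normality), which the
injected-effect simulations confirm within simulation error.

## Synthetic data: what it emulates, and what not

The generator produces: a two-cell-type reference panel with a
configurable count of discriminative CpGs (a planted marker carries the
near-binary values 0.82/0.05; other discriminative separations are
drawn in [separation, 0.75] so the planted marker is deterministically
the top screen hit; non-discriminative reference differences are
uniform in [0, 0.05], below the MVP effect threshold); paired cohorts
with within-pair composition correlation (`pair_corr`), an optional
systematic extra buccal fraction in the heavy member (`heavy_offset`,
the confounding scenario — in the motivating data the deviating samples
were predominantly heavy co-twins); injected heavy−light β effects;
dilution series; read-level bisulfite data (per-read Bernoulli calls,
conversion failures that read as spurious methylation, binomial
per-read conversion estimates, optional amplicon-SNP allele calls); and
SIRPH peak areas with Gaussian area noise. SNP-probe-like loci
(genotype levels {0, ½, 1} shared within a pair) provide an array-side
technical-noise floor. Defaults: proportions uniform on [0.1, 0.9],
β noise σ = 0.02, conversion rate 0.995, coverage 1000 reads.

Real data differ in ways the generator deliberately ignores: probe
chemistry heterogeneity (Infinium I vs II), heteroscedastic β noise
(variance shrinks near 0 and 1), cross-hybridizing and polymorphic
probes, batch effects, more than two cell types, and PCR amplification
bias in read data. Passing tests therefore demonstrate correctness of
the *procedures* under the stated mixture model, not robustness to
every array artifact. The within-pair correlation of buccal
proportions in real saliva is unknown; `pair_corr` is a free parameter
(default 0.5 in the pipeline), not an estimate.

## Problem sizes

Simulation-backed checks run at 2,000 CpGs × 16 pairs (100 replicates
for the confounded-null MVP contrast, 25 in the acceptance script),
101-point dilution series, 50,000 Monte-Carlo experiments for the power
cross-check, and coverage 200–5,000 for read-level checks. These sizes
put Monte-Carlo standard errors well below the decision margins of each
check while keeping the full suite around ten seconds.

## Known limitations

* The exact Wilcoxon enumerator is O(n · Σr) per distinct tie pattern;
  above 25 nonzero pairs it switches to the normal approximation
  (without continuity correction, which is conservative only in part).
* The Freeman–Halton DFS enumerates exhaustively; it is not a network
  algorithm and will not scale to large-margin tables.
* Proportion estimation inverts a single marker; it inherits that
  marker's technical noise scaled by 1/separation (≈ 1.3× at the
  planted marker) and truncates at the [0,1] boundary, which biases
  estimates slightly inward at the extremes.
* Composition adjustment assumes the mixture acts linearly on β; where
  clipping at the β boundaries violates linearity the correction is
  approximate, and truncation re-introduces a small marker correlation
  at a few CpGs (reported, see above).
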