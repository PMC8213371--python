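# Methods

## Measurement model

A qPCR reaction with per-cycle amplification efficiency `E ∈ (1, 2.2]`
starting from template quantity `q` crosses the fluorescence threshold
`F_t` at

    Cq = (ln F_t − ln q) / ln E + ε,   ε ~ N(0, σ_Cq) per technical replicate.

The synthetic generator parameterizes the threshold as `F_t = 2^c0`
(default `c0 = 28`), so a perfect doubling assay reads `Cq = c0 − log2 q`.
Writing the model with a *common fluorescence threshold* rather than a
common intercept is deliberate: it makes the efficiency-corrected quantity
`E^(−Cq) = q / F_t` proportional to template with the same constant for
every assay, so ratios of efficiency-corrected abundances (dosage ratios,
allelic fractions) are identified even when the two assays of an allele
pair have different measured efficiencies. Reactions run for 40 cycles; a
Cq at the cap is treated as a non-detection and becomes missing data, not
zero expression.

Relative abundance normalizes a target against the geometric mean of two
reference genes,

    RA = E_t^(−Cq_t) / geomean_r( E_r^(−Cq_r) ),

the standard multi-reference scheme; it keeps RA multiplicative, makes it
invariant to adding a common shift to all Cqs of a sample (equal
efficiencies), and reduces to `2^(−ΔΔCq)` at `E = 2`. Technical replicates
are averaged on the Cq scale (arithmetic mean of cycles = geometric mean
of quantities); a replicate spread above 0.5 cycles raises a QC flag but
does not drop the measurement.

Standard curves regress Cq on log10 relative input over a 1:5–1:100
dilution series; `E = 10^(−1/slope)`. Allele-specific assays with
`E < 1.9` fail QC, mirroring the acceptance threshold used when such
assays are designed; panel genes without allele-specific measurements
assume `E = 2`.

## Dosage and allelic-imbalance inference

The breakpoint gene's per-bird ratio `RA_across / RA_outside` estimates the
ancestral-allele share `a` of its transcription (with optional
read-through `ρ` of the inverted allele past the breakpoint, the noise-free
ratio is `a + ρ(1 − a)`; `ρ = 0` by default). Ratios are computed per
sample and then averaged — matching the per-bird one-sample *t*-test
design against the all-ancestral expectation of 1 — rather than as a ratio
of group means. Groups whose ratios are all exactly 1 report `t = 0, p = 1`
instead of a zero-variance error, since such data carry no evidence
against the null.

The allelic-imbalance fraction `100·RA_inv/(RA_inv + RA_anc)` consumes
efficiency-corrected abundances so primer-efficiency differences between
the allele-specific assays do not masquerade as imbalance. Departure from
50% is tested per gene × tissue over heterozygous individuals (Satellites
and Faeders pooled by default; separable by config) and Bonferroni-Dunn
adjusted (`min(1, p·m)`). By default `m` counts testable cells (≥2
heterozygotes, non-degenerate); fixing `m` to the full grid size is a
config option, since the two conventions coincide only when every cell is
testable.

## Statistical kernels

*Mann-Whitney U.* The exact null pmf of U is enumerated by dynamic
programming over rank-arrangement counts (the Gaussian-binomial
recurrence `c(u; m, n) = c(u−n; m−1, n) + c(u; m, n−1)`), used whenever
`n1·n2 ≤ 400` and the data are tie-free; otherwise the tie-corrected
normal approximation with continuity correction applies. The two-sided p
doubles the lower tail of `U = min(U1, U2)` and caps at 1 — because the
null pmf is symmetric this equals summing both tails, and it reproduces
the reference small-sample values (U = 0 at 7 vs 4 → 0.006; U = 4 at 8
vs 4 → 0.048; U = 5 → 0.07).

*Benjamini-Hochberg.* The step-up adjustment is computed directly (sort,
`p_(i)·m/i`, enforce monotonicity from the top, cap at 1) and is applied
at q = 0.10 as the screening level for the correlation family. The family
pools all morphs' pairs (360 for a 16-variable panel) by default;
per-morph adjustment is available.

*t, ANOVA, Tukey.* Student-t tail probabilities, the one-way F test and
Tukey HSD delegate to scipy's distributions (`t.sf`, `f_oneway`,
`tukey_hsd`); the kernels add the domain validation and degenerate-input
contracts the pipeline relies on.

## Discriminant analysis

LDA is solved as the symmetric-definite generalized eigenproblem
`S_b w = λ S_w w` with `S_w` the pooled within-class covariance
(`Σ_c SS_c / (N − k)`) and `S_b` the priors-weighted between-class
covariance; priors default to class proportions, with an equal-priors
option. Each discriminant's eigenvalue share is its proportion of trace.
Numerical choices: discriminants are scaled to unit pooled within-class
variance; signs are fixed so the largest-magnitude coefficient is
positive (reproducible traces); a (near-)singular `S_w` — detected by an
eigenvalue ratio below 1e-10 — triggers a logged ridge of
`1e-8 · tr(S_w)/p` rather than failure. Expression enters untransformed by
default with a log2 option; both choices are recorded in reports.

Cluster separation, judged visually in traditional LDA plots, is
formalized as disjointness: two morphs separate on LD1 when their
projection intervals are disjoint, and in LD1/LD2 when their convex hulls
(shapely) are disjoint; hulls sharing even a boundary point count as
overlapping. Sequential removal refits after dropping, per step, the most
positive and most negative LD1 loadings (`heaviest`) or the
smallest-magnitude positive and negative loadings (`lightest`), two per
step by default, stopping at a floor of three variables with a partial
last step if needed; ties break by variable name. When one sign of
loading is absent the pick falls back to overall extremes (respectively
smallest magnitudes).

## Synthetic cohorts: what they emulate, and what not

Biological variation is log-normal per gene with morph mean shifts on the
log2 scale; within-morph covariance is diagonal except for designated
correlated pairs with morph-specific target ρ (non-positive-definite
combinations are repaired by spectrum clipping, with a warning). Defaults
set within-morph SD to 0.4 log2 units and place shifts of 1.2–2.0 (three
to five within-morph SDs) on several steroidogenesis-axis genes per
heterozygote morph, so the three morphs are separable by design; the
default correlated pair (`SDR42E1`–`AROM`, ρ = 0.99 in Independents and
Satellites, 0 in Faeders) mirrors the strongest co-expression pattern such
panels report. Cohort sizes default to 13/7/5 (panel) and 8/2/2 across
three tissues (inversion-gene cohort). Testosterone is log-normal with the
ancestral morph an order of magnitude above the heterozygote morphs; GSI
is Gaussian with the Faeder mean highest. Inversion homozygotes are never
generated.

The generator reproduces the *statistical* structure the estimators
assume — dosage arithmetic, allele-specific templating, efficiency
differences, censoring, covariate contrasts — but not plate effects,
inter-run calibration drift, melt-curve artifacts, amplification
inhibitors, or biological covariance beyond the configured pairs. Passing
recovery tests therefore validates the estimators' correctness under the
declared noise model, not robustness to those unmodeled artifacts.

Determinism: each simulation draws from a single `numpy` Generator seeded
explicitly, in a fixed iteration order; identical seeds give byte-identical
tables and, through the pipeline, bit-identical reports.

## Problem sizes used in validation

Validation suites run at desk scale: exact-U brute-force cross-checks over
all designs with `n1 + n2 ≤ 10`; allelic-imbalance recovery over 500
simulated heterozygotes at σ_Cq = 0.2 (tolerance ±2 percentage points);
dosage recovery over 400 heterozygotes (mean within [0.45, 0.55]);
FDR control over 60 replicate null panels of 360 tests; LDA separation and
strong-pair recovery over 40 seeds of the default generator; the
one-sample-t type-I rate over 10,000 null replicates at n = 4.

## Known limitations

- The strong-pair Venn analysis is sensitive to the smallest cohort: at
  n = 5 a null pair reaches |r| ≥ 0.8 with probability ≈ 0.10, so
  "exclusive to two morphs" misclassifies a truly two-morph pair into the
  three-way region in about one seed in ten under the default design.
  This is a property of the design, not of the estimator.
- Exact Mann-Whitney enumeration assumes tie-free data; ties fall back to
  the normal approximation (continuous simulated data never tie).
- The dosage model identifies the ancestral-allele share only up to
  read-through; `a` and `ρ` are not separately identifiable from the two
  amplicons alone.
- LDA assumes a shared within-morph covariance; strongly heteroscedastic
  morphs would call for quadratic discriminants, which are out of scope.
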