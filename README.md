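# ruffinv

Allele-specific qPCR analysis of gene expression in a heterozygous-only
chromosomal inversion, built for studies of discrete morphs — such as the
three male morphs of the ruff (*Calidris pugnax*), where an ancestral
homozygote (Independent) coexists with two inversion-heterozygote morphs
(Satellite and Faeder) and inversion homozygotes are not viable.

The package takes tidy tables of qPCR quantification cycles (Cq) and turns
them into morph-level inference:

1. **Quantification.** Technical replicates are collapsed and expression is
   reported as efficiency-corrected relative abundance,
   `RA = E_t^(−Cq_t) / geomean_r(E_r^(−Cq_r))`, against two reference genes.
   Primer efficiencies come from standard curves, `E = 10^(−1/slope)` of Cq
   vs log10 input, with a QC cut at `E ≥ 1.9` for allele-specific assays.
2. **Breakpoint dosage.** A gene truncated by the inversion is probed by an
   amplicon *outside* the inverted region (both alleles) and one *across*
   the breakpoint (ancestral allele only). The per-bird ratio
   `RA_across / RA_outside` estimates the ancestral-allele share of
   transcription: ≈1 in ancestral homozygotes, ≈0.5 in balanced
   heterozygotes. Groups are tested against 1 with a one-sample *t*-test;
   morph differences in non-truncated transcript abundance use an exact
   Mann-Whitney *U* test (full null enumeration for small samples).
3. **Allelic imbalance.** For genes with allele-specific assays, the
   inversion-allele share `100·RA_inv/(RA_inv + RA_anc)` is tested against
   50% per gene × tissue, with Bonferroni-Dunn correction over the grid.
4. **Morph discrimination.** A from-scratch multi-class LDA (generalized
   eigenproblem of between- vs pooled within-morph scatter) with two
   step-wise gene-removal procedures (heaviest- and lightest-loading genes
   on LD1) and a formal separation criterion (disjoint LD1 intervals or
   LD1/LD2 convex hulls).
5. **Co-expression networks.** Morph-stratified Pearson correlations of the
   gene panel plus testosterone and gonadosomatic index (GSI = gonad mass ×
   100 / body mass), Benjamini-Hochberg FDR screening at q = 0.10, and
   Venn-style comparison of strongly correlated pairs (|r| ≥ 0.8).

A seeded synthetic-cohort generator (`ruffinv.synthetic_data`) emulates the
full study design — breakpoint dosage structure, tunable allelic-imbalance
fractions, morph mean shifts, designated correlated pairs, hormone and GSI
covariates — with ground-truth tables, so every estimator is validated by
parameter recovery.

## Worked example

```python
from ruffinv import (GenerativeConfig, simulate_qpcr_cohort,
                     collapse_replicates, relative_abundance_table,
                     dosage_table, test_dosage_group)

gen = GenerativeConfig()                       # 8/2/2 birds, 3 tissues
records, truth = simulate_qpcr_cohort(gen, seed=1)
ra = relative_abundance_table(collapse_replicates(records),
                              gen.amplicon_specs(), ["GAPDH", "RPL30"])
dosage = dosage_table(ra, "CENPN")
gonad = dosage[dosage["tissue"] == "gonad"]
het = gonad[gonad["morph"] != "Independent"]["ratio"]
res = test_dosage_group(het)
print(f"mean het ratio {het.mean():.3f}, t_{int(res.df)} = {res.statistic:.2f}, "
      f"p = {res.p_two_sided:.4f}")
```

prints

```
mean het ratio 0.449, t_3 = -13.22, p = 0.0009
```

i.e. the four heterozygous birds express the across-breakpoint fragment at
roughly half the outside fragment, and the one-sample *t*-test rejects the
"all transcripts are full-length ancestral" expectation of 1 — while the
same test on Independents does not (mean 1.017, p = 0.74).

The same analysis runs from the shell:

```sh
ruffinv all --seed 1 --outdir results/run1
```

writing `relative_abundance.csv`, `dosage.csv`/`dosage_tests.json`,
`allelic_imbalance.csv`/`ai_grid.json`, `foldchange.csv`,
`lda_model.json`/`lda_projections.csv`, both `removal_*.json` traces,
`correlations.csv`, `venn.json` and a `run_log.json` echoing the seed and
configuration. Reruns with the same seed reproduce every file bit for bit.

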