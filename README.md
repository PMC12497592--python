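# mitocohort

Case-control analysis of human mitochondrial genome variation, built for
studies that sequence whole mitogenomes in a disease cohort and matched
controls and ask three questions: *which variants are heteroplasmic and
how much*, *which variants are plausibly pathogenic*, and *which maternal
lineages (haplogroups) or individual SNPs are associated with the
disease*.

The package ingests multi-sample VCFs with per-allele read depths and
provides, as composable library modules plus a thin CLI:

- **Heteroplasmy quantification** — the heteroplasmy fraction of a call is
  HF = alt reads / total reads; calls with HF < 1% are excluded as likely
  artefacts, 1% ≤ HF < 98% is heteroplasmic, HF ≥ 98% homoplasmic.
- **Functional annotation** — region assignment on the 16,569 bp circular
  rCRS coordinate system (37 genes + control region, wrap-aware),
  transition/transversion/indel classes, and synonymous /
  nonsynonymous / frameshift / stop-gain calls under the vertebrate
  mitochondrial genetic code (light-strand genes reverse-complemented
  before translation).
- **Pathogenicity prioritization cascade** — control-population frequency
  filter (< 1% carrier frequency), conservation-index filter (CI > 75%
  across a user-supplied multi-species alignment), then MitoTIP raw-score
  quartile classes for tRNA variants or a ≥ 7-of-13 consensus vote over
  missense predictors for protein variants, with a full per-variant audit
  trail.
- **Haplogroup assignment** — a deterministic Kulczynski-style match score
  against a phylotree of defining variants,
  score(h) = ½ (|S∩D_h|/|D_h| + |S∩D_h|/|S_inf|),
  with depth-then-lexicographic tie-breaks and a hotspot mask.
- **Association statistics** — carrier-vs-others odds ratios
  OR = ad/bc with Woolf 95% CIs exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)) and
  Haldane 0.5 correction for zero cells; Fisher exact, chi-square and
  IRLS logistic (Wald) p-values side by side; SNP association with a
  dual-cohort 5% MAF floor and Benjamini–Hochberg adjustment; per-region
  variant-burden Mann-Whitney comparisons; indel-enrichment contrasts.
- **Population structure** — covariance PCA on haplogroup-frequency
  profiles across populations with variance-explained reporting and
  PC-space nearest-population ranking.
- **Synthetic cohorts** — a seeded generator producing two-group cohorts
  with haplogroup-structured homoplasmic variants, heteroplasmic private
  variants and binomial read sampling, so the whole pipeline is testable
  end-to-end without access to subject data.

## Worked example

Simulate a cohort of 146 cases and 120 controls (the default design draws
haplogroups from the case/control frequencies of the published study this
scale mirrors, which encode a protective D4 odds ratio of ≈ 0.45), then
run the full haplogroup association:

```python
from mitocohort import simulate, calls, haplotyping, association

design = simulate.CohortDesign(seed=7)          # 146 cases / 120 controls
cohort = simulate.simulate_cohort(design)
simulate.write_vcf(cohort, "cohort.vcf")

sample_calls = calls.read_vcf("cohort.vcf")
groups = {s.sample_id: s.group for s in cohort}

tree = haplotyping.Phylotree.default()
by_sample = {}
for c in sample_calls:
    if c.state != "excluded":
        by_sample.setdefault(c.sample_id, []).append(c.variant)
assignments = [haplotyping.assign_haplogroup(v, tree, sample_id=s)
               for s, v in sorted(by_sample.items())]
pooled = haplotyping.pool_haplogroups(assignments, groups=groups)
report = association.haplogroup_association(pooled)
print(report[["cases", "controls", "OR", "ci_low", "ci_high", "p_fisher"]].round(3))
```

```
            cases  controls     OR  ci_low  ci_high  p_fisher
haplogroup
A              16         5  2.831   1.006    7.969     0.065
B              28        11  2.351   1.117    4.950     0.024
D4             16        27  0.424   0.216    0.831     0.012
D5              5         1  4.220   0.486   36.622     0.227
F              32        22  1.250   0.682    2.293     0.541
G              11         7  1.315   0.494    3.505     0.632
M7             13         9  1.206   0.497    2.925     0.824
R              10        15  0.515   0.222    1.192     0.141
Z               4         8  0.394   0.116    1.343     0.146
Others         11        15  0.570   0.252    1.293     0.214
```

Each row contrasts carriers of one macro-haplogroup against all other
samples: D4 is recovered as protective (OR 0.424, 95% CI 0.216–0.831,
Fisher p 0.012 in this replicate), matching the frequency structure the
simulation was built with; the other lineages scatter around the null.

The same pipeline is available from the shell:

```sh
mitocohort simulate --seed 7 --out-prefix cohort
mitocohort assoc cohort.vcf cohort.groups.tsv
mitocohort burden cohort.vcf cohort.groups.tsv --heteroplasmic-only
mitocohort indel-test cohort.vcf cohort.groups.tsv
```

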