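# Methods

This note documents the models and procedures implemented in `mitocohort`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical conventions adopted where a design
was genuinely open.

## Coordinate system and annotation

All positions are 1-based on the circular 16,569 bp human mitochondrial
reference (rCRS numbering).  The packaged gene map
(`data/rcrs_genes.tsv`) carries the published coordinates of the 13
protein-coding genes, 22 tRNAs, 2 rRNAs and the control region; the
control region wraps the origin (16024–576) and is stored with an
explicit wrap flag.  Several ORFs (ND1, ND2, COX3, ND3, ND4, CYTB) end in
an incomplete stop codon completed by mRNA polyadenylation; they carry an
`incomplete_stop` flag and variants falling in the trailing partial codon
are reported without amino-acid calls.

Overlapping genes (ATP8/ATP6, ND4L/ND4, several tRNA pairs) are resolved
by attributing the position to the first feature in map order; the
alternatives are logged.  This is a documented convention — annotation
databases differ here and no choice is canonical.

Effect prediction rebuilds the affected codon in the gene's reading
frame, reverse-complementing light-strand genes (ND6 and eight tRNAs)
before translation with the vertebrate mitochondrial code (NCBI table 2:
ATA = Met, TGA = Trp, AGA/AGG = stop).  Indels with net length change not
divisible by three are frameshifts; in-frame indels are reported as
nonsynonymous with amino acids unset.

The package does not ship the rCRS base sequence.  Analyses needing base
identities accept any FASTA; for simulation and testing a deterministic
*synthetic* 16,569 bp sequence (`reference.synthetic_rcrs`) is used.  Its
composition loosely mimics mtDNA but the bases carry no biological
meaning, and the packaged phylotree's alleles are derived from it for
internal consistency.

## Heteroplasmy

The heteroplasmy fraction of a call is HF = alternate reads / total reads
at the site.  Thresholds: HF < 1% excluded (sequencing noise), 1% ≤ HF
< 98% heteroplasmic, HF ≥ 98% homoplasmic.  The boundary conventions
(0.01 heteroplasmic, 0.98 homoplasmic) follow the stricter of the two
inequality readings in circulation and are pinned by tests.  Cohort-level
variant summaries label a variant `both` when it has at least one
heteroplasmic and one homoplasmic carrier after exclusion.  The number of
variants dropped entirely by the exclusion rule is logged so the
difference between "variants observed" and "variants analyzed" stays
auditable.

Control-population frequency is the *carrier* frequency among control
individuals (mtDNA treated as effectively haploid per individual), not an
allele-count frequency.

## Conservation index

CI of a site is the proportion of non-reference species in a
multi-species alignment whose symbol equals the human (reference)
wild-type symbol — nucleotide level for RNA/non-coding variants,
amino-acid level (per-gene protein alignments) for missense variants.
The reference row is excluded from numerator and denominator; a switch
(`include_reference=True`) is provided because published descriptions are
ambiguous about a 43- vs 44-species denominator.  Gaps and ambiguity
codes count as mismatches (conservative: never inflates CI).  Sites that
cannot be mapped through the reference row (reference gap, missing gene
alignment) are flagged `no_ci` and never silently passed.  The
prioritization filter requires CI strictly greater than 0.75.

## Prioritization cascade

Stages, in order, each recorded in a per-variant audit trail:

1. **Region gate** — only tRNA variants and nonsynonymous protein
   variants can be prioritized; synonymous, rRNA, and non-coding variants
   stop at stage `region`.  (Stop-gains are deliberately excluded from the
   consensus path: missense predictors do not score them.)
2. **Frequency filter** — control carrier frequency must be < 1%;
   variants at or above are polymorphisms.
3. **Conservation filter** — CI > 75%, with `no_ci` as a distinct
   terminal stage.
4. **Classifier** — tRNA: MitoTIP raw-score quartiles, > 16.25 Likely
   Pathogenic, [12.66, 16.25] Possibly Pathogenic, [8.44, 12.66) Possibly
   Benign, < 8.44 Likely Benign; LP and PP count as deleterious.
   Boundary scores go to the higher class because only the LP bound is
   printed strictly in the source quartile table.  Protein: more than six
   of the 13 registered predictors must call the variant deleterious;
   missing predictions count as non-deleterious votes against the fixed
   13-tool denominator (conservative).

The 13-tool registry (`data/predictor_tools.yaml`) converts scores to
verdicts via per-tool thresholds and directions.  The shipped thresholds
are package defaults on each tool's published scale, documented as
synthetic stand-ins — users with calibrated cut-offs should supply their
own registry.  The cascade never executes external predictors; scores are
inputs.

Monotonicity properties are enforced by tests: adding a deleterious vote
can never demote a variant, and raising control frequency can never
promote one.

## Haplogroup assignment

The packaged phylotree (`data/phylotree_synthetic.tsv`) is a synthetic
stand-in with a realistic macro-topology (M and N clades; D4, D5, A, B,
F, G, M7, R, Z and sub-lineages) whose defining alleles come from the
synthetic reference.  Production use should supply a real phylotree in
the same three-column TSV format.

A sample's variant set S (after masking hotspot positions 302, 309, 315,
523, 524, 16182, 16183, 16189, 16519 — length-polymorphic runs and a
near-ubiquitous control-region site) is scored against every node h with
defining closure D_h (union of defining variants along the root path):

    score(h) = ½ ( |S∩D_h| / |D_h| + |S∩D_h| / |S_inf| )

where S_inf is the subset of S appearing anywhere in the tree, so private
variants never dilute the score.  The first term penalizes missing
defining variants, the second penalizes informative variants unexplained
by the node.  Ties break to the deeper node, then the lexicographically
smaller label.  This deterministic symmetric-match scorer replaces
weighted-rank classifiers deliberately: the package's focus is the
downstream association, and the scorer is validated by simulation
recovery (100% on noise-free cohorts; ≥ 95% under the default noise
model) rather than by rank-weight fidelity.  Back-mutations and recurrent
variants are treated as plain set membership.

Macro-haplogroup pooling truncates labels to the longest matching major
prefix (D4a → D4, F1 → F) and pools everything else, including
`unclassified`, into `Others`.  The default major list (A, B, D4, D5, F,
G, M7, R, Z) matches the nine lineages reported in the study design this
package mirrors; it is a plain argument.

## Case-control statistics

* **Odds ratio**: OR = ad/bc on the 2×2 carrier-vs-others table, Woolf CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)).  Any zero cell triggers the
  Haldane correction (0.5 added to every cell) for OR/CI/Wald; exact and
  chi-square p-values always use the raw counts.
* **Fisher exact**: two-sided by the point-probability method (sum of
  hypergeometric probabilities ≤ the observed table's), via
  `scipy.stats.fisher_exact` and cross-checked against a `math.comb`
  enumeration oracle for every table with n ≤ 30.  Notably, the published
  haplogroup table that fixes this package's scale prints p-values that
  equal this two-sided Fisher p to all nine printed decimals, so the
  test suite pins that correspondence.
* **Chi-square**: Pearson, no Yates correction by default (a flag
  enables it); zero-margin tables return a flagged invalid result.
* **Logistic regression**: own IRLS implementation (intercept + slope,
  gradient-norm tolerance 1e-10, ≤ 100 iterations), cross-checked against
  `statsmodels` in tests.  For a binary covariate the MLE odds ratio
  equals the contingency cross-product ratio, which the suite verifies to
  1e-6 on 1000 random non-separated tables.  Separation (a zero cell)
  falls back to the Haldane-corrected contingency OR with a warning.
* **SNP association**: a SNP is dropped only when its minor allele
  frequency is below 5% in *both* cohorts; retained SNPs are tested by
  logistic regression, and raw plus Benjamini–Hochberg-adjusted p-values
  are reported side by side.  Output is never gated on the adjusted
  values.
* **Mann-Whitney U**: exact enumeration when the combined sample size is
  ≤ 20 and tie-free, else normal approximation with tie and continuity
  corrections; fully tied data returns U = n_x·n_y/2, p = 1.  The suite
  checks exact agreement with rank enumeration for n = 3..8 per group and
  type-I-error calibration (0.05 ± 0.01 over 2000 null replicates at
  cohort scale).
* **Burden comparisons**: per-sample variant counts by region plus
  `total` and `coding` aggregates, optionally restricted to heteroplasmic
  calls; group means/SDs and a Mann-Whitney p per region.
* **Indel enrichment**: 2×2 heteroplasmic-only/homoplasmic-only ×
  indel/SNV table (variants in `both` states inform only the region
  table, since they have no single state), tested by chi-square and
  Fisher; plus a region-category × indel/SNV table tested by chi-square.
  Both tables are returned alongside p-values for auditability.

## Population PCA

Covariance PCA on raw haplogroup-frequency rows (populations ×
haplogroups), centered by column; variance-explained entries are
eigenvalue fractions of total variance.  A correlation mode is exposed
because the normalization used by common desktop PCA tools is often
unstated.  Sign convention: each loading vector's largest-magnitude entry
is positive.  Rows that do not sum to 1 within 1e-6 are renormalized with
a log entry; an all-identical-rows matrix is returned flagged degenerate.
Nearest-population queries rank by Euclidean distance in PC space with
lexicographic tie-breaks.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, at
the scale of the motivating study (146 cases / 120 controls):

* haplogroups drawn per group from the published macro-haplogroup
  frequencies (defaults encode a protective D4 odds ratio of ≈ 0.447,
  with the `Others` mass placed on the N9a stand-in lineage);
* the drawn haplogroup's defining closure emitted homoplasmic (true
  HF = 1);
* private variants ~ Poisson(5) per individual at uniform random
  non-defining positions, each heteroplasmic with probability 0.5, with
  heteroplasmic fractions ~ Uniform(0.01, 0.98) — spanning the full
  observable band so both classification boundaries are exercised;
* read support: depth ~ 1 + Poisson(mean − 1) with default mean 500
  (typical of mtDNA capture panels), alternate reads ~ Binomial(depth,
  f′) with f′ = f(1−e) + (1−f)e and symmetric per-read miscall rate
  e = 0.001 — the mechanism that makes the 1% exclusion floor meaningful.

One integer seed drives all draws through a single NumPy generator;
cohorts and their VCF serializations are byte-reproducible.  The private
variant rate and depth are realism choices, not fits: private rate 5 per
individual approximates the rare/private component of per-individual
variant loads reported in mitogenome cohort studies, while shared
population polymorphism beyond haplogroup-defining sites is *not*
modeled.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: nuMT contamination, strand bias, alignment
artefacts around homopolymer runs, position-dependent error rates,
recurrent/back mutations, within-lineage sub-structure below the packaged
tree's resolution, and linkage between private variants.  Simulation
results validate the estimators' self-consistency under the stated model,
not the upstream sequencing pipeline.

## Problem sizes used in checks

The replicate counts and depths used by the test suite and the acceptance
script (500 and 200 cohort replicates for odds-ratio recovery, 2000 calls
per depth for RMSE curves, 2000 null replicates for test calibration) are
chosen so that Monte-Carlo standard errors are several times smaller than
the tolerances being checked, which the corresponding moment formulas
confirm.

## Known limitations

* The haplogroup scorer ignores heteroplasmy level and back-mutations; on
  real trees with recurrent sites its accuracy depends on the hotspot
  mask being adequate.
* The packaged phylotree, reference sequence, alignment fixture and
  predictor thresholds are synthetic stand-ins intended for testing and
  simulation; substantive analyses must supply real resources through the
  documented TSV/FASTA/YAML interfaces.
* The cascade treats predictor scores as exchangeable votes; no
  tool-specific calibration or weighting is attempted.
* Only single-covariate (unadjusted) logistic models are provided, by
  design; covariate-adjusted modeling is out of scope.
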