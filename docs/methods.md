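# Methods

## The breeding design and what is being modeled

The package models a three-generation ENU screen.  A G1 male is heterozygous
for a panel of induced point mutations ("alleles"), each placed at a
continuous centimorgan position on a 19-autosome genetic map.  His G2
daughters each inherit one of his gametes (so they are REF or HET at every
allele), and the G2 × G1 backcross produces the screened G3 cohort.  For any
single allele, the probability that a G3 mouse is homozygous is 1/8: 1/2
that its dam carries the allele times 1/4 for the HOM outcome of a HET × HET
cross.  Phenotypes are binary; a pedigree may carry one causal allele whose
genotype-dependent penetrance (f_REF, f_HET, f_HOM) determines scoring,
with a background rate modeling false radiographic calls applied as
`max(background, penetrance)`.

## Meiosis model

Crossovers per chromosome are Poisson with mean `length_cM / 100`, positions
uniform, starting strand a fair coin, and no interference.  This is the
unique model under which the simulated recombination fraction between loci
`d` cM apart equals the Haldane map function r = ½(1 − e^(−2d/100)) exactly,
so the simulator and the closed form can be tested against each other.
Kosambi-style interference, sex-specific maps and physical (bp) coordinates
are deliberately out of scope.  The packaged autosome lengths
(`data/mouse_autosomes_cM.tsv`, 19 autosomes totalling ~1440 cM) are a
modeling default with plausible mouse-map magnitudes, not measured data; any
map can be substituted via a two-column TSV.

Numerical detail: the Haldane function saturates to exactly 0.5 in double
precision near d ≈ 1850 cM; the implementation clamps its return value to
the largest double below 0.5 to preserve the strict r < 0.5 contract.

## The mapping test

For each allele and each inheritance model (recessive (0,0,1), dominant
(0,1,1), additive (0,1,2) over (REF, HET, HOM)), the scored G3 phenotype is
regressed on the encoded genotype by maximum-likelihood logistic regression
and a two-sided Wald p-value is computed from the genotype coefficient
(z² against χ²₁).  MISSING genotypes drop the mouse from that allele's test;
unscored and dead mice are excluded from the cohort entirely.  An allele is
significant when p ≤ α / n_alleles under any fitted model.

* **Bonferroni denominator.**  The family is the set of alleles tested in
  the pedigree, not alleles × models; a `per_model_bonferroni` switch
  enables the stricter denominator.  The additive model is available but
  excluded from default significance calling, since the screen design's
  natural hypotheses are recessive and dominant.
* **Estimation.**  The one-predictor model is fit by Newton–Raphson (IRLS)
  on the counts aggregated by genotype level — the sufficient statistics —
  with step-halving, convergence at a step of 1e-10, and a cap of 50
  iterations.  This is exact and fast (at most three aggregated rows).
* **Separation.**  A fully penetrant causal allele separates the phenotype
  perfectly and the MLE diverges.  Divergence is detected by
  non-convergence, a coefficient escaping |β| > 15, or a singular
  information matrix; the model is then refit with Firth's penalized
  likelihood (Jeffreys-prior penalty ½·log det I(β), modified score with
  hat-value correction, step-halving, tolerance 1e-9) and the test flagged
  `Firth`.  Standard errors come from the inverse information at the
  optimum in both cases.  Firth–Wald p-values are conservative for small
  homozygote counts; pedigrees with ~5 affected homozygotes routinely land
  just above a 60-allele Bonferroni threshold, which is why mapped pedigrees
  are enriched for high affected-mouse counts.
* **Degenerate tests.**  A constant phenotype or constant predictor makes
  the test meaningless; it is recorded with p = 1 and method `degenerate`.
* **Reporting.**  p-values are floored at 1e-300 so −log10(p) stays finite
  in the Manhattan table, which orders alleles by chromosome then position.

## Screen analytics

A pedigree is *affected* when ≥ 2 scored G3 mice are affected, and *mapped*
when its mapping result contains a significant allele.  The minimal-p
significant test labels the mapped locus and attributes the pedigree's
inheritance mode; co-segregating passengers remain visible in the full test
table.  Penetrance is affected/scored within a genotype class, reported with
its counts.  Reported percentages are rounded half-up — one decimal for
screen-level percentages, zero decimals for penetrance percentages — with
raw fractions retained.

The Wilcoxon rank-sum comparison (affected-mouse counts, mapped vs unmapped
pedigrees) uses mid-ranks.  Up to a combined n of 25 the two-sided p is
exact: mid-ranks are multiples of ½, so doubling them makes the permutation
distribution of the rank sum countable by an integer dynamic program even
with ties.  Above that, a normal approximation with tie-corrected variance
and continuity correction is used.

Saturation counting tallies genes with at least one damaging-class allele
(probably_damaging, possibly_damaging or putative_null; configurable)
examined at least twice in the homozygous state among scored G3 mice, as a
fraction of a supplied autosomal gene universe.  The package computes only
this counting rule on its own simulated tables; it does not attempt the
lethality-calibrated saturation estimate of a real screen, which requires
real exome data and a curated essential-gene collection.

Power curves simulate pedigrees with a planted recessive allele over a
(penetrance × cohort size) grid; success means a significant allele within a
window (default 5 cM) of the causal locus.  Genotype and phenotype
randomness use separate substreams keyed by (cohort-size index, replicate),
and phenotype assignment consumes one uniform per mouse in cohort order, so
power is exactly monotone-coupled in penetrance at a fixed cohort size.

## Synthetic-data defaults and what they do (and do not) emulate

| parameter | default | rationale |
|---|---|---|
| alleles per pedigree | 60 | order of magnitude of an exome-detected ENU panel per G1 sire; the Bonferroni family size |
| effect-class weights | 0.25 / 0.15 / 0.40 / 0.05 / 0.15 | mostly missense with a minority of putative nulls and synonymous passengers |
| G2 dams × litter | 6 × 6–8 | ≈ 42 G3 mice per pedigree, the scale of a 54,497-mouse, 1275-pedigree screen |
| causal fraction | 0.10 | puts screen-level affected/mapped rates in the observed regime (~7–12% affected) |
| dominant fraction | 0.05 | mapped screens are dominated by recessive alleles (≈ 19:1) |
| penetrance | Uniform(0.3, 1.0) | spans low-penetrance hypomorphs to fully penetrant nulls |
| background rate | 0.005 | rare false-positive radiographic calls |
| HOM lethality | 0 | off by default; enables viable-vs-lethal contrasts |
| α | 0.05 | conventional family-wise level |

The generator reproduces the statistical structure of a screen — linkage,
Mendelian transmission through the G2 bottleneck, penetrance, scoring noise,
per-pedigree multiplicity — not its biology.  It does not model ENU
dose–response, germline mosaicism, exome-capture false negatives, genotype
missingness (supported in the data model but absent by default), sexually
dimorphic penetrance (a config option, off by default), or radiographic
images.  Passing tests therefore demonstrate properties of the *method*
under controlled conditions, not claims about any real screen's data;
simulated cM positions have no correspondence to real mouse coordinates.

## Reproducibility and problem sizes

All randomness flows from `numpy` generators threaded explicitly through
every stochastic operation; there is no global state.  Screens derive one
substream per pedigree via `SeedSequence(seed, spawn_key=(k,))`, so pedigree
k is bit-reproducible regardless of how many pedigrees are requested.  CLI
outputs are deterministic functions of (config, seed), and each invocation
appends a JSON run-log record (timestamp, config digest, seed, versions,
stage counts).

The test suite and the acceptance script use desk-scale problem sizes chosen
to make their statistical checks sharp while keeping runs quick: 10,000+
pooled G3 genotypes for the Mendelian chi-square, 20,000 gametes per
recombination-fraction check, 500 null pedigrees for family-wise error
control, 200 conditioned replicates for planted-allele recovery, and
brute-force oracle comparisons on cohorts of at most 12 mice.

## Known limitations

* Firth–Wald p-values are conservative under separation; a profile-penalized-
  likelihood test would be more powerful but is not what the Wald-test
  contract specifies.
* Mice round-trip through the TSV tables without an explicit alive flag;
  lethality-culled animals reappear as `unscored`, which leaves every scored
  cohort and mapping result unchanged.
* The exact Wilcoxon enumeration counts subsets, so its two-sided p is the
  probability of a rank sum at least as extreme in absolute deviation from
  the mean — with heavy ties other two-sided conventions can differ.
* The mapping test fits each allele marginally; kinship or mixed-model
  corrections and quantitative traits are out of scope.
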