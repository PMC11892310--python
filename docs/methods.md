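# Methods

## The mining model

`cottonmine` treats candidate-gene discovery as an intersection of evidence
streams rather than a single statistical test. Each stream has a simple,
auditable operational definition:

* **Consequential DNA variation.** A gene carries a mined allele when some
  variant annotated to it survives the chain QUAL > 500 (strict), impact ∈
  {HIGH, MODERATE} (any annotation on the record suffices, matching
  line-level `grep -E 'HIGH|MODERATE'` semantics), and ≥ 1 line called
  homozygous-ALT (`1/1`). The hom-ALT requirement reflects inbred germplasm:
  a real fixed allele, not a possibly artifactual heterozygous call. Records
  with missing QUAL are excluded and logged. Multi-allelic calls count as
  hom-ALT when both allele indices are equal and non-reference.
* **Bimodal expression.** For each gene, samples are sorted and the lowest
  and highest floor(n/10) values (minimum 1; missing dropped first)
  averaged into p10 and p90. The default dispersion statistic is
  pcSD = 100·(p90 − p10)/(p90 + p10) — the percent population SD of the two
  decile means about their mean. It is scale-free, bounded in [0, 100], hits
  100 exactly when p10 = 0 < p90, and is defined as 0 when p90 = p10 = 0.
  A cross-sample coefficient of variation (100·SD/mean, population SD) is
  selectable via `method="cv"` for sensitivity analysis. Gates are strict:
  pcSD > 45 and p90 > 3 RPKM; the p90 gate doubles as the "fiber expressed"
  criterion. The 45% threshold is an empirical operating point that captures
  roughly the top few percent of dispersed genes in a 550-RIL population;
  it is a screen, not a formal bimodality test (no dip test or mixture fit
  is attempted, by design).
* **Region phylogeny.** Pairwise distance is 1 − mean IBS allele sharing:
  identical homozygotes share 1.0, a het shares 0.5 with any homozygote,
  opposite homozygotes share 0. Het-vs-het sharing defaults to 1.0
  (identical unordered allele multisets) and is configurable to 0.5 for
  strict ordered-sharing emulation. Loci missing in either line are dropped
  from that pair; a pair with zero comparable loci is an error naming the
  pair. UPGMA merges the closest pair, with inter-cluster distances the
  size-weighted average and node height = merge distance / 2; ties are
  broken by the lexicographically smallest pair of cluster labels (a
  cluster is labelled by its smallest member), so output is invariant to
  taxon order. Newick output quotes labels containing metacharacters.
  UPGMA trees are rooted by construction; an outgroup taxon is included as
  an extra row to orient interpretation, not to re-root.
* **Two-locus epistasis.** Only the four homozygous classes enter the 2×2
  analysis; heterozygous and missing lines are excluded and tallied, since
  residual heterozygosity in RILs is rare and of ambiguous provenance.
  The ANOVA uses Type II sums of squares (statsmodels OLS) because class
  sizes are strongly unbalanced — the favorable ALT class can be ~10% of
  lines. Both main effects and the interaction are always reported.
  Contrasts against the highest-mean class are Welch t-tests with no
  multiplicity correction beyond reporting fixed alpha levels (0.01,
  0.001); this mirrors how such comparisons are conventionally stated and
  keeps the output interpretable as per-comparison evidence.
* **Integration.** One row per gene seen in any input; five boolean flags
  (DNA variant, fiber expressed, bimodal at 8-DPA, bimodal at 16-DPA,
  family member) plus QTL overlap (any-overlap on 1-based inclusive
  intervals, zero flank by default). Rank = descending evidence count, ties
  by descending max pcSD then gene id. The ranking is this package's
  convention — the evidence streams themselves carry no natural total
  order. The flammability screen is the family-restricted variant requiring
  bimodality at both timepoints.

## The synthetic study

The generator emulates the statistical structure of a MAGIC population
without re-enacting the breeding design: each RIL chromosome is a mosaic of
founder haplotypes with Poisson(`recomb_rate`) breakpoints and a fresh
founder per segment. `recomb_rate` is the crossover count accumulated in
the final mosaic (default 10 per chromosome, ≈1 per meiosis across the
~11 generations of intermating and single-seed descent). Residual
heterozygosity is injected per locus at rate `residual_het_rate`
(default 0.005). Founders carry ALT at 30% of haplotype-locus combinations,
giving the intermediate allele frequencies the two-locus analysis needs.

Expression is multiplicative: baseline (lognormal, median 20 RPKM,
σ_ln = 1) × `eqtl_fold`^(dosage/2) at the driver locus × lognormal noise
with unit mean and CV `noise_cv` (default 0.2). At that noise level a
non-eQTL gene's decile ratio implies pcSD ≈ 33%, safely below the 45% gate,
while a 5-fold eQTL at any driver allele frequency ≥ 1 founder puts at
least one decile on the other mode and pcSD ≈ 65% or more. The eQTL→locus
map is derived from the seed alone, so both timepoints share it, as the
both-timepoint screens assume. The phenotype is
μ + β_a·I(A=ALT/ALT) + β_d·I(D=ALT/ALT) + β_i·I(both) + N(0, σ) with
defaults μ=30, β_a=2, β_d=1, β_i=0, σ=1 on a fiber-strength-like scale;
β_i defaults to zero to make additivity the simulated truth.

The two driver loci are the loci (one per chromosome) with founder ALT
count closest to 30%, and are emitted as confirmed MODERATE-impact variants
(QUAL 999) annotated to their nearest genes, which are forced into the eQTL
set — this *defines* the dataset's designated candidate genes, mirroring a
study design in which candidates are strong-variant eQTL genes. All other
QUAL values are Uniform(0, 1000) and impacts are drawn HIGH/MODERATE/LOW/
MODIFIER at 5/20/35/40%, so the filter chain has a known, non-trivial
composition recorded in `manifest.json` (computed from the simulation
arrays, independently of the VCF serialization path).

What the generator does **not** emulate: linkage disequilibrium decay
calibrated to real cotton maps, allotetraploid homeologous cross-mapping,
count-level sampling noise (expression is emitted directly as RPKM-scale
values), year/field effects, and selection. Passing tests therefore
demonstrate that the statistics and filters behave as specified on data
with the assumed generative structure — not that the thresholds are optimal
for any particular real dataset.

## Numerical and design notes

* pcSD computes the decile ratio before multiplying by 100, so p10 = 0
  yields exactly 100 in floating point.
* Determinism: every stage draws from `default_rng([seed, stream_id])`
  with fixed stream ids; identical configs give byte-identical output
  files (floats serialized with fixed `%.6g` formatting).
* The one-way year-effect ANOVA is computed from group sums of squares
  directly (and cross-checked against an independent implementation in the
  tests); zero within-group variance returns p = 1 when group means are
  equal and p = 0 otherwise.
* Decile size floor(n/10) with a minimum of 1 keeps the statistic defined
  down to n = 10; fewer samples raise an error rather than returning a
  noisy value.
* Problem sizes in the test-suite and acceptance runs — 550 RILs, 2,000
  genes, 1,000 variant records, 1,000 simulation/oracle replicates — match
  the population scale the analysis targets while keeping a full run in
  tens of seconds.
* Haplotype counting excludes lines with missing marker calls from group
  formation and reports them separately; forming singleton haplotypes from
  incomplete vectors would inflate diversity.
* The epistasis module accepts any per-RIL phenotype vector; mixed-model
  (BLUP) normalization across environments is deliberately out of scope
  and should be done upstream if needed.

## Known limitations

* The decile screen has low power for eQTLs with minor-allele frequency
  well below 10% or fold changes under ~2.5 — both modes then fall inside
  one decile.
* With an empty 2×2 cell the interaction is inestimable; the ANOVA
  requires ≥ 2 lines in at least three classes and will not silently drop
  the term.
* IBS distance treats all loci equally; no LD pruning or weighting is
  applied within the interval.
* UPGMA assumes ultrametricity (clock-like divergence); for strongly
  rate-heterogeneous germplasm a neighbor-joining tree (out of scope) may
  order deep branches differently.
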