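# Methods

## Problem and model

A founder pathogenic variant is a disease allele whose copies in a
population descend from a single ancestral chromosome. In a case–control
design it leaves two signatures: (i) carrier enrichment among affected
index cases relative to population controls, and (ii) a conserved
haplotype flanking the locus on all carrier chromosomes, eroded only by
ancestral recombination. The pipeline tests both.

Counting is carrier-based (individuals with ≥ 1 alternate allele), not
allele-based: the hypergeometric model is explicitly about the number of
mutation *carriers* a random cohort-sized sample of the population would
contain, and carrier counting is robust to the rare homozygote. Allele
counts (het = 1, hom = 2) are tracked and reported alongside, and the
2×2 unit is a configuration switch (`EnrichmentConfig.unit`).

### Filtration cascade

Stage order (configurable; this is the default): index reduction →
allelic-fraction filter → panel → population frequency → consequence.

* **Index reduction** keeps every control and exactly one flagged index
  case per case family; a case family without an index flag is an error,
  never a silent guess. Removing relatedness *before* testing prevents
  family-shared variants from inflating carrier counts.
* **Allelic fraction.** Germline het calls cluster near 0.5; calls with
  alt-read fraction strictly below 0.3 are treated as artifacts. The
  filter blanks the offending *call* (sets it to missing) rather than
  deleting the variant, so one sample's artifact cannot destroy a variant
  genuinely carried elsewhere; a variant with no surviving alt call is
  dropped. Calls without depth information are exempt — absence of
  evidence is not evidence of an artifact. Applied uniformly to het and
  hom calls (genuine hom-alt calls sit near 1.0 and are unaffected).
* **Population frequency** keeps variants at reference (gnomAD)
  frequency ≤ 0.01 — inclusive, per the "0.01 or lower" convention — and
  variants absent from the reference (absent = rare).
* **Consequence** keeps non-synonymous and splicing variants plus any
  variant carrying a RefSeq/Ensembl/Encode/ORegAnno regulatory
  annotation.
* **Structural variants** are kept when the interval intersects any
  panel interval by ≥ 1 base (all interval arithmetic is 0-based
  half-open; VCF positions stay 1-based).

The panel, frequency and consequence filters are per-variant predicates
and hence commute; the allelic-fraction filter commutes with all of them
(it edits calls, the others read annotations). These algebraic facts are
property-tested.

### Odds-ratio model

2×2 table (x₁, n₁−x₁; x₀, n₀−x₀). If any cell is zero, 0.5 is added to
*every* cell (Haldane–Anscombe) before both the estimate and the
interval. OR is the cross-product ratio; the 95% CI is Woolf's
log-normal interval with z = 1.959964; the p-value is the two-sided
normal tail of ln(OR)/SE(ln OR). The enrichment flag requires OR >
`or_threshold` *and* the CI to exclude 1. The threshold defaults to 1.5:
the flag is an enrichment rule, so the bound must sit above 1 to have
any effect beyond the CI condition; smaller values (including the
degenerate 0.5, under which any CI-significant enrichment passes) are
accepted via configuration for compatibility experiments.

Measured under the null (true OR = 1, carrier probability 0.01,
n = 225/649, 2,000 tables): the 95% CI covers 1 in ≈ 97.7% of tables —
conservative, as expected for Wald intervals on sparse tables with the
0.5 correction.

### Hypergeometric carrier model

The control carrier frequency estimates the carrier count
K = round(q̂ N_pop) in a modeled general population of size N_pop
(default 10⁷, the order of a mid-size European country; configurable,
with `model="binomial"` giving the N → ∞ limit). The p-value is the
upper tail P(X ≥ x₁) for X ~ Hypergeometric(N_pop, K, n₁), computed via
scipy's log-space survival function; x₁ = 0 gives p = 1.

**Zero-control floor.** With q̂ = x₀/n₀ taken literally, a variant with
zero observed control carriers gets K = 0 and p = 0 — *every* singleton
case variant becomes infinitely significant, and on a 200-variant panel
several null variants (P(x₀ = 0) ≈ 0.04 each) outrank any true signal.
The estimate is therefore floored at one observed carrier:
q̂ = max(x₀, `zero_control_floor`)/n₀ with a default floor of 1.0 — the
smallest frequency the control sample could have resolved. Setting the
floor to 0 restores the raw plug-in estimator.

**Bonferroni.** Both models' p-values are multiplied by m, the number of
variants actually present in the final call set (never a constant), and
capped at 1. A founder candidate needs the OR flag plus corrected
hypergeometric p < α (default 0.05); ranking is by corrected
hypergeometric p, tie-broken by corrected OR p, then genomic key.

**Operating characteristics and a fundamental trade-off.** Under the
emulated study conditions (planted case/control carrier frequencies
0.05/0.003, null background 0.005 in both cohorts, n = 225/649, m = 200,
α = 0.05), an exact Neyman–Pearson computation over the joint carrier
distribution shows the best *achievable* power of any decision rule
whose family-wise error stays near 0.05 is ≈ 0.95. The implemented
rule recovers the planted variant top-ranked with founder = true in
≈ 95% of replicates, but its family-wise error on fully null panels is
≈ 0.2: the per-variant OR confidence interval is intentionally *not*
multiplicity-adjusted (adjusting it collapses sensitivity to ≈ 0.33,
because the Haldane-corrected SE with zero control carriers caps the
Wald z near 3). The package keeps the sensitive rule: in this design a
founder call is a screening outcome that the haplotype stage must
corroborate, not a final inference, and both rates are measured and
reported by `scripts/acceptance.py` rather than assumed.

**Binomial limit.** The hypergeometric tail converges to the
Binomial(n₁, q̂) tail as N_pop grows; at N_pop = 10⁸ with the
worked-example rate q̂ = 2/649, the relative difference is < 1e-4 across
x₁ = 1…6 — the regime where p crosses the testing threshold α/m. The
finite-population correction grows with x₁ (≈ 1.6e-4 by x₁ = 11), so
agreement is asserted where it matters for decisions, not arbitrarily
deep in the tail.

### Zygosity and phase classification

Per sample and gene: any hom-alt call → homozygous; two het calls →
compound heterozygote *confirmed* only with pedigree evidence that the
variants lie on opposite parental chromosomes (one parent carries
exactly variant A, the other — or, with a single genotyped parent, the
untyped one by attribution — carries exactly variant B); otherwise
biallelic with unknown phase. One het → single het. With ≥ 3 het
variants, the two with the lowest population frequency are phased
(missing frequency counts as rarest; ties broken by genomic key), the
rest remain listed. A child variant carried by neither genotyped parent
is a Mendelian inconsistency: flagged in `phase_evidence`, status falls
back to phase-unknown. Confirmed compound heterozygosity is never
emitted without trio evidence (property-tested).

### Haplotype sharing

Phasing: for a proband homozygous for the disease allele, both
chromosomes are founder chromosomes, so every marker where the proband
is homozygous is determined. For a het carrier with a known transmitting
parent, a marker is determined when the child is homozygous there, or
when exactly one child allele is present in the transmitting parent's
genotype (the other being attributable only to the untransmitting
parent). Anything else — including a child pair impossible given the
parents, which is additionally flagged — is undetermined.

Consensus: per marker, the unique determined allele across phased
chromosomes; disagreement is a conflict state; no information leaves the
marker undetermined.

Shared region: starting from the two markers immediately flanking the
locus and extending outward one marker at a time, a marker is shared iff
the consensus is determined there and every unphased carrier's genotype
pair contains the consensus allele. A missing genotype cannot contradict
sharing and counts as compatible (the number of such decisions is
reported); a stricter mode demands homozygosity for the consensus
allele. Extension stops at the first non-shared marker per side. The
span between the outermost shared markers is the *minimum* bound on the
conserved region — the printed convention — and the flank-to-flank span
is the maximum bound; both are emitted because marker spacing leaves the
true boundary anywhere between them. A conflict or non-sharing at an
innermost marker is an error: no well-defined region exists.

Sharing is anti-monotone in carriers (adding one can only shrink the
region) and unaffected by removing markers outside the region — both
property-tested.

## Synthetic-data generator

The generator emulates the study structure so that every stage has a
verifiable ground truth:

* **Cohort**: 225 case families — 205 singletons, 11 trios, 9 affected
  sib-pairs, giving 234 affected members (deterministic counts) — plus
  649 control singletons. One index case per family.
* **Founder variant**: carrier status drawn per index case at 5% (15% of
  carriers homozygous) and per control at 0.3%. Trio parents are
  Mendelian-consistent (het child: one transmitting carrier parent,
  recorded in truth; hom child: both parents het).
* **Phasing families**: among the drawn carriers, one trio family with a
  homozygous proband and — when at least four carriers exist, so that
  two remain unphased — one with a heterozygous proband are designated
  as the parent-available phasing families, mirroring a study where
  segregation analysis is possible only where parents could be sampled.
  The homozygous proband guarantees a determined consensus across the
  conserved window.
* **Background variants**: 200 null variants inside panel genes,
  carriers Bernoulli(0.005) per cohort; 30% get a common population
  frequency (> 0.01, removed by the frequency filter), a fifth of the
  rest are absent from the reference; consequences mixed 55/10/20/15
  (nonsynonymous/splicing/synonymous/other), with 20% of the silent
  classes carrying a regulatory flag.
* **Allelic fractions**: genuine het calls uniform on (0.35, 0.65) —
  symmetric about 0.5 and clear of the 0.3 threshold so the artifact
  filter never removes true calls at defaults; hom calls on (0.95, 1.0);
  artifact calls (2% of all calls, sprinkled over non-carriers) on
  (0.05, 0.29). Fractions are quantized to 4 decimals so files
  round-trip bit-exactly.
* **Structural variants**: one deletion overlapping the disease gene in
  a random case (emulating an exon deletion detectable only by
  genome sequencing) plus one decoy outside the panel.
* **Markers**: the ten real D1S marker names with synthetic positions
  over 3.0 Mb (the physical map is user-suppliable; positions were not
  available to bundle), locus at 1.75 Mb, conserved window
  D1S2640–D1S2751 = 0.7 Mb. Eight alleles per marker with
  Dirichlet-distributed frequencies, integer allele codes 150–164
  resembling capillary-electrophoresis repeat lengths. Founder
  chromosomes carry the founder haplotype across the window and
  recombine onto random backgrounds outside it (breakpoints uniform over
  the outside gaps).
* **Informative flanks** (`ensure_informative_flanks`, default on): the
  first one or two unphased carriers receive a recombination immediately
  outside each window edge *and* a genotype there that excludes the
  founder allele, so a noise-free run identifies both boundaries
  exactly. With no unphased carriers at all, the homozygous proband's
  two chromosomes recombine at both edges onto distinct alleles, ending
  the consensus at the window. Marker missingness (default 0) is applied
  to unphased carriers; since missing genotypes cannot contradict
  sharing, missingness can only grow the region, never lose the window.
* **Seeding**: one master seed; the cohort and marker streams are
  spawned from it (`numpy SeedSequence`), so marker data can be
  regenerated independently of the cohort. Identical configuration gives
  byte-identical files.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: linkage disequilibrium beyond the
planted window, population stratification between cases and controls,
genotyping error at markers (beyond missingness), variant-calling error
beyond the low-fraction artifact model, relatedness between nominally
unrelated families, and per-site depth variation. Null background
variants are independent across sites, which real panels are not.

## Clinical summaries

Onset entries are either a number of years or the token `childhood`;
numeric ages below 18 count as childhood onset. Adult-onset means are
computed over onsets ≥ 18, childhood onsets are a separate count — the
distinction matters because late, mild presentations are exactly how a
founder genotype escapes pediatric ascertainment. Biallelic patients are
summarised over every tabulated family member (clinical description
keeps relatives that enrichment statistics must drop); heterozygous-
carrier summaries use index cases only. Means are reported raw and
rounded half-away-from-zero to one decimal; sample SDs use the n−1
denominator and are undefined (reported missing) for a single value.
Allele-frequency percentages use 2N chromosomes per N individuals and
half-away-from-zero rounding at the column's declared decimals.

## Numerical and degenerate-input conventions

* Hypergeometric tails via scipy's log-space survival function; exact
  agreement (≤ 1e-12) with integer-combinatorics enumeration on all urns
  with N ≤ 30 is part of the acceptance checks.
* A fully empty 2×2 table yields OR = nan, flag false, p = 1.
* `allele_frequency_percent` and report rounding use decimal
  half-away-from-zero (never banker's rounding).
* VCF allelic fractions: an explicit `VAF` FORMAT field takes precedence
  over AD-derived alt/total depth; fractions are read at 6-decimal
  precision (float32 transport) and written at 4; zero-depth AD gives a
  missing fraction.
* Multi-allelic records are split per alternate allele with genotypes
  mapped per allele; any missing allele in a genotype makes the call
  missing.
* Sex chromosomes are treated as diploid (the disease gene here is
  autosomal; a simplification, documented as such).
* `classify_zygosity` treats every pedigree member as genotyped unless
  an explicit `genotyped_samples` set restricts it.

## Problem sizes used in the validation studies

Replicate counts follow the study design they probe: 2,000 null tables
for CI coverage, 200 replicates for planted-founder recovery and for
each haplotype study, 500 null panels for the family-wise error, urns up
to N = 30 for exact enumeration. The full suite runs in about a minute
on one CPU; `scripts/acceptance.py` re-derives every number it reports
at run time.

## Known limitations

* The hypergeometric model treats q̂ as known; control-sample sampling
  error is not propagated (the zero-floor mitigates only the degenerate
  case). A Bayesian or exact conditional treatment would calibrate the
  null better at the cost of the sensitivity discussed above.
* The OR model's Wald machinery is asymptotic; with expected carrier
  counts of a few, its CI is conservative rather than exact.
* Trio phasing is rule-based and per-marker; it does not borrow
  information across markers (no HMM), matching how microsatellite
  haplotypes are read in practice but leaving some markers undetermined
  that a statistical phaser would call.
* The shared-region boundary resolution is limited to marker spacing;
  the emitted min/max spans bracket, not pinpoint, the true conserved
  segment.
* Index-case reduction assumes the family and index annotations are
  correct; cryptic relatedness between families is not detected.
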