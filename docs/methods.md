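# Methods

This note documents the statistical model behind `lupustrio`, the defaults
it ships with, what the synthetic cohort generator does and does not
emulate, and the numerical choices made where the design was genuinely
open.

## Trio model and inheritance classification

Each family contributes a proband–father–mother trio genotyped at a shared
set of decomposed biallelic sites. Classification of a proband
alt-carrying variant proceeds by parental comparison:

- a heterozygous proband with exactly one carrier parent is paternal or
  maternal; with two carrier parents the haplotype of origin cannot be
  resolved without phasing, so the call is *biparental-ambiguous* and is
  excluded from compound-heterozygote pairing;
- a homozygous-alt proband with two carrier parents is
  *homozygous-recessive*;
- a proband carrying the alternate allele with both parents confidently
  homozygous reference is a Mendelian violation and becomes a de novo call
  only if quality gates pass. Missing or degraded parental evidence always
  resolves to *unresolved*, never to de novo — the conservative direction
  for a variant class whose interpretation depends on it being absent from
  the parents.

Quality gates: proband DP ≥ 10, GQ ≥ 20 and alt reads ≥ 5; each parent
DP ≥ 10 with at most 1 alt read. The alt-read floor implements a
minor-allele read-count filter (alt support < 5 discarded). The one-read
parental tolerance accepts that index hopping and base errors put stray
alt reads in parents at deep coverage; requiring exactly zero would
discard true de novo events at a rate growing with parental depth. Both
values are configurable (`InheritanceThresholds`).

The filter "minor allele count < 5" admits two readings — per-sample alt
read support, or cohort-level allele count. The per-sample read-support
reading is implemented: it acts at the evidence level where trio logic
operates, and in a 50-family cohort of private rare variants a cohort
allele count rarely exceeds a handful anyway.

**VAF bands.** A germline heterozygote is binomially sampled around
VAF 0.5; post-zygotic (somatic or mosaic) variants sit lower. De novo
calls with observed VAF ≥ 0.30 are classified germline; [0.10, 0.30)
mosaic-suspect; below 0.10 the call is left unresolved as indistinguishable
from artifact. The 0.30 boundary is a round, configurable value chosen to
contain the descriptive 10–26% band reported for somatic-dominated
probands while leaving headroom for binomial noise around it.

**Interaction of the band with the read gate** (known limitation): at mean
depth 40, a true VAF just above 0.10 yields ~4 alt reads and fails the
5-read gate, so a small fraction (typically < 10%) of band-range mosaic
variants are recovered as unresolved rather than mosaic-suspect. They are
never misclassified as germline. Raising depth or lowering
`min_alt_reads` trades this loss against artifact admission.

**Hemizygous X.** Male probands are hemizygous on X; calls there are
normalized to a diploid-style representation, flagged, and compared
against the mother only.

## Relatedness

Kinship is estimated with the robust within-pair estimator

φ̂ = (N_Aa,Aa − 2·N_AA,aa) / (N_Aa(1) + N_Aa(2)),

counting doubly-heterozygous and opposite-homozygous (IBS0) site pairs.
It requires no allele-frequency model, which keeps it valid under
population misspecification. Expected values: 0.5 for duplicates or
monozygotic twins, ≈ 0.25 for parent–offspring (IBS0 ≈ 0), ≈ 0 for
unrelated pairs. The pipeline requires ≥ 200 informative sites and accepts
parent–offspring kinship in [0.17, 0.354]; families outside the window are
excluded with a log entry. The estimator is validated in the tests against
an independent gene-dropping Monte-Carlo oracle.

## Rare-variant screen

Stages run in a fixed, configurable order with per-stage attrition
logging: consequence inclusion → dual-population MAF → read QC → panel
tagging. Laws asserted by property tests: lowering the MAF threshold never
enlarges the surviving set; the cascade is idempotent; the MAF and
consequence stages commute.

- *Consequence inclusion*: missense, nonsense, coding indels
  (frameshift and in-frame) and canonical splice-site variants (+1/+2 of
  the donor, −1/−2 of the acceptor). Unknown labels map to `other` and are
  excluded with a warning.
- *Frequency filter*: excluded iff MAF **strictly greater** than 0.005 in
  either the global or the East-Asian reference panel, so a variant at
  exactly 0.005 passes. Absent frequencies are a distinct state — a novel
  variant must pass, never be treated as frequency 0 by coincidence of
  encoding.
- *Damage consensus*: likely damaging iff ≥ 2 of the available predictors
  vote damaging (PolyPhen-2 probably/possibly damaging; SIFT deleterious;
  CADD phred ≥ 20, the conventional cutoff) with ≥ 2 predictors present;
  otherwise not-damaging or indeterminate. A 2-of-3 majority was chosen
  because the three tools are named jointly without a combining rule in
  common practice; the rule is config-exposed since damaging-fraction
  summaries are sensitive to it.
- Gene symbols are matched exactly after uppercase normalization; alias
  resolution is an annotation-time concern, out of scope here.

## Burden statistics

Per-individual counts of qualifying rare variants are compared between
cohorts by Pearson χ² (no continuity correction) on a groups × bins table
over count bins 0,1,2,3,4,≥5. The binned design compares the whole count
distribution; a carrier/non-carrier 2×2 mode is provided as the
alternative reading. Expected counts are reported and a warning is issued
when any expected cell is below 5. Identical distributions short-circuit
to statistic 0, p = 1. Calibration: under a shared Poisson null
(n = 50 vs 105, 1000 replicates) the rejection rate at α = 0.05 stays
within [0.03, 0.07] (asserted in the acceptance tests).

Per-gene carrier screening reports case and control carrier proportions
and keeps genes at ratio ≥ 2; zero control carriers with ≥ 1 case carrier
gives an infinite ratio and is retained, flagged as infinite rather than
silently capped. De novo burden is compared as a rate ratio of per-sample
means plus a two-sided Mann–Whitney test, with a sensitivity re-run
excluding flagged outlier probands. Outlier flagging uses
count > Q3 + 3·IQR (ties broken toward not flagging; cohorts under 5
probands are never flagged) and reports each proband's fraction of de novo
calls with VAF < 0.30. Medians use the midpoint-of-central-pair convention
(numpy default), which is what makes half-integer cohort medians possible.

The 2^−ΔΔCt helper implements relative qPCR expression:
fold = 2^−((Ct_target,case − Ct_ref,case) − (Ct_target,ctrl − Ct_ref,ctrl)).

## Prioritization

Over-representation uses the hypergeometric upper tail with BH adjustment
across tested sets; sets with fewer than 3 background genes are skipped;
the background defaults to the full gene universe supplied alongside the
annotation and is configurable. Top pathways are the 20 most significant
sets with −log10 p > 4 (ties broken lexicographically by term id). Term
databases are consumed as plain GMT; similarity-based clustering of
related terms is deliberately **not** reproduced — each term is tested
independently, so a gene's "cluster count" is its membership count among
the selected top sets.

"Highly expressed" in ABCs or plasma cells is undefined in common usage,
so two modes are provided: argmax (default — the gene's expression in a
target cell type strictly exceeds every non-target column; constant rows
are false) and z-score (≥ 1.5 across cell types in a target column).
Candidates are de novo genes with both top-pathway membership and
ABC/plasma expression support, sorted by pathway cluster count; the Venn
decomposition (pathway-only / expression-only / both) is emitted
alongside.

## Synthetic cohort generator

The generator fabricates the study conditions end to end:

- 50 trios; parental genotypes at 1200 shared background sites drawn under
  Hardy–Weinberg from a U(0.05, 0.5) allele-frequency spectrum, children
  by Mendelian gene dropping (these common sites drive the kinship check
  and exercise the frequency filter);
- inherited rare implants per proband: Poisson(1.3) in the 49-gene
  monogenic panel plus Poisson(4.7) in the 213-gene GWAS panel — total
  mean 6.0, giving a per-proband median of 6 qualifying SLE-panel
  variants; a handful of well-known genes are up-weighted so the carrier
  screen surfaces hot genes as real cohorts do;
- de novo implants: Poisson(1.2) per proband (median 1 with a realistic
  upper tail), a configurable fraction mosaic with true VAF ~ U(0.10,
  0.26); the last two families additionally receive a Poisson(30)
  somatic-like component entirely in that VAF band, mirroring
  somatic-mosaicism outlier probands;
- reads: depth ~ negative binomial (mean 40, dispersion 8), alt reads ~
  Binomial(depth, true VAF), hom-ref samples at a 0.002 error VAF; GQ is a
  deterministic function of depth. A noiseless mode (fixed depth, rounded
  allele depths, GQ 99) supports exact recovery accounting;
- annotation: 92% missense among qualifying classes, 20% of rare implants
  novel (absent from both frequency panels), damaging-predictor fractions
  0.42 (panel variants) and 0.216 (de novo) feeding the consensus rule;
- controls without case enrichment: 105 individuals at Poisson(3.0) rare
  variants each, and 2049 individuals at Poisson(0.79) de novo variants
  (1619 variants / 2049 individuals), with control gene carriers spread
  uniformly over the eQTL panel;
- a 3000-gene background universe, a GMT with 20 enriched SLE-like sets
  (the designated de novo pathway genes spread with fixed cluster
  multiplicities 7,5,5,5,4,4,…) plus 20 decoy sets, and an expression
  matrix in which exactly 19 de novo-pool genes peak in ABCs and 12 in
  plasma cells (31 of 50, of which 12 also sit in top pathways — Venn
  9/19/12 by construction).

Randomness is streamed per family, keyed by (seed, family index), so
extending a cohort leaves existing families byte-identical; cohort-level
assets (site AFs, pathway sets, expression) use separate streams off the
same seed. Output is plain VCF 4.2 + PED + TSV/GMT/JSON.

**What the generator does not emulate** — and therefore what passing tests
do not demonstrate about real data: linkage disequilibrium and population
structure (sites are independent; one homogeneous population), multi-sample
joint-calling artifacts, genotyping error beyond a constant per-read error
rate, indel realignment ambiguity, multi-allelic sites (decomposition is
exercised by dedicated fixtures instead), X-chromosome sites, and panel
gene lists beyond the well-known members (panels are padded to 49/213/64
with synthetic placeholder symbols).

## Problem sizes and runtime choices

The default test and reproduction runs use the 50-trio cohort with 1200
background sites, a 500-proband lightweight count replicate for median
checks, 1000 replicates for χ² calibration, and 5000-site gene-dropping
for kinship oracles. These sizes make every documented quantity stable to
the asserted tolerances while keeping a full run in seconds on one core.

## Known limitations

- No read-backed phasing: compound heterozygotes rely on parental origin,
  so double-het parents leave pairs unresolved.
- Parental gonadal mosaicism is not modelled beyond the descriptive
  low-VAF flag on probands.
- The mosaic band's lower edge interacts with the alt-read gate at
  moderate depth (see above).
- ORA treats terms independently; overlapping gene sets inflate the
  number of significant terms relative to a clustered analysis.
- Control cohorts are consumed as pre-filtered count tables; harmonizing
  filtering between differently sequenced cohorts is upstream of this
  package.
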