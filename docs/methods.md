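# Methods

## The prioritization problem

A familial MDS/AML cohort consists of pedigrees in which two or more
relatives were diagnosed with a hematological disorder, at least one of them
MDS or AML. Each sequenced individual contributes hundreds of rare coding
variants, almost all irrelevant. The package separates the problem into two
arms:

1. **Known-locus triage.** If any family member carries a qualifying
   variant at an established predisposition locus, the family is resolved
   ("Group 1") and never enters discovery.
2. **Discovery cascade.** Remaining families ("Group 2") are screened
   genome-wide with a cascade of variant-level filters followed by
   gene-level aggregation across families.

Families whose only known-locus finding is a variant of unknown
significance are *held out of both arms*: they are not resolved, but
allowing them into discovery would contaminate the denominator with
partially explained families. In the packaged reference fixture this
convention reproduces the published split (49 known-locus families
including two VUS-holds, 37 discovery families).

## Known-locus triage

A variant at a configured locus is **pathogenic** when previously described
in familial MDS/AML (lookup against a curated table), or **likely
pathogenic** when a novel variant satisfies all of:

* reference-population frequency (ExAC and gnomAD) < 1e-5, or absent;
* VAF > 0.30 — strict inequality; a VAF of exactly 0.30 fails;
* two-of-four predictor consensus (PolyPhen2, MutationTaster, SIFT,
  Provean), with loss-of-function classes exempt (below);
* no benign assertion under ACMG review — supplied as a curator flag, not
  recomputed: a full ACMG engine needs population/literature databases that
  are out of scope here;
* segregation not refuted where testing was possible.

Partial evidence yields a VUS; a benign ACMG assertion or refuted
segregation excludes the variant. Zygosity is checked against the per-gene
inheritance model: heterozygous-dominant loci expect VAF in (0.3, 0.7) and
flag VAF >= 0.9 as a possible loss-of-heterozygosity **anomaly without
changing the category**; biallelic loci accept homozygosity or a second
heterozygous variant in the same gene (trans phase unverified, noted);
X-linked loci expect hemizygous males near VAF 1.

## The discovery cascade

Variants first pass the sequencing-level pre-filter: frequency < 0.005 in
ExAC *and* gnomAD (absence passes), depth >= 20, outside segmental
duplications. The per-variant criteria are then:

(i) VAF > 0.30; (ii) a qualifying consequence on the canonical transcript —
indels (frameshift or in-frame), nonsense, start-lost, splice variants with
intronic offset within ±3, or missense; (iii) segregation not refuted
(untestable passes — index-only families are retained); (iv) ExAC frequency
< 1e-4 or absent; (v) two-of-four predictor consensus.

Three distinct frequency thresholds deliberately coexist (0.005 pre-filter,
1e-4 discovery, 1e-5 known-locus): they belong to different stages with
different tolerance for false negatives and are kept as independent
configuration values.

**Predictor exemption for LoF classes.** The four predictors are
missense-oriented and routinely abstain on truncating variants, so
nonsense, frameshift, start-lost (p.Met1? is treated as LoF-class) and
essential-splice variants pass criterion (v) unconditionally by default; a
strict mode applies the count to every class.

**Gene-level recurrence counts families, not variants.** Two qualifying
variants in one family count once. A gene is included when non-missense
(LoF-class or in-frame indel) variants occur in >= 2 families; when >= 1
non-missense family joins >= 2 total families (mixed); or when missense
variants occur in >= 3 families — the higher missense bar tames the 86%
missense background. All thresholds are configurable.

**Cross-cohort rescue.** A gene failing recurrence is still included when
it carries >= 1 criteria-passing variant *and* appears in an external
candidate list from a prior familial MDS/AML or inherited bone-marrow-
failure series. The packaged lists are reduced to the printed overlaps of
the three published series they represent; users supply fuller lists as
one-symbol-per-line files. Rescue deliberately requires the full criteria
(i)-(v) on the supporting variant.

**Synonymous splice scan.** Synonymous variants are outside the cascade; a
separate scan returns synonymous variants whose upstream splice-impact
annotation exceeds a threshold (default 0.5) and which are absent from both
reference databases.

**CHIP cautions.** Final-list variants in TET2, DNMT3A or ASXL1 carry a
caution flag: age-related clonal hematopoiesis in blood DNA can sit well
inside the germline VAF window and is not distinguishable at the variant
level; only segregation or recurrence evidence can exclude it.

## Segregation

Only genotyped *affected* members can refute a variant (any affected
non-carrier). "Segregates" requires >= 2 genotyped affected members, all
carriers; fewer than two genotyped affected members is "untestable" and
passes downstream filters. Unaffected carriers never penalize — reduced
penetrance and late onset are recurring features of these loci — but are
recorded, as are healthy non-carriers (supporting, never decisive). A
strict mode that lets unaffected carriers refute is available and off by
default. Requiring two genotyped affected members for a positive call is a
deliberate reading of "where testing was possible"; one additional carrier
is not treated as confirmation.

## Constitutional deletion intervals

Coordinates are stored 1-based fully inclusive so printed breakpoints
reproduce bit-exactly; BED I/O converts to 0-based half-open at the file
boundary. Intersection of same-chromosome intervals is
[max(starts), min(ends)] or null. The packaged breakpoint table retains
both published coordinate pairs for the third deletion family (tabulated
and narrative; which is authoritative is unresolved), defaulting to the
tabulated set — the intersection is insensitive to the choice because the
first family's endpoint is the minimum. Lengths are reported as computed
(the hotspot spans 172,180 bp = 172 kb); prose approximations of the
segment length are never substituted for arithmetic. The packaged gene
feature model uses synthetic stand-in coordinates (flagged in the file) to
express "covers the distal promoter and first two exons"; curated
annotation should replace it for real analyses.

## Telomere qPCR

Standard curves are least-squares fits Cq = slope·log10(q) + intercept with
slope < 0 enforced; efficiency = 10^(−1/slope) − 1. Replicate Cq values
(quadruplicate in routine use) are converted to quantities *before*
averaging — quantity, not cycle number, is the additive scale — and the
T/S ratio is the ratio of channel means. Replicate spread beyond a
configurable Cq tolerance (default 0.5 cycles) warns without blocking. The
short-telomere flag uses a rank-based empirical percentile against >= 20
control ratios (proportion strictly below) with a strict inequality at the
centile (default 10th); no distributional assumption is made. The
published 225-control distribution is not redistributable, so tests use
synthetic control sets.

## The synthetic cohort generator

The generator's defaults encode the study conditions the pipeline targets:

| parameter | default | rationale |
|---|---|---|
| families | 37 | size of the discovery arm |
| sampling structures | index-only 0.38, duo 0.06, trio 0.31, extended 0.25 | matches the cohort's reported sampling mix (38% index-only, ~6% index + unaffected, rest multiplex) |
| rare variants / patient | negative binomial, mean 311, size 20, truncated to [161, 781] | reported mean and range; the size keeps the truncated mean unbiased (bias ≈ +2 « 3 SE) while staying overdispersed relative to Poisson |
| consequence mix | missense 0.863, indel 0.062, nonsense 0.024, splice 0.051 | reported mix; indels split 50/50 frameshift/in-frame; splice offsets uniform on ±1..8 |
| read depth | Poisson(80), 3% of sites Poisson(10) | typical exome coverage; the low-depth trickle exercises the depth filter |
| germline VAF | alt reads ~ Binomial(depth, 0.5) | heterozygous germline sampling; yields an empirical median in [0.47, 0.53] |
| ExAC/gnomAD | absent 2%, too-common (0.005–0.05) 2%, else log-uniform on [1e-4, 5e-3) | per-individual rare-variant burdens are dominated by variants present in large references; ultra-rare variants are modeled as database-absent |
| predictors | damaging per-tool 0.9 (causal/CHIP), 0.15 (background) | causal and clonal driver variants look damaging; background mostly does not |
| CHIP | ≤ 3 contaminants, distinct genes, VAF U(0.10, 0.50), single carrier | clonal hematopoiesis is private to one individual |
| gene pool | 20,000 synthetic symbols (`BG#####`) | exome-scale; disjoint from known-locus, CHIP and rescue-list symbols by construction |

Injected causal variants are shared identically by all sampled affected
members of their recipient families (unaffected members carry them with
probability 0.2, exercising the reduced-penetrance path) and are built to
satisfy criteria (i)-(v) — VAF resampled into the germline window,
predictors topped up to the consensus minimum — unless deliberately
spoiled. This "satisfy by construction" guarantee is what makes the
recovery evaluation a test of the pipeline rather than of sampling noise.

**What the simulator does not model**, and hence what passing tests do not
show about real data: linkage and haplotype sharing, annotation errors and
transcript-choice ambiguity, batch effects and joint-calling artifacts,
population stratification of allele frequencies, relatedness between
background variants (each is private to one carrier), and somatic
architecture beyond single CHIP contaminants. Recovery of injected genes
on simulated cohorts demonstrates the correctness of the filtering and
aggregation logic, not the sensitivity of the criteria on real exomes.

Background variants are private, so in families with two or more genotyped
affected members they are refuted by segregation; chance gene-level
recurrence of background variants across families is possible in principle
but has expectation well below one gene per cohort at the defaults
(~20,000 genes, ~1 qualifying ultra-rare non-missense variant per
contributing family), which is what the zero-false-inclusion evaluation
relies on.

## Numerical and interface choices

* VAF thresholds are strict inequalities throughout; frequency thresholds
  are strict `<`.
* Missing annotations become nulls, never zeros; null frequencies pass
  frequency filters, null VAFs fail VAF criteria.
* Multi-allelic VCF records are decomposed to biallelic rows before the
  annotation join; records with no annotation row are excluded with a
  counted warning.
* Exclusion tallies count every failed rule per variant, so per-rule counts
  can exceed the number of excluded variants.
* Percentages in cohort summaries are reported to one decimal; group
  percentages and the sporadic-AML overlap to the nearest integer; per-
  family variant means to one decimal — matching report conventions.
* Determinism: the simulator consumes a single `numpy` generator seeded by
  the caller; identical seeds give byte-identical output files.

## Problem sizes in the test suite

The end-to-end evaluations run at the generator defaults (37 families,
~20,000 variant rows per cohort): twenty replicate cohorts for parameter
recovery, two hundred randomized incidence matrices for the recurrence
oracle, one thousand random triples for the interval oracle, and fifty
forward-simulated plates for the qPCR model. These sizes give stable,
discriminating checks while keeping the whole suite under a minute.

## Known limitations

* The known-locus triage consumes curator-supplied ACMG judgements; it
  cannot itself demote a variant to benign.
* Compound-heterozygous handling does not verify trans phase.
* The cross-reference rescue is only as good as the supplied lists; the
  packaged ones are minimal.
* Telomere analysis starts at Cq values; raw fluorescence processing and
  plate-effect models are out of scope.
* The pipeline consumes annotated variants; alignment, calling and
  annotation (and their error modes) are upstream.
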