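# Methods

## Setting and model

A dried bone-marrow smear yields fragmented, partially denatured DNA.
Amplicon sequencing of that DNA still maps and covers the panel well, but a
low-VAF-sensitive somatic caller emits many spurious calls that a paired
fresh bone-marrow-cell (BMC) sample does not show. The package models a
variant call set as a map from normalized allele keys (chrom, pos, ref,
alt) to observations (VAF as a fraction, read depth, caller filter flags,
annotations), and treats the smear/BMC comparison as a set partition:
shared, smear-unique, BMC-unique. The working assumptions are

* genuine variants (germline and clonal somatic) appear in both members of
  a pair with nearly equal VAF;
* smear artifacts are smear-unique, concentrated below a low-VAF boundary,
  and mostly low-depth;
* assay artifacts recur across unrelated samples, so a panel of normals
  (PON) built from tumor-free samples identifies them;
* common polymorphisms are identifiable by population frequency.

None of these assumptions is re-estimated from data; they define the
filtering cascade.

## Allele normalization

Keys are made comparable by trimming the longest shared allele suffix, then
the longest shared prefix, keeping at least one base on each side and
advancing the position by the prefix length trimmed. The transform is
idempotent (property-tested). Reference-FASTA left-alignment is *not*
performed — the package is deliberately download-free — so two callers
that place the same indel at different anchors in a repeat run can produce
distinct keys. This is a documented limitation; in amplicon panels the
callers under consideration anchor indels consistently in practice.

## The cascade

Stages run in a fixed order; every record is accounted for (removed counts
plus retained counts are conserved stage to stage, enforced at run time):

| stage | rule | default |
|---|---|---|
| caller flags (somatic-style) | keep FILTER == PASS | — |
| hard filters (germline-style) | QD >= qd_min, MQ >= mq_min, FS <= fs_max; missing annotation passes | 2.0 / 40.0 / 60.0 |
| PON subtraction | remove keys present in >= min_samples normals | min_samples = 2 |
| VAF threshold | remove VAF < t | t = 0.025 |
| population frequency | remove prevalence > 1% (exactly 1% kept) | 0.01 |

Design choices that were genuinely open:

* **min_samples = 2.** Merging 13 normals without a membership rule risks
  subtracting a private germline variant that one normal happens to carry;
  requiring recurrence in two normals protects real variants while still
  catching systematic assay artifacts. Exposed in configuration.
* **Hard-filter values.** Only the parameter families (quality/depth,
  mapping quality, strand bias) are dictated by the workflow this package
  operationalizes; the numeric defaults follow widespread GATK-style
  practice and are configuration-exposed.
* **VAF cut is `remove < t`, not `<= t`.** A 3.04% variant must survive a
  2.5% threshold; the boundary value itself is kept.
* **Order.** Flag filtering first mirrors the upstream caller's own
  pipeline; the VAF and population filters are annotation-local and
  commute (property-tested), so their relative order is immaterial.

## Noise-boundary estimation

The 2.5% boundary is usually chosen by inspecting the post-subtraction VAF
histogram. The package replaces inspection with a rule: bin VAFs in
half-open bins of width 0.005 up to a 0.10 ceiling; compute per bin the
enrichment r_b = (# smear-unique in b) / (# shared in b + 1); report the
upper edge of the maximal initial contiguous run of bins with r_b >= 2, or
no boundary if the first bin already fails. The +1 regularizes empty
shared bins (without it a single stray artifact in an empty bin yields an
infinite ratio and spurious runs). Because the statistic is a ratio of
counts, duplicating every input leaves the estimate unchanged. Grid 0.5%,
rho = 2 and the 10% ceiling are defaults chosen so that noise shaped like
the smear artifact distribution (uniform mass below the true boundary,
shared calls above ~5%) is recovered to within one grid step; all three
are exposed. Mixture-model or kernel-density alternatives are possible
future work; the run rule is transparent and auditable.

## Coverage QC and the exact rank-sum test

Per-amplicon mean coverages are summarized by their median; uniformity is
the fraction of amplicons strictly above 20% of the median (per-amplicon,
not per-base — the input is an amplicon table); normalized coverage
divides by the median, making both statistics scale-invariant. The
two-group comparison uses the Mann-Whitney U test with an exact null for
n_a + n_b <= 14: the U distribution is enumerated over all C(n, n_a)
assignments of the pooled midranks (ties therefore handled exactly), and
the two-sided p is the doubled smaller tail, capped at 1. Larger samples
use the tie-corrected normal approximation (scipy). The exact path is
cross-checked in tests against scipy's exact method on tie-free data and
against an independent enumeration oracle with ties.

## Fusion consensus and karyotype concordance

Each RNA sample is processed by two fusion detectors whose output tables
are merged order-insensitively on the gene pair. Expression is RPM =
supporting reads / mapped reads x 1e6, computed from the larger of the two
callers' supporting-read counts (the detectors count junction evidence
differently; the larger count is the better lower bound on expression).
Positivity requires detection by **both** callers and RPM >= rpm_min.
"Highly expressed" has no published numeric definition; rpm_min = 1000 is
this package's inference — the smallest RPM among published positive calls
is 1524 and single-caller decoys sit far lower — and it is
configuration-exposed.

Karyotype concordance parses ISCN strings for t(a;b)(band;band) and
inv(c)(band1band2) tokens across all clones, ignoring counts, gains/
losses and add/del/mar/idem tokens; unparseable rearrangement tokens are
skipped with a warning. A fusion is concordant when a token involves both
partner chromosomes (from a built-in gene -> cytoband table of the panel's
driver loci) with bands matching at arm + major-band level (q22 matches
q22.1, accommodating varying report resolution). A gene absent from the
locus table yields *undetermined*, never a false negative.

## HGVS span arithmetic

The supported HGVS-c subset is exactly what myeloid-panel reports print:
point substitutions (with splice offsets), dup/del with optional stated
sequence (whose length must equal the span), ins/delins with a stated
sequence. nt-length and frame arithmetic give ITD amino-acid lengths
(48 nt dup -> 16 aa). One published composite entry
(`c.1836_1837insCGGC1788_1836dup`, labeled a 17-aa ITD although
4 + 49 = 53 nt is not a multiple of 3) is carried verbatim in the bundled
table but rejected by the parser and excluded from round-trip tests; its
intended coordinates are not guessed.

## Synthetic cohort

The generator reproduces the structure the pipeline exists to handle, with
per-variant truth labels. Defaults are the study conditions:

| quantity | default | rationale |
|---|---|---|
| pairs | 5 | cohort size of the paired comparison |
| germline SNPs / pair | 30 het + 15 hom | VAF peaks ~N(0.5, 0.03) and near 1.0; population AF > 1% |
| somatic variants / pair | 60 | VAF ~ U(5%, 50%), drawn once, jittered +/-2 pp per tissue |
| smear artifacts / pair | Poisson(400) | VAF ~ U(0.1%, 2.5%) below the boundary; smear only |
| BMC errors / pair | 20 | same VAF shape, BMC only |
| assay artifacts | 10 | same keys in every pair and all normals |
| normals | 13 | PON source |
| depth | NB mean 500 (real), 60 (artifacts), dispersion 8 | low-depth noise is not quantified upstream; these are invented and documented |
| non-PASS pre-flags | 30% of artifacts | emulates the upstream caller's own filter stage |

Positions are deterministic synthetic coordinates on pseudo-chromosomes
with disjoint per-class ranges — matching logic, not genome biology, is
under test. Everything is reproducible byte-for-byte under a fixed
(seed, pair index); the artifact VAF shape can be switched from uniform to
a beta shape.

What passing tests on this cohort do show: the partition, the cascade, the
boundary estimator and the consensus rule behave as specified under the
stated noise model, with >= 95% somatic retention and >= 95% artifact
removal. What they do not show: performance on real smears, where artifact
VAFs need not be uniform, artifacts can replicate across a pair, indel
representation varies, and depth interacts with VAF; headline percentages
from real cohorts are therefore not reproduced here.

## Numerical and degenerate-input choices

* VAF is a fraction internally; reports print percent.
* Bin edges are computed by integer flooring of vaf/step (no floating-edge
  histograms); boundaries are rounded to the grid.
* Duplicate keys within one call set collapse to the deeper record.
* Empty inputs: an empty pair union, an empty normal list, an empty group
  in the rank-sum test, and a zero median coverage are errors; an empty
  smear-unique VAF list yields "no boundary", not an error.
* Report directories are written to a temporary sibling and renamed into
  place, so a failed run leaves no partial outputs.

## Problem sizes

Test-suite and acceptance runs use the default synthetic conditions (five
pairs, ~2,600 variants per replicate, 13 normals) and 10–100 seeded
replicates per property; a full run of suite plus acceptance script
completes in well under a minute on one CPU.
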