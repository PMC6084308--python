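# Methods

This note records the models, defaults and numerical choices behind the
package, and what the simulator does and does not emulate.

## Simulated study conditions

The generator stands in for whole-gene HLA amplicon sequencing of a
heterozygous donor sample.

**Gene templates.** `classI` is a 3404 bp gene with 8 exons and the
UTR5–exon/intron–UTR3 layout typical of HLA-A/B/C; `classII` is ~8 kb
with 6 exons and long introns, placing it at 2–3× the class I length
(the published size relationship between the locus classes). Reference
sets are drawn uniformly over ACGT with homopolymer runs of length 5–9
planted in introns/UTRs (random sequence alone underrepresents the long
runs where single-molecule indel error concentrates); additional alleles
differ by a configurable substitution divergence (default 1%).

**The default heterozygote.** Haplotype 1 carries 4 substitutions at
fractions 0.06/0.15/0.55/0.92 of the gene; haplotype 2 removes one base
from the longest homopolymer run. This encodes the two documented
failure modes at once: two consecutive het sites sit >1 kb apart
(short-read phasing must fail) and the run-length difference is exactly
the state long reads cannot resolve alone. Novel alleles differing from
the closest reference in only a few bases is the typical case this
workflow exists for.

**Error presets.** Long reads: full-amplicon single-end, per-base error
13% total (1% substitution, 6% insertion, 6% deletion), indel rates
doubled inside homopolymer runs of length ≥ 4. The published constraint
is only ">10% per-read, indel-dominated, homopolymer-concentrated";
13% with a 2× run multiplier satisfies it while stressing run calling.
Insertions duplicate the current base inside runs (the plausible error
mode) and insert a random base elsewhere. Short reads: 251 bp pairs
from fragments uniform on [400, 1000] bp (hard 1 kb ceiling — the
phasing limit), 0.2% substitutions, no indels; the platform's real
error profile is not published, and only "accurate, substitution-like"
matters for the pipeline's logic. Realized per-read long-read error
measured by unit-cost alignment is ~12.2% (adjacent indel/substitution
events partially cancel under alignment), within the 13% ± 1% design
band.

**What the simulator does not emulate:** PCR chimeras, barcode hopping,
quality-score miscalibration, coverage bias (GC or positional),
correlated error bursts, and subread/CCS structure of real
single-molecule data. Passing tests therefore demonstrate the logic of
the dual-evidence reconciliation, not robustness to every real-data
artifact.

## Alignment machinery

`align_global` is an exact affine-gap (Gotoh) global aligner
(match +1, mismatch −1, gap open −2, gap extend −0.5 by default) with a
fixed traceback preference — diagonal > gap-in-query > gap-in-target,
and the same order at the end cell — so every downstream result is
deterministic. It is checked against an explicit last-op-state dynamic
program on random 50-mers.

Long-read pileups use `align_banded`: the edlib unit-cost optimal path
provides a guide line, and the affine DP is run in a ±48 column band
around it. Affine scoring is essential here, not cosmetic: under unit
costs a true substitution in an indel-heavy read can be rewritten as a
gap pair and drift columns, eroding minor-allele counts at het sites
below the informative-position window; affine gap opening keeps
substitutions as mismatches. The banded result is best-in-band, not
certified optimal — acceptable for evidence counting, and ~200× faster
than the full DP at amplicon scale. Short accurate reads are placed
semi-globally with edlib directly (no ambiguity at 0.2% error);
ambiguous placements (tied locations) are dropped rather than counted
twice.

## Short-read route

Consensus calling is per-column majority over A/C/G/T/deletion with a
het call when the runner-up symbol's fraction lies in [0.25, 0.75] at
≥ 10× coverage (defaults; the production analysis software this stands
in for is proprietary and publishes neither). At 100× a balanced
binomial site falls inside that band with probability > 0.999. Phase
blocks are connected components of the fragment co-coverage relation:
two hets link when one fragment (pair counted jointly) covers both with
het-consistent alleles. More than one block ⇒ whole-gene phasing
undefined.

## Long-read route

Informative positions are columns whose runner-up symbol frequency lies
in [0.30, 0.70]; deletion-candidates inside homopolymer runs are
excluded (run lengths are decided by the run caller, not the column
caller). Clustering reduces each read to its symbols at informative
positions, orients columns against the first position by majority
co-occurrence, and assigns each read to the all-first or all-second
centroid; reads disagreeing with their best centroid at > 40% of covered
positions (or exactly tied) stay unassigned. Homozygous samples (no
informative positions) yield one cluster, flagged.

Per-allele consensus is column majority outside homopolymer runs; each
run's length is the mode of per-read supported lengths over reads
spanning the run (anchored one column on each side, insertions of the
run base inside the run counted). A run is flagged ambiguous when the
mode's support is < 60% or tied — the state in which long-read data
must not decide the call. Ties resolve to the smaller length for
determinism, pending polishing.

## Reconciliation and polishing

Conflicts are classified on the closest-reference coordinate system.
Outside homopolymer runs the comparison is per column (call sets vs the
reference base). Inside a run the two routes may place an equivalent
indel at different columns (gap placement within a run is arbitrary),
so runs are compared as *sets of supported run lengths* per route; an
ambiguity flag on either haplotype marks the run as long-read indel
trouble outright. A conflict where both routes deviate discordantly is
treated as a short-read-only deviation (the repeat-analysis rule is the
safe default). Phase gaps between consecutive phase blocks are emitted
as their own conflict class.

The decision function is total and ordered: repeat-analysis dominates
cluster-and-polish dominates submit-short-read; no conflicts ⇒ submit
the concordant sequence. The precedence is configurable; the default
order puts the most conservative action first.

Polishing maps every short-read fragment against both preliminary
haplotype consensus sequences and keeps it on the strictly
better-matching one. Two refinements proved necessary:

* **Run-collapsed assignment.** Distances are computed against copies
  of the haplotypes whose runs of ≥ 3 identical bases are collapsed to
  2. A miscalled run length would otherwise repel a haplotype's own
  corrective reads (they match the *other* haplotype better at that
  locus), so the error could never be fixed. Collapsing removes
  run-length information from the assignment while leaving substitution
  hets — the phasing signal — fully discriminative.
* **Shared-evidence fallback.** Fragments matching both haplotypes
  equally span regions where the two are indistinguishable; they are
  pooled as shared evidence and consulted only where haplotype-specific
  coverage is below the correction threshold (5×). Dropping them
  entirely starves loci out of linkage range of any het (e.g. terminal
  homopolymers); counting them everywhere dilutes true het runs with a
  50/50 mixture. The hierarchy uses specific evidence where it exists
  and unbiased shared evidence where it cannot.

A position is rewritten only where the short-read majority contradicts
the preliminary call at ≥ 5× (specific, else pooled) coverage;
concordant positions are never edited. In 20 seeded replicates under
the default study conditions both polished haplotypes equal the
simulated truth exactly in 20/20 (the acceptance threshold is 19/20).

## Annotation

The closest reference is the minimum-edit-distance allele (ties broken
by name). Feature boundaries project through the global alignment
mapping; insertions inside a feature extend it and junction insertions
join the upstream feature; projection is refused below 90% alignment
identity (the mapping is no longer meaningful). Expression class: the
spliced CDS is translated (standard nuclear code) and a stop codon
strictly before the reference protein's stop — nonsense substitution or
frameshift-induced — gives class N (null); otherwise any enumerated
difference matching the configurable Q catalog (variants known to
affect expression in other alleles; the catalog itself is user data)
gives class Q; otherwise normal.

## Reporting

Registry statistics use half-up rounding: full-characterisation shares
to one decimal, null/Q proportions to whole percent — matching the two
table styles they reproduce. Allele frequencies divide observation
counts by 2 × genotyped samples (two gene copies per donor); the
denominator convention is stated because source publications often
print only the sample base. The flat-file writer emits a minimal
EMBL-style subset (ID, FT with source/CDS `join(...)`/exon/intron/UTR
features and a wrapped `/translation`, SQ with 60-column lines and
running positions, 1-based inclusive coordinates); its paired reader
round-trips the format exactly, which the tests exercise on randomized
records.

## Problem sizes and determinism

Defaults throughout are the class I template (3404 bp), 100 long reads
and ~678 short-read pairs (100× each) — sizes at which one end-to-end
run takes a few seconds and the 20-replicate recovery battery a few
minutes on one CPU. Every stochastic step takes an explicit seed;
derived stage seeds are small fixed offsets of the pipeline seed, and
reruns are byte-identical.

## Known limitations

* Clustering assumes a diploid (≤ 2-allele) sample; contamination or
  chimeras would need a cluster count search.
* Short-read-only insertions are not scored as conflicts (the short
  preset is substitution-only; a real insertion seen by both routes
  surfaces through the concordant path).
* The banded aligner is heuristic near its band edges; pathological
  reads (> ~50-base drift from the unit-cost path) could be misplaced.
* A true het run-length difference with no substitution het within
  fragment range is unresolvable by design — the same sample would
  defeat the laboratory workflow this mirrors.
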