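# Methods

## Model and coordinate conventions

The mitochondrial genome is treated as a circular molecule of length L with
1-based inclusive coordinates throughout, matching the positional notation
of the mtDNA literature (m.263A>G).  Any integer position is normalized by
`((p − 1) mod L) + 1`; flank windows and loci may wrap across the origin
(the control region does in the real genome).  Conversion to 0-based
half-open coordinates happens only in the BED writer, which emits the
0-based start / 1-based end convention.

Heteroplasmy is modeled as an allele fraction among sequenced molecules.
The estimator is the plug-in ratio

    HF = alt_depth / total_depth,

with the denominator measured at the variant's own position for mismatches
and deletions and at the 5′ anchor position for insertions.  Total depth at
a position counts matched bases plus deletion-spanning reads: a read whose
deletion spans the position is evidence about the position, and including
it in the denominator is what makes the deletion's own HF a fraction of all
observations (so HF ≤ 1 by construction).  This choice is configurable but
is the default because it is the only reading under which the HF of a
homoplasmic deletion equals 1.00.

At coverage d and true fraction h, the estimator is binomial:
sd(HF) = sqrt(h(1−h)/d).  The self-checks use the 3σ band, which a correct
pipeline should satisfy in ≈99.7% of replicates; the acceptance suite
requires ≥99%.

## Calling filters and their boundaries

* Mismatches and insertions: position depth rd ≥ 5 and median supporting
  Phred QS ≥ 25.  Both comparisons are inclusive — 25 and 5 pass, 24 and 4
  fail — and the boundary suite pins exactly this flip.
* Deletions: the 5-bp upstream and 5-bp downstream flanking regions are
  evaluated separately; each side must reach median QS ≥ 25 and median
  rd ≥ 5.  Per-side evaluation is the stricter of the two defensible
  readings of "the flanking regions" and is the default (a pooled
  10-position mode is one code change away; the flank rd median counts
  zero-depth positions as zeros).  The flank QS median pools the match-base
  Phreds of the five positions; the rd median is over the five per-position
  depths.
* `min_alt_reads` defaults to 1: no alternative-depth floor is imposed, so
  low-level heteroplasmies down to a single high-quality read are reported.
  This maximizes sensitivity (the published use case detects HF < 0.10) at
  the cost of passing isolated high-quality sequencing errors as ≈0.01-HF
  candidates; noisy libraries should raise it.
* The deletion HF denominator is the depth at the first deleted position —
  a deterministic choice for multi-base deletions, where "the same
  position" is otherwise ambiguous.
* Multi-allelic sites emit one call per alternative allele with no joint
  normalization.

Median of an even-length multiset is the mean of the central pair; an empty
multiset has median 0 (with rd = 0).  Pileups store per-base Phred
histograms (0–93), so medians are exact, not approximated.

## Duplicate marking

Fragments are grouped by the unclipped 5′ coordinates and orientations of
both mates (single reads by their own coordinate), the standard coordinate
criterion.  Within a group the pair with the largest summed base quality —
both mates' qualities summed, configurable to per-read maxima — survives;
ties break deterministically on the lexicographically smallest read name.
Marking is recomputed from scratch on every call and is therefore
idempotent; the survivor count equals the number of distinct fragment
groups.  MAPQ is deliberately not used as a filter (none is part of the
published procedure); it is exposed on the reads for callers that want it.

## Consensus construction

Per position, in order of precedence: depth below `min_rd` → `N` (a gap);
one PASS mismatch with HF ≥ 0.75 → the alternative base (the threshold is
inclusive); PASS mismatches all below 0.75 → the IUPAC code covering the
reference base and all called alternatives; otherwise the reference base.
Two alternatives with HF ≥ 0.75 at one site cannot occur (their HFs would
sum above 1) and are guarded by an assertion.  Indels are never applied, so
the consensus length equals L — an explicit limitation, which keeps every
downstream coordinate system intact.  Gap counting (`gap_count`) supports
the "fewer than 500 gaps" style of sample triage.

## Haplogroup scoring

Definitions are an input table (haplogroup → defining position/allele
pairs) expressed in whatever reference frame the user's classification
tree uses; the toolkit only requires that the consensus share that
coordinate system.  For each haplogroup, Nph counts defining sites whose
consensus character contains the derived allele under IUPAC set expansion
— heteroplasmic sites below the consensus threshold therefore still
contribute — and `N` never matches.  P_Hg = Nph / N_ph_exp, with uncovered
(`N`) sites counted in the denominator by default (the conservative
choice; exclusion mode available).  The best haplogroup is the P_Hg
argmax, ties broken by larger expected-site count and then by name, and
the assignment is flagged reliable only when P_Hg > 0.90, strictly.  No
phylogenetic path scoring is attempted: back-mutations and missing sites
simply lower P_Hg.

## Cohort analytics

* Annotation: homopolymers are maximal runs of ≥ 2 identical adjacent
  bases (wrap-aware; `N` joins no run).  An insertion counts as inside a
  homopolymer when its anchor or the position after the anchor lies in a
  run, since an inserted base that extends a run should count.  The
  low-variability flag is strict (< 0.20); the MutPred damaging threshold
  is inclusive (≥ 0.70); classifier calls are damaging on a
  case-insensitive "disease" class.  `damaging_any` ORs over the tools
  present, `damaging_all` requires all three present and damaging.
* Source classification: EBV coverage 0 → blood, > 400 (strict) → LCL,
  anything between → unknown.
* The sample × 11-HF-class matrix is clustered hierarchically on rows and
  columns with Euclidean distance and complete linkage (the default of the
  R `hclust`/`heatmap` stack this emulates; average/single available).
  scipy's index-based tie-breaking makes leaf orders deterministic, and
  trees are exportable as Newick with merge heights.
* Group comparisons: Welch (unequal-variance) t-tests, chosen because the
  variance assumption is unstated in the procedure being reproduced
  (pooled mode available); the one-tailed form tests mean(A) > mean(B).
  2×2 tables use the exact two-sided Fisher test; r×c tables use a seeded
  Monte-Carlo permutation over tables with the observed margins
  (Patefield sampling), with the add-one p-value estimate and the
  replicate count reported.

## The read simulator: what it emulates, and what it does not

Fragments are sampled uniformly on the circle with Normal(mean, sd)
lengths (clipped to at least one read length), and each fragment carries
each planted variant independently with probability equal to its target
HF — a haplotype mixture at the fragment level, so paired mates agree, as
molecules do.  Per-base Phreds are Normal(33, 4) clipped to [2, 60],
matching the quality range of the capture data this emulates; sequencing
errors are injected uniformly per base (default 0.1%) with the Phred
reduced by 15, never raised.  PCR duplicates re-emit a fraction (default
15%) of fragments with fresh qualities.  Defaults — 100-bp mates, 300 ± 60
bp fragments, 200× target depth — reflect deep off-target mtDNA capture.

Origin handling is a config switch: by default origin-spanning fragments
are rejected and resampled, keeping standard linear SAM records (the edge
positions then have reduced depth, as on a linear contig); with
`allow_origin_spanning=True` such fragments are kept and reads crossing
the origin are split into two unpaired records, which restores uniform
depth on the whole circle and is what the consensus round-trip check uses.

The truth table records, per planted variant, the realized covering and
supporting read counts over the unique (pre-duplication) fragments, from
the actually emitted bases — so realized HF = support/cover exactly, and
sequencing errors that destroy a planted allele are accounted for.

Not emulated: platform-specific error profiles (homopolymer-length errors
in particular), alignment ambiguity and mapping error, NUMT
contamination, strand bias, and indel realignment artifacts.  Passing the
simulation-based checks therefore demonstrates the correctness of the
counting, filtering and scoring machinery under the stated sampling model,
not robustness to alignment pathology in real libraries.

## Problem sizes used by the self-checks

The validation experiments run on scaled-down genomes, chosen so the whole
suite stays interactive while every check retains its statistical meaning:
HF recovery uses a 460-bp circle at 200× with 500 replicates per HF in
{0.05, 0.10, 0.25, 0.50, 0.75, 0.90, 1.00} (error-free, since the h = 1.00
band has zero width and any sequencing error would void it; 15% duplicates
are still injected and removed); oracle equivalence uses 100 random ≤200-read
simulations including indels, errors and duplicates; the consensus
round-trip uses an 800-bp circle with origin-spanning reads at 60×; the
haplogroup fixture is 20 samples from 5 synthetic haplogroups with 10
defining sites each on a 2-kb circle at 80×; the Fisher cross-check is
exhaustive over all 2×2 tables with N ≤ 40 against exact rational
enumeration.

## Known limitations

Indels are not applied to the consensus; no realignment, base-quality
recalibration or strand-bias testing is performed; the haplogroup scorer is
a flat per-site matcher, not a tree traversal; variability and
pathogenicity scores are consumed as inputs, never computed; r×c Fisher
p-values are Monte-Carlo estimates, not exact.
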