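# Methods

## The problem and the decision procedure

A clone library made from a PCR amplicon of mtDNA is a sample of single
template molecules, each carrying whatever errors the polymerase introduced
along its synthesis lineage. Four template classes can contribute: the
individual's genuine mtDNA haplotype, heteroplasmic mtDNA copies, nuclear
mitochondrial pseudogenes (NUMTs) whose primer sites still match, and —
after amplification — Taq-error variants of any of these. `numtriage`
labels each clone by combining three lines of evidence:

1. **Identity to the direct read.** The genuine haplotype is operationally
   the clone haplotype identical (zero differences, indel runs counted as
   single events) to the direct-sequencing read over the shared trimmed
   window. Without a direct read, it is the haplotype shared identically by
   the most clones, requiring multiplicity ≥ `min_genuine_support` (default
   2); ties go to the class with the lexicographically smallest clone id.
2. **Difference counts.** With `d` the number of differences (events mode by
   default: a contiguous indel counts once, because the unit of mutation is
   the event; a columns mode is available) between a clone and its
   individual's genuine haplotype: `d = 0` → genuine; `1 ≤ d ≤ 2` →
   `pcr_error_variant`; `d ≥ 3` → `heteroplasmy` — *provided* the clone is
   in the genuine group. The 2-vs-3 boundary follows from the polymerase
   error burden: at ~10⁻⁴ errors per base per synthesis over 35 cycles a
   ~800 bp clone accumulates ≈ 1.4 errors on average, so 1–2 differences
   are expected from amplification alone while ≥ 3 are not. No upper bound
   is placed on heteroplasmy differences; group membership bounds it.
3. **Grouping.** Clones outside the genuine group are NUMTs. Groups are
   formed from the K2P distance matrix and the NJ tree (below); groups
   beyond the genuine group A are lettered B, C, … by increasing mean
   distance from A.

Stop codons and frameshifts are recorded as evidence but never decide a
label by themselves: a genuine-group clone with a stop is annotated
"pseudogene-like" (a real heteroplasmic copy can carry a stop), and stops in
a divergent group merely corroborate the NUMT call.

## Distances, trees, supports

K2P distances use pairwise deletion: for each sequence pair, columns with a
gap or N in either row are excluded, then `K = -½ ln[(1−2P−Q)√(1−2Q)]` with
`P = transitions/L`, `Q = transversions/L`. Saturated pairs (either log
argument ≤ 0) are *undefined* and carried as flagged NA sentinels — relevant
for control-region NUMTs at tens of percent divergence — and are excluded
from means with the excluded fraction reported.

Neighbor joining uses the standard Q-criterion with a deterministic
tie-break (among minimal-Q pairs, the lexicographically smallest pair of
cluster representative labels), so degenerate matrices yield reproducible
topologies. Negative branch lengths are clamped to zero with the deficit
logged. On additive matrices the implementation recovers topology and path
lengths exactly (property-tested up to 12 taxa). Bootstrap support of an
internal edge is the percentage of column-resampled replicate trees (B =
1000 by default) containing the same leaf bipartition; replicates with
undefined distances are discarded and counted, with a warning above 10 %.

## Group assignment

Single-linkage clustering at a per-region K2P cutoff (defaults: COI 5 %,
12S 1 %, control region 10 %) provides the distance evidence; the NJ tree
provides the clade evidence. The 12S cutoff is deliberately low because
published between-group divergences there reach down to ~1.3 %, overlapping
within-group variation.

The tree rule needed care. Because NUMT lineages branch off the genuine
haplotype itself, the genuine group is in general *paraphyletic*: on the NJ
tree the NUMT branches attach among near-zero-length edges inside the
genuine radiation, and no well-supported clade separates the genuine group
from all NUMTs. Walking up from the anchors' MRCA until a ≥ 60 %-supported
clade is found would therefore balloon the genuine group toward the whole
tree. The implemented rule anchors on the genuine haplotypes plus their
identical supporting clones, takes their MRCA, walks upward only through
poorly supported edges **and only while the absorbed leaves stay within the
single-linkage cutoff of the anchors**, and finally prunes any clade member
beyond that cutoff. Group A is the union of this tree evidence and the
single-linkage group; members supported by only one line of evidence are
flagged in the per-clone notes rather than relabeled, so the conflict is
visible without destabilizing the labels.

## Codon diagnostics

Translation uses the invertebrate mitochondrial code (NCBI table 5: ATA→Met,
TGA→Trp, AGA/AGG→Ser; stops TAA/TAG only), held as an explicit codon map and
verified in the test suite against an independently constructed table over
all 576 single-nucleotide codon changes. The reading frame of a fragment is
inferred as the frame minimizing internal stops (ties to the smallest
offset); genuine haplotypes are expected to reach zero stops. Codon
positions of substitutions are defined on the genuine row's ungapped
coordinates — clone indels never re-frame the genuine sequence — and a gap
run whose length is not a multiple of three marks a frameshift, after which
clone translation is treated as unreliable.

## The peak-mixture model

Direct sequencing reads the weighted sum of all templates. Per alignment
column, each nucleotide's signal is the summed weight of the rows carrying
it; nucleotides at or above a flat detection threshold (default 0.10) form
the peak set, and a column where gapped rows carry ≥ threshold weight is
flagged gap-disrupted (frame slip wrecks the downstream trace). The model is
linear in template fraction with no dye or context effects, because the
mechanism of interest is purely that *shared* alternative bases of several
NUMTs sum to a visible secondary peak while private variants do not.
Base-calling takes the maximum-weight nucleotide, ties broken toward the
heaviest single row and then alphabetically. `numtriage.mixtures` builds a
synthetic 1-genuine + 9-NUMT alignment with an imposed sharing pattern to
demonstrate the mechanism (the deposited trace window is not bundled).

## The synthetic library generator

`simdata` emulates the experiment end to end; its defaults are the study
conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| fragment length | 807 (coding) / 820 (noncoding) | insert size, bp |
| base composition | A .31, C .18, G .17, T .34 | AT-rich invertebrate mtDNA |
| heteroplasmic templates | 2 at weight 0.05 each | 3–10 substitutions from genuine |
| NUMT loci | 3 at weight 0.02 each | target divergence U(0.07, 0.24) coding, U(0.07, 0.70) noncoding |
| NUMT indel rate | 0.001 / 0.005 per site | geometric lengths, mean 2 |
| transition bias κ | 4 | P(transition) = κ/(κ+1) per substitution |
| Taq error rate μ | 1×10⁻⁴ per base per synthesis | documented range 7.2×10⁻⁵–10⁻⁴ |
| cycles | 35 | amplification program |
| clones | 30 | sampled per library |

The genuine sequence is drawn from the base composition with stop codons
resampled (coding case). NUMT substitutions are placed per site with the
Kimura-model forward probabilities `P(d, κ)`, `Q(d, κ)` — the exact inverse
of the K2P formula — so the realized K2P distance of a NUMT is an unbiased
estimate of its drawn target divergence (placing a raw Binomial(L, d) number
of changes would bias K2P upward by ~0.07 at d = 0.24). Coding NUMTs at
divergence ≥ 0.10 are redrawn (up to 100 times) until they contain a
frameshift or internal stop, since an old pseudogene without either would be
biologically implausible. Every mutation is ledgered, and replaying a ledger
against the genuine sequence reproduces the template exactly (tested).

Two amplification models are provided. The **genealogy** model follows an
initial pool of 1000 molecules through the cycles, each molecule copied with
probability = efficiency (default 0.8) per cycle; it tracks exact molecule
*counts* per (template, synthesis depth) state because the pool reaches
~10¹² molecules, then samples clones without replacement and applies
depth-many Binomial(L, μ) error rounds per clone. Sampled lineages are
treated as independent given their depth: coalescent sharing of early-cycle
errors between two sampled clones is ignored, which is negligible when
sampling tens of clones from 1000 founders. The **binomial** model draws
each clone's synthesis depth directly as Binomial(C, ½) — the depth law of a
random final molecule under ideal doubling — giving E[errors/clone] =
L·μ·C/2 ≈ 1.41 at defaults; the two models agree on this mean within 15 % at
efficiency 1.0 (tested) and bracket the truth at lower efficiency. Taq
errors are substitutions only; polymerase indels are rare enough at these
scales that they are not modeled.

All randomness flows from a single seed; identical configurations produce
byte-identical fixtures.

### What the simulation does not capture

No PCR chimeras, cloning-vector artifacts, mixed-colony picks, or
length-biased cloning; heteroplasmic and NUMT templates derive from the
genuine sequence rather than deeper outgroup lineages; template weights are
invented (the experiment observes clone proportions, not template
fractions). Passing recovery tests therefore shows the decision procedure is
correct *given* the mixture model, not that real libraries are this clean —
in particular, real manual alignment editing of highly diverged control-
region groups cannot be reproduced, and distances over such groups should be
read as alignment-sensitive.

## Numerical and design choices

* Alignment parameters default to match +2, mismatch −1, gap open 5, gap
  extend 2 (a one-symbol gap costs open+extend). Within-group fragments are
  > 90 % identical, so results are insensitive here; parameters are exposed
  because highly diverged noncoding NUMTs need gentler gap costs.
  Traceback prefers diagonal, then up, then left, making alignments
  deterministic. Guide-tree distances use 1 − identity with terminal gap
  columns excluded (read-length differences are artifact, not divergence).
* "Manual editing" after automatic alignment is replaced by deterministic
  alignment only; there is no interactive step.
* Primer matching is ungapped Hamming (primers are short; amplification was
  clean); N counts as a mismatch; reference mitogenomes are searched
  circularly only when flagged. Reported amplicon sizes are full product
  lengths including both primer footprints.
* Clones whose insert length deviates > 20 % from the region's expected size
  are excluded up front and listed (the invented threshold is exposed in the
  run configuration), mirroring the discard of wrong-size inserts before
  sequencing.
* Chromatogram weights in the pipeline default to observed per-individual
  clone frequencies — clone counts are the only available proxy for template
  abundance.
* The acceptance script runs ten simulated libraries of 30 clones with
  bootstrap B = 200 and a 10 000-clone binomial error check; these sizes
  give stable rates (recovery is at or near 100 % across seeds) while
  keeping the whole script within a couple of minutes.

## Known limitations

* Group boundaries of real data drawn by eye from published trees are not
  guaranteed to be reproduced exactly, especially where between-group
  divergence overlaps within-group variation (12S) or where alignment of
  ~70 %-diverged noncoding groups is itself uncertain; undefined (saturated)
  K2P pairs force those groups to be ordered last and flagged.
* Heteroplasmy vs polymerase error is a statistical boundary, not a
  biological one; clones from the genuine template with ≥ 3 Taq errors are
  indistinguishable from low-copy heteroplasmy without cDNA evidence, and
  the measured confusion is reported rather than hidden.
* Tree-based and distance-based genuine-group evidence can disagree; the
  per-clone notes record it, and the labels follow the union.
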