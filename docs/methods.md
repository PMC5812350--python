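# Methods

`plastomekit` analyses the structural organisation of plastomes
(chloroplast genomes): the quadripartite LSC/IR/SSC architecture and its
boundary shifts, short inverted-repeat-mediated "flip-flop" inversions and
the resulting coexisting isomeric genome conformations, and gene-order
inversions between related plastomes.  This note records the models,
conventions, parameter choices and known limitations.

## Genome model and coordinate conventions

A plastome is a circular DNA string with strand-aware gene features
(categories PCG / tRNA / rRNA; multi-part features encode introns, intron
count = parts − 1).  All interfaces use 1-based inclusive coordinates, the
GenBank convention, so reported intervals can be compared directly with
deposited records.

The **canonical frame** places the regions as LSC | IR_B | SSC | IR_A along
the forward strand with position 1 the first LSC base after the J_LA
junction.  The four junctions are reported as the last base of the
upstream region: J_LB = LSC end, J_SB = IR_B end, J_SA = SSC end,
J_LA = IR_A end.  Strand orientation is fixed by requiring ndhF to lie in
the SSC nearer J_SB (its usual position in angiosperm plastomes); if ndhF
is unannotated the orientation with the lexicographically smaller sequence
is chosen, which keeps canonicalization deterministic on arbitrary input.

GC% uses only A/C/G/T in the denominator (N carries no compositional
signal) and is rounded half-away-from-zero to one decimal; isomer
frequencies to two decimals, the precisions used in published tables.
Unique gene counts deduplicate IR copies by name; a gene is "in IR" when
any copy's part overlaps either IR; trans-spliced rps12, annotated as
separate features, counts once as a two-intron gene.

## Large-IR detection

The large inverted repeat is found by exact 21-mer seeding between the
sequence and its reverse complement.  A base pairing (p, q) with
seq[p] complementary to seq[q] satisfies p + q = constant, so every repeat
pair lies on one anti-diagonal of the (implicit) match matrix.  Seeds are
grouped by anti-diagonal; on each candidate diagonal the longest exact run
is located and, when mismatch tolerance is enabled, extended to the
maximum of a +1 (match) / −30 (mismatch) score.  This absorbs the sparse
interior mismatches real IR copies occasionally carry while making it
practically impossible for random flanking sequence to extend the repeat
(a net gain would require ≥ 31 consecutive chance matches), so detected
boundaries stay exact on clean data.  A final filter enforces the mismatch
fraction (default 0.001; 0 would reject genuinely imperfect IR copies,
larger values risk false merges).  Circularity is handled by searching the
doubled sequence and rejecting self-overlapping pairs; ties are broken by
the smallest start coordinate.  The shorter gap between the two arms
becomes the SSC.  On genomes of a few kb the procedure is verified
exactly against an exhaustive quadratic dynamic-programming oracle over
all anti-diagonals.

Junction reports give, per junction, the gene spanning it (or the nearest
flanking genes), the bp of a spanning gene inside the IR (interval
intersection of the gene extent with the adjacent IR — this duplicated
portion appears twice in the genome) and which gene end (5′/3′) is
duplicated.  Duplicated lengths are measured on the annotated CDS extent;
whether that includes the stop codon therefore follows the annotation, a
convention the reports inherit rather than impose.

**Boundary shifts** between two genomes are measured per junction as the
displacement of the junction relative to the midpoint of the two nearest
shared single-copy anchor genes on the junction's *single-copy side*.
Anchors inside the IR are deliberately excluded: they move with the
boundary event itself, and mixing IR-side and SC-side anchors halves the
measured shift (verified on planted expansions).  Using two SC-side
anchors keeps the measure robust to indels elsewhere in the genome.
Genes whose IR membership differs between the genomes are listed as
gained/lost at their nearest junction; junctions without usable anchors
are reported as undetermined rather than guessed.

## Short inverted repeats and flip-flop isomers

Flip-flop recombination between a pair of short, perfectly
reverse-complementary arms reverse-complements the segment they bound,
producing two coexisting isomeric arrangements.  Arm discovery reuses the
anti-diagonal machinery with exact matching only: the short arms that
mediate these events (canonically 29 bp, in the 3′ ends of the two trnS
genes) are perfect repeats, and exactness makes maximality well defined.
Defaults: arm length 20–100 bp, bounded segment ≥ 1 kb, arms inside the
large IR excluded (single-copy regions only); nested pairs are suppressed.

The inverted segment is defined arms-inclusive, which preserves the
boundary arms under inversion and makes the operation an involution —
applying it twice restores the genome exactly, a property asserted in the
tests.  Features wholly inside the segment are remapped with flipped
strand; a feature straddling a segment boundary is kept unchanged with a
warning (the planted geometry never produces one: each arm is the shared
3′ end of its anchor gene, so both anchors travel with the segment).

**Junction references.** For a genome in the canonical (IPWC) arrangement
and its flip-flop isomer (IPWI), four references are built — one per arm
per conformation — each W bp of left flank + arm + W bp of right flank,
labelled by the flanking genes (e.g. psbI–trnS-GGA–ycf3).  W defaults to
500 bp: comfortably longer than a short read, so read placement is never
flank-limited, while keeping the references locally unique.  W = 0 is
rejected, since bare arms are identical between conformations.

## Read classification and isomer frequencies

A mate supports a conformation when it aligns ungapped to one of that
conformation's references with ≤ max_mismatch mismatches (default 2) over
the whole read, covering the full arm plus ≥ anchor_bp (default 10)
flanking bases on both sides; both read orientations are tested.  The
10 bp anchor puts the per-side chance-match probability near 4⁻¹⁰.
Ungapped scoring with a mismatch budget suffices because the decisive
signal is flank identity at a fixed offset from the arm; indel handling
would add ambiguity without benefit.  Quality scores are ignored, keeping
the contract independent of any particular mapper.  Mates scoring equally
for both conformations are ambiguous; mates supporting neither are
nonspanning; both are excluded from the frequency denominator, which uses
only conformation-informative reads.  The counting unit is the mate, not
the fragment: a pair whose two mates both span contributes two.

Frequencies are f_IPWI = 100·n_IPWI/(n_IPWI + n_IPWC) (two decimals) with
a Wilson 95% score interval on the IPWI proportion (computed via
statsmodels; tests cross-check it against an exact Clopper–Pearson bound
obtained by direct binomial tail summation).  With the published counts
1,579 vs 15 this yields 99.06% / 0.94%.

Implementation notes: candidate mates are prefiltered by exact q-mer
content of the arms with q = max(4, arm_len // (max_mismatch + 1)); by
pigeonhole a read that aligns within budget always retains one exact
arm q-mer, so the prefilter is lossless.  Scoring then slides the read
over the admissible offsets with vectorised comparisons.  Increasing
max_mismatch never decreases the informative count, and swapping the
conformation labels of the references swaps the pooled counts exactly —
both asserted as properties.

## Gene-order inversion calling

Inversions between two annotated plastomes are called on the signed
permutation of shared unique loci (tRNA loci included — small inversions
can be tRNA-bounded; IR-duplicated genes are represented by their
single-copy-region copy when a quadripartite structure is supplied, and
dropped otherwise).  Maximal runs that are consecutive in both genomes,
reversed in order, and uniformly sign-flipped are emitted one call each,
with the block's reference-order bounds, its bp span in the query
(5′-most to 3′-most coordinate of the outermost block features — an
approximation that does not claim sub-gene breakpoints), and the novel
gene adjacencies created at the block edges.  Annotation-based comparison
replaces sequence-level collinear-block alignment: it is deterministic,
dependency-free, and resolves every inversion class of interest here at
the cost of sub-gene precision.  Every output is self-checked by applying
the called reversals to the permutation and testing for identity; if the
calls do not fully explain the permutation (nested/overlapping events)
they are flagged as complex rather than silently re-ordered — full
sorting-by-reversals reconstruction is out of scope.

**Ortholog end comparison** aligns two coding sequences globally with free
end gaps (match +1, mismatch −1, gap open −5, extend −0.5); the signed
5′/3′ deltas (query − reference) are the differences in unaligned
overhang, and `orf_intact` checks the query CDS for a start codon
(ATG/GTG/TTG), a terminal stop, length divisible by three and no internal
in-frame stop.  This reproduces 5′-truncation measurements of the
accD/matK type.

## Synthetic data

The generators define the test conditions.  Background sequence is i.i.d.
at the requested GC (default 0.36, the observed plastome range being
36.0–36.9%) with no repeat structure beyond what is planted, which keeps
the brute-force oracles valid.  Protein-coding genes are random ORFs
(start codon, no internal stop, terminal stop) so end-comparison logic is
exercisable; real codon usage is not modelled.  The default template is an
~80-feature miniature of the canonical plastid gene order (region sizes
default to LSC 86 kb / IR 26 kb / SSC 18 kb, mid-range of the published
genomes); a compact template supports scaled-down (~40 kb) genomes for
read simulation, where the segment bounded by the trnS-gene arms (~9 kb)
is the scaled analog of the published 38-kb inversion.  IR_A is the exact
reverse complement of IR_B by construction, with genes annotated in both
copies; spacer bases flanking planted repeats are adjusted so chance
complementarity can never extend them, making detected coordinates equal
construction truth exactly.

The short-IR plant writes one arm sequence into the 3′ ends of the two
anchor genes — the left anchor on the minus strand, the right on the plus
strand — so both anchors terminate in the same sequence, the genome
carries it as an inverted repeat, and the bounded segment contains both
anchors entirely, reproducing the observed breakpoint adjacencies.

Paired-end reads: fragments drawn from the IPWI isomer with probability
`ipwi_fraction`, uniform circular start, normal insert (mean 400 bp,
sd 50 bp, clamped at read length — the scale implied by a short-insert
library mapped with a 800 bp insert bound), read length 150 bp, i.i.d.
substitution errors (default 1%), constant quality, no indels or chimeras.
All generators are byte-reproducible under a fixed seed.

## Problem sizes used in the checks

The shipped checks use sizes chosen to exercise each property at
full strength on a desktop: the isomer-recovery experiment runs 20
replicates of 20,000 pairs (~150× coverage of a 40-kb genome, a few
hundred informative junction mates per replicate, so the Wilson interval
is a few percentage points wide); the IR-scan oracle comparison uses 200
(tests) / 100 (acceptance script) random genomes ≤ 5 kb with planted IRs
of 200–800 bp; inversion recovery plants 50 random single-gene-block
reversals on the full template.  Deposited-accession comparisons require
the GenBank records under `data/genbank/` (not redistributed); without
them that check reports failure rather than silently passing.

## What passing tests do and do not show

The synthetic conditions omit several features of real data: structural
heteroplasmy beyond the single modelled flip-flop, dispersed repeats
(which can seed spurious short-IR hits in real genomes), sequencing
error profiles (quality-dependent, indel-containing), coverage bias, and
imperfect annotation.  Passing tests therefore demonstrate correctness of
the algorithms under their stated models — exact planted-truth recovery,
statistical calibration of the frequency estimator, agreement with
independent oracles — not robustness to every artefact of real
sequencing experiments.  One further known discrepancy: published text
ranges and table values for GC content disagree slightly in the source
material (36.0–36.6% vs a tabulated 36.9%); reports here follow the
tabulated convention and the discrepancy is noted rather than resolved in
code.
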