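# Methods

This note documents the models and procedures implemented in `bchrom`,
the parameters that matter with their defaults and rationale, what the
synthetic data do and do not emulate, and the numerical conventions.
Coordinates are 0-based, half-open everywhere; truth tables serialize as
BED, assemblies as AGP 2.1.

## Synthetic genomes

The generator builds an essential A-chromosome complement and one
dispensable, acrocentric B chromosome, with every feature recorded in a
truth table so downstream inference can be scored exactly.

**Repeat library.** Four monomers: a B-specific tandem repeat (150 bp
default), a 180-bp knob repeat, a centromeric satellite (156 bp) and a
short telomeric unit. The B-specific monomer is derived from the knob by
substitution so the two are related but held below 80% global identity
(checked at generation time with the package's own aligner); this mirrors
systems where a chromosome-specific repeat arose from a shared
heterochromatic repeat, and keeps their k-mer separation non-trivial.
Transposable-element templates are LTR retrotransposon archetypes
(~350-bp LTRs flanking a 1.2–2.4-kb internal region). The default of 24
template families keeps family sizes at a few dozen members, the scale at
which family-level summaries (≥ 10 members) are meaningful.

**B chromosome.** Segments follow the fixed order BS, BC, PH, PE,
DH1–DH4, DE with per-segment composition: the short arm and centromere
are dominated by the B-specific repeat interleaved with centromeric
satellite; heterochromatin blocks carry knob arrays (also present on the
A chromosomes); TEs fill each segment to its target fraction so that
overall TE occupancy lands at 0.60 of the B length (the generator's truth
coverage is asserted to 0.60 ± 0.05). Array copies diverge from their
monomer consensus by a per-segment substitution load (1% near the
centromere, 8% for the dispersed distal arrays, so distal satellite
copies are measurably more diverged than centromeric ones). Each TE
insertion draws an age from an exponential distribution (median 0.46 My
by default — used as a simulation default, not a target), mutates the
element by `age x rate` from its template, and mutates the two LTRs
independently by a further `age x rate` each, so the expected pairwise
LTR divergence is `2 x age x rate`. A and B draw from the same template
pool and the same age distribution, reflecting insertion histories shared
between the chromosomes.

**Genes.** A-chromosome genes are random stop-free CDS (100–200 codons).
Each B gene is a copy of a random A donor evolved along a branch of 0.12
proposed substitutions/site with nonsynonymous acceptance 0.6 (relaxed
relative to the purifying defaults used for A-side evolution). The
resulting ~9% divergence matters twice: it plants the relaxed-selection
signal for the Ka/Ks analysis, and it keeps B gene reads from being
subtracted as host-unique during mapping (a read 75 bp long with ~6
expected mismatches to the donor rarely passes the ≤ 2-mismatch host
filter).

**Line panel.** A full-B control, a 0B line, `n_terminal` nested
terminal-deletion lines retaining [0, bp_i) with pairwise-distinct
jittered breakpoints, mini-chromosome lines retaining an interval that
contains the centromere segment entirely, and two dosage variants: one A
segment at 2 copies in a haploid background (disomy) and one at 1 copy in
a diploid background (monosomy). Breakpoint collisions (integer ties) are
redrawn; panels failing distinctness raise.

**Reads.** Single-end reads drawn uniformly from the line's effective
genome (each A segment at its dosage, each retained B interval at the
line's B copy number), defaults 75 bp at 6x coverage, i.i.d. substitution
errors, constant-quality FASTQ. A configurable 5% of reads carries a 3'
poly-G or poly-N tail (overwriting the 3' end, keeping read length
constant) to exercise the trimmer. Reads never span segment boundaries
(pieces are sampled independently), a negligible edge effect at 75 bp vs
30-kb segments. Indels are not simulated: the mapper is substitution-only
by design, and indel errors would add nothing the tests could measure.

## K-mer classification

K-mers are canonicalized (lexicographic min of k-mer and reverse
complement) because reads are unstranded; the default k is 49. A scaffold
is profiled per position against the A index (occurrence counts) and a
B-enriched read index (presence). Positions with A-count ≥ 4 form the
repetitive mask (the threshold echoes the convention that a subsequence
recurring at least four times is repeat-derived; it is configurable).
Classification over non-repetitive positions: label A when ≥ 50% hit the
A index at all (this replaces a whole-scaffold alignment screen with the
same containment decision); otherwise B when ≥ 80% are covered by the
enriched-read index; otherwise ambiguous. Scaffolds shorter than 10 kb
are excluded and reported; scaffolds with no non-repetitive positions are
routed to a separate "repeat-only" report — the satellite-only short-arm
scaffolds of a real B chromosome are the analog, and they are deliberately
left unordered by the mapping stage as well.

## Read mapping engine

A seed-and-verify substitution-only mapper built for bit-exact semantics
at desk scale. Reads are tiled with k-mer blocks (k = 10) covering every
base; the first `m+1` blocks serve as anchors, so a read with ≤ m
mismatches must have at least one exact anchor (pigeonhole) and candidate
generation is complete. Verification compares block codes against
precomputed per-position reference codes: zero mismatching blocks proves
an exact match (blocks cover the read); the count of mismatching blocks
lower-bounds the Hamming distance, so only candidates whose bound falls
within the mismatch budget need a base-level comparison. Alignment counts
are exact (up to a reporting cap, 11 by default, mirroring an aligner
that reports at most 10 placements); uniqueness decisions therefore never
depend on heuristics, and the engine is tested for exact agreement with
an all-positions Hamming-scan oracle, including tandem-repeat references.

## Deficiency mapping

**Preprocessing.** Maximal 3' runs of N and/or G of length ≥ 3 are
removed; reads shorter than 30 bp are dropped.

**Host subtraction.** A read is removed iff it has exactly one alignment
to the A complement with ≤ 2 mismatches. Reads with zero alignments
(B-specific sequence) or several (repeats shared with A) are retained;
the latter end up in masked windows and never distort presence calls.

**Unique placement and windows.** Survivors are placed only where they
match a scaffold exactly and uniquely (both strands, zero mismatches).
Placements are counted in 1-kb windows by their start coordinate. The
repetitive mask for windows is computed over the combined corpus of
scaffolds plus A complement — canonical 31-mers occurring at least
twice — because any stretch duplicated even once can attract reads from
its sister copy, and satellite arrays, knob blocks and young TE copies
cannot receive unique reads regardless of their chromosome of origin.
Placements whose start position is masked are not counted: a read that
maps "uniquely" into a region it did not come from lies entirely within
a duplicated stretch, so its start is masked, while genuinely local
reads also start on the unique sequence around it. Windows ≥ 50% masked,
and tail windows shorter than half a window (too few potential read
starts), are excluded from presence denominators.

**Presence calls.** Covered fraction = informative windows holding at
least `min_count` reads. The operation's default is 1; the pipeline runs
with 3, which separates two regimes cleanly: genuinely retained windows
collect tens of placements at 6x, while "error echo" placements — a
sequencing error that lands exactly on the one site distinguishing two
young TE copies recreates the sister copy verbatim and places uniquely in
the wrong scaffold — arrive one or two per window. Calls: present ≥ 0.9,
absent ≤ 0.1, else partial. The thresholds are declared defaults
(coverage-plot judgment in the original workflow was manual); under the
pipeline's regime the calls are effectively noise-free and the
thresholds only matter for breakpoint-spanning scaffolds.

**Ordering.** Terminal lines retain nested prefixes, so each scaffold's
call vector over terminal lines ordered by retention must be
absent…absent, (partial), present…present — consecutive-ones on a
containment chain. The chain order itself is derived from the calls
(total covered footprint per line), not from panel metadata. Scaffolds
with identical signatures share a bin (flagged unresolved, ordered by
descending length for determinism); bins are ordered by descending
footprint, which places the centromere-proximal bin first. Any call that
violates the chain is surfaced as a conflict and the operation fails
unless forced — conflicts are reported, never silently resolved. Mini
lines confirm bins near the centromere; they carry no ordering
information for distal bins and are not used there.

**Orientation and build.** A scaffold spanning a breakpoint is oriented
by comparing unique-read coverage of its two halves in the line defining
that breakpoint: the covered half faces the retained (centromere-
proximal) side. Halves within a 10% relative margin give orientation
"unknown" (emitted as '+', flagged). Non-spanning scaffolds cannot be
oriented by the panel at all and are marked unknown. Scaffolds are joined
with 100 N (gap handling is a declared choice; the AGP gap rows carry
evidence tag "map"). Verification re-runs the whole read pipeline against
the built pseudomolecule and requires every line's covered informative
windows to form one contiguous block (10% hole tolerance inside the
block); a shuffled layout fails this check.

**Dosage.** Each library's reads are placed uniquely on the A genome;
gene-region counts are normalized per million placed reads and divided by
the haploid control. Per-region ratios are median-centered per library
(dividing by the genome-wide median ratio), the standard CNV practice
that removes the shift a large aberrant segment induces in the library
size itself — material here because the synthetic genome is small
relative to the segment. Segment calls use the median of member regions:
gain ≥ 1.5, loss ≤ 0.66. The dosage experiment uses a genome with denser
gene models (800/Mb of 150–250 codons) and 20x libraries so that the
per-segment median resolves a two-fold change with ~2% standard error;
these are generator-side design choices, fixed before the thresholds are
applied.

## Repeat scanning and nucleosome midpoints

**Monomer scanning** is an iterative greedy search: the best remaining
infix alignment of the consensus (either strand, edit-distance alignment
via edlib with identity = matches / alignment columns — the
alignment-column denominator is stated explicitly since percent identity
is otherwise ambiguous) is accepted if ≥ 70% identity, masked out, and
the search repeats. Hits are non-overlapping by construction.

**Pair merging** accepts the 3'-overlap with the best matches-minus-
mismatches score among overlaps ≥ 10 bp with at most one mismatch per
10 bp; ties prefer the larger overlap. Unmergeable pairs are dropped and
counted.

**Midpoint profiles.** Merged fragments are placed at their best location
on a trimer of the consensus (exact substring search, edit-distance
fallback); the fragment midpoint floor((start+end)/2) modulo the monomer
length is recorded. The offset is invariant to which tandem copy the
fragment is placed on, which is what makes placement ambiguity on a
multimer harmless — asserted by a multi-placement test. Profile mass
equals the number of placed fragments.

**Peaks.** The chip/input ratio (counts per million each, pseudocount on
empty input offsets) is circularly smoothed (5-bp window); local maxima
with prominence ≥ 0.1 of the maximum are ranked by height and split into
major/minor classes by a 1-D 2-means boundary. The smoothing and
prominence values are declared choices; the planted-dyad tests recover
offsets within ±3 bp at n = 10,000 pairs and jitter σ = 5 bp.

**Identity statistics** use Welch's two-sided t test per group pair, with
a guard for zero-variance pairs (flagged, p set to 0 or 1 by mean
equality).

## LTR dating and Ka/Ks

**Families** are single-linkage clusters on pairwise 5'-LTR global
identity ≥ 80% (neither the linkage nor the threshold is canonical;
both are exposed). Clustering is verified against an independent
connected-components oracle.

**Ages.** Equal-length LTR pairs are compared position-by-position; a
minimum-edit alignment is used only for unequal lengths, because optimal
edit alignments occasionally trade clustered substitutions for gap pairs
and deflate the p-distance (a measurable bias at the divergences in
play). JC69 (default) corrects d = -3/4 ln(1 - 4p/3), with saturation
raised at p ≥ 0.75; K2P is available where transition bias matters. Age
T = d / (2r) with r = 1.3e-8 substitutions/site/year, a standard grass
LTR clock — r is a configurable parameter external to any dataset.
Cohort summaries exclude elements above the 99th age percentile and
report per-family A-class and B-class medians side by side. Default
simulated LTR length is 4 kb (the scale of gypsy-superfamily LTRs); at
the median divergence of ~1.2% this keeps per-element age noise small
enough that the cohort median is a stable statistic.

**Codon alignment** translates both CDS (trailing stops and incomplete
codons trimmed; internal stops are errors naming the sequence), aligns
the proteins globally (BLOSUM62, gap open -11, extend -1), and
back-threads nucleotides so every gap is a codon triplet. The alignment
is verified against an independent affine-gap DP oracle by score.

**NG86.** Synonymous site fractions per codon count, for each position,
the fraction of the three single-base changes that preserve the amino
acid; changes to stop codons count as nonsynonymous, so N + S = 3 x
codons exactly. Observed substitutions average over all shortest
mutational paths with equal weights, excluding paths through stop codons
unless every path is blocked. pN and pS receive the Jukes–Cantor
correction; Ka/Ks is undefined (flagged) when Ks = 0, and saturation
(p ≥ 0.75) is flagged with uncorrected values still reported. The
neutral-calibration experiment uses pairs at 2 x 0.075 proposals/site:
deep enough that the ratio's denominator carries tens of synonymous
events (a shallower divergence leaves mean Ka/Ks dominated by small-count
noise in Ks), far from saturation.

**Selection comparison** computes Ka/Ks for B–A, B–outgroup and
A–outgroup per triple and tests Ka/Ks(B,A) > Ka/Ks(A,outgroup) with a
one-sided Wilcoxon signed-rank test, dropping undefined ratios pairwise.

## What the simulations do and do not show

The generator reproduces the *structure* of the inference problems —
nested deletion panels, repeat-masked windows, shared vs specific
repeats, planted divergences and dyads — with exactly known truth, so a
passing test demonstrates that each procedure recovers what it claims
from data of that structure. It does not reproduce real maize k-mer
spectra, real repeat family structure, indel and quality-score error
profiles, assembly artifacts, or biological coverage biases (GC,
mappability); recovery rates here are therefore upper bounds on, not
estimates of, real-data performance. No empirical sequence is bundled;
any real consensus or genome is supplied by the user as FASTA.

## Experiment sizes

The end-to-end mapping experiments use a 2-Mb B chromosome in 20
scaffolds (≥ 10 kb), a 2 x 150-kb A complement, 8 terminal + 2 mini
lines at 6x — sizes at which every pipeline stage, including repeat
multi-mapping and host subtraction, is exercised with realistic
structure while a full 5-seed sweep completes in minutes. The dosage
experiment uses a 2 x 600-kb A complement as described above. These are
the package's standard study conditions; all are keyword parameters.
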