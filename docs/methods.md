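# Methods

## Motif model and scanning

Motifs are degenerate IUPAC consensi, not weight matrices: a position
either matches one of its code's bases or it does not. The shipped set
is the Su(H) transcription-factor consensus `YGTGRGAA` (4 literal
expansions), the proneural A box `RCAGSTG` (4), and the 3' UTR Brd
(`AGCTTTA`), GY (`GTCTTCC`) and K (`TGTGAT`) boxes. Scanning is
exhaustive on both strands via a capturing-lookahead regex, so
overlapping and nested hits are all reported and a palindromic position
yields two hits. Ambiguity characters in the *sequence* (e.g. N runs)
never match, because each pattern position compiles to its explicit
base class. Soft-masked (lowercase) sequence matches by default; a
flag drops hits containing lowercase, since repeat handling is a
data-set-level decision the scanner should not make silently.

Coordinates are 0-based half-open internally and 1-based inclusive in
all written reports (GFF3 convention).

On uniform background the expected both-strand hit count for a motif of
length `m` with `k` expansions on a contig of length `L` is
`2(L−m+1)k/4^m`; for Su(H) on 10 kb this is ≈ 1.22. The test suite and
acceptance script verify the empirical mean against this closed form.

## Pair building and module classification

An SPS is an inverted (opposite-strand, non-overlapping) pair of Su(H)
hits. The spacer counts bases strictly between the two 8-mer
intervals, so the canonical "17 bp separation" means 17 intervening
bases. The default spacer window is 0–30 bp, wide enough to capture
the published 7 and 15 bp variants; any opposite-strand pair counts as
inverted, with convergent/divergent orientation recorded but not
filtered, since head-to-head vs tail-to-tail is not constrained by the
consensus. When one site could join several candidate pairs, a greedy
pass keeps the pair whose spacer is closest to 17 (ties toward the
smaller spacer, then the leftmost pair): one module per locus is the
intended reading of the architecture. Tests pin this rule against a
brute-force double-loop oracle.

A boxes within `max_dist = 500` bp of either pair edge — and within the
same non-coding interval — are attached, making the module SPS+A; the
default is deliberately generous because published censuses count
A boxes 232 bp and 405 bp away as part of the module. A boxes are
accepted on both strands by default (`RCAGSTG` is not its own reverse
complement, so this is the conservative superset; a flag restricts to
the plus strand). The sensitivity of an SPS+A/SPS split to `max_dist`
is reported by `abox_distance_sensitivity`, and on the shipped census
the split moves from 6/5 at 100 bp to 7/4 at 232–500 bp and 8/3 at
1000 bp (a neighbouring module's A box enters) — a caution against
over-reading any single threshold.

The "Y" position is the first base of the motif-oriented site sequence.
It is typed only after a module is assigned to a gene: the gene-upstream
S site is the 5'-most in the gene's reading orientation (left site for a
plus-strand gene). `y_canonical` means T upstream and C downstream.

## Gene context

"Non-coding" means non-CDS: introns remain searchable, which matters
because conserved modules can sit downstream of two genes at once. A
module is assigned to the gene whose start codon is nearest downstream
of it in that gene's orientation; the distance excludes both the module
bases and the start codon itself, matching the "N bp upstream of the
start codon" convention. All genes a module is upstream of are
reported nearest-first, so intergenic modules between divergently
transcribed genes list both neighbours. 3' UTR windows are
transcript-defined when a transcript is available, else the 1000 bp 3'
of the stop codon, truncated at contig ends and flagged, because a
truncated window is weak evidence of box absence.

## UTR organization comparison

The three boxes are mRNA-level miRNA targets, so UTR scanning is
sense-strand-only. Conservation of organization between orthologs is
judged on the ordered strings of box types via longest common
subsequence, ignoring offsets: shared shapes in shared order, not
shared positions. Classes: `identical` (equal, non-empty),
`identical-empty` (both empty — kept distinct because "no boxes in
either species" is itself a conserved state), `none` (no common
subsequence with at least one side non-empty), `partial` (otherwise).
The classification is symmetric under argument swap. With these three
literal motifs, boxes of different types cannot physically overlap
(no suffix of one is a prefix of another), though the scanner would
report overlapping types if given motifs where they can.

## Pairwise conservation

Module cores are extracted with 200 bp flanks and aligned with an
affine-gap global aligner (Needleman–Wunsch/Gotoh via
`Bio.Align.PairwiseAligner`; match +1, mismatch −1, gap open −5
covering the first gap base, extend −1). The original observations
were made with a segment-based aligner, so published identity figures
may differ by a few percent under aligner choice; to bracket the
unstated definition, percent identity is reported both over all
alignment columns (gap columns count against identity) and over
aligned-residue columns only. Among co-optimal alignments the
aligner's first traceback is used; the score is unique, and tests
verify it against an exhaustive alignment enumeration on tiny inputs
and an independent affine recursion up to 8 bp. Conserved blocks are
maximal runs of ≥ k (default 10) identical columns, in
sequence-a coordinates.

## Synthetic data

The generator emulates a multi-gene fly contig: i.i.d. background at
GC 0.40 (fly-like intergenic; configurable), CDS on either strand with
planted start/stop codons, modules planted at controlled spacer,
orientation, Y characters, A-box offsets and upstream distance, and
UTR box strings at controlled offsets. Elements may not overlap each
other or CDS, and an infeasible plan raises rather than silently
shifting. In clean-background mode (default) a rejection pass re-draws
background bases inside any unplanted motif match until none remain, so
planted recall and false-positive counts are exact pipeline properties;
raw mode leaves background matches for power studies, where the module
false-positive rate should track the closed-form motif expectation.

Ortholog pairs are derived by i.i.d. substitution at probability `d`
plus optional geometric-length indels; planted footprints — including
whole pair spans, so spacer lengths survive — are protected by default.
At divergence `d` with no indels, flank identity is binomial with mean
`100(1−d)`, which the acceptance suite checks to within 3 standard
errors over 100 simulated pairs.

What the generator does *not* emulate: substitution-rate heterogeneity,
phylogenetic structure, repeats, compositional skew and real gene
structure (UTR introns, alternative stops). Passing tests therefore
demonstrate correctness of the scanning/classification machinery under
known truth, not performance on real genomic sequence — on real data
the A-box threshold and spacer-window choices dominate the census, which
is why their sensitivity is surfaced explicitly.

The shipped census specs (`data/synthetic_census_*.json`) are synthetic
stand-ins encoding the published 11-gene architecture — 7 SPS+A + 4
SPS (one 15 bp spacer) and UTR strings giving 6/11 identical
organizations including the empty-empty case, with the reported
upstream distances (4970/553/469/338 bp) and A-box offsets (232 bp) —
so the end-to-end counts are forced by construction and verify
plumbing, not discovery.

## Problem sizes and determinism

Default validation sizes — 20 oracle contigs of 5–10 kb, 50 clean
specs, 200 background contigs of 10 kb, 100 ortholog pairs — keep the
whole suite in a few seconds while leaving standard errors small
relative to the 3-SE acceptance bands. Every stochastic step takes an
explicit integer seed (numpy `default_rng`); identical spec + seed
yields byte-identical FASTA/GFF3/truth output, and the CLI exposes the
seed directly.

## Known limitations

- Degenerate-consensus matching has no notion of binding affinity; a
  single mismatch is a non-site. This mirrors the census definition
  but is blunter than PWM scoring.
- The greedy pair rule can re-pair a planted site with a
  divergence-created neighbour whose spacer is nearer 17; on diverged
  (non-clean) sequence, exact recovery of planted pairs is therefore
  not guaranteed — a property of the method, preserved deliberately.
- Module-to-gene assignment uses straight-line genomic distance and
  ignores intervening genes.
- `identical-empty` judgements on truncated UTR windows are flagged but
  not suppressed; callers decide whether absence-of-evidence counts.
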