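# Methods

## Scope and coordinate conventions

All in-memory coordinates are 0-based half-open; GFF3 and the 12-column
hit table keep their native 1-based inclusive convention on disk, BED
stays 0-based half-open. Circular molecules are handled with the doubled
sequence device inside the homology and structure operations; features
that cross the origin are carried with unwrapped coordinates
(`end > length`) and split into two segments wherever a linear tiling is
required. Focal genomes are linearized at offset 0 for reporting.

## Homology engine

The engine is a deliberately small seed-and-extend aligner, because every
downstream operation only needs interval-level homology calls under
explicit identity and E-value thresholds, not full BLAST statistics.

* Seeding: exact `word_size`-mer matches (default 16), found by a numpy
  sort/merge intersection of 2-bit k-mer codes on both strands. Words
  containing N never seed; single-hit seeding (no two-hit heuristic) is
  enough at desk-scale genome sizes.
* Extension: seeds sharing a diagonal are clustered (gaps ≤ 66 nt) and
  extended ungapped in both directions with an x-drop of 20 under the
  scoring scheme +1/−2 with gap open −5, extend −2 per base (megablast-
  like). The extension ends at its maximum-scoring column, never beyond.
* Gapped joining: adjacent hits whose diagonals differ by ≤ 30 and whose
  query/subject gaps are ≤ 50 nt are fused when the join is net positive;
  the diagonal shift is charged as one gap open plus per-base extension,
  and unaligned gap bases count as mismatches in the fused statistics.
* Statistics: identity = matches / alignment span, with N columns never
  counted as matches. Bitscores and E-values use Karlin–Altschul
  statistics with the ungapped nucleotide defaults (K = 0.71, λ = 1.37)
  applied to gapped scores. This is an approximation; the engine's role
  is thresholding at E ≤ 1e−5, where the approximation is immaterial.
  Exact agreement with BLAST output is explicitly a non-goal, but an
  optional pass-through backend (`find_hits_blastn`) shells out to a real
  BLASTN and parses its tabular output into the same hit type for
  cross-checking.
* Determinism: ties are broken by (bitscore desc, alignment length desc,
  subject id, subject start), making hit tables byte-identical across
  runs.
* Oracle: `sw_oracle` is a full Smith–Waterman local alignment
  (Biopython's `PairwiseAligner`, C implementation) under the same
  scoring scheme, guarded to products of lengths ≤ 4·10⁶. The test-suite
  asserts the engine never exceeds the optimum and stays within 10% of it
  on seeded ≥ 90%-identity instances; the oracle is never on a production
  path.

## Five-class partition

Raw homology calls overlap, so a fixed precedence makes the five classes
disjoint: `plastid_like > repetitive > conserved > specific > other`.
Plastid-like comes first because those bases have a known
non-mitochondrial origin regardless of any other homology; the remaining
order runs from the most specific evidence to the residual class. The
thresholds are: plastid-like, identity > 90% versus any supplied
plastome; repetitive, identity > 95% in a self-search with the trivial
self-diagonal removed; conserved, a qualifying hit (E ≤ 1e−5) in every
other supplied family mitogenome (species-level scope; a genus-level
switch exists); specific, the complement of hits against mitogenomes of
other genera, with the species-specific subset additionally available
when congeners are supplied. Per-base labels are painted into a numpy
array in increasing precedence and emitted as maximal equal-label runs,
which guarantees the tiling invariant structurally. The minimum segment
is 1 bp; no smoothing is applied.

Whether specific sequences should be computed before or after masking
plastid-like and repetitive bases is ambiguous in principle; here all
classes are computed independently on the raw sequence and the precedence
resolves conflicts, which keeps each class's definition pure.

## Donor attribution and coverage

"Best match" means the best single hit under the engine's deterministic
tie-break chain, not the best cumulative subject. Hits shorter than
100 bp are treated as no hit; per-order totals above 5 kb form the
display subset; HGT-like requires a best hit strictly longer than
500 bp. Coverage is per-base union coverage of the segment by qualifying
hits (so values cannot exceed 1), not summed hit lengths. Donor records
carry their taxonomic order as metadata — there is no live taxonomy
lookup, which keeps the module offline-testable; a per-order summarizer
(`coverage_by_order`) aggregates the per-segment matrix when a coarser
view is wanted.

## Synteny

Fragmenting uses consecutive non-overlapping windows (default 50 bp,
trailing remainder dropped). Anchoring accepts the best fragment-level
match at ≥ 90% identity over ≥ 80% of the window on either strand,
compared at the best ungapped offset within ±10 nt; ties prefer the
partner nearest the diagonal. Chaining is a native collinear-run scan on
A-ordered anchors — a run continues while the strand is constant and the
partner index advances monotonically (forward or backward) by at most
10 fragments — rather than a shelled-out MCscan; runs shorter than 5
anchors are discarded. Anchor output in the MCscan `.anchors` tab format
is provided so users can cross-check with JCVI. Because anchors are
quantized to the fragment grid, the rearrangement fixture snaps event
boundaries to fragment-length multiples; an off-grid inversion shifts the
frame of the flipped copy and its anchors genuinely dissolve under the
fragments-as-genes device (a known property of the device, not of the
chainer).

## Plastome quadripartite detection

Inverted-repeat pairs are found by a self-search of the doubled circle
restricted to minus-strand hits ≥ `min_ir_len` (default 1000) at
≥ 99.9% identity — real IR copies are rarely perfectly identical, so the
tolerance is above zero but tight. The best pair is extended base by base
in both directions while exact reverse complementarity holds, i.e. the
boundary is the last complementary column. The two single-copy gaps are
named by length (LSC ≥ SSC) and coordinates are rotated so the LSC starts
at 0; the rotation offset is reported. Region lengths are invariant under
rotation of the input circle. Linear input is an error; absence of a
qualifying pair returns `None` (the IR-loss case). SSC strand is reported
as found, with no canonical flip.

## Gene-fission analysis

The reference gene is handled in gene-local coordinates: nt offsets along
the 5′→3′ oriented exon–intron–exon sequence, so position 0 is the first
base of the start codon and frame arithmetic is direct.

* Fragment location: hits of the oriented reference gene against the
  target, merged when collinear and adjacent (reference and target gaps
  each < 100 nt, same strand), labelled FR1, FR2, … by reference order.
  Zero fragments is a result (absent gene), not an error.
* Breakpoints: reference-span gaps between consecutive fragments are
  classified by their midpoint; a gap inside an exon is coding loss,
  reported as floor(nt/3) amino acids, a gap inside the intron is
  reported in nt. The fixture's deleted span is 129 nt = 43 codons,
  matching the inclusive codon count of the deleted reference positions.
  Fragments overlapping on the reference by more than one seed word
  indicate an inconsistent layout and raise.
* FR2–FR3 gap: "adjacent" requires the same orientation, FR3 downstream
  of FR2 in gene orientation, and at most 10 kb between them (the
  configurable `max_adjacent_gap`); the insertion length is that gap and
  its plastid content reuses the partition rule (> 90% identity vs the
  supplied plastomes). Anything else is "separated".
* Expansions: the FR1-side expansion counts complete in-frame codons from
  the break to the first stop (exclusive), within a 3,000 nt scan window;
  no stop flags the scan unresolved. The FR2-side expansion walks
  upstream codon by codon to the first in-frame ATG; a stop encountered
  first makes the expansion unresolved, since no upstream start could
  read through it — this also guarantees reported expansions translate
  cleanly up to their boundary. A FR1-side stop within 30 codons
  (configurable) is additionally flagged as a truncation back to the
  breakpoint, the nonsense-mutation signature; the count itself is
  reported either way.
* Translation uses the standard genetic code (plant mitochondria use it).
  RNA editing is not modelled; this matters for editing-dense genes but
  not for the expansion scans this module performs, and is listed as a
  limitation.
* Gene status: pseudo on premature internal stop, length change not
  divisible by 3, or truncation beyond 20% of the reference protein;
  missing when there is no sequence or (if a reference CDS is supplied)
  no homology at permissive settings; intact otherwise.
* Splicing call: E = median depth over the exonic bases of FR2 and FR3,
  I = median depth over a window (default 1 kb) immediately 3′ of FR2 on
  the intron side. Call trans when I < 50 and E > 400; cis when
  I ≥ 0.5·E; ambiguous otherwise, and always ambiguous when E < 50 — a
  minimum-signal guard, since depth ratios below the low-coverage
  threshold support no call in either direction. The 50/400 defaults and
  the 0.5 ratio are declared heuristics, all configurable.
* Binding window: the reference 48-nt intron window is aligned to the
  target with edlib. Preserved requires a full-length, indel-free match
  within a 15% edit budget. Otherwise the two window halves are located
  independently and the bases between them measure the internal
  insertion; if the halves cannot be placed, the window is disrupted with
  no length. The two-anchor construction is used because a global edit
  path around a long insertion is free to trade the gap for scattered
  matches inside the insert, corrupting the length estimate.

## Synthetic data

`simulate_family` grows each genome from one ancestral random core
(default 50 kb) mutated independently per branch of a star topology at
2% substitutions, then interleaves planted features at random cut points:
plastome-window copies (~10% of the genome), dispersed repeat pairs
(~5%), donor-derived specific segments (~15%, drawn from disjoint windows
of per-order donor genomes), and blocks shared with exactly one genome of
another genus (~5%, the planted "other" class). Indel rate defaults to 0;
indel tolerance of the engine is exercised separately. The truth table
records every planted interval with its class and donor order; truth
intervals tile each genome by construction. A deliberately skewed
configuration (one species loaded with donor segments) reproduces the
inflated-mitogenome scenario with a ~2× size ratio.

`simulate_fission_fixture` builds a 2,526 nt reference gene (720 nt
exon 1, 1,200 nt intron with a 48-nt binding window at intron offset
780–828, 606 nt exon 2) and plants the preset layouts: the first break
deletes coding nt 489–618 (codons 164–206, 43 aa); the intron break at
gene-local 1320 loses no bases; the adjacent layouts carry a 3,500 bp
(or 1,300 bp) insertion whose plastid part is an exact plastome window;
the separated layouts put 15 kb between FR2 and FR3; the binding-window
insert (28 bp) sits at the window midpoint so both halves stay
measurable; expansion presets place the first in-frame stop exactly 185
codons past FR1 (or a nonsense codon at +10) and the nearest usable
in-frame ATG 118 codons before FR2, with the intervening codons free of
stops and ATGs.

Junction sanitization: the two target bases flanking every planted
fragment are forced to differ from the corresponding reference
continuation (likewise plastome-copy edges inside insertions, and the
IR-flanking bases of the quadripartite fixture, which must break reverse
complementarity). Without this, chance continuation (P = 1/4 per base)
lets maximal extension run past the planted boundary and the exact worked
numbers would only hold approximately. This is a property of any
maximal-extension definition of a boundary, not of the implementation.

Coverage profiles are Poisson: mean `base_depth` (default 500) over
expressed intervals, mean 10 (trans-like) or 0.8·base (cis-like) over the
intron-side gaps, mean 2 background.

What the generator does not emulate: recombination-driven structural
dynamics, transition/transversion bias (irrelevant to identity-threshold
logic), sequencing error, real intergenic composition, and RNA-editing.
Passing tests therefore demonstrate correctness of the interval logic,
threshold semantics, and coordinate arithmetic under realistic divergence
levels — not performance on raw reads or heavily rearranged natural
genomes.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: 50 kb cores (~75 kb
genomes), six-genome families, fixtures of 8–22 kb, chosen so the full
suite completes in about a minute on one CPU while all layout-defining
offsets (489/618, 1320, 3,500/2,800, 1,300, 185, 118, 48, 28) are
preserved absolutely regardless of scale. Random number streams are
`numpy.random.default_rng` seeded per genome via `SeedSequence`, so
identical configs and seeds give byte-identical FASTA output.
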