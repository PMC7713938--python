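# Methods

This note documents the models and conventions behind mitokit's statistics,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Coordinates and circularity

All coordinates are 1-based, fully closed intervals on the H (heavy)
strand, matching the convention of published mitogenome annotation tables.
The genome is a circle whose origin is wherever the annotation puts
position 1 (for the shipped reference annotation, the start of trnL2). A
feature spanning the origin carries an explicit `wraps_origin` flag rather
than being inferred from `end < start`; its length is
`genome_length − start + 1 + end`. L-strand features are stored by their
H-strand footprint and extracted as the reverse complement.

## Composition and skew

AT-skew = (A−T)/(A+T), GC-skew = (G−C)/(G+C), computed over unambiguous
bases only (IUPAC ambiguity codes are excluded from every denominator).
A zero denominator is reported as skew 0.0 with an explicit
`*_skew_defined = False` flag instead of raising: a caller summarizing many
windows should not crash on an AT-only window. Codon-position composition
pools positions 1/2/3 across all complete codons; the 1–2 trailing bases of
frames whose length is not a multiple of 3 are excluded.

Printed-table parity: reports round half away from zero to 2 decimals
(1.625 → 1.63); internal values keep full precision. This is the rounding
that reproduces the published codon-usage column exactly.

## Codon usage and RSCU

The genetic code is fixed to the vertebrate mitochondrial code (NCBI table
2): AUA encodes Met, UGA encodes Trp, and AGA/AGG join UAA/UAG in a
four-codon stop family, giving a six-codon Ser family (UCN + AGU/AGC).
RSCU(c) = count(c) × |family| / Σ_family counts, so within every family
with nonzero total the values sum to the family size (mean 1). Zero-count
families get RSCU 0 for all members plus a flag, not NaN. Stop codons are
counted when complete; a CDS whose length is ≡ 1 or 2 (mod 3) contributes
no terminal codon and increments an `incomplete_stops` counter — these are
the "T--"/"TA-" frames completed to UAA by polyadenylation of the
transcript. Frequency rankings break count ties by codon lexicographic
order; percentages are percent of total codons, 2 decimals.

## Circular layout

For adjacent features the signed spacer is
`downstream.start − upstream.end − 1`; n features yield n boundary entries,
the last closing the circle. Features with identical starts are ordered
longer-first (an arbitrary but documented tie-break). Summaries
(gap/overlap counts, totals, ranges) are always recomputed from
coordinates; a published intergenic column can additionally be summarized
directly ("column mode") or compared cell-by-cell against the computed
spacers, in which case disagreements are returned as flags. For the shipped
reference annotation exactly two printed cells disagree with the printed
coordinates (trnL1: 6 printed vs 3 computed; ATP8: −23 printed vs −7
computed); the package reports the coordinate-derived values and surfaces
both flags.

## Control-region model

The tandem-repeat detector implements an exact-match model: for each
candidate period p (default 5–400 nt) it extends runs where
`seq[i] == seq[i−p]`; a maximal run yields an array whose unit is its first
p bases (leftmost phase). Arrays below `min_total_copies` (default 1.8,
span/period) are discarded. When one span is explained by several periods
(p and a multiple of p), the smallest period wins: an array contained in an
equal-or-longer one whose period divides its own is pruned. Copy number is
span/period rounded (half away from zero) to 1 decimal, and arrays render
in the "F × P+r" notation of published control-region tables. Intra-array
mutations (fuzzy repeats) are out of scope for this version; the shipped
reference arrays are exactly representable under this model.

Conserved-motif search is a sliding Hamming scan on the H strand against a
shipped library of TAS, OH and CSB-1/2/3 sequences from six ranid species;
the per-motif budget is `floor(frac × motif length)` with frac default 0.2.
Overlapping same-motif hits are reduced to local minima (a hit survives
unless an overlapping hit has strictly fewer mismatches), so a zero budget
degenerates to exact substring search; the best hit per motif is flagged.

## Gene orders and TDRL

Orders are circular sequences of signed tokens over a 39-symbol canonical
alphabet (13 PCGs, 22 anticodon-qualified tRNAs, 2 rRNAs, CR, OL) plus NCR.
Rotations compare equal; reflections do not (the strands are biologically
distinct). Display anchors rotate to trnF when present, else 12S — stable
across all ten shipped arrangement types (one of which lacks trnF). NCR
tokens are ignored by breakpoint distance and type classification unless a
type signature names them, since minor noncoding regions are
annotation-dependent.

Breakpoint distance counts circular adjacencies (ordered neighbor pairs
with strand) present in one order but absent from the other, after dropping
tokens private to either order; on equal multisets it is symmetric. The
diff against a reference reports lost genes (no functional copy),
duplications (≥2 functional copies), pseudogenes, and a translocated set
found greedily: repeatedly remove the token whose removal repairs the most
broken adjacencies until the adjacency multisets agree. Greedy ties — an
adjacent exchange is explainable by either partner — prefer the mobile
non-gene elements (OL/CR/NCR), which are the elements that translocate most
often in ranid genomes.

Arrangement types I–X are structural predicates (segment containment,
pseudogene flags, copy counts, losses) evaluated in fixed order after an
exact reference check; type IX (trnP/trnF loss) additionally requires the
truncated trnL2–trnT cluster so that rearranged duplicated-CR segments are
not misattributed to it.

A TDRL event duplicates a contiguous block in tandem and keeps, per gene,
the first or the second copy ("both" allowed only for CR/NCR class tokens,
mirroring the observed duplicate-CR genomes). The search is exhaustive
brute force over all O(n²) blocks; for each block the target is aligned
against the duplicated string and every consistent kept-assignment is
enumerated by backtracking — correctness over speed, which is ample at the
≤40-token scale of mitogenomes. Scenarios are returned shortest-block
first. Up to two events are supported by composing single-event searches;
the two-event path enumerates all events of the intermediate order and is
intended for short orders only.

## Synthetic-data generator

Defaults reproduce the study conditions of the reference genome: the
40-feature plan uses the published lengths, strands, start/stop codons and
coordinate-derived signed spacers (so the genome is 20,120 bp with a
4,210 bp control region and 3,755 PCG codons), background composition
A 27.29% / T 28.85% / C 28.87% / G 15.00%, and a control region carrying
the published 5′ 18 × 38+36 array, the TAS/OH/CSB1/CSB3/CSB2 motifs and the
published 3′ arrays, separated by random spacers of 30–80 nt.

CDS are sampled codon-by-codon: amino acids from a configurable weight
vector (uniform by default), codons within each family from per-codon
weights whose normalized values are the target RSCU; stop conventions
(complete or incomplete T--/TA-) follow the plan. Features are placed to
realize the planned spacers exactly; where features overlap, the
later-placed feature's bases win, and the recorded ground-truth codon usage
is measured from the emitted genome, so it stays consistent by
construction.

Background screening: spacer and padding segments are resampled until the
detector reports no tandem array of span ≥ 20 nt in them. Shorter chance
micro-repeats (e.g. a 2 × 5 array) arise roughly once per kilobase in any
AT-rich random sequence and are left in place — screening them out is
statistically impossible and unnecessary, since recovery tests identify
planted arrays by period and span. Spacer bases abutting a planted array
are additionally constrained not to continue its period, so the detector
recovers each planted array's exact span. Planted-array property tests keep
planted spans ≥ 25 nt (above the micro-repeat regime) and reject degenerate
units whose minimal period is a proper divisor of the planted period, in
which case the detector would — correctly — report the divisor.

What the generator does not emulate: substitution or indel processes,
fuzzy/diverged repeat copies, tRNA secondary structure, realistic
inter-gene sequence dependence, or evolution along a phylogeny. Passing
recovery tests therefore shows the analysis stages invert the generative
model exactly; it does not show robustness to mutational noise in real
data.

## Problem sizes and determinism

All analyses run in seconds at mitogenome scale (20 kb genomes, ≤40-token
orders). Parameter-recovery tests sample 60k–120k codons, where the
binomial sampling error of RSCU is well inside the ±0.1 acceptance band
used; whole-genome simulation plus full repeat detection takes well under a
second. Every stochastic path is driven by a single integer-seeded NumPy
generator: fixed seed, byte-identical outputs.

## Known limitations

- The repeat model is exact-match; diverged repeat copies in real control
  regions fragment into multiple reported arrays.
- The greedy translocation set is a heuristic minimal set, not a provably
  minimal one; adjacent exchanges are attributed by the tie-break above.
- Type signatures I–X encode the shipped survey's vocabulary; novel
  arrangements classify as "unknown" rather than being force-fitted.
- GenBank parsing covers the flat-file subset mitogenome submissions use
  (LOCUS length; CDS/tRNA/rRNA/D-loop/rep_origin/misc_feature features);
  it is not a general-purpose GenBank reader.
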