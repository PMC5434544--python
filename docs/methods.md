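# Methods

## SD/aSD pairing and D_toStart

The anti-SD tail is stored 5′→3′ (default: the 13 nt *E. coli* tail
`GAUCACCUCCUUA`) with sites numbered from the 3′ terminus: site 1 is the
3′-terminal base, so the heavily used `UCCUC` run occupies sites 3–7. A
match of length L places upstream-window positions `p..p+L−1` against tail
sites `a..a+L−1` (antiparallel, so ascending site number tracks ascending
mRNA position); the SD motif is reported in the RNA alphabet on the mRNA
sense strand.

The scanner reports every *maximal* ungapped run of Watson–Crick pairs
(G:U wobble behind a flag, off by default; IUPAC ambiguity codes never
pair) with length ≥ `min_len` (default 4, window default 20 nt). Maximality
is per diagonal: no reported match is a sub-run of another at the same
window/tail offset. A consequence worth knowing: a 4-mer motif embedded in
context that extends its pairing is reported as the longer run (e.g. `GAGG`
followed by a U that pairs tail site 9 is reported as `GAGGU`); a, spacer
geometry and D_toStart are unaffected by 3′-side extension.

D_toStart extends the duplex `a−1` positions in the mRNA 5′ direction to
find the mRNA position opposite the rRNA 3′ terminus and measures from
there to the first base of the start codon:

    D_toStart = (U + 1) − p + (a − 1) = L + spacer + (a − 1).

If the projected position falls before the window start the match is
flagged but still reported. This convention is fixed by requiring the
canonical AGGA/spacer-7 geometry (a = 3) to give D_toStart = 13.

Genome-wide summaries count **one SD per gene**: the longest match, ties
broken by proximity to the start codon (largest p), then by smallest tail
site a. The rule is a deliberate design choice — the longest duplex is the
strongest, and proximity mimics optimal positioning — and is deterministic;
all matches are retained in the per-gene table for users who prefer other
selections. Genes whose window is shorter than `min_len` count as scanned
but cannot match.

## I_TE and CAI

Weights are computed within synonymous-codon families:

    r_i = (H_i + c) / (B_i + c),   w_i = r_i / max_{j∈family} r_j,

with HEG counts H, background counts B, pseudocount c (default 0.5,
standard CAI practice for zero counts). The gene score is the geometric
mean of w over countable codons. Exclusions: the first codon (initiation,
not elongation), stop codons, single-codon families (ATG, TGG in the
bacterial code), and codons containing ambiguity characters. With a uniform
background the weights reduce to `(H_i + c)/max(H_j + c)` and I_TE equals
CAI to full floating precision — the ratio-then-normalise form is the
minimal one with both properties (mutation-bias correction; exact CAI
reduction), which is why it was adopted.

Note on pseudocounts: an additive pseudocount on raw counts means weights
are not exactly invariant to rescaling both usage tables by a constant;
the effect is `O(c/count)` and negligible for real tables (counts in the
thousands). Invariance is exact at c = 0, which requires strictly positive
counts.

Family partitions (bacterial code 11 by default, any NCBI table supported):

* **box** (default): synonyms grouped by their first two bases, which splits
  six-fold families (Leu, Ser, Arg) into a four-codon and a two-codon family
  read by different tRNAs, and leaves smaller families intact; compound
  eight-fold families in other codes split the same way.
* **ry**: box families further split into purine-ending (A/G) and
  pyrimidine-ending (C/T) halves — Gly becomes {GGA,GGG} + {GGC,GGT}. The
  split is applied after the box split so families never mix tRNA boxes.
* **lump**: one family per amino acid.
* **r-only**: box families restricted to their R-ending codons (Ala →
  {GCA,GCG}); Y-ending codons are not countable. Useful where bias is
  strong among R-ending but weak among Y-ending codons.

The default background when none is supplied is the whole-input codon
usage; `uniform` gives CAI. Usage tables are read from EMBOSS `.cut` files
(codon + trailing count column) or counted from CDS FASTA.

## Folding profiles

The built-in engine maximizes weighted nested base pairs by dynamic
programming: pair scores GC = −3, AU = −2, GU = −1 (arbitrary units,
configurable), minimum hairpin loop 3, ambiguity codes unpairable. It is
*not* a thermodynamic nearest-neighbour model; it was chosen because it is
self-contained and exactly verifiable against brute-force enumeration of
all nested structures, which suffices for profile shapes. Ties in the
traceback are resolved by pairing the 5′-most base with its 5′-most optimal
partner, making structures deterministic; scores are unaffected. The
`ViennaRNAEngine` plug-in satisfies the same contract and returns kcal/mol;
profiles record which engine produced them. The DP fill is numba-compiled
on first use.

Regions are anchored so the start codon occupies sites 101–103 (last 100 nt
of upstream flank + first 100 nt of CDS) and the stop codon sites 98–100
(last 100 nt of CDS + first 100 nt downstream); the 100+100 spans are
chosen to honour those anchor sites. Genes too short for a span are dropped
and counted. Callers should pre-filter to intergenic distances ≥ 100 nt so
a neighbour's signal does not confound the profile. Each 40 nt window's
score is assigned to its 5′ start position (configurable step); per-class
mean/sd/n are computed per position. HEG/LEG classes come from a
user-supplied list or, failing that, from I_TE ranking (top/bottom N) — an
index-based fallback, not expression evidence.

## Simulator

The simulator plants the three signals the profiling stages detect:

* **SD windows**: the motif is placed at the requested spacer inside each
  20 nt upstream window; rejection sampling (capped at 1000 attempts per
  gene, then re-drawn with a warning) regenerates the random filler until
  the scanner finds exactly the planted duplex, so fixtures contain no
  accidental complementary runs ≥ min_len. Motifs that are not reverse
  complements of a tail substring are rejected up front.
* **codon bias**: each codon position draws a countable family uniformly,
  then the family-optimal codon with probability b, otherwise a uniform
  family member. The optimal codon per family is a fixed deterministic
  choice (or the argmax of a supplied usage table). b = 1 gives I_TE = 1
  by construction; graded b values give a recoverable ranking.
* **hairpins**: GC-only stems with A-only loops, which are unambiguously
  pairable against the A/C-only "unstructured" stretches used around
  anchors (A and C cannot pair with each other under WC+GU rules). The
  folding fixture places a stem-loop and a G-tract in the upstream flank,
  keeps sites 91–139 of the start region A/C-only, and plants a stem-loop
  at a configurable offset (default 30 nt) past the stop.

Genes alternate over both strands with intergenic gaps ≥ 150 nt by default
(comfortably above the 100 nt profiling filter). One seeded
`numpy.random.Generator` drives all draws; the same seed reproduces files
byte-identically. The simulator emulates signals, not genomes: intergenic
composition is i.i.d., there is no operon structure or leaderless gene, and
codon bias is position-independent — so passing tests demonstrate correct
signal recovery, not realism of real-genome summaries.

## Problem sizes and tolerances

Default verification sizes, chosen to make every check run in seconds on
one CPU while leaving no stochastic margin to chance: scanner-vs-oracle on
1000 random 20–30 nt windows (exact set equality); planted-spacing recovery
on 60-gene genomes (exact); CAI≡I_TE on 100 genes (bitwise); bias-rank
recovery with 200 genes × 300 codons (Spearman ρ > 0.95; observed ≈ 0.99);
folding-vs-enumeration on 300 sequences of length ≤ 12 (exact); profile
shapes on 40 genes (peak within sites 91–113, trough past site 100).
Floating comparisons elsewhere use relative tolerance 1e-12; the traceback
uses an absolute tie tolerance of 1e-9 on integer-valued scores.

## Known limitations

* The scanner models ungapped duplexes only; bulged SDs are out of scope.
* The built-in folding scores are not free energies; compare shapes, not
  magnitudes, across engines.
* Real-genome summary values depend on the annotation release used; the
  toolkit treats genome choice as user input and ships no genome data.
* Leaderless transcripts (no SD) simply appear as genes without matches.
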