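# Methods

## The mismatch map

A feature-barcode whitelist is a set of n designed DNA sequences of common
length L over {A,C,G,T}. The mismatch map expands each barcode into itself
plus its 3L single-substitution variants, every entry labelled with its
parent. Assignment of a read then reduces to exact lookup of read windows,
and summing counts per parent label performs 1-substitution error
correction. This is exactly the behaviour a k-mer index built over such an
expanded FASTA induces when k equals the tag length, which is why window
length = L is the only scanning choice made here: it reproduces the
mismatch-index semantics without building an actual de Bruijn graph.

Collisions arise whenever two barcodes are within Hamming distance 2:

* a parent's **exact sequence always wins** — it maps to its own parent even
  if it lies in another parent's distance-1 neighbourhood (the other
  parent's claim is recorded in `exact_collisions`);
* a variant generated by **two or more parents is dropped entirely**
  (`ambiguous_variants`), mirroring the observable effect of a multi-mapping
  read being discarded.

This is deliberately conservative: a colliding variant could be assigned by
majority abundance, but that would make assignment depend on the dataset
rather than the design. A warning is emitted at map-build time for any
parent pair at distance ≤ 2, since such pairs are guaranteed to lose
variants. For any pair at distance ≥ 3 the distance-1 neighbourhoods are
disjoint (triangle inequality) and nothing is lost — this is the design
criterion the QC module's warnings push users toward.

Variants are substitutions only; indels are out of scope, consistent with a
1-mismatch correction model. Variant order is deterministic (position-major,
then alphabetical substitute base) so the serialized mismatch FASTA is
byte-reproducible; headers are `>{parent}` and `>{parent}-{pos}.{base}` with
0-based positions.

## Quantification pipeline

Per read pair: slice cell barcode and UMI out of read 1 (0-based half-open
spans), optionally correct the cell barcode against an on-list (exact match,
else the unique on-list member at distance 1, else discard — the standard
droplet-chemistry correction), trim the tag read (anchor first: first exact
occurrence, keep the named flank, discard reads without it; then fixed
5′/3′ trimming), and look up every length-L window of what remains.

Classification is exhaustive: exactly one distinct parent across all
matching windows → assigned; ≥ 2 parents → ambiguous (discarded); none →
unassigned. Within the assigned parent an exact-sequence window is
preferred over a variant window (n_mismatches 0 vs 1), and the leftmost
qualifying window supplies the reported offset — deterministic, and
consistent with the designed tag position being the real one. Windows
containing non-ACGT characters never match. Reverse-complement scanning is
off by default (tag orientation is known in the assays this serves) and
enabled per layout. Quality strings are ignored: the method uses sequence
only.

UMI deduplication collapses identical (cell, UMI, feature) triples; a
(cell, UMI) pair seen with two distinct features is dropped entirely rather
than majority-voted — conservative, order-independent, and therefore
permutation-invariant. Cell barcodes containing N are discarded (they
cannot be corrected); UMIs keep N verbatim and deduplicate as literal
strings. Matrix rows are lexicographically sorted cell barcodes, columns
are whitelist-ordered features; output is MatrixMarket coordinate integer
with 1-based indices plus `barcodes.txt`/`features.txt`, and a
`run_info.json` carrying seven counters (pairs read, two discard classes,
unassigned, ambiguous, assigned, UMIs after dedup) that satisfy the
conservation identity: the five disposition counters sum to pairs read.

## Barcode-design QC

* **Diversity**: the number of usable length-L barcodes under a minimum
  pairwise distance d is bracketed by two classical bounds, both computed in
  exact integer arithmetic — Singleton 4^(L−d+1) and sphere-packing
  ⌊4^L / Σ_{i≤t} C(L,i)·3^i⌋ with t = ⌊(d−1)/2⌋. Whether a published
  diversity curve is a bound or a constructed code size is ambiguous in
  general; both are reported, and tests verify each dominates greedily
  constructed codes at small L.
* **Shared substrings**: contiguous length-k substrings occurring in ≥ 2
  barcodes; the ambiguous-barcode count is non-increasing in k and reaches 0
  at k = L for any valid (duplicate-free) whitelist. "Subsequence" is used
  in the contiguous sense throughout; non-contiguous subsequences are out of
  scope.
* **Hamming histograms**: all unordered equal-length pairs, plus the same
  against reverse complements. A barcode versus its own reverse complement
  is reported separately per barcode rather than pooled, since the pooled
  histogram would otherwise mix self- and cross-pairs. Ragged whitelists
  skip unequal-length pairs and count them explicitly.
* **Homopolymers**: maximal runs ≥ a threshold (default 2); a length-5 run
  is one event of length 5, not nested shorter events.
* **Per-position content**: base fractions among the barcodes long enough to
  cover each position; each row sums to 1.

Report warnings flag minimum pairwise distance ≤ 2 and shared substrings of
length ≥ L−1. Histogram keys are stringified so the JSON report is a fixed
point of a serialization round trip.

## Error simulation

Each simulated read draws a parent (uniform by default; a weight vector is
accepted), substitutes every base independently with probability p
(uniformly over the three alternatives), and is looked up whole — no
windowing — in the mismatch map. Outcomes: correct, misassigned (lookup
returns a different parent), or lost (no lookup: unassigned or dropped-as-
ambiguous). Lost and misassigned are tracked separately because their design
remedies differ (length/diversity vs pairwise distance); their sum is the
classical "lost barcodes" figure. For a single isolated barcode,

    P(correct) = (1 − p)^L + L·p·(1 − p)^(L−1),

the binomial probability of at most one substitution; the suite requires
simulated survival to match this within 4 standard errors at n = 100 000
for p ∈ {0.005, 0.01, 0.05} and L ∈ {8, 15}. Two consequences worth noting:
at fixed per-base p, *longer* barcodes suffer more multi-substitution losses
(the binomial term grows with L), while *shorter* barcodes at realistic set
sizes suffer diversity-driven losses — mutated reads landing on removed or
foreign variants. The suite therefore tests the short-barcode penalty as
loss **in excess of** the closed-form binomial loss, which isolates the
crowding effect from read-length error accumulation. Sweep seeds are
`(master_seed + rate_index) mod 2^31`, making sweeps reproducible and
parallelizable.

## Fixture generator

The generator emulates the read structure of droplet feature-barcode
libraries: R1 = cell barcode + UMI (defaults 16 + 12 bp, the common v3
droplet geometry) plus optional filler; R2 = 5′ filler + tag + 3′ filler,
with the tag at a fixed or uniformly random offset, substitution errors at a
configurable per-base rate confined to the tag region, and optional PCR
duplicates (each molecule emitted multiple times with identical cell/UMI/
tag). Cell barcodes are drawn at pairwise distance ≥ 2 by rejection. A TSV
truth table records every read's cell, UMI, parent, injected substitution
count and offset. Output is byte-deterministic per seed (gzip members are
written with a zero mtime).

What the generator does **not** emulate: quality-score-correlated errors,
indels, adapter read-through, abundance skew between features, doublets, or
ambient contamination. Tests passing on these fixtures therefore validate
the assignment/counting logic and its error-correction semantics, not
robustness to every artefact of real libraries.

A note on filler: with a random-composition filler, a filler-spanning window
can by chance fall within distance 1 of a *different* parent and render a
read ambiguous (at a rate of roughly (3L+1)/4^L per window per foreign
parent). Tests that require exact truth recovery therefore use a
homopolymer filler (`filler_base="A"`, mirroring the poly-A flanks of real
sample-multiplexing libraries) with a whitelist verified to produce no
cross-parent windows at error 0 at any offset; tests with random filler
assert conservation and invariance properties instead of exact recovery.

## Problem sizes and numerical choices

The exhaustive mismatch-map oracle checks every sequence of length L against
brute-force distance-1 neighbourhoods for whitelists up to L = 6 (4^6
lookups per case); the scan oracle covers 10 000 random reads over random
whitelists with n ≤ 8, L ≤ 8; simulations run at n = 100 000 reads with a
4-standard-error acceptance band on the closed form. These sizes give
sub-minute suites while keeping the exhaustive checks genuinely exhaustive.
All integer QC formulas avoid floating point entirely. Degenerate inputs are
errors, not silent fixes: empty whitelists, duplicate ids or sequences,
non-ACGT characters (including N and lowercase), ragged whitelists where
uniformity is required, and d outside [1, L].

## Synthetic stand-in barcode sets

`tagquant.synthetic_sets` builds two deterministic, clearly synthetic sets
used by the acceptance script and tests: a 96 × 8 bp sample-barcode set in
which exactly one pair (labelled BC49/BC74 after the published pair whose
clash structure it emulates) shares a 7-bp substring, and a 90 × 20 bp
sgRNA-style set in which EZR-1/EZR-2 and PPIB-2/PPIB-1 each share a 16-bp
substring (with EZR-2 and PPIB-1 beginning GCG and GGA). Construction
rejects any unintended clash at the engineered length, so a QC sweep flags
exactly the designed pairs. These are not the real assay sequences; they
reproduce the documented design pathology so the QC metrics can be
exercised end to end.
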