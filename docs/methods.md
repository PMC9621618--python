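# Methods

## The motif model

A heat shock element (HSE) is the binding site of heat shock
transcription factors. Its building block is the pentanucleotide unit
5'-nGAAn-3' or its exact reverse complement 5'-nTTCn-3': offsets 2–4
carry the fixed core (GAA or TTC), offsets 1 and 5 are free. An HSE is a
run of at least three contiguous, non-overlapping units read left to
right with period 5. Two classes are recognised:

* **typical** — zero core mismatches across the whole run;
* **varied** — exactly one core mismatch across the whole run, with one
  positional restriction: when the run is exactly three units long, the
  mismatch may not fall on the invariant G of an nGAAn unit (offset 2)
  or the invariant C of an nTTCn unit (offset 4) in the first or last
  unit. These terminal core bases make the strongest HSF contacts, so a
  substitution there in a minimal-length element is treated as
  disqualifying.

The mismatch budget is one per whole element, not one per unit; this is
the only reading consistent with the published worked examples, all of
which are three-unit elements with a single annotated mismatch.

Unit orientation is assigned by minimum core mismatch count. The GAA and
TTC cores are Hamming distance 3 apart, so a unit within one mismatch of
either core has an unambiguous orientation; ties (possible only at two
or more mismatches) are broken toward GAA-type and never survive the
budget. N — or any IUPAC ambiguity code — at a core position counts as a
mismatch; at a free position it is accepted. Input is case-folded to
uppercase on ingestion.

## Scanning

`scan_sequence` enumerates all five period-5 frames and reports every
*maximal* accepted run: a run that cannot be extended by one unit on
either side without violating the budget, the terminal-protection rule,
or (if enabled) orientation alternation. Internally it precomputes
per-unit mismatch counts with prefix sums and finds each start's
feasible right edge with a two-pointer sweep, so scanning is linear in
sequence length per frame; a 100-kb sequence scans in well under a
second. Matches are reported sorted by 3'-anchored start with identical
intervals deduplicated.

Scanning is single-strand: because nGAAn and nTTCn are mutual reverse
complements, every element on the opposite strand appears on the scanned
strand with orientations swapped, so a one-strand scan is
orientation-complete (a tested invariant: scanning the reverse
complement yields the mirror-image match set).

`brute_force_scan` is a deliberately separate oracle: it walks every
offset, grows the window one unit at a time while the running mismatch
total stays within budget (longer windows at an offset only add
mismatches, so the walk can stop early without skipping any acceptable
window), judges each candidate with `classify_window`, and applies the
same maximality rule. The test suite asserts scanner/oracle equality on
1000 seeded random 200-nt sequences and under the stricter
configuration flags.

Two definitional choices were genuinely open and are exposed as
configuration rather than guessed:

* **Alternation.** Classical HSE descriptions have head-to-head units
  alternating GAA/TTC orientation; the procedure reproduced here does
  not state that requirement, although all 17 published examples happen
  to alternate. Default: not required (`require_alternation=False`).
* **Protection scope.** The terminal-core restriction is stated for
  three-unit runs only; `protect_terminal_core_only_when_three=False`
  extends it to all run lengths for users who want the stricter rule.

## Coordinates

Internally all coordinates are 0-based half-open. Reporting uses the
3'-anchored convention of the source tables: the last nucleotide of the
analyzed sequence is −1 and intervals are inclusive, so a 15-mer whose
first base is at −331 ends at −317. The conversion is a pure
presentation-layer function (`to_3prime_coords`) with a tested
round-trip inverse.

## Promoter extraction

Two promoter modes mirror the analysis conventions:

* `UPSTREAM_2KB`: up to 2,000 nt immediately 5' of the transcription
  initiation site (TSS);
* `EXTENDED_5KB_PLUS_5UTR`: up to 5,000 nt upstream of the TSS plus the
  TSS→start-codon segment, with the analyzed length reported as
  "total (utr)".

The TSS is the transcript 5' end (it includes the 5' UTR), distinct from
the start codon. For genes with several splice variants the transcript
with the 5'-most end is chosen — a deterministic rule that keeps the
promoter window clear of every variant's transcribed sequence — and the
winning transcript id is recorded per gene for audit. GFF3 coordinates
are treated as 1-based inclusive and converted at the boundary; windows
are truncated (never padded) at contig edges, and runs of N from
assembly gaps are preserved verbatim. Minus-strand promoters are
reverse-complemented so output is always sense-strand 5'→3'.

## Synthetic benchmarks

The generator produces HSE-free backgrounds and substitutes known
elements at chosen 3'-anchored positions, returning a ground-truth
table:

* `GC_ONLY` (default for anchor tests): G/C-only background. Freedom
  from HSEs is *provable*, not sampled — every unit core needs an A or a
  T, so each unit costs at least one mismatch and three units always
  exceed the one-mismatch budget.
* `RANDOM_REJECTED`: i.i.d. A/C/G/T at configurable GC content
  (default 0.5), with any oracle-accepted window redrawn until the
  sequence is oracle-empty (bounded retries). This gives a more
  realistic composition at the cost of a sampled, not provable,
  guarantee.

Planting validates each insert (a declared typical/varied element must
classify as declared; a decoy must be rejected) and re-checks the
planted sequence with the oracle so junction artefacts raise instead of
silently corrupting the truth table. Both background modes are
deterministic given a seed.

What the generator does **not** emulate: real promoter base composition
(wheat promoters are not i.i.d.), dinucleotide or higher-order
structure, repeats, and assembly gaps. Passing the planted-recovery
suites therefore demonstrates correctness of the scanning logic and
coordinate bookkeeping, not detection performance on real genomes —
for this deterministic consensus definition the two coincide wherever
the definition itself applies.

The packaged fixtures are the two printed tables the package is
anchored on: the 17-row HSE table (four rows from 2-kb promoters, 13
from extended promoters) and the 9-gene × 56-element cis-element
presence table. They are stored as TSV data files, not code literals,
so loading them doubles as a parsing test.

## Triad comparison

`compare_triad` partitions the element repertoires of a homoeologue
triad (one gene per A/B/D subgenome) into the standard three-set Venn:
shared by all three, shared by exactly one pair, specific to one gene.
Element identity is exact string equality after whitespace trimming; no
fuzzy merging ("MYB" and "MYB recognition site" stay distinct). The
partition property (pairwise disjoint, jointly exhaustive per gene) is
tested against an independent per-element membership tally and on
randomized matrices.

On the packaged presence table the recomputed all-gene intersection has
seven elements — the six named in the source narrative (CAAT-box, MYB,
STRE, as-1, CGTCA-motif, TGACG-motif) plus MYC — and 56 distinct element
names; the narrative's own counts ("six", "57") disagree with its table
by exactly these margins. Tests therefore assert containment of the six
and internal consistency, never the narrative counts.

## Problem sizes and numerics

Anchor tests run on backgrounds of 2,000–5,274 nt (the printed analyzed
lengths); the property suite uses 1000 random 200-nt sequences for
oracle equivalence and one 100-kb sequence for the long-scan invariants.
Everything is integer arithmetic — there are no tolerances, optimizers
or floating-point comparisons anywhere in the pipeline — so results are
exactly reproducible; the only randomness is the seeded background
generator.

## Known limitations

* Single-strand reporting: matches are not re-expressed in minus-strand
  genomic coordinates (promoters are already sense-strand).
* No statistical model: no PWM scoring, no enrichment testing, no HSF
  affinity prediction — the definition is a hard consensus rule.
* `RANDOM_REJECTED` backgrounds are practical up to a few kilobases
  (the rejection step runs the quadratic oracle).
* The cis-element comparison consumes a presence table; it does not
  detect elements itself.
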