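# hsescan

Heat shock element (HSE) scanning of promoter sequences, built for
regulatory analyses of heat-responsive genes such as the *Fes1*
nucleotide exchange factors of HSP70 in hexaploid wheat — genes whose
promoters lack HSEs under stock motif databases yet contain them under
the relaxed "varied HSE" definition this package implements.

## The motif definition

An HSE is a run of contiguous pentanucleotide units

```
5'-nGAAn-3'   or its reverse complement   5'-nTTCn-3'
```

where n is any base; offsets 2–4 carry the fixed core, offsets 1 and 5
are free. A run of ≥ 3 units with

* **0** core mismatches is a **typical** HSE;
* **exactly 1** core mismatch is a **varied** HSE — except that in a
  three-unit run the mismatch may not fall on the G of nGAAn (the C of
  nTTCn) in the first or last unit.

Because nGAAn and nTTCn are mutual reverse complements, a single-strand
scan is orientation-complete. Matches are reported in 3'-anchored
coordinates (last base = −1, inclusive), mismatches as an
observed+expected two-letter code (e.g. `CA` = C observed where A
expected).

The package also provides strand-aware promoter extraction from genome
FASTA + GFF3 (2-kb upstream of the TSS, or 5-kb upstream plus the 5'
UTR), a synthetic planted-motif benchmark generator with provably
HSE-free backgrounds, and a Venn comparison of cis-element repertoires
across wheat homoeologue triads.

## Worked example

Classify one 15-mer window (three units):

```
$ hsescan classify GGCACATTCCAGAAA
VARIED	CA
```

`GGCAC·ATTCC·AGAAA` decomposes into a GAA-type unit with one core
mismatch (C observed at offset 3 where the consensus has A — the `CA`
code), then perfect TTC- and GAA-type units: one mismatch total, so a
varied HSE.

Plant that element in a 2,000-nt HSE-free background with its first base
at 3'-anchored position −331, then scan:

```
$ hsescan simulate --length 2000 --seed 1 --plant GGCACATTCCAGAAA@-331 --out-fasta demo.fa
$ hsescan scan --fasta demo.fa
No.	Gene	Position Start	Position End	HSE_seq	Mismatch	Analyzed sequence length
1	synthetic	-331	-317	GGCACATTCCAGAAA	CA	2000
```

Exactly one match, recovered at the planted interval: −331 for the first
base and −317 for the fifteenth, under the last-base-is-−1 convention.

Compare cis-element repertoires within a homoeologue triad (the packaged
gene × element table ships with the package):

```
$ hsescan fixtures cis --out cis_elements.tsv
$ hsescan compare --matrix cis_elements.tsv --triad Fes1B
elements in all 9 genes (7): CAAT-box, CGTCA-motif, MYB, MYC, STRE, TGACG-motif, as-1

triad Fes1B (TaFes1B-4A, TaFes1B-4B, TaFes1B-4D)
  shared by all 3 (15): A-box, ACE, CAAT-box, CCGTCC motif, CGTCA-motif, DRE core, GC-motif, MYB, MYC, STRE, TCA-element, TCCC-motif, TGACG-motif, WRE3, as-1
  TaFes1B-4A & TaFes1B-4B only (0): 
  TaFes1B-4A & TaFes1B-4D only (3): ABRE, G-box, Sp1
  TaFes1B-4B & TaFes1B-4D only (6): AAGAA-motif, AuxRR-core, CTAG-motif, LTR, TATA-box, box S
  specific to TaFes1B-4A (4): ARE, CAT-box, CCAAT-box, MYB recognition site
  ...
```

`TaFes1B-4D` is the one homoeologue with no specific elements — its
repertoire is fully covered by its triad partners.

The library API mirrors the CLI: `classify_window`, `scan_sequence`,
`brute_force_scan` (an independent exhaustive oracle), `extract_promoter`,
`generate_background`/`plant`, and `compare_triad`. See `docs/methods.md`
for the model, the design choices, and the generator's scope.

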