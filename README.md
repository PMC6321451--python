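# premotif

Motif search and discriminative motif discovery in microRNA precursor
stem-loops.

RNA-binding proteins (Lin28, MCPIP1, DGCR8, hnRNP A1, DEAD-box
helicases, …) regulate miRNA biogenesis by recognizing short sequence
motifs in specific parts of the pre-miRNA hairpin — most often the
terminal loop, but also the stem and the region between the two mature
miRNAs. `premotif` is a library and command-line tool for researchers
asking two questions about a miRBase-style precursor database:

1. **Which precursors carry a known motif in a given structural
   region?** Motifs are written in the IUPAC degenerate code
   (R = G/A, Y = U/C, …, N = any) and searched forward (5'→3') or also
   as the reversed string, restricted to the terminal loop, the linking
   sequence (between the two mature arms), the mature miRNAs, or the
   whole precursor. One- and two-motif searches are supported, the
   latter with an occurrence-overlap policy.
2. **Which motifs are enriched in a group of precursors?** Given a list
   of precursor names or raw sequences and a background set, a
   deterministic DREME-style search enumerates words, scores them with
   a one-sided Fisher's exact test on sequence-level counts
   — the upper hypergeometric tail
   P(X ≥ p_with) for p_with of p_total positives vs n_with of n_total
   negatives containing the motif — generalizes the best seeds into
   IUPAC classes, and reports motifs whose E-value `p · 15^w`
   (Bonferroni over the IUPAC pattern space at width w) passes a
   threshold, erasing matching sequences between rounds.

Structure comes from a pluggable fold engine: a bundled deterministic
maximum-base-pairing (Nussinov) folder with pairs {A·U, G·C, G·U} and
minimum hairpin loop 3, or ViennaRNA's `RNAfold` for thermodynamic
structures. The terminal loop is the apical unpaired run of the main
stem extended by a 2-nt overhang on each side; the passenger strand of a
single-arm precursor is predicted from the duplex partners of its mature
miRNA with the canonical 2-nt 3' overhang.

A deterministic fixture generator builds miniature hairpin/mature FASTA
pairs with known geometry and optionally planted motifs, so everything
is testable without downloading a database. Details of every model and
convention are in [docs/methods.md](docs/methods.md).

## Worked example

Generate a 40-precursor synthetic database in which 12 precursors carry
a Lin28-like GGAG motif planted in the terminal loop, then search and
discover:

```sh
premotif fixtures --n 40 --plant GGAG --plant-fraction 0.3 --seed 7 --out data
premotif search1 --db data/hairpin.fa --mature data/mature.fa \
    --motif GGAG --region loop --out search_out
```

prints

```
12 precursor(s) with >=1 GGAG hit in region loop; 0 skipped
```

i.e. exactly the planted precursors (compare `data/truth.tsv`), with the
per-occurrence coordinates in `search_out/hits.tsv`:

```
precursor_id  region  direction  start1  end1  matched_seq  motif
syn-mir-1     loop    forward    21      24    GGAG         GGAG
...
```

Now discover motifs in the loops of the first 15 precursors (12 planted
+ 3 clean), against the loops of the remaining 25 as background:

```sh
printf 'syn-mir-%d\n' $(seq 1 15) > positives.txt
premotif discover --db data/hairpin.fa --mature data/mature.fa \
    --positives positives.txt --region loop --max-motifs 1 --out disc_out
```

```
1. GAG  p=8.14e-08  E=0.000275  (12/15 vs 0/25)
```

The reported pattern is carried by exactly the 12 planted loops and by
no background loop; p is the Fisher tail of that 12/15-vs-0/25 table,
and E multiplies it by the 15³ candidate patterns at width 3. The
search reports the minimal core `GAG` rather than `GGAG` here because
both match the same sequences in this small database and the shorter
pattern pays a smaller multiple-testing penalty; on backgrounds where
`GAG` occurs by chance (e.g. whole precursors), the full `GGAG` wins.

Two-motif searches work the same way, e.g. the MCPIP1/DGCR8 pair

```sh
premotif search2 --db data/hairpin.fa --mature data/mature.fa \
    --motif1 UGC --motif2 UGU --region loop --no-overlap --out pair_out
```

and every run writes a `run_summary.json` with the full configuration
and a database fingerprint, from which the run can be reproduced.

## Output formats

* `hits.tsv` — one motif occurrence per row: precursor, region,
  direction, 1-based inclusive coordinates, matched subsequence, motif.
* `categories.tsv` — two-motif search: precursor → motif1_only /
  motif2_only / both / neither (with the overlap policy applied).
* `report.txt` — region sequences with matches bracketed.
* `motifs.tsv`, `motifs.meme`, `sites.fa` — discovery results: patterns
  with p/E and counts, MEME-minimal position frequency matrices, and
  matched sites.
* `regions.tsv`, `structures.txt` — BED-like region decomposition and
  per-precursor dot-bracket structures.
* `run_summary.json` — version, configuration echo, database
  fingerprint, and run-level counts.
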