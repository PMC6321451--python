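# Methods

`premotif` answers two questions about microRNA precursor (pre-miRNA)
stem-loops: *which precursors in a database carry a given protein-binding
sequence motif in a given structural region*, and *which motifs are
enriched in a user-defined group of precursors relative to a background
set*. This note records the models, conventions, and numerical choices
behind both, and what the synthetic validation data does and does not
demonstrate.

## Precursor databases and mature mapping

Input databases are miRBase-style FASTA files: a hairpin file (one
record per precursor, header `>name accession description…`) and an
optional mature file in the same layout. Sequences are uppercased and
T→U normalized on input; the three-letter species prefix of the name
(`hsa`, `mmu`, `ath`, …) supports species filtering.

Mature miRNAs are located inside precursors by exact substring matching
after normalization. Candidate precursors for a mature record are those
whose name, after stripping one trailing `-<digits>` copy suffix, equals
the mature name after stripping a trailing `-5p`/`-3p` (or legacy `*`)
suffix, case-insensitively. A mature that maps to several paralogous
precursors yields a locus in each. When the mature sequence occurs more
than once inside one precursor, one occurrence is kept: the leftmost for
a `-5p` arm, the rightmost for `-3p`, and, for an unknown arm, the
occurrence whose midpoint lies farthest from the precursor midpoint —
arms sit at the hairpin extremities, so the extremal occurrence is the
biologically plausible one. For exact control (e.g. genome-derived
coordinates) a TSV pathway (`precursor_id, mature_id, arm, start, end`,
1-based inclusive) bypasses substring mapping entirely.

All internal coordinates are 0-based half-open; every human-facing file
is 1-based inclusive.

## Secondary structure and region decomposition

Structure prediction is behind a one-method `FoldEngine` contract
(sequence → dot-bracket), so the decomposition logic is independent of
the folding model. Two engines ship:

* **`NussinovFold`** (default, bundled): deterministic maximum
  base-pairing dynamic programming over the pair set {A·U, G·C, G·U}
  with a minimum hairpin loop of 3 unpaired nt. Traceback preference at
  each interval is: close the `(i, j)` pair; else split at the smallest
  point whose left part contains at least one pair (an empty right part
  is allowed, which closes pairs ending before unpaired tails); else
  leave `i` unpaired. This yields a unique structure per sequence, and
  its pair count is verified against an exhaustive enumeration of all
  nested structures for every 7-mer and for random sequences up to
  length 12.
* **`RNAfoldEngine`**: an adapter to ViennaRNA's `RNAfold` executable
  for thermodynamic (MFE) structures, for users who prefer the
  free-energy model. Any conforming engine changes only
  structure-dependent regions; whole-precursor searches are engine-free.

Regions are derived from the structure as follows.

* **Terminal loop**: among all hairpin loops (maximal unpaired runs
  directly closed by a pair), the one whose closing stem carries the
  most enclosing pairs is the terminal loop of the main stem; ties break
  toward the loop nearest the sequence midpoint, then the lower start.
  The unpaired run is extended by a 2-nt overhang *on each side* into
  the stem. The symmetric reading was chosen because loop-binding
  proteins contact the loop-closing stem edge on both strands; the
  overhang width is exposed as a parameter.
* **Linking sequence**: the interval between the 5'-arm and 3'-arm
  mature miRNAs (empty for an adjacent duplex). With a single annotated
  mature, linking runs between the mature and the predicted passenger.
* **Passenger strand**: for precursors with a mature on one arm only,
  the partners of all paired mature positions span the passenger, which
  is then extended 2 nt at its 3' side (the canonical Dicer duplex
  overhang), clipped to bounds and truncated at the mature interval.
  A fully unpaired mature yields no passenger (warning).

Per-precursor failures (no pairs, no loop, unmapped matures) are
collected in a skipped list and never abort a batch; such precursors
remain searchable as whole sequences.

## Motif matching

Motifs use the IUPAC nucleic-acid code (R=G/A, Y=U/C, M=A/C, K=G/U,
S=G/C, W=A/U, H=A/C/U, B=G/U/C, V=G/C/A, D=G/U/A, N=any). Matching
compiles the pattern to a character-class regular expression inside a
lookahead so that overlapping occurrences are all reported. The matcher
is validated against a brute-force oracle that expands the pattern to
every concrete word and scans naively.

The *reverse* direction scans for the reversed motif string, **not** the
reverse complement: precursors are single-stranded, and the option
exists for protein motifs reported 3'→5'. In both-direction mode,
identical intervals from a reversal-palindromic motif are deduplicated.

The two-motif search categorizes each searchable precursor as
`motif1_only`, `motif2_only`, `both`, or `neither`; occurrence overlap is
closed-interval intersection, and the "exclude overlapping" policy keeps
a precursor in the effective `both` list only if *some* occurrence pair
is disjoint. Two laws tie the searches together and are asserted in the
test suite: a degenerate motif equals the union of its expansions
(searching UGY reproduces exactly the union of UGC and UGU pair-search
categories), and every region-restricted hit is contained in the
whole-precursor search.

## Discriminative motif discovery

Discovery is a deterministic word-enumeration search in the style of
DREME (Bailey 2011), scoring candidate motifs by a one-sided Fisher's
exact test on sequence-level counts: `p_with` of `p_total` positives and
`n_with` of `n_total` negatives contain at least one occurrence. The
p-value is the upper hypergeometric tail, evaluated via
`scipy.stats.hypergeom.sf` (log-gamma based); it is checked against an
exact-fraction enumeration for every table with population ≤ 60.

Each round:

1. for each width w (default 3–8), every exact w-mer occurring in ≥ 2
   positive sequences is a seed;
2. seeds are scored by Fisher p; the best `beam_width` (default 8) per
   width are greedily generalized — at each step every concrete position
   is tentatively replaced by each 2-/3-base IUPAC class and the variant
   with the lowest p is kept, stopping when no variant strictly improves
   p (generalization can only widen the matched set, so `p_with` and
   `n_with` never decrease; this is asserted during the search);
3. the round winner is the candidate with the smallest **E-value**
   `E = p · 15^w`, a Bonferroni correction over the full IUPAC pattern
   space at its width. Widths must compete on the E scale: the
   multiplier grows with width, so raw p would favour long, overfit
   patterns. The full-space multiplier, rather than a count of seeds
   actually scored, is deliberate: the greedy generalization effectively
   selects over the degenerate-pattern space, and label-shuffle
   experiments show that weaker corrections report spurious motifs with
   E ≤ 0.05 on the majority of random label assignments, while the full
   correction stays silent in ≥ 95% of shuffles and still recovers
   planted motifs with E ≈ 10⁻⁹. The cost is conservatism: genuinely
   enriched motifs with p above roughly `0.05/15^w` are not reported.
4. if the winner passes `e_threshold` (default 0.05) it is reported and
   *erased* — every positive and negative sequence containing it is
   removed — and the search repeats, up to `max_motifs` (default 10).

By default the background is all precursors of the database minus the
positives (self-competition is avoided; a flag keeps them). Positive
inputs may be miRBase-style names (resolved case-insensitively, with
`miR`/`mir` spelling ignored) or raw sequences; unresolvable names are
reported and skipped, and the chosen region (default: terminal loop) is
extracted per precursor. Reported motifs come with their matched sites,
a position frequency matrix, and MEME-minimal output.

## Synthetic data

The fixture generator emulates miRBase-style data with known ground
truth. Each precursor is `5'-arm + loop + reverse-complement(5'-arm)`
with G·C pairs relaxed to G·U wobbles at probability 0.1 — realistic
enough to exercise wobble pairing without making the intended stem
ambiguous. The apical loop is a 4-nt poly-A run by default: no base pair
can form inside a 4-nt loop (partners must be ≥ 4 apart) and A pairs
with neither A nor itself across the loop, so the maximum-pairing folder
provably recovers the constructed stem and the terminal loop. Mature
records cover the outer `stem_length − 4` nt of each arm, leaving a
linking sequence that properly contains the loop. Planted motifs are
concrete random instantiations of an IUPAC pattern written into the
requested region before the 3' arm is derived, so planting never breaks
the hairpin; every planted interval is recorded in a truth TSV. All
randomness flows from a single integer seed; identical specs produce
byte-identical files.

For discovery benchmarks a separate generator produces i.i.d. uniform
random sequences (length 70) rather than hairpins: planting a motif into
a hairpin always co-plants its reverse complement on the opposite arm,
which would create a second, unintended enriched motif. Candidates with
chance occurrences of the planted pattern (either scan direction) are
rejection-sampled away, so the planted pattern's true contingency table
is known exactly. Default benchmark conditions: 15 positives of which 12
carry the motif, 100 clean negatives.

What passing these tests shows — and does not. The synthetic stem-loops
are clean two-arm hairpins with uniform base composition; real pre-miRNAs
have bulges, internal loops, non-uniform composition, and mature arms
annotated from biology rather than geometry. Agreement on fixtures
therefore validates the *logic* (region arithmetic, matching laws,
enrichment statistics), not the adequacy of maximum-pairing folding for
real precursors, where an MFE engine and curated coordinates are the
recommended configuration. Search counts that depend on loop boundaries
are fold-model-specific; only structure-free quantities (whole-precursor
counts) are comparable across folding engines.

## Numerical and degenerate-input choices

* Fisher p for `p_with = 0` is exactly 1 (the upper tail is the whole
  distribution); tables are validated on construction.
* Folding requires length ≥ 10 (a shorter RNA cannot form a stem worth
  decomposing); tests relax this bound explicitly where the oracle needs
  tiny sequences.
* Empty linking intervals (adjacent duplex) are legal; overlapping
  mature intervals are an error.
* Duplicate precursor ids are a hard error; duplicate mature records
  simply produce duplicate loci.
* Output files are written atomically (temp file + rename); every CLI
  run emits a JSON summary with the tool version, a database fingerprint
  (record count + SHA-256 over ids and sequences) and the full
  configuration, from which the run can be reproduced.

## Validation problem sizes

The shipped validation (`tests/`, `scripts/acceptance.py`) uses: 1,000
random (sequence, pattern) cases for the matcher oracle; all ~6.4·10⁵
contingency tables with population ≤ 60 for the Fisher oracle; all
16,384 RNA 7-mers plus 60 random 10–12-mers for the folding oracle; the
12/15-vs-100 planted benchmark; and 100 label shuffles for the null
control. These sizes make the full validation run in a few minutes on a
single CPU while keeping every oracle sweep exhaustive at its scale.

## Known limitations

* Maximum-pairing folding ignores thermodynamics; on branched or
  AU-poor precursors its terminal loop can differ from MFE predictions.
  Loop-dependent published counts are therefore reproduced only up to
  the folding model.
* No mismatch-tolerant or weighted (PWM) scanning, no reverse-complement
  scanning, no positional enrichment, no Markov background.
* The E-value correction is conservative by design (see above); users
  hunting weak signals can raise `--e-threshold` deliberately.
* miRBase name-history remapping is out of scope: legacy names simply
  surface as unresolved inputs.
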