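# Methods

## The problem and the model

Baculoviruses are insect viruses with circular dsDNA genomes of roughly
88–200 kbp and 90–180 genes on both strands. Their mRNAs are 3′-end
processed much like host transcripts: a positioning hexamer (PAS,
canonically `AAUAAA`, alternatively `AUUAAA`) is flanked by a U-rich
upstream sequence element (USE), an optional CFIm `UGUA` motif, a cleavage
site (CS) just 3′ of a `CA` dinucleotide, a U/GU-rich downstream sequence
element (DSE) and a G-rich auxiliary element (Aux-DSE). This package
implements positional models of that cassette — admissible distance windows
between the elements — and everything needed to evaluate them: extraction
of downstream gene regions (DGRs), degenerate-motif scanning, cassette
assembly, validation against control sets, secondary-structure context of
the cleavage site, and sequence logos. Because the analysis is validated on
synthetic genomes with planted cassettes, every stage is testable against
known ground truth.

## Coordinates and distance conventions

A DGR is the 450-nt window around a gene's stop codon, read 5′→3′ in gene
orientation: relative positions −100..−1 are the last 100 nt of the gene
(the stop codon at −3..−1) and +1..+350 the 350 nt immediately 3′. There
is no position 0. The source ranges behind the models are prose
("the USE was located 5–30 nt upstream of the PAS"), so the package fixes
explicit conventions:

* **gap** windows count the nucleotides strictly between the upstream
  element's last base and the downstream element's first base (negative
  for overlaps);
* **start** windows are start-to-start (used for UGUA→PAS, where overlap
  with the PAS is explicitly possible);
* the CS is represented by its CA candidate dinucleotide; all distances
  involving it are measured at the cleavage point, immediately 3′ of the A;
* the PAS anchor window constrains the PAS start in relative coordinates,
  with "*k* nt downstream of the stop codon" written +*k* (0 ≡ +1).

The −100 boundary convention ("does −100 count from the first or last base
of the stop codon?") is genuinely open; the implementation anchors on the
stop codon's last base and the window is configurable by a few nt in
`extract_dgr`.

Two presets are shipped (`src/baculopolya/data/*.yaml`):

| window | initial2003 | improved2020 |
|---|---|---|
| PAS start vs stop | +1..+51 | −12..+7 |
| USE → PAS | 5–30 | 5–30 |
| UGUA → PAS (start) | 0–8 | 0–8 |
| PAS → CS | 12–42 | 0–75 |
| PAS → DSE | — | 21–29 |
| CS → DSE | 4–40 | 0–50 |
| DSE → Aux-DSE | 1–100 | 1–100 |

The UGUA window (the prose says only "immediately upstream or overlayed")
and the Aux-DSE range (only "downstream of the DSE") have no stated
numbers; 0–8 start-to-start and 1–100 gap are this package's defaults,
both configurable. Aux-DSE has no literal motif either; the default rule
is any 6-nt window with ≥ 4 G in the downstream region (+1..+350),
configurable via `g_rich_windows`. Model files are checked for mutual
satisfiability at load time by difference-constraint propagation over
nominal motif lengths, so contradictory windows fail at configuration, not
per call.

## Element definitions

USE `TTTT`; UGUA `TGTA`; PAS `AATAAA`/`ATTAAA`; CS candidate `CA`;
DSE `TTTTT`/`GTTGT`; Aux-DSE by the G-rich rule; optionally a late-gene
U-rich terminator `TTTTTT` (excluded from cassette assembly by default).
Patterns are IUPAC with T≡U; an N in the scanned sequence matches nothing
(conservative). All overlapping occurrences are kept — deduplication is
the assignment layer's job.

## Cassette assignment

`assign_cassette` returns the placement of hits that maximizes, in order:
(1) the number of element classes placed consistently with every window
between placed classes (PAS and CS are required; the PAS must lie in the
anchor window); (2) minimal summed deviation of each satisfied window's
distance from its window centre (the anchor window included); (3) the PAS
closest to the stop anchor; (4) the leftmost CS; with a final lexicographic
comparison over (class, position, motif) tuples making the order total.
The tie-break order is this package's choice — the source analysis does not
say how competing placements were resolved. The search is an exact
depth-first enumeration with window filtering and bounds that only prune
provably dominated branches; the test suite compares it against brute-force
enumeration of all hit combinations. `verify_assignment` re-checks every
emitted assignment's distances independently of the search.

Positional "hot spots" are summarized as the smallest contiguous window
containing ≥ q of all hits (q = 0.75 by default; the source does not state
its hot-spot criterion, so this is a documented default, not a claim of
fidelity).

## The synthetic generator

`plant_cassette` draws one full cassette into a 450-nt DGR:

* inter-element distances are drawn independently and uniformly from the
  model windows (the ranges are all the sources give). Layouts are
  rejection-sampled against joint constraints: motifs must not overlap,
  the composed PAS→CS and CS→DSE draws must fall inside the PAS→DSE
  window, and the stop codon (drawn uniformly from TAA/TAG/TGA) must be
  expressible at −3..−1 given any motif overlapping it. Consequently the
  independently drawn windows (USE→PAS, PAS→DSE, DSE→Aux-DSE) are realized
  over their full ranges, while the jointly constrained ones (PAS anchor,
  PAS→CS, CS→DSE) cover only their feasible subsets — the window-coverage
  tests assert exactly that;
* the PAS is `AATAAA` with probability 0.8 and `ATTAAA` with 0.2
  (the sources name both variants without frequencies; configurable);
* the 40-nt window centred on the PAS is AU-enriched to the target
  fraction (default 0.80, the reported AU content of PAS neighbourhoods)
  by resampling its free background positions;
* the rest of the DGR uses the background composition, default 30/20/20/30
  (≈ 60% AU, echoing the AU-richness of these genomes; whole-genome
  composition is configurable rather than asserted).

`generate_genome_set` embeds such cassettes in annotated circular genomes:
genes of 300–900 nt (uniform codon count, no in-frame stops) laid out
sequentially with a free 450-nt downstream block, strands assigned per
`frac_minus_strand`, and the finished genome rotated to a random
intergenic origin so some DGRs wrap the circular origin. Half the genes
carry names from the shipped core-gene table so core/non-core selection is
exercised. Output (GenBank or FASTA+GFF3, truth TSV, params JSON) is
byte-identical for identical parameters. Note the planted cassette
overwrites the gene's final 100 nt, so gene tails are not codon-clean;
the coding control set is therefore harvested from independent
codon-sampled sequence, not from gene tails.

What the generator does **not** emulate: real gene content and homology,
transcription units and UTR overlaps, genome-wide compositional
heterogeneity, or signal degeneracy beyond the modelled motif lists.
Passing tests show the pipeline recovers what the model describes under
the model's own assumptions — they do not certify detection performance on
real genomes, where the validation showed the improved model does not
cover all 3′-UTRs.

## Secondary structure

`fold_max_pairing` maximizes the number of Watson–Crick pairs (G·U wobble
optional, off by default) over all nested structures with hairpin loops of
≥ 3 nt, via Nussinov-style dynamic programming. The traceback is
deterministic: a position is left unpaired whenever that is optimal,
otherwise paired with its smallest admissible partner. This is a
thermodynamics-free stand-in for MFE folding — the downstream
classification (is the cleavage position paired, in an enclosed loop, or
external; modal pairing state of the PAS span) depends only on the pair
set, and the folding engine is pluggable behind that interface. No
pseudoknots, no energies. The consensus-structure report is the frequency
table over (PAS-context × CS-context) labels, an explicit approximation of
the pictorial structure classes it mirrors.

Inter-element complementarity reports maximal antiparallel complementary
stretches of 4–6 nt (longer runs clipped at the run start) between the
five element pairs USE-PAS, USE-CS, PAS-CS, PAS-DSE and CS-DSE, with each
element's span widened by 5 nt of flank since the complementary stretches
overlap the elements rather than coinciding with them.

## Logos and reports

PFMs align each recovered element on its start with ±10 nt of context
(approximate, the source logos' exact flanks are not stated); columns are
(A,C,G,U) frequencies with N excluded column-wise; information content is
2 − H bits per column with no small-sample correction. Logos are rendered
with matplotlib; PFMs export as TSV and MEME minimal format. `emit_report`
bundles artifacts deterministically and flags missing sections.

## Problem sizes and numerical choices

The analysis drivers and the acceptance script use 500 planted DGRs per
recovery/validation experiment, 500-sequence control sets, 87 folded
cassettes and 50 designed hairpin fixtures, with 6 × 88-kbp genomes for
the genome-level pipeline — sizes chosen so the whole study reruns in
seconds while every distance in the free windows is realized many times
over. All randomness flows from a single seed through
`numpy.random.Generator`; identical seeds give identical outputs,
including files.

## Known limitations

* Core-gene membership is configuration (a default 38-name table), not
  computation; real annotations need a matching name table.
* Spliced/joined gene features are rejected; these genes are unspliced,
  and a join in this context usually signals an origin-spanning artifact.
* The hexamer-level PAS model has no probabilistic scoring of signal
  strength; detection is binary per model windows.
* Maximum-base-pairing folds overestimate pairing relative to
  thermodynamic folds; stem/loop labels should be read as complementarity
  context, not free-energy structure.
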