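# Methods

## Coordinate and strand conventions

All internal coordinates are 1-based inclusive (the GFF convention); BED6
input/output is converted at the I/O boundary. A gene always lies on a definite
strand; an sRNA gene may carry an unknown strand, because several of the sRNA
catalogs this kind of screen draws on report loci without strand assignment.
Overlap between two features is the length of their coordinate intersection;
the gap between disjoint features is the number of nucleotides strictly
between them (adjacent features have gap 0).

## Orientation model

The classifier partitions every same-chromosome gene–sRNA pair into exactly
one of six categories using three pieces of geometry:

* the **adjacency window** *w* (default 100 nt): the maximal gap at which a
  non-overlapping sRNA still counts as a neighbour. Published screens of this
  kind speak of sRNAs "in the proximity" of a gene without quantifying it, so
  the distance is an explicit, configurable parameter rather than a hidden
  constant;
* the **5' window**, by default 15 nt upstream of the start codon through 3 nt
  into the CDS. This covers a typical ribosome-binding site plus the start
  codon — the same region the RACE primers and northern probes are designed
  over, and the region an asRNA must pair with to block translation
  initiation;
* the **3' window**, by default the last 50 nt of the gene plus 50 nt
  downstream, delimiting the territory of convergent overlapping transcripts
  (cutoRNAs) that act on the messenger's 3' end.

Rule order (first match wins): unknown-strand neighbour → `AMBIGUOUS`;
antisense touching the 5' window → `CIS_AS_5PRIME`; antisense touching the 3'
window or lying within *w* on the 3' side → `CUTORNA`; any other antisense
overlap or in-window antisense neighbour → `CIS_AS_OTHER`; same-strand overlap
→ `SENSE_OVERLAP`; otherwise `NONE`. The 5'-over-3' precedence reflects the
screen's primer design: when an sRNA spans the whole gene, the 5' evidence is
the actionable one. `CIS_AS_OTHER` exists so the antisense partition is total;
for antisense and unknown-strand sRNAs, `NONE` is therefore exactly "no
overlap and gap > *w*". A same-strand non-overlapping neighbour is `NONE` as
well — it is not an antisense candidate and inventing a category for it would
dilute the funnel. Trans-chromosomal pairs are `NONE` with overlap and gap
reported as 0 (distance is undefined across replicons).

The classifier is verified against an independent brute-force oracle that
represents intervals and windows as explicit position sets and evaluates every
rule by set intersection (10,000 random geometries on a 300-nt toy chromosome
per run), and obeys strand-flip symmetry: reverse-complementing a whole locus
(mirroring coordinates, flipping strands) never changes a category.

## Candidate funnel

Selection reads "increased by more than two-fold" strictly and on **signed**
folds: a −2.6-fold change is not an increase, though such a gene may still
enter through the BARD (binding) arm of the `fold_or_bard` union. The
threshold (default 2.0), the inclusive BARD floor (default 1.0) and a
`>=` variant for sensitivity analyses are parameters. Funnel counts are of
distinct gene ids: a gene with *k* partner sRNAs contributes *k* report rows
but one count at each stage, which is why the bundled 49-row pair survey
collapses to 45 distinct target genes. The funnel is monotone non-increasing
by construction, and `fold_or_bard` equals the union of the two single modes
(both properties are tested).

The bundled pair survey carries no per-row binding flag (that information is
typographic in the published table and not recoverable from its text), so the
"also in BARD" stage is exercised on synthetic data, where ground truth is
known by construction.

## Oligo design and virtual PCR

RACE primers and northern probes are taken from the mRNA-sense strand with a
genomic footprint containing the entire 5' window, so they prime reverse
transcription of the antisense transcript. Melting temperature uses the
Wallace rule, Tm = 2·(A+T) + 4·(G+C) °C — deterministic, dependency-free and
adequate for 18–25-mers; the Tm function is a pluggable argument for users who
want nearest-neighbour thermodynamics. Constraint defaults (length 18–25, Tm
55–65 °C, GC 0.40–0.75) are ordinary primer-design bounds. Among valid
candidates the design returns the Tm closest to the Tm-band midpoint, ties to
the shorter oligo, then the leftmost position — a deterministic total order.
"No candidate" is a regular return value (`None`); a window falling off the
contig is an error. The search is exhaustive over all admissible footprints,
and tests compare it against an independently coded exhaustive oracle.

Virtual RT-PCR uses exact primer sites only (the screen's primers are exact
genome substrings), requires the reverse site downstream of the forward site
on the same strand, reports the shortest product when several site pairs
exist (the dominant species in a real reaction), and searches both template
orientations so the result does not depend on which primer is called
"forward". Product length is (end of reverse site) − (start of forward site)
+ 1.

Trans-target scanning is ungapped: every genome window of query length on
either strand with identity ≥ the threshold (default 0.9) is a hit, and
overlapping hits are merged keeping the best identity. An ungapped model is
appropriate for "nearly identical" sequence copies at sRNA scale; indel-
tolerant alignment is out of scope.

## Northern quantification

Each band is divided by the same lane's 5S rRNA signal (loading control). The
rnc response of a feature is called from r_t = (rnc_t + f)/(wt_t + f) at each
shared time point, where f is the detection floor (default 0.01 in normalised
units, doubling as pseudocount), and the geometric mean G of the r_t: G ≥ 2 →
`increased_in_rnc`, G ≤ 0.5 → `decreased_in_rnc`, all values in both strains
below f → `not_detected`, otherwise `unchanged`. The 2-fold default mirrors
the screen's own convention for expression changes; no published threshold
exists for the northern calls, so both the ratio and the floor are parameters,
and per-time-point ratios are reported alongside the summary call so a
single-time-point reading can be checked. The geometric mean (rather than the
maximum) is robust to a single-lane artifact and makes the call symmetric
under swapping the strain labels, which the tests assert; the call is also
invariant under rescaling both strains' intensities together with the floor.

## Synthetic data

The generator emulates the study's conditions, not its sequences: a single
GC-rich chromosome (72% GC, *Streptomyces*-like, so designed oligos face
realistic Tm/GC constraints), loci planted for each orientation category with
randomised gene lengths (300–600 nt) and offsets that satisfy the defining
rule of their category with margin, gene strands randomised by mirroring the
plus-frame geometry (legitimate because of strand-flip symmetry), and 120-nt
padding on each side of every locus so no feature lies within the adjacency
window of a foreign gene. Expression tables separate selected from unselected
genes by construction (selected fold drawn in [3, 6] at one random time point,
background magnitudes in [1.01, 1.5] with random sign; BARD ratios in
[2, 250] versus sub-threshold values below 1); equal separation bounds raise a
generation error. Northern tables plant rnc/wt ratios of 4, 0.25, 1 and
"undetectable" with independent lognormal multiplicative noise (CV 5% by
default; CV 0 reproduces the ratios exactly). Everything is driven by
`numpy.random.default_rng(seed)` and byte-identical across runs of the same
seed.

What the generator does **not** emulate: real promoter/terminator structure,
transcription-unit boundaries, expression correlations between neighbouring
genes, RNase III cleavage chemistry, or read-level noise. Passing the recovery
tests therefore demonstrates the correctness of the classification, filtering
and calling logic under the stated geometry and noise — not detection power on
real transcriptomes.

## Problem sizes and determinism

The randomized suites use 10,000 geometries for the classifier–oracle
comparison, 2,000 for symmetry spot-checks in unit tests, 50-gene catalogs
for monotonicity, and 3 loci per category (18 loci) for parameter recovery;
`scripts/acceptance.py` re-derives all of its randomness from the single
`--seed` argument. Two quantities require the real *S. coelicolor* chromosome
(accession AL645882, not redistributable here): the 635-nt virtual RT-PCR
product between the published operon-test primers and the 2,220-nt SCO5737
CDS length. The corresponding test looks for `scratch/AL645882.fa` and fails
with instructions when the genome is absent.

## Known limitations

* The orientation rules are interval geometry; they do not model expression
  overlap evidence or RNA duplex thermodynamics.
* Exact-match primer sites mean a single SNP voids a virtual PCR product;
  that is intended for primer-design validation, not for cross-strain use.
* The northern response call treats time points as exchangeable; a feature
  increased at one stage and decreased at another averages toward
  `unchanged` (the per-time-point ratios expose such cases).
* BED parsing accepts only the 6-column core; GFF3 parsing reads `gene`/`CDS`
  features with `ID` and `product` attributes and ignores feature hierarchy.
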