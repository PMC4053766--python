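# Methods

## Coordinate and read model

Internal coordinates are 0-based half-open on the genomic forward strand;
GFF3 is emitted 1-based inclusive and BED 0-based half-open. A collapsed
aligned read carries its interval, a copy count and a list of observed
substitutions whose offsets are relative to the interval start regardless
of strand; the cross-link-diagnostic T→C conversion therefore appears as a
genomic A→G on minus-strand reads, and all consumers (cluster T→C counts,
profile conversion tracks) interpret substitutions strand-aware. This keeps
the on-disk alignment dialect orientation-free.

Each library records `total_mapped`, the denominator for tags-per-million
(TPM) scaling: one read copy contributes `1e6 / total_mapped` TPM, so a
library whose denominator equals its copy sum carries exactly 1,000,000 TPM.

## Read clustering

Reads on one chromosome and strand are merged into a cluster when the gap
between the genomic end (exclusive) of the earlier read and the start of
the next is at most 25 nt; touching or overlapping reads always merge.
Clusters are ranked by raw read count or by read density (TPM per
nucleotide); ties break on the cluster's strand-aware T→C count (more
cross-link evidence first) and then on the leftmost coordinate, so output
order is fully deterministic. When a cluster overlaps annotated features of
several categories it takes the highest-priority one (snoRNA/scaRNA first,
then miRNA, tRNA, snRNA, rRNA, repeat, mRNA exon, other; configurable).
Clusters feeding the gene finder are extended by 25 nt per side.

## C/D box gene finder

* **C box**: every 7-mer within one mismatch of `RUGAUGA`; A or G at the
  degenerate first position counts as a match, `N` never matches.
* **D box**: exact `CUGA` or `AUGA`, entirely 3' of the C box.
* **Terminal stem**: searched in the ≤ 10 nt windows immediately 5' of the
  C box and 3' of the D box. A stem is a *contiguous* antiparallel duplex
  (no bulges) of at least 4 canonical pairs with at least 2 G-C/C-G.
  "Canonical" means Watson–Crick only; G-U wobble is available behind the
  `allow_gu` flag but off by default, which is the stricter and fully
  testable reading. Among valid stems the winner maximises pair count, then
  G-C count, then minimises the summed distance of the arms to the boxes,
  with any remaining tie broken toward smaller window offsets.
* **Mature boundaries** are the outermost paired nucleotides of the two
  arms. Candidates sharing a C box are reduced to the best-stem one
  (then fewest mature nucleotides, then smallest D box start); candidates
  with distinct C boxes are all reported, so tandem genes are not
  suppressed.

U and T are equivalent on input; output sequences are RNA. The detector is
verified against an independent exhaustive enumeration of every
(C box, D box, stem placement) triple on random sequences up to 60 nt.

Two post-filters mirror the discovery screen: an **expression filter**
keeping candidates with mean coverage ≥ 1 TPM per nucleotide both in the
small-RNA library (counting only reads covering ≥ 50% of the candidate) and
in at least one CLIP library, and a **conservation filter** passing a
candidate when the mean per-nucleotide conservation score over its 11 C+D
box positions is strictly greater than 0.25 (missing positions score 0).

## Binding profiles

Per-snoRNA coverage counts every read copy at every position it covers
(reads, not 5' ends, following read-profile convention); conversion counts
are copies-weighted strand-aware T→C events. Minus-strand profiles are
reported in transcript orientation. Profile similarity is Pearson
correlation of the coverage arrays (scale-invariant, so raw vs TPM coverage
is immaterial); a constant profile has undefined correlation and is
excluded from summary fractions. Per-position *z*-scores use the population
(n) standard deviation over the whole snoRNA — the *z* transform here is
descriptive of a fixed profile, not inferential — and region scores are
mean *z* over the region's positions. Guide regions are the nine
nucleotides upstream of the D and D' boxes; the guide-with-target versus
orphan comparison reports the fraction of regions with strictly positive
mean *z* per group plus the full empirical distributions.

## Processing boundaries

Read 5' ends are histogrammed as signed offsets from the first nucleotide
of the C box and 3' ends from the last nucleotide of the D box, in
transcript orientation, copies-weighted (a distinct-read weighting flag
exists). The modal boundary is the histogram argmax; ties prefer offsets in
the canonical mature windows (−4/−5 for starts, +2..+5 for ends), then
offsets closer to zero. Long/short library agreement asks for exact
nucleotide identity of the modal offsets over the top-expressed snoRNAs
(ranked by long-library read count). Reads are classified as 5'-derived,
3'-derived, spanning or internal by whether their ends fall within ±2 nt
(configurable) of the mature boundaries; mature boundaries come from modal
read offsets when reads are available, else from the stem-derived candidate
span.

## Guide targets and enrichment

Guides are the 8-mers (optionally 9-mers) immediately or one nucleotide
upstream of the D/D' box. A target hit is an exact reverse-complement
occurrence (Watson–Crick only by default). The predicted methylation site
follows the D+5 rule: the target nucleotide paired with the fifth guide
nucleotide upstream of the box, counting the nucleotide abutting the box as
position 1. For an antiparallel duplex where target position `t+i` pairs
guide position `7−i`, that is `t + 4 − offset`; the alternative counting
that calls the abutting nucleotide position 0 (`t + 5 − offset`) is
available via `counting="adjacent-is-zero"`.

The shuffle-enrichment test counts cluster sequences containing at least
one guide complement and compares against the mean over 100 (default)
mononucleotide shuffles of every cluster sequence (composition preserved;
Fisher–Yates via one seeded generator). A dinucleotide-preserving mode
exists as an option; its random successor walk can dead-end, in which case
it retries up to 100 times and finally falls back to the identity walk —
the default mononucleotide shuffle is exact and is what the enrichment
statistics use.

The percentile calibration wrapper emulates an energy-cutoff procedure for
an external duplex scorer: it scores the query against `n_random` (default
1,000) uniform-random sequences of length 100 over the query's alphabet and
returns the cutoff such that a prediction passes only when it scores
strictly lower (better) than at least 90% (default) of the random scores;
`passes_cutoff` additionally enforces ≥ 3 canonical pairs per duplex side
when the scorer supplies per-side pair counts. Composition-matched random
backgrounds are a caller-side choice of alphabet weights; the default is
uniform because no background model is prescribed. Thermodynamic duplex
prediction itself is deliberately out of scope — any external scorer's
output plugs in.

## Class composition and Ago2 loading

Library composition is the copies-weighted percent of reads per RNA class
(miRNA, tRNA, snRNA, C/D snoRNA, H/ACA snoRNA) with an explicit `none`
category, so each column sums to 100% of mapped reads. A read overlapping
several classes counts once at the highest-priority class; multi-mapping
reads count once at their single assigned category (fractional 1/n
weighting is available behind a flag). Ratios are kept at full precision
and rounded only for display. The package ships a small reference
class-composition table (HEK293 18–30 nt small-RNA pool; HeLa Ago2 IP,
asynchronous and mitotic) used by the ratio and loading-efficiency
examples.

## Synthetic data generator

The generator is the package's study-condition definition, not a tuning
knob; all randomness flows through one numpy Generator seeded from the
mandatory config seed, so outputs are byte-identical across runs.

* **Genome**: i.i.d. uniform nucleotides (60 kb default) with 30 embedded
  intact C/D box loci on random strands. Each locus is, in transcript
  order: a 5 bp stem arm (≥ 3 G-C), the C box, an internal region of
  35–55 nt that by default carries a 9-nt guide window, a D' box, a
  degenerate C' box (two mismatches from the C consensus so the scanner
  does not treat it as a second C box) and a second 9-nt guide window, then
  the D box and the complementary 3' stem arm. Spacer sequence is rejection-
  sampled to be free of box motifs, and every embedded locus is validated
  by running the detector in its genomic context — the locus is resampled
  until the candidate reported for the planted C box reproduces the planted
  boxes and mature span exactly. Because the stem windows are a fixed
  ±10 nt genomic context, this validation holds for any later cluster
  extent.
* **PAR-CLIP reads**: anchors drawn per-position with region weights
  following the empirical core-protein preference D' > C ≈ C' > D > rest
  (defaults 6 : 3 : 3 : 1.5 : 1); guide windows get weight 3, tripled for
  the half of snoRNAs simulated as having a known target. Read lengths are
  12–20 nt (nuclease-trimmed fragments); these two choices were calibrated
  so the synthetic data reproduces the qualitative profile structure of
  real core-protein CLIP — D' z-scores above the rest in ≥ 90% of loci,
  and a majority of targeted but a minority of orphan guide regions with
  positive *z*. Every covered uridine converts T→C with probability 0.15.
  A background of 1,000 scattered reads provides unannotated clusters.
* **Small-RNA reads**: long-fraction reads span a mature form whose ends
  are drawn per read from the boundary-offset distributions
  ({−4: 0.7, −5: 0.3} upstream of the C box; {+2: 0.4, +3: 0.3, +4: 0.2,
  +5: 0.1} downstream of the D box). Short-fraction reads are 18–30 nt
  terminus-derived fragments mixed 39% 5'-derived, 46% 3'-derived and 15%
  internal (internal fragments keep ≥ 4 nt from both boundaries). Note that
  3'-derived reads sampled at offset +5 sit outside the ±2 classification
  window of the modal (+2) boundary and are counted internal — the
  recovered 3' fraction is therefore the mixture times the within-window
  offset mass (0.46 × 0.9 ≈ 41%), a deliberate property of the variable 3'
  end.
* **Ago2 IP**: the total library is multinomial over a realistic class pool
  (miRNA 18.3%, tRNA 9.7%, snRNA 5.3%, C/D 1.75%, H/ACA 0.32%, rest
  unannotated) and the IP library multinomial over pool × inclusion-weight
  proportions. Weight-recovery checks use the miRNA-vs-unannotated pair:
  at 10⁵ reads the rare classes (C/D at ~0.005% of the IP) carry
  multinomial noise far above 10%, so precision statements are made where
  the counts support them.
* **Mini-snoRNA stand-ins**: `make_mini_snorna` builds fully synthetic
  minimal C/D sequences (a 4 bp G/C stem, one-nt gap 5' of the C box) whose
  stem-bounded mature length is `guide + 20` nt — 27 nt at the shortest
  7-nt guide — used to exercise the detector on extreme gene sizes.

What the generator does **not** emulate: sequencing errors and quality,
ligation and amplification biases, host-gene splicing and intron context,
expression heterogeneity across loci, multi-mapping ambiguity, and real
genomic composition (background is uniform unless configured otherwise).
Passing recovery tests therefore demonstrates correctness of the
algorithms under the stated statistical structure, not performance on real
libraries.

## Problem sizes and determinism

Default analyses use 30 snoRNAs × 500 reads per library, 10⁵-read
class-mixture libraries, 1,000 random sequences for detector-oracle and
cutoff-calibration checks, and 100 shuffles for enrichment — sizes at which
every recovery statistic is stable across seeds while the full test suite
and the acceptance script each run in seconds. Every stochastic entry point
takes an explicit seed or derives independent streams from the config seed.

## Known limitations

* The stem search is purely combinatorial; no thermodynamics, so among
  equally long duplexes the G-C-richest wins regardless of stacking.
* C'/D' boxes are planted by the generator but not *discovered* by the
  detector (homology evidence would be required); guide-region analyses
  read them from annotation.
* H/ACA snoRNA prediction is delegated to external tools via the annotation
  interface; only C/D detection is native.
* The dinucleotide shuffle option is heuristic (see above); use the default
  mononucleotide shuffle for exact composition-preserving nulls.
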