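# snopipe

Analysis pipeline for **C/D box snoRNA biogenesis and processing** from
PAR-CLIP of snoRNP core proteins (Fibrillarin, NOP56, NOP58) and small-RNA
sequencing. It is aimed at computational RNA biologists who want to

* discover C/D box(-like) snoRNA genes from clusters of protein cross-link
  reads,
* quantify where the core proteins bind along each snoRNA,
* map the processing boundaries of the mature snoRNA relative to its C and D
  boxes,
* predict 2'-O-methylation targets of the guide regions, and
* measure how efficiently snoRNA-derived small RNAs are loaded into
  Argonaute 2,

with a first-class synthetic-data generator so that every stage is testable
end to end without any sequencing download.

## The model

A C/D box snoRNA carries a **C box** (consensus `RUGAUGA`, R = A/G) near its
5' end and a **D box** (`CUGA` or `AUGA`) near its 3' end, brought together
by a short **terminal stem** formed by the flanking nucleotides. The gene
finder scans a sequence for every C box hit within one mismatch of the
consensus and every exact D box 3' of it, then requires a compact closing
stem — a contiguous antiparallel duplex of ≥ 4 Watson–Crick pairs with
≥ 2 G-C — within the 10 nt flanking each box. The mature candidate spans the
outermost paired nucleotides of the stem.

Downstream statistics follow standard definitions: reads are clustered when
their loci are ≤ 25 nt apart; libraries are scaled to tags per million
(TPM); per-position coverage *z*-scores use the population standard
deviation over the snoRNA; read 5'/3' ends are histogrammed relative to the
C box start and D box end (mature forms typically run from −4/−5 to
+2..+5); guide regions are the 8 nt immediately (or one nt) upstream of a
D/D' box, and the target nucleotide paired with the **fifth** guide
nucleotide upstream of the box is the predicted 2'-O-methylation site
(counting the nucleotide abutting the box as position 1). Loading
efficiency of class *a* vs *b* is `(IP_a/IP_b) / (total_a/total_b)`.

## Worked example

Run the numbered analysis scripts in order from the repository root; each is
a thin driver over the library in `src/snopipe/`:

```bash
python analysis/01_simulate.py --seed 1      # genome + libraries under results/sim/
python analysis/02_detect_snornas.py
python analysis/03_binding_profiles.py
python analysis/04_boundaries.py
python analysis/05_guide_targets.py
python analysis/06_ago_loading.py
```

With the default conditions (30 embedded snoRNA loci, 500 reads per locus,
seed 1), step 02 prints

```
top-200 cluster annotation: {'CD_snoRNA': 30, 'none': 170}
candidates: 37 detected, 32 pass the 1 TPM/nt expression filter
recovery with exact box coordinates: 100.0% (after expression filter: 100.0%)
```

meaning all 30 embedded loci are found by the cluster-and-detect pipeline
with their C and D boxes at the exact planted coordinates. Step 04 prints

```
modal 5' offsets: {-4: 30}
modal 3' offsets: {2: 30}
long/short modal agreement over top 30: start 100.0%, end 96.7%
short-read origin classes: {'five_prime_derived': '39.0%', 'three_prime_derived': '41.4%', ...}
```

the recovered mature boundaries (5' end 4 nt upstream of the C box, 3' end
2 nt downstream of the D box — the modes of the generator's offset
distributions) and the terminus-derived composition of the 18–30 nt read
fraction. Step 06 recomputes the reference class-composition ratios (C/D
fragments 5.5× more abundant than H/ACA in the total pool; H/ACA 5.2× more
abundant than C/D in the Ago2 IP, hence ≈ 28.6× more efficiently loaded)
and recovers the generator's miRNA inclusion weight within 0.2% from 10⁵
simulated reads.

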