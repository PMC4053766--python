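"""Independent brute-force oracle for the C/D box detector.

Exhaustively enumerates every (C box, D box, stem placement) triple with
plain nested loops and no shared code with the implementation, applying the
documented selection rules:

* C box: 7-mer within one mismatch of RUGAUGA (A/G at the first position);
* D box: exact CUGA or AUGA, entirely 3' of the C box;
* stem: contiguous antiparallel duplex of >= 4 Watson-Crick pairs with
  >= 2 G-C, arms inside the 10-nt windows flanking the boxes; best stem =
  most pairs, then most G-C, then smallest summed arm-to-box distance, then
  smallest downstream offset, then smallest upstream offset;
* one candidate per C box: best stem, then fewest mature nucleotides, then
  smallest D box start.

Returns, per candidate, the tuple
``(c_start, d_start, n_pairs, n_gc, mature_lo, mature_hi)``.
"""

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
PATTERN = "RUGAUGA"


def oracle_detect(sequence, extension=10, min_pairs=4, min_gc=2):
    seq = sequence.upper().replace("T", "U")
    c_hits = []
    for i in range(len(seq) - 6):
        mm = 0
        for p in range(7):
            allowed = "AG" if PATTERN[p] == "R" else PATTERN[p]
            if seq[i + p] not in allowed:
                mm += 1
        if mm <= 1:
            c_hits.append(i)
    d_hits = [i for i in range(len(seq) - 3) if seq[i : i + 4] in ("CUGA", "AUGA")]

    best_per_c = {}
    for c in c_hits:
        for d in d_hits:
            if d < c + 7:
                continue
            up = seq[max(0, c - extension) : c]
            down = seq[d + 4 : d + 4 + extension]
            stems = []
            for L in range(min_pairs, min(len(up), len(down)) + 1):
                for i in range(len(up) - L + 1):
                    for j in range(len(down) - L + 1):
                        pairs = [(i + k, j + L - 1 - k) for k in range(L)]
                        if not all((up[a], down[b]) in WC for a, b in pairs):
                            continue
                        gc = sum(
                            1 for a, b in pairs if {up[a], down[b]} == {"G", "C"}
                        )
                        if gc < min_gc:
                            continue
                        dist = (len(up) - (i + L)) + j
                        stems.append((-L, -gc, dist, j, i, pairs))
            if not stems:
                continue
            stems.sort(key=lambda s: s[:5])
            negL, neggc, _, _, _, pairs = stems[0]
            lo = (c - len(up)) + min(a for a, _ in pairs)
            hi = d + 4 + max(b for _, b in pairs) + 1
            rank = (negL, neggc, hi - lo, d)
            if c not in best_per_c or rank < best_per_c[c][0]:
                best_per_c[c] = (rank, (c, d, -negL, -neggc, lo, hi))
    return sorted(cand for _, cand in best_per_c.values())


def candidate_tuple(cand):
    """Implementation candidate -> oracle tuple form."""
    return (
        cand.c_box.start,
        cand.d_box.start,
        cand.stem.n_pairs,
        cand.stem.n_gc,
        cand.mature_span[0],
        cand.mature_span[1],
    )
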