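"""Small nucleotide-string helpers (RNA/DNA agnostic; U and T equivalent)."""

from __future__ import annotations

_RNA = str.maketrans("Tt", "Uu")
_COMPLEMENT = str.maketrans("ACGUTacgut", "UGCAAugcaa")

#: Watson-Crick pairs on RNA alphabet.
WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
#: Additional wobble pairs, enabled by ``allow_gu`` flags.
GU_PAIRS = {("G", "U"), ("U", "G")}


def as_rna(seq: str) -> str:
    """Uppercase RNA form of a sequence (T becomes U)."""
    return seq.upper().translate(_RNA)


def complement(seq: str) -> str:
    return as_rna(seq).translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement on the RNA alphabet."""
    return complement(seq)[::-1]


def is_wc_pair(a: str, b: str, allow_gu: bool = False) -> bool:
    pair = (as_rna(a), as_rna(b))
    if pair in WC_PAIRS:
        return True
    return allow_gu and pair in GU_PAIRS
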