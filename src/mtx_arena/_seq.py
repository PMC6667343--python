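"""Low-level nucleotide/peptide helpers shared across modules.

Sequences are plain Python strings over {A,C,G,T} (reads may carry N).
Bulk routines work on uint8 code arrays (A=0, C=1, G=2, T=3) so the
simulator and assembler can stay vectorised.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")

# uint8 base codes <-> ASCII
_CODE_OF = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_OF[ord(_b)] = _i
_ASCII_OF = np.frombuffer(BASES.encode(), dtype=np.uint8)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _build_codon_table() -> dict:
    table = {}
    for a in BASES:
        for b in BASES:
            for c in BASES:
                codon = a + b + c
                table[codon] = str(Seq(codon).translate())
    return table


CODON_TABLE = _build_codon_table()
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

# codon index (16*b0 + 4*b1 + b2) -> amino-acid ASCII code, for bulk work
CODON_AA_CODES = np.zeros(64, dtype=np.uint8)
for _c, _aa in CODON_TABLE.items():
    _idx = 16 * BASES.index(_c[0]) + 4 * BASES.index(_c[1]) + BASES.index(_c[2])
    CODON_AA_CODES[_idx] = ord(_aa)


def translate(seq: str) -> str:
    """Standard-code translation; codons containing non-ACGT become X."""
    aas = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i : i + 3]
        aas.append(CODON_TABLE.get(codon, "X"))
    return "".join(aas)


def encode(seq: str) -> np.ndarray:
    """String -> uint8 codes. Raises on non-ACGT symbols."""
    arr = _CODE_OF[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if arr.max(initial=0) > 3:
        raise ValueError("sequence contains non-ACGT symbols")
    return arr


def decode(codes: np.ndarray) -> str:
    return _ASCII_OF[codes].tobytes().decode()


def encode_reads(seqs: list[str], length: int) -> np.ndarray:
    """Equal-length read list -> (n, length) uint8 matrix."""
    buf = np.frombuffer("".join(seqs).encode(), dtype=np.uint8)
    return _CODE_OF[buf].reshape(len(seqs), length)


def rolling_kmer_codes(mat: np.ndarray, k: int) -> np.ndarray:
    """(n, L) base-code matrix -> (n, L-k+1) uint64 2-bit-packed k-mer codes."""
    n, L = mat.shape
    m = mat.astype(np.uint64)
    codes = np.zeros((n, L - k + 1), dtype=np.uint64)
    first = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        first = (first << np.uint64(2)) | m[:, j]
    codes[:, 0] = first
    mask = np.uint64((1 << (2 * k)) - 1)
    cur = first
    for j in range(1, L - k + 1):
        cur = ((cur << np.uint64(2)) | m[:, j + k - 1]) & mask
        codes[:, j] = cur
    return codes


def revcomp_kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of 2-bit-packed k-mer codes (vectorised)."""
    out = np.zeros_like(codes)
    cur = codes.copy()
    three = np.uint64(3)
    for _ in range(k):
        out = (out << np.uint64(2)) | (three - (cur & three))
        cur = cur >> np.uint64(2)
    return out


def kmer_code_to_str(code: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(BASES[code & 3])
        code >>= 2
    return "".join(reversed(chars))


def canonical(seq: str) -> str:
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
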