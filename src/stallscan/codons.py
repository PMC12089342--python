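"""Genetic-code tables and fast codon encoding shared across the package.

Codons are encoded as integers in [0, 64): ``16*b0 + 4*b1 + b2`` with
A=0, C=1, G=2, T=3. The standard nuclear genetic code is hard-coded;
selenocysteine recoding and stop read-through are ignored.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_TO_INT = {b: i for i, b in enumerate(BASES)}

# uint8 lookup: ASCII byte -> base integer, 255 for anything else (N etc.)
_ASCII_TO_BASE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_TO_INT.items():
    _ASCII_TO_BASE[ord(_b)] = _i
    _ASCII_TO_BASE[ord(_b.lower())] = _i

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))
AMINO_ACIDS = tuple(sorted(set(GENETIC_CODE.values()) - {"*"}))

ALL_CODONS = tuple(sorted(GENETIC_CODE))  # 64, lexicographic == encoding order
CODON_TO_AA = dict(GENETIC_CODE)


def encode_codon(codon: str) -> int:
    """Integer id of a triplet (lexicographic rank over ACGT alphabet)."""
    c = codon.upper()
    return 16 * BASE_TO_INT[c[0]] + 4 * BASE_TO_INT[c[1]] + BASE_TO_INT[c[2]]


def decode_codon(cid: int) -> str:
    return BASES[(cid >> 4) & 3] + BASES[(cid >> 2) & 3] + BASES[cid & 3]


STOP_IDS = frozenset(encode_codon(c) for c in STOP_CODONS)
SENSE_IDS = np.array(sorted(encode_codon(c) for c in SENSE_CODONS))

# decode_codon(i) == ALL_CODONS[i] by construction
assert all(decode_codon(i) == c for i, c in enumerate(ALL_CODONS))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0,C=1,G=2,T=3; 255 = other)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ASCII_TO_BASE[raw]


def codon_ids_per_position(encoded: np.ndarray) -> np.ndarray:
    """Codon id of the triplet starting at every position of an encoded sequence.

    Positions whose triplet runs off the end, or contains a non-ACGT base,
    get id 255. Returned array has the same length as the input.
    """
    n = encoded.size
    out = np.full(n, 255, dtype=np.uint8)
    if n < 3:
        return out
    b0 = encoded[:-2].astype(np.int16)
    b1 = encoded[1:-1].astype(np.int16)
    b2 = encoded[2:].astype(np.int16)
    valid = (b0 < 4) & (b1 < 4) & (b2 < 4)
    ids = 16 * b0 + 4 * b1 + b2
    out[: n - 2][valid] = ids[valid].astype(np.uint8)
    return out


def is_sense(codon: str) -> bool:
    return codon.upper() in GENETIC_CODE and codon.upper() not in STOP_CODONS
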