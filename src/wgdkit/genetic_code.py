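"""Standard genetic code and precomputed Nei–Gojobori codon tables.

Everything downstream (the NG86 estimator, the sequence simulator, identity
computations) works on integer codon indices 0..63 (``index = 16*b0 + 4*b1 +
b2`` with A,C,G,T = 0..3).  The tables built here implement the counting
conventions of the Nei–Gojobori (1986) method:

* synonymous *sites* per codon: at each of the three positions, the fraction
  of the three possible single-nucleotide changes that preserve the encoded
  amino acid.  Changes creating a stop codon count as nonsynonymous, so
  S + N = 3 for every sense codon.
* synonymous/nonsynonymous *differences* between two codons: averaged over
  all orderings of the single-nucleotide steps separating them; a step is
  synonymous iff it preserves the amino acid (steps into or out of a stop
  intermediate are nonsynonymous).
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

CODON_TABLE = {
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

ALL_CODONS = tuple(
    a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES
)
CODON_INDEX = {codon: i for i, codon in enumerate(ALL_CODONS)}
AMINO_ACIDS = tuple(CODON_TABLE[c] for c in ALL_CODONS)
IS_STOP = np.array([aa == "*" for aa in AMINO_ACIDS], dtype=bool)
SENSE_CODONS = tuple(c for c in ALL_CODONS if CODON_TABLE[c] != "*")
SENSE_INDICES = np.array([CODON_INDEX[c] for c in SENSE_CODONS], dtype=np.int64)


def codon_to_index(codon: str) -> int:
    """Index of an ACGT codon; KeyError for ambiguous symbols."""
    return (
        16 * NT_INDEX[codon[0]] + 4 * NT_INDEX[codon[1]] + NT_INDEX[codon[2]]
    )


def _neighbors(idx: int):
    """All (position, new_index) single-nucleotide neighbours of a codon."""
    digits = [(idx >> 4) & 3, (idx >> 2) & 3, idx & 3]
    for pos in range(3):
        for nt in range(4):
            if nt == digits[pos]:
                continue
            shift = (2 - pos) * 2
            yield pos, (idx & ~(3 << shift)) | (nt << shift)


def _build_site_table() -> np.ndarray:
    syn = np.zeros(64)
    for idx in range(64):
        if IS_STOP[idx]:
            continue
        s = 0.0
        for _pos, alt in _neighbors(idx):
            if not IS_STOP[alt] and AMINO_ACIDS[alt] == AMINO_ACIDS[idx]:
                s += 1.0 / 3.0
        syn[idx] = s
    return syn


def _step(idx: int, pos: int, nt: int) -> int:
    shift = (2 - pos) * 2
    return (idx & ~(3 << shift)) | (nt << shift)


def _build_difference_tables():
    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    ntdiff = np.zeros((64, 64), dtype=np.int64)
    for i in range(64):
        di = [(i >> 4) & 3, (i >> 2) & 3, i & 3]
        for j in range(64):
            dj = [(j >> 4) & 3, (j >> 2) & 3, j & 3]
            diff_pos = [p for p in range(3) if di[p] != dj[p]]
            ntdiff[i, j] = len(diff_pos)
            if not diff_pos:
                continue
            syn_total = 0.0
            non_total = 0.0
            n_paths = 0
            for order in itertools.permutations(diff_pos):
                cur = i
                s = n = 0
                for pos in order:
                    nxt = _step(cur, pos, dj[pos])
                    if AMINO_ACIDS[cur] == AMINO_ACIDS[nxt] and not (
                        IS_STOP[cur] or IS_STOP[nxt]
                    ):
                        s += 1
                    else:
                        n += 1
                    cur = nxt
                syn_total += s
                non_total += n
                n_paths += 1
            sd[i, j] = syn_total / n_paths
            nd[i, j] = non_total / n_paths
    return sd, nd, ntdiff


SYN_SITES = _build_site_table()
NONSYN_SITES = np.where(IS_STOP, 0.0, 3.0 - SYN_SITES)
SYN_DIFFS, NONSYN_DIFFS, NT_DIFFS = _build_difference_tables()

# synonymous alternatives per sense codon (same amino acid, excluding itself)
SYNONYMOUS_ALTERNATIVES: dict[int, np.ndarray] = {}
for _idx in SENSE_INDICES:
    _alts = [
        j
        for j in range(64)
        if j != _idx and not IS_STOP[j] and AMINO_ACIDS[j] == AMINO_ACIDS[_idx]
    ]
    SYNONYMOUS_ALTERNATIVES[int(_idx)] = np.array(_alts, dtype=np.int64)

# single-step nonsynonymous, non-stop neighbours per sense codon
NONSYN_NEIGHBORS: dict[int, np.ndarray] = {}
for _idx in SENSE_INDICES:
    _alts = [
        alt
        for _pos, alt in _neighbors(int(_idx))
        if not IS_STOP[alt] and AMINO_ACIDS[alt] != AMINO_ACIDS[_idx]
    ]
    NONSYN_NEIGHBORS[int(_idx)] = np.array(_alts, dtype=np.int64)


def encode_cds(seq: str) -> np.ndarray:
    """Encode an in-frame CDS string into codon indices (case-insensitive).

    Raises ValueError if the length is not a multiple of three or if the
    sequence contains non-ACGT symbols.
    """
    s = seq.upper()
    if len(s) == 0 or len(s) % 3:
        raise ValueError(
            f"CDS length {len(s)} is not a positive multiple of 3"
        )
    try:
        return np.array(
            [codon_to_index(s[i : i + 3]) for i in range(0, len(s), 3)],
            dtype=np.int64,
        )
    except KeyError as exc:
        raise ValueError(f"non-ACGT symbol in CDS: {exc}") from exc


def decode_codons(indices: np.ndarray) -> str:
    return "".join(ALL_CODONS[int(i)] for i in indices)


def translate_indices(indices: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[int(i)] for i in indices)
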