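"""Protein-guided pairwise codon alignment.

Coding sequences are translated, the proteins are globally aligned
(Needleman–Wunsch, BLOSUM62, affine gaps), and the protein alignment is
back-threaded onto the nucleotide sequences so that every gap is a whole
codon.  This mirrors what codon-aware aligners do for homolog pairs before
substitution-rate estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from .genetic_code import ALL_CODONS, CODON_TABLE

GAP_CODON = "---"

_ALIGNER = PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
_ALIGNER.open_gap_score = -10.0
_ALIGNER.extend_gap_score = -0.5


@dataclass
class CodonAlignment:
    """Aligned codon columns of two coding sequences.

    ``codons_a``/``codons_b`` have equal length; a gap is the string ``---``.
    ``has_internal_stop`` flags sequences whose translation contains a stop
    before the final codon (tolerated, but such columns are excluded from
    NG86 site counts downstream).
    """

    codons_a: list[str]
    codons_b: list[str]
    score: float = 0.0
    has_internal_stop: bool = False
    flags: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.codons_a)

    def ungapped(self) -> tuple[str, str]:
        """Input sequences recovered by dropping gap columns."""
        a = "".join(c for c in self.codons_a if c != GAP_CODON)
        b = "".join(c for c in self.codons_b if c != GAP_CODON)
        return a, b


def _split_codons(cds: str) -> list[str]:
    s = cds.upper().replace("U", "T")
    if len(s) < 3:
        raise ValueError("coding sequence shorter than one codon")
    if len(s) % 3:
        raise ValueError(f"CDS length {len(s)} is not a multiple of 3")
    return [s[i : i + 3] for i in range(0, len(s), 3)]


def _translate(codons: list[str]) -> str:
    # '*' for stops, 'X' for codons with ambiguous symbols
    return "".join(
        CODON_TABLE.get(c, "X") if c in CODON_TABLE or c not in ALL_CODONS
        else "*"
        for c in codons
    )


def align_codons(cds_a: str, cds_b: str) -> CodonAlignment:
    """Globally align two coding sequences codon-by-codon.

    The alignment is computed at the protein level and threaded back to the
    codons, so removing gap columns always restores the input sequences and
    the translated columns coincide with the protein alignment.
    """
    codons_a = _split_codons(cds_a)
    codons_b = _split_codons(cds_b)
    prot_a = _translate(codons_a)
    prot_b = _translate(codons_b)
    flags: list[str] = []
    internal_stop = "*" in prot_a[:-1] or "*" in prot_b[:-1]
    if internal_stop:
        flags.append("internal_stop")
    # BLOSUM62 carries '*' and 'X' columns, so stops/ambiguities align too.
    aln = _ALIGNER.align(prot_a, prot_b)[0]
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for col_a, col_b in zip(aln[0], aln[1]):
        if col_a == "-":
            out_a.append(GAP_CODON)
        else:
            out_a.append(codons_a[ia])
            ia += 1
        if col_b == "-":
            out_b.append(GAP_CODON)
        else:
            out_b.append(codons_b[ib])
            ib += 1
    return CodonAlignment(
        codons_a=out_a,
        codons_b=out_b,
        score=float(aln.score),
        has_internal_stop=internal_stop,
        flags=flags,
    )


def protein_alignment_score(prot_a: str, prot_b: str) -> float:
    """Optimal global protein alignment score under the module's scoring."""
    return float(_ALIGNER.score(prot_a, prot_b))
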