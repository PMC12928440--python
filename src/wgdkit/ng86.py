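"""Nei–Gojobori (1986) synonymous/nonsynonymous divergence estimator.

Counting method: per codon, synonymous sites are the fraction of one-step
changes preserving the amino acid (stop-creating changes are nonsynonymous,
so S + N = 3 per compared codon); differences between codons are averaged
over all orderings of the single-nucleotide steps separating them.  The
proportions ps = Sd/S and pn = Nd/N are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4)·ln(1 - 4p/3); p >= 3/4 is reported as
saturated rather than as a number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import genetic_code as gc
from .alignment import GAP_CODON, CodonAlignment

SATURATION_P = 0.75


@dataclass
class NG86Result:
    """Site and difference counts plus corrected rates for one gene pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    ks: float | None
    ka: float | None
    codons_compared: int
    flags: list[str] = field(default_factory=list)

    @property
    def saturated(self) -> bool:
        return "saturated_ks" in self.flags or "saturated_ka" in self.flags


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None at or beyond saturation."""
    if p < 0:
        raise ValueError("proportion of differences must be >= 0")
    if p >= SATURATION_P:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_from_indices(idx_a: np.ndarray, idx_b: np.ndarray) -> NG86Result:
    """NG86 over two equal-length codon-index arrays (no gaps).

    Columns containing a stop codon in either sequence are excluded from
    site and difference counts.
    """
    if idx_a.shape != idx_b.shape:
        raise ValueError("codon index arrays differ in length")
    keep = ~(gc.IS_STOP[idx_a] | gc.IS_STOP[idx_b])
    a = idx_a[keep]
    b = idx_b[keep]
    n_codons = int(a.size)
    if n_codons == 0:
        raise ValueError("no comparable (gap-free, stop-free) codon columns")
    # sites averaged between the two sequences
    S = float((gc.SYN_SITES[a].sum() + gc.SYN_SITES[b].sum()) / 2.0)
    N = float((gc.NONSYN_SITES[a].sum() + gc.NONSYN_SITES[b].sum()) / 2.0)
    Sd = float(gc.SYN_DIFFS[a, b].sum())
    Nd = float(gc.NONSYN_DIFFS[a, b].sum())
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    flags: list[str] = []
    ks = jukes_cantor(ps) if S > 0 else None
    ka = jukes_cantor(pn) if N > 0 else None
    if S > 0 and ks is None:
        flags.append("saturated_ks")
    if N > 0 and ka is None:
        flags.append("saturated_ka")
    if S == 0:
        flags.append("no_synonymous_sites")
    return NG86Result(
        S=S, N=N, Sd=Sd, Nd=Nd, ps=ps, pn=pn, ks=ks, ka=ka,
        codons_compared=n_codons, flags=flags,
    )


def ng86(alignment: CodonAlignment) -> NG86Result:
    """NG86 over a codon alignment.

    Gap columns and columns with ambiguous (non-ACGT) symbols are excluded;
    so are stop-containing columns.  Raises ValueError when no comparable
    codon column remains.
    """
    idx_a: list[int] = []
    idx_b: list[int] = []
    for ca, cb in zip(alignment.codons_a, alignment.codons_b):
        if ca == GAP_CODON or cb == GAP_CODON:
            continue
        if any(ch not in "ACGT" for ch in ca + cb):
            continue
        idx_a.append(gc.codon_to_index(ca))
        idx_b.append(gc.codon_to_index(cb))
    if not idx_a:
        raise ValueError("no comparable (gap-free, unambiguous) codon columns")
    return ng86_from_indices(
        np.array(idx_a, dtype=np.int64), np.array(idx_b, dtype=np.int64)
    )


def ng86_pair(cds_a: str, cds_b: str) -> NG86Result:
    """Convenience wrapper: protein-guided alignment followed by NG86."""
    from .alignment import align_codons

    return ng86(align_codons(cds_a, cds_b))
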