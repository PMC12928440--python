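"""Independent brute-force oracles used to verify the implementation.

These deliberately re-derive everything from first principles (Biopython
translation, explicit recursion, dense DP) without importing the package's
precomputed tables or chaining code, so agreement is a meaningful check.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) sites of one codon: per position, the
    fraction of the three single-base changes that preserve the amino acid
    (stop-creating changes count as nonsynonymous)."""
    aa = _aa(codon)
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _aa(alt) != "*" and _aa(alt) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _path_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons
    over all orderings of the single-base steps separating them."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    syn_sum = non_sum = 0.0
    n_orders = 0
    for order in itertools.permutations(diff):
        cur = c1
        s = n = 0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if (
                _aa(cur) == _aa(nxt)
                and _aa(cur) != "*"
                and _aa(nxt) != "*"
            ):
                s += 1
            else:
                n += 1
            cur = nxt
        syn_sum += s
        non_sum += n
        n_orders += 1
    return syn_sum / n_orders, non_sum / n_orders


def ng86_oracle(cds_a: str, cds_b: str):
    """Pathway-enumeration NG86 on two aligned, equal-length CDS strings.

    Returns (S, N, Sd, Nd, ks, ka); ks/ka are None at saturation.
    Stop-containing codon columns are excluded.
    """
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if _aa(ca) == "*" or _aa(cb) == "*":
            continue
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _path_counts(ca, cb)
        Sd += sd
        Nd += nd

    def jc(p):
        if p >= 0.75:
            return None
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    return S, N, Sd, Nd, jc(ps), jc(pn)


def gotoh_score(a: str, b: str, matrix, gap_open: float, gap_extend: float):
    """Optimal global affine-gap alignment score (Gotoh DP, dense)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1],
                          Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def chain_oracle(matches, min_pairs: int, max_gap: int):
    """Brute-force chain peeling over (rank_a, rank_b) matches.

    Independent O(n^2) longest-chain DP with the canonical tie-breaks
    (best predecessor = smallest index among maxima; chain end = first
    index attaining the maximum length), peeled until the best chain is
    shorter than min_pairs.  Returns a list of chains (lists of matches).
    """

    def best_chain(ms):
        n = len(ms)
        if n == 0:
            return []
        length = [1] * n
        back = [-1] * n
        for i in range(n):
            for j in range(i):
                ok = (
                    ms[j][0] < ms[i][0]
                    and ms[j][1] < ms[i][1]
                    and ms[i][0] - ms[j][0] - 1 <= max_gap
                    and ms[i][1] - ms[j][1] - 1 <= max_gap
                )
                if ok and length[j] + 1 > length[i]:
                    length[i] = length[j] + 1
                    back[i] = j
        end = length.index(max(length))
        chain = []
        while end != -1:
            chain.append(end)
            end = back[end]
        return chain[::-1]

    remaining = sorted(matches)
    chains = []
    while True:
        idx = best_chain(remaining)
        if len(idx) < min_pairs:
            break
        chains.append([remaining[i] for i in idx])
        picked = set(idx)
        remaining = [m for i, m in enumerate(remaining) if i not in picked]
    return chains


def majority_probability_oracle(probs, m: int):
    """P(origin i is the strict plurality of m iid draws), by enumerating
    all k^m label sequences."""
    k = len(probs)
    out = [0.0] * k
    for seq in itertools.product(range(k), repeat=m):
        counts = [0] * k
        for lab in seq:
            counts[lab] += 1
        top = max(counts)
        winners = [i for i, c in enumerate(counts) if c == top]
        if len(winners) != 1:
            continue
        p = 1.0
        for lab in seq:
            p *= probs[lab]
        out[winners[0]] += p
    return out
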