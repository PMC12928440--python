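"""Collinear synteny-block chaining, syntenic depth and pseudochromosomes.

Homolog pairs are placed in gene-rank space (the ordinal position of each
gene along its chromosome or scaffold) and chained per (chromosome pair,
orientation) into collinear blocks: runs of pairs with monotone rank
progression on both genomes, at most ``max_gap`` intervening genes between
consecutive pairs on *each* genome, and at least ``min_pairs`` pairs.

Chaining is an exact longest-chain dynamic program with deterministic
tie-breaks, applied repeatedly (peeling the best chain, then re-chaining
the remainder) so the block set is reproducible and oracle-testable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_MIN_PAIRS = 5
DEFAULT_MAX_GAP = 100


# ---------------------------------------------------------------------------
# gene positions


def positions_from_bed(bed: pd.DataFrame) -> pd.DataFrame:
    """Rank genes along each chromosome from a BED-like table.

    Expects columns (chrom, start, end, strand, gene_id); returns a frame
    with (gene_id, chrom, rank, strand) where rank is the 0-based ordinal
    of the gene along its chromosome, ordered by start coordinate.
    """
    required = {"chrom", "start", "gene_id"}
    if not required <= set(bed.columns):
        raise ValueError(f"BED-like table must have columns {sorted(required)}")
    df = bed.sort_values(["chrom", "start", "gene_id"], kind="mergesort").copy()
    df["rank"] = df.groupby("chrom").cumcount()
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df[["gene_id", "chrom", "rank", "strand"]].reset_index(drop=True)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "strand", "gene_id"],
    )
    return df.astype({"chrom": str, "gene_id": str})


def _position_lookup(positions: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {
        g: (c, int(r))
        for g, c, r in zip(
            positions["gene_id"], positions["chrom"], positions["rank"]
        )
    }


# ---------------------------------------------------------------------------
# pair-level filters


def drop_same_chromosome_multicopy(
    pairs: pd.DataFrame,
    positions_a: pd.DataFrame,
    positions_b: pd.DataFrame,
) -> pd.DataFrame:
    """Remove pairs of genes with >= 2 homologous copies on one partner
    chromosome (local/tandem duplications that would seed spurious blocks).

    Applied symmetrically: if gene_a has two partners on a single B
    chromosome, all of gene_a's pairs on that chromosome are removed, and
    vice versa.
    """
    if pairs.empty:
        return pairs.copy()
    lut_a = _position_lookup(positions_a)
    lut_b = _position_lookup(positions_b)
    for col, lut in (("gene_a", lut_a), ("gene_b", lut_b)):
        missing = sorted(set(pairs[col]) - set(lut))
        if missing:
            raise KeyError(f"no position for gene(s): {missing[:10]}")
    df = pairs.copy()
    df["_chr_a"] = [lut_a[g][0] for g in df["gene_a"]]
    df["_chr_b"] = [lut_b[g][0] for g in df["gene_b"]]
    bad_a = (
        df.groupby(["gene_a", "_chr_b"]).size().loc[lambda s: s >= 2].index
    )
    bad_b = (
        df.groupby(["gene_b", "_chr_a"]).size().loc[lambda s: s >= 2].index
    )
    keep = ~(
        pd.MultiIndex.from_frame(df[["gene_a", "_chr_b"]]).isin(bad_a)
        | pd.MultiIndex.from_frame(df[["gene_b", "_chr_a"]]).isin(bad_b)
    )
    return (
        df.loc[keep]
        .drop(columns=["_chr_a", "_chr_b"])
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# chaining


@dataclass
class SyntenyBlock:
    """A chained run of collinear homolog pairs between two chromosomes."""

    block_id: int
    chrom_a: str
    chrom_b: str
    orientation: str  # '+' same, '-' inverted
    pairs: list[tuple[str, str, int, int]]  # (gene_a, gene_b, rank_a, rank_b)
    ks_median: float | None = None
    ks_range: tuple[float, float] | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def longest_chain(matches, max_gap: int):
    """Longest strictly-monotone chain (rank_a and rank_b increasing) with
    <= max_gap intervening ranks on both axes.

    ``matches`` is a sequence of (rank_a, rank_b, payload...) tuples sorted
    by (rank_a, rank_b).  Deterministic: ties in chain length prefer the
    smallest predecessor/end index.  Returns a list of indices into
    ``matches``.
    """
    n = len(matches)
    if n == 0:
        return []
    ra = np.fromiter((m[0] for m in matches), dtype=np.int64, count=n)
    rb = np.fromiter((m[1] for m in matches), dtype=np.int64, count=n)
    dp = np.ones(n, dtype=np.int64)
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        ok = (
            (ra[:i] < ra[i])
            & (rb[:i] < rb[i])
            & (ra[i] - ra[:i] - 1 <= max_gap)
            & (rb[i] - rb[:i] - 1 <= max_gap)
        )
        if ok.any():
            cand = np.where(ok, dp[:i], 0)
            j = int(np.argmax(cand))  # first max index
            if cand[j] > 0:
                dp[i] = cand[j] + 1
                prev[i] = j
    end = int(np.argmax(dp))  # first max index
    chain = []
    while end != -1:
        chain.append(end)
        end = int(prev[end])
    chain.reverse()
    return chain


def _chain_cell(matches, min_pairs: int, max_gap: int):
    """Peel maximal chains from one (chromosome pair, orientation) cell."""
    remaining = list(matches)
    chains = []
    while len(remaining) >= min_pairs:
        idx = longest_chain(remaining, max_gap)
        if len(idx) < min_pairs:
            break
        chains.append([remaining[i] for i in idx])
        taken = set(idx)
        remaining = [m for i, m in enumerate(remaining) if i not in taken]
    return chains


def chain_blocks(
    pairs: pd.DataFrame,
    positions_a: pd.DataFrame,
    positions_b: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    max_gap: int = DEFAULT_MAX_GAP,
) -> list[SyntenyBlock]:
    """Chain homolog pairs into syntenic blocks.

    ``pairs`` needs columns (gene_a, gene_b) and optionally ks.  Blocks on
    the same chromosome pair with opposite orientations are distinct; the
    inverted orientation chains descending rank_b progressions (rank_b is
    negated internally so the same DP applies).
    """
    if pairs.empty:
        return []
    lut_a = _position_lookup(positions_a)
    lut_b = _position_lookup(positions_b)
    has_ks = "ks" in pairs.columns
    cells: dict[tuple[str, str], list] = {}
    for row in pairs.itertuples(index=False):
        ca, ra = lut_a[row.gene_a]
        cb, rb = lut_b[row.gene_b]
        ks = getattr(row, "ks", None) if has_ks else None
        cells.setdefault((ca, cb), []).append(
            (ra, rb, row.gene_a, row.gene_b, ks)
        )
    blocks: list[SyntenyBlock] = []
    next_id = 0
    for (ca, cb) in sorted(cells):
        matches = sorted(cells[(ca, cb)])
        for orientation in ("+", "-"):
            if orientation == "+":
                oriented = matches
            else:
                oriented = sorted((ra, -rb, ga, gb, ks)
                                  for ra, rb, ga, gb, ks in matches)
            for chain in _chain_cell(oriented, min_pairs, max_gap):
                members = [
                    (ga, gb, ra, rb if orientation == "+" else -rb)
                    for ra, rb, ga, gb, _ks in chain
                ]
                ks_vals = [
                    ks for *_ignore, ks in chain if ks is not None
                    and not (isinstance(ks, float) and np.isnan(ks))
                ]
                blocks.append(
                    SyntenyBlock(
                        block_id=next_id,
                        chrom_a=ca,
                        chrom_b=cb,
                        orientation=orientation,
                        pairs=members,
                        ks_median=float(np.median(ks_vals)) if ks_vals else None,
                        ks_range=(float(min(ks_vals)), float(max(ks_vals)))
                        if ks_vals
                        else None,
                    )
                )
                next_id += 1
    return blocks


# ---------------------------------------------------------------------------
# depth & pseudochromosomes


@dataclass
class DepthProfile:
    """Per-reference-chromosome count of distinct syntenic partners."""

    per_chromosome: dict[str, int]
    modal_depth: int
    partners: dict[str, set] = field(default_factory=dict)


def syntenic_depth(
    blocks: list[SyntenyBlock],
    reference: str = "a",
    chromosomes=None,
    exclude_self: bool = False,
) -> DepthProfile:
    """Count, per reference chromosome, the distinct partner chromosomes
    covered by >= 1 block; report the modal depth across chromosomes.

    ``reference`` selects which side of the blocks is the reference ('a' or
    'b').  ``exclude_self`` drops same-name chromosome pairs (for
    self-comparisons).  ``chromosomes`` optionally lists all reference
    chromosomes so that ones without blocks count as depth 0.
    """
    partners: dict[str, set] = {}
    if chromosomes:
        partners = {c: set() for c in chromosomes}
    for b in blocks:
        ref, tgt = (
            (b.chrom_a, b.chrom_b) if reference == "a" else (b.chrom_b, b.chrom_a)
        )
        if exclude_self and ref == tgt:
            continue
        partners.setdefault(ref, set()).add(tgt)
    depths = {c: len(s) for c, s in partners.items()}
    if not depths:
        return DepthProfile(per_chromosome={}, modal_depth=0, partners={})
    counts = Counter(depths.values())
    top = max(counts.values())
    modal = min(d for d, n in counts.items() if n == top)
    return DepthProfile(
        per_chromosome=depths, modal_depth=int(modal), partners=partners
    )


def assemble_pseudochromosomes(
    blocks: list[SyntenyBlock],
    scaffold_side: str = "a",
    scaffolds=None,
):
    """Assign scaffolds to reference chromosomes by plurality of chained
    pairs; pseudochromosomes take the reference numbering.

    Returns (assignment, unplaced) where assignment maps scaffold ->
    {"pseudochromosome", "n_pairs", "tie"}.  Ties go to the lower-numbered
    (natural sort) reference chromosome and are flagged.
    """
    votes: dict[str, Counter] = {}
    for b in blocks:
        scaf, ref = (
            (b.chrom_a, b.chrom_b) if scaffold_side == "a" else (b.chrom_b, b.chrom_a)
        )
        votes.setdefault(scaf, Counter())[ref] += b.n_pairs

    def _natkey(name: str):
        digits = "".join(c for c in str(name) if c.isdigit())
        return (int(digits) if digits else 0, str(name))

    assignment = {}
    for scaf, counter in votes.items():
        top = max(counter.values())
        winners = sorted((c for c, n in counter.items() if n == top), key=_natkey)
        assignment[scaf] = {
            "pseudochromosome": winners[0],
            "n_pairs": top,
            "tie": len(winners) > 1,
        }
    unplaced = sorted(set(scaffolds or []) - set(votes))
    return assignment, unplaced


# ---------------------------------------------------------------------------
# dotplot export


def export_dotplot_table(
    pairs: pd.DataFrame,
    positions_a: pd.DataFrame,
    positions_b: pd.DataFrame,
    ks_bands=None,
) -> pd.DataFrame:
    """One row per homolog pair with both rank coordinates and a Ks-band
    label; bands are closed-open [lo, hi) intervals, uncovered Ks -> 'other'.
    """
    lut_a = _position_lookup(positions_a)
    lut_b = _position_lookup(positions_b)
    bands = []
    for band in ks_bands or []:
        if len(band) == 3:
            lo, hi, label = band
        else:
            lo, hi = band
            label = f"[{lo},{hi})"
        bands.append((float(lo), float(hi), str(label)))

    rows = []
    for row in pairs.itertuples(index=False):
        ca, ra = lut_a[row.gene_a]
        cb, rb = lut_b[row.gene_b]
        ks = getattr(row, "ks", None)
        label = "other"
        if ks is not None and not (isinstance(ks, float) and np.isnan(ks)):
            for lo, hi, name in bands:
                if lo <= ks < hi:
                    label = name
                    break
        rows.append((row.gene_a, row.gene_b, ca, ra, cb, rb, ks, label))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_a", "gene_b", "chrom_a", "rank_a", "chrom_b", "rank_b",
            "ks", "band",
        ],
    )


def blocks_to_frame(blocks: list[SyntenyBlock]) -> pd.DataFrame:
    """Flat TSV-ready view of a block set (one row per block)."""
    return pd.DataFrame(
        [
            (
                b.block_id, b.chrom_a, b.chrom_b, b.orientation, b.n_pairs,
                b.ks_median,
                ";".join(f"{ga}|{gb}" for ga, gb, _ra, _rb in b.pairs),
            )
            for b in blocks
        ],
        columns=[
            "block_id", "chrom_a", "chrom_b", "orientation", "n_pairs",
            "ks_median", "members",
        ],
    )
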