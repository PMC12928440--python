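"""Ancestral-karyotype painting and rearrangement calling.

Each focal-genome gene is assigned an ancestral grass chromosome (A1..A12)
from its cross-species similarity hits: the chromosome of every comparator
hit is translated into one or more ancestral chromosomes through a
chromosome homology map, hit bitscores are summed per candidate origin and
normalized into an empirical origin distribution, and a bootstrap over that
distribution yields a support value per origin.  Genes whose best origin
reaches support >= 0.5 with a margin >= 0.05 over the runner-up are
'unique'; the rest are 'ambiguous' and are resolved, where possible, by the
dominant origin of their syntenic block.  Runs of consistently painted
genes along each chromosome then expose rearrangements: an
outer-inner-outer pattern is a nested chromosome insertion (NCI), a foreign
terminal segment is an end fusion, or a translocation when the exchange is
reciprocal.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ANCESTRAL_CHROMOSOMES = tuple(f"A{i}" for i in range(1, 13))

DEFAULT_SUPPORT_MIN = 0.5
DEFAULT_MARGIN_MIN = 0.05
DEFAULT_N_BOOTSTRAP = 1000
DEFAULT_MIN_SEGMENT = 5
DEFAULT_WINDOW = 10
DEFAULT_AMBIGUITY_THRESHOLD = 0.5


# ---------------------------------------------------------------------------
# homology map (comparator chromosome -> ancestral chromosomes)


class HomologyMap:
    """Per-species mapping from comparator chromosome to ancestral
    chromosome set, built from a table in ancestral-chromosome layout
    (one row per A1..A12, one column per species, comma-separated
    chromosome lists)."""

    def __init__(self, table: dict[str, dict[str, frozenset[str]]]):
        # table[species][chromosome] = frozenset of ancestral chromosomes
        self.table = table
        for species, chroms in table.items():
            seen = set().union(*chroms.values()) if chroms else set()
            missing = set(ANCESTRAL_CHROMOSOMES) - seen
            if missing:
                raise ValueError(
                    f"species {species!r}: ancestral chromosomes never "
                    f"mapped: {sorted(missing)}"
                )

    @classmethod
    def from_ancestral_table(cls, df: pd.DataFrame) -> "HomologyMap":
        """Build from a frame whose first column is the ancestral chromosome
        and remaining columns are species with comma-separated chromosome
        lists."""
        anc_col = df.columns[0]
        table: dict[str, dict[str, set]] = {}
        for species in df.columns[1:]:
            mapping: dict[str, set] = defaultdict(set)
            for anc, cell in zip(df[anc_col], df[species]):
                if pd.isna(cell):
                    continue
                for chrom in str(cell).split(","):
                    chrom = chrom.strip()
                    if chrom:
                        mapping[chrom].add(str(anc))
            table[str(species)] = {
                c: frozenset(v) for c, v in mapping.items()
            }
        return cls(table)

    @classmethod
    def from_tsv(cls, path) -> "HomologyMap":
        return cls.from_ancestral_table(pd.read_csv(path, sep="\t"))

    def origins(self, species: str, chromosome: str) -> frozenset[str]:
        try:
            by_chrom = self.table[species]
        except KeyError:
            raise KeyError(f"species {species!r} not in homology map")
        try:
            return by_chrom[str(chromosome)]
        except KeyError:
            raise KeyError(
                f"chromosome {chromosome!r} of species {species!r} not in "
                f"homology map"
            )

    def species(self) -> list[str]:
        return sorted(self.table)


def packaged_homology_map() -> HomologyMap:
    """The Poaceae chromosome homology table shipped with the package
    (O. sativa, S. bicolor, E. tef, O. thomaeum, Z. japonica,
    S. alterniflorus)."""
    from importlib.resources import files

    path = files("wgdkit.data") / "homology_map_poaceae.tsv"
    with path.open() as fh:
        return HomologyMap.from_ancestral_table(pd.read_csv(fh, sep="\t"))


# ---------------------------------------------------------------------------
# origin vectors and bootstrap assignment


@dataclass
class OriginVector:
    """Empirical ancestral-origin distribution for one gene (normalized
    bitscore mass per candidate origin)."""

    gene_id: str
    probabilities: dict[str, float]
    n_hits: int

    def __post_init__(self):
        total = sum(self.probabilities.values())
        if self.probabilities and abs(total - 1.0) > 1e-9:
            raise ValueError(f"origin probabilities sum to {total}, not 1")


@dataclass
class OriginAssignment:
    gene_id: str
    origins: list[str]  # best first
    support: float
    margin: float
    status: str  # 'unique' | 'ambiguous'
    candidate_origins: frozenset[str] = field(default_factory=frozenset)

    @property
    def best(self) -> str | None:
        return self.origins[0] if self.origins else None


def map_hits_to_ancestral(
    gene_id: str,
    gene_hits,
    homology_map: HomologyMap,
) -> OriginVector:
    """Translate a gene's comparator hits into an origin distribution.

    ``gene_hits`` is an iterable of (species, chromosome, bitscore).  A hit
    whose comparator chromosome maps to several ancestral chromosomes
    splits its bitscore mass equally among them; masses are normalized by
    the total bitscore over all hits.
    """
    hits = list(gene_hits)
    if not hits:
        raise ValueError(f"gene {gene_id!r}: no comparative hits")
    mass: dict[str, float] = defaultdict(float)
    total = 0.0
    for species, chrom, bitscore in hits:
        origins = homology_map.origins(species, chrom)
        share = float(bitscore) / len(origins)
        for o in origins:
            mass[o] += share
        total += float(bitscore)
    probs = {o: m / total for o, m in mass.items()}
    return OriginVector(gene_id=gene_id, probabilities=probs, n_hits=len(hits))


def bootstrap_assign(
    vector: OriginVector,
    n_bootstrap: int = DEFAULT_N_BOOTSTRAP,
    support_min: float = DEFAULT_SUPPORT_MIN,
    margin_min: float = DEFAULT_MARGIN_MIN,
    seed: int | np.random.Generator = 0,
) -> OriginAssignment:
    """Bootstrap the origin distribution and assign the gene.

    Each replicate draws m labels (m = number of contributing hits) from
    the empirical distribution; an origin's support is the fraction of
    replicates in which it is the strict plurality label.  The gene is
    'unique' iff the best support >= support_min and exceeds the runner-up
    by >= margin_min.
    """
    origins = sorted(vector.probabilities)
    probs = np.array([vector.probabilities[o] for o in origins])
    candidates = frozenset(origins)
    if len(origins) == 1:
        return OriginAssignment(
            gene_id=vector.gene_id, origins=origins, support=1.0,
            margin=1.0, status="unique", candidate_origins=candidates,
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    m = max(vector.n_hits, 1)
    counts = rng.multinomial(m, probs, size=int(n_bootstrap))
    top = counts.max(axis=1)
    is_top = counts == top[:, None]
    strict = is_top.sum(axis=1) == 1  # ties give no majority
    wins = (is_top & strict[:, None]).sum(axis=0) / float(n_bootstrap)
    order = np.argsort(-wins, kind="stable")
    support = float(wins[order[0]])
    runner = float(wins[order[1]]) if len(order) > 1 else 0.0
    margin = support - runner
    unique = support >= support_min and margin >= margin_min
    if unique:
        kept = [origins[order[0]]]
    else:
        # no clear winner: retain the supported origins, best first
        kept = [origins[i] for i in order if wins[i] > 0] or origins
    return OriginAssignment(
        gene_id=vector.gene_id,
        origins=kept,
        support=support,
        margin=margin,
        status="unique" if unique else "ambiguous",
        candidate_origins=candidates,
    )


def exact_majority_support(probs, m: int) -> dict[int, float]:
    """Exact probability that each origin is the strict plurality among m
    draws from ``probs`` (enumeration over all count compositions).

    Independent closed-form check for the bootstrap; practical for small m.
    """
    from itertools import product
    from math import factorial

    probs = list(probs)
    k = len(probs)
    out = {i: 0.0 for i in range(k)}
    for counts in product(range(m + 1), repeat=k):
        if sum(counts) != m:
            continue
        top = max(counts)
        winners = [i for i, c in enumerate(counts) if c == top]
        if len(winners) != 1:
            continue
        coef = factorial(m)
        p = 1.0
        for c, pr in zip(counts, probs):
            coef //= factorial(c)
            p *= pr**c
        out[winners[0]] += coef * p
    return out


# ---------------------------------------------------------------------------
# block painting


@dataclass
class PaintedBlock:
    """A syntenic block with one resolved ancestral origin (or terminated)."""

    block_id: int
    chromosome: str
    origin: str | None
    genes: list[str]
    ranks: list[int]
    terminated: bool = False


def _split_runs(entries, key):
    """Split a sequence into maximal runs of equal key(entry)."""
    runs = []
    current = []
    current_key = object()
    for e in entries:
        k = key(e)
        if current and k != current_key:
            runs.append((current_key, current))
            current = []
        current_key = k
        current.append(e)
    if current:
        runs.append((current_key, current))
    return runs


def paint_blocks(
    assignments: dict[str, OriginAssignment],
    blocks,
    positions: pd.DataFrame,
) -> list[PaintedBlock]:
    """Resolve one ancestral origin per syntenic block.

    The block origin is the shared origin of its unambiguous member genes;
    ambiguous members inherit it when it is among their candidate origins.
    If unambiguous members disagree, the block is split at each
    disagreement point into consistent sub-blocks.
    """
    from .synteny import _position_lookup

    lut = _position_lookup(positions)
    painted: list[PaintedBlock] = []
    next_id = 0
    for block in blocks:
        members = []
        for ga, _gb, _ra, _rb in block.pairs:
            if ga not in assignments:
                continue
            chrom, rank = lut[ga]
            members.append((rank, ga, assignments[ga]))
        if not members:
            continue
        members.sort()
        chrom = lut[members[0][1]][0]
        # split wherever consecutive unambiguous origins disagree
        segments: list[list] = [[]]
        last_unambig: str | None = None
        for rank, gene, asn in members:
            if asn.status == "unique":
                if last_unambig is not None and asn.best != last_unambig:
                    segments.append([])
                last_unambig = asn.best
            segments[-1].append((rank, gene, asn))
        for seg in segments:
            if not seg:
                continue
            uniq = [a.best for _r, _g, a in seg if a.status == "unique"]
            origin = uniq[0] if uniq else None
            genes, ranks = [], []
            for rank, gene, asn in seg:
                if asn.status == "unique":
                    keep = asn.best == origin
                else:
                    keep = origin is not None and (
                        origin in asn.candidate_origins
                    )
                if keep:
                    genes.append(gene)
                    ranks.append(rank)
            painted.append(
                PaintedBlock(
                    block_id=next_id,
                    chromosome=chrom,
                    origin=origin,
                    genes=genes,
                    ranks=ranks,
                    terminated=origin is None,
                )
            )
            next_id += 1
    return painted


def terminate_transition_zones(
    painted: list[PaintedBlock],
    assignments: dict[str, OriginAssignment],
    ambiguity_fraction_threshold: float = DEFAULT_AMBIGUITY_THRESHOLD,
    window: int = DEFAULT_WINDOW,
) -> list[PaintedBlock]:
    """Excise high-ambiguity windows from painted blocks.

    Sliding windows of ``window`` genes whose ambiguous fraction exceeds
    the threshold are removed from their block and re-emitted as
    terminated (origin-less) transition-zone blocks.
    """
    out: list[PaintedBlock] = []
    next_id = 0
    for block in painted:
        if block.terminated or len(block.genes) == 0:
            block.block_id = next_id
            next_id += 1
            out.append(block)
            continue
        flags = [
            assignments[g].status == "ambiguous" if g in assignments else False
            for g in block.genes
        ]
        n = len(flags)
        drop = np.zeros(n, dtype=bool)
        w = min(window, n)
        for start in range(0, n - w + 1):
            frac = sum(flags[start : start + w]) / w
            if frac > ambiguity_fraction_threshold:
                drop[start : start + w] = True
        if not drop.any():
            block.block_id = next_id
            next_id += 1
            out.append(block)
            continue
        entries = list(zip(block.ranks, block.genes, drop))
        for dropped, run in _split_runs(entries, key=lambda e: bool(e[2])):
            genes = [g for _r, g, _d in run]
            ranks = [r for r, _g, _d in run]
            out.append(
                PaintedBlock(
                    block_id=next_id,
                    chromosome=block.chromosome,
                    origin=None if dropped else block.origin,
                    genes=genes,
                    ranks=ranks,
                    terminated=bool(dropped),
                )
            )
            next_id += 1
    return out


# ---------------------------------------------------------------------------
# painted chromosomes and rearrangement calling


def painted_chromosome_segments(
    painted: list[PaintedBlock],
    positions: pd.DataFrame,
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> dict[str, list[tuple[str, int, int, int]]]:
    """Ordered painted segments per chromosome.

    Gene-level origins from non-terminated painted blocks are laid out
    along each chromosome in rank order and collapsed into maximal
    same-origin runs; runs shorter than ``min_segment`` genes are dropped
    as noise.  Returns chromosome -> [(origin, start_rank, end_rank,
    n_genes)].
    """
    per_chrom: dict[str, list[tuple[int, str]]] = defaultdict(list)
    for block in painted:
        if block.terminated or block.origin is None:
            continue
        for rank in block.ranks:
            per_chrom[block.chromosome].append((rank, block.origin))
    segments: dict[str, list[tuple[str, int, int, int]]] = {}
    for chrom, entries in per_chrom.items():
        entries = sorted(set(entries))
        segs = []
        for origin, run in _split_runs(entries, key=lambda e: e[1]):
            if len(run) < min_segment:
                continue
            segs.append((origin, run[0][0], run[-1][0], len(run)))
        # merge adjacent same-origin segments left by dropped noise runs
        merged: list[tuple[str, int, int, int]] = []
        for seg in segs:
            if merged and merged[-1][0] == seg[0]:
                prev = merged.pop()
                merged.append((prev[0], prev[1], seg[2], prev[3] + seg[3]))
            else:
                merged.append(seg)
        if merged:
            segments[chrom] = merged
    return segments


@dataclass(frozen=True)
class FusionEvent:
    """A called rearrangement on one painted chromosome."""

    type: str  # 'NCI' | 'end_fusion' | 'translocation'
    outer: str
    inserted: str  # inserted origin (NCI) or partner origin otherwise
    chromosome: str
    start_rank: int
    end_rank: int
    resolved: bool = True

    @property
    def signature(self) -> tuple[str, str, str]:
        if self.type == "translocation":
            a, b = sorted((self.outer, self.inserted))
            return (self.type, a, b)
        return (self.type, self.outer, self.inserted)


def _reduce_ncis(segments, chromosome: str):
    """Stack-reduce outer-inner-outer patterns into NCI events.

    Innermost insertions are emitted first (a nested A2-A10-A12-A10-A2
    pattern yields NCI(A12 into A10), then NCI(A10 into A2)).
    """
    events: list[FusionEvent] = []
    seq = list(segments)  # (origin, start, end, n)
    changed = True
    while changed:
        changed = False
        for i in range(len(seq) - 2):
            left, mid, right = seq[i], seq[i + 1], seq[i + 2]
            if left[0] == right[0] and mid[0] != left[0]:
                events.append(
                    FusionEvent(
                        type="NCI",
                        outer=left[0],
                        inserted=mid[0],
                        chromosome=chromosome,
                        start_rank=mid[1],
                        end_rank=mid[2],
                    )
                )
                seq[i : i + 3] = [
                    (left[0], left[1], right[2], left[3] + right[3])
                ]
                changed = True
                break
    return events, seq


def call_rearrangements(
    segments_by_chromosome: dict[str, list[tuple[str, int, int, int]]],
    min_segment: int = DEFAULT_MIN_SEGMENT,
) -> list[FusionEvent]:
    """Call NCIs, end fusions and translocations from painted segments.

    Per chromosome, X..Y..X patterns reduce to NCI(Y into X) (innermost
    first); the residual multi-origin pattern marks terminal
    fusion/translocation junctions.  A junction is a translocation when the
    reciprocal truncation is seen on another chromosome (the partner origin
    also terminates a foreign chromosome); otherwise it is an end fusion
    (flagged unresolved when the evidence is one-sided).
    """
    events: list[FusionEvent] = []
    residual_junctions = []  # (chromosome, left_origin, right_origin, span)
    for chrom in sorted(segments_by_chromosome):
        segs = [
            s for s in segments_by_chromosome[chrom] if s[3] >= min_segment
        ]
        # merge same-origin neighbours left behind by dropped noise runs
        merged: list = []
        for seg in segs:
            if merged and merged[-1][0] == seg[0]:
                prev = merged.pop()
                merged.append((prev[0], prev[1], seg[2], prev[3] + seg[3]))
            else:
                merged.append(seg)
        ncis, residue = _reduce_ncis(merged, chrom)
        events.extend(ncis)
        for i in range(len(residue) - 1):
            left, right = residue[i], residue[i + 1]
            residual_junctions.append((chrom, left, right))
    # reciprocal-truncation test: origins of a junction seen (in either
    # order) on a different chromosome
    pair_locations: dict[tuple[str, str], set[str]] = defaultdict(set)
    for chrom, left, right in residual_junctions:
        key = tuple(sorted((left[0], right[0])))
        pair_locations[key].add(chrom)
    for chrom, left, right in residual_junctions:
        key = tuple(sorted((left[0], right[0])))
        reciprocal = len(pair_locations[key]) > 1
        events.append(
            FusionEvent(
                type="translocation" if reciprocal else "end_fusion",
                outer=left[0],
                inserted=right[0],
                chromosome=chrom,
                start_rank=left[1],
                end_rank=right[2],
                resolved=reciprocal,
            )
        )
    return events


def aggregate_events(events) -> dict[tuple[str, str, str], int]:
    """Multiplicity of each event signature across chromosomes (homeologous
    copies of the same historical event share a signature)."""
    return dict(Counter(e.signature for e in events))


@dataclass
class StageKaryotypes:
    """Chromosome counts of the reconstructed intermediate karyotypes."""

    pre_wgd1_n: int
    pre_wgd2_n: int
    shared_ncis: list[tuple[str, str]]
    specific_fusions: list[tuple[str, str]]
    translocations: list[tuple[str, str]]


def reconstruct_stage_karyotypes(
    events,
    n_ancestral: int = 12,
    shared_min_copies: int = 3,
) -> StageKaryotypes:
    """Infer the pre-WGD1 and pre-WGD2 monoploid chromosome numbers from
    called events on a twice-duplicated genome.

    Fusion events observed in >= ``shared_min_copies`` of the (up to four)
    homeologous copies predate WGD1; events in fewer copies fall between
    WGD1 and WGD2.  Counting: each fusion (NCI or resolved end fusion)
    reduces the chromosome number by one; translocations leave it
    unchanged; WGDs double it.
    """
    counts = aggregate_events(events)
    shared, specific, trans = [], [], []
    for (etype, x, y), mult in sorted(counts.items()):
        if etype == "translocation":
            trans.append((x, y))
            continue
        if mult >= shared_min_copies:
            shared.append((x, y))
        else:
            specific.append((x, y))
    pre_wgd1 = n_ancestral - len(shared)
    pre_wgd2 = 2 * pre_wgd1 - len(specific)
    return StageKaryotypes(
        pre_wgd1_n=pre_wgd1,
        pre_wgd2_n=pre_wgd2,
        shared_ncis=shared,
        specific_fusions=specific,
        translocations=trans,
    )


def assignments_to_frame(
    assignments: dict[str, OriginAssignment]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                a.gene_id, ",".join(a.origins), a.support, a.margin, a.status,
            )
            for a in assignments.values()
        ],
        columns=["gene_id", "origins", "support", "margin", "status"],
    )
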