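"""Similarity-hit filtering and reciprocal-best-hit (RBH) extraction.

Works on BLAST tabular (outfmt 6) hit tables held as pandas DataFrames.
The filters reproduce a permissive CDS-level homolog search: e-value
strictly below 1e-5, percent identity >= 70, HSP length >= 60 bp, and
removal of every hit touching a CDS whose soft-masked (lowercase, i.e.
repeat-annotated) fraction exceeds 25%.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import pandas as pd

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_IDENTITY = 70.0
DEFAULT_MIN_LENGTH = 60
DEFAULT_MAX_REPEAT_FRACTION = 0.25


@dataclass(frozen=True)
class HomologPair:
    """An unordered reciprocal-best pair; bitscore is the max of the two
    directional best hits."""

    gene_a: str
    gene_b: str
    bitscore: float
    score_ab: float
    score_ba: float


def read_blast_table(source) -> pd.DataFrame:
    """Read a BLAST outfmt-6 TSV (path, file object, or string content).

    Columns are taken positionally; extra trailing columns are ignored.
    """
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t", header=None, comment="#")
    if df.shape[1] < 12:
        raise ValueError(
            f"expected >= 12 outfmt-6 columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :12]
    df.columns = OUTFMT6_COLUMNS
    return df.astype(
        {"qseqid": str, "sseqid": str, "pident": float, "length": int,
         "evalue": float, "bitscore": float}
    )


def repeat_fraction(sequence: str) -> float:
    """Soft-masked fraction of a CDS: lowercase bases / total length."""
    if len(sequence) == 0:
        raise ValueError("cannot compute repeat fraction of empty sequence")
    return sum(1 for c in sequence if c.islower()) / len(sequence)


def filter_hits(
    hits: pd.DataFrame,
    masked_cds: dict[str, str],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
    max_repeat_fraction: float = DEFAULT_MAX_REPEAT_FRACTION,
) -> pd.DataFrame:
    """Apply the four homolog-search filters to a hit table.

    Per-hit rules: evalue < max_evalue (strict), pident >= min_identity,
    length >= min_length.  The repeat rule is per-gene: a CDS whose
    soft-masked fraction exceeds max_repeat_fraction (strict '>') poisons
    every hit touching it.  Every gene id appearing in ``hits`` must be
    present in ``masked_cds``.
    """
    ids = set(hits["qseqid"]) | set(hits["sseqid"])
    missing = sorted(ids - set(masked_cds))
    if missing:
        raise KeyError(
            f"gene ids in hits absent from masked_cds: {missing[:10]}"
        )
    repeat_frac = {g: repeat_fraction(masked_cds[g]) for g in ids}
    repetitive = {g for g, f in repeat_frac.items() if f > max_repeat_fraction}
    keep = (
        (hits["evalue"] < max_evalue)
        & (hits["pident"] >= min_identity)
        & (hits["length"] >= min_length)
        & ~hits["qseqid"].isin(repetitive)
        & ~hits["sseqid"].isin(repetitive)
    )
    return hits.loc[keep].reset_index(drop=True)


def collapse_hsps(hits: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple HSPs per (query, subject) pair to the max-bitscore
    HSP (ties: lower e-value, then higher identity)."""
    if hits.empty:
        return hits.copy()
    ordered = hits.sort_values(
        ["qseqid", "sseqid", "bitscore", "evalue", "pident"],
        ascending=[True, True, False, True, False],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["qseqid", "sseqid"]).reset_index(drop=True)


def _best_per_query(hits: pd.DataFrame) -> pd.DataFrame:
    """Best subject per query: max bitscore, ties broken by lower e-value,
    higher identity, then lexicographic subject id."""
    ordered = hits.sort_values(
        ["qseqid", "bitscore", "evalue", "pident", "sseqid"],
        ascending=[True, False, True, False, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates(["qseqid"]).reset_index(drop=True)


def reciprocal_best_hits(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> list[HomologPair]:
    """Reciprocal best hits between gene sets A and B.

    A pair (a, b) is returned iff b is a's best surviving hit among B and a
    is b's best among A ('best' = max bitscore, deterministic tie-breaks).
    Inputs are expected to be already filtered; multiple HSPs are collapsed
    internally.  Output is sorted by gene_a for determinism.
    """
    if hits_ab.empty or hits_ba.empty:
        return []
    best_ab = _best_per_query(collapse_hsps(hits_ab))
    best_ba = _best_per_query(collapse_hsps(hits_ba))
    fwd = {
        (q, s): sc
        for q, s, sc in zip(
            best_ab["qseqid"], best_ab["sseqid"], best_ab["bitscore"]
        )
    }
    rev = {
        (q, s): sc
        for q, s, sc in zip(
            best_ba["qseqid"], best_ba["sseqid"], best_ba["bitscore"]
        )
    }
    pairs = []
    for (a, b), score_ab in fwd.items():
        score_ba = rev.get((b, a))
        if score_ba is not None:
            pairs.append(
                HomologPair(
                    gene_a=a,
                    gene_b=b,
                    bitscore=max(score_ab, score_ba),
                    score_ab=score_ab,
                    score_ba=score_ba,
                )
            )
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def reciprocal_hit_pairs(
    hits_ab: pd.DataFrame, hits_ba: pd.DataFrame
) -> pd.DataFrame:
    """All bidirectionally supported homolog pairs (not only the best).

    A gene pair is kept when a hit exists in both directions after HSP
    collapsing; its score is the max bitscore over the two directions.
    This is the pair set the synteny stage consumes: unlike strict RBH it
    retains the multiple homeologous copies produced by WGDs, which is what
    makes syntenic-depth ratios observable.
    """
    if hits_ab.empty or hits_ba.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b", "bitscore"])
    ab = collapse_hsps(hits_ab)[["qseqid", "sseqid", "bitscore"]]
    ba = collapse_hsps(hits_ba)[["qseqid", "sseqid", "bitscore"]]
    ba = ba.rename(
        columns={"qseqid": "sseqid", "sseqid": "qseqid", "bitscore": "bits_ba"}
    )
    merged = ab.merge(ba, on=["qseqid", "sseqid"], how="inner")
    merged["bitscore"] = merged[["bitscore", "bits_ba"]].max(axis=1)
    out = merged.rename(columns={"qseqid": "gene_a", "sseqid": "gene_b"})[
        ["gene_a", "gene_b", "bitscore"]
    ]
    return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def write_pairs_tsv(pairs: list[HomologPair], path) -> None:
    pd.DataFrame(
        [(p.gene_a, p.gene_b, p.bitscore) for p in pairs],
        columns=["gene_a", "gene_b", "bitscore"],
    ).to_csv(path, sep="\t", index=False)
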