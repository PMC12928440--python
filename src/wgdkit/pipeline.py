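"""End-to-end workflow: simulate -> homology -> Ks -> synteny -> karyotype.

`run_replay` executes the full desk-scale reconstruction on the simulated
twice-duplicated genome: it generates the scripted history, synthesizes
and filters similarity hits, estimates NG86 divergence for reciprocal
homolog pairs, chains syntenic blocks at the discovery (gap 100) and
painting (gap 20) stringencies, paints ancestral origins by bitscore
bootstrap, calls rearrangements, and reconstructs the intermediate
karyotypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import homology as hm
from . import karyotype as kt
from . import synteny as sy
from .ksdist import KS_MAX, KS_MIN
from .ng86 import ng86_from_indices, ng86_pair
from .simulate import (
    Genome,
    SimulationResult,
    genome_genes,
    genome_to_bed,
    genome_to_sequences,
    homology_map_from_truth,
    mirror_hits,
    sect_spartina_scenario,
    simulate_scenario,
    simulate_similarity_hits,
)
from .genetic_code import decode_codons


def _codon_lookup(genome: Genome) -> dict[str, np.ndarray]:
    return {g.gene_id: g.codons for g in genome_genes(genome)}


def ks_for_pairs(
    pairs: pd.DataFrame,
    codons_a: dict[str, np.ndarray],
    codons_b: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Attach NG86 Ks/Ka to a gene-pair table.

    Equal-length sequences (the simulator introduces no indels, so the
    protein-guided alignment is the identity threading) go straight to the
    estimator; unequal lengths are aligned first.
    """
    ks, ka, flags = [], [], []
    for ga, gb in zip(pairs["gene_a"], pairs["gene_b"]):
        ca, cb = codons_a[ga], codons_b[gb]
        if ca.size == cb.size:
            res = ng86_from_indices(ca, cb)
        else:
            res = ng86_pair(decode_codons(ca), decode_codons(cb))
        ks.append(np.nan if res.ks is None else res.ks)
        ka.append(np.nan if res.ka is None else res.ka)
        flags.append(";".join(res.flags))
    out = pairs.copy()
    out["ks"] = ks
    out["ka"] = ka
    out["flags"] = flags
    return out


def filter_pair_ks(
    pairs: pd.DataFrame, ks_min: float = KS_MIN, ks_max: float = KS_MAX
) -> pd.DataFrame:
    """Retain pairs with ks_min <= Ks < ks_max (saturated/NaN removed)."""
    keep = (pairs["ks"] >= ks_min) & (pairs["ks"] < ks_max)
    keep &= pairs["ks"].notna()
    return pairs.loc[keep].reset_index(drop=True)


def homolog_pairs_between(
    genome_a: Genome,
    genome_b: Genome,
    min_identity: float = 0.60,
) -> pd.DataFrame:
    """Filtered reciprocal homolog pairs with Ks between two genomes."""
    hits_ab = simulate_similarity_hits(genome_a, genome_b, min_identity)
    if hits_ab.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b", "bitscore", "ks"])
    hits_ba = mirror_hits(hits_ab)
    seqs = {
        **genome_to_sequences(genome_a), **genome_to_sequences(genome_b)
    }
    hits_ab = hm.filter_hits(hits_ab, seqs)
    hits_ba = hm.filter_hits(hits_ba, seqs)
    pairs = hm.reciprocal_hit_pairs(hits_ab, hits_ba)
    pairs = ks_for_pairs(
        pairs, _codon_lookup(genome_a), _codon_lookup(genome_b)
    )
    return filter_pair_ks(pairs)


@dataclass
class ReplayResult:
    """Everything the replay computed, for inspection and testing."""

    simulation: SimulationResult
    assignments: dict[str, kt.OriginAssignment]
    painted: list[kt.PaintedBlock]
    segments: dict[str, list]
    events: list[kt.FusionEvent]
    stages: kt.StageKaryotypes
    depth: sy.DepthProfile
    blocks_discovery: list[sy.SyntenyBlock]
    blocks_painting: list[sy.SyntenyBlock]
    focal_sister_pairs: pd.DataFrame
    painting_accuracy: float
    painted_origin: dict[str, str] = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "pre_wgd1_n": self.stages.pre_wgd1_n,
            "pre_wgd2_n": self.stages.pre_wgd2_n,
            "modal_depth_outgroup": self.depth.modal_depth,
            "n_shared_ncis": len(self.stages.shared_ncis),
            "n_specific_fusions": len(self.stages.specific_fusions),
            "n_translocations": len(self.stages.translocations),
            "painting_accuracy": self.painting_accuracy,
            "n_blocks_discovery": len(self.blocks_discovery),
            "n_syntenic_pairs": int(self.focal_sister_pairs.shape[0]),
        }


def run_replay(
    seed: int = 0,
    genes_per_chromosome: int = 50,
    fractionation: float = 0.0,
    n_bootstrap: int = 1000,
    comparators=("outgroup_n12", "outgroup_n12b", "outgroup_n10"),
    simulation: SimulationResult | None = None,
) -> ReplayResult:
    """Run the full reconstruction on the simulated cordgrass history."""
    if simulation is None:
        scenario, ancestor = sect_spartina_scenario(
            genes_per_chromosome=genes_per_chromosome,
            seed=seed,
            fractionation=fractionation,
        )
        simulation = simulate_scenario(scenario, ancestor)
    focal = simulation.species["focal"]
    sister = simulation.species["sister"]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))

    # --- painting evidence: filtered hits focal -> each comparator --------
    homology_map = kt.HomologyMap.from_ancestral_table(
        homology_map_from_truth(simulation, list(comparators))
    )
    evidence: dict[str, list[tuple[str, str, float]]] = {}
    for label in comparators:
        comp = simulation.species[label]
        hits = simulate_similarity_hits(focal, comp)
        if hits.empty:
            continue
        seqs = {**genome_to_sequences(focal), **genome_to_sequences(comp)}
        hits = hm.collapse_hsps(hm.filter_hits(hits, seqs))
        chrom_of = {
            g.gene_id: chrom
            for chrom, genes in comp.items()
            for g in genes
        }
        for row in hits.itertuples(index=False):
            evidence.setdefault(row.qseqid, []).append(
                (label, chrom_of[row.sseqid], float(row.bitscore))
            )

    assignments: dict[str, kt.OriginAssignment] = {}
    for gene_id in sorted(evidence):
        vector = kt.map_hits_to_ancestral(
            gene_id, evidence[gene_id], homology_map
        )
        assignments[gene_id] = kt.bootstrap_assign(
            vector, n_bootstrap=n_bootstrap, seed=rng
        )

    # --- synteny focal vs sister -----------------------------------------
    pairs = homolog_pairs_between(focal, sister)
    bed_focal = genome_to_bed(focal)
    bed_sister = genome_to_bed(sister)
    pos_focal = sy.positions_from_bed(bed_focal)
    pos_sister = sy.positions_from_bed(bed_sister)
    pairs = sy.drop_same_chromosome_multicopy(pairs, pos_focal, pos_sister)
    blocks_discovery = sy.chain_blocks(
        pairs, pos_focal, pos_sister, min_pairs=5, max_gap=100
    )
    blocks_painting = sy.chain_blocks(
        pairs, pos_focal, pos_sister, min_pairs=5, max_gap=20
    )

    # --- painting ---------------------------------------------------------
    painted = kt.paint_blocks(assignments, blocks_painting, pos_focal)
    painted = kt.terminate_transition_zones(painted, assignments)
    segments = kt.painted_chromosome_segments(painted, pos_focal)
    events = kt.call_rearrangements(segments)
    stages = kt.reconstruct_stage_karyotypes(events)

    painted_origin: dict[str, str] = {}
    for block in painted:
        if block.terminated or block.origin is None:
            continue
        for gene in block.genes:
            painted_origin[gene] = block.origin
    truth_origin = simulation.truth.gene_origins["focal"]
    if painted_origin:
        correct = sum(
            1 for g, o in painted_origin.items() if truth_origin.get(g) == o
        )
        accuracy = correct / len(painted_origin)
    else:
        accuracy = 0.0

    # --- syntenic depth: diploid outgroup vs the twice-duplicated genome -
    outgroup = simulation.species["outgroup_n10"]
    og_pairs = homolog_pairs_between(outgroup, focal)
    pos_og = sy.positions_from_bed(genome_to_bed(outgroup))
    og_pairs = sy.drop_same_chromosome_multicopy(og_pairs, pos_og, pos_focal)
    og_blocks = sy.chain_blocks(
        og_pairs, pos_og, pos_focal, min_pairs=5, max_gap=100
    )
    depth = sy.syntenic_depth(
        og_blocks, reference="a", chromosomes=list(outgroup)
    )

    return ReplayResult(
        simulation=simulation,
        assignments=assignments,
        painted=painted,
        segments=segments,
        events=events,
        stages=stages,
        depth=depth,
        blocks_discovery=blocks_discovery,
        blocks_painting=blocks_painting,
        focal_sister_pairs=pairs,
        painting_accuracy=accuracy,
        painted_origin=painted_origin,
    )
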