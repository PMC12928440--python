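import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from wgdkit import genetic_code as gc  # noqa: E402


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """Random stop-free CDS of n_codons codons."""
    idx = gc.SENSE_INDICES[rng.integers(0, len(gc.SENSE_INDICES), n_codons)]
    return gc.decode_codons(idx)


def simulated_synteny_instance(seed: int, n_chrom: int = 3, genes: int = 40):
    """A filtered homolog-pair table with positions, derived from a small
    simulated genome pair (one WGD + fractionation on the focal branch)."""
    from wgdkit import synteny as sy
    from wgdkit.pipeline import homolog_pairs_between
    from wgdkit.simulate import (
        WGD,
        AncestralGenome,
        Diverge,
        EvolutionScenario,
        Fractionation,
        Speciation,
        genome_to_bed,
        simulate_scenario,
    )

    srng = np.random.default_rng(seed)
    frac = float(srng.uniform(0.1, 0.4))
    dv = float(srng.uniform(0.03, 0.12))
    events = [
        Speciation("out", terminal_ks=0.15, terminal_ka=0.03),
        Diverge(0.05, 0.01),
        WGD(),
        Diverge(dv, dv / 5),
        Fractionation(frac),
        Diverge(0.05, 0.01),
        Speciation("foc", terminal_ks=0.03, terminal_ka=0.006),
    ]
    result = simulate_scenario(
        EvolutionScenario(events=events, seed=seed),
        AncestralGenome(n_chrom, genes, 60),
    )
    pairs = homolog_pairs_between(
        result.species["out"], result.species["foc"]
    )
    pos_a = sy.positions_from_bed(genome_to_bed(result.species["out"]))
    pos_b = sy.positions_from_bed(genome_to_bed(result.species["foc"]))
    pairs = sy.drop_same_chromosome_multicopy(pairs, pos_a, pos_b)
    return pairs, pos_a, pos_b


def mutated_copy(cds: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply n random single-nucleotide substitutions avoiding stop codons."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for _ in range(n_subs):
        for _attempt in range(50):
            ci = int(rng.integers(0, len(codons)))
            pos = int(rng.integers(0, 3))
            base = "ACGT"[int(rng.integers(0, 4))]
            cod = codons[ci]
            new = cod[:pos] + base + cod[pos + 1 :]
            if new != cod and gc.CODON_TABLE[new] != "*":
                codons[ci] = new
                break
    return "".join(codons)
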