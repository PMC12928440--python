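"""Synteny chaining vs brute-force DP oracle, depth and pseudochromosomes."""

import numpy as np
import pandas as pd
import pytest

from wgdkit.synteny import (
    SyntenyBlock,
    assemble_pseudochromosomes,
    chain_blocks,
    drop_same_chromosome_multicopy,
    export_dotplot_table,
    longest_chain,
    syntenic_depth,
)

from oracles import chain_oracle


def positions(spec):
    """spec: {chrom: [gene ids in order]} -> positions frame."""
    rows = []
    for chrom, genes in spec.items():
        for rank, g in enumerate(genes):
            rows.append((g, chrom, rank, "+"))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "rank", "strand"])


def pair_frame(pairs, ks=None):
    df = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
    if ks is not None:
        df["ks"] = ks
    return df


class TestMulticopyRule:
    def test_two_copies_on_one_partner_chromosome_removed(self):
        pos_a = positions({"c1": ["a1"]})
        pos_b = positions({"d1": ["b1", "b2"]})
        pairs = pair_frame([("a1", "b1"), ("a1", "b2")])
        out = drop_same_chromosome_multicopy(pairs, pos_a, pos_b)
        assert out.empty

    def test_single_copies_on_distinct_chromosomes_kept(self):
        pos_a = positions({"c1": ["a1"]})
        pos_b = positions({"d1": ["b1"], "d2": ["b2"]})
        pairs = pair_frame([("a1", "b1"), ("a1", "b2")])
        out = drop_same_chromosome_multicopy(pairs, pos_a, pos_b)
        assert len(out) == 2

    def test_missing_position_names_gene(self):
        pos_a = positions({"c1": ["a1"]})
        pos_b = positions({"d1": ["b1"]})
        pairs = pair_frame([("a1", "b1"), ("a9", "b1")])
        with pytest.raises(KeyError, match="a9"):
            drop_same_chromosome_multicopy(pairs, pos_a, pos_b)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_count_filter(self, seed):
        rng = np.random.default_rng(seed)
        pos_a = positions({"c1": [f"a{i}" for i in range(10)]})
        pos_b = positions(
            {"d1": [f"b{i}" for i in range(5)],
             "d2": [f"b{i}" for i in range(5, 10)]}
        )
        raw = {
            (f"a{rng.integers(10)}", f"b{rng.integers(10)}")
            for _ in range(25)
        }
        pairs = pair_frame(sorted(raw))
        out = drop_same_chromosome_multicopy(pairs, pos_a, pos_b)
        # brute force: per (gene, partner chromosome) counting
        chrom_b = {f"b{i}": ("d1" if i < 5 else "d2") for i in range(10)}
        expected = []
        for ga, gb in sorted(raw):
            n_same_b = sum(
                1 for (xa, xb) in raw
                if xa == ga and chrom_b[xb] == chrom_b[gb]
            )
            # all a-genes sit on the single chromosome c1
            n_same_a = sum(1 for (_xa, xb) in raw if xb == gb)
            if n_same_b < 2 and n_same_a < 2:
                expected.append((ga, gb))
        assert list(zip(out["gene_a"], out["gene_b"])) == expected


class TestChaining:
    def collinear_case(self, n):
        pos_a = positions({"c1": [f"a{i}" for i in range(n)]})
        pos_b = positions({"d1": [f"b{i}" for i in range(n)]})
        pairs = pair_frame([(f"a{i}", f"b{i}") for i in range(n)])
        return pairs, pos_a, pos_b

    def test_five_collinear_pairs_form_one_block(self):
        blocks = chain_blocks(*self.collinear_case(5))
        assert len(blocks) == 1 and blocks[0].n_pairs == 5
        assert blocks[0].orientation == "+"

    def test_four_pairs_are_below_minimum(self):
        assert chain_blocks(*self.collinear_case(4)) == []

    def test_inverted_blocks_get_minus_orientation(self):
        n = 6
        pos_a = positions({"c1": [f"a{i}" for i in range(n)]})
        pos_b = positions({"d1": [f"b{i}" for i in range(n)]})
        pairs = pair_frame([(f"a{i}", f"b{n - 1 - i}") for i in range(n)])
        blocks = chain_blocks(pairs, pos_a, pos_b)
        assert len(blocks) == 1 and blocks[0].orientation == "-"
        assert blocks[0].n_pairs == n

    def test_gap_constraint_splits_chains(self):
        pos_a = positions({"c1": [f"a{i}" for i in range(40)]})
        pos_b = positions({"d1": [f"b{i}" for i in range(40)]})
        # two runs of 6 separated by a 20-gene gap on both genomes
        idx = list(range(6)) + list(range(26, 32))
        pairs = pair_frame([(f"a{i}", f"b{i}") for i in idx])
        assert len(chain_blocks(pairs, pos_a, pos_b, max_gap=100)) == 1
        assert len(chain_blocks(pairs, pos_a, pos_b, max_gap=10)) == 2

    def _random_instance(self, seed, n_genes=200, density=0.04):
        rng = np.random.default_rng(seed)
        pos_a = positions({"c1": [f"a{i}" for i in range(n_genes)]})
        pos_b = positions({"d1": [f"b{i}" for i in range(n_genes)]})
        raw = sorted(
            {
                (int(rng.integers(n_genes)), int(rng.integers(n_genes)))
                for _ in range(int(density * n_genes * n_genes))
            }
        )
        pairs = pair_frame([(f"a{i}", f"b{j}") for i, j in raw])
        return pairs, pos_a, pos_b, raw

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("max_gap", [20, 100])
    def test_equals_brute_force_dp_oracle(self, seed, max_gap):
        pairs, pos_a, pos_b, raw = self._random_instance(seed, 120)
        blocks = chain_blocks(pairs, pos_a, pos_b, max_gap=max_gap)
        got = [
            [(ra, rb) for _ga, _gb, ra, rb in b.pairs]
            for b in blocks
            if b.orientation == "+"
        ]
        expected = chain_oracle(raw, 5, max_gap)
        assert got == expected

    @pytest.mark.parametrize("seed", range(3))
    def test_tighter_gap_never_chains_more_pairs(self, seed):
        """Stringency sweep on genome-like pair tables: dropping the gap
        threshold 100 -> 20 never increases the chained-pair total."""
        from conftest import simulated_synteny_instance

        pairs, pos_a, pos_b = simulated_synteny_instance(seed)
        totals = []
        for gap in (100, 20):
            blocks = chain_blocks(pairs, pos_a, pos_b, max_gap=gap)
            totals.append(sum(b.n_pairs for b in blocks))
        assert totals[0] >= totals[1]

    def test_pair_appears_at_most_once_per_orientation(self):
        pairs, pos_a, pos_b, _ = self._random_instance(3, 100)
        blocks = chain_blocks(pairs, pos_a, pos_b, min_pairs=2)
        for orientation in "+-":
            seen = set()
            for b in blocks:
                if b.orientation != orientation:
                    continue
                for ga, gb, _ra, _rb in b.pairs:
                    assert (ga, gb) not in seen
                    seen.add((ga, gb))

    def test_longest_chain_respects_strict_monotonicity(self):
        matches = [(0, 0), (0, 1), (1, 1), (2, 2)]
        idx = longest_chain(sorted(matches), max_gap=100)
        ranks = [sorted(matches)[i] for i in idx]
        assert all(
            a1 < a2 and b1 < b2
            for (a1, b1), (a2, b2) in zip(ranks, ranks[1:])
        )


class TestDepth:
    def blocks_of(self, mapping):
        out = []
        for i, (ref, tgt) in enumerate(mapping):
            out.append(
                SyntenyBlock(
                    block_id=i, chrom_a=ref, chrom_b=tgt, orientation="+",
                    pairs=[("x", "y", 0, 0)] * 5,
                )
            )
        return out

    def test_self_comparison_modal_depth_one(self):
        blocks = self.blocks_of(
            [("c1", "c1"), ("c1", "c2"), ("c2", "c2"), ("c2", "c1")]
        )
        profile = syntenic_depth(blocks, exclude_self=True)
        assert profile.modal_depth == 1

    def test_one_to_four_correspondence(self):
        mapping = [
            (f"c{i}", f"t{i}.{j}") for i in range(1, 6) for j in range(4)
        ]
        profile = syntenic_depth(self.blocks_of(mapping))
        assert profile.modal_depth == 4
        assert all(d == 4 for d in profile.per_chromosome.values())

    def test_chromosomes_without_blocks_count_zero(self):
        profile = syntenic_depth(
            self.blocks_of([("c1", "t1")]), chromosomes=["c1", "c2"]
        )
        assert profile.per_chromosome["c2"] == 0


class TestPseudochromosomes:
    def test_plurality_assignment(self):
        blocks = [
            SyntenyBlock(0, "s1", "chr3", "+", [("x", "y", 0, 0)] * 8),
            SyntenyBlock(1, "s1", "chr5", "+", [("x", "y", 0, 0)] * 3),
            SyntenyBlock(2, "s2", "chr3", "+", [("x", "y", 0, 0)] * 6),
        ]
        assignment, unplaced = assemble_pseudochromosomes(
            blocks, scaffolds=["s1", "s2", "s3"]
        )
        assert assignment["s1"]["pseudochromosome"] == "chr3"
        assert not assignment["s1"]["tie"]
        assert unplaced == ["s3"]

    def test_tie_breaks_to_lower_numbered_reference_and_flags(self):
        blocks = [
            SyntenyBlock(0, "s1", "chr7", "+", [("x", "y", 0, 0)] * 5),
            SyntenyBlock(1, "s1", "chr2", "+", [("x", "y", 0, 0)] * 5),
        ]
        assignment, _ = assemble_pseudochromosomes(blocks)
        assert assignment["s1"]["pseudochromosome"] == "chr2"
        assert assignment["s1"]["tie"]

    def test_recovers_simulated_fragmentation(self, rng):
        # split 3 known chromosomes into scaffolds; grouping must match
        truth = {f"scaf{i}": f"chr{i % 3 + 1}" for i in range(9)}
        blocks = []
        for i, (scaf, chrom) in enumerate(truth.items()):
            blocks.append(
                SyntenyBlock(
                    i, scaf, chrom, "+",
                    [("x", "y", 0, 0)] * int(rng.integers(5, 20)),
                )
            )
        assignment, unplaced = assemble_pseudochromosomes(blocks)
        assert not unplaced
        assert {
            s: a["pseudochromosome"] for s, a in assignment.items()
        } == truth


class TestDotplot:
    def test_band_assignment_closed_open(self):
        pos_a = positions({"c1": ["a1", "a2", "a3"]})
        pos_b = positions({"d1": ["b1", "b2", "b3"]})
        pairs = pair_frame(
            [("a1", "b1"), ("a2", "b2"), ("a3", "b3")],
            ks=[0.5, 0.786, 0.2],
        )
        out = export_dotplot_table(
            pairs, pos_a, pos_b, ks_bands=[(0.478, 0.786, "wgd")]
        )
        assert list(out["band"]) == ["wgd", "other", "other"]

    def test_empty_pairs_give_header_only(self):
        pos = positions({"c1": ["a1"]})
        out = export_dotplot_table(pair_frame([]), pos, pos)
        assert out.empty and "band" in out.columns

    def test_random_banding_matches_direct_rebinning(self, rng):
        n = 50
        pos_a = positions({"c1": [f"a{i}" for i in range(n)]})
        pos_b = positions({"d1": [f"b{i}" for i in range(n)]})
        ks = rng.uniform(0, 1.2, size=n)
        pairs = pair_frame(
            [(f"a{i}", f"b{i}") for i in range(n)], ks=list(ks)
        )
        bands = [(0.0, 0.3, "low"), (0.3, 0.6, "mid"), (0.9, 1.0, "high")]
        out = export_dotplot_table(pairs, pos_a, pos_b, ks_bands=bands)
        for value, label in zip(ks, out["band"]):
            expected = "other"
            for lo, hi, name in bands:
                if lo <= value < hi:
                    expected = name
                    break
            assert label == expected
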