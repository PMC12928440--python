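"""Origin mapping, bootstrap assignment, block painting, event calling."""

import numpy as np
import pandas as pd
import pytest

from wgdkit.karyotype import (
    ANCESTRAL_CHROMOSOMES,
    FusionEvent,
    HomologyMap,
    OriginAssignment,
    OriginVector,
    bootstrap_assign,
    call_rearrangements,
    exact_majority_support,
    map_hits_to_ancestral,
    packaged_homology_map,
    paint_blocks,
    painted_chromosome_segments,
    reconstruct_stage_karyotypes,
    terminate_transition_zones,
)
from wgdkit.synteny import SyntenyBlock

from oracles import majority_probability_oracle


class TestHomologyMap:
    def test_packaged_map_covers_all_ancestral_chromosomes(self):
        hmap = packaged_homology_map()
        assert len(hmap.species()) == 6
        for species in hmap.species():
            seen = set()
            for origins in hmap.table[species].values():
                seen |= origins
            assert seen == set(ANCESTRAL_CHROMOSOMES)

    def test_rice_chromosomes_map_one_to_one(self):
        hmap = packaged_homology_map()
        assert hmap.origins("Oryza sativa", "1") == frozenset({"A1"})
        assert hmap.origins("Oryza sativa", "12") == frozenset({"A12"})

    def test_fused_sorghum_chromosome_maps_to_multiple_origins(self):
        hmap = packaged_homology_map()
        assert hmap.origins("Sorghum bicolor", "2") == frozenset(
            {"A6", "A7", "A9"}
        )

    def test_unknown_chromosome_error_names_species(self):
        hmap = packaged_homology_map()
        with pytest.raises(KeyError, match="Oryza"):
            hmap.origins("Oryza sativa", "99")

    def test_incomplete_map_rejected(self):
        df = pd.DataFrame(
            {"ancestral_chromosome": ["A1"], "sp": ["1"]}
        )
        with pytest.raises(ValueError, match="never mapped"):
            HomologyMap.from_ancestral_table(df)


class TestOriginVector:
    def test_single_chromosome_evidence_gives_probability_one(self):
        hmap = packaged_homology_map()
        vec = map_hits_to_ancestral(
            "g", [("Oryza sativa", "1", 100.0),
                  ("Oryza sativa", "1", 50.0)], hmap
        )
        assert vec.probabilities == {"A1": 1.0}

    def test_multi_origin_hit_splits_bitscore_mass(self):
        hmap = packaged_homology_map()
        vec = map_hits_to_ancestral(
            "g", [("Sorghum bicolor", "2", 90.0)], hmap
        )
        assert vec.probabilities == pytest.approx(
            {"A6": 1 / 3, "A7": 1 / 3, "A9": 1 / 3}
        )

    def test_probabilities_normalized_over_mixed_evidence(self):
        hmap = packaged_homology_map()
        vec = map_hits_to_ancestral(
            "g",
            [("Oryza sativa", "6", 100.0), ("Sorghum bicolor", "2", 60.0)],
            hmap,
        )
        assert sum(vec.probabilities.values()) == pytest.approx(1.0)
        assert vec.probabilities["A6"] == pytest.approx(
            (100 + 20) / 160
        )

    def test_no_hits_is_an_error(self):
        with pytest.raises(ValueError):
            map_hits_to_ancestral("g", [], packaged_homology_map())


class TestBootstrapAssign:
    def test_certain_origin_gets_full_support(self):
        vec = OriginVector("g", {"A3": 1.0}, n_hits=4)
        asn = bootstrap_assign(vec)
        assert asn.best == "A3" and asn.support == 1.0
        assert asn.status == "unique"

    def test_even_split_is_ambiguous(self):
        # strict-plurality support of either origin is well below 0.5
        vec = OriginVector("g", {"A1": 0.5, "A2": 0.5}, n_hits=6)
        asn = bootstrap_assign(vec, seed=0)
        assert asn.status == "ambiguous"
        assert asn.support < 0.5
        assert set(asn.origins) == {"A1", "A2"}

    @pytest.mark.parametrize(
        "probs,m",
        [((0.6, 0.3, 0.1), 5), ((0.5, 0.3, 0.2), 4), ((0.7, 0.2, 0.1), 6)],
    )
    def test_support_matches_exact_multinomial_majority(self, probs, m):
        """Mean support over independent 1000-replicate bootstraps agrees
        with the exact strict-plurality probability to +-0.02."""
        origins = ["A1", "A2", "A3"]
        vec = OriginVector("g", dict(zip(origins, probs)), n_hits=m)
        supports = [
            bootstrap_assign(vec, n_bootstrap=1000, seed=s).support
            for s in range(10)
        ]
        exact = exact_majority_support(probs, m)
        assert np.mean(supports) == pytest.approx(
            max(exact.values()), abs=0.02
        )

    def test_exact_enumeration_matches_independent_oracle(self):
        for probs, m in [((0.6, 0.3, 0.1), 5), ((0.4, 0.35, 0.25), 6),
                         ((0.9, 0.05, 0.05), 3)]:
            ours = exact_majority_support(probs, m)
            theirs = majority_probability_oracle(probs, m)
            for i in range(3):
                assert ours[i] == pytest.approx(theirs[i], abs=1e-12)

    def test_stricter_thresholds_never_create_unique_calls(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.dirichlet([1.0, 1.0, 1.0])
            vec = OriginVector(
                "g", dict(zip(["A1", "A2", "A3"], p)), n_hits=5
            )
            lax = bootstrap_assign(
                vec, support_min=0.5, margin_min=0.05, seed=9
            )
            strict = bootstrap_assign(
                vec, support_min=0.7, margin_min=0.2, seed=9
            )
            if lax.status == "ambiguous":
                assert strict.status == "ambiguous"

    def test_deterministic_under_seed(self):
        vec = OriginVector("g", {"A1": 0.55, "A2": 0.45}, n_hits=8)
        a = bootstrap_assign(vec, seed=3)
        b = bootstrap_assign(vec, seed=3)
        assert (a.support, a.margin, a.status) == (
            b.support, b.margin, b.status
        )


def unique(gene, origin):
    return OriginAssignment(
        gene_id=gene, origins=[origin], support=1.0, margin=1.0,
        status="unique", candidate_origins=frozenset({origin}),
    )


def ambiguous(gene, origins):
    return OriginAssignment(
        gene_id=gene, origins=sorted(origins), support=0.4, margin=0.01,
        status="ambiguous", candidate_origins=frozenset(origins),
    )


def one_block(genes, chrom="c1"):
    pairs = [(g, f"{g}_partner", i, i) for i, g in enumerate(genes)]
    return SyntenyBlock(
        block_id=0, chrom_a=chrom, chrom_b="d1", orientation="+",
        pairs=pairs,
    )


def position_frame(genes, chrom="c1"):
    return pd.DataFrame(
        [(g, chrom, i, "+") for i, g in enumerate(genes)],
        columns=["gene_id", "chrom", "rank", "strand"],
    )


class TestPaintBlocks:
    def test_ambiguous_members_inherit_block_origin(self):
        genes = [f"g{i}" for i in range(10)]
        assignments = {g: unique(g, "A5") for g in genes[:8]}
        for g in genes[8:]:
            assignments[g] = ambiguous(g, {"A5", "A3"})
        painted = paint_blocks(
            assignments, [one_block(genes)], position_frame(genes)
        )
        assert len(painted) == 1
        assert painted[0].origin == "A5"
        assert set(painted[0].genes) == set(genes)

    def test_disagreeing_unambiguous_members_split_block(self):
        genes = [f"g{i}" for i in range(10)]
        assignments = {
            g: unique(g, "A5" if i < 5 else "A3")
            for i, g in enumerate(genes)
        }
        painted = paint_blocks(
            assignments, [one_block(genes)], position_frame(genes)
        )
        assert len(painted) == 2
        assert [p.origin for p in painted] == ["A5", "A3"]

    def test_ambiguous_member_without_block_origin_excluded(self):
        genes = [f"g{i}" for i in range(6)]
        assignments = {g: unique(g, "A5") for g in genes[:5]}
        assignments[genes[5]] = ambiguous(genes[5], {"A1", "A2"})
        painted = paint_blocks(
            assignments, [one_block(genes)], position_frame(genes)
        )
        assert genes[5] not in painted[0].genes

    def test_painting_invariant_to_gene_relabeling(self):
        genes = [f"g{i}" for i in range(8)]
        assignments = {g: unique(g, "A7") for g in genes}
        painted = paint_blocks(
            assignments, [one_block(genes)], position_frame(genes)
        )
        renamed = [f"x{i}" for i in range(8)]
        assignments2 = {g: unique(g, "A7") for g in renamed}
        painted2 = paint_blocks(
            assignments2, [one_block(renamed)], position_frame(renamed)
        )
        assert [p.origin for p in painted] == [p.origin for p in painted2]
        assert [p.ranks for p in painted] == [p.ranks for p in painted2]


class TestTransitionZones:
    def test_clean_block_untouched(self):
        genes = [f"g{i}" for i in range(12)]
        assignments = {g: unique(g, "A2") for g in genes}
        painted = paint_blocks(
            assignments, [one_block(genes)], position_frame(genes)
        )
        out = terminate_transition_zones(painted, assignments)
        assert len(out) == 1 and not out[0].terminated

    def test_high_ambiguity_window_terminated(self):
        genes = [f"g{i}" for i in range(20)]
        assignments = {}
        for i, g in enumerate(genes):
            if 5 <= i < 13:  # 8 of 10 ambiguous inside the window
                assignments[g] = ambiguous(g, {"A2", "A4"})
            else:
                assignments[g] = unique(g, "A2")
        painted = paint_blocks(
            assignments, [one_block(genes)], position_frame(genes)
        )
        out = terminate_transition_zones(
            painted, assignments, ambiguity_fraction_threshold=0.5,
            window=10,
        )
        assert any(b.terminated for b in out)
        kept = [b for b in out if not b.terminated]
        assert all(b.origin == "A2" for b in kept)


class TestEventCalling:
    def segs(self, origins, n=10):
        out = []
        start = 0
        for o in origins:
            out.append((o, start, start + n - 1, n))
            start += n
        return out

    def test_single_origin_chromosome_is_quiet(self):
        events = call_rearrangements({"c1": self.segs(["A4"])})
        assert events == []

    def test_simple_nci_called(self):
        events = call_rearrangements({"c1": self.segs(["A6", "A9", "A6"])})
        assert len(events) == 1
        assert events[0].type == "NCI"
        assert (events[0].outer, events[0].inserted) == ("A6", "A9")

    def test_nested_ncis_reported_inner_first(self):
        events = call_rearrangements(
            {"c1": self.segs(["A2", "A10", "A12", "A10", "A2"])}
        )
        assert [(e.outer, e.inserted) for e in events] == [
            ("A10", "A12"), ("A2", "A10")
        ]

    def test_short_segments_ignored_as_noise(self):
        segs = [("A6", 0, 9, 10), ("A9", 10, 12, 3), ("A6", 13, 22, 10)]
        events = call_rearrangements({"c1": segs}, min_segment=5)
        assert events == []

    def test_reciprocal_terminal_exchange_is_translocation(self):
        events = call_rearrangements(
            {
                "c1": self.segs(["A1", "A6"]),
                "c2": self.segs(["A6", "A1"]),
            }
        )
        assert {e.type for e in events} == {"translocation"}
        assert all(e.resolved for e in events)

    def test_one_sided_terminal_segment_is_unresolved_end_fusion(self):
        events = call_rearrangements({"c1": self.segs(["A1", "A6"])})
        assert len(events) == 1
        assert events[0].type == "end_fusion"
        assert not events[0].resolved


class TestStageKaryotypes:
    def test_counts_from_shared_and_specific_events(self):
        events = []
        # two ancestral NCIs present in all four copies
        for copy in range(4):
            events.append(FusionEvent("NCI", "A2", "A10", f"x{copy}", 0, 1))
            events.append(FusionEvent("NCI", "A6", "A9", f"y{copy}", 0, 1))
        # five lineage-specific fusions in two copies each
        for outer, inner in [("A10", "A12"), ("A7", "A12"), ("A3", "A5"),
                             ("A3", "A11"), ("A8", "A11")]:
            for copy in range(2):
                events.append(
                    FusionEvent("NCI", outer, inner, f"z{copy}", 0, 1)
                )
        events.append(
            FusionEvent("translocation", "A1", "A6", "t0", 0, 1)
        )
        stages = reconstruct_stage_karyotypes(events)
        assert stages.pre_wgd1_n == 10
        assert stages.pre_wgd2_n == 15
        assert len(stages.shared_ncis) == 2
        assert len(stages.specific_fusions) == 5
        assert stages.translocations == [("A1", "A6")]


class TestPaintedSegments:
    def test_runs_collapse_and_short_runs_drop(self):
        genes = [f"g{i}" for i in range(30)]
        positions = position_frame(genes)
        assignments = {}
        blocks = []
        # 12 genes A1, 3 noise genes A9, 15 genes A2
        origins = ["A1"] * 12 + ["A9"] * 3 + ["A2"] * 15
        for g, o in zip(genes, origins):
            assignments[g] = unique(g, o)
        block = one_block(genes)
        painted = paint_blocks(assignments, [block], positions)
        segments = painted_chromosome_segments(
            painted, positions, min_segment=5
        )
        assert [s[0] for s in segments["c1"]] == ["A1", "A2"]
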