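import pytest

from endoreduce.gene_array import (
    ArrayRow,
    GeneArray,
    build_array,
    detect_splits,
    order_violations,
    pan_core,
    presence_matrix,
    strand_deviations,
    syntenic_blocks,
)

from conftest import make_genome

SEQS = {
    "A": "ATGAAAGAACATTGGAAATAA",
    "B": "ATGCCCGATCGATTTGGGTAA",
    "C": "ATGGGGAAATGGCATAATTAA",
}


def _named_genomes(orders):
    """Toy genomes whose genes anchor purely by shared names."""
    genomes = []
    for i, order in enumerate(orders):
        specs = [(f"g{i}_{name}", name, SEQS[name], "+") for name in order]
        genomes.append(make_genome(f"G{i}", specs, circular=False))
    return genomes


def _toy_array():
    genomes = _named_genomes([["A", "B", "C"], ["A", "C"], ["A", "B", "C"]])
    return genomes, build_array(genomes, assignments={})


class TestBuildArray:
    def test_name_anchored_presence_patterns(self):
        _, array = _toy_array()
        assert len(array) == 3
        matrix = presence_matrix(array)
        assert matrix.to_numpy().tolist() == [[1, 1, 1], [1, 0, 1], [1, 1, 1]]

    def test_single_genome_array_is_its_gene_list(self):
        genomes = _named_genomes([["A", "B", "C"]])
        array = build_array(genomes, assignments={})
        assert len(array) == 3
        assert [r.cells["G0"][0][0] for r in array.rows] == ["g0_A", "g0_B", "g0_C"]

    def test_no_shared_anchors_raises_naming_pair(self):
        g0 = make_genome("G0", [("x", "aa", SEQS["A"], "+")], circular=False)
        g1 = make_genome("G1", [("y", "bb", SEQS["B"], "+")], circular=False)
        with pytest.raises(ValueError, match="G0.*G1"):
            build_array([g0, g1], assignments={})

    def test_per_genome_order_preserved(self, small_sim):
        array = small_sim["array"]
        truth = small_sim["truth"]
        for genome in small_sim["descendants"]:
            inverted = sum(
                inv["size"]
                for gid in truth.inversions
                for inv in truth.inversions[gid]
            )
            # inversions are genuine local order reversals; anything beyond
            # them would be a placement bug
            assert order_violations(array, genome) <= inverted

    def test_rotated_circular_order_is_aligned_back(self):
        genomes = _named_genomes([["A", "B", "C"], ["B", "C", "A"]])
        for g in genomes:
            g.circular = True
        array = build_array(genomes, assignments={})
        assert len(array) == 3
        assert presence_matrix(array).to_numpy().sum() == 6


class TestPanCore:
    def test_toy_pan_core(self):
        _, array = _toy_array()
        pc = pan_core(array)
        assert pc["pan_total"] == 3
        assert pc["core_total"] == 2

    def test_identical_genomes_pan_equals_core(self):
        genomes = _named_genomes([["A", "B"], ["A", "B"]])
        pc = pan_core(build_array(genomes, assignments={}))
        assert pc["pan_total"] == pc["core_total"] == 2

    def test_pan_at_least_core_and_core_bounded_by_smallest_genome(self, small_sim):
        pc = pan_core(small_sim["array"])
        assert pc["pan_total"] >= pc["core_total"]
        assert pc["core_total"] <= min(
            len(g.genes) for g in small_sim["descendants"]
        )

    def test_rows_sharing_ref_compact_to_one_pan_unit(self):
        rows = [
            ArrayRow(0, "grpE", "CDS", {"G0": [("a", "+")]}),
            ArrayRow(1, "grpE", "CDS", {"G1": [("b", "+")]}),
            ArrayRow(2, "other", "CDS", {"G0": [("c", "+")], "G1": [("d", "+")]}),
        ]
        pc = pan_core(GeneArray(rows=rows, genome_ids=["G0", "G1"]))
        assert pc["pan_total"] == 2
        # the compacted grpE unit spans both genomes, so it is core
        assert pc["core_total"] == 2

    def test_simulated_pan_core_match_truth(self, small_sim):
        pc = pan_core(small_sim["array"])
        truth = small_sim["truth"]
        assert pc["pan_total"] == truth.expected_pan()
        assert pc["core_total"] == truth.expected_core()


class TestDetectSplits:
    def test_simulated_splits_recovered_without_false_positives(self, small_sim):
        report = detect_splits(
            small_sim["array"],
            small_sim["assignments"],
            small_sim["descendants"],
            internal_stop_genes=small_sim["internal_stops"],
        )
        adjacent = report[report["evidence"] == "adjacent_same_ref"]
        truth = small_sim["truth"]
        planted = {
            (gid, s["ancestor"])
            for gid in truth.splits
            for s in truth.splits[gid]
        }
        detected = {(r.genome_id, r.ref_gene) for r in adjacent.itertuples()}
        assert detected <= planted | detected  # no nonsense rows
        assert not (detected - planted), "false positive split calls"
        assert len(planted & detected) == len(planted)

    def test_adjacent_full_length_paralogs_are_not_a_split(self, small_sim):
        report = detect_splits(
            small_sim["array"],
            small_sim["assignments"],
            small_sim["descendants"],
        )
        truth = small_sim["truth"]
        dup_ancestors = {
            (gid, d["ancestor"])
            for gid in truth.duplications
            for d in truth.duplications[gid]
        }
        called = {
            (r.genome_id, r.ref_gene)
            for r in report.itertuples()
            if r.evidence == "adjacent_same_ref"
        }
        assert not (called & dup_ancestors)

    def test_clean_genomes_give_empty_report(self):
        genomes, array = _toy_array()
        report = detect_splits(array, {}, genomes)
        assert report.empty


class TestStrandDeviations:
    def test_single_flip_is_direction_change(self):
        genomes = _named_genomes([["A", "B", "C"], ["A", "B", "C"]])
        flipped = make_genome(
            "G1",
            [
                ("g1_A", "A", SEQS["A"], "+"),
                ("g1_B", "B", SEQS["B"], "-"),
                ("g1_C", "C", SEQS["C"], "+"),
            ],
            circular=False,
        )
        array = build_array([genomes[0], flipped], assignments={})
        dev = strand_deviations(array, [genomes[0], flipped])
        assert len(dev["direction_changes"]) == 1
        assert dev["direction_changes"][0]["gene_id"] == "g1_B"
        assert dev["inversions"] == []

    def test_no_flips_gives_empty_lists(self):
        genomes, array = _toy_array()
        dev = strand_deviations(array, genomes)
        assert dev["direction_changes"] == [] and dev["inversions"] == []

    def test_simulator_inversions_detected_as_reversed_runs(self):
        from endoreduce import genome_io, homology, synthetic_data

        cfg = synthetic_data.SimulationConfig(
            seed=3,
            n_descendants=2,
            n_ancestor_genes=30,
            inversion_rate=1.5,
            inversion_len=(3, 6),
            rotate_origin=False,
            loss_rate=0.0,
            split_prob=0.0,
            dup_prob=0.0,
            strand_flip_prob=0.0,
            erosion_mean=0.01,
        )
        anc, ref_prot = synthetic_data.generate_ancestor(cfg)
        descs, truth = synthetic_data.simulate_reduction(anc, cfg)
        planted = truth.inversions
        n_planted = sum(len(v) for v in planted.values())
        assert n_planted > 0  # this config draws inversions
        # anchor the array on the (inversion-free) ancestor so deviations
        # are relative to the ancestral order, as they would be vs. a
        # free-living reference
        genomes = [anc] + descs
        assignments = {}
        proteomes = {}
        for g in genomes:
            pr = genome_io.extract_proteome(g)
            proteomes[g.genome_id] = pr.proteins
            assignments[g.genome_id] = homology.reciprocal_best_hits(
                pr.proteins, ref_prot
            )
        array = build_array(genomes, assignments, proteomes)
        ref_strands = {g.gene_id: g.strand for g in anc.genes}
        dev = strand_deviations(array, genomes, ref_strands=ref_strands)
        detected = {
            (i["genome_id"], frozenset(i["genes"])) for i in dev["inversions"]
        }
        for gid, invs in planted.items():
            for inv in invs:
                assert (gid, frozenset(inv["genes"])) in detected


class TestSyntenicBlocks:
    def _array_with_refs(self, refs):
        rows = [
            ArrayRow(i, ref, "CDS", {"G0": [(f"x{i}", "+")]})
            for i, ref in enumerate(refs)
        ]
        return GeneArray(rows=rows, genome_ids=["G0"])

    def test_gap_in_reference_indices_breaks_block(self):
        ref_order = [f"r{i}" for i in range(10)]
        array = self._array_with_refs(["r1", "r2", "r3", "r5", "r6"])
        blocks = syntenic_blocks(array, ref_order)
        assert [(b.ref_start, b.ref_end, b.size) for b in blocks] == [
            (1, 3, 3),
            (5, 6, 2),
        ]

    def test_collinear_array_single_block(self):
        ref_order = [f"r{i}" for i in range(5)]
        array = self._array_with_refs(ref_order)
        blocks = syntenic_blocks(array, ref_order)
        assert len(blocks) == 1 and blocks[0].size == 5

    def test_descending_indices_form_reversed_block(self):
        ref_order = [f"r{i}" for i in range(4)]
        array = self._array_with_refs(["r3", "r2", "r1"])
        blocks = syntenic_blocks(array, ref_order)
        assert len(blocks) == 1
        assert blocks[0].orientation == "reversed" and blocks[0].size == 3

    def test_unassigned_rows_skipped_by_default_but_can_break(self):
        ref_order = [f"r{i}" for i in range(6)]
        array = self._array_with_refs(["r1", "r2", None, "r3", "r4"])
        assert len(syntenic_blocks(array, ref_order)) == 1
        assert len(syntenic_blocks(array, ref_order, skip_unassigned=False)) == 2

    def test_no_assigned_rows_raises(self):
        array = self._array_with_refs([None, None])
        with pytest.raises(ValueError):
            syntenic_blocks(array, ["r1"])


class TestPresenceMatrix:
    def test_row_sums_match_pan_core_presence(self, small_sim):
        array = small_sim["array"]
        matrix = presence_matrix(array)
        for row in array.rows:
            assert matrix.loc[row.row_index].sum() == row.n_present

    def test_all_present_matrix_is_ones(self):
        genomes = _named_genomes([["A", "B"], ["A", "B"]])
        matrix = presence_matrix(build_array(genomes, assignments={}))
        assert (matrix.to_numpy() == 1).all()
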