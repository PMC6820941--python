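from lrstitch.alignment_prep import Thresholds
from lrstitch.classification import classify_contigs, neighbour_census
from lrstitch.scaffold_builder import (
    Scaffold,
    ScaffoldPart,
    build_scaffolds,
    extend_ends,
    extract_simple_paths,
    insert_ambiguous,
    merge_scaffolds,
)
from lrstitch.scaffold_graph import GraphEdge, OrientationType, ScaffoldGraph

from conftest import make_contigs, make_ls


def scaffold_of(*parts):
    out = []
    for k, (cid, ori, gap) in enumerate(parts):
        out.append(ScaffoldPart(cid, ori, float(gap)))
    return Scaffold(id="+".join(p[0] for p in parts), parts=out)


def classify(LS, contigs, thresholds=Thresholds()):
    return classify_contigs(neighbour_census(LS, contigs, thresholds), contigs, thresholds)


class TestExtractSimplePaths:
    def test_edgeless_graph_singletons(self):
        g = ScaffoldGraph(["a", "b", "c"])
        drafts = extract_simple_paths(g)
        assert len(drafts) == 3
        assert all(len(d.parts) == 1 and d.parts[0].orientation == 1 for d in drafts)

    def test_chain_preserves_gaps_and_orientations(self):
        g = ScaffoldGraph()
        g.add_edge(GraphEdge("a", "b", OrientationType.FF, 100, 9))
        g.add_edge(GraphEdge("b", "c", OrientationType.FR, 200, 9))
        (draft,) = extract_simple_paths(g)
        sig = draft.signature()
        # FR means c joins b's 3' end on the opposite strand
        assert sig in (
            (("a", 1), ("b", 1), ("c", 0)),
            (("c", 1), ("b", 0), ("a", 0)),
        )
        gaps = [p.gap_after for p in draft.parts]
        assert gaps[:2] in ([100.0, 200.0], [200.0, 100.0])

    def test_first_contig_emitted_forward(self):
        g = ScaffoldGraph()
        g.add_edge(GraphEdge("a", "b", OrientationType.RR, 100, 9))
        (draft,) = extract_simple_paths(g)
        assert draft.parts[0].orientation == 1


class TestInsertAmbiguous:
    def make_inputs(self):
        contigs = make_contigs({"U1": 2000, "U2": 2000, "a": 500, "b": 500})
        LS = [
            make_ls("r1", [("U1", 1, 10, 900), ("a", 1, 20, 400), ("U2", 1, 0, 900)]),
            make_ls("r2", [("U1", 1, 10, 900), ("a", 1, 20, 400), ("U2", 1, 0, 900)]),
            make_ls("r3", [("U1", 1, 10, 950), ("a", 1, 20, 400), ("U2", 1, 0, 950)]),
            make_ls("r4", [("U1", 1, 11, 900), ("b", 1, 21, 400), ("U2", 1, 0, 900)]),
        ]
        classes = classify(LS, contigs)
        return contigs, LS, classes

    def test_majority_candidate_inserted_with_best_gaps(self):
        contigs, LS, classes = self.make_inputs()
        draft = scaffold_of(("U1", 1, 530.0), ("U2", 1, 0.0))
        result = insert_ambiguous(draft, LS, classes, contigs)
        assert result.signature() == (("U1", 1), ("a", 1), ("U2", 1))
        assert [p.gap_after for p in result.parts] == [10.0, 20.0, 0.0]

    def test_reverse_frame_support_counts(self):
        contigs = make_contigs({"U1": 2000, "U2": 2000, "a": 500})
        LS = [make_ls("r1", [("U2", 0, 20, 900), ("a", 0, 10, 400), ("U1", 0, 0, 900)])]
        classes = classify(LS, contigs)
        draft = scaffold_of(("U1", 1, 530.0), ("U2", 1, 0.0))
        result = insert_ambiguous(draft, LS, classes, contigs)
        assert result.signature() == (("U1", 1), ("a", 1), ("U2", 1))

    def test_no_intervening_run_leaves_draft(self):
        contigs = make_contigs({"U1": 2000, "U2": 2000})
        LS = [make_ls("r1", [("U1", 1, 10, 900), ("U2", 1, 0, 900)])]
        classes = classify(LS, contigs)
        draft = scaffold_of(("U1", 1, 10.0), ("U2", 1, 0.0))
        result = insert_ambiguous(draft, LS, classes, contigs)
        assert result.signature() == draft.signature()

    def test_singleton_draft_untouched(self):
        contigs, LS, classes = self.make_inputs()
        draft = scaffold_of(("U1", 1, 0.0))
        assert insert_ambiguous(draft, LS, classes, contigs).signature() == (("U1", 1),)


class TestExtendEnds:
    def test_head_extension_with_unplaced_ambiguous(self):
        # 'amb' is short (ambiguous) and precedes U1 in two reads; U1 heads
        # the scaffold, so the mini graph extends it leftward
        contigs = make_contigs({"U1": 2000, "U2": 2000, "amb": 800})
        LS = [
            make_ls("r1", [("amb", 1, 30, 700), ("U1", 1, 0, 900)]),
            make_ls("r2", [("amb", 1, 30, 700), ("U1", 1, 0, 900)]),
            make_ls("r3", [("U1", 1, 10, 900), ("U2", 1, 0, 900)]),
        ]
        classes = classify(LS, contigs)
        scaffold = scaffold_of(("U1", 1, 10.0), ("U2", 1, 0.0))
        placed = {"U1", "U2"}
        result, changed = extend_ends(scaffold, LS, classes, contigs, Thresholds(), placed)
        assert changed
        assert result.signature() == (("amb", 1), ("U1", 1), ("U2", 1))
        assert result.parts[0].gap_after == 30.0

    def test_no_companions_identity(self):
        contigs = make_contigs({"U1": 2000, "U2": 2000})
        LS = [make_ls("r1", [("U1", 1, 10, 900), ("U2", 1, 0, 900)])]
        classes = classify(LS, contigs)
        scaffold = scaffold_of(("U1", 1, 10.0), ("U2", 1, 0.0))
        result, changed = extend_ends(
            scaffold, LS, classes, contigs, Thresholds(), {"U1", "U2"}
        )
        assert not changed

    def test_already_placed_unique_not_readded(self):
        # U0 precedes U1 in a read but is already placed in another scaffold
        contigs = make_contigs({"U0": 2000, "U1": 2000, "U2": 2000})
        LS = [
            make_ls("r1", [("U0", 1, 30, 900), ("U1", 1, 0, 900)]),
            make_ls("r2", [("U1", 1, 10, 900), ("U2", 1, 0, 900)]),
        ]
        classes = classify(LS, contigs)
        scaffold = scaffold_of(("U1", 1, 10.0), ("U2", 1, 0.0))
        placed = {"U0", "U1", "U2"}
        result, changed = extend_ends(scaffold, LS, classes, contigs, Thresholds(), placed)
        assert not changed
        assert result.signature() == (("U1", 1), ("U2", 1))


class TestMergeScaffolds:
    def test_two_part_overlap_merges(self):
        a = scaffold_of(("x", 1, 10), ("y", 1, 20), ("u", 1, 30), ("v", 1, 0))
        b = scaffold_of(("u", 1, 32), ("v", 1, 40), ("z", 1, 0))
        (merged,) = merge_scaffolds([a, b], t=2)
        assert merged.signature() == (("x", 1), ("y", 1), ("u", 1), ("v", 1), ("z", 1))
        gaps = [p.gap_after for p in merged.parts]
        assert gaps == [10.0, 20.0, 31.0, 40.0, 0.0]  # overlap gap averaged

    def test_no_overlap_identity(self):
        a = scaffold_of(("x", 1, 10), ("y", 1, 0))
        b = scaffold_of(("u", 1, 10), ("v", 1, 0))
        assert len(merge_scaffolds([a, b], t=2)) == 2

    def test_merge_after_reversal(self):
        a = scaffold_of(("x", 1, 10), ("u", 1, 30), ("v", 1, 0))
        # b reversed is (u, v, z): stored as (z-, v-, u-)
        b = scaffold_of(("z", 0, 40), ("v", 0, 30), ("u", 0, 0))
        (merged,) = merge_scaffolds([a, b], t=2)
        assert merged.signature() == (("x", 1), ("u", 1), ("v", 1), ("z", 1))

    def test_orientation_mismatch_blocks_merge(self):
        a = scaffold_of(("x", 1, 10), ("u", 1, 30), ("v", 1, 0))
        b = scaffold_of(("u", 0, 30), ("v", 1, 40), ("z", 1, 0))
        assert len(merge_scaffolds([a, b], t=2)) == 2

    def test_chain_of_merges_reaches_fixpoint(self):
        a = scaffold_of(("a", 1, 1), ("b", 1, 1), ("c", 1, 0))
        b = scaffold_of(("b", 1, 1), ("c", 1, 1), ("d", 1, 0))
        c = scaffold_of(("c", 1, 1), ("d", 1, 1), ("e", 1, 0))
        (merged,) = merge_scaffolds([a, b, c], t=2)
        assert [p.contig_id for p in merged.parts] == ["a", "b", "c", "d", "e"]


class TestBuildScaffolds:
    def test_unique_contig_conservation(self):
        contigs = make_contigs({"U1": 2000, "U2": 2000, "U3": 2000, "amb": 600})
        LS = [
            make_ls("r1", [("U1", 1, 10, 900), ("amb", 1, 20, 500), ("U2", 1, 0, 900)]),
            make_ls("r2", [("U1", 1, 10, 900), ("amb", 1, 20, 500), ("U2", 1, 0, 900)]),
            make_ls("r3", [("U2", 1, 15, 900), ("U3", 1, 0, 900)]),
        ]
        classes = classify(LS, contigs)
        from lrstitch.scaffold_graph import build_graph
        from lrstitch.contradiction_removal import remove_contradictions

        graph = build_graph(LS, classes, contigs)
        lengths = {cid: contigs.length(cid) for cid in contigs}
        cleaned, _, _, _ = remove_contradictions(graph, lengths)
        scaffolds = build_scaffolds(cleaned, LS, classes, contigs, Thresholds())
        placed = [
            p.contig_id
            for s in scaffolds
            for p in s.parts
            if classes[p.contig_id].is_unique
        ]
        assert sorted(placed) == ["U1", "U2", "U3"]
        assert len(placed) == len(set(placed))
        # the ambiguous contig was inserted at the junction it supports
        big = max(scaffolds, key=lambda s: len(s.parts))
        sig = big.signature()
        assert sig in (
            (("U1", 1), ("amb", 1), ("U2", 1), ("U3", 1)),
            (("U3", 0), ("U2", 0), ("amb", 0), ("U1", 0)),
        )
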