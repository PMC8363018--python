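"""Label digestion, ordering, merge/gap resolution, scaffold emission."""

import numpy as np
import pytest

from asmqc import digest, emit_scaffold, order_and_orient, resolve_adjacent
from asmqc.scaffolding import (LabelMap, MapPlacement, build_plan,
                               incorporate_contained, place_by_offset)
from asmqc.simdata import GenomeSpec, MotifLattice, render

from conftest import py_revcomp


class TestDigest:
    def test_planted_motifs_found(self, random_seq):
        seq = "T" * 100 + "CTTAAG" + "T" * 4994 + "CTTAAG" + "T" * 100
        lmap = digest(seq)
        assert lmap.labels.tolist() == [100, 5100]

    def test_motif_free_sequence(self):
        assert digest("A" * 5000).n_labels == 0

    def test_lattice_positions_recovered(self):
        spec = GenomeSpec(length=100_000, seed=7, features=[
            MotifLattice(start=0, length=100_000, spacing=8000, name="dle1")])
        seq, _ = render(spec, "A")
        from asmqc.simdata import _materialize
        _, _, _, motif_positions = _materialize(spec)
        labels = set(digest(seq).labels.tolist())
        assert set(motif_positions["dle1"]) <= labels

    def test_label_map_validation(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            LabelMap("m", 100, np.array([5, 5]))
        with pytest.raises(ValueError, match="outside"):
            LabelMap("m", 100, np.array([150]))


def _contig_setup():
    gm = LabelMap("m", 1_000_000,
                  np.array([50_000, 100_000, 140_000, 160_000, 180_000, 200_000]))
    return gm


class TestOrderAndOrient:
    def test_sorted_by_first_aligned_map_label(self):
        gm = _contig_setup()
        a = MapPlacement("A", "m", "+", [(0, 2), (1, 3)], 2)
        b = MapPlacement("B", "m", "+", [(0, 0), (1, 1)], 2)
        assert [p.contig for p in order_and_orient([a, b], gm)] == ["B", "A"]

    def test_multi_placement_resolved_by_confidence(self):
        gm = _contig_setup()
        low = MapPlacement("A", "m", "+", [(0, 0)], 1)
        high = MapPlacement("A", "m", "+", [(0, 3)], 5)
        ordered = order_and_orient([low, high], gm)
        assert len(ordered) == 1 and ordered[0].confidence == 5

    def test_equal_confidence_conflict_raises(self):
        gm = _contig_setup()
        p1 = MapPlacement("A", "m", "+", [(0, 0)], 2)
        p2 = MapPlacement("A", "m", "+", [(0, 3)], 2)
        with pytest.raises(ValueError, match="conflicting"):
            order_and_orient([p1, p2], gm)

    def test_monotonicity_validation(self):
        with pytest.raises(ValueError, match="monotone"):
            MapPlacement("A", "m", "+", [(1, 0), (0, 1)], 1)
        # decreasing contig indices are correct for reverse orientation
        MapPlacement("A", "m", "-", [(1, 0), (0, 1)], 1)


class TestResolveAdjacent:
    def test_shared_labels_merge(self):
        gm = _contig_setup()
        cm_p = LabelMap("p", 120_000, np.array([10_000, 100_000, 120_000 - 6]))
        cm_n = LabelMap("n", 80_000, np.array([100, 20_100, 60_100]))
        prev = MapPlacement("p", "m", "+", [(0, 1), (1, 2), (2, 3)], 3)
        next_ = MapPlacement("n", "m", "+", [(0, 2), (1, 3), (2, 4)], 3)
        action, gap, prev_cut, next_skip = resolve_adjacent(
            prev, next_, gm, {"p": cm_p, "n": cm_n})
        assert action == "merge_with_previous"
        assert prev_cut == 100_000 and next_skip == 100

    def test_gap_arithmetic_fifteen_kb(self):
        # facing aligned labels 20 kb apart on the map; prev extends 2 kb
        # past its last aligned label, next begins 3 kb before its first
        gm = _contig_setup()
        cm_p = LabelMap("p", 42_000, np.array([2_000, 40_000]))
        cm_n = LabelMap("n", 50_000, np.array([3_000, 43_000]))
        prev = MapPlacement("p", "m", "+", [(0, 1), (1, 2)], 2)  # last at 140 kb
        next_ = MapPlacement("n", "m", "+", [(0, 3), (1, 4)], 2)  # first at 160 kb
        action, gap, *_ = resolve_adjacent(prev, next_, gm,
                                           {"p": cm_p, "n": cm_n})
        assert action == "keep" and gap == 15_000

    def test_negative_gap_floored_with_warning(self):
        gm = _contig_setup()
        cm_p = LabelMap("p", 60_000, np.array([1_000, 30_000]))  # 30 kb tail
        cm_n = LabelMap("n", 40_000, np.array([2_000, 39_000]))
        prev = MapPlacement("p", "m", "+", [(0, 1), (1, 2)], 2)
        next_ = MapPlacement("n", "m", "+", [(0, 3), (1, 4)], 2)
        with pytest.warns(UserWarning, match="floored"):
            action, gap, *_ = resolve_adjacent(prev, next_, gm,
                                               {"p": cm_p, "n": cm_n})
        assert action == "keep" and gap == 1


class TestIncorporateContained:
    def _plan_for(self, placements):
        from asmqc.scaffolding import PlanEntry, ScaffoldPlan
        return ScaffoldPlan(entries=[
            PlanEntry(p.contig, p.orientation, "keep") for p in placements])

    def test_contained_candidate_incorporated(self):
        gm = _contig_setup()
        host = MapPlacement("H", "m", "+", [(i, i) for i in range(6)], 6)
        cand = MapPlacement("c", "m", "+", [(0, 2), (1, 3)], 2)
        plan = self._plan_for([host, cand])
        incorporate_contained(plan, [host, cand], "c", gm)
        actions = {e.contig: e.action for e in plan.entries}
        assert actions == {"H": "keep", "c": "incorporated"}

    def test_candidate_extending_past_host_kept(self):
        gm = _contig_setup()
        host = MapPlacement("H", "m", "+", [(i, i) for i in range(4)], 4)
        cand = MapPlacement("c", "m", "+", [(0, 3), (1, 5)], 2)  # past host
        plan = self._plan_for([host, cand])
        incorporate_contained(plan, [host, cand], "c", gm)
        assert all(e.action == "keep" for e in plan.entries)

    def test_better_aligned_candidate_kept(self):
        gm = _contig_setup()
        # host aligns only the flanks of the candidate interval
        host = MapPlacement("H", "m", "+", [(0, 1), (1, 5)], 2)
        cand = MapPlacement("c", "m", "+", [(0, 2), (1, 3), (2, 4)], 3)
        plan = self._plan_for([host, cand])
        incorporate_contained(plan, [host, cand], "c", gm)
        assert all(e.action == "keep" for e in plan.entries)


class TestEmitScaffold:
    def test_single_contig_identity(self, random_seq):
        seq = random_seq(10_000)
        gm = digest(seq, name="m")
        cm = digest(seq, name="c")
        p = place_by_offset(cm, gm, 0, contig="c")
        plan = build_plan([p], gm, {"c": cm})
        out, ledger = emit_scaffold(plan, {"c": seq})
        assert out == seq
        assert ledger == [(0, 10_000, "c", 0, 10_000, "+")]

    def test_two_contigs_with_gap(self):
        gm = _contig_setup()
        cm_p = LabelMap("p", 10_000, np.array([2_000, 8_000]))
        cm_n = LabelMap("n", 10_000, np.array([3_000, 4_000]))
        prev = MapPlacement("p", "m", "+", [(0, 1), (1, 2)], 2)
        next_ = MapPlacement("n", "m", "+", [(0, 4), (1, 5)], 2)
        plan = build_plan([prev, next_], gm, {"p": cm_p, "n": cm_n})
        gap = plan.entries[1].gap_before
        assert gap == (180_000 - 140_000) - 2_000 - 3_000
        out, ledger = emit_scaffold(plan, {"p": "A" * 10_000, "n": "G" * 10_000})
        assert len(out) == 20_000 + gap
        assert out[10_000:10_000 + gap] == "N" * gap

    def test_missing_sequence_rejected(self):
        gm = _contig_setup()
        cm = LabelMap("c", 1000, np.array([10]))
        plan = build_plan([MapPlacement("c", "m", "+", [(0, 0)], 1)],
                          gm, {"c": cm})
        with pytest.raises(ValueError, match="no sequence"):
            emit_scaffold(plan, {})


class TestRoundTrip:
    def _lattice_sequence(self, length, seed):
        spec = GenomeSpec(length=length, seed=seed, features=[
            MotifLattice(start=0, length=length, spacing=8000, name="dle1")])
        seq, _ = render(spec, "A")
        return seq

    def test_overlapping_fragments_reassemble_exactly(self):
        truth = self._lattice_sequence(500_000, seed=19)
        gmap = digest(truth, name="map")
        frags = {"c1": truth[:200_000], "c2": truth[180_000:350_000],
                 "c3": truth[330_000:]}
        offsets = {"c1": 0, "c2": 180_000, "c3": 330_000}
        cmaps = {n: digest(s, name=n) for n, s in frags.items()}
        placements = [place_by_offset(cmaps[n], gmap, offsets[n], contig=n)
                      for n in frags]
        plan = build_plan(placements, gmap, cmaps)
        out, _ = emit_scaffold(plan, frags)
        assert out == truth
        assert np.array_equal(digest(out).labels, gmap.labels)

    def test_reverse_oriented_fragment_recovered(self):
        truth = self._lattice_sequence(200_000, seed=23)
        gmap = digest(truth, name="map")
        frags = {"c1": truth[:120_000],
                 "c2": py_revcomp(truth[100_000:])}  # delivered reversed
        cmaps = {n: digest(s, name=n) for n, s in frags.items()}
        placements = [
            place_by_offset(cmaps["c1"], gmap, 0, "+", contig="c1"),
            place_by_offset(cmaps["c2"], gmap, 100_000, "-", contig="c2"),
        ]
        plan = build_plan(placements, gmap, cmaps)
        assert plan.entries[1].orientation == "-"
        out, _ = emit_scaffold(plan, frags)
        assert out == truth

    def test_fragments_with_gaps_preserve_label_spacing(self):
        truth = self._lattice_sequence(300_000, seed=29)
        gmap = digest(truth, name="map")
        # non-overlapping fragments leave a true gap of 20 kb
        frags = {"c1": truth[:140_000], "c2": truth[160_000:]}
        cmaps = {n: digest(s, name=n) for n, s in frags.items()}
        placements = [
            place_by_offset(cmaps["c1"], gmap, 0, contig="c1"),
            place_by_offset(cmaps["c2"], gmap, 160_000, contig="c2"),
        ]
        plan = build_plan(placements, gmap, cmaps)
        out, _ = emit_scaffold(plan, frags)
        # emitted scaffold length matches truth up to the estimated gap
        assert abs(len(out) - len(truth)) <= 100
        # labels after the gap keep their truth spacing
        out_labels = digest(out).labels
        assert out_labels.size >= gmap.n_labels - 10


class TestPlanInvariants:
    def test_every_contig_appears_once(self):
        # three overlapping fragments of a labelled sequence
        spec = GenomeSpec(length=90_000, seed=31, features=[
            MotifLattice(start=0, length=90_000, spacing=5000, name="dle1")])
        seq, _ = render(spec, "A")
        gmap = digest(seq, name="map")
        frags = {"a": seq[:40_000], "b": seq[30_000:70_000], "c": seq[60_000:]}
        cmaps = {n: digest(s, name=n) for n, s in frags.items()}
        placements = [place_by_offset(cmaps[n], gmap, off, contig=n)
                      for n, off in [("a", 0), ("b", 30_000), ("c", 60_000)]]
        plan = build_plan(placements, gmap, cmaps)
        assert sorted(plan.contigs()) == ["a", "b", "c"]
        plan.validate()
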