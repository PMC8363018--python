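"""Optical-map-guided contig merging and scaffold emission.

Contigs are placed along an optical genome map (label coordinates of a
nicking-enzyme recognition motif, DLE-1's CTTAAG by default) by an
external aligner; placements arrive here as lists of aligned label pairs.
This module orders and orients the placed contigs, merges adjacent contigs
that demonstrably overlap (shared aligned map labels, or an optional
sequence suffix-prefix check), sizes the gap between non-overlapping
neighbours from the map distance of the nearest aligned labels minus the
contigs' unaligned overhangs, and incorporates contigs whose placement is
contained within (and no better aligned than) another contig's.

The in-silico digestion of a sequence into a label map is exact motif
matching; CTTAAG is reverse-complement palindromic so a single-strand scan
suffices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dotplot import find_motif_occurrences

DLE1_MOTIF = "CTTAAG"


@dataclass
class LabelMap:
    """Label (motif) positions along one sequence or map."""

    name: str
    length: int
    labels: np.ndarray  # strictly increasing motif-start positions (bp)
    motif: str = DLE1_MOTIF

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size:
            if not np.all(np.diff(self.labels) > 0):
                raise ValueError(f"{self.name}: label positions must be strictly increasing")
            if self.labels[0] < 0 or self.labels[-1] >= self.length:
                raise ValueError(f"{self.name}: labels outside [0, length)")

    @property
    def n_labels(self) -> int:
        return int(self.labels.size)

    def oriented_label_pos(self, index: int, orientation: str) -> int:
        """Label-start position in oriented (as-emitted) coordinates."""
        pos = int(self.labels[index])
        if orientation == "+":
            return pos
        return self.length - pos - len(self.motif)


@dataclass
class MapPlacement:
    """Alignment of one contig to a genome map, as aligned label pairs."""

    contig: str
    map_name: str
    orientation: str  # '+' or '-'
    pairs: list[tuple[int, int]]  # (contig label index, map label index)
    confidence: float = 0.0

    def __post_init__(self):
        if not self.pairs:
            raise ValueError(f"{self.contig}: placement needs at least one label pair")
        mis = [mi for _, mi in self.pairs]
        cis = [ci for ci, _ in self.pairs]
        if sorted(mis) != mis:
            raise ValueError(f"{self.contig}: map label indices must increase")
        expect = sorted(cis) if self.orientation == "+" else sorted(cis, reverse=True)
        if cis != expect:
            raise ValueError(f"{self.contig}: contig label indices not monotone "
                             f"for orientation {self.orientation!r}")

    @property
    def map_indices(self) -> list[int]:
        return [mi for _, mi in self.pairs]

    def first_map_index(self) -> int:
        return self.pairs[0][1]

    def last_map_index(self) -> int:
        return self.pairs[-1][1]


@dataclass
class PlanEntry:
    contig: str
    orientation: str
    action: str  # keep | merge_with_previous | incorporated
    gap_before: int = 0
    # for merge_with_previous: cut previous contribution at oriented
    # position ``prev_cut`` of the previous contig, resume the current
    # contig from oriented position ``next_skip``
    prev_cut: int | None = None
    next_skip: int | None = None


@dataclass
class ScaffoldPlan:
    entries: list[PlanEntry] = field(default_factory=list)

    def contigs(self) -> list[str]:
        return [e.contig for e in self.entries]

    def validate(self):
        names = self.contigs()
        if len(set(names)) != len(names):
            raise ValueError("plan lists a contig more than once")
        emitting = [e for e in self.entries if e.action != "incorporated"]
        if emitting and emitting[0].gap_before != 0:
            raise ValueError("first emitted contig must have gap_before == 0")


def digest(sequence: str, motif: str = DLE1_MOTIF, name: str = "seq") -> LabelMap:
    """In-silico digestion: exact motif occurrences as a label map.

    Occurrences on both strands are reported (a single-strand scan
    suffices for palindromic motifs such as CTTAAG); overlapping
    occurrences are allowed.
    """
    positions = find_motif_occurrences(sequence, motif)
    return LabelMap(name=name, length=len(sequence),
                    labels=np.array(positions, dtype=np.int64), motif=motif)


def order_and_orient(placements: list[MapPlacement],
                     genome_map: LabelMap) -> list[MapPlacement]:
    """Sort placements by the map coordinate of their first aligned label.

    A contig placed more than once is resolved to its highest-confidence
    placement; equal-confidence conflicts raise an error naming them.
    """
    best: dict[str, MapPlacement] = {}
    for p in placements:
        if p.map_name != genome_map.name:
            raise ValueError(f"{p.contig}: placed on {p.map_name!r}, "
                             f"not {genome_map.name!r}")
        q = best.get(p.contig)
        if q is None or p.confidence > q.confidence:
            best[p.contig] = p
        elif p.confidence == q.confidence and p is not q:
            raise ValueError(
                f"conflicting equal-confidence placements for {p.contig!r} "
                f"(confidence {p.confidence})")
    return sorted(best.values(),
                  key=lambda p: int(genome_map.labels[p.first_map_index()]))


def _overhangs(p: MapPlacement, contig_map: LabelMap) -> tuple[int, int]:
    """(head, tail) unaligned bp before the first / after the last aligned label."""
    ci_first = p.pairs[0][0]
    ci_last = p.pairs[-1][0]
    head = contig_map.oriented_label_pos(ci_first, p.orientation)
    tail = contig_map.length - contig_map.oriented_label_pos(ci_last, p.orientation)
    return head, tail


def _sequence_overlap(prev_tail: str, next_head: str,
                      min_len: int, min_identity: float):
    """Suffix(prev)-prefix(next) overlap check via edit-distance alignment.

    Returns the position in ``next_head`` just past the matched copy of
    ``prev_tail``'s suffix, or None when no acceptable overlap exists.
    """
    import edlib

    query = prev_tail[-max(min_len, 1):]
    if len(query) < min_len or len(next_head) < min_len:
        return None
    res = edlib.align(query, next_head, mode="HW", task="locations")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    if 1 - res["editDistance"] / len(query) < min_identity:
        return None
    return res["locations"][0][1] + 1


def resolve_adjacent(
    prev: MapPlacement,
    next_: MapPlacement,
    genome_map: LabelMap,
    contig_maps: dict[str, LabelMap],
    shared_label_threshold: int = 2,
    gap_floor: int = 1,
    sequences: dict[str, str] | None = None,
    overlap_min_len: int = 1000,
    overlap_min_identity: float = 0.95,
):
    """Decide merge-vs-gap for two map-adjacent placed contigs.

    Returns ``(action, gap_before, prev_cut, next_skip)``.  Contigs
    sharing at least ``shared_label_threshold`` aligned map labels are
    merged at the first shared label.  Otherwise (optionally) an exact
    sequence suffix-prefix check may establish overlap; failing that the
    gap is the map distance between the facing aligned labels minus both
    unaligned overhangs, floored at ``gap_floor`` (a negative computed gap
    without overlap evidence is flagged as a conflict).
    """
    pm = {mi: ci for ci, mi in prev.pairs}
    nm = {mi: ci for ci, mi in next_.pairs}
    shared = sorted(set(pm) & set(nm))
    cm_prev = contig_maps[prev.contig]
    cm_next = contig_maps[next_.contig]
    if len(shared) >= shared_label_threshold:
        m0 = shared[0]
        prev_cut = cm_prev.oriented_label_pos(pm[m0], prev.orientation)
        next_skip = cm_next.oriented_label_pos(nm[m0], next_.orientation)
        return "merge_with_previous", 0, prev_cut, next_skip

    if sequences is not None:
        prev_seq = _oriented(sequences[prev.contig], prev.orientation)
        next_seq = _oriented(sequences[next_.contig], next_.orientation)
        skip = _sequence_overlap(prev_seq, next_seq,
                                 overlap_min_len, overlap_min_identity)
        if skip is not None:
            return "merge_with_previous", 0, cm_prev.length, skip

    prev_map_pos = int(genome_map.labels[prev.last_map_index()])
    next_map_pos = int(genome_map.labels[next_.first_map_index()])
    _, prev_tail = _overhangs(prev, cm_prev)
    next_head, _ = _overhangs(next_, cm_next)
    gap = (next_map_pos - prev_map_pos) - prev_tail - next_head
    if gap < gap_floor:
        warnings.warn(
            f"{prev.contig} -> {next_.contig}: computed gap {gap} bp without "
            f"overlap evidence; floored to {gap_floor}", stacklevel=2)
        gap = gap_floor
    return "keep", gap, None, None


def _containment_host(candidate: MapPlacement, hosts: list[MapPlacement],
                      genome_map: LabelMap) -> MapPlacement | None:
    cmis = set(candidate.map_indices)
    c_lo = int(genome_map.labels[candidate.first_map_index()])
    c_hi = int(genome_map.labels[candidate.last_map_index()])
    for host in hosts:
        if host.contig == candidate.contig:
            continue
        h_lo = int(genome_map.labels[host.first_map_index()])
        h_hi = int(genome_map.labels[host.last_map_index()])
        if not (h_lo <= c_lo and c_hi <= h_hi):
            continue
        hmis = set(host.map_indices)
        if not cmis <= hmis:
            continue  # candidate aligns labels the host does not
        host_in_interval = sum(
            1 for mi in hmis
            if c_lo <= int(genome_map.labels[mi]) <= c_hi)
        if host_in_interval > len(cmis) or host.confidence >= candidate.confidence:
            return host
    return None


def incorporate_contained(plan: ScaffoldPlan, placements: list[MapPlacement],
                          candidate: str, genome_map: LabelMap) -> ScaffoldPlan:
    """Mark ``candidate`` incorporated if a better-aligned host contains it."""
    by_name = {p.contig: p for p in placements}
    cand = by_name[candidate]
    hosts = [p for p in placements
             if p.contig != candidate
             and any(e.contig == p.contig and e.action != "incorporated"
                     for e in plan.entries)]
    host = _containment_host(cand, hosts, genome_map)
    if host is None:
        return plan
    for e in plan.entries:
        if e.contig == candidate:
            e.action = "incorporated"
            e.gap_before = 0
            e.prev_cut = e.next_skip = None
    return plan


def build_plan(
    placements: list[MapPlacement],
    genome_map: LabelMap,
    contig_maps: dict[str, LabelMap],
    sequences: dict[str, str] | None = None,
    shared_label_threshold: int = 2,
    gap_floor: int = 1,
    incorporate: bool = True,
) -> ScaffoldPlan:
    """Full merge logic: order, incorporate contained contigs, resolve joins."""
    ordered = order_and_orient(placements, genome_map)
    plan = ScaffoldPlan(entries=[
        PlanEntry(p.contig, p.orientation, "keep") for p in ordered])
    if incorporate:
        for p in ordered:
            incorporate_contained(plan, ordered, p.contig, genome_map)
    live = [p for p in ordered
            if next(e for e in plan.entries if e.contig == p.contig).action
            != "incorporated"]
    for prev, nxt in zip(live[:-1], live[1:]):
        action, gap, prev_cut, next_skip = resolve_adjacent(
            prev, nxt, genome_map, contig_maps,
            shared_label_threshold=shared_label_threshold,
            gap_floor=gap_floor, sequences=sequences)
        entry = next(e for e in plan.entries if e.contig == nxt.contig)
        entry.action = action if action == "merge_with_previous" else "keep"
        entry.gap_before = gap
        entry.prev_cut = prev_cut
        entry.next_skip = next_skip
    plan.validate()
    return plan


def _oriented(seq: str, orientation: str) -> str:
    if orientation == "+":
        return seq
    from ._encode import revcomp
    return revcomp(seq)


def emit_scaffold(plan: ScaffoldPlan, sequences: dict[str, str]):
    """Emit the scaffold sequence and a base-level provenance ledger.

    Gaps become runs of 'N'.  The ledger maps every scaffold interval to
    ``(contig, oriented_start, oriented_end, orientation)``; incorporated
    contigs contribute no sequence.
    """
    plan.validate()
    out: list[str] = []
    ledger: list[tuple[int, int, str, int, int, str]] = []
    pos = 0
    for e in plan.entries:
        if e.action == "incorporated":
            continue
        if e.contig not in sequences:
            raise ValueError(f"no sequence provided for planned contig {e.contig!r}")
        seq = _oriented(sequences[e.contig], e.orientation)
        if e.action == "merge_with_previous" and ledger:
            # trim the previous contribution back to its cut point
            ps, pe, pc, pcs, pce, po = ledger[-1]
            cut = ps + (e.prev_cut - pcs)
            trimmed = pos - cut
            if trimmed > 0:
                out[-1] = out[-1][:-trimmed]
                pos = cut
                ledger[-1] = (ps, pos, pc, pcs, e.prev_cut, po)
            seq = seq[e.next_skip:]
            ledger.append((pos, pos + len(seq), e.contig, e.next_skip,
                           e.next_skip + len(seq), e.orientation))
            out.append(seq)
            pos += len(seq)
            continue
        if e.gap_before and ledger:
            out.append("N" * e.gap_before)
            pos += e.gap_before
        ledger.append((pos, pos + len(seq), e.contig, 0, len(seq), e.orientation))
        out.append(seq)
        pos += len(seq)
    return "".join(out), ledger


def place_by_offset(contig_map: LabelMap, genome_map: LabelMap,
                    offset: int, orientation: str = "+",
                    tol: int = 0, contig: str | None = None) -> MapPlacement:
    """Perfect placement of a contig whose oriented start lies at ``offset``.

    Every contig label whose oriented position + offset matches a genome
    map label within ``tol`` bp becomes an aligned pair; confidence is the
    number of pairs.  Intended for fixtures and examples where the true
    layout is known.
    """
    pairs = []
    n = contig_map.n_labels
    indices = range(n) if orientation == "+" else range(n - 1, -1, -1)
    for ci in indices:
        expect = offset + contig_map.oriented_label_pos(ci, orientation)
        j = int(np.searchsorted(genome_map.labels, expect))
        for cand in (j - 1, j, j + 1):
            if 0 <= cand < genome_map.n_labels and \
                    abs(int(genome_map.labels[cand]) - expect) <= tol:
                pairs.append((ci, cand))
                break
    return MapPlacement(contig=contig or contig_map.name,
                        map_name=genome_map.name, orientation=orientation,
                        pairs=pairs, confidence=float(len(pairs)))
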