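"""k-mer sharing dot plots, diagonal chaining, and SV size estimation.

A dot plot marks every pair of positions (x in sequence A, y in sequence
B) whose k-mers match under canonical (strand-independent) comparison;
with k = 50 a match is essentially exact sequence identity.  Collinear
runs of points form diagonal segments; a structural variant between A and
B appears as a displacement between adjacent segments, and its size is the
difference between the x-gap and the y-gap at the breakpoint.

This module also provides exact motif scanning on both strands, used e.g.
to annotate HSat2B satellite arrays by their signature sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._encode import revcomp


@dataclass
class DotPoints:
    """Shared-k-mer occurrence pairs between two sequences."""

    k: int
    x: np.ndarray  # positions in A
    y: np.ndarray  # positions in B
    forward: np.ndarray  # bool; False = reverse-orientation match

    def __len__(self):
        return self.x.size


@dataclass
class DiagonalSegment:
    xs: int
    xe: int
    ys: int
    ye: int
    forward: bool
    n_points: int
    offset: int  # y - x for forward segments, y + x for reverse

    @property
    def orientation(self) -> str:
        return "forward" if self.forward else "reverse"


@dataclass
class SVEstimate:
    type: str  # insertion | deletion | offset
    size: int
    x_gap: int
    y_gap: int


def _kmer_positions(seq: str, k: int, cap: int) -> dict[str, list[tuple[int, bool]]]:
    """Canonical k-mer -> [(position, is_forward)], dropping over-occurring k-mers."""
    seq = seq.upper()
    occ: dict[str, list[tuple[int, bool]]] = {}
    banned: set[str] = set()
    valid = set("ACGT")
    bad = np.array([c not in valid for c in seq])
    run = np.concatenate([[0], np.cumsum(bad)])
    for i in range(len(seq) - k + 1):
        if run[i + k] - run[i]:
            continue
        w = seq[i:i + k]
        rc = revcomp(w)
        key, fwd = (w, True) if w <= rc else (rc, False)
        if key in banned:
            continue
        lst = occ.setdefault(key, [])
        lst.append((i, fwd))
        if len(lst) > cap:
            del occ[key]
            banned.add(key)
    return occ


def shared_kmers(seqA: str, seqB: str, k: int = 50,
                 max_occurrences_per_kmer: int = 10) -> DotPoints:
    """All occurrence pairs of k-mers shared by A and B (canonical match).

    K-mers occurring more than ``max_occurrences_per_kmer`` times in
    either sequence are dropped, bounding the quadratic blow-up inside
    long tandem repeats.  A pair is forward when both occurrences have the
    same strand relative to the canonical form.
    """
    if len(seqA) < k or len(seqB) < k:
        raise ValueError(f"both sequences must be at least k={k} long")
    occA = _kmer_positions(seqA, k, max_occurrences_per_kmer)
    occB = _kmer_positions(seqB, k, max_occurrences_per_kmer)
    xs, ys, fw = [], [], []
    for key, la in occA.items():
        lb = occB.get(key)
        if not lb:
            continue
        for xa, fa in la:
            for xb, fb in lb:
                xs.append(xa)
                ys.append(xb)
                fw.append(fa == fb)
    x = np.array(xs, dtype=np.int64)
    y = np.array(ys, dtype=np.int64)
    f = np.array(fw, dtype=bool)
    order = np.lexsort((y, x))
    return DotPoints(k=k, x=x[order], y=y[order], forward=f[order])


def chain_diagonals(points: DotPoints, max_gap: int = 2000,
                    min_points: int = 5,
                    max_offset_jump: int | None = None) -> list[DiagonalSegment]:
    """Group points into maximal same-orientation diagonal segments.

    Forward points share an offset y - x, reverse points an anti-diagonal
    offset y + x.  A run is split when successive points are more than
    ``max_gap`` apart in x, or when the offset jumps by more than
    ``max_offset_jump`` (default k - 1, so any indel of at least k bases
    starts a new segment and can be sized from the breakpoint).  Runs
    with fewer than ``min_points`` points are dropped.
    """
    if max_offset_jump is None:
        max_offset_jump = points.k - 1
    segments: list[DiagonalSegment] = []
    for fwd in (True, False):
        sel = points.forward == fwd
        x, y = points.x[sel], points.y[sel]
        if x.size == 0:
            continue
        off = (y - x) if fwd else (y + x)
        order = np.lexsort((x, off))
        x, y, off = x[order], y[order], off[order]
        split = np.flatnonzero(
            (np.abs(np.diff(off)) > max_offset_jump)
            | (np.abs(np.diff(x)) > max_gap))
        bounds = np.concatenate([[0], split + 1, [x.size]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a < min_points:
                continue
            cx, cy = x[a:b], y[a:b]
            o = np.argsort(cx)
            cx, cy = cx[o], cy[o]
            segments.append(DiagonalSegment(
                xs=int(cx[0]), xe=int(cx[-1]), ys=int(cy[0]), ye=int(cy[-1]),
                forward=fwd, n_points=int(b - a),
                offset=int(np.median(off[a:b]))))
    segments.sort(key=lambda s: (s.xs, s.ys))
    return segments


def estimate_sv_size(seg1: DiagonalSegment, seg2: DiagonalSegment) -> SVEstimate:
    """Size the variant implied by the breakpoint between two segments.

    Both segments must be same-orientation and ordered along x.  The x-gap
    and y-gap between the facing segment ends are compared: a larger x-gap
    means sequence of A is missing from B (a deletion in B); a larger
    y-gap means extra sequence in B (an insertion).  Overlapping segments
    are reported as type ``offset`` with both gaps.
    """
    if seg1.forward != seg2.forward:
        raise ValueError("segments must share orientation")
    if seg1.xs > seg2.xs:
        seg1, seg2 = seg2, seg1
    x_gap = seg2.xs - seg1.xe
    if seg1.forward:
        y_gap = seg2.ys - seg1.ye
    else:
        # reverse segments run top-to-bottom in y as x increases
        y_gap = seg1.ye - seg2.ys
    size = abs(x_gap - y_gap)
    if x_gap < 0 or y_gap < 0:
        return SVEstimate("offset", size, x_gap, y_gap)
    if x_gap > y_gap:
        return SVEstimate("deletion", size, x_gap, y_gap)
    if y_gap > x_gap:
        return SVEstimate("insertion", size, x_gap, y_gap)
    return SVEstimate("offset", 0, x_gap, y_gap)


def find_motif_occurrences(seq: str, motif: str) -> list[int]:
    """0-based starts of exact occurrences of a motif on either strand.

    Occurrences of the reverse complement are reported at their position
    on the forward sequence; overlapping occurrences are all returned.
    A palindromic motif contributes each site once.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    seq = seq.upper()
    hits: set[int] = set()
    for m in {motif.upper(), revcomp(motif.upper())}:
        i = seq.find(m)
        while i != -1:
            hits.add(i)
            i = seq.find(m, i + 1)
    return sorted(hits)
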