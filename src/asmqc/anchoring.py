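"""Unique-k-mer anchored selection among candidate long-read alignments.

In repeat-rich loci an aligner often reports many plausible placements for
a read.  Anchoring k-mers are k-mers that are unique in both the
sequencing reads (multiplicity within [31, 231], i.e. consistent with a
single diploid copy at the observed depth) and the reference (copy number
exactly 1, with no occurrence outside the locus of interest).  Among the
candidate alignments of a read, the one covering the most reference bases
that belong to an anchoring k-mer window is selected; alignments whose
reference span is shorter than 5 kb are discarded first.

Candidate alignments are produced externally (e.g. ``minimap2 -n 50
-r 10000``) and consumed here as PAF or SAM/BAM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._encode import window_codes
from .kmerlib import KmerSpectrum, index_assembly


@dataclass
class AnchorSet:
    """Locus-specific anchoring k-mers (canonical packed codes)."""

    k: int
    codes: np.ndarray  # sorted int64
    read_mult_bounds: tuple[int, int] = (31, 231)
    provenance: str = ""

    def __len__(self):
        return int(self.codes.size)

    def __contains__(self, kmer: str) -> bool:
        from ._encode import canonical, encode_kmer
        code = encode_kmer(canonical(kmer))
        i = np.searchsorted(self.codes, code)
        return bool(i < self.codes.size and self.codes[i] == code)

    @property
    def kmers(self) -> frozenset:
        from ._encode import decode_kmer
        return frozenset(decode_kmer(int(c), self.k) for c in self.codes)


@dataclass
class CandidateAlignment:
    """One candidate placement of a read on a target scaffold."""

    read_id: str
    target: str
    target_start: int
    target_end: int  # 0-based half-open
    strand: str = "+"
    read_start: int = 0
    read_end: int = 0
    anchored_bases: int | None = None
    tags: dict = field(default_factory=dict)

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    def __post_init__(self):
        if self.target_end <= self.target_start:
            raise ValueError(f"{self.read_id}: empty/negative target interval")


def select_anchors(
    read_spectrum: KmerSpectrum,
    reference,
    locus: tuple[str, int, int],
    lo: int = 31,
    hi: int = 231,
) -> AnchorSet:
    """Select anchoring k-mers for one locus.

    A k-mer qualifies iff its multiplicity in ``read_spectrum`` lies in
    [lo, hi], it occurs exactly once in the whole ``reference`` sequence
    set, and that single occurrence lies inside ``locus`` (a
    ``(scaffold, start, end)`` half-open interval).
    """
    name, start, end = locus
    k = read_spectrum.k
    index = index_assembly(reference, k)
    if name not in index.names:
        raise ValueError(f"locus scaffold {name!r} not in reference")
    if not (0 <= start < end <= index.lengths[name]):
        raise ValueError("locus outside reference bounds")

    valid = index.valid_windows(name)
    positions = np.flatnonzero(valid)
    in_locus = (positions >= start) & (positions + k <= end)
    codes = index.window_codes_of(name)[valid][in_locus]
    C = index.copy_number(name)[valid][in_locus]
    # copy number 1 across the whole reference set implies the single
    # occurrence is the in-locus one (no occurrence outside the locus).
    codes = np.unique(codes[C == 1])
    M = read_spectrum.lookup(codes)
    codes = codes[(M >= lo) & (M <= hi)]
    if codes.size == 0:
        warnings.warn("no anchoring k-mers selected; best-alignment choice "
                      "degenerates to tie-breaks only", stacklevel=2)
    return AnchorSet(k=k, codes=codes, read_mult_bounds=(lo, hi),
                     provenance=f"{name}:{start}-{end}")


def anchor_intervals(anchors: AnchorSet, target_sequence) -> np.ndarray:
    """Merged (start, end) intervals covered by anchor windows on a target.

    Each occurrence of an anchor k-mer covers [pos, pos + k); overlapping
    windows are merged.  Returns an (n, 2) int64 array sorted by start.
    """
    codes, valid = window_codes(target_sequence, anchors.k)
    pos = np.flatnonzero(valid)
    codes = codes[valid]
    idx = np.searchsorted(anchors.codes, codes)
    idx = np.clip(idx, 0, max(anchors.codes.size - 1, 0))
    hit = anchors.codes.size > 0
    is_anchor = hit & (anchors.codes[idx] == codes) if anchors.codes.size else \
        np.zeros(codes.size, dtype=bool)
    starts = pos[is_anchor]
    if starts.size == 0:
        return np.zeros((0, 2), dtype=np.int64)
    merged = []
    cur_s = int(starts[0])
    cur_e = cur_s + anchors.k
    for s in starts[1:]:
        s = int(s)
        if s <= cur_e:
            cur_e = max(cur_e, s + anchors.k)
        else:
            merged.append((cur_s, cur_e))
            cur_s, cur_e = s, s + anchors.k
    merged.append((cur_s, cur_e))
    return np.array(merged, dtype=np.int64)


def score_alignment(
    aln: CandidateAlignment,
    anchors: AnchorSet,
    target_sequence=None,
    intervals: np.ndarray | None = None,
) -> int:
    """Count target bases in the aligned interval covered by an anchor window.

    The score is the length of the union of anchor windows intersected
    with ``[target_start, target_end)``.  Precomputed ``intervals`` (from
    :func:`anchor_intervals`) may be passed to avoid rescanning the target.
    The score is stored on ``aln.anchored_bases`` and returned.
    """
    if intervals is None:
        if target_sequence is None:
            raise ValueError("need target_sequence or precomputed intervals")
        if aln.target_end > len(target_sequence):
            raise ValueError(f"{aln.read_id}: alignment exceeds target bounds")
        intervals = anchor_intervals(anchors, target_sequence)
    total = 0
    for s, e in intervals:
        lo_ = max(int(s), aln.target_start)
        hi_ = min(int(e), aln.target_end)
        if hi_ > lo_:
            total += hi_ - lo_
    aln.anchored_bases = total
    return total


def select_best(
    candidates: list[CandidateAlignment],
    anchors: AnchorSet | None = None,
    min_length: int = 5000,
    target_seqs=None,
) -> CandidateAlignment | None:
    """Pick the best candidate alignment for one read.

    Candidates with target span below ``min_length`` are dropped; among
    the rest the alignment with the most anchored bases wins.  Ties break
    deterministically: smaller target start, then forward strand, then
    target name.  Returns None when no candidate qualifies.
    """
    if not candidates:
        warnings.warn("empty candidate list", stacklevel=2)
        return None
    ids = {c.read_id for c in candidates}
    if len(ids) > 1:
        raise ValueError(f"candidates from multiple reads: {sorted(ids)}")
    pool = [c for c in candidates if c.target_span >= min_length]
    if not pool:
        return None
    cache: dict[str, np.ndarray] = {}
    for c in pool:
        if c.anchored_bases is None:
            if anchors is None or target_seqs is None:
                raise ValueError("anchored_bases unset; pass anchors and target_seqs")
            if c.target not in cache:
                cache[c.target] = anchor_intervals(anchors, target_seqs[c.target])
            score_alignment(c, anchors, intervals=cache[c.target])
    return min(pool, key=lambda c: (-c.anchored_bases, c.target_start,
                                    c.strand != "+", c.target))


def select_all(
    candidates: list[CandidateAlignment],
    anchors: AnchorSet,
    target_seqs,
    min_length: int = 5000,
):
    """Group candidates by read and select one best alignment per read.

    Returns ``(selected, unplaced)`` where ``unplaced`` lists read ids
    with no qualifying candidate (read accounting is preserved).
    """
    by_read: dict[str, list[CandidateAlignment]] = {}
    for c in candidates:
        by_read.setdefault(c.read_id, []).append(c)
    selected, unplaced = [], []
    for rid in sorted(by_read):
        best = select_best(by_read[rid], anchors, min_length, target_seqs)
        if best is None:
            unplaced.append(rid)
        else:
            selected.append(best)
    return selected, unplaced
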