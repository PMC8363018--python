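"""Region definition arithmetic and per-region assembly metrics.

A region of interest is a core gene range plus flanking sequence (1 Mb per
side by default, clamped to chromosome ends, with per-side overrides).
Metrics computed per region: displayed length in Mb, repeat fraction (the
proportion of 31-mers repeated at least once within the region), segmental
duplication overlap, and the within-region NG50 of an assembly's aligned
intervals.

Coordinates are 0-based half-open internally; display (and the built-in
table of the eight human immune loci) uses the conventional 1-based
inclusive form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple

import numpy as np

from ._encode import window_codes


@dataclass
class GenomicRegion:
    """A core range with flanks; all internal coordinates 0-based half-open."""

    name: str
    chromosome: str
    core_start: int
    core_end: int
    final_start: int
    final_end: int
    flank_left: int = 0
    flank_right: int = 0
    clamped: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.final_start <= self.core_start <= self.core_end <= self.final_end):
            raise ValueError(f"{self.name}: inconsistent core/final bounds")

    @property
    def length(self) -> int:
        return self.final_end - self.final_start

    @property
    def display(self) -> str:
        """1-based inclusive coordinate string."""
        return f"{self.chromosome}:{self.final_start + 1:,}-{self.final_end:,}"

    @classmethod
    def from_display(cls, name, chromosome, start1, end1, **kw):
        """Build from 1-based inclusive final coordinates."""
        kw.setdefault("core_start", start1 - 1)
        kw.setdefault("core_end", end1)
        return cls(name=name, chromosome=chromosome,
                   final_start=start1 - 1, final_end=end1, **kw)


#: The eight immune-system loci (GRCh38, 1-based inclusive final coordinates).
IMMUNE_REGIONS: dict[str, GenomicRegion] = {
    name: GenomicRegion.from_display(name, chrom, s, e)
    for name, chrom, s, e in [
        ("IGH", "chr14", 104_586_437, 107_043_718),
        ("IGK", "chr2", 87_857_361, 91_902_511),
        ("IGL", "chr22", 21_026_076, 23_922_913),
        ("HLA", "chr6", 28_602_238, 34_409_896),
        ("TRA", "chr14", 20_621_904, 23_552_132),
        ("TRB", "chr7", 141_299_011, 143_813_287),
        ("TRG", "chr7", 37_240_024, 39_368_055),
        ("KIR", "chr19", 53_724_447, 55_867_209),
    ]
}


def expand_region(
    core: tuple[str, int, int],
    chrom_length: int,
    flank: int = 1_000_000,
    overrides: dict | None = None,
    name: str = "region",
) -> GenomicRegion:
    """Expand a core interval by flanks, clamping to chromosome bounds.

    ``core`` is ``(chromosome, start, end)`` 0-based half-open.
    ``overrides`` may set ``left`` and/or ``right`` flank sizes.
    Clamping at either end is recorded in ``region.clamped``.
    """
    chrom, start, end = core
    if not (0 <= start < end <= chrom_length):
        raise ValueError(f"{name}: core outside chromosome (length {chrom_length})")
    left = (overrides or {}).get("left", flank)
    right = (overrides or {}).get("right", flank)
    fs, fe = start - left, end + right
    clamped = {}
    if fs < 0:
        clamped["left"] = -fs
        fs = 0
    if fe > chrom_length:
        clamped["right"] = fe - chrom_length
        fe = chrom_length
    return GenomicRegion(name=name, chromosome=chrom, core_start=start,
                         core_end=end, final_start=fs, final_end=fe,
                         flank_left=left, flank_right=right, clamped=clamped)


def region_length_mb(region: GenomicRegion) -> float:
    """Region length in Mb under the 1-based inclusive display convention,
    rounded half-up to two decimals (as printed in summary tables)."""
    length = region.final_end - region.final_start  # == inclusive end-start+1
    mb = (Decimal(length) / Decimal(10**6)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(mb)


def repeat_fraction(sequence: str, k: int = 31) -> float:
    """Proportion of the sequence's k-mers repeated at least once within it.

    Computed over valid windows with canonical (strand-independent)
    matching: the fraction of windows whose canonical k-mer occurs two or
    more times in the sequence.
    """
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes, valid = window_codes(sequence, k)
    codes = codes[valid]
    if codes.size == 0:
        raise ValueError("no valid windows (non-ACGT content)")
    _, inv, counts = np.unique(codes, return_inverse=True, return_counts=True)
    return float((counts[inv] >= 2).mean())


def _union_length(intervals, lo: int, hi: int) -> int:
    clipped = sorted((max(s, lo), min(e, hi)) for s, e in intervals
                     if min(e, hi) > max(s, lo))
    total = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def sd_overlap_fraction(region: GenomicRegion, annotations,
                        identity_min: float | None = None) -> float:
    """Percentage of the region covered by (qualifying) annotations.

    ``annotations`` is an iterable of ``(chromosome, start, end,
    identity)`` tuples (0-based half-open); overlapping intervals are
    counted once (union semantics).  ``identity_min`` restricts to
    high-identity segmental duplications when given.
    """
    ivals = [(s, e) for chrom, s, e, ident in annotations
             if chrom == region.chromosome
             and (identity_min is None or ident >= identity_min)]
    covered = _union_length(ivals, region.final_start, region.final_end)
    return 100.0 * covered / region.length


class NG50Result(NamedTuple):
    value: int
    covered_fraction: float
    reached: bool


def regional_ng50(region_length: int, alignment_intervals: dict) -> NG50Result:
    """Within-region NG50 of per-contig aligned intervals.

    For each contig the within-region length is the union of its
    intervals; contigs are ranked by that length and the NG50 is the
    length at which the running sum first covers half of
    ``region_length``.  ``value`` is 0 (``reached`` False) if 50% coverage
    is never attained.
    """
    lengths = sorted(
        (_union_length(iv, 0, region_length) if not isinstance(iv, (int, np.integer))
         else int(iv)
         for iv in alignment_intervals.values()),
        reverse=True)
    half = region_length / 2
    running = 0
    total = sum(lengths)
    for ln in lengths:
        running += ln
        if running >= half:
            return NG50Result(int(ln), total / region_length, True)
    return NG50Result(0, total / region_length, False)
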