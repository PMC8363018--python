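"""Reference-free assembly validation from k-mer multiplicities.

The central quantity is the normalized multiplicity of an assembly k-mer,

    N = M / (C x D)

where M is the k-mer's multiplicity in a validation read set, C its copy
number in the assembly, and D the modal multiplicity of unique homozygous
k-mers in the reads.  For a correctly assembled homozygous k-mer N is about
1; about 0.5 over a heterozygous deletion (the reads carry only one
haplotype's worth of coverage); and about 2 over a collapsed duplication
(two genomic copies are represented once in the assembly).

The module also implements the cluster-based error-rate estimator: assembly
k-mers (k = 22) with validation multiplicity below a threshold (default 5)
are classified erroneous and clustered along the assembly, allowing at most
k - 1 correct k-mers between adjacent erroneous ones; the number of
clusters per Mb of assembled sequence is the error-rate indicator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .kmerlib import AssemblyKmerIndex, KmerSpectrum

#: default interpretation bands for the median N of a discrepant region
DEFAULT_BANDS = (
    ("coverage_gap_like", 0.0, 0.1),
    ("het_deletion_like", 0.35, 0.65),
    ("het_duplication_like", 1.35, 1.65),
    ("collapsed_duplication_like", 1.75, 2.5),
)


@dataclass
class NormalizedTrack:
    """Per-window normalized multiplicity along one scaffold.

    ``positions`` are 0-based starts of the valid windows; ``informative``
    is False where the window's k-mer also occurs outside the supplied
    region mask (such k-mers cannot distinguish local from distal copies).
    K-mers absent from the validation reads get N = 0, never missing.
    """

    scaffold: str
    positions: np.ndarray
    N: np.ndarray
    M: np.ndarray
    C: np.ndarray
    informative: np.ndarray
    k: int
    D: int

    def __len__(self):
        return self.positions.size


@dataclass
class DiscrepantRegion:
    scaffold: str
    start: int
    end: int  # 0-based half-open
    median_N: float
    n_informative: int
    interpretation: str


@dataclass
class ErrorClusterSet:
    """Clusters of erroneous k-mers and the per-Mb error-rate estimate."""

    clusters: list[tuple[str, int, int, int]]  # (scaffold, start, end, n kmers)
    k: int
    multiplicity_threshold: int
    n_erroneous_windows: int
    n_windows: int
    assembly_length: int
    per_scaffold: dict[str, int] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def rate_per_mb(self) -> float:
        return self.n_clusters / (self.assembly_length / 1e6)

    @property
    def erroneous_percent(self) -> float:
        """Erroneous windows as a percentage of evaluated windows."""
        return error_percentage(self.n_erroneous_windows, self.n_windows)

    def scaffold_rate(self, name: str, length: int) -> float:
        return self.per_scaffold.get(name, 0) / (length / 1e6)


def error_percentage(n_erroneous: int, n_total: int) -> float:
    """Percentage of k-mers deemed erroneous (plain 100 x ratio)."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_erroneous / n_total


def _occurrence_in_mask(index: AssemblyKmerIndex, region_mask) -> np.ndarray:
    """Per-occurrence flag: the full window lies inside the mask."""
    sid_of = {name: i for i, name in enumerate(index.names)}
    inside = np.zeros(index._occ_pos.size, dtype=bool)
    k = index.k
    if isinstance(region_mask, (set, frozenset, list)) and all(
            isinstance(x, str) for x in region_mask):
        wanted = {sid_of[n] for n in region_mask if n in sid_of}
        inside = np.isin(index._occ_sid, list(wanted))
        return inside
    for name, intervals in region_mask.items():
        if name not in sid_of:
            continue
        sel = index._occ_sid == sid_of[name]
        pos = index._occ_pos[sel]
        ok = np.zeros(pos.size, dtype=bool)
        if intervals is None:  # whole scaffold
            ok[:] = True
        else:
            for s, e in intervals:
                ok |= (pos >= s) & (pos + k <= e)
        inside[sel] = ok
    return inside


def normalized_track(
    index: AssemblyKmerIndex,
    validation: KmerSpectrum,
    D: int,
    region_mask=None,
) -> dict[str, NormalizedTrack]:
    """Compute N = M/(C x D) for every valid window of every scaffold.

    ``region_mask`` restricts which k-mers are informative: a k-mer with
    any occurrence outside the mask (a set of scaffold names, or a dict
    scaffold -> list of (start, end) intervals / None for the whole
    scaffold) is flagged noninformative.  Without a mask every window is
    informative.
    """
    if index.k != validation.k:
        raise ValueError(f"k mismatch: index k={index.k}, validation k={validation.k}")
    if D is None:
        raise ValueError("D is undetermined; run build_histogram first or supply D")
    if D < 1:
        raise ValueError("D must be >= 1")

    if region_mask is not None:
        group_informative = np.logical_and.reduceat(
            _occurrence_in_mask(index, region_mask), index._group_start)

    tracks = {}
    for name in index.names:
        valid = index.valid_windows(name)
        positions = np.flatnonzero(valid).astype(np.int64)
        codes = index.window_codes_of(name)[valid]
        M = validation.lookup(codes)
        C = index.copy_number(name)[valid].astype(np.int64)
        N = M / (C * float(D))
        if region_mask is None:
            informative = np.ones(positions.size, dtype=bool)
        else:
            informative = group_informative[index.per_window_group_index(name)]
        tracks[name] = NormalizedTrack(
            scaffold=name, positions=positions, N=N, M=M,
            C=C.astype(np.int32), informative=informative,
            k=index.k, D=int(D))
    return tracks


def flag_discrepancies(
    track: NormalizedTrack,
    low: float = 0.75,
    high: float = 1.25,
    min_span: int = 2000,
    min_informative: int = 20,
    max_gap: int = 1000,
    min_run: int = 5,
    bands=DEFAULT_BANDS,
) -> list[DiscrepantRegion]:
    """Flag maximal stretches of informative windows with N outside [low, high].

    Deviant informative windows (N below ``low`` or above ``high``) are
    clustered along the scaffold, joining windows at most ``max_gap`` bp
    apart — so isolated in-band windows from sampling noise do not split a
    genuine event.  Noninformative windows neither extend nor break a
    cluster.  Each cluster is then trimmed to the outermost run of
    ``min_run`` consecutive deviant windows: inside a real event nearly
    every window is out of band, whereas isolated sampling outliers almost
    never occur ``min_run`` times in a row, so trimming removes chained
    noise at the edges without eroding the event.  A trimmed cluster is
    reported if it spans at least ``min_span`` bp, contains at least
    ``min_informative`` informative windows, and the median N over ALL
    informative windows in its span is itself outside the band; that
    median is mapped to an interpretation via ``bands``.
    """
    if not (0 <= low < 1 < high):
        raise ValueError("need 0 <= low < 1 < high")
    info = track.informative
    if not info.any():
        warnings.warn(f"{track.scaffold}: no informative windows", stacklevel=2)
        return []
    pos = track.positions[info]
    N = track.N[info]
    deviant = (N < low) | (N > high)
    dev_idx = np.flatnonzero(deviant)
    out: list[DiscrepantRegion] = []
    if dev_idx.size == 0:
        return out
    dev_pos = pos[dev_idx]
    breaks = np.flatnonzero(np.diff(dev_pos) > max_gap)
    bounds = np.concatenate([[0], breaks + 1, [dev_pos.size]])
    for a, b in zip(bounds[:-1], bounds[1:]):
        # trim to the outermost dense run of deviant windows: min_run
        # consecutive informative windows that are all deviant
        idx = dev_idx[a:b]
        if idx.size < min_run:
            continue
        consecutive = np.convolve((np.diff(idx) == 1).astype(int),
                                  np.ones(min_run - 1, dtype=int), "valid")
        run_starts = np.flatnonzero(consecutive == min_run - 1)
        if run_starts.size == 0:
            continue
        start = int(pos[idx[run_starts[0]]])
        end = int(pos[idx[run_starts[-1] + min_run - 1]]) + track.k
        span = (pos >= start) & (pos < end)
        span_N = N[span]
        med = float(np.median(span_N))
        if end - start < min_span or span_N.size < min_informative:
            continue
        if low <= med <= high:
            continue
        interp = "unclassified"
        for label, lo_b, hi_b in bands:
            if lo_b <= med < hi_b if label == "coverage_gap_like" \
                    else lo_b <= med <= hi_b:
                interp = label
                break
        out.append(DiscrepantRegion(track.scaffold, start, end, med,
                                    int(span_N.size), interp))
    return out


def cluster_starts(starts, k: int) -> list[tuple[int, int, int]]:
    """Cluster erroneous-window start positions along one scaffold.

    Two erroneous windows at starts p < q belong to the same cluster iff
    q - p <= k, i.e. at most k - 1 correct windows lie between them.
    Returns (start, end, n) per cluster with end = last start + k.
    """
    starts = np.asarray(sorted(starts), dtype=np.int64)
    if starts.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(starts) > k)
    bounds = np.concatenate([[0], breaks + 1, [starts.size]])
    return [(int(starts[a]), int(starts[b - 1]) + k, int(b - a))
            for a, b in zip(bounds[:-1], bounds[1:])]


def error_rate(
    index: AssemblyKmerIndex,
    validation: KmerSpectrum,
    multiplicity_threshold: int = 5,
) -> ErrorClusterSet:
    """Cluster-based error-rate estimate (clusters per Mb of assembly).

    A window is erroneous iff its canonical k-mer has validation
    multiplicity below ``multiplicity_threshold`` (absent counts as 0).
    """
    if index.k != validation.k:
        raise ValueError(f"k mismatch: index k={index.k}, validation k={validation.k}")
    if len(validation) == 0:
        raise ValueError("validation spectrum is empty: cannot distinguish "
                         "absent k-mers from erroneous ones")
    if multiplicity_threshold < 1:
        raise ValueError("multiplicity_threshold must be >= 1")

    clusters = []
    per_scaffold: dict[str, int] = {}
    n_err = 0
    n_win = 0
    for name in index.names:
        valid = index.valid_windows(name)
        codes = index.window_codes_of(name)[valid]
        positions = np.flatnonzero(valid)
        M = validation.lookup(codes)
        err = M < multiplicity_threshold
        n_err += int(err.sum())
        n_win += int(valid.sum())
        cl = cluster_starts(positions[err], index.k)
        per_scaffold[name] = len(cl)
        clusters.extend((name, s, e, c) for s, e, c in cl)
    return ErrorClusterSet(
        clusters=clusters, k=index.k,
        multiplicity_threshold=multiplicity_threshold,
        n_erroneous_windows=n_err, n_windows=n_win,
        assembly_length=index.total_length, per_scaffold=per_scaffold)


def normalize_coverage(depths, baseline: float) -> np.ndarray:
    """Divide a per-position depth array by a baseline depth."""
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    return np.asarray(depths, dtype=float) / baseline
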