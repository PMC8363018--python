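"""Normalized multiplicity tracks, discrepancy flagging, error clustering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asmqc import count_kmers, index_assembly
from asmqc.kmerlib import KmerSpectrum
from asmqc.simdata import (Duplication, GenomeSpec, HetDeletion, build_diploid,
                           plant_errors, render, simulate_reads)
from asmqc.validation import (NormalizedTrack, cluster_starts,
                              error_percentage, error_rate,
                              flag_discrepancies, normalize_coverage,
                              normalized_track)

from conftest import py_canonical


def _track(N, positions=None, informative=None, k=31, scaffold="s"):
    N = np.asarray(N, dtype=float)
    positions = (np.arange(N.size, dtype=np.int64)
                 if positions is None else np.asarray(positions))
    info = (np.ones(N.size, dtype=bool)
            if informative is None else np.asarray(informative))
    return NormalizedTrack(scaffold=scaffold, positions=positions, N=N,
                           M=(N * 100).astype(np.int64),
                           C=np.ones(N.size, dtype=np.int32),
                           informative=info, k=k, D=100)


class TestNormalizedTrack:
    @pytest.mark.parametrize("M,C,D,expected", [
        (300, 2, 150, 1.0),
        (75, 1, 150, 0.5),   # heterozygous-deletion signature
        (300, 1, 150, 2.0),  # collapsed-duplication signature
    ])
    def test_formula(self, random_seq, M, C, D, expected):
        unit = random_seq(31)
        seq = unit * C if C > 1 else unit
        idx = index_assembly({"s": seq}, k=31)
        spec = KmerSpectrum.from_counts({py_canonical(unit): M}, k=31)
        tr = normalized_track(idx, spec, D)["s"]
        # windows matching the planted 31-mer exactly
        exact = tr.M == M
        assert exact.any()
        assert tr.N[exact] == pytest.approx(expected)

    def test_absent_kmer_gets_zero_not_missing(self, random_seq):
        seq = random_seq(100)
        idx = index_assembly({"s": seq}, k=31)
        spec = KmerSpectrum.from_counts({py_canonical(seq[:31]): 50}, k=31)
        tr = normalized_track(idx, spec, 50)["s"]
        assert tr.N.size == 70  # every valid window present
        assert tr.N[1:].sum() == 0.0

    def test_k_mismatch_rejected(self, random_seq):
        idx = index_assembly({"s": random_seq(100)}, k=31)
        spec = KmerSpectrum.from_counts({"A" * 22: 5}, k=22)
        with pytest.raises(ValueError, match="k mismatch"):
            normalized_track(idx, spec, 50)

    def test_undetermined_D_rejected(self, random_seq):
        idx = index_assembly({"s": random_seq(100)}, k=31)
        spec = KmerSpectrum.from_counts({py_canonical("A" * 31): 5}, k=31)
        with pytest.raises(ValueError, match="histogram"):
            normalized_track(idx, spec, None)

    def test_region_mask_marks_outside_occurrences_noninformative(self, random_seq):
        shared = random_seq(31)
        a = random_seq(50) + shared + random_seq(50)
        b = random_seq(60) + shared + random_seq(60)
        idx = index_assembly({"locus": a, "distal": b}, k=31)
        spec = KmerSpectrum.from_counts(
            {py_canonical(a[i:i + 31]): 100 for i in range(len(a) - 30)}, k=31)
        tr = normalized_track(idx, spec, 100, region_mask={"locus": None})["locus"]
        shared_windows = tr.M > 0
        noninf = ~tr.informative
        # exactly the windows whose k-mer also occurs on the distal scaffold
        hits = [i for i in range(len(a) - 30)
                if py_canonical(a[i:i + 31]) in
                {py_canonical(b[j:j + 31]) for j in range(len(b) - 30)}]
        assert sorted(tr.positions[noninf]) == hits

    def test_scale_invariance_under_read_duplication(self, random_seq):
        from asmqc import build_histogram
        from asmqc.simdata import ReadBatch

        genome = random_seq(50_000, seed=3)
        reads = simulate_reads(genome, depth=40, seed=4, circular=True)
        idx = index_assembly({"s": genome}, k=31)
        sp1 = count_kmers(reads, k=31)
        sp2 = count_kmers(ReadBatch.concatenate([reads, reads]), k=31)
        D1 = build_histogram(sp1).require_D()
        D2 = build_histogram(sp2).require_D()
        assert D2 == 2 * D1
        t1 = normalized_track(idx, sp1, D1)["s"]
        t2 = normalized_track(idx, sp2, D2)["s"]
        assert np.allclose(t1.N, t2.N)


class TestFlagDiscrepancies:
    def test_uniform_track_clean(self):
        assert flag_discrepancies(_track(np.ones(5000))) == []

    def test_no_informative_windows_warns_empty(self):
        tr = _track(np.ones(100), informative=np.zeros(100, dtype=bool))
        with pytest.warns(UserWarning, match="no informative"):
            assert flag_discrepancies(tr) == []

    def test_invalid_bands_rejected(self):
        with pytest.raises(ValueError):
            flag_discrepancies(_track(np.ones(10)), low=1.2, high=1.4)

    @pytest.mark.parametrize("level,interp", [
        (0.5, "het_deletion_like"),
        (1.5, "het_duplication_like"),
        (2.0, "collapsed_duplication_like"),
        (0.0, "coverage_gap_like"),
        (3.5, "unclassified"),
    ])
    def test_interpretation_bands(self, level, interp):
        N = np.ones(10_000)
        N[4000:7000] = level
        regions = flag_discrepancies(_track(N))
        assert len(regions) == 1
        assert regions[0].interpretation == interp
        assert regions[0].start == 4000 and regions[0].end == 6999 + 31

    def test_short_dips_suppressed(self):
        N = np.ones(10_000)
        N[5000:5010] = 0.5  # SNP-scale dip, below min_span
        assert flag_discrepancies(_track(N)) == []


class TestPlantedSVRecovery:
    @staticmethod
    def _reciprocal_overlap(a, b):
        inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
        return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))

    def _run(self, spec, assembly_role, feature):
        from asmqc import build_histogram

        hapA, hapB, truth = build_diploid(spec)
        asm, intervals = render(spec, assembly_role)
        reads = simulate_reads([hapA, hapB], depth=60, seed=spec.seed + 1)
        sp = count_kmers(reads, k=31)
        D = build_histogram(sp).require_D()
        idx = index_assembly({"asm": asm}, k=31)
        tr = normalized_track(idx, sp, D)["asm"]
        return flag_discrepancies(tr), intervals[feature]

    def test_het_deletion_recovered(self):
        spec = GenomeSpec(length=300_000, seed=61, features=[
            HetDeletion(start=130_000, length=40_000)])
        regions, planted = self._run(spec, "A", "het_deletion")
        dels = [r for r in regions if r.interpretation == "het_deletion_like"]
        assert len(dels) == 1
        got = (dels[0].start, dels[0].end)
        assert self._reciprocal_overlap(got, planted) >= 0.90

    def test_collapse_recovered(self):
        spec = GenomeSpec(length=300_000, seed=62, features=[
            Duplication(start=130_000, length=30_000, copies_a=2, copies_b=2,
                        name="collapse")])
        regions, planted = self._run(spec, "consensus", "collapse")
        cols = [r for r in regions
                if r.interpretation == "collapsed_duplication_like"]
        assert len(cols) == 1
        got = (cols[0].start, cols[0].end)
        assert self._reciprocal_overlap(got, planted) >= 0.90


class TestErrorRate:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=30), st.integers(2, 40))
    def test_cluster_rule_matches_bruteforce(self, starts, k):
        starts = sorted(set(starts))
        clusters = cluster_starts(starts, k)
        # brute force: walk and split where gap > k
        expected = 1
        for p, q in zip(starts[:-1], starts[1:]):
            if q - p > k:
                expected += 1
        assert len(clusters) == expected
        assert sum(c[2] for c in clusters) == len(starts)

    def test_stated_boundary(self):
        assert len(cluster_starts([0, 22], 22)) == 1  # 21 intervening <= k-1
        assert len(cluster_starts([0, 23], 22)) == 2  # 22 intervening > k-1

    def test_clean_assembly_rate_zero(self, random_seq):
        genome = random_seq(200_000, seed=71)
        reads = simulate_reads(genome, depth=40, seed=72, circular=True)
        sp = count_kmers(reads, k=22)
        idx = index_assembly({"asm": genome}, k=22)
        res = error_rate(idx, sp)
        assert res.n_clusters == 0 and res.rate_per_mb == 0.0

    def test_planted_substitutions_one_cluster_each(self, random_seq):
        genome = random_seq(200_000, seed=73)
        mutated, positions = plant_errors(genome, 3, 2000, seed=74)
        reads = simulate_reads(genome, depth=40, seed=75, circular=True)
        sp = count_kmers(reads, k=22)
        idx = index_assembly({"asm": mutated}, k=22)
        res = error_rate(idx, sp)
        assert res.n_clusters == 3
        assert res.rate_per_mb == pytest.approx(15.0)
        for (scaf, s, e, n), p in zip(res.clusters, positions):
            assert s <= p < e

    def test_threshold_monotonicity(self, random_seq):
        genome = random_seq(50_000, seed=76)
        reads = simulate_reads(genome, depth=6, seed=77, circular=True)
        sp = count_kmers(reads, k=22)
        idx = index_assembly({"asm": genome}, k=22)
        counts = [error_rate(idx, sp, t).n_erroneous_windows
                  for t in (1, 3, 5, 8)]
        assert counts == sorted(counts)

    def test_empty_spectrum_rejected(self, random_seq):
        idx = index_assembly({"asm": random_seq(1000)}, k=22)
        empty = KmerSpectrum(k=22, codes=np.zeros(0, np.int64),
                             multiplicities=np.zeros(0, np.int64))
        with pytest.raises(ValueError, match="empty"):
            error_rate(idx, empty)

    def test_error_percentage(self):
        assert error_percentage(8786, 3.16e7) == pytest.approx(0.0278, abs=5e-5)


class TestNormalizeCoverage:
    def test_elementwise(self):
        out = normalize_coverage([63, 126, 0], 63)
        assert out.tolist() == [1.0, 2.0, 0.0]

    def test_constant_is_one(self):
        assert np.allclose(normalize_coverage([40] * 10, 40), 1.0)

    def test_bad_baseline(self):
        with pytest.raises(ValueError):
            normalize_coverage([1, 2], 0)

    def test_poisson_coverage_concentrates_near_one(self, rng):
        # uniform shotgun coverage is Poisson; at depth >= 30 the
        # normalized values concentrate in [0.5, 1.5]
        depths = rng.poisson(30, size=100_000)
        norm = normalize_coverage(depths, depths.mean())
        assert ((norm >= 0.5) & (norm <= 1.5)).mean() >= 0.95
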