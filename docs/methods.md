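# Methods

This note records the models, conventions, parameter choices and known
limitations behind `asmqc`, in the order the pieces are used.

## Canonical k-mer counting

All counting is exact and strand-independent: a window's canonical form is
the lexicographic minimum of the k-mer and its reverse complement (with
A<C<G<T, this equals the numeric minimum of the two 2-bit packed codes).
Windows containing any non-ACGT symbol (N included; lowercase is
normalized first) or any base with Phred quality below `min_quality` are
rejected, not zeroed, and the accounting identity

    sum of multiplicities = windows total − windows rejected

is asserted on every run.  The default quality threshold is 20;
practitioners sometimes run the equivalent Jellyfish step with a Q30
character threshold instead, so the value is configurable rather than
baked in.  Packed counting supports k ≤ 31 (single 64-bit word); larger k
(up to 64, used only for dot plots at k = 50) falls back to a
string-keyed path.  Counts are exact in memory — no sketches — with the
window scan compiled via numba and counting done in chunks so that a
240 Mb read set at k = 31 stays well under 4 GB.

## The multiplicity histogram and D

`D` is the modal multiplicity of unique homozygous k-mers, the
denominator that converts multiplicities into genome copy numbers.  Peaks
are found on a moving-average smoothed copy of the histogram (window 3),
keeping candidates with height ≥ 1% of the global maximum and
multiplicity ≥ 5 (discarding the sequencing-error spike), then refining
each peak to the raw-histogram maximum in its neighbourhood — smoothing
locates, the raw bins decide, which matters when the histogram is
supported on sparse multiplicities.

Among the two highest peaks, D is the one at greater multiplicity (the
homozygous peak lies right of the heterozygous peak) **unless** the
right-hand peak's height is below 10% of the highest peak's.  That guard
exists because a genome with 2-copy repeats and little heterozygosity
produces a small repeat harmonic at ≈ 2D which the naive
"rightmost-of-top-two" rule would mistake for the homozygous peak; a
genuine homozygous peak to the right of a strong heterozygous peak is
always a substantial fraction of it.  The 10% fraction
(`right_peak_min_frac`) and every other peak parameter are exposed; the
guard fails, by design, on genomes whose 2-copy repeat content rivals
their unique content — for such data set D explicitly.

With finite read length L, a k-mer's expected multiplicity is depth ×
(L−k+1)/L per genome copy, not depth itself; D absorbs this factor, which
is why N is centred on 1 regardless of read length.

## Normalized multiplicity tracks and discrepancy calling

`N = M/(C×D)` is computed at every valid assembly window.  K-mers absent
from the validation reads get N = 0 — an observation ("no read support"),
never missing data.  When a region mask is supplied, a k-mer with any
occurrence outside the mask is flagged noninformative: its multiplicity
pools local and distal copies and cannot support a local copy-number
statement.  Noninformative windows stay in the track (they are plotted
gray, in the usual convention) but are excluded from flagging.

Discrepancy calling takes windows with N outside [low, high] (defaults
0.75 and 1.25), clusters them along the scaffold joining neighbours
≤ `max_gap` = 1 kb apart, and then trims each cluster to the outermost
run of `min_run` = 5 consecutive deviant windows.  The trimming step is
what makes the caller robust at realistic depths: individual windows
fluctuate out of band a few percent of the time (Poisson sampling), and
gap-joining alone would chain those singletons far past a real event's
edges, whereas five consecutive out-of-band windows essentially never
happen by chance.  A trimmed cluster is reported if it spans ≥ `min_span`
= 2 kb with ≥ 20 informative windows (suppressing SNP-scale dips) and the
median N over all informative windows in its span is itself out of band.
The median is then mapped to an interpretation: [0.35, 0.65] →
heterozygous-deletion-like, [1.35, 1.65] → heterozygous-duplication-like,
[1.75, 2.5] → collapsed-duplication-like, < 0.1 → coverage-gap-like, else
unclassified.  The bands are reporting conveniences, not calibrated
genotype calls, and are configurable.

## Cluster-based error rate

Assembly k-mers (k = 22) with validation multiplicity below 5 are
classified erroneous; erroneous window starts p < q join one cluster iff
q − p ≤ k, i.e. at most k−1 correct k-mers may sit between neighbours.
Clustering operates on window start positions, matching the "correct
k-mers between" phrasing.  One isolated substitution corrupts up to k
consecutive windows and therefore yields exactly one cluster, so clusters
per Mb approximates substitution errors per Mb.  The estimator requires a
non-empty validation spectrum: with no reads at all, absence of support
is indistinguishable from error.  Classical per-base quality-value (QV)
estimation from k-mer survival is intentionally not implemented; the
cluster count is the error statistic here.

## Haplotig purging

Contigs are compared shortest-first by their sets of distinct canonical
22-mers; a contig whose sharing fraction against any longer surviving
contig exceeds 0.8 is removed.  Processing shortest-first means a haplotig
cannot shelter another haplotig.  "Unique 22-mers" is read as *distinct
22-mers*; the alternative occurs-exactly-once reading is available via
`kmer_semantics="occurs_once"`.  Equal-length ties treat the
lexicographically later name as the shorter contig — arbitrary but
deterministic, and it guarantees exactly one of two identical contigs is
removed.  Comparison is all-vs-all and quadratic in contig count, which
is fine at locus scale (tens of contigs).

## Anchored alignment selection

Anchor k is 21 by default (not dictated by the anchoring bounds; any k
≤ 31 works and the filters adapt).  The anchored-base score of a
candidate alignment is the length of the union of anchor-k-mer windows on
the *target*, intersected with the aligned target interval; insertions in
the read add nothing.  Scoring does not re-verify per-base matches inside
anchor windows — candidates come from an aligner that already established
base-level correspondence.  Ties break by smaller target start, then
forward strand, then target name, making selection deterministic.  Reads
with no qualifying candidate (all spans < 5 kb) are reported unplaced so
read accounting is preserved.

## Dot plots and SV sizing

Shared-k-mer points are computed under canonical matching with per-pair
orientation; k-mers occurring more than 10 times in either sequence are
dropped (`max_occurrences_per_kmer`), bounding the quadratic blow-up
inside satellite arrays.  Chaining groups same-orientation points by
diagonal offset (y−x forward, y+x reverse), splitting where the offset
jumps by ≥ k or the x-gap exceeds 2 kb; the offset-jump threshold of k−1
makes every indel of at least k bases start a new segment, which is what
allows exact sizing: the variant size is |x-gap − y-gap| at the
breakpoint, a deletion in B when the x-gap is larger, an insertion when
the y-gap is.  Overlapping segments are reported as type "offset" with
both gaps, leaving interpretation (duplication, translocation...) to the
analyst.  Rendering is a thin optional matplotlib layer over the point
arrays.

## Optical-map scaffolding

Contig-to-map alignment is an input (aligned label-index pairs with a
confidence), not reimplemented; fixtures generate perfect placements from
known offsets.  Contigs are ordered by the map coordinate of their first
aligned label.  Adjacent contigs sharing ≥ 2 aligned map labels merge at
the first shared label (prev contributes up to its copy of the label,
next continues from its own copy).  Otherwise the gap is

    (map distance between facing aligned labels)
    − prev's tail overhang − next's head overhang

floored at 1 bp; a negative computed gap without overlap evidence is a
conflict and is floored with a warning.  An optional sequence check
(edit-distance suffix-prefix alignment, ≥ 1 kb at ≥ 95% identity) can
establish overlap where labels are absent.  A contig whose aligned map
interval lies inside another's is incorporated (contributes no sequence)
only if the host also aligns every map label the candidate aligns and is
itself at least as well aligned (more labels over the interval, then
higher confidence) — a candidate that aligns labels its host missed is
evidence of real extra sequence and is kept.  Label positions are motif
*start* coordinates; reverse-orientation arithmetic accounts for the
motif length so digest-placement round trips are exact.

## Region metrics

Coordinates are 0-based half-open internally and 1-based inclusive for
display; the two conventions differ by 1 bp in length, which never moves
a printed 2-decimal Mb value, and rounding is half-up to match printed
tables.  The repeat fraction of a sequence is the proportion of its valid
31-mer windows whose canonical k-mer occurs ≥ 2 times *within that
sequence* (region-local, strand-folded — the stated reading of the
corresponding published table).  Segmental-duplication overlap uses union
semantics with an optional identity floor.  Within-region NG50 ranks
contigs by the union length of their within-region aligned intervals and
returns the length at which the running sum first covers half the region,
0 (with a coverage fraction) when it never does.

## The synthetic-data generator

`simdata` emulates the structures that make immune loci hard: a uniform
random backbone (optional GC control; no higher-order composition model)
carrying non-overlapping planted features — heterozygous deletions
(haplotype B lacks the interval), duplications with per-haplotype tandem
copy numbers (2/2 collapsed-duplication, 1/3 compound-CNV), homozygous
tandem arrays (unit, copies, per-copy substitution divergence, optional
protected signature motif once per unit), and label-motif lattices for
digestion.  Three renderings share one backbone: haplotypes A and B, and
a "consensus" with every duplication at one copy — the natural stand-in
for a collapsed consensus assembly.  The truth set records every
feature's interval in each rendering and its expected N over the
consensus: (copies_A + copies_B)/2.

Reads are fixed-length with uniform starts, random strand, i.i.d.
substitution errors (no indel errors by default — sufficient for
exercising counting, anchoring and dot plots) and constant or two-tier
qualities.  Linear sampling under-covers the terminal read-length of each
sequence exactly as real shotgun data does at contig ends; a `circular`
option removes that artifact for fixtures that must isolate another
signal (the error-rate tests use it, since terminal coverage loss would
otherwise add two spurious clusters).  All randomness flows from one
seed; identical specs render byte-identical genomes.

What passing these simulations does *not* show: robustness to
platform-specific error profiles (homopolymer indels, chimeras), GC
coverage bias, mapping artifacts in candidate alignments, or
heterozygosity beyond the planted features.  Real data adds all of these.

## Problem sizes

The bundled tests run the full pipelines at the scales the statistics
need rather than the scales real projects use: signature recovery on 2 Mb
diploids at 60× per haplotype (the depth at which the ±0.25 N bands are
clean; at 30× about 10% of windows leave the band by sampling alone),
error-rate recovery on 1 Mb at 40×, recovery-property tests on 300 kb,
and oracle comparisons on ≤ 50 kb inputs where brute-force enumeration is
instant.  `scripts/acceptance.py` re-runs the two signature pipelines at
the 2 Mb / 60× scale from a single seed.

## Known limitations

- D detection assumes the homozygous peak dominates or nearly dominates
  the histogram; heavily repetitive genomes need an explicit D.
- Interpretation bands are heuristics over the median N; they do not
  genotype events or assign them to haplotypes.
- The haplotig rule is sequence-composition based; a contig that is a
  genuine segmental duplicate (not an alternate haplotype) with > 80%
  shared k-mers would also be removed.
- Scaffold gap estimates inherit optical-map label sparsity: a gap
  containing labels loses them to the emitted N run.
- Dot-plot chaining reports segments and offsets; it does not name
  complex events (inverted duplications, translocations).
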