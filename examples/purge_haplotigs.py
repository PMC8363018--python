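"""Remove duplicate contigs that represent the alternate haplotype.

Builds a small contig set in which one contig is an exact subsequence of
a longer one (a haplotig) and another shares only 70% of its 22-mers
(kept).  A shorter contig is purged when more than 80% of its distinct
canonical 22-mers also occur in a longer contig.
"""

import numpy as np

from asmqc import detect_haplotigs
from asmqc._encode import random_sequence

rng = np.random.default_rng(301)
backbone = random_sequence(120_000, rng)
contigs = {
    "scaffold_1": backbone,
    "haplotig": backbone[40_000:75_000],          # exact duplicate: removed
    "divergent": backbone[:21_000] + random_sequence(9_000, rng),  # 70%: kept
    "unrelated": random_sequence(30_000, rng),
}

report = detect_haplotigs(contigs, k=22, threshold=0.80)
print(f"{'shorter':<12}{'longer':<12}{'shared':>8}  decision")
for shorter, longer, frac in report.pairs:
    decision = "removed" if shorter in report.removed else "retained"
    print(f"{shorter:<12}{longer:<12}{frac:>8.3f}  {decision}")
print("retained contigs:", report.retained)
# 'haplotig' shares 100% of its 22-mers with scaffold_1 and is removed;
# 'divergent' (0.70 <= 0.80) and 'unrelated' (~0) survive.
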