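"""Decoy-counting FDR estimation and threshold selection.

Simulates 10,000 identifications (10% false, with one matched decoy per
false target), picks the score threshold for a 0.0001 PSM-level FDR and
prints a Mayu-style summary block.
"""

from proteorf.fdr import estimate_fdr, estimate_fdr_from_counts, format_summary_block, threshold_for_fdr
from proteorf.synthetic import simulate_scored_ids

ids, _ = simulate_scored_ids(10_000, pi0=0.1, seed=3)
threshold = threshold_for_fdr(ids, target_fdr=0.0001)
summary = estimate_fdr(ids, threshold)
print(f"threshold for FDR <= 1e-4 : score >= {threshold:.2f}")
print(format_summary_block([summary]))

# The same arithmetic applied to a published atlas summary: 1,339,586
# target PSMs and 110 decoy PSMs above threshold.
print(format_summary_block([estimate_fdr_from_counts(1_339_586, 110)]))
# FDR 8.21e-05: about 110 of the 1.34M accepted PSMs are expected false.
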