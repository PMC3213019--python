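"""Vote a consensus spectrum out of noisy replicate spectra.

Five replicates share four true fragment peaks; each also carries
private noise peaks. The vote (peak kept if seen in >= 60% of
replicates) retains the reproducible peaks and drops the noise.
"""

import numpy as np

from proteorf.consensus_library import Spectrum, build_consensus, write_msp

rng = np.random.default_rng(5)
true_mzs = [175.12, 402.23, 530.28, 659.33]
replicates = []
for i in range(5):
    peaks = [(mz + rng.normal(0, 0.01), rng.uniform(40, 100)) for mz in true_mzs]
    peaks += [(rng.uniform(200, 900), rng.uniform(5, 15)) for _ in range(3)]  # noise
    replicates.append(Spectrum(f"rep{i}", "LNSPPTPTTSTPTFR", 2, tuple(sorted(peaks))))

consensus = build_consensus(replicates, mz_tol=0.05, vote_frac=0.6)
print(f"replicates pooled : {consensus.n_replicates}")
print(f"consensus peaks   : {len(consensus.peaks)} (from {sum(len(r.peaks) for r in replicates)} raw)")
for p in consensus.peaks:
    print(f"  m/z {p.mz:8.3f}  intensity {p.intensity:6.1f}  support {p.support:.2f}")
write_msp([consensus], "consensus_demo.msp")
print("wrote consensus_demo.msp")
# Only the four reproducible fragment peaks survive, each at support 1.0.
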