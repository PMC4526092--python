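"""Cross-validate sequencing fold changes with ddCt RT-qPCR.

Triplicate Ct values are averaged and normalized to U6 within each fluid
(dCt); the serum-minus-plasma difference (ddCt) gives fold change
2^(-ddCt).  Agreement with sequencing is the Pearson correlation of log2
fold changes.
"""

import math

import numpy as np

from circmir.qpcr import analyze_ct_table, correlate_platforms
from circmir.sim import SimConfig, simulate_qpcr

config = SimConfig(seed=1)
true_fc = {f"mir-{i:02d}": float(fc)
           for i, fc in enumerate(np.geomspace(0.25, 4.0, 12))}

ct = simulate_qpcr(true_fc, config, noise_sd=0.1)
results = analyze_ct_table(ct, efficiency=2.0)
print(f"{len(results)} miRNAs quantified from {len(ct)} Ct rows")
for r in results[:3]:
    print(f"  {r.mirna}: ddCt={r.ddct:+.2f} fold change={r.fold_change:.2f} "
          f"(truth {true_fc[r.mirna]:.2f})")

seq_log2fc = {m: math.log2(fc) for m, fc in true_fc.items()}
qpcr_log2fc = {r.mirna: r.log2_fold_change for r in results}
corr = correlate_platforms(seq_log2fc, qpcr_log2fc)
print(f"Pearson r between platforms: {corr.r:.3f} over {corr.n} miRNAs")
# At replicate noise 0.1 cycles the two platforms agree tightly (r > 0.95);
# with noise 0 the round trip is exact and r = 1.
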