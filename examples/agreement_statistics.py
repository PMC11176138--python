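"""Agreement statistics on a toy set of paired tumor measurements.

Fifteen subjects measured twice with a small bias and noise: Lin's CCC
(precision and accuracy), Bland-Altman mean difference with 95% limits of
agreement, and the test-retest CoV with its qualitative band.
"""

import numpy as np

from relaxrepro import bland_altman, ccc, classify_cov, cov_pairs

rng = np.random.default_rng(42)
truth = rng.normal(26.75, 5.56, 15)          # between-subject spread (ms)
acq1 = truth + rng.normal(0.0, 0.8, 15)      # first measurement
acq2 = truth + 0.3 + rng.normal(0.0, 0.8, 15)  # second, with +0.3 ms bias

c, (lo, hi) = ccc(acq1, acq2)
ba = bland_altman(acq1, acq2)
cov = cov_pairs(x=acq1, y=acq2)

print(f"CCC: {c:.3f} (95% CI {lo:.3f}-{hi:.3f})   1 = perfect agreement")
print(f"Bland-Altman: mean diff {ba.mean_diff:+.2f} ms, "
      f"95% LOA [{ba.loa95[0]:+.2f}, {ba.loa95[1]:+.2f}] ms")
print(f"CoV: {cov:.2f}%  ->  {classify_cov(cov)} "
      "(<=5% excellent, <=10% good, <=20% moderate, >20% poor)")
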