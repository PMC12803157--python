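"""Manders overlap on synthetic two-channel punctate images.

Generates image pairs whose spot centres overlap by a known fraction,
thresholds each channel with Otsu's criterion, and compares the
recovered M1 coefficient with the planted ground truth; a Welch test
then compares two groups of per-image coefficients.
"""

import numpy as np

from denngap import make_two_channel, manders_otsu, welch_t

print(f"{'planted φ':>10} {'mean M1 (5 seeds)':>18}")
groups = {}
for phi in (0.2, 0.8):
    m1s = []
    for seed in range(5):
        ch1, ch2, _ = make_two_channel(overlap_fraction=phi, noise_sd=1.0, seed=seed)
        m1s.append(manders_otsu(ch1, ch2).m1)
    groups[phi] = m1s
    print(f"{phi:>10.1f} {np.mean(m1s):>18.3f}")

res = welch_t(groups[0.8], groups[0.2])
print(f"\nWelch's t-test, high- vs low-overlap group: t={res.t:.2f}, "
      f"df={res.df:.1f}, p={res.p:.2e}")
print(
    "\nM1 tracks the planted overlap fraction, and the group comparison"
    "\nseparates conditions that differ in colocalization."
)
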