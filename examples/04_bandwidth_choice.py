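"""Choosing the smoothing window from the expected peak shape.

The expected G' profile around a QTL decays with map distance as
recombination decouples markers from the causal allele.  Its full width
at half maximum (FWHM) is the matched-filter reference for the kernel
window: a smoothing ratio (window / FWHM) of 1-1.5 maximises
signal-to-noise for an isolated peak, while ~0.7 preserves the ability
to separate adjacent peaks.
"""

import numpy as np

import bsascan as b

grid = np.linspace(0.0, 40.0, 9)
profile, hwhm = b.expected_gprime_profile(freq_L=0.5, freq_H=1.0, coverage=50,
                                          effective_alleles=300,
                                          distance_grid_cm=grid)
print("offset (cM) :", "  ".join(f"{x:5.1f}" for x in grid))
print("expected G' :", "  ".join(f"{v:5.1f}" for v in profile))
print(f"half-width at half maximum = {hwhm:.2f} cM -> FWHM = {2 * hwhm:.2f} cM")

for target in ("single_peak", "resolve_adjacent_peaks"):
    spec = b.recommend_bandwidth(target, cm_per_kb=0.3)
    print(f"{target:>22}: half-bandwidth {spec.half_width / 1000:.1f} kb "
          f"(window {2 * spec.half_width / 1000:.0f} kb at 0.3 cM/kb)")
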