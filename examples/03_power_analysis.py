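"""Power to detect a weak QTL as a function of sequencing coverage.

The QTL explains 2% of phenotypic variance.  Raw G scored against the
naive chi-square(1) cutoff has poor power; the smoothed G' scored
against its log-normal null detects the same QTL most of the time.
Power rises with coverage up to roughly the number of alleles per bulk
and plateaus beyond.
"""

import numpy as np

import bsascan as b

delta = b.qtl_effect_for_variance(0.02)
spec = b.KernelSpec(half_width=5.0, unit="cm")
grid = [b.SimDesign(C=c, qtl_effect_delta=delta) for c in (10, 25, 50, 100, 300)]

table = b.run_power(grid, spec, reps=800, rng=np.random.default_rng(3),
                    levels=(0.05, 0.01))
cols = ["C", "mean_gprime_causal", "power_naive_0.05", "power_gprime_0.05"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\nbulks hold", grid[0].effective_alleles, "alleles; coverage beyond that "
      "buys little extra power")
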