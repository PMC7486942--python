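"""Estimate nuclear import/export rates from compartment-bleach recoveries.

Simulates two-pool exchange after bleaching either compartment and applies
the slope estimator: nuclear signal change over the first 30 s (frames 1-4
at 10-s framing), normalized by the source compartment's postbleach
intensity.  The import/export *ratio* is recovered exactly because both
experiments share the same relaxation rate.
"""

import numpy as np

from locreset import frap
from locreset.synthetic import simulate_compartment_bleach

k_export = 0.002  # 1/s
for name, ratio in (("MCF10A-like", 3.9), ("transformed-like", 1.6)):
    k_import = ratio * k_export
    t = np.arange(0.0, 120.0, 10.0)
    imp, n0i, c0i = simulate_compartment_bleach(k_import, k_export,
                                                "nucleus", t)
    exp, n0e, c0e = simulate_compartment_bleach(k_import, k_export,
                                                "cytoplasm", t)
    r_imp = frap.estimate_rate(imp, "import", n0i, c0i).rate
    r_exp = frap.estimate_rate(exp, "export", n0e, c0e).rate
    print(f"{name}: k_imp={r_imp:.5f}/s k_exp={r_exp:.5f}/s "
          f"ratio={r_imp / r_exp:.3f} (programmed {ratio})")
# The individual rates are slightly underestimated by the 30-s linear fit,
# but the bias cancels in the ratio, which matches the programmed value.
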