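"""Show that the naive interval undercovers at ANY sample size.

Plugging estimated precisions into the pooled estimate inflates its true
variance by a factor 1 + 2*phi*zeta2 (balanced two-arm case) that does not
shrink as studies grow.  This script computes the analytic asymptotic
coverage of the nominal-95% naive interval at inflation factor 1.5 and
verifies it by simulation at n = 100 subjects per study.
"""

import numpy as np

from femeta import coverage_experiment, make_scenario, naive_asymptotic_coverage

factor = 1.5  # k=5, n=100, within-variance 1, zeta2=1 -> 1 + 2*0.25*1
coverage, type1 = naive_asymptotic_coverage(factor, level=0.95)
print(f"analytic asymptotic coverage of the naive 95% interval at "
      f"inflation factor {factor}: {coverage:.4f} (type-I error {type1:.4f})")

scenario = make_scenario(k=5, n=100, zeta2_true=1.0, sigma2_within=1.0)
table = coverage_experiment(scenario, ["naive", "lssa"], reps=2000, seed=8)
print(table.to_string(index=False))
print("\nThe empirical naive coverage sits near the analytic value, about "
      "6 points below nominal,\nwhile the inflation-corrected LSSA interval "
      "restores close-to-nominal coverage.")
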