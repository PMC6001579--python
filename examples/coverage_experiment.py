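"""Compare interval methods for beta_F and zeta2 in one coverage experiment.

Simulates k=5 balanced two-arm studies (n=100, within-variance 1) with true
effects spread to zeta2 = 1, and reports the empirical coverage and mean
width of each interval construction over 1000 replicates (bootstrap B=500).
"""

from femeta import coverage_experiment, make_scenario

scenario = make_scenario(k=5, n=100, zeta2_true=1.0, beta_F_true=0.0,
                         sigma2_within=1.0)
methods = ["naive", "lssa", "quasi_f", "boot_normal", "boot_percentile",
           "boot_t_naive", "boot_t_lssa", "dersimonian_laird",
           "noncentral_chi2", "zeta2_boot_percentile"]
table = coverage_experiment(scenario, methods, reps=1000, B=500, seed=5)
print(table.to_string(index=False))
print("\nCoverage is the fraction of replicates whose interval contains the "
      "generating truth\n(beta_F = 0 for location methods, zeta2 = 1 for the "
      "heterogeneity methods); mc_se is\nthe binomial Monte-Carlo standard "
      "error.  The naive interval undercovers; the corrected\nlocation "
      "intervals and the noncentral chi-square zeta2 interval sit near 0.95.")
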