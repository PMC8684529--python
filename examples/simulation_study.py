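"""A reduced Monte Carlo comparison of all estimator columns.

Runs 2,000 replicates at (beta, n) in {1, 2} x {25, 100} with the default
design (sigma=3, prior (0.6, 0.5), v=1, omega=0.5, c in {0.5, 1.5}) and
prints the mean-averaged-squared-error table for the E-Bayes columns.
Smaller MASE is better; every column shrinks roughly like 1/n, and the
LINEX/weighted-composite columns sit below the squared-error ones.
"""

import lomaxbayes as lb

cfg = lb.StudyConfig(n_values=(25, 100), beta_values=(1.0, 2.0), reps=2000, seed=7)
table = lb.run_study(cfg)

print("MASE, E-Bayes columns (2,000 replicates):")
print(table.wide("MASE", "ebayes").round(4).to_string())
print("\nMASE, MLE + Bayes columns:")
print(table.wide("MASE", "bayes").round(4).to_string())
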