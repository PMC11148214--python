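"""Truth-recovery study: replicate the MR analysis over many synthetic
datasets and tabulate bias, RMSE, coverage and power against the known
causal effect.
"""

import pandas as pd

from gdmliver import GwasSimConfig, simulate_gwas_pair, truth_report
from gdmliver.mr import harmonize, ivw, mr_egger, weighted_median

THETA = 0.25
rows = []
for rep in range(60):
    exp, out, _, truth = simulate_gwas_pair(
        GwasSimConfig(m_snps=100, seed=1000 + rep, theta=THETA))
    h = harmonize(exp, out)
    for name, est in [("ivw", ivw(h)), ("mr_egger", mr_egger(h)[0]),
                      ("weighted_median", weighted_median(h, n_boot=200, seed=rep))]:
        rows.append(dict(method=name, beta=est.beta, se=est.se,
                         ci_low=est.ci_low, ci_high=est.ci_high, p=est.p))

report = truth_report(THETA, pd.DataFrame(rows))
print(f"true causal log-OR: {THETA}\n")
print(report.to_string(index=False))
print("\nbias near 0 and coverage near 0.95 mean the estimator and its CI")
print("are behaving as designed under valid instruments; power is the rate")
print("at which the (real) effect is declared significant.")
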