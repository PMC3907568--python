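"""Replicated simulation study: estimator bias and prediction accuracy.

Runs a small heritability grid (truth 0 and 0.3 for each component, 3
replicates per cell at q=200) and prints per-cell bias/MSE of the GREML
heritability estimates and the gain of genotypic-value over
breeding-value prediction.
"""

import gdblup as g
from gdblup.simulate import summarize_study

configs = [
    g.SimConfig(n_individuals=200, m_qtl=400, h2_a=a, h2_d=d, n_reps=3)
    for a in (0.0, 0.3)
    for d in (0.0, 0.3)
]
df = g.run_study(configs, master_seed=4, max_iter=150, tol=1e-6)
summary = summarize_study(df)

cols = ["h2_a_true", "h2_d_true", "h2_a_mean", "h2_a_bias", "h2_a_mse",
        "h2_d_mean", "h2_d_bias", "h2_d_mse"]
print(summary[cols].round(4).to_string(index=False))
print()
acc = summary[["h2_a_true", "h2_d_true", "r_g_ahat_mean", "r_g_ghat_mean"]].dropna()
print(acc.round(3).to_string(index=False))
print()
print("reading the tables: with only q=200 and 3 replicates the per-cell")
print("means are noisy (single-replicate SD of a heritability estimate is")
print("roughly 0.1 here), so biases of that size are sampling noise; at")
print("q=500 with 10 replicates, as in the test suite, they shrink toward 0.")
print("in cells with dominance (h2_d=0.3) the genotypic-value accuracy")
print("r(g, g_hat) exceeds the breeding-value accuracy r(g, a_hat); the two")
print("coincide when h2_d=0.")
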