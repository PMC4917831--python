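"""The diagnostic statistics layer on its own, without images.

Runs the 2x2 association test on the emulated pattern-by-perfusion
table, an ROC analysis on scores drawn from the two perfusion groups'
parallelism distributions, the likelihood-ratio arithmetic, and the
two-mean sample-size planning calculation.
"""

import numpy as np

from parafundus import (
    ContingencyTable2x2,
    chi2_association,
    fisher_exact_association,
    likelihood_ratios,
    roc_analysis,
    sample_size_two_means,
)

tab = ContingencyTable2x2(39, 0, 6, 13)  # pattern rows x perfusion columns
chi2, p = chi2_association(tab)
_, fisher_p = fisher_exact_association(tab)
print(f"pattern x perfusion: chi2={chi2:.2f}, p={p:.2e} (Fisher p={fisher_p:.2e})")

rng = np.random.default_rng(0)
nonischemic = rng.normal(0.362, 0.115, 45)  # parallelism, nonischemic maculas
ischemic = rng.normal(0.222, 0.126, 13)
scores = np.concatenate([nonischemic, ischemic])
labels = np.array([0] * 45 + [1] * 13)
res = roc_analysis(scores, labels, positive_means_low_score=True)
print(
    f"ROC: AUROC={res.auroc:.3f} (95% CI {res.ci95[0]:.3f}-{res.ci95[1]:.3f}), "
    f"cutoff={res.cutoff:.3f}, sens={res.sensitivity_pct:.1f}%, "
    f"spec={res.specificity_pct:.1f}%"
)
print("  low scores flag the ischemic macula (the positive class)")

lr_pos, lr_neg = likelihood_ratios(94.59, 100.0)
print(f"likelihood ratios at sens 94.59%/spec 100%: +LR undefined, -LR={lr_neg:.2f}")

n_isch, n_nonisch, total = sample_size_two_means(
    0.33, 0.13, 0.20, 0.11, alpha=0.05, beta=0.20, allocation_ratio=0.75
)
print(
    f"sample size for pilot means 0.33+/-0.13 vs 0.20+/-0.11: "
    f"{n_nonisch} + {n_isch} = {total} eyes"
)
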