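"""Triage target pseudolabels into accept / defer / reject regions.

Builds each target sample's triangular fuzzy number from its
information-difference structure, computes pairwise fuzzy similarities,
evaluates the pseudolabel-agreement probability over delta-level
neighbourhoods, and applies the (alpha, beta) decision rule — shown here
both with directly supplied thresholds and thresholds derived from a
misclassification cost matrix.
"""

import numpy as np

from siteadapt import (
    CostMatrix,
    DomainPair,
    ShiftConfig,
    gen_domain_shift,
    project,
    solve_projection,
    thresholds_from_costs,
    triage,
)

alpha, beta = thresholds_from_costs(CostMatrix(lPP=0, lBP=2, lNP=6, lNN=0, lBN=2, lPN=8))
print(f"cost matrix (0,2,6 | 0,2,8) -> alpha = {alpha:.3f}, beta = {beta:.3f}")
print("  accept a pseudolabel when its membership probability >= alpha,")
print("  reject when <= beta, defer to a secondary decision in between")

src, tgt, truth = gen_domain_shift(ShiftConfig(seed=0))
pair = DomainPair(Xs=src.X.T, ys=src.labels, Xt=tgt.X.T)
model = solve_projection(pair, k=3, lambda_reg=1.0)
Zt = project(pair.Xt, model)

from sklearn.svm import SVC

clf = SVC(kernel="linear", C=1.0).fit(project(pair.Xs, model).T, pair.ys)
pseudo = clf.predict(Zt.T).astype(int)

partition, probs = triage(Zt, pseudo, delta=0.3, alpha=alpha, beta=beta)
n_pos, n_bnd, n_neg = partition.sizes()
print(f"\ntarget cohort of {partition.n}: {n_pos} accepted, {n_bnd} deferred, {n_neg} rejected")
print(f"membership probabilities span [{probs.min():.2f}, {probs.max():.2f}]")
print("  deferred/rejected samples are handed to graph label propagation")
print(f"pseudolabel accuracy before any refinement: {np.mean(pseudo == truth):.3f}")
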