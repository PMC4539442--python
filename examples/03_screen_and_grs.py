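"""F-ratio screening and a genetic risk score on a train/test split.

Markers are ranked by the between- to within-group sum-of-squares ratio of
their dosages on the training half only; the GRS sums the dosages of the
marginally significant markers (oriented by the sign of the case-control
mean difference) and is calibrated by logistic regression.  The held-out
AUC shows how much signal the marginal score captures.
"""

import numpy as np

from penrisk import SimulationSpec, auc, screen_top, simulate_study
from penrisk.screening import grs_model

study = simulate_study(
    SimulationSpec(
        n_individuals=1200, n_snps=400, n_causal=25, h2=0.5, prevalence=0.35, seed=11
    )
)
X, y = study.genotypes.dosages, study.phenotypes.y
train, test = np.arange(800), np.arange(800, 1200)

top = screen_top(X[train], y[train], p1=50)
n_causal_found = len(set(top) & set(study.causal_indices))
print(f"top 50 screened SNPs contain {n_causal_found} of the 25 causal SNPs")

model = grs_model(X[train][:, top], y[train], alpha=0.05)
print(f"{len(model.selected)} SNPs significant at alpha=0.05 enter the score")

probs = model.predict_prob(X[test][:, top])
print(f"held-out AUC of the GRS model: {auc(probs, y[test]):.3f}")
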