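"""Latent-trait scores, their precision, reliability, loadings, and ECV.

Fits the HADS-like bifactor model, scores persons (EAP, since the
bifactor reduces to 2 integral dimensions), and summarizes measurement
quality: empirical reliability per factor, standardized loadings, and the
explained common variance of the general emotional-distress factor.
"""

import numpy as np

import irtqol as q

spec = q.preset("hads", n_persons=1500, seed=4)
data = q.simulate(spec)
model = q.fit_em(data, spec.structure, seed=1)

scores = q.irt_scores(data, model)  # EAP for <= 2 integral dimensions
print(f"scored {scores.n_persons} persons by {scores.method}")
print(f"general-factor scores: mean {scores.estimates[:, 0].mean():+.2f}, "
      f"SD {scores.estimates[:, 0].std():.2f} logits; "
      f"median SE {np.median(scores.ses[:, 0]):.2f}")

for f, name in enumerate(model.structure.factor_names):
    rel = q.empirical_reliability(scores, f)
    verdict = "acceptable" if rel >= 0.70 else "below 0.70"
    print(f"empirical reliability [{name}]: {rel:.2f} ({verdict})")

lam = q.standardized_loadings(model)
print(f"\nmean |standardized loading| on the general factor: "
      f"{np.abs(lam[:, 0]).mean():.2f}")
print(f"ECV of the general factor: {q.ecv(model)[0]:.3f}")
# ECV >= 0.85 would suggest a unidimensional model suffices; the preset is
# built with clearly dominant general loadings but non-trivial specifics,
# so ECV lands below that bar while the general factor stays reliable.
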