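"""Eye- and hair-colour prediction with the shipped synthetic models.

The package ships multinomial models *fitted on a planted-parameter
synthetic cohort* -- they demonstrate the machinery, not real predictive
coefficients.  A casework deployment would load published coefficients
through the same file format.
"""

import numpy as np

from forensnp.panel import GenotypeMatrix, MarkerPanel
from forensnp.phenotype import (
    default_eye_model,
    default_hair_model,
    predict_eye,
    predict_hair,
)

eye_model = default_eye_model()
hair_model = default_hair_model()

rng = np.random.default_rng(4)
snps = list(eye_model.snp_ids) + [
    s for s in hair_model.snp_ids if s not in eye_model.snp_ids
]
panel = MarkerPanel.from_arrays(snps, ["autosomal"] * len(snps))
g = GenotypeMatrix(
    sample_ids=["case3"],
    panel=panel,
    dosage=rng.binomial(2, 0.35, size=(1, len(snps))).astype(float),
)

eye = predict_eye(g, "case3", eye_model)
print("eye probabilities:",
      {c: round(p, 3) for c, p in eye.probabilities.items()})
print(f"eye call: {eye.call!r}  (called only when max p > 0.7)")

hair = predict_hair(g, "case3", hair_model)
print("hair probabilities:",
      {c: round(p, 3) for c, p in hair.probabilities.items()})
print(f"hair call: {hair.call!r}  (prediction-guide argmax)")

# knock out one predictor SNP: no call without the full complement
g.dosage[0, 0] = np.nan
incomplete = predict_eye(g, "case3", eye_model)
print(f"with one SNP missing: complete={incomplete.complete}, "
      f"call={incomplete.call}")
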