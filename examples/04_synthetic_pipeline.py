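"""End-to-end synthetic pipeline: grammar-sampled panel → graphs →
descriptors → model-generated activities → OLS refit.

With the residual noise set to the calibrated value, refits on synthetic
panels of 23 compounds scatter around the quality of fit observed on the
real panel; with sigma = 0 the generating coefficients come back exactly.
"""

import numpy as np

import triazopep as tp

spec = tp.SyntheticPanelSpec(n_compounds=23, seed=123)
panel = tp.gen_compound_panel(spec)
print(panel.head(6).to_string(index=False))

compounds = [(row.id, tp.parse_sequence(row.sequence))
             for row in panel.itertuples()]
desc = tp.build_descriptor_matrix(compounds)
X = desc[["dis_N-C,norm", "am_2N", "2Trl_C-N"]]

exact = tp.gen_activity_from_model(desc, sigma=0.0)
fit0 = tp.ols_fit(X, exact["inh"].to_numpy())
print(f"\nsigma=0 refit: coefficients {np.round(fit0.params, 6)} "
      f"(generating: {tp.MODEL_COEFFICIENTS}), R2 = {fit0.r_squared:.3f}")

r2s = []
for seed in range(100):
    act = tp.gen_activity_from_model(desc, seed=seed)
    r2s.append(tp.ols_fit(X, act["inh"].to_numpy()).r_squared)
print(f"calibrated-noise refits over 100 seeds: mean R2 = "
      f"{np.mean(r2s):.2f} (sd {np.std(r2s):.2f})")
print("Interpretation: the calibrated residual sigma reproduces the "
      "signal-to-noise regime of the real 23-compound panel.")
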