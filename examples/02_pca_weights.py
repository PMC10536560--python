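"""Derive indicator weights from standardized relative densities by PCA.

Computes per-stratum reference values, indicator relative densities (IRD),
z-scores them, and runs the PCA weighting: correlation matrix ->
eigendecomposition -> contribution rates -> importances -> weights.
"""

import numpy as np

from eqiscope import (ScenarioConfig, compute_ird, compute_reference,
                      generate_scenario, pca_weights, standardize)

scenario = generate_scenario(ScenarioConfig(seed=7))
sm = scenario.strata(2016)

z_fields = {}
for ind in ("lai", "fvc", "gpp"):
    grid = scenario.annual[ind][2016]
    refs = compute_reference(grid, sm)          # stratum maxima (Fmax)
    ird = compute_ird(grid, sm, refs)           # F / Fmax in [0, 1]
    z, params = standardize(ird)                # mean 0, sd 1
    z_fields[ind] = z
    print(f"{ind}: mean IRD {ird.valid_values().mean():.3f}, "
          f"z-params mean={params.mean:.4f} sd={params.std:.4f}")

valid = np.logical_and.reduce([z.valid_mask() for z in z_fields.values()])
X = np.stack([z.values[valid] for z in z_fields.values()], axis=1)
ws, pca = pca_weights(X, rho=0.85, names=("lai", "fvc", "gpp"))
print(f"\neigenvalues: {np.round(pca.eigenvalues, 4)}")
print(f"contribution rates: {np.round(pca.contribution_rates, 4)}, "
      f"retained components p = {pca.n_retained}")
print(f"weights: {ws.as_dict()}")
print("\nWith symmetric inter-indicator correlation the weights are near 1/3")
print("each; on real data they tilt toward the indicator with most shared variance.")
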