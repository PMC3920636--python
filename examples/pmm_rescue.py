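"""Predictive mean matching as the fix for raw-scale passive imputation.

On a high-CV-denominator dataset, plain M5 can impute denominators near
zero, producing ratios far outside anything observed. PMM donates observed
component values instead, so every imputed ratio is bounded by
(min a1)/(max a2) and (max a1)/(min a2). The script prints the imputed-ratio
ranges under both approaches.
"""

import numpy as np

from ratiomi import EngineSettings, PMMSettings, impute_pmm_passive, impute_with_strategy
from ratiomi import simulation as sim

cfg = sim.make_config(0.1, "MCAR", cv_a2=0.3, n=2000, seed=3)
g = np.random.default_rng(3)
a1, a2, x = sim.gen_components(cfg, g)
_, var_x = sim.ratio_moments(cfg)
y = sim.gen_outcome(x, cfg.beta1, cfg.r_squared, g, var_x)
r1, r2 = sim.gen_missingness(y, sim.mcar_params(), g)
ds = sim.build_incomplete(a1, a2, x, y, r1, r2)

obs_a1 = ds.data.loc[ds.mask["a1"], "a1"]
obs_a2 = ds.data.loc[ds.mask["a2"], "a2"]
lo, hi = obs_a1.min() / obs_a2.max(), obs_a1.max() / obs_a2.min()
mis = ~ds.mask["x"].to_numpy()
obs_x = ds.data.loc[ds.mask["x"], "x"]
print(f"observed ratio range          [{obs_x.min():6.2f}, {obs_x.max():6.2f}]")
print(f"attainable PMM ratio bounds   [{lo:6.2f}, {hi:6.2f}]")

m5 = impute_with_strategy(ds, "M5", EngineSettings(m=5, seed=11))
m5_vals = np.concatenate([d["x"].to_numpy()[mis] for d in m5.datasets])
print(f"M5 imputed ratio range        [{m5_vals.min():6.2f}, {m5_vals.max():6.2f}]"
      f"   ({np.mean((m5_vals < lo) | (m5_vals > hi)):.1%} outside bounds)")

pmm = impute_pmm_passive(ds, PMMSettings(k_donors=10, cycles=10, m=5, seed=11))
pmm_vals = np.concatenate([d["x"].to_numpy()[mis] for d in pmm.datasets])
print(f"M5-PMM imputed ratio range    [{pmm_vals.min():6.2f}, {pmm_vals.max():6.2f}]"
      f"   ({np.mean((pmm_vals < lo) | (pmm_vals > hi)):.1%} outside bounds)")
print("\nExtreme M5 draws are high-leverage points that drag the fitted")
print("slope towards zero; PMM's donated values cannot leave the observed range.")
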