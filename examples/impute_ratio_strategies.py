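"""Compare the six imputation strategies for an incomplete ratio covariate.

Builds a synthetic cohort in which the analysis covariate x = a1/a2 has a
high-variability denominator (CV 0.3), knocks out 25% of each component,
multiply-imputes the ratio under every strategy and pools the slope of
y on x by Rubin's rules. The true slope is 2; watch the raw-scale passive
strategy M5 collapse towards zero while the others stay close.
"""

import numpy as np
import pandas as pd

from ratiomi import (
    ColumnRoles,
    EngineSettings,
    IncompleteDataset,
    compatibility_class,
    impute_with_strategy,
    pool_stack,
)

rng = np.random.default_rng(12)
n, beta1 = 2000, 2.0

# bivariate lognormal components; denominator CV = 0.3
ln_a1 = 4.0 + 0.21 * rng.standard_normal(n)
ln_a2 = 0.97 + 0.294 * (0.22 * (ln_a1 - 4.0) / 0.21
                        + np.sqrt(1 - 0.22**2) * rng.standard_normal(n))
a1, a2 = np.exp(ln_a1), np.exp(ln_a2)
x = a1 / a2
y = beta1 * x + beta1 * x.std() * np.sqrt(0.9 / 0.1) * rng.standard_normal(n)

# 25% of each component missing completely at random
r1, r2 = rng.random(n) > 0.25, rng.random(n) > 0.25
df = pd.DataFrame(
    {"a1": np.where(r1, a1, np.nan), "a2": np.where(r2, a2, np.nan), "y": y}
)
roles = ColumnRoles(numerator="a1", denominator="a2", ratio="x", outcome="y")
ds = IncompleteDataset.from_dataframe(df, roles)

print(f"n = {n}, missing ratio in {ds.data['x'].isna().mean():.0%} of rows, "
      f"true slope = {beta1}")
print(f"{'strategy':>8} {'class':>16} {'slope':>7} {'SE':>6} {'95% CI':>18} {'FMI':>5}")
for label in ("M1", "M2", "M3", "M4", "M5", "M6"):
    stack = impute_with_strategy(ds, label, EngineSettings(m=10, seed=7))
    row = pool_stack(stack).loc["x"]
    print(f"{label:>8} {compatibility_class(label):>16} "
          f"{row['estimate']:7.3f} {row['se']:6.3f} "
          f"[{row['ci_low']:7.3f}, {row['ci_high']:6.3f}] {row['fmi']:5.2f}")
print("\nA slope near 2 with an interval covering 2 is a faithful recovery;")
print("M5's attenuated slope is the raw-scale passive-imputation pathology.")
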