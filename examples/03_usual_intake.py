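"""Estimate a usual-intake distribution from repeated record days.

Day-level amounts carry large within-person noise; the Box-Cox mixed
amount model separates between- from within-person variation and a Monte
Carlo pass builds the population distribution of long-term (usual) intake.
"""

import numpy as np
import pandas as pd

from dietgap import fit_amount_model, summarize_and_attain, usual_intake_distribution
from dietgap.targets import ScaledTarget

rng = np.random.default_rng(7)
n_children, n_days = 400, 3
person = np.repeat(np.arange(n_children), n_days)
usual_true = 120.0 + 30.0 * rng.standard_normal(n_children)  # person-level truth
y = np.clip(usual_true.repeat(n_days) + 45.0 * rng.standard_normal(n_children * n_days), 0.5, None)

params = fit_amount_model(y, person, np.ones((len(y), 1)), ["intercept"])
print(f"fitted: lambda={params.lam:.2f}, sigma_u={params.sigma_u:.2f}, sigma_e={params.sigma_e:.2f}")

dist = usual_intake_distribution(
    params, pd.DataFrame({"intercept": np.ones(n_children)}), n_mc=40_000, seed=11
)
target = ScaledTarget("vegetables", 157.0, 105.0, 315.0, "minimum")
stats = summarize_and_attain(dist, target)
for k, v in stats.items():
    print(f"  {k:<12s} {v:8.1f}")

# Day-level spread (~sd 54) shrinks to the between-person spread (~30) in
# the usual-intake distribution; pct_meeting is the share of the
# population whose long-term intake reaches the 157 g minimum target —
# far fewer than the share of single days above it.
print(f"\nshare of single DAYS >= target: {100 * np.mean(y >= 157):.1f}%  (inflated by day-to-day noise)")
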