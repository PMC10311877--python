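"""Draw a pool of rerandomized allocations and inspect its calibration.

Builds a small synthetic observational study, samples complete-randomization
allocations, and keeps those whose Mahalanobis distance clears the
chi-squared threshold for acceptance probability p_a = 0.2.
"""

import numpy as np

from qrer import CovariateMatrix, RerandSpec, chi2_threshold, rerandomize_pool

rng = np.random.default_rng(7)
N1, N0, d = 60, 80, 5
X = np.vstack([rng.standard_normal((N1, d)) + 0.3,   # imbalanced treated arm
               rng.standard_normal((N0, d))])
T = np.array([1] * N1 + [0] * N0)
cov = CovariateMatrix.from_arrays(X, T)

spec = RerandSpec(p_a=0.2, B=500)
pool = rerandomize_pool(cov, spec, rng)
D = np.array([a.D for a in pool])

print(f"threshold a = {chi2_threshold(d, 0.2):.3f} "
      f"(p_a=0.2 quantile of chi-squared with {d} df)")
print(f"accepted {len(pool)} allocations; D in [{D.min():.3f}, {D.max():.3f}]")
print(f"mean accepted D = {D.mean():.3f}")
print("Every accepted allocation keeps the treated group size fixed and its")
print("arm covariate means closer than", f"{spec.threshold(d):.2f}",
      "Mahalanobis units -- the balance a rerandomized experiment enforces.")
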