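"""The three synthetic benchmark generators and what they stress.

TwoLinearXY has exploitable cross-variable structure (x and z are noisy
copies; y is |x| up to a hidden sign), UniformRandom3VarIndependent has
none, and Hepta is a 7-cluster layout for downstream-clustering studies.
The printed correlations make the difference concrete: on structured data
multivariate imputers have something to work with, on pure noise they
cannot beat a column median.
"""

import numpy as np

from imputerank import gen_hepta, gen_two_linear_xy, gen_uniform_independent

xy = gen_two_linear_xy(500, noise_sd=0.05, seed=1)
print("TwoLinearXY corr(x, z) =",
      f"{np.corrcoef(xy.values[:, 0], xy.values[:, 2])[0, 1]:.3f}",
      "| corr(x, y) =",
      f"{np.corrcoef(xy.values[:, 0], xy.values[:, 1])[0, 1]:.3f}")

uni = gen_uniform_independent(500, seed=1)
corr = np.corrcoef(uni.values.T)
print("UniformRandom3VarIndependent max |corr| =",
      f"{np.abs(corr[~np.eye(3, dtype=bool)]).max():.3f}")

hepta, labels = gen_hepta(700, seed=1)
sizes = np.bincount(labels)
print("Hepta cluster sizes:", sizes.tolist())
spread = [np.linalg.norm(hepta.values[labels == c].std(axis=0)) for c in range(7)]
print("Hepta per-cluster coordinate sd ~", f"{np.mean(spread):.2f}",
      "(centers 3 units apart: well separated)")
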