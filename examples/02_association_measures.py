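"""The six pairwise association measures on one small matrix.

Builds a 4-variable toy dataset with known structure (a linear driver, a
nonlinear monotone response, and an independent variable) and prints each
measure's score matrix entry for the informative and uninformative pairs.
"""

import numpy as np

from phosphonet import measures as M

rng = np.random.default_rng(0)
n = 40
x = rng.normal(size=n)
linear = 2 * x + 0.3 * rng.normal(size=n)
cubic = x**3 + 0.3 * rng.normal(size=n)  # nonlinear but monotone
noise = rng.normal(size=n)
X = np.vstack([x, linear, cubic, noise])
names = ["x", "linear", "cubic", "noise"]

print(f"{'measure':<10} {'x~linear':>9} {'x~cubic':>9} {'x~noise':>9}")
for m in M.MEASURES:
    am = M.score_matrix(X, m)
    print(f"{m:<10} {am.scores[0, 1]:9.3f} {am.scores[0, 2]:9.3f} {am.scores[0, 3]:9.3f}")

print("\nPearson favours the linear pair, the rank measures treat both",
      "monotone pairs alike, MI/FunChiSq work on discretized levels, and",
      "the GGM reports partial correlations given all other variables.",
      "Scores for the independent pair sit near zero throughout.")
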