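"""Show that the copula transform makes inference rank-based.

Applies a strongly nonlinear but monotone distortion (exp) to one variable
and reruns the pipeline: the inferred network is unchanged, because the
Gaussian-copula transform depends only on the ranks within each column.
With the transform disabled, the same distortion can change the answer.
"""

import numpy as np

from ecgc import TimeSeriesMatrix, infer_network, simulate_dataset1

X, _ = simulate_dataset1(T=200, seed=3)
distorted_values = X.values.copy()
distorted_values[:, 1] = np.exp(distorted_values[:, 1] / np.abs(distorted_values[:, 1]).max())
X_distorted = TimeSeriesMatrix(distorted_values, names=X.names)

with_copula = infer_network(X, L=2).adjacency
with_copula_distorted = infer_network(X_distorted, L=2).adjacency
plain = infer_network(X, L=2, use_copula=False).adjacency
plain_distorted = infer_network(X_distorted, L=2, use_copula=False).adjacency

print("adjacency (rows = source, cols = target), copula mode, raw data:")
print(with_copula.astype(int))
print("copula mode after exp-distorting x2 (identical by construction):")
print(with_copula_distorted.astype(int))
print("identical:", np.array_equal(with_copula, with_copula_distorted))
print()
print("plain (no copula) mode, raw vs distorted identical:",
      np.array_equal(plain, plain_distorted))
print("The copula-mode equality is guaranteed — the transform sees only "
      "ranks, which exp() preserves; plain mode has no such guarantee.")
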