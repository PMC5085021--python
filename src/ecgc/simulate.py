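"""Benchmark VAR systems with known ground-truth influence graphs.

Two fixed systems are provided:

* ``simulate_dataset1`` — a 3-variable VAR(2) widely used in gene-network
  benchmarking, with 3 true cross edges (3->1 at lag 1, 3->2 at lag 2,
  2->3 at lag 1) and self-dependence in every variable.
* ``simulate_dataset2`` — a 5-variable Schelter-style VAR(4) with 7 true
  cross edges; the deepest dependency (3->2) acts at lag 4, so benchmarks
  of this system need lag order L >= 4.

Innovations are i.i.d. standard normal, mutually independent across
variables and time.  Both fixed systems follow the generation protocol
exactly: the first max-lag values of each series are drawn from N(0, 1) and
the equations are then iterated forward, with no burn-in by default.  The
3-variable system as printed is in fact marginally explosive (companion
spectral radius ~1.002), so no stationary law exists for it and a burn-in
would systematically amplify the near-unit-root oscillation rather than
converge anywhere; a ``burn_in`` argument is still exposed for stationary
systems.  ``simulate_random_var`` draws generic sparse stable systems for
property tests and does use a burn-in (default 1000) since those systems are
stationary by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .copula import TimeSeriesMatrix

__all__ = [
    "GroundTruthGraph",
    "companion_matrix",
    "spectral_radius",
    "simulate_dataset1",
    "simulate_dataset2",
    "simulate_random_var",
]

DEFAULT_BURN_IN = 0
RANDOM_VAR_BURN_IN = 1000
_MIN_T = 15


@dataclass(frozen=True)
class GroundTruthGraph:
    """Generating graph of a simulated VAR system.

    ``adjacency[j, i]`` is True when x_j appears (at any lag) in the
    generating equation of x_i; the diagonal holds self-dependence, also
    mirrored in ``self_edges``.  ``lag_annotations`` maps (source, target)
    to the list of (lag, coefficient) terms that create the edge.
    """

    adjacency: np.ndarray
    self_edges: np.ndarray
    lag_annotations: dict[tuple[int, int], tuple[tuple[int, float], ...]]

    @property
    def p(self) -> int:
        return self.adjacency.shape[0]

    def cross_adjacency(self) -> np.ndarray:
        out = self.adjacency.copy()
        np.fill_diagonal(out, False)
        return out

    def n_cross_edges(self) -> int:
        return int(self.cross_adjacency().sum())


def _coeffs_to_truth(A: np.ndarray) -> GroundTruthGraph:
    """Build the ground-truth graph from lag matrices A[l-1][i, j]."""
    L, p, _ = A.shape
    adjacency = np.zeros((p, p), dtype=bool)
    annotations: dict[tuple[int, int], list[tuple[int, float]]] = {}
    for lag in range(1, L + 1):
        for i in range(p):
            for j in range(p):
                coef = A[lag - 1, i, j]
                if coef != 0.0:
                    adjacency[j, i] = True
                    annotations.setdefault((j, i), []).append((lag, float(coef)))
    return GroundTruthGraph(
        adjacency=adjacency,
        self_edges=np.diag(adjacency).copy(),
        lag_annotations={k: tuple(v) for k, v in annotations.items()},
    )


def companion_matrix(A: np.ndarray) -> np.ndarray:
    """Stack VAR(L) lag matrices into the (p*L) x (p*L) companion form."""
    L, p, _ = A.shape
    C = np.zeros((p * L, p * L))
    C[:p, :] = np.concatenate(list(A), axis=1)
    if L > 1:
        C[p:, : p * (L - 1)] = np.eye(p * (L - 1))
    return C


def spectral_radius(A: np.ndarray) -> float:
    """Largest eigenvalue magnitude of the companion matrix (<1 = stationary)."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))))


def _iterate_var(
    A: np.ndarray, T: int, rng: np.random.Generator, burn_in: int
) -> np.ndarray:
    L, p, _ = A.shape
    total = L + burn_in + T
    x = np.empty((total, p))
    x[:L] = rng.standard_normal((L, p))
    for t in range(L, total):
        acc = rng.standard_normal(p)
        for lag in range(1, L + 1):
            acc += A[lag - 1] @ x[t - lag]
        x[t] = acc
    return x[-T:]


# lag matrices A[l-1][i, j]: coefficient of x_j(t - l) in the equation of x_i(t)
_DATASET1_A = np.array(
    [
        [[0.8, 0.0, 0.4],
         [0.0, 0.9, 0.0],
         [0.0, 0.5, 0.5]],
        [[-0.5, 0.0, 0.0],
         [0.0, 0.0, -0.8],
         [0.0, 0.0, -0.2]],
    ]
)

_DATASET2_A = np.zeros((4, 5, 5))
_DATASET2_A[0] = [
    [0.6, 0.0, 0.0, 0.0, 0.0],
    [0.0, 0.5, 0.0, 0.6, 0.0],
    [0.0, 0.0, 0.8, 0.0, 0.0],
    [0.0, 0.0, 0.0, 0.5, 0.0],
    [0.0, 0.0, -0.2, 0.0, 0.7],
]
_DATASET2_A[1] = [
    [0.0, 0.65, 0.0, 0.0, 0.0],
    [0.0, -0.3, 0.0, 0.0, 0.0],
    [0.0, 0.0, -0.7, 0.0, 0.0],
    [0.0, 0.0, 0.9, 0.0, 0.4],
    [0.0, 0.0, 0.0, 0.0, -0.5],
]
_DATASET2_A[2] = np.zeros((5, 5))
_DATASET2_A[2][2, 4] = -0.1
_DATASET2_A[3] = np.zeros((5, 5))
_DATASET2_A[3][1, 2] = -0.3


def _simulate_fixed(
    A: np.ndarray, T: int, seed: int, burn_in: int, names: tuple[str, ...]
) -> tuple[TimeSeriesMatrix, GroundTruthGraph]:
    if T < _MIN_T:
        raise ValueError(f"need T >= {_MIN_T}, got T={T}")
    rng = np.random.default_rng(seed)
    values = _iterate_var(A, T, rng, burn_in)
    X = TimeSeriesMatrix(values=values, names=names)
    return X, _coeffs_to_truth(A)


def simulate_dataset1(
    T: int, seed: int, burn_in: int = DEFAULT_BURN_IN
) -> tuple[TimeSeriesMatrix, GroundTruthGraph]:
    """3-variable VAR(2) benchmark system; deterministic given (T, seed).

    Equations (epsilon i.i.d. N(0,1)):

        x1(t) = 0.8 x1(t-1) - 0.5 x1(t-2) + 0.4 x3(t-1) + e1(t)
        x2(t) = 0.9 x2(t-1) - 0.8 x3(t-2)              + e2(t)
        x3(t) = 0.5 x3(t-1) - 0.2 x3(t-2) + 0.5 x2(t-1) + e3(t)
    """
    return _simulate_fixed(_DATASET1_A, T, seed, burn_in, ("x1", "x2", "x3"))


def simulate_dataset2(
    T: int, seed: int, burn_in: int = DEFAULT_BURN_IN
) -> tuple[TimeSeriesMatrix, GroundTruthGraph]:
    """5-variable VAR(4) benchmark system; deterministic given (T, seed).

    Equations (epsilon i.i.d. N(0,1)):

        x1(t) = 0.6 x1(t-1) + 0.65 x2(t-2)                               + e1(t)
        x2(t) = 0.5 x2(t-1) - 0.3 x2(t-2) - 0.3 x3(t-4) + 0.6 x4(t-1)   + e2(t)
        x3(t) = 0.8 x3(t-1) - 0.7 x3(t-2) - 0.1 x5(t-3)                  + e3(t)
        x4(t) = 0.5 x4(t-1) + 0.9 x3(t-2) + 0.4 x5(t-2)                  + e4(t)
        x5(t) = 0.7 x5(t-1) - 0.5 x5(t-2) - 0.2 x3(t-1)                  + e5(t)
    """
    return _simulate_fixed(
        _DATASET2_A, T, seed, burn_in, ("x1", "x2", "x3", "x4", "x5")
    )


def simulate_random_var(
    p: int,
    L: int,
    density: float,
    T: int,
    seed: int,
    burn_in: int = RANDOM_VAR_BURN_IN,
    max_retries: int = 200,
) -> tuple[TimeSeriesMatrix, GroundTruthGraph]:
    """Draw a random sparse stable VAR(L) and simulate T points from it.

    Each ordered cross pair (j, i) receives an edge with probability
    ``density`` at one uniformly chosen lag; every variable keeps a lag-1
    self-dependence.  Coefficients are rescaled geometrically until the
    companion spectral radius is <= 0.9, guaranteeing stationarity.
    """
    if p < 2:
        raise ValueError(f"need p >= 2, got p={p}")
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must lie in (0, 1], got {density}")
    if L < 1:
        raise ValueError(f"lag order must be >= 1, got L={L}")
    if T < L + 2:
        raise ValueError(f"need T >= L + 2, got T={T}")
    rng = np.random.default_rng(seed)

    A = np.zeros((L, p, p))
    for i in range(p):
        A[0, i, i] = rng.uniform(0.2, 0.5) * rng.choice([-1.0, 1.0])
    for i in range(p):
        for j in range(p):
            if i != j and rng.random() < density:
                lag = int(rng.integers(1, L + 1))
                A[lag - 1, i, j] = rng.uniform(0.3, 0.8) * rng.choice([-1.0, 1.0])

    retries = 0
    while spectral_radius(A) > 0.9:
        A *= 0.95
        retries += 1
        if retries > max_retries:
            raise RuntimeError("could not stabilize the random VAR system")

    values = _iterate_var(A, T, rng, burn_in)
    names = tuple(f"x{i + 1}" for i in range(p))
    return TimeSeriesMatrix(values=values, names=names), _coeffs_to_truth(A)
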