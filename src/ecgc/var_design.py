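"""Lagged regression design for one target variable of a VAR(L) model.

The response is the target series at times t = L+1 .. T (1-based); the
predictor matrix stacks every variable's lagged values, ordered source-major
and lag-minor, so the L coefficients of one source are contiguous.  That
contiguous block is the unit over which a directed edge is later declared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .copula import CopulaSeries, TimeSeriesMatrix

__all__ = ["LaggedDesign", "build_lagged_design"]


@dataclass(frozen=True)
class LaggedDesign:
    """Response vector and lagged predictor matrix for one target.

    ``column_map[k] = (source_index, lag)`` identifies predictor column k;
    lags run 1..L within each source.  Row r corresponds to time point
    t = L + r (0-based), and ``predictors[r, k]`` holds source's value at
    time t - lag.
    """

    target_index: int
    response: np.ndarray
    predictors: np.ndarray
    column_map: tuple[tuple[int, int], ...]
    L: int

    @property
    def n(self) -> int:
        return self.response.shape[0]

    @property
    def m(self) -> int:
        return self.predictors.shape[1]


def build_lagged_design(
    Z: CopulaSeries | TimeSeriesMatrix | np.ndarray,
    target: int,
    L: int,
) -> LaggedDesign:
    """Assemble the lagged least-squares problem for ``target`` at lag order L.

    Works on a copula-transformed series, a raw matrix wrapper, or a plain
    (T, p) array.  Requires 1 <= L <= T - 2 so at least two response rows
    remain.
    """
    values = Z.values if hasattr(Z, "values") else np.asarray(Z, dtype=float)
    T, p = values.shape
    if not 0 <= target < p:
        raise IndexError(f"target index {target} out of range for p={p}")
    if L < 1:
        raise ValueError(f"lag order must be >= 1, got L={L}")
    if L > T - 2:
        raise ValueError(
            f"insufficient time points: need T >= L + 2, got T={T}, L={L}"
        )

    n = T - L
    response = values[L:, target].copy()
    predictors = np.empty((n, p * L))
    column_map = []
    for j in range(p):
        for lag in range(1, L + 1):
            predictors[:, j * L + (lag - 1)] = values[L - lag : T - lag, j]
            column_map.append((j, lag))
    return LaggedDesign(
        target_index=target,
        response=response,
        predictors=predictors,
        column_map=tuple(column_map),
        L=L,
    )
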