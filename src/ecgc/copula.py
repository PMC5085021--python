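"""Gaussian-copula (nonparanormal) marginal transform.

Each column of a multivariate time series is mapped through its Winsorized
empirical CDF and the standard-normal quantile function, then rescaled to the
column's sample mean and standard deviation.  The transform is a pointwise,
rank-preserving function of each marginal (weakly monotone: Winsorization
ties the clamped extreme order statistics; strictly monotone on the
interior), so downstream linear
(Granger) modelling in the transformed space is invariant to any strictly
monotone distortion of the raw marginals — this is what lets a linear VAR fit
capture nonlinear (monotone) dependencies in the observed scale.

Winsorization clamps the empirical CDF into ``[delta_n, 1 - delta_n]`` so the
normal quantile never sees 0 or 1 (which would map to +/- infinity).  The
truncation level shrinks with the sample size n at the standard nonparanormal
rate ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TimeSeriesMatrix",
    "CopulaSeries",
    "empirical_cdf",
    "winsorization_bound",
    "winsorize_cdf",
    "copula_transform",
]


@dataclass(frozen=True)
class TimeSeriesMatrix:
    """A T x p block of observations: rows are time points, columns variables.

    Parameters
    ----------
    values
        Real matrix of shape (T, p) with no missing or non-finite entries.
    names
        p unique variable identifiers (gene names, ROI labels, ...).
    """

    values: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"expected a 2-D matrix, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("time-series matrix contains non-finite entries")
        T, p = values.shape
        if T < 2:
            raise ValueError(f"need at least 2 time points, got T={T}")
        if p < 1:
            raise ValueError("need at least one variable")
        names = tuple(str(n) for n in self.names)
        if len(names) != p:
            raise ValueError(f"{len(names)} names for {p} columns")
        if len(set(names)) != p:
            raise ValueError("variable names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", names)

    @property
    def T_points(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class CopulaSeries:
    """Copula-space image Z of a :class:`TimeSeriesMatrix` (same shape).

    Column-wise rank order follows the source column (extreme order
    statistics clamped by Winsorization may tie); ``delta_n`` is the
    Winsorization bound that was applied to the empirical CDF values.
    """

    values: np.ndarray
    delta_n: float
    source_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("copula-space matrix contains non-finite entries")
        if not 0.0 < self.delta_n < 0.5:
            raise ValueError(f"delta_n must lie in (0, 0.5), got {self.delta_n}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "source_names", tuple(self.source_names))

    @property
    def T_points(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def empirical_cdf(sample: np.ndarray, t: float) -> float:
    """Right-continuous empirical CDF: (# sample elements <= t) / n.

    Ties share a value and the sample maximum maps to exactly 1.
    """
    sample = np.asarray(sample, dtype=float).ravel()
    if sample.size == 0:
        raise ValueError("empirical CDF of an empty sample is undefined")
    return float(np.count_nonzero(sample <= t)) / sample.size


def winsorization_bound(n: int) -> float:
    """Truncation level ``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))``.

    Strictly decreasing in n and inside (0, 0.5) for every n >= 2.
    """
    if n < 2:
        raise ValueError(f"winsorization bound requires n >= 2, got n={n}")
    return 1.0 / (4.0 * n ** 0.25 * math.sqrt(math.pi * math.log(n)))


def winsorize_cdf(u, delta_n: float):
    """Clamp CDF values into ``[delta_n, 1 - delta_n]``.

    Idempotent and order-preserving; accepts scalars or arrays.
    """
    if not 0.0 < delta_n < 0.5:
        raise ValueError(f"delta_n must lie in (0, 0.5), got {delta_n}")
    u_arr = np.asarray(u, dtype=float)
    out = np.clip(u_arr, delta_n, 1.0 - delta_n)
    return float(out) if np.isscalar(u) or u_arr.ndim == 0 else out


def copula_transform(X: TimeSeriesMatrix, delta_n: float | None = None) -> CopulaSeries:
    """Map each column into Gaussian copula space.

    For column i with observations x and sample size T:

    1. u_t = F_hat_i(x_t) = (# elements <= x_t) / T,
    2. clamp u into [delta_T, 1 - delta_T],
    3. z_t = mu_hat_i + sigma_hat_i * Phi^{-1}(u_t),

    where mu_hat / sigma_hat are the sample mean and standard deviation
    (denominator T - 1) of the raw column.  A constant column has sigma_hat = 0;
    its quantiles are left unscaled (shifted by mu_hat only) and a warning is
    emitted, since rank information is void there anyway.
    """
    values = X.values
    T = X.T_points
    if delta_n is None:
        delta_n = winsorization_bound(T)
    if not 0.0 < delta_n < 0.5:
        raise ValueError(f"delta_n must lie in (0, 0.5), got {delta_n}")

    Z = np.empty_like(values)
    for i in range(X.p):
        col = values[:, i]
        # rankdata(method="max") / T is exactly the "count of elements <= x" CDF
        u = stats.rankdata(col, method="max") / T
        u = np.clip(u, delta_n, 1.0 - delta_n)
        q = stats.norm.ppf(u)
        sigma = float(np.std(col, ddof=1))
        mu = float(np.mean(col))
        if sigma == 0.0:
            warnings.warn(
                f"column {X.names[i]!r} is constant; copula transform left unscaled",
                RuntimeWarning,
                stacklevel=2,
            )
            Z[:, i] = mu + q
        else:
            Z[:, i] = mu + sigma * q
    return CopulaSeries(values=Z, delta_n=float(delta_n), source_names=X.names)
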