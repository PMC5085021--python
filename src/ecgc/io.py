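"""Reading time-series tables and writing network estimates.

Time series arrive as CSV or TSV with a header row of variable names and one
row per time point, in temporal order.  Networks leave as an edge-list CSV
(source, target, max_abs_coefficient, lags_nonzero, self_edge) plus an
optional dense 0/1 adjacency CSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .copula import TimeSeriesMatrix
from .network import NetworkEstimate

__all__ = [
    "read_timeseries",
    "write_timeseries",
    "write_network",
    "read_edge_list",
    "edges_to_adjacency",
]


def _separator(path: str) -> str:
    return "\t" if os.path.splitext(path)[1].lower() in {".tsv", ".tab"} else ","


def read_timeseries(path: str) -> TimeSeriesMatrix:
    """Read a header-ed CSV/TSV of observations into a validated matrix.

    Rows are kept in file order (assumed temporal).  Missing or non-numeric
    cells raise with the 1-based data row and the column name.
    """
    df = pd.read_csv(path, sep=_separator(path), float_precision="round_trip")
    if df.columns.duplicated().any() or df.columns.str.match(r".*\.\d+$").any():
        # pandas mangles duplicate headers to name.1, name.2, ...
        raw = pd.read_csv(path, sep=_separator(path), header=None, nrows=1).iloc[0]
        if raw.duplicated().any():
            dups = sorted(set(raw[raw.duplicated()].astype(str)))
            raise ValueError(f"duplicate variable names in header: {dups}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise ValueError(
                f"non-numeric value {df[col][bad.idxmax()]!r} at row {row}, "
                f"column {col!r}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 1
            raise ValueError(f"missing value at row {row}, column {col!r}")
        df[col] = numeric
    return TimeSeriesMatrix(values=df.to_numpy(dtype=float), names=tuple(df.columns))


def write_timeseries(X: TimeSeriesMatrix, path: str) -> None:
    """Write a time-series matrix in the same CSV/TSV dialect it is read in."""
    pd.DataFrame(X.values, columns=list(X.names)).to_csv(
        path, sep=_separator(path), index=False, float_format="%.17g"
    )


def write_network(
    estimate: NetworkEstimate, path: str, adjacency_path: str | None = None
) -> None:
    """Write the estimate as an edge list, optionally plus a dense adjacency.

    One row per directed edge; ``lags_nonzero`` is a ';'-joined list of the
    lags whose coefficients survived selection.
    """
    zero_tol = 1e-8
    rows = []
    coef_by_target = {i: fit.coefficients for i, fit in enumerate(estimate.fits)}
    for j, i in np.argwhere(estimate.adjacency):
        coefs = coef_by_target[int(i)]
        lags = [
            lag
            for k, (src, lag) in enumerate(estimate.column_map)
            if src == j and abs(coefs[k]) > zero_tol
        ]
        max_abs = max(
            abs(coefs[k])
            for k, (src, _lag) in enumerate(estimate.column_map)
            if src == j
        )
        rows.append(
            {
                "source": estimate.names[j],
                "target": estimate.names[i],
                "max_abs_coefficient": max_abs,
                "lags_nonzero": ";".join(str(lag) for lag in sorted(lags)),
                "self_edge": bool(j == i),
            }
        )
    columns = ["source", "target", "max_abs_coefficient", "lags_nonzero", "self_edge"]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)

    if adjacency_path is not None:
        adj = pd.DataFrame(
            estimate.adjacency.astype(int),
            index=list(estimate.names),
            columns=list(estimate.names),
        )
        adj.to_csv(adjacency_path, index_label="source")


def read_edge_list(path: str) -> pd.DataFrame:
    """Read back an edge-list CSV written by :func:`write_network`."""
    return pd.read_csv(
        path, dtype={"source": str, "target": str, "lags_nonzero": str}
    )


def edges_to_adjacency(edges: pd.DataFrame, names: tuple[str, ...]) -> np.ndarray:
    """Reconstruct the boolean adjacency matrix from an edge list."""
    index = {name: k for k, name in enumerate(names)}
    adjacency = np.zeros((len(names), len(names)), dtype=bool)
    for _, row in edges.iterrows():
        adjacency[index[row["source"]], index[row["target"]]] = True
    return adjacency
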