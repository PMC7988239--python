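"""File I/O in the protocol's layouts.

Two canonical inputs drive the modelling:

* an *mRNA file* — two columns (time, mRNA value), one row per grid point
  of the densely interpolated profile;
* a *logistic-parameter file* — exactly three rows (K, t_i, r) with one
  column per biological replicate.

The rate outputs are four CSV files (synthesis and degradation rates plus
their confidence intervals), one row per replicate.

CSV dialect: comma-separated, period decimal, a single optional header
line (written by default, tolerated and skipped on read).  Times are hours
internally; minute-denominated files can be converted on read.  A
converter for supplementary-style Excel workbooks (one sheet per dataset)
is also provided.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import LogisticParams, TimeSeries, TurnoverEstimate

__all__ = [
    "read_mrna_csv",
    "write_mrna_csv",
    "read_logistic_csv",
    "write_logistic_csv",
    "read_protein_csv",
    "write_protein_csv",
    "write_rate_outputs",
    "read_rates_csv",
    "convert_workbook",
    "RATE_FILENAMES",
]

RATE_FILENAMES = (
    "synthesis_rates.csv",
    "degradation_rates.csv",
    "synthesis_ci.csv",
    "degradation_ci.csv",
)


def _read_table(path, min_cols: int) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    # tolerate a single non-numeric header line
    first = df.iloc[0]
    if first.map(lambda v: isinstance(v, str) and not _is_number(v)).any():
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed numeric data ({exc})") from None
    if df.shape[1] < min_cols:
        raise ValueError(f"{path}: expected at least {min_cols} columns")
    return df


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def read_mrna_csv(path, time_unit: str = "h") -> TimeSeries:
    """Read a two-column (time, mRNA) file; rows are sorted by time.

    ``time_unit`` may be "h" (default) or "min"; minutes are converted to
    hours on read.  Duplicate time points are an error.
    """
    df = _read_table(path, min_cols=2)
    t = df.iloc[:, 0].to_numpy()
    v = df.iloc[:, 1].to_numpy()
    if time_unit == "min":
        t = t / 60.0
    elif time_unit != "h":
        raise ValueError(f"unknown time unit {time_unit!r}")
    order = np.argsort(t, kind="stable")
    t, v = t[order], v[order]
    if np.any(np.diff(t) == 0):
        raise ValueError(f"{path}: duplicate time points")
    return TimeSeries(t, v)


def write_mrna_csv(series: TimeSeries, path, header: bool = True) -> None:
    df = pd.DataFrame({"time_h": series.times, "mrna_au": series.values})
    df.to_csv(path, index=False, header=header)


def read_logistic_csv(path) -> list[LogisticParams]:
    """Read the (K, t_i, r) file: exactly 3 rows, one column per replicate.

    ``bottom`` defaults to 0 (backgrounds are subtracted upstream) and no
    R² is attached.  A wrong row count is an error — in particular a 4-row
    file, since Bottom is not part of this format.
    """
    df = _read_table(path, min_cols=1)
    if df.shape[0] != 3:
        raise ValueError(
            f"{path}: expected exactly 3 rows (K, t_i, r), got {df.shape[0]}"
        )
    out = []
    for j in range(df.shape[1]):
        K, t_i, r = (float(df.iloc[i, j]) for i in range(3))
        try:
            out.append(LogisticParams(K=K, t_i=t_i, r=r))
        except ValueError as exc:
            raise ValueError(f"{path}: replicate column {j + 1}: {exc}") from None
    return out


def write_logistic_csv(
    params: Sequence[LogisticParams], path, header: bool = True
) -> None:
    """Write the 3-row (K, t_i, r) layout, one column per replicate."""
    data = np.array([[p.K for p in params], [p.t_i for p in params],
                     [p.r for p in params]])
    cols = [f"rep_{i + 1}" for i in range(len(params))]
    pd.DataFrame(data, columns=cols).to_csv(path, index=False, header=header)


def read_protein_csv(path, time_unit: str = "h") -> list[TimeSeries]:
    """Read raw protein traces: first column time, one column per replicate."""
    df = _read_table(path, min_cols=2)
    t = df.iloc[:, 0].to_numpy()
    if time_unit == "min":
        t = t / 60.0
    order = np.argsort(t, kind="stable")
    t = t[order]
    if np.any(np.diff(t) == 0):
        raise ValueError(f"{path}: duplicate time points")
    return [
        TimeSeries(t, df.iloc[:, j].to_numpy()[order], raw=True)
        for j in range(1, df.shape[1])
    ]


def write_protein_csv(
    traces: Sequence[TimeSeries], path, header: bool = True
) -> None:
    """Write raw traces sharing one time grid: time + one column per replicate."""
    t0 = traces[0].times
    for tr in traces[1:]:
        if not np.allclose(tr.times, t0):
            raise ValueError("all traces must share the same time grid")
    data = {"time_h": t0}
    for i, tr in enumerate(traces):
        data[f"rep_{i + 1}"] = tr.values
    pd.DataFrame(data).to_csv(path, index=False, header=header)


def write_rate_outputs(
    estimates: Sequence[TurnoverEstimate], directory
) -> dict:
    """Write the four protocol output files, one row per replicate.

    ``synthesis_rates.csv`` / ``degradation_rates.csv`` carry the point
    estimates; ``synthesis_ci.csv`` / ``degradation_ci.csv`` carry the 95%
    lower and upper bounds.  All estimates must share one fitting mode;
    replicate order is preserved.
    """
    if len(estimates) == 0:
        raise ValueError("need at least one estimate")
    modes = {e.mode for e in estimates}
    if len(modes) > 1:
        raise ValueError(f"mixed fitting modes in one output: {sorted(modes)}")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [e.replicate_id or str(i + 1) for i, e in enumerate(estimates)]
    frames = {
        "synthesis_rates.csv": pd.DataFrame(
            {"replicate": ids, "Sp": [e.Sp for e in estimates]}
        ),
        "degradation_rates.csv": pd.DataFrame(
            {"replicate": ids, "Dp": [e.Dp for e in estimates]}
        ),
        "synthesis_ci.csv": pd.DataFrame(
            {
                "replicate": ids,
                "lower": [e.Sp_ci_low for e in estimates],
                "upper": [e.Sp_ci_high for e in estimates],
            }
        ),
        "degradation_ci.csv": pd.DataFrame(
            {
                "replicate": ids,
                "lower": [e.Dp_ci_low for e in estimates],
                "upper": [e.Dp_ci_high for e in estimates],
            }
        ),
    }
    paths = {}
    for name, df in frames.items():
        p = directory / name
        df.to_csv(p, index=False, float_format="%.17g")
        paths[name] = p
    return paths


def read_rates_csv(path) -> np.ndarray:
    """Read a rates file back as a value array (last column; header optional).

    Accepts both the two-column (replicate, value) layout written by
    :func:`write_rate_outputs` and a bare single-column list of rates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: file is empty") from None
    first = df.iloc[0]
    if first.map(lambda v: isinstance(v, str) and not _is_number(v)).any():
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    vals = pd.to_numeric(df.iloc[:, df.shape[1] - 1], errors="raise").to_numpy(float)
    if not np.all(np.isfinite(vals)):
        raise ValueError(f"{path}: non-finite rate values")
    return vals


def convert_workbook(
    xlsx_path,
    out_dir,
    mrna_sheet: str,
    protein_sheet: str,
    time_column: int = 0,
) -> dict:
    """Convert a supplementary-style Excel workbook to the canonical CSVs.

    Expects one sheet holding the (time, mRNA) profile and one sheet
    holding the protein traces (time + one column per replicate); sheet
    names are configurable because workbook layouts vary.  Emits
    ``mrna.csv`` and ``protein.csv`` into ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mrna_df = pd.read_excel(xlsx_path, sheet_name=mrna_sheet).dropna(how="all")
    prot_df = pd.read_excel(xlsx_path, sheet_name=protein_sheet).dropna(how="all")
    mrna_path = out_dir / "mrna.csv"
    prot_path = out_dir / "protein.csv"
    cols = list(mrna_df.columns)
    cols.insert(0, cols.pop(time_column))
    mrna_df[cols[:2]].to_csv(mrna_path, index=False)
    pcols = list(prot_df.columns)
    pcols.insert(0, pcols.pop(time_column))
    prot_df[pcols].to_csv(prot_path, index=False)
    return {"mrna": mrna_path, "protein": prot_path}
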