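"""CSV/heatmap readers and writers shared by all modules.

Dialect: comma-separated, ``.`` decimal, UTF-8, mandatory header row.
Matrices are stored row-major with no index column and probabilities are
serialized with 12 significant digits (enough to round-trip a double for
testing purposes).  Readers reject malformed input with location-bearing
messages (line numbers for CSV).
"""

from __future__ import annotations

import csv
from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless rendering; PNG output only
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .exceptions import ContractError
from .logistic import GrowthRateEstimates, PlaqueTrajectory

__all__ = [
    "write_matrix_csv",
    "read_matrix_csv",
    "write_two_state_matrix",
    "read_two_state_matrix",
    "write_measurement_series",
    "read_measurement_series",
    "write_r_estimates",
    "write_trajectory",
    "write_heatmap",
]

_FMT = "{:.12g}"


def write_matrix_csv(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 2-D array row-major with a ``c0,c1,...`` header row."""
    arr = np.atleast_2d(np.asarray(matrix, dtype=float))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([f"c{j}" for j in range(arr.shape[1])])
        for row in arr:
            writer.writerow([_FMT.format(v) for v in row])


def read_matrix_csv(path: str | Path) -> np.ndarray:
    """Read a matrix written by :func:`write_matrix_csv`, validating shape
    and numeric content with line/column positions in error messages."""
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ContractError(f"{path}: empty file, expected a header row") from None
        width = len(header)
        for lineno, row in enumerate(reader, start=2):
            if len(row) != width:
                raise ContractError(
                    f"{path}: line {lineno}: {len(row)} fields, expected {width}"
                )
            parsed = []
            for col, value in enumerate(row, start=1):
                try:
                    parsed.append(float(value))
                except ValueError:
                    raise ContractError(
                        f"{path}: line {lineno}, column {col}: "
                        f"{value!r} is not a number"
                    ) from None
            rows.append(parsed)
    if not rows:
        raise ContractError(f"{path}: no data rows")
    return np.array(rows)


def write_two_state_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 2x2 transition matrix with S/U row and column labels."""
    arr = np.asarray(matrix, dtype=float)
    if arr.shape != (2, 2):
        raise ContractError(f"expected a 2x2 matrix, got shape {arr.shape}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["", "S", "U"])
        for label, row in zip(("S", "U"), arr):
            writer.writerow([label] + [_FMT.format(v) for v in row])


def read_two_state_matrix(path: str | Path) -> np.ndarray:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["", "S", "U"]:
            raise ContractError(f"{path}: line 1: expected header ',S,U'")
        rows = []
        for lineno, expected_label in ((2, "S"), (3, "U")):
            row = next(reader, None)
            if row is None or row[0] != expected_label or len(row) != 3:
                raise ContractError(
                    f"{path}: line {lineno}: expected row labelled {expected_label!r}"
                )
            try:
                rows.append([float(row[1]), float(row[2])])
            except ValueError:
                raise ContractError(
                    f"{path}: line {lineno}: non-numeric matrix entry"
                ) from None
    return np.array(rows)


def write_measurement_series(df: pd.DataFrame, path: str | Path) -> None:
    """Write a surveillance series with header ``patient_id,visit_index,P``
    (P as a decimal fraction, not percent)."""
    missing = {"patient_id", "visit_index", "P"} - set(df.columns)
    if missing:
        raise ContractError(f"measurement table missing column(s): {sorted(missing)}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "visit_index", "P"])
        for _, row in df.iterrows():
            writer.writerow(
                [row["patient_id"], int(row["visit_index"]), _FMT.format(row["P"])]
            )


def read_measurement_series(path: str | Path) -> pd.DataFrame:
    """Read a measurement CSV, validating the header and each value (P must
    be a decimal fraction in [0, 1])."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["patient_id", "visit_index", "P"]:
            raise ContractError(
                f"{path}: line 1: expected header 'patient_id,visit_index,P', got {header}"
            )
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise ContractError(f"{path}: line {lineno}: expected 3 fields")
            try:
                visit = int(row[1])
            except ValueError:
                raise ContractError(
                    f"{path}: line {lineno}, column 2: visit_index {row[1]!r} "
                    "is not an integer"
                ) from None
            try:
                p = float(row[2])
            except ValueError:
                raise ContractError(
                    f"{path}: line {lineno}, column 3: P {row[2]!r} is not a number"
                ) from None
            if not (0.0 <= p <= 1.0):
                raise ContractError(
                    f"{path}: line {lineno}, column 3: P={p} outside [0, 1] "
                    "(P must be a decimal fraction, not a percentage)"
                )
            records.append({"patient_id": row[0], "visit_index": visit, "P": p})
    if not records:
        raise ContractError(f"{path}: no measurement rows")
    return pd.DataFrame(records)


def write_r_estimates(
    estimates: GrowthRateEstimates, patient_id: str, path: str | Path
) -> None:
    """Write per-interval growth-rate estimates with header
    ``patient_id,interval_index,r_hat,flag``; undefined intervals carry an
    empty r_hat and the flag ``undefined``."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "interval_index", "r_hat", "flag"])
        for k, (r_hat, undef) in enumerate(zip(estimates.r_hat, estimates.undefined)):
            writer.writerow(
                [
                    patient_id,
                    k,
                    "" if undef else _FMT.format(r_hat),
                    "undefined" if undef else "ok",
                ]
            )


def write_trajectory(traj: PlaqueTrajectory, path: str | Path) -> None:
    """Write a trajectory with header ``visit,P,r,A,stenosis_vs_baseline``."""
    stenosis = traj.stenosis_vs_baseline
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["visit", "P", "r", "A", "stenosis_vs_baseline"])
        for t in range(len(traj.P_series)):
            writer.writerow(
                [
                    t,
                    _FMT.format(traj.P_series[t]),
                    "" if np.isnan(traj.r_series[t]) else _FMT.format(traj.r_series[t]),
                    _FMT.format(traj.A_series[t]),
                    _FMT.format(stenosis[t]),
                ]
            )


def write_heatmap(field: np.ndarray, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write a per-site probability field as ``<prefix>.csv`` (authoritative)
    and ``<prefix>.png`` (presentation).

    The PNG uses a fixed blue-to-red scale over [0, 1] (blue = low
    probability of destabilization, red = high) so renders of different
    fields are directly comparable.
    """
    arr = np.atleast_2d(np.asarray(field, dtype=float))
    if np.any(~np.isfinite(arr)) or np.any((arr < 0.0) | (arr > 1.0)):
        raise ContractError("heatmap field must contain probabilities in [0, 1]")
    out_prefix = Path(out_prefix)
    csv_path = out_prefix.with_suffix(".csv")
    png_path = out_prefix.with_suffix(".png")
    write_matrix_csv(arr, csv_path)
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(arr, cmap="RdBu_r", vmin=0.0, vmax=1.0, origin="upper")
    fig.colorbar(im, ax=ax, label="P(stable → unstable)")
    ax.set_xlabel("column")
    ax.set_ylabel("row")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path
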