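"""Curve CSV format and result serialization.

Curve files are plain comma-separated text: the first row holds the time
grid, each subsequent row one curve sampled on it.  With ``has_labels`` the
data rows carry a leading 0/1 anomaly-label column (the header row holds
only the grid).  This layout also accommodates mortality-table-style data
(ages as the grid, one year per row, log-rates as values) without special
casing.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__ as _pkg_version
from .detection import DetectionResult
from .evaluation import MonteCarloReport
from .representation import CoefficientSet, SampledCurveSet

__all__ = ["read_curves", "write_curves", "write_results"]


class CurveParseError(ValueError):
    """A curve CSV file could not be parsed; the message names the position."""


def _parse_row(row, path, line_no):
    try:
        return [float(cell) for cell in row]
    except ValueError:
        for col, cell in enumerate(row, start=1):
            try:
                float(cell)
            except ValueError:
                raise CurveParseError(
                    f"{path}: non-numeric cell {cell!r} at row {line_no}, column {col}"
                ) from None
        raise


def read_curves(path: Union[str, Path], has_labels: bool = False) -> SampledCurveSet:
    """Read a curve sample from CSV.

    First row: grid values (strictly increasing).  Subsequent rows: one
    curve each, optionally preceded by a 0/1 label column when
    ``has_labels`` is set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curve file not found: {path}")
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        rows = [row for row in reader if row and any(cell.strip() for cell in row)]
    if len(rows) < 2:
        raise CurveParseError(f"{path}: need a grid row and at least one curve row")
    grid = _parse_row(rows[0], path, 1)
    if any(b - a <= 0 for a, b in zip(grid, grid[1:])):
        raise CurveParseError(f"{path}: header grid is not strictly increasing")
    m = len(grid)
    expected = m + 1 if has_labels else m
    values, labels = [], []
    for line_no, row in enumerate(rows[1:], start=2):
        if len(row) != expected:
            raise CurveParseError(
                f"{path}: row {line_no} has {len(row)} cells, expected {expected}"
            )
        cells = _parse_row(row, path, line_no)
        if has_labels:
            labels.append(int(cells[0]))
            cells = cells[1:]
        values.append(cells)
    return SampledCurveSet(
        grid=np.asarray(grid),
        values=np.asarray(values),
        labels=np.asarray(labels, dtype=int) if has_labels else None,
    )


def _check_writable(path: Path, force: bool) -> None:
    if path.exists() and not force:
        raise FileExistsError(f"refusing to overwrite {path}; pass force=True / --force")


def write_curves(curves: SampledCurveSet, path: Union[str, Path],
                 with_labels: bool = False, force: bool = False) -> None:
    """Write a curve sample in the format :func:`read_curves` expects."""
    path = Path(path)
    _check_writable(path, force)
    if with_labels and curves.labels is None:
        raise ValueError("curve set has no labels to write")
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([repr(float(v)) for v in curves.grid])
        for i, row in enumerate(curves.values):
            cells = [repr(float(v)) for v in row]
            if with_labels:
                cells = [str(int(curves.labels[i]))] + cells
            writer.writerow(cells)


def _detection_payload(result: DetectionResult) -> dict:
    return {
        "method": result.method,
        "scores": result.scores.tolist(),
        "labels": result.labels.tolist(),
        "flagged": result.flagged.tolist(),
        "settings": _jsonable(result.settings),
        "version": _pkg_version,
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


def read_detection_result(path: Union[str, Path]) -> DetectionResult:
    """Load a detection result previously written by :func:`write_results`."""
    with Path(path).open() as fh:
        payload = json.load(fh)
    return DetectionResult(
        scores=np.asarray(payload["scores"], dtype=float),
        labels=np.asarray(payload["labels"], dtype=int),
        flagged=np.asarray(payload["flagged"], dtype=int),
        method=payload["method"],
        settings=payload["settings"],
    )


def write_results(result, path: Union[str, Path], format: Optional[str] = None,
                  force: bool = False) -> None:
    """Serialize a detection result, Monte-Carlo report or coefficient set.

    Detection results go to JSON; Monte-Carlo reports to CSV with a JSON
    settings sidecar; coefficient sets to CSV (header z1..zd) with a sidecar
    JSON recording sigma, gamma, d and the eigenvalues used.  Field ordering
    is deterministic and numbers are written at full precision.
    """
    path = Path(path)
    _check_writable(path, force)
    if isinstance(result, DetectionResult):
        with path.open("w") as fh:
            json.dump(_detection_payload(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif isinstance(result, MonteCarloReport):
        result.table.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".settings.json")
        _check_writable(sidecar, force)
        with sidecar.open("w") as fh:
            json.dump(_jsonable(result.settings), fh, indent=2, sort_keys=True)
            fh.write("\n")
    elif isinstance(result, CoefficientSet):
        header = [f"z{j + 1}" for j in range(result.d)]
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for row in result.coefficients:
                writer.writerow([repr(float(v)) for v in row])
        sidecar = path.with_suffix(path.suffix + ".settings.json")
        _check_writable(sidecar, force)
        meta = {
            "sigma": result.kernel_spec.sigma,
            "gamma": result.kernel_spec.gamma,
            "d": result.d,
            "eigenvalues": result.eigenvalues_used.tolist(),
            "version": _pkg_version,
        }
        with sidecar.open("w") as fh:
            json.dump(meta, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise TypeError(f"unsupported result type {type(result).__name__}")
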