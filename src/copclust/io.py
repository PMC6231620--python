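"""Text-format I/O: panels, distance matrices, labels and reports.

Everything is plain CSV or JSON so results stay inspectable and diffable.
Panels come in two layouts:

* wide — one column per series, one row per time point; ragged series are
  allowed as *trailing* empty cells;
* long — columns ``id,time,value`` with a 1-based, consecutive time index per
  series.

Missing values are empty cells only; an internal (non-trailing) gap is an
error rather than something to impute silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, InvalidInputError, Panel, TimeSeries
from .simulate import Partition

__all__ = [
    "read_panel",
    "write_panel",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_labels",
    "write_labels",
    "write_report",
    "write_silhouette_profile",
]


class PanelFormatError(InvalidInputError):
    """Raised when a panel file violates the layout contract."""


def _series_from_column(sid: str, col: pd.Series, source: str) -> TimeSeries:
    vals = col.to_numpy(dtype=float)
    missing = np.isnan(vals)
    if missing.any():
        first = int(np.argmax(missing))
        if not missing[first:].all():
            raise PanelFormatError(
                f"{source}: series {sid!r} has an internal gap at row {first + 1}")
        vals = vals[:first]
    if vals.size == 0:
        raise PanelFormatError(f"{source}: series {sid!r} is empty")
    return TimeSeries(id=sid, values=vals)


def read_panel(path, layout: str = "wide") -> Panel:
    """Read a panel CSV; series order follows file order."""
    path = Path(path)
    if layout == "wide":
        df = pd.read_csv(path)
        if df.columns.duplicated().any() or any(c.startswith("Unnamed:") for c in df.columns):
            raise PanelFormatError(f"{path}: wide layout needs unique named headers")
        try:
            series = tuple(_series_from_column(str(c), df[c], str(path)) for c in df.columns)
        except ValueError as exc:
            raise PanelFormatError(f"{path}: non-numeric cell ({exc})") from exc
        return Panel(series=series)
    if layout == "long":
        df = pd.read_csv(path)
        required = {"id", "time", "value"}
        if not required.issubset(df.columns):
            raise PanelFormatError(f"{path}: long layout needs columns {sorted(required)}")
        series = []
        for sid in df["id"].drop_duplicates():
            sub = df[df["id"] == sid].sort_values("time", kind="stable")
            times = sub["time"].to_numpy()
            if not np.array_equal(times, np.arange(1, len(times) + 1)):
                raise PanelFormatError(
                    f"{path}: series {sid!r} time index must be 1..T consecutive")
            vals = sub["value"].to_numpy(dtype=float)
            if np.isnan(vals).any():
                raise PanelFormatError(f"{path}: series {sid!r} has missing values")
            series.append(TimeSeries(id=str(sid), values=vals))
        return Panel(series=tuple(series))
    raise PanelFormatError(f"unknown layout {layout!r}; use 'wide' or 'long'")


def write_panel(panel: Panel, path) -> None:
    """Write a panel as wide CSV; shorter series get trailing empty cells."""
    T_max = max(s.length for s in panel)
    data = {s.id: np.concatenate([s.values, np.full(T_max - s.length, np.nan)])
            for s in panel}
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def write_distance_matrix(D: DistanceMatrix, path) -> None:
    """Full symmetric labeled CSV at near-machine precision."""
    df = pd.DataFrame(D.values, index=list(D.ids), columns=list(D.ids))
    df.to_csv(path, float_format="%.15g", index_label="id")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    ids = [str(c) for c in df.columns]
    if [str(i) for i in df.index] != ids:
        raise InvalidInputError(f"{path}: row and column labels disagree")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, rtol=0.0, atol=1e-9):
        raise InvalidInputError(f"{path}: matrix is asymmetric beyond 1e-9")
    values = 0.5 * (values + values.T)  # scrub sub-tolerance formatting noise
    return DistanceMatrix(ids=tuple(ids), values=values)


def write_labels(labels, path) -> None:
    """Labels CSV with columns ``id,cluster`` (one row per series)."""
    mapping = labels.labels if hasattr(labels, "labels") else dict(labels)
    pd.DataFrame({"id": list(mapping), "cluster": list(mapping.values())}
                 ).to_csv(path, index=False)


def read_labels(path) -> Partition:
    """Read an ``id,cluster`` (or ``id,group``) CSV as a Partition."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 2:
        raise InvalidInputError(f"{path}: need id and cluster/group columns")
    return Partition.from_labels(dict(zip(df[cols[0]].astype(str), df[cols[1]])))


def write_report(report: dict, path) -> None:
    """Dump a JSON report (settings, seed, per-replicate outputs)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
        fh.write("\n")


def write_silhouette_profile(J_star: int, profile: dict[int, float], path) -> None:
    write_report({"J_star": J_star,
                  "profile": {str(J): s for J, s in sorted(profile.items())}}, path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
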