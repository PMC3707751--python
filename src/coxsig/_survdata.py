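"""Internal helpers for right-censored survival responses."""

from __future__ import annotations

import numpy as np
import pandas as pd


def check_survival(y, n: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Coerce ``y`` to ``(times, events)`` float arrays.

    Accepts a ``(times, events)`` tuple/list, an ``(n, 2)`` array with
    time in the first column, a structured array with time/event fields
    (any order, names containing "time"/"event"), or a DataFrame with
    such columns.
    """
    if isinstance(y, pd.DataFrame):
        tcol = [c for c in y.columns if "time" in c.lower() or "month" in c.lower()]
        ecol = [c for c in y.columns if "event" in c.lower()]
        if not tcol or not ecol:
            raise ValueError("DataFrame y needs time and event columns")
        times, events = y[tcol[0]].to_numpy(float), y[ecol[0]].to_numpy(float)
    elif isinstance(y, (tuple, list)) and len(y) == 2:
        times, events = np.asarray(y[0], float), np.asarray(y[1], float)
    else:
        y = np.asarray(y)
        if y.dtype.names:
            tname = [f for f in y.dtype.names if "time" in f.lower()]
            ename = [f for f in y.dtype.names if "event" in f.lower()]
            if not tname or not ename:
                raise ValueError("structured y needs time and event fields")
            times = y[tname[0]].astype(float)
            events = y[ename[0]].astype(float)
        elif y.ndim == 2 and y.shape[1] == 2:
            times, events = y[:, 0].astype(float), y[:, 1].astype(float)
        else:
            raise ValueError("cannot interpret y as survival data")
    if times.shape != events.shape:
        raise ValueError("times and events differ in length")
    if n is not None and len(times) != n:
        raise ValueError(f"y has {len(times)} rows, X has {n}")
    if not np.isfinite(times).all() or not np.isfinite(events).all():
        raise ValueError("non-finite survival times or events")
    if (times < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(events, (0.0, 1.0)).all():
        raise ValueError("events must be 0/1")
    return times, events


def check_covariates(X) -> tuple[np.ndarray, list[str]]:
    """Coerce covariates to a float matrix, returning (matrix, names)."""
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        mat = X.to_numpy(float)
    else:
        mat = np.asarray(X, float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{j}" for j in range(mat.shape[1])]
    if not np.isfinite(mat).all():
        raise ValueError("non-finite covariate values")
    return np.ascontiguousarray(mat), names


def risk_set_starts(times_sorted: np.ndarray) -> np.ndarray:
    """For times sorted ascending, index of the first row tied with each row.

    The risk set of the event at sorted position i is rows
    ``risk_set_starts[i] .. n-1`` (subjects with time >= that event time).
    """
    n = len(times_sorted)
    first = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        first[i] = first[i - 1] if times_sorted[i] == times_sorted[i - 1] else i
    return first


def sort_survival(times, events, X=None):
    """Sort by ascending time (events before censorings at ties, which is
    immaterial for the likelihood but keeps groups contiguous).

    Returns ``(order, t_sorted, e_sorted, X_sorted_or_None, first_idx)``.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, float)
    order = np.lexsort((1 - events, times))
    t = times[order]
    e = events[order]
    Xs = None if X is None else np.ascontiguousarray(np.asarray(X, float)[order])
    return order, t, e, Xs, risk_set_starts(t)
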