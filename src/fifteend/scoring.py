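"""Scoring 15D health states with a value algorithm.

The model is purely additive: a state's disutility is the sum of the 15
per-dimension decrements for its levels, and its value is one minus that sum.
Value and disutility are duals (they always sum to exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import DIMENSIONS, HealthState, ValueAlgorithm, validate_health_state


@dataclass(frozen=True)
class ScoredState:
    state: HealthState
    disutility: float
    value: float


def additive_disutility(levels: Sequence[int], T: pd.DataFrame) -> float:
    """Sum of per-dimension decrements ``T[j, l_j]`` for any level table.

    Works for reduced instruments too: ``T`` may have any set of dimension
    columns (rows indexed by level 1..5), and ``levels`` must match its width.
    """
    T = T.sort_index()
    if len(levels) != T.shape[1]:
        raise ValueError(f"state has {len(levels)} levels but table has {T.shape[1]} dimensions")
    idx = np.asarray(levels, dtype=int) - 1
    if (idx < 0).any() or (idx >= T.shape[0]).any():
        raise ValueError("levels out of range for the table")
    return float(T.to_numpy()[idx, np.arange(T.shape[1])].sum())


def score_state(
    state: HealthState | Sequence[int] | str, algorithm: ValueAlgorithm
) -> ScoredState:
    """Score one health state: disutility ``sum_j T[j, l_j]`` and value ``1 - disutility``."""
    state = validate_health_state(state)
    d = additive_disutility(state.levels, algorithm.T)
    return ScoredState(state=state, disutility=d, value=1.0 - d)


def batch_score(
    states: Iterable, algorithm: ValueAlgorithm, permissive: bool = False
) -> pd.DataFrame:
    """Score a batch of states, preserving order.

    Returns a frame with columns ``state``, ``disutility``, ``value``.  Rows
    that fail validation raise by default with their positions listed; with
    ``permissive=True`` they are kept as NaN and flagged in a boolean
    ``invalid`` column.
    """
    records = []
    invalid: list[int] = []
    for pos, raw in enumerate(states):
        try:
            scored = score_state(raw, algorithm)
            records.append((str(scored.state), scored.disutility, scored.value, False))
        except ValueError:
            invalid.append(pos)
            records.append((None, np.nan, np.nan, True))
    if invalid and not permissive:
        raise ValueError(f"invalid health state(s) at position(s): {invalid}")
    df = pd.DataFrame(records, columns=["state", "disutility", "value", "invalid"])
    if not permissive:
        df = df.drop(columns="invalid")
    return df


def summarize_scores(values: Sequence[float]) -> dict:
    """Mean and quartiles of a collection of state values."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no values to summarise")
    qs = np.percentile(v, [0, 25, 50, 75, 100])
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "min": float(qs[0]),
        "q25": float(qs[1]),
        "median": float(qs[2]),
        "q75": float(qs[3]),
        "max": float(qs[4]),
    }


def algorithm_summary(algorithm: ValueAlgorithm) -> dict:
    """Headline description of an algorithm.

    Reports the value range ``[1 - sum_j T[j,5], 1]``, the disutility range,
    and the dimensions ranked by their level-5 decrement (largest first, ties
    broken by canonical dimension order).
    """
    level5 = algorithm.T.loc[5]
    order = sorted(
        DIMENSIONS, key=lambda d: (-level5[d], DIMENSIONS.index(d))
    )
    ranking = [(d, float(level5[d])) for d in order]
    total = float(level5.sum())
    return {
        "disutility_range": (0.0, total),
        "value_range": (1.0 - total, 1.0),
        "v_pits": float(algorithm.v_pits),
        "ranking_by_level5": ranking,
        "largest_level5": ranking[0],
        "smallest_level5": ranking[-1],
    }


def percentile_curve(values: Sequence[float], n_points: int) -> pd.DataFrame:
    """Mean value by ranked percentile bin.

    Values are sorted ascending and split into ``n_points`` equal-count bins
    (any remainder spread over the leading bins); each bin reports its
    mid-rank percentile and mean value.  The curve is non-decreasing.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    if n == 0:
        raise ValueError("no scores supplied")
    if n_points > n:
        raise ValueError(f"n_points={n_points} exceeds the number of scores ({n})")
    base, rem = divmod(n, n_points)
    sizes = np.full(n_points, base)
    sizes[:rem] += 1
    stops = np.cumsum(sizes)
    starts = stops - sizes
    pct = 100.0 * (starts + sizes / 2.0) / n
    means = [v[a:b].mean() for a, b in zip(starts, stops)]
    return pd.DataFrame({"percentile": pct, "mean_value": means})
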