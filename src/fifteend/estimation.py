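"""Value-algorithm estimation from VAS valuation data.

The procedure turns raw within-dimension VAS scores and a pits-task anchor
into a disutility look-up table in four steps:

1. weighted mean VAS score per (dimension, level) cell, levels L2-L5 and
   "being dead" (L1 is fixed at 100 by task design);
2. within-dimension relative disutility scores
   ``S[j,i] = (100 - mean[j,i]) / (100 - mean_dead[j])``;
3. empirical pits anchor ``V_pits = (100 - mean_pits) / (100 - mean_dead)``
   from the pits task (complete responses only);
4. rescale: ``omega = V_pits / sum_j S[j,5]`` and ``T[j,i] = omega * S[j,i]``,
   so that full health scores 1 and the all-worst state scores ``1 - V_pits``.

All means are post-stratification weighted; each task uses its own weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    DEAD,
    DIMENSIONS,
    LEVELS,
    PITS_TASK,
    WITHIN_SCORE_COLUMNS,
    ValueAlgorithm,
    validate_demographics,
    validate_pits_responses,
    validate_within_responses,
)
from .weighting import WeightingResult, compute_poststrat_weights, weighted_mean

#: Minimum VAS distance between the mean "dead" score and 100.  Relative
#: scores divide by this distance, so a mean near 100 would explode; falling
#: below the guard is an error, never a silent clamp.
MIN_DEAD_GAP = 1.0

_LEVEL_FIELD = {2: "score_L2", 3: "score_L3", 4: "score_L4", 5: "score_L5"}


@dataclass
class PitsEstimate:
    """Step-3 output: the empirical disutility of the all-worst state."""

    v_pits: float
    mean_pits: float
    mean_dead: float
    n_complete: int
    n_excluded: int


@dataclass
class EstimationResult:
    """Full audit of one estimation run."""

    algorithm: ValueAlgorithm
    level_means: pd.DataFrame
    relative_scores: pd.DataFrame
    pits: PitsEstimate
    weights_within: WeightingResult
    weights_pits: WeightingResult
    log: dict = field(default_factory=dict)


def _weights_for(weights, task_id: str) -> pd.Series | None:
    """Accept a WeightingResult, long DataFrame, mapping or None."""
    if weights is None:
        return None
    if isinstance(weights, WeightingResult):
        return weights.for_task(task_id)
    if isinstance(weights, pd.DataFrame):
        sub = weights[weights["task_id"] == task_id]
        return sub.set_index("respondent_id")["weight"]
    if isinstance(weights, Mapping):
        w = weights.get(task_id)
        return None if w is None else pd.Series(w)
    raise TypeError(f"unsupported weights object: {type(weights)!r}")


def weighted_level_means(
    within: pd.DataFrame,
    weights=None,
    complete_case: bool = False,
) -> pd.DataFrame:
    """Step 1: weighted mean VAS score per (dimension, level) cell.

    Returns a frame indexed by level (1..5 plus ``"dead"``) with one column
    per dimension present in the data; the level-1 row is fixed at 100.  By
    default a respondent contributes to every cell they answered; with
    ``complete_case=True`` only rows with all five scores present are used.
    Respondents without a weight for the task are dropped.  A cell with no
    usable responses is an error.
    """
    within = validate_within_responses(within)
    dims = [d for d in DIMENSIONS if d in set(within["dimension"])]
    means = pd.DataFrame(
        index=pd.Index(list(LEVELS) + [DEAD], name="level"),
        columns=dims,
        dtype=float,
    )
    for dim in dims:
        rows = within[within["dimension"] == dim]
        if complete_case:
            rows = rows.dropna(subset=list(WITHIN_SCORE_COLUMNS))
        w = _weights_for(weights, dim)
        if w is not None:
            rows = rows[rows["respondent_id"].isin(w.index)]
            wv = w.reindex(rows["respondent_id"]).to_numpy()
        else:
            wv = None
        for level, col in list(_LEVEL_FIELD.items()) + [(DEAD, "score_dead")]:
            try:
                means.at[level, dim] = weighted_mean(rows[col].to_numpy(), wv)
            except ValueError as err:
                raise ValueError(
                    f"no usable responses for dimension {dim!r}, level {level!r}"
                ) from err
        means.at[1, dim] = 100.0
    return means


def relative_scores(
    means: pd.DataFrame, min_dead_gap: float = MIN_DEAD_GAP
) -> pd.DataFrame:
    """Step 2: within-dimension relative disutility scores.

    ``S[j,i] = (100 - mean[j,i]) / (100 - mean_dead[j])`` for levels 2-5;
    ``S[j,1] = 0`` since level 1 is fixed at 100.  Scores above 1 mean the
    level was rated below "being dead".  Dimensions whose mean dead score is
    within ``min_dead_gap`` VAS units of 100 are rejected.
    """
    dead = means.loc[DEAD].astype(float)
    gap = 100.0 - dead
    bad = gap[gap < min_dead_gap].index.tolist()
    if bad:
        raise ValueError(
            f"mean 'dead' score too close to 100 (gap < {min_dead_gap}) for "
            f"dimension(s): {bad}"
        )
    S = (100.0 - means.loc[list(LEVELS)].astype(float)) / gap
    S.loc[1] = 0.0
    if (S.to_numpy() < 0).any():
        raise ValueError("negative relative score: a mean level score exceeds 100")
    return S


def filter_complete_pits(pits: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep pits responses with both scores present; report how many dropped."""
    pits = validate_pits_responses(pits)
    complete = pits.dropna(subset=["score_pits", "score_dead"])
    return complete.reset_index(drop=True), len(pits) - len(complete)


def pits_estimate(
    pits: pd.DataFrame,
    weights: pd.Series | None = None,
    min_dead_gap: float = MIN_DEAD_GAP,
) -> PitsEstimate:
    """Step 3: the empirical pits-state disutility.

    Incomplete responses are excluded first; the two weighted means then give
    ``V_pits = (100 - mean_pits) / (100 - mean_dead)``.  ``V_pits > 1`` means
    the all-worst state was on average rated below "being dead".
    """
    complete, n_excluded = filter_complete_pits(pits)
    if complete.empty:
        raise ValueError("no complete pits responses")
    if weights is not None:
        complete = complete[complete["respondent_id"].isin(weights.index)]
        if complete.empty:
            raise ValueError("no complete pits responses with weights")
        wv = weights.reindex(complete["respondent_id"]).to_numpy()
    else:
        wv = None
    mean_pits = weighted_mean(complete["score_pits"].to_numpy(), wv)
    mean_dead = weighted_mean(complete["score_dead"].to_numpy(), wv)
    gap = 100.0 - mean_dead
    if gap < min_dead_gap:
        raise ValueError(
            f"pits task: mean 'dead' score too close to 100 (gap {gap:.3f} < {min_dead_gap})"
        )
    return PitsEstimate(
        v_pits=(100.0 - mean_pits) / gap,
        mean_pits=mean_pits,
        mean_dead=mean_dead,
        n_complete=len(complete),
        n_excluded=n_excluded,
    )


def build_algorithm(
    S: pd.DataFrame, pits: PitsEstimate | float, metadata: dict | None = None
) -> ValueAlgorithm:
    """Step 4: rescale relative scores into the final disutility table.

    ``omega = V_pits / sum_j S[j,5]``, ``T = omega * S``; by construction the
    level-5 row of ``T`` sums to ``V_pits`` and level 1 carries no decrement,
    so values span ``[1 - V_pits, 1]``.
    """
    v_pits = pits.v_pits if isinstance(pits, PitsEstimate) else float(pits)
    s5 = float(S.loc[5].sum())
    if not s5 > 0:
        raise ValueError("sum of level-5 relative scores must be positive")
    omega = v_pits / s5
    T = omega * S.astype(float)
    return ValueAlgorithm(T=T, v_pits=v_pits, omega=omega, metadata=metadata or {})


def estimate_algorithm(
    within: pd.DataFrame,
    pits: pd.DataFrame,
    demographics: pd.DataFrame,
    population: pd.DataFrame,
    scheme: str = "crossed",
    complete_case: bool = False,
    min_dead_gap: float = MIN_DEAD_GAP,
    cap: float | None = None,
) -> EstimationResult:
    """Run the full weighted estimation pipeline (weights + Steps 1-4).

    Each of the 15 within-dimension tasks is weighted on gender, age group
    and education; the pits task on gender and age group only (its field
    protocol collects no education).  All 15 dimensions must be present.
    The returned log records completer counts, exclusions, collapses, the
    two pits-task means, ``omega`` and ``V_pits``.
    """
    within = validate_within_responses(within)
    pits = validate_pits_responses(pits)
    demographics = validate_demographics(demographics)

    present = set(within["dimension"])
    missing_dims = [d for d in DIMENSIONS if d not in present]
    if missing_dims:
        raise ValueError(f"no responses for dimension task(s): {missing_dims}")

    score_any = within[list(WITHIN_SCORE_COLUMNS)].notna().any(axis=1)
    completers = {
        dim: within.loc[(within["dimension"] == dim) & score_any, "respondent_id"].tolist()
        for dim in DIMENSIONS
    }
    pits_complete, _ = filter_complete_pits(pits)
    pits_completers = {PITS_TASK: pits_complete["respondent_id"].tolist()}

    w_within = compute_poststrat_weights(
        demographics, population, completers, scheme=scheme,
        variables=("gender", "age_group", "education"), cap=cap,
    )
    w_pits = compute_poststrat_weights(
        demographics, population, pits_completers, scheme=scheme,
        variables=("gender", "age_group"), cap=cap,
    )

    means = weighted_level_means(within, w_within, complete_case=complete_case)
    S = relative_scores(means, min_dead_gap=min_dead_gap)
    pe = pits_estimate(pits, w_pits.for_task(PITS_TASK), min_dead_gap=min_dead_gap)
    algorithm = build_algorithm(
        S, pe, metadata={"source": "estimated from respondent VAS data"}
    )

    log = {
        "scheme": scheme,
        "completers_per_task": {d: len(ids) for d, ids in completers.items()},
        "pits_complete": pe.n_complete,
        "pits_excluded_incomplete": pe.n_excluded,
        "excluded_missing_demographics": sorted(
            set(w_within.excluded) | set(w_pits.excluded)
        ),
        "cell_collapses": {**w_within.collapses, **w_pits.collapses},
        "pits_weight_variables": ["gender", "age_group"],
        "mean_pits": pe.mean_pits,
        "mean_dead_pits_task": pe.mean_dead,
        "mean_dead_by_dimension": means.loc[DEAD].to_dict(),
        "omega": float(algorithm.omega),
        "v_pits": float(algorithm.v_pits),
    }
    return EstimationResult(
        algorithm=algorithm,
        level_means=means,
        relative_scores=S,
        pits=pe,
        weights_within=w_within,
        weights_pits=w_pits,
        log=log,
    )
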