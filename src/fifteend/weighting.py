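"""Post-stratification weights for the valuation tasks.

Each of the 16 valuation tasks (15 within-dimension tasks plus the pits task)
gets its own set of weights, computed over that task's completers only: a
completer in demographic cell ``c`` receives ``w_c = P_pop(c) / P_sample(c)``,
so that the weighted completer composition matches the general population.

Two schemes are supported:

* ``crossed`` (default): cells are the full cross-classification of the
  chosen variables; requires a joint population table.  If a populated cell
  has no completers, adjacent categories are collapsed -- education first,
  then age -- before failing.
* ``marginal``: the weight is the product of one-way ratios
  ``P_pop(v=c) / P_sample(v=c)`` over the chosen variables; with a single
  variable this is plain one-way post-stratification and only needs the
  published population margins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import DEMOGRAPHIC_VARIABLES, validate_demographics

#: Ordered variables eligible for the adjacent-category collapse rule, in the
#: order they are collapsed.  Gender has no adjacency and is never collapsed.
COLLAPSE_ORDER = ("education", "age_group")

ALL_VARIABLES = ("gender", "age_group", "education")


@dataclass
class WeightingResult:
    """Weights plus an audit trail of what happened while computing them."""

    #: long table: task_id, respondent_id, weight (> 0)
    weights: pd.DataFrame
    #: task_id -> list of human-readable collapse events
    collapses: dict[str, list[str]] = field(default_factory=dict)
    #: respondent ids dropped for missing demographic values
    excluded: list = field(default_factory=list)

    def for_task(self, task_id: str) -> pd.Series:
        """Weights for one task as a Series indexed by respondent_id."""
        sub = self.weights[self.weights["task_id"] == task_id]
        return sub.set_index("respondent_id")["weight"]


def weighted_mean(values, weights=None) -> float:
    """Weighted mean over non-missing values.

    ``weights`` defaults to uniform; weights paired with missing values are
    ignored.  Raises if any weight is non-positive or no value is present.
    """
    v = np.asarray(values, dtype=float)
    if weights is None:
        w = np.ones_like(v)
    else:
        w = np.asarray(weights, dtype=float)
    if v.shape != w.shape:
        raise ValueError(f"values and weights differ in length: {v.shape} vs {w.shape}")
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be positive and finite")
    keep = ~np.isnan(v)
    if not keep.any():
        raise ValueError("all values are missing")
    v, w = v[keep], w[keep]
    return float(np.sum(w * v) / np.sum(w))


# --------------------------------------------------------------------------
# Population table handling
# --------------------------------------------------------------------------


def population_margins(population: pd.DataFrame) -> dict[str, pd.Series]:
    """Per-variable population proportions from a marginal or crossed table."""
    margins: dict[str, pd.Series] = {}
    if {"variable", "category", "count"}.issubset(population.columns):
        for var, categories in DEMOGRAPHIC_VARIABLES.items():
            sub = population[population["variable"] == var]
            if sub.empty:
                continue
            counts = sub.set_index("category")["count"].astype(float)
            _check_categories(var, counts.index)
            margins[var] = counts.reindex(categories, fill_value=0.0)
    else:
        cells = population_cells(population, [v for v in ALL_VARIABLES if v in population.columns])
        for var in cells.index.names:
            margins[var] = cells.groupby(level=var).sum().reindex(
                DEMOGRAPHIC_VARIABLES[var], fill_value=0.0
            )
    for var, counts in margins.items():
        if (counts < 0).any():
            raise ValueError(f"negative population count for {var}")
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"population margin for {var} does not normalise")
        margins[var] = counts / total
    return margins


def population_cells(population: pd.DataFrame, variables: Sequence[str]) -> pd.Series:
    """Joint population counts over ``variables`` from a crossed table.

    A marginal (variable/category/count) table cannot supply a joint
    distribution, so passing one raises with a pointer to the marginal scheme.
    """
    if {"variable", "category", "count"}.issubset(population.columns):
        raise ValueError(
            "crossed weighting needs a joint population table with one column "
            "per variable; the marginal layout only supports scheme='marginal'"
        )
    missing = [v for v in variables if v not in population.columns]
    if missing:
        raise ValueError(f"population table is missing variable column(s): {missing}")
    if "count" not in population.columns:
        raise ValueError("population table is missing the 'count' column")
    for var in variables:
        _check_categories(var, population[var])
    cells = population.groupby(list(variables))["count"].sum().astype(float)
    if (cells < 0).any():
        raise ValueError("negative population count")
    if cells.sum() <= 0:
        raise ValueError("population table does not normalise")
    if len(variables) == 1:
        cells.index = pd.MultiIndex.from_arrays([cells.index], names=[variables[0]])
    return cells


def _check_categories(var: str, values: Iterable) -> None:
    allowed = set(DEMOGRAPHIC_VARIABLES[var])
    bad = set(values) - allowed
    if bad:
        raise ValueError(f"unknown {var} categor(ies) in population table: {sorted(bad)}")


# --------------------------------------------------------------------------
# Crossed-cell weighting with adjacent-category collapse
# --------------------------------------------------------------------------


def _initial_groups(variables: Sequence[str]) -> dict[str, list[list[str]]]:
    return {v: [[c] for c in DEMOGRAPHIC_VARIABLES[v]] for v in variables}


def _group_label(group: list[str]) -> str:
    return "+".join(group)


def _category_map(groups: dict[str, list[list[str]]]) -> dict[str, dict[str, str]]:
    return {
        var: {cat: _group_label(g) for g in var_groups for cat in g}
        for var, var_groups in groups.items()
    }


def _grouped_counts(
    cells: pd.Series, groups: dict[str, list[list[str]]], variables: Sequence[str]
) -> pd.Series:
    cmap = _category_map(groups)
    frame = cells.reset_index()
    for var in variables:
        frame[var] = frame[var].map(cmap[var])
    grouped = frame.groupby(list(variables))["count"].sum()
    # canonical ordering: group lists are kept in category order
    order = pd.MultiIndex.from_product(
        [[_group_label(g) for g in groups[v]] for v in variables], names=list(variables)
    )
    return grouped.reindex(order, fill_value=0.0)


def _crossed_task_weights(
    pop_cells: pd.Series,
    sample_cells: pd.DataFrame,
    variables: Sequence[str],
    task_id: str,
) -> tuple[pd.Series, list[str]]:
    """Per-respondent weights for one task, collapsing empty cells as needed."""
    sample_counts = (
        sample_cells.groupby(list(variables)).size().rename("count").astype(float)
    )
    pop = pop_cells.rename("count")
    groups = _initial_groups(variables)
    events: list[str] = []
    while True:
        gp = _grouped_counts(pop, groups, variables)
        gs = _grouped_counts(sample_counts, groups, variables)
        empty = [cell for cell in gp.index if gp[cell] > 0 and gs[cell] == 0]
        if not empty:
            break
        cell = empty[0]
        merged = False
        for var in COLLAPSE_ORDER:
            if var not in variables or len(groups[var]) <= 1:
                continue
            label = cell[list(variables).index(var)]
            gi = next(
                i for i, g in enumerate(groups[var]) if _group_label(g) == label
            )
            other = gi - 1 if gi > 0 else gi + 1
            a, b = sorted((gi, other))
            merged_group = groups[var][a] + groups[var][b]
            events.append(
                f"{task_id}: collapsed {var} "
                f"{_group_label(groups[var][a])} + {_group_label(groups[var][b])}"
            )
            groups[var][a:b + 1] = [merged_group]
            merged = True
            break
        if not merged:
            raise ValueError(
                f"task {task_id!r}: cell {dict(zip(variables, cell))} has "
                "population mass but no completers, and no further collapse "
                "is possible (gender is never collapsed)"
            )
    gp = gp / gp.sum()
    gs = gs / gs.sum()
    cmap = _category_map(groups)
    keys = pd.MultiIndex.from_frame(
        pd.DataFrame({v: sample_cells[v].map(cmap[v]) for v in variables})
    )
    ratios = (gp / gs).reindex(keys).to_numpy()
    return pd.Series(ratios, index=sample_cells.index, name="weight"), events


# --------------------------------------------------------------------------
# Marginal (one-way product) weighting
# --------------------------------------------------------------------------


def _marginal_task_weights(
    margins: dict[str, pd.Series],
    sample_cells: pd.DataFrame,
    variables: Sequence[str],
    task_id: str,
) -> tuple[pd.Series, list[str]]:
    n = len(sample_cells)
    weight = pd.Series(1.0, index=sample_cells.index, name="weight")
    events: list[str] = []
    for var in variables:
        pop = margins[var].copy()
        groups = [[c] for c in DEMOGRAPHIC_VARIABLES[var]]
        while True:
            cmap = {cat: _group_label(g) for g in groups for cat in g}
            gp = pop.groupby(pop.index.map(cmap)).sum()
            gs = sample_cells[var].map(cmap).value_counts().reindex(gp.index, fill_value=0)
            empty = [c for c in gp.index if gp[c] > 0 and gs[c] == 0]
            if not empty:
                break
            if len(groups) <= 1 or var not in COLLAPSE_ORDER:
                raise ValueError(
                    f"task {task_id!r}: {var} category {empty[0]!r} has population "
                    "mass but no completers and cannot be collapsed"
                )
            gi = next(i for i, g in enumerate(groups) if _group_label(g) == empty[0])
            other = gi - 1 if gi > 0 else gi + 1
            a, b = sorted((gi, other))
            events.append(
                f"{task_id}: collapsed {var} "
                f"{_group_label(groups[a])} + {_group_label(groups[b])}"
            )
            groups[a:b + 1] = [groups[a] + groups[b]]
        gp = gp / gp.sum()
        ratio = gp / (gs / n)
        weight *= sample_cells[var].map(cmap).map(ratio)
    return weight, events


# --------------------------------------------------------------------------
# Public entry point
# --------------------------------------------------------------------------


def compute_poststrat_weights(
    demographics: pd.DataFrame,
    population: pd.DataFrame,
    completers: Mapping[str, Iterable],
    scheme: str = "crossed",
    variables: Sequence[str] = ALL_VARIABLES,
    cap: float | None = None,
) -> WeightingResult:
    """Post-stratification weights, one set per task.

    Parameters
    ----------
    demographics
        Respondent table (respondent_id, gender, age_group, education).
        Respondents with a missing value on any weighting variable are
        excluded (and listed in the result); a completer absent from the
        table altogether is an error.
    population
        Either a joint table (one column per variable plus ``count``) or the
        marginal layout (``variable``, ``category``, ``count``).
    completers
        Mapping task_id -> iterable of respondent ids who completed the task.
    scheme
        ``"crossed"`` or ``"marginal"`` (see module docstring).
    variables
        Weighting variables, subset of gender/age_group/education.
    cap
        Optional upper bound applied to the final weights (no trimming by
        default).
    """
    if scheme not in ("crossed", "marginal"):
        raise ValueError(f"unknown weighting scheme: {scheme!r}")
    unknown_vars = [v for v in variables if v not in DEMOGRAPHIC_VARIABLES]
    if unknown_vars:
        raise ValueError(f"unknown weighting variable(s): {unknown_vars}")
    if not variables:
        raise ValueError("at least one weighting variable is required")
    demo = validate_demographics(demographics).set_index("respondent_id")

    usable = demo[list(variables)].dropna()
    excluded = sorted(set(demo.index) - set(usable.index))

    if scheme == "crossed":
        pop_cells = population_cells(population, variables)
    else:
        margins = population_margins(population)
        missing = [v for v in variables if v not in margins]
        if missing:
            raise ValueError(f"population table lacks margin(s) for: {missing}")

    frames: list[pd.DataFrame] = []
    collapses: dict[str, list[str]] = {}
    for task_id, ids in completers.items():
        ids = list(ids)
        if not ids:
            raise ValueError(f"task {task_id!r} has no completers")
        unknown = sorted(set(ids) - set(demo.index))
        if unknown:
            raise ValueError(
                f"task {task_id!r}: completer(s) without demographics: {unknown[:5]}"
            )
        cells = usable.loc[[i for i in ids if i in usable.index]]
        if cells.empty:
            raise ValueError(
                f"task {task_id!r}: no completers with complete demographics"
            )
        if scheme == "crossed":
            w, events = _crossed_task_weights(pop_cells, cells, variables, task_id)
        else:
            w, events = _marginal_task_weights(margins, cells, variables, task_id)
        if cap is not None:
            w = w.clip(upper=cap)
        if events:
            collapses[task_id] = events
        frames.append(
            pd.DataFrame(
                {"task_id": task_id, "respondent_id": w.index, "weight": w.to_numpy()}
            )
        )
    weights = pd.concat(frames, ignore_index=True)
    if (weights["weight"] <= 0).any() or not np.isfinite(weights["weight"]).all():
        raise ValueError("computed weights must be positive and finite")
    return WeightingResult(weights=weights, collapses=collapses, excluded=excluded)
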