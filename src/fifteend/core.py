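"""Domain types and table I/O for 15D health-state valuation.

The 15D is a generic preference-based health-related quality-of-life
instrument.  A health state is a vector ``l = (l1, ..., l15)`` of function
levels, one per dimension, where level 1 is full function and level 5 the
worst.  A *value algorithm* (value set, tariff) is a 15 x 5 look-up table of
disutility decrements ``T[j, i]``; the value of a health state is
``V(l) = 1 - sum_j T[j, l_j]``.

This module fixes the canonical dimension ordering, validates health states
and algorithm tables, reads and writes the CSV/JSON file formats used across
the package, and ships the published Norwegian value algorithm together with
the 2010 Norwegian population margins used for post-stratification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

# --------------------------------------------------------------------------
# Canonical dimension set and closed demographic category sets
# --------------------------------------------------------------------------

#: Canonical dimension order.  All tables, files and level vectors use it.
DIMENSIONS: tuple[str, ...] = (
    "mobility",
    "vision",
    "hearing",
    "breathing",
    "sleep",
    "eating",
    "speech",
    "elimination",
    "usual_activities",
    "mental_function",
    "discomfort",
    "depression",
    "distress",
    "vitality",
    "sexual_activity",
)

N_DIMENSIONS: int = len(DIMENSIONS)

#: Function levels, 1 = best, 5 = worst.
LEVELS: tuple[int, ...] = (1, 2, 3, 4, 5)

#: Row label for the "being dead" anchor in level-score tables.
DEAD: str = "dead"

#: Task identifier for the pits (all-worst state) valuation task; the 15
#: within-dimension tasks are identified by their dimension name.
PITS_TASK: str = "pits"

GENDERS: tuple[str, ...] = ("men", "women")
AGE_GROUPS: tuple[str, ...] = ("18-24", "25-39", "40-59", "60-66", "67+")
EDUCATION_LEVELS: tuple[str, ...] = (
    "no_formal",
    "elementary",
    "high_school",
    "university_ba",
    "university_ma",
)

#: Demographic post-stratification variables and their closed category sets.
#: age_group and education are ordered (used by the empty-cell collapse rule);
#: gender has no meaningful adjacency and is never collapsed.
DEMOGRAPHIC_VARIABLES: dict[str, tuple[str, ...]] = {
    "gender": GENDERS,
    "age_group": AGE_GROUPS,
    "education": EDUCATION_LEVELS,
}

_LEVEL_ROW_LABELS = {f"level_{i}": i for i in LEVELS}

# Export precision for algorithm tables (matches the published table).
TABLE_DECIMALS = 4

# Allowed drift between the stored pits disutility and the level-5 row sum.
# Covers round-off from exporting T at TABLE_DECIMALS precision.
VPITS_TOLERANCE = 1e-3


# --------------------------------------------------------------------------
# Health states
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class HealthState:
    """A 15D health state: one function level (1-5) per dimension.

    Instances are validated on construction; use :func:`validate_health_state`
    for a checked conversion from an arbitrary sequence.
    """

    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) != N_DIMENSIONS:
            raise ValueError(
                f"health state must have {N_DIMENSIONS} levels, got {len(self.levels)}"
            )
        for j, level in enumerate(self.levels):
            if isinstance(level, bool) or not isinstance(level, (int, np.integer)):
                raise ValueError(
                    f"level for dimension '{DIMENSIONS[j]}' (position {j}) "
                    f"is not an integer: {level!r}"
                )
            if not 1 <= int(level) <= 5:
                raise ValueError(
                    f"level for dimension '{DIMENSIONS[j]}' (position {j}) "
                    f"must be in 1..5, got {level}"
                )
        object.__setattr__(self, "levels", tuple(int(v) for v in self.levels))

    @classmethod
    def from_string(cls, digits: str) -> "HealthState":
        """Parse a 15-character digit string such as ``"111112345111111"``."""
        digits = digits.strip()
        if len(digits) != N_DIMENSIONS or not digits.isdigit():
            raise ValueError(
                f"expected a {N_DIMENSIONS}-digit string, got {digits!r}"
            )
        return cls(tuple(int(c) for c in digits))

    def __str__(self) -> str:
        return "".join(str(v) for v in self.levels)

    def __iter__(self) -> Iterator[int]:
        return iter(self.levels)

    def __len__(self) -> int:
        return N_DIMENSIONS


#: The best possible state, level 1 on every dimension (value 1 by anchoring).
PERFECT_HEALTH = HealthState((1,) * N_DIMENSIONS)

#: The worst possible ("pits") state, level 5 on every dimension.
PITS_STATE = HealthState((5,) * N_DIMENSIONS)


def validate_health_state(levels: Sequence[int] | str | HealthState) -> HealthState:
    """Validate a level vector (or 15-digit string) into a :class:`HealthState`.

    Raises :class:`ValueError` naming the first offending entry if the input
    is not a length-15 vector of integers in 1..5.
    """
    if isinstance(levels, HealthState):
        return levels
    if isinstance(levels, str):
        return HealthState.from_string(levels)
    return HealthState(tuple(levels))


# --------------------------------------------------------------------------
# Value algorithms
# --------------------------------------------------------------------------


@dataclass
class ValueAlgorithm:
    """A 15D value algorithm: the disutility look-up table and its anchors.

    Parameters
    ----------
    T
        Disutility decrements, indexed by level (1..5, level-1 row all zero)
        with one column per dimension in canonical order.  A frame with only
        levels 2..5 is accepted; the level-1 row is added as zeros.
    v_pits
        Disutility of the all-worst (pits) state; must equal the level-5 row
        sum of ``T`` within :data:`VPITS_TOLERANCE`.  Defaults to that sum.
    omega
        The rescaling factor that produced ``T`` from within-dimension
        relative scores, if known.  Provenance only; never used for scoring.
    metadata
        Free-form provenance (source description, estimation log, ...).
    """

    T: pd.DataFrame
    v_pits: float | None = None
    omega: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = pd.DataFrame(self.T).copy()
        missing = [d for d in DIMENSIONS if d not in T.columns]
        if missing:
            raise ValueError(f"algorithm table is missing dimension column(s): {missing}")
        extra = [c for c in T.columns if c not in DIMENSIONS]
        if extra:
            raise ValueError(f"algorithm table has unknown column(s): {extra}")
        T = T.loc[:, list(DIMENSIONS)].astype(float)
        T.index = [_coerce_level_label(ix) for ix in T.index]
        if 1 not in T.index:
            T.loc[1] = 0.0
        if sorted(T.index) != list(LEVELS):
            raise ValueError(f"algorithm table rows must be levels 1..5, got {list(T.index)}")
        T = T.sort_index()
        if not np.isfinite(T.to_numpy()).all():
            raise ValueError("algorithm table contains non-finite entries")
        if (T.to_numpy() < 0).any():
            bad = T.columns[(T < 0).any(axis=0)].tolist()
            raise ValueError(f"negative disutility entries in dimension(s): {bad}")
        if not np.allclose(T.loc[1].to_numpy(), 0.0):
            raise ValueError("level-1 disutilities must all be zero")
        T.loc[1] = 0.0
        level5_sum = float(T.loc[5].sum())
        v_pits = level5_sum if self.v_pits is None else float(self.v_pits)
        if abs(v_pits - level5_sum) > VPITS_TOLERANCE:
            raise ValueError(
                f"v_pits={v_pits:.6f} inconsistent with level-5 row sum "
                f"{level5_sum:.6f} (tolerance {VPITS_TOLERANCE})"
            )
        if self.omega is not None and not self.omega > 0:
            raise ValueError(f"omega must be positive, got {self.omega}")
        self.T = T
        self.v_pits = v_pits

    @property
    def level5_sum(self) -> float:
        """Maximum possible disutility, ``sum_j T[j, 5]``."""
        return float(self.T.loc[5].sum())

    def disutility(self, dimension: str, level: int) -> float:
        """Look up a single decrement ``T[j, i]``."""
        return float(self.T.at[level, dimension])

    def rounded(self, decimals: int = TABLE_DECIMALS) -> "ValueAlgorithm":
        """Return a copy with ``T`` rounded to the export precision."""
        T = self.T.round(decimals)
        return ValueAlgorithm(
            T=T, v_pits=float(T.loc[5].sum()), omega=self.omega, metadata=dict(self.metadata)
        )


def _coerce_level_label(label) -> int:
    if isinstance(label, str):
        key = label.strip().lower()
        if key in _LEVEL_ROW_LABELS:
            return _LEVEL_ROW_LABELS[key]
        if key.isdigit():
            return int(key)
        raise ValueError(f"unrecognised level row label: {label!r}")
    return int(label)


def _metadata_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_algorithm_table(
    path: str | Path, metadata_path: str | Path | None = None
) -> ValueAlgorithm:
    """Read a value algorithm from a CSV table plus optional JSON metadata.

    The CSV has a ``level`` index column with rows ``level_2..level_5`` (a
    ``level_1`` row of zeros is also accepted) and one column per dimension in
    canonical order.  The companion JSON, by default the same path with a
    ``.json`` suffix, may carry ``omega``, ``v_pits`` and ``source``; if it is
    absent, ``v_pits`` defaults to the level-5 row sum.
    """
    path = Path(path)
    T = pd.read_csv(path, index_col=0)
    meta_file = Path(metadata_path) if metadata_path is not None else _metadata_path(path)
    omega = None
    v_pits = None
    metadata: dict = {}
    if meta_file.exists():
        with open(meta_file) as fh:
            raw = json.load(fh)
        omega = raw.pop("omega", None)
        v_pits = raw.pop("v_pits", None)
        metadata = raw
    return ValueAlgorithm(T=T, v_pits=v_pits, omega=omega, metadata=metadata)


def write_algorithm_table(algorithm: ValueAlgorithm, path: str | Path) -> Path:
    """Write an algorithm as CSV (4-decimal precision) plus JSON metadata.

    Reading the written pair back and writing it again reproduces both files
    byte for byte.  Returns the metadata path.
    """
    path = Path(path)
    T = algorithm.T.loc[list(LEVELS[1:])].round(TABLE_DECIMALS)
    out = T.copy()
    out.index = [f"level_{i}" for i in out.index]
    out.index.name = "level"
    out.to_csv(path, float_format=f"%.{TABLE_DECIMALS}f")
    meta_file = _metadata_path(path)
    payload = {
        "omega": None if algorithm.omega is None else round(float(algorithm.omega), 6),
        "v_pits": round(float(T.loc[5].sum()), 6),
        **{k: algorithm.metadata[k] for k in sorted(algorithm.metadata)},
    }
    with open(meta_file, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")
    return meta_file


# --------------------------------------------------------------------------
# Packaged reference data
# --------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(resources.files("fifteend").joinpath("data", name))


def norwegian_algorithm() -> ValueAlgorithm:
    """The published Norwegian 15D value algorithm (4-decimal precision).

    Estimated from VAS valuations by the Norwegian general population and
    anchored in an empirically scored all-worst state; values range from 1
    (full health) down to about -0.52.
    """
    return read_algorithm_table(_data_path("norwegian_2018.csv"))


def norwegian_population() -> pd.DataFrame:
    """Marginal demographic counts of the Norwegian adult population (2010).

    Long format: columns ``variable`` (gender / age_group / education),
    ``category`` and ``count``.  Only margins are published, so this fixture
    supports marginal post-stratification exactly; crossed-cell weighting
    needs a joint table.
    """
    return pd.read_csv(_data_path("population_norway_2010.csv"))


def norwegian_sample_margins() -> pd.DataFrame:
    """Marginal demographic counts of the unweighted valuation sample (n=2256)."""
    return pd.read_csv(_data_path("sample_norway_2010.csv"))


# --------------------------------------------------------------------------
# Respondent-level file formats
# --------------------------------------------------------------------------

WITHIN_SCORE_COLUMNS = ("score_L2", "score_L3", "score_L4", "score_L5", "score_dead")
WITHIN_COLUMNS = ("respondent_id", "dimension") + WITHIN_SCORE_COLUMNS
PITS_COLUMNS = ("respondent_id", "score_pits", "score_dead")
DEMOGRAPHICS_COLUMNS = ("respondent_id", "gender", "age_group", "education")


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing column(s): {missing}")


def _check_scores(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    for col in columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        raw_present = df[col].notna()
        if (raw_present & vals.isna()).any():
            raise ValueError(f"{what}: non-numeric entries in {col}")
        bad = vals.dropna()
        if ((bad < 0) | (bad > 100)).any():
            raise ValueError(f"{what}: {col} has VAS scores outside [0, 100]")


def validate_within_responses(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a within-dimension response table (one row per respondent x task).

    Scores are VAS marks in [0, 100]; missing entries are NaN.  Level 1 is
    never stored -- it is fixed at 100 by task design.
    """
    _check_columns(df, WITHIN_COLUMNS, "within-dimension responses")
    unknown = set(df["dimension"]) - set(DIMENSIONS)
    if unknown:
        raise ValueError(f"unknown dimension label(s): {sorted(unknown)}")
    _check_scores(df, WITHIN_SCORE_COLUMNS, "within-dimension responses")
    out = df.copy()
    for col in WITHIN_SCORE_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
    dup = out.duplicated(subset=["respondent_id", "dimension"])
    if dup.any():
        raise ValueError("duplicate (respondent_id, dimension) rows in within responses")
    return out


def validate_pits_responses(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a pits-task response table (one row per respondent)."""
    _check_columns(df, PITS_COLUMNS, "pits responses")
    _check_scores(df, ("score_pits", "score_dead"), "pits responses")
    out = df.copy()
    for col in ("score_pits", "score_dead"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    if out["respondent_id"].duplicated().any():
        raise ValueError("duplicate respondent_id rows in pits responses")
    return out


def validate_demographics(df: pd.DataFrame) -> pd.DataFrame:
    """Validate respondent demographics against the closed category sets.

    Missing values (NaN) are allowed and handled downstream (such respondents
    are excluded from weighting); out-of-set labels are an error.
    """
    _check_columns(df, DEMOGRAPHICS_COLUMNS, "demographics")
    out = df.copy()
    for var, categories in DEMOGRAPHIC_VARIABLES.items():
        col = out[var]
        bad = col.dropna()[~col.dropna().isin(categories)]
        if len(bad):
            raise ValueError(
                f"demographics: unknown {var} categor(ies) {sorted(set(bad))}; "
                f"allowed: {list(categories)}"
            )
    if out["respondent_id"].duplicated().any():
        raise ValueError("duplicate respondent_id rows in demographics")
    return out


def read_within_responses(path: str | Path) -> pd.DataFrame:
    return validate_within_responses(pd.read_csv(path))


def read_pits_responses(path: str | Path) -> pd.DataFrame:
    return validate_pits_responses(pd.read_csv(path))


def read_demographics(path: str | Path) -> pd.DataFrame:
    return validate_demographics(pd.read_csv(path))


def read_health_states(path: str | Path) -> list[HealthState]:
    """Read health states from CSV in either supported layout.

    Either 15 per-dimension level columns (canonical names) or a single
    ``state`` column of 15-digit strings.
    """
    df = pd.read_csv(path, dtype={"state": str})
    if "state" in df.columns:
        return [HealthState.from_string(s) for s in df["state"]]
    _check_columns(df, DIMENSIONS, "health-state file")
    return [
        validate_health_state([int(row[d]) for d in DIMENSIONS])
        for _, row in df.iterrows()
    ]


def write_health_states(states: Iterable[HealthState], path: str | Path) -> None:
    pd.DataFrame({"state": [str(s) for s in states]}).to_csv(path, index=False)
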