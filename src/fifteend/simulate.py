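"""Synthetic valuation-survey generator with known ground truth.

Emulates the data the estimation pipeline expects: per-respondent VAS scores
for the 15 within-dimension tasks and the pits task, plus demographics drawn
from population margins.  The construction inverts the estimation algebra --
each respondent places "dead" at ``d`` on their task's VAS and marks level
``i`` of dimension ``j`` at ``100 - S[j,i] * (100 - d)`` plus truncated
Gaussian response noise -- so with zero noise the pipeline recovers the truth
table exactly, and with noise the recovery error shrinks as ``1/sqrt(n)``.

A truth :class:`~fifteend.core.ValueAlgorithm` only pins down the relative
scores ``S`` up to a positive scale (estimation is scale-invariant in ``S``),
so the generator uses ``S = T / omega`` when the truth table stores its
rescaling factor, and otherwise normalises ``S`` so the level-5 scores sum
to 15 (mean level-5 score 1, i.e. a typical worst level rated at "dead").

Optional realism knobs: per-cell missingness, a point mass of respondents
scoring both pits and dead at zero, education-dependent "dead" placement,
and education-dependent preference scaling.  Note that a uniform scalar
preference scale cancels out of the estimated table (Step 4 renormalises),
so to make demographic weighting matter the scaling must change the shape
of preferences: restrict it to a subset of dimensions via
``scaled_dimensions``.  The pits severity is scaled consistently with the
respondent's within-dimension preferences.

All randomness flows from one integer seed through named
``numpy.random.SeedSequence`` children (demographics, within, pits,
pits_demographics), so each sub-stream is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DIMENSIONS,
    N_DIMENSIONS,
    ValueAlgorithm,
    norwegian_population,
)
from .weighting import population_margins

_STREAMS = ("demographics", "within", "pits", "pits_demographics")


@dataclass
class GeneratorConfig:
    """Study conditions for one simulated valuation survey.

    Defaults mirror the Norwegian study layout: 2256 within-dimension
    respondents, 120 pits-task respondents, demographics drawn from the 2010
    population margins, VAS response noise of 10 units, and "dead" placed at
    40 on the 0-100 scale.
    """

    truth: ValueAlgorithm
    seed: int
    n_respondents: int = 2256
    n_pits: int = 120
    noise_sd: float = 10.0
    dead_location: float | Mapping[str, float] = 40.0
    missing_rate: float = 0.0
    zero_mass: float = 0.0
    demographics_margins: pd.DataFrame | None = None
    preference_scale_by_education: Mapping[str, float] | None = None
    scaled_dimensions: tuple[str, ...] | None = None
    s_table: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.n_respondents <= 0 or self.n_pits <= 0:
            raise ValueError("sample sizes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.zero_mass <= 1:
            raise ValueError("zero_mass must be in [0, 1]")
        for loc in self._dead_locations().values():
            if not 0 <= loc < 100:
                raise ValueError(f"dead_location {loc} outside [0, 100)")

    def _dead_locations(self) -> dict[str, float]:
        if isinstance(self.dead_location, Mapping):
            return {k: float(v) for k, v in self.dead_location.items()}
        return {"__default__": float(self.dead_location)}

    def dead_location_for(self, education: pd.Series) -> np.ndarray:
        locs = self._dead_locations()
        default = locs.get("__default__", next(iter(locs.values())))
        return education.map(lambda e: locs.get(e, default)).to_numpy(dtype=float)

    def preference_scale_for(self, education: pd.Series) -> np.ndarray:
        scales = self.preference_scale_by_education or {}
        return education.map(lambda e: float(scales.get(e, 1.0))).to_numpy(dtype=float)

    def dimension_scale_for(self, education: pd.Series, dimension: str) -> np.ndarray:
        """Per-respondent multiplier on ``S[dimension, :]``."""
        if self.scaled_dimensions is not None and dimension not in self.scaled_dimensions:
            return np.ones(len(education))
        return self.preference_scale_for(education)

    def pits_scale_for(self, education: pd.Series, S: pd.DataFrame) -> np.ndarray:
        """Per-respondent multiplier on the true pits severity.

        Consistent with the within-dimension scaling: scaling dimensions D by
        c multiplies the total level-5 severity, hence the pits disutility,
        by ``1 + (c - 1) * sum_{j in D} S[j,5] / sum_j S[j,5]``.
        """
        s5 = S.loc[5]
        scaled = (
            list(S.columns)
            if self.scaled_dimensions is None
            else [d for d in S.columns if d in self.scaled_dimensions]
        )
        frac = float(s5[scaled].sum()) / float(s5.sum())
        return 1.0 + (self.preference_scale_for(education) - 1.0) * frac

    def relative_scores_truth(self) -> pd.DataFrame:
        """The generator's true relative-score table ``S`` (levels 1..5)."""
        if self.s_table is not None:
            S = self.s_table.astype(float).sort_index()
        else:
            T = self.truth.T
            if self.truth.omega is not None:
                S = T / float(self.truth.omega)
            else:
                S = T * (N_DIMENSIONS / float(T.loc[5].sum()))
        return S

    def v_pits_truth(self) -> float:
        return float(self.truth.v_pits)


@dataclass
class SimulatedData:
    within: pd.DataFrame
    pits: pd.DataFrame
    demographics: pd.DataFrame
    truth: ValueAlgorithm
    s_table: pd.DataFrame


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def _truncnorm(
    rng: np.random.Generator, loc: np.ndarray, scale: float, low: float, high: float
) -> np.ndarray:
    loc = np.asarray(loc, dtype=float)
    if scale == 0:
        return np.clip(loc.copy(), low, high)
    a = (low - loc) / scale
    b = (high - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, random_state=rng)


def _margins(config: GeneratorConfig) -> dict[str, pd.Series]:
    table = (
        config.demographics_margins
        if config.demographics_margins is not None
        else norwegian_population()
    )
    return population_margins(table)


def generate_demographics(
    config: GeneratorConfig,
    n: int | None = None,
    id_prefix: str = "r",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw respondent demographics from the configured population margins.

    Variables are drawn independently (the joint population distribution is
    not published); crossed cells arise implicitly.  Same seed, same output.
    """
    if rng is None:
        rng = _rngs(config.seed)["demographics"]
    n = config.n_respondents if n is None else n
    margins = _margins(config)
    data = {"respondent_id": [f"{id_prefix}{i:05d}" for i in range(1, n + 1)]}
    for var, props in margins.items():
        data[var] = rng.choice(props.index.to_numpy(), size=n, p=props.to_numpy())
    return pd.DataFrame(data)


def generate_within_responses(
    config: GeneratorConfig, demographics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Simulate the 15 within-dimension tasks for every respondent.

    For respondent ``r`` on task ``j``: dead score ``d`` ~ truncated normal
    at the respondent's dead location, then level scores
    ``clip(100 - S[j,i] * scale_r * (100 - d) + eps, 0, 100)``
    with ``eps`` ~ N(0, noise_sd).  With ``noise_sd = 0`` this inverts the
    relative-score formula exactly (as long as no clipping binds).  Each
    score cell is independently missing with probability ``missing_rate``.
    """
    rngs = _rngs(config.seed)
    if demographics is None:
        demographics = generate_demographics(config, rng=rngs["demographics"])
    rng = rngs["within"]
    S = config.relative_scores_truth()
    n = len(demographics)
    dead_loc = config.dead_location_for(demographics["education"])
    frames = []
    for dim in DIMENSIONS:
        scale = config.dimension_scale_for(demographics["education"], dim)
        d = _truncnorm(rng, dead_loc, config.noise_sd, 0.0, 100.0)
        cols = {"respondent_id": demographics["respondent_id"].to_numpy(), "dimension": dim}
        for level in (2, 3, 4, 5):
            eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
            s = np.clip(100.0 - float(S.at[level, dim]) * scale * (100.0 - d) + eps, 0.0, 100.0)
            cols[f"score_L{level}"] = s
        cols["score_dead"] = d
        frames.append(pd.DataFrame(cols))
    within = pd.concat(frames, ignore_index=True)
    if config.missing_rate > 0:
        score_cols = ["score_L2", "score_L3", "score_L4", "score_L5", "score_dead"]
        mask = rng.random((len(within), len(score_cols))) < config.missing_rate
        for k, col in enumerate(score_cols):
            within.loc[mask[:, k], col] = np.nan
    return within


def generate_pits_responses(
    config: GeneratorConfig, demographics: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Simulate the pits task: all-worst state and "dead" on one VAS.

    ``score_pits = clip(100 - V_pits * scale_r * (100 - d) + eps, 0, 100)``.
    With ``V_pits > 1`` some respondents rate the all-worst state below
    "dead", as observed in real data.  A ``zero_mass`` fraction scores both
    at exactly zero (a documented response style in the field sample).
    """
    rngs = _rngs(config.seed)
    if demographics is None:
        demographics = generate_demographics(
            config, n=config.n_pits, id_prefix="p", rng=rngs["pits_demographics"]
        )
    rng = rngs["pits"]
    n = len(demographics)
    dead_loc = config.dead_location_for(demographics["education"])
    scale = config.pits_scale_for(demographics["education"], config.relative_scores_truth())
    d = _truncnorm(rng, dead_loc, config.noise_sd, 0.0, 100.0)
    eps = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    s_pits = np.clip(100.0 - config.v_pits_truth() * scale * (100.0 - d) + eps, 0.0, 100.0)
    pits = pd.DataFrame(
        {
            "respondent_id": demographics["respondent_id"].to_numpy(),
            "score_pits": s_pits,
            "score_dead": d,
        }
    )
    if config.zero_mass > 0:
        at_zero = rng.random(n) < config.zero_mass
        pits.loc[at_zero, ["score_pits", "score_dead"]] = 0.0
    if config.missing_rate > 0:
        mask = rng.random((n, 2)) < config.missing_rate
        pits.loc[mask[:, 0], "score_pits"] = np.nan
        pits.loc[mask[:, 1], "score_dead"] = np.nan
    return pits


def simulate_dataset(config: GeneratorConfig) -> SimulatedData:
    """Generate a complete, mutually consistent survey dataset.

    Within-task respondents get ids ``r00001...``; the (separate) pits-task
    sample gets ids ``p00001...``.  The returned demographics table covers
    both samples.
    """
    rngs = _rngs(config.seed)
    demo_within = generate_demographics(config, rng=rngs["demographics"])
    demo_pits = generate_demographics(
        config, n=config.n_pits, id_prefix="p", rng=rngs["pits_demographics"]
    )
    within = generate_within_responses(config, demo_within)
    pits = generate_pits_responses(config, demo_pits)
    return SimulatedData(
        within=within,
        pits=pits,
        demographics=pd.concat([demo_within, demo_pits], ignore_index=True),
        truth=config.truth,
        s_table=config.relative_scores_truth(),
    )
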