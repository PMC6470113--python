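# Methods

## Model

A 15D health state is a vector `l = (l1, …, l15)` of function levels over
the instrument's 15 dimensions, level 1 best and level 5 worst. Values are
modelled additively:

```
V(l) = 1 − Σⱼ T[j, lⱼ],        T[j, 1] = 0 for every dimension j.
```

Additivity assumes the dimensions are structurally independent — no
interaction terms. The one place interactions can enter is the anchor: the
all-worst ("pits") state is valued directly as a whole, and its empirical
disutility `V_pits` fixes the scale. Value and disutility are duals
(`v = 1 − u`), so the table can be read as value losses.

The estimation procedure has four steps, run on post-stratification-weighted
VAS data:

1. **Level means.** For each dimension `j` and level `i ∈ {2..5, dead}`, the
   weighted mean `s̄ᵢʲ` of the raw 0–100 VAS scores from that dimension's
   task. Level 1 is 100 by task design and is never elicited.
2. **Relative scores.** `S[j,i] = (100 − s̄ᵢʲ) / (100 − s̄_deadʲ)`. Each
   dimension is normalised by its *own* dead mean (no pooling across tasks);
   the pits task likewise uses its own dead mean. `S` may exceed 1 when a
   level is rated below dead.
3. **Pits anchor.** `V_pits = (100 − s̄_pits) / (100 − s̄_dead)` over
   complete pits responses only (a response missing either score is excluded
   and counted).
4. **Rescaling.** `ω = V_pits / Σⱼ S[j,5]`, `T = ω·S`. By construction the
   level-5 row of `T` sums to `V_pits`, so values span `[1 − V_pits, 1]`
   with full health exactly 1.

`ω` is always computed from the data. The published Norwegian constant
(0.113, stored as provenance metadata with the packaged table) is a rounded
value and does not exactly reproduce the table's internal ratios; scoring
never uses it.

## Weighting

Weights are per task: for each of the 15 within-dimension tasks and the pits
task separately, a completer in demographic cell `c` receives
`P_pop(c) / P_sample,task(c)`.

* **Crossed scheme** (default): cells are the full gender × age-group ×
  education cross-classification; it needs a joint population table. Only
  marginal counts are published for the Norwegian population, so crossed
  weighting is exercised on synthetic joint tables.
* **Marginal scheme**: the weight is the product of one-way
  population-to-sample ratios over the chosen variables; with one variable
  it is plain one-way post-stratification. This is the scheme usable with
  the packaged margins. It matches crossed weighting exactly when the
  weighting-relevant heterogeneity loads on a single variable, and is not
  raking (no iterative fitting; the weighted margins beyond the first
  variable are only approximately matched).
* **Empty cells**: a populated cell with no completers triggers a
  deterministic adjacent-category collapse — education first, then age;
  gender is never collapsed (no adjacency), so an empty gender cell is an
  error. Collapse events are reported in the weighting result and the
  estimation log.
* The pits task is weighted on gender × age group only, because its field
  protocol collects no education; the estimation log records this.
* No weight trimming by default; an optional cap is available. Respondents
  with a missing weighting variable are excluded from weighting (and hence
  estimation) and listed in the log.

Item-level missingness in a within-dimension task is handled availably by
default: a respondent contributes to the level cells they answered.
Complete-case-per-task is available behind `complete_case=True`.

## Numerical choices

* Raw scores outside [0, 100] are rejected at validation; no winsorising.
* A mean dead score within 1 VAS unit of 100 (configurable `min_dead_gap`)
  is an error, not a clamp — the relative-score denominator would explode.
* No rounding inside the pipeline; tables are exported at 4 decimals (the
  published precision) and the CSV/JSON pair round-trips byte-identically.
* Ranking ties (equal level-5 decrements) break by canonical dimension
  order. Percentile curves use equal-count bins on sorted values, remainder
  spread over the leading bins — the binning behind published mean-value-by-
  percentile figures is not specified, so this deterministic choice is our
  own.
* Scoring applies the table as published (4 decimals) when the packaged
  algorithm is used; estimated algorithms score at full precision.
* Health states with missing levels are rejected; `batch_score` has a
  permissive mode that scores valid rows and flags the rest, but no
  imputation is performed.

## Synthetic-respondent generator

No respondent-level valuation data are public, so validation runs on
simulated surveys with known ground truth. The generator inverts the
estimation algebra: a respondent places dead at `d` (truncated normal on
[0, 100) around `dead_location`) and marks level `i` of dimension `j` at
`clip(100 − S[j,i]·(100 − d) + ε, 0, 100)` with `ε ~ N(0, noise_sd)`; the
pits task uses `V_pits` in place of `S[j,i]`. With zero noise and no
clipping this makes Steps 1–3 the exact inverse of the construction, which
is what the round-trip tests exploit.

Defaults mirror the study layout and are fixed once:

* `n_respondents = 2256` within-task respondents, `n_pits = 120`;
* demographics drawn independently per variable from the 2010 Norwegian
  population margins (the joint distribution is not published; a joint
  override is accepted);
* `noise_sd = 10` VAS units — a realistic magnitude for VAS placement error;
* `dead_location = 40` — with the Norwegian truth (`V_pits ≈ 1.516`) this
  puts the noise-free pits score at `100 − 1.516·60 ≈ 9`, i.e. an
  all-worst state rated below dead without clipping;
* no missingness and no zero-point-mass by default; both are available
  (`missing_rate`, `zero_mass`) to emulate incomplete responses and the
  respondents who pin both pits and dead at 0.

A truth table only determines `S` up to a positive scale (Step 4
renormalises), so the generator uses `S = T/ω` when the truth stores its
rescaling factor and otherwise normalises `Σⱼ S[j,5] = 15`.

Two heterogeneity knobs exist for weighting experiments. Education-dependent
`dead_location` shifts where groups anchor dead, but — a direct consequence
of Step 2 — it does **not** move `S` and therefore cannot make weighting
matter on its own. What does is education-dependent *preference* scaling
restricted to a subset of dimensions (`preference_scale_by_education` +
`scaled_dimensions`): a uniform scalar scale also cancels in Step 4, so the
scaling must change the preference profile. The pits severity is scaled
consistently (`1 + (c−1)·Σ_{j∈D} S[j,5]/Σⱼ S[j,5]`). Under this design the
population-mixture truth is `T_mix[j,i] = E_pop[c_j]·T[j,i]`, and weighted
estimates are provably (and testably) closer to it than unweighted ones on
skewed samples.

All randomness flows from one integer seed through named
`SeedSequence` children (demographics, within, pits, pits_demographics), so
any sub-stream reproduces independently.

### What the generator does not emulate

Score heaping at multiples of 5/10 and end-aversion, mode effects
(web vs postal task presentation), within-respondent correlation of errors
across tasks, and any joint demographic structure beyond independent
margins. Passing tests therefore show the pipeline is algebraically correct
and statistically consistent under a clean response model — not that the
procedure is robust to every response style in real field data.

### Recovery behaviour under noise

With `noise_sd = 10`, clipping at the VAS floor biases the pits mean upward
(the noise-free pits score sits near 9), which puts a small bias floor of
roughly 0.003 per cell under the estimated table. Per-cell RMSE therefore
decays with the per-task sample size in its variance component and flattens
toward that floor: across seeds, mean RMSE falls monotonically over
n = 250 → 1000 → 4000, but single-seed realisations at adjacent n can
cross. Tests of the decay therefore average RMSE over a fixed block of
seeds. The validation runs use n up to 4000 per task and 10 seeds, sizes
chosen to keep the whole suite fast while leaving the monotone decay
clearly resolved.

## Known limitations

* Whether the original field study crossed or raked its weighting cells is
  not public; crossed weighting on a joint table may differ from the
  published weights. The marginal scheme is exact for the published margins.
* The population margins start at age 16 while valuation samples start at
  18; the 18–24 weight therefore slightly overcorrects, and no adjustment is
  attempted.
* `V_pits` is a ratio of means, not a mean of ratios; respondent-level
  worse-than-dead heterogeneity is summarised only through the two task
  means, as in the estimation procedure itself.
* No uncertainty quantification (bootstrap CIs for `T`) is provided.
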