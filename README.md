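# fifteend

Tools for estimating and applying **15D value algorithms** from visual
analogue scale (VAS) valuation data.

The 15D is a generic preference-based health-related quality-of-life
instrument: a health state is a vector `l = (l1, …, l15)` of function levels
(1 = best, 5 = worst) over 15 dimensions (mobility, vision, hearing, …,
sexual activity). For use in QALY calculations each state needs a value on a
scale where full health is 1 and "being dead" is 0. A *value algorithm*
(value set, tariff) is a 15 × 5 look-up table of disutility decrements
`T[j, i]`; the value of a state is the additive form

```
V(l) = 1 − Σⱼ T[j, lⱼ]
```

This package implements the estimation procedure that turns raw VAS survey
responses into such a table, anchored in an empirically scored all-worst
("pits") state:

1. **Weighted level means** — per (dimension, level) weighted mean VAS score
   over the within-dimension tasks (levels L2–L5 and "being dead"; L1 is
   fixed at 100). Each of the 16 tasks gets its own post-stratification
   weights so completers match the general-population margins.
2. **Relative scores** — `S[j,i] = (100 − s̄ᵢʲ) / (100 − s̄_deadʲ)`, a
   within-dimension disutility on a dead-= 1 scale (values above 1 mean the
   level was rated below dead).
3. **Pits anchor** — `V_pits = (100 − s̄_pits) / (100 − s̄_dead)` from the
   pits task, after excluding incomplete responses.
4. **Rescaling** — `ω = V_pits / Σⱼ S[j,5]` and `T[j,i] = ω·S[j,i]`, so
   values span `[1 − V_pits, 1]`.

It also ships the published **Norwegian value algorithm** (whose values run
from 1 down to −0.52) and the 2010 Norwegian population margins as packaged
reference data, a scoring engine, and a seeded synthetic-respondent
simulator that generates surveys with known ground truth for validation.

Intended users: health economists and HRQoL researchers running or auditing
15D valuation studies, and analysts scoring 15D descriptive-system data.

## Worked example

```python
import fifteend as f

algo = f.norwegian_algorithm()

print(f.score_state(f.PERFECT_HEALTH, algo).value)   # 1.0
print(f.score_state(f.PITS_STATE, algo).value)       # -0.5157999999999998
print(f.score_state((2,) + (1,)*14, algo).value)     # 0.9643  (mobility at level 2)

info = f.algorithm_summary(algo)
print(info["value_range"])      # (-0.5157999999999998, 1.0)
print(info["largest_level5"])   # ('mobility', 0.1083)
print(info["smallest_level5"])  # ('hearing', 0.0959)
```

Full health scores exactly 1; the all-worst state scores 1 − 1.5158 ≈ −0.52,
the empirically anchored lower end of the Norwegian value range. Mobility
carries the largest level-5 decrement, hearing the smallest.

Round-trip validation from the shell (simulate a noise-free survey from the
Norwegian truth table, re-estimate it, verify exact recovery):

```sh
fifteend demo --seed 1 --out-dir demo_out
# round trip ok: max |T_hat - T| = 4.16e-17, V_pits = 1.5158, ...
```

Other subcommands: `simulate`, `weights`, `estimate`, `score`, `summary`
(see `fifteend --help`).

## Scope

The original three-task 15D estimation procedure (top/bottom tasks with
linear extrapolation), value sets of other instruments, and QALY aggregation
over time are out of scope. See `docs/methods.md` for the model's
assumptions, the generator's design and known limitations.
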