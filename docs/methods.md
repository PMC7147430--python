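# Methods

## Models

Both models are population-based threshold models. Seed `i` germinates at
water potential `Ψ` only if `Ψ` exceeds its base water potential `Ψ_b,i`,
and the time it takes is set by accumulating the excess:

- **Hydrotime (HT), one temperature.** `t_i = θ_H / (Ψ − Ψ_b,i)` with
  `Ψ_b,i ~ N(Ψ_b(50), σ_Ψb²)`. Parameters: `θ_H` (MPa d), `Ψ_b(50)` (MPa),
  `σ_Ψb` (MPa).
- **Hydrothermal time (HTT), pooled.** Below the optimum temperature,
  `t_i = θ_HT / ((T − T_b)(Ψ − Ψ_b,i))`. Above it the threshold shifts:
  `Ψ_b,i → Ψ_b,i + K_T (T − T_o)`, and the thermal factor is frozen at
  `(T_o − T_b)` — the convention that the threshold distribution and the
  thermal time are those prevailing at `T_o`. The alternative reading, an
  actual `(T − T_b)` factor in the supra-optimal branch, is available
  everywhere via `supra_thermal="actual"`; the two agree at `T = T_o` and
  differ only in supra-optimal speed, not in FGP or in `T_c(g)`.

The ceiling temperature follows in closed form:
`T_c(g) = T_o + (Ψ − Ψ_b(g))/K_T`, so in water
`T_c(50) = T_o − Ψ_b(50)/K_T`.

## Likelihood and fitting

Every (dish × scoring day) cell is one binomial observation: cumulative
germinated count out of seeds sown, success probability
`Φ(intercept + slope · x)` with predictor

- HT: `x = Ψ − θ_H/t`,
- HTT sub-optimal: `x = Ψ − θ_HT/((T − T_b)·t)`,
- HTT supra-optimal: `x = Ψ − θ_HT/((T_o − T_b)·t) − K_T (T − T_o)`,

so `Ψ_b(50) = −intercept/slope` and `σ_Ψb = 1/slope`. Replicates are
pooled, not averaged; all-zero early cells stay in the likelihood (they are
informative about thresholds); `t` for a cell is the scoring day itself, the
right endpoint of its censoring interval. Scoring-day counts within a dish
are treated as independent binomials — the standard repeated-probit
approximation for these models; it understates standard errors but leaves
point estimates consistent, and the package reports no probit standard
errors.

The inner probit regression is Fisher-scoring Newton on the exact binomial
log-likelihood (step-halving, convergence 1e-8 on the log-likelihood,
Nelder-Mead fallback). Completely separated data — all-0 fractions below
some `x`, all-1 above — have no finite optimum; the fit is returned flagged
`converged=False` rather than raising, since profiled searches may pass
through such corners. Fractions of exactly 0 or 1 enter the likelihood but
are excluded from the reported R² (probit is undefined there); R² is the
squared Pearson correlation between observed and fitted probit-transformed
fractions, a diagnostic only — different software computes probit R²
differently, so cross-package R² comparisons are not meaningful. No
overdispersion correction is applied.

Profiling:

- `θ_H` (and `θ_HT` at fixed `T_b`): golden-section search, default bounds
  [0.05, 50] MPa d (HT) and [0.5, 500] MPa °C d (HTT), refined to 1e-3, ties
  toward the smaller constant. The profiled likelihood is unimodal in the
  constant in practice; a bounded deterministic search is exactly
  reproducible.
- `T_b`: grid at 0.1 °C on [0 °C, min(T) − 0.5 °C]. The default search is
  two-stage (coarse 1 °C pass, then the full 0.1 °C resolution within
  ±1.5 °C of the coarse optimum); the profiled likelihood in `T_b` is smooth
  and unimodal on this model family, so the result matches the exhaustive
  grid (tested) at about a third of the cost. `t_b_search="exhaustive"`
  forces the full grid. A boundary optimum is flagged and warned about.
- `(T_o, K_T)`: grid search, `T_o` at 0.1 °C between the largest
  sub-optimal and smallest supra-optimal tested temperature (outside that
  interval `T_o` is not identified by the design), `K_T` on (0, 1] at 0.01
  MPa °C⁻¹, with `θ_HT`, `T_b` fixed from the sub-optimal fit. Among
  candidate pairs whose implied `Ψ_b(50)` and `σ_Ψb` match the sub-optimal
  estimates within |ΔΨ_b(50)| ≤ 0.02 MPa and |Δσ| ≤ 0.05 MPa, the
  likelihood-best pair wins; if none match, the overall best is returned
  with `supra_match_ok=False`. Exact matching is deliberately not enforced:
  fitted sub- and supra-optimal σ differ in practice (e.g. 0.28 vs 0.32 MPa
  on real data of this kind).
- The full-factorial wrapper partitions sub/supra at the tested temperature
  with the highest mean final germination percentage (FGP); the boundary
  temperature goes to the sub-optimal branch (`classify_branch(T_o) = sub`),
  and the final `T_o` comes from the supra-optimal search.

## Synthetic data generator

The generator is the exact forward model of the fitted likelihood: one
normal `Ψ_b` draw per seed, deterministic germination time given the draw
(no extra timing noise), interval censoring at the scoring grid (a seed
germinating in `(d−1, d]` is scored on day `d`). Defaults emulate the study
protocol the package targets: 5 temperatures (11, 15, 20, 24, 28 °C) ×
4 water potentials (0, −0.2, −0.4, −0.6 MPa) × 4 replicate dishes ×
100 seeds, daily scoring, termination after 3 consecutive zero-germination
days, 60-day cap. Each dish draws from an independent RNG stream keyed by
(seed, condition index, replicate index), so identical configurations are
byte-identical regardless of execution order.

One protocol reading is deliberate: the three-zero-day termination clock
starts only after the first germination event in a dish. Applied literally
from day 1 it would terminate every slow dish (at 11 °C the fastest latent
times under realistic parameters are ~8 days) at day 3 with zero counts,
which contradicts how such assays are actually run and recorded.

What the generator does *not* emulate: seed mortality and fungal loss,
secondary-dormancy induction at high `T`/low `Ψ`, timing noise beyond the
threshold distribution, light effects, and drift of PEG solutions between
refreshes. Parameter-recovery results therefore show that the fitting
machinery inverts the model it states, under the study's design and
censoring — not that real germination data satisfy the model.

## Numerical choices and degenerate inputs

- Time-to-fraction interpolation is piecewise-linear on cumulative fraction
  vs day, with an implicit (day 0, fraction 0) point; the first scoring day
  attaining the fraction exactly is returned as-is. The choice is recorded
  in output metadata via the run-config record.
- "Never germinates" is represented as `inf` (`seedhtt.NEVER`), never as an
  exception; predictions at `T ≤ T_b`, at/above `T_c(g)`, or at/below the
  (shifted) threshold return it. A float tolerance of 1e-12 on the
  supra-optimal margin absorbs rounding at the exact ceiling.
- `normalize_time` rejects percentiles with `|Ψ_b(g)| < 1e-12` (the
  normalization factor `1 − Ψ/Ψ_b(g)` degenerates when the threshold sits
  at pure water).
- Non-identifiable inputs fail loudly: a single temperature in the pooled
  fit (`T_b` and `θ_HT` confounded — use the HT fit), fewer than two water
  potentials, a vanishing probit slope (no threshold signal).

## Problem sizes

Recovery experiments (tests and `scripts/acceptance.py`) use the full study
design — 4 dishes × 100 seeds per condition — and report medians over 20
replicate simulations; single fits take seconds, the full acceptance run
about two minutes on one CPU. Oracle-equivalence checks run on deliberately
tiny instances (8 binomial cells) where exhaustive grid enumeration of the
likelihood is feasible.

## Known limitations

- Interval censoring biases the profiled constants slightly upward (the
  right-endpoint `t` overstates each seed's true germination time by up to
  one scoring interval); with daily scoring and median times of 4–16 days
  the bias is a few percent, well inside the recovery tolerances, and it
  shrinks with finer scoring.
- `T_o` is only localised between the tested temperatures bracketing the
  FGP maximum; designs with a coarse temperature grid bound it loosely.
- The models carry no dormancy dynamics: time-varying `Ψ_b(50)`
  (after-ripening, priming) and thermal-time-only variants are out of scope.
- R² values are diagnostics with a package-specific convention (see above).
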