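# Methods

## The optimization problem

The decision vector is the daily intake `Q_i ≥ 0` (grams) of each food
item in a fixed nomenclature.  All diet properties used anywhere in the
package — energy, nutrient totals, weight, GHGE — are linear in `Q`, so
every model is an LP and the reported optimum is global.

**Objective.**  `f = Σ_i |Q_i − Q_i^obs| / Q_i^obs` over items with a
positive observed intake.  The absolute value is linearized with one
auxiliary variable `d_i ≥ ±(Q_i − Q_i^obs)/Q_i^obs` per item, which is
exact for an LP; no smoothing is applied.  Items observed at zero have an
undefined relative change: by default they are excluded from the objective
but remain decision variables inside their acceptability box
(`zero_obs_policy="exclude"`); the `"epsilon"` policy instead divides by a
0.1 g floor.  The percent-based diagnostics in `metrics` use the same
exclusion so the objective and the reported statistics agree.

**Nutritional constraints.**  32 bounds per gender from the
recommendation table in `constraints.py` (a range row contributes a lower
and an upper bound).  Three bound kinds:

* *absolute* — daily amount in the nutrient's own unit (g, mg, µg, µg RE);
* *per kg body weight* — protein ≥ 0.83 g/kg/day, scaled by the profile's
  body weight;
* *percent of energy* — carbohydrates (45–60 %E), fats (20–35 %E),
  SFA (<10 %E), free sugars (<10 %E).  A %E bound is nonlinear in `Q` in
  general, but total energy is pinned to its observed value by an
  acceptability constraint, so nutrient energy is bounded against
  `(bound/100) × E_obs` — linear, and equivalent up to the width of the
  energy band.  Nutrient energy uses fixed Atwater factors: 4 kcal/g for
  carbohydrate, protein and free sugars, 9 kcal/g for fat and SFA,
  7 kcal/g for alcohol (configurable constants).

The vitamin B6 range is carried in mg/day (1.1–25 women, 1.5–25 men),
the unit in which adult reference values for B6 are customarily stated.

**Acceptability constraints.**  Total weight within ±20% of observed;
per-item and per-L1-group boxes between the 10th percentile over the whole
population and the 90th among consumers; the solid/liquid weight ratio
fixed at its observed value; energy fixed at its observed value; intakes
of alcoholic beverages, fish oil and offal capped at observed amounts
(read as maxima, not equalities).  Two equalities are emitted as narrow
two-sided bands rather than exact equalities — energy at ±0.1% relative
and the solid/liquid ratio at ±1% — because exact float equality makes
LPs spuriously infeasible; the bands are configuration constants in
`constraints.py`.  The ratio is linearized exactly as
`Σ_solid Q − r_obs Σ_liquid Q = 0` and is rejected as degenerate when the
observed diet has zero weight in either phase.

**Environmental constraint and the ladder.**  `Σ Q_i g_i ≤ (1−ρ) GHGE_obs`.
`run_ladder` solves ρ = 0 (NUTR), then 10%, 20%, … with a fixed default
step of 10% (overridable for testing).  Feasible regions are nested in ρ,
so the scan stops at the first infeasible step; that step is kept in the
result as the infeasibility marker.  NUTR-GHGE-MINI minimizes `Σ Q_i g_i`
directly.  By default it keeps the acceptability constraints alongside the
nutritional ones (`keep_acceptability=False` drops them), and by default
no secondary objective is applied — the minimum-GHGE diet is whatever
vertex the solver returns, and its departure is typically enormous.  The
`lexicographic` flag adds a second stage that minimizes departure with
GHGE pinned at its optimum (1e-9 relative slack).

**Numerics.**  HiGHS via `scipy.optimize.linprog`, feasibility and
optimality tolerances 1e-7.  Every returned solution is audited against
its own constraint set at 1e-6 relative tolerance; solver tie-breaks among
alternative optima are accepted, so downstream code asserts objective
values and constraint activity, never the exact quantity vector.
Infeasibility is a result (`status="infeasible"`), not an exception —
except in `run_ladder`, which raises if the ladder cannot even start.

## Diet-change diagnostics

* *Mean absolute quantity variation* — `(1/n) Σ |ΔQ_i|/Q_i^obs × 100`
  over items with positive observed intake.
* *Within/between-group substitution split* — per group `g`,
  `gross_g = Σ_{i∈g} |ΔQ_i|` and `net_g = |Σ_{i∈g} ΔQ_i|`; within =
  `Σ (gross − net)`, between = `Σ net`.  The two parts sum to `Σ|ΔQ_i|`
  exactly for any grouping.  This gross-minus-net rule is an
  *interpretation*: it is the unique additive split in which a perfect
  1-for-1 swap inside a group counts entirely as within-group and a
  group's net weight shift entirely as between-group, but other
  decompositions of "substitution" are conceivable.  The split is
  computed at L1 level by default (`level="main"` switches to the 10
  main groups).
* *Item classes* — deleted (positive observed, optimized ≤ 0.01 g),
  increased/decreased beyond `0.01 g + 1e-6 × Q_obs`, else unmodified.
  The explicit tolerance is stated because "modified" is otherwise
  solver-noise-dependent.
* *Group contributions* — exact per-main-group sums of energy and GHGE;
  display floors (50 kcal, 100 g CO₂eq) apply only to rendered output,
  never to stored values.

## The synthetic survey generator

The generator emulates the *summary statistics* of a national food survey
— a mean observed diet per gender with its percentile envelopes — not
individual-level records.  Its defaults define the canonical study
conditions: 151 items / 27 L1 groups / 10 main groups; women at
1800 kcal/day and 66 kg, men at 2300 kcal/day and 80 kg (mid-range values
for European adults); observed diets deficient in fiber (both genders)
and iron (women) and in excess on free sugars and SFA, each by a 15%
margin relative to its bound; animal-derived items four times as
GHGE-intense as the plant median.

Construction, per gender:

1. **Habit diet** `h` — typical daily grams per L1 group (constants in
   `synthetic_data.py`), split across the group's items with random
   shares and scaled to the gender's energy target.  Compositions per
   item are group-typical per-100 g profiles with lognormal jitter
   (σ = 0.25): plant groups rich in fiber, vitamin C and folate; dairy in
   calcium; meat/fish/offal in iron, zinc and B12; fortified breakfast
   cereals; energy-dense, micronutrient-poor sugar/fat/alcohol.
2. **Observed diet** `o` — the LP-closest diet to `h` (same departure
   objective as the main models) that hits the energy target and violates
   every configured deficiency/excess target at its margin.  This keeps
   the observed diet realistic (it *is* approximately the habit diet)
   while making the violations certain rather than probabilistic.
3. **Reference diet** `r` — the LP-closest diet to `o` satisfying every
   nutritional bound tightened by 2%, inside *tightened* acceptability
   envelopes around `o` (weight ±15%, energy ±0.05%, ratio ±0.5%, special
   caps at observed amounts).
4. **Envelopes** — item and L1-group boxes are then placed to contain
   both `o` and `r` (lower bounds at 0 for a random 30% of items,
   mimicking the dominance of non-consumers in a 10th percentile that
   includes them).  Because the real envelopes are strictly wider than
   the tightened ones used for `r`, the reference diet is a *feasibility
   certificate*: the NUTR model on the emitted profile is feasible by
   construction, and the generator audits this before returning.  If any
   stage fails, it retries with fresh jitter up to five times and then
   raises, never emitting a silently infeasible instance.

GHGE intensities: all items draw from per-L1 lognormal scales; animal
items are then rescaled so their median equals
`animal_ghge_multiplier ×` the plant median and floored at that level.
With a multiplier of 1 the animal and plant medians coincide, and
intensities are linear in the multiplier, so raising it can only raise a
fixed diet's total GHGE.

Randomness uses labeled `SeedSequence` substreams of the master seed
(database: one stream; each gender × attempt: its own stream), so adding
a population never changes the database and a fixed seed reproduces every
byte, including written CSVs (values are quantized to the per-100 g grid
of the interchange format so write→read round-trips are exact).

Percentile envelopes are computed per gender by default.  Whether a real
survey would pool genders when computing them is a design choice the
generator exposes as `bounds_per_gender`; the pooled variant is emulated
by widening the envelopes by 25%, since pooled percentiles across two
differently-eating strata are wider than within-stratum ones.

**What the generator does not emulate** — and hence what green tests do
not demonstrate about real data: country-specific consumption patterns,
survey sampling weights, intra-population variance (the models optimize
population means), seasonal or correlated nutrient structure beyond the
group-level profiles, and measured (rather than group-caricature) food
compositions.  Results on synthetic instances validate the machinery and
the qualitative mechanisms, not any country's numbers.

## Problem sizes and runtime

The default instance has 151 items; a full ladder (NUTR, four to six
reduction steps, MINI) solves in well under a second on one CPU, and the
entire test suite — including a brute-force grid oracle over ~200k diet
combinations used to verify the LP objective on small instances — runs in
a few seconds.  Hand-solved toys (2–4 items) pin down the objective value,
the GHGE floor of the ladder, and the minimum-GHGE vertex exactly.

## Known limitations

* Single environmental indicator (GHGE); no cost or affordability
  constraints.
* Population-mean optimization only; no individual-level modelling or
  portion-size (integer) constraints.
* The within/between substitution split is one defensible definition
  among several (see above) and is flagged as such wherever reported.
* Nutrient bioavailability is ignored; compositions enter the constraints
  as-is.
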