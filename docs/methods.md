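# Methods

`trajmine` mines longitudinal diagnosis registries for ordered code pairs
D1 → D2 whose co-occurrence and temporal direction are statistically
significant, chains them into linear disease trajectories, and merges the
trajectories into directed multimorbidity networks.  Because
population-scale registry data is person-sensitive, the package ships a
synthetic-registry simulator with planted progression effects of known
strength; every statistical guarantee is validated against that known
truth.

## The mining procedure

All temporal statistics anchor on **first occurrences**: the first
occurrence of a code for a patient is the minimum date over that
patient's events with the code.  Working on first occurrences keeps the
pair tests, the directionality test and the trajectory-follower
definition mutually consistent.

**Pre-processing.** Raw codes are truncated to ICD-10 level 3 (letter +
two digits, with the Danish-style single-letter national prefix
stripped).  Events from five chapters are dropped by default —
perinatal conditions (XVI), symptoms and findings (XVIII), injury (XIX),
external causes (XX), and contact-with-health-services factors (XXI) —
because they describe circumstances rather than diseases.  Mortality is
folded in as an artificial terminal code Y99: one event per deceased
patient, dated at death.  Y99's letter falls inside excluded chapter XX,
so it is carried on an explicit allow-list; a D1 → Y99 pair then counts a
patient exactly when death falls within the analysis window (5 years by
default) of D1's first occurrence, which is the intended "death within
5 years of D1" semantics.

**Pre-filter.** For each ordered pair, count the D1 patients whose first
D2 occurrence falls within the window after their first D1 occurrence,
and test that count with an exact one-sided binomial tail against the
null success probability `P(patient holds D2 at all)`.  Pairs with
P < 1.21 × 10⁻⁹ proceed.  The null probability uses lifetime prevalence
while the alternative is confined to a 5-year window, so the screen is
deliberately conservative: its only job is to pass a cheap superset of
the truly associated pairs, and its false-positive behaviour is part of
what the null-calibration test measures.

**Matched controls and relative risk.**  Every exposed patient is
anchored at their first D1 event and matched to unexposed patients who
have at least one event with the identical key (sex, whole-year age,
discharge type, ISO-8601 week).  Two refinements matter in sparse data:

- *The comparison event may not be the outcome itself.*  Pools are built
  per pair, excluding D2-coded (and Y99) events from granting pool
  membership.  Otherwise a fraction of controls — roughly D2's share of
  all event mass — is anchored at its own first D2 occurrence, which can
  then never count as a subsequent occurrence; in registries with around
  one event per patient this deflates control counts by ~15% and
  inflates RR accordingly.  With the exclusion, the exposed and control
  anchors are exactly symmetric under the null (the exposed anchor is a
  D1 event, never D2).
- *Fallback matching.*  When no unexposed patient shares the full key,
  the week relaxes to the same quarter, then drops, then discharge type
  drops, then matching is on sex and age only, and finally any unexposed
  patient is accepted.  Every relaxation is counted and logged.  The
  published procedure never faces this because its cohort is three
  orders of magnitude larger.

Replicate i draws one matched control per exposed patient (without
replacement within the replicate where pool sizes permit) and counts
C_i, the controls whose first D2 occurrence lands in the window after
their matched event.  The relative risk is

    RR = C_exposed / ( (1/N) Σᵢ C_i )

with an infinite-RR sentinel when all control counts are zero.  For the
pair P-value, each matched control individual is one Bernoulli trial for
acquiring D2 in-window: the N replicates pool into the rate estimate
p̂ = ΣC_i / (N·n_exposed) and the P-value is the exact binomial tail
P(X ≥ C_exposed) for X ~ Binomial(n_exposed, p̂), one-sided for excess
risk, with the default cut-off 1.21 × 10⁻⁸.  This parametric form is the
calibrated reading of "a binomial distribution modelling each single
comparison": a seemingly natural alternative — scoring each replicate
comparison C_exposed vs C_i as a Bernoulli(½) success and taking the
Binomial(N, ½) tail — is not a valid test, because all N comparisons
share the single C_exposed realisation; its success fraction is the
*rank* of C_exposed (uniform under the null), and it rejects ~40% of
true nulls at level 0.05.  The parametric tail rejects 3–4.5% at level
0.05 under an independent null (slightly conservative, as exact binomial
tests are).  N defaults to 10,000; simulation-backed tests use N = 100,
which only coarsens the estimate of p̂.

One caveat measured and documented rather than hidden: in registries
small enough that matching pools hold only tens of patients, the C_i
ensemble under-disperses (replicates largely re-draw the same pool
members) and control anchors sit slightly earlier within their matching
cell than exposure anchors, so the standalone pair test is only
approximately calibrated at desk scale.  The pipeline's false-positive
control does not rest on it alone: the pre-filter's far stricter
threshold screens first, and the end-to-end null-calibration test (20
null registries, zero directional pairs) checks the pipeline as a whole.

**Directionality.**  Among patients whose first occurrences of both
codes lie within the window of each other, count D1-first versus
D2-first orderings (same-day ties are excluded — no direction is
observable) and take the exact one-sided binomial tail at probability ½,
significant at 0.05.  A pair is *directional* when it passes all four
tests with RR > 1.  The two Bonferroni-style cut-offs are configuration
defaults taken verbatim from the published pipeline rather than
recomputed: the family size behind them is not stated there, and
0.05 / 3,155,952 does not reproduce either printed value, so no
derivation is guessed.

**Trajectories.**  Directional pairs chain end-to-end into trajectories
of length 2–6.  A patient follows a trajectory when the first
occurrences of all its codes are strictly increasing in trajectory
order; other diagnoses may interleave freely.  Each reported trajectory
of each length must have at least 20 followers (configurable); a
qualifying length-3 chain never suppresses its length-2 prefixes, codes
never repeat, and Y99 can only terminate a chain.  Follower counting is
anti-monotone under extension, which the depth-first builder uses for
pruning; on small instances the builder is tested set-identical to an
exhaustive enumeration with brute-force counting.  Chaining never
synthesises a direct pair A → C from A → B → C.

**Summaries, networks, export.**  Over the follower set only, each
trajectory reports mean age (whole years, floor) at the first code's
first occurrence, mean years between consecutive first occurrences per
edge, and deaths within five years of the final code's first occurrence.
Merging trajectories unions their nodes and adjacent-pair edges into a
directed graph whose edges carry the underlying pair statistics and
length-2 follower counts — identical regardless of how many trajectories
share the edge, so merging is order-independent and idempotent.
Serialisation (Cytoscape JSON and delimited tables) applies privacy
suppression by default: nothing assigned to fewer than five patients is
written.

## The synthetic registry

Each simulated patient carries sex (Bernoulli), a birth date uniform over
the configured birth-year range (1920–2015 by default), and is at risk
from max(window start, birth) to min(death, window end); the default
window is 1994-01-01 to 2018-04-30.  Death follows piecewise-constant
annual hazards by age band (defaults from 0.0005/y below 40 to 0.10/y
above 85, giving ≈15% deaths per cohort).  For each code, baseline
events form a homogeneous Poisson process at the code's annual incidence,
with within-year intensity modulated by a sinusoid (amplitude 0.2) so the
discharge-week matching covariate is non-trivial.  Discharge types are
uniform over {inpatient, outpatient, emergency}.

A progression rule (source → target, multiplier m, optional sex
restriction) multiplies the target's hazard by m for a fixed effect
horizon (5 years) after the source's first occurrence.  Extra events
number Poisson((m−1)·λ_target·min(remaining, horizon)) and are placed at
the source's first occurrence plus a log-normal lag (mean 2 years,
shape 0.75, resampled to fit the boosted span).  Rules apply in
configuration order, each seeing earlier rules' events, so chains
generate genuine three-step progressions.  With a rare target and the
analysis window equal to the horizon, the pair's RR tends to m.

The default universe holds 26 codes across many chapters (four from
excluded chapters, exercising the chapter filter) with annual incidences
of 0.5–3 per 1000 patient-years, and five planted rules — a chain
I10 → I50 → N18 plus E11 → I21, J44 → J18 and G30 → F00, multipliers
15–18.  Rule sources have ≥ 500 expected exposed patients at the default
20,000-patient cohort; target incidences of 1.5–2 per 1000 patient-years
keep planted co-occurrence counts comfortably above the conservative
pre-filter's detection floor and keep control counts large enough that
per-seed RR estimates are not dominated by control-side Poisson noise.
These defaults were fixed in a single calibration pass and then frozen.

**What the simulator does not emulate:** real comorbidity correlation
structure (codes are independent absent rules), age- or sex-dependent
incidence, diagnostic coding noise, care-seeking behaviour, admission
clustering within hospital stays, or realistic national demography.
Passing tests therefore demonstrate that the pipeline recovers the
generative truth of this model — directional effects, their magnitude,
and null calibration — not that it reproduces any published cohort's
pair list.

## The closed-form RR oracle

`expected_pair_rr` predicts a pair's relative risk from the
configuration alone: it integrates, over the birth-cohort distribution
and the d1 first-occurrence law, the probability that the first d2
occurrence lands in the window after exposure, for the boosted (exposed)
and baseline (matched control) arms, including the residual-life
distribution implied by the age-band death hazards in both arms.
Mortality matters: without it the control arm's uniform-in-window events
are over-counted relative to the exposed arm's early-lag boosted events
and the prediction sits 30–50% low at the default hazards.  Seasonality
and indirect boosts through chained rules are not modelled, so the value
is exact for single-rule configurations (it agrees with a 100,000-patient
Monte-Carlo frequency estimate within 2%) and a documented approximation
otherwise.  It exists to set test tolerances, not to serve as an
estimator.

## Numerical and edge-case conventions

- Dates are calendar days; ages are completed years (floor); weeks are
  ISO-8601.
- Ties: same-day first occurrences carry no direction and break follower
  chains.
- RR with zero mean control count is +∞ (ranked above any finite RR);
  zero in both arms is an error (such pairs cannot pass the pre-filter).
- A directionality test with zero usable patients is undefined and the
  pair is dropped, never silently passed.
- Control-draw seeds derive from (seed, D1 code) via `SeedSequence`, so a
  pair's statistics do not depend on which other pairs survived the
  pre-filter; tightening any threshold can only remove pairs.
- Mining never returns both orientations of a pair: two opposite
  one-sided binomial tails cannot both fall below ½.

## Problem sizes used in tests

Simulation-backed tests run at the defaults the conditions specify:
null calibration and planted-effect recovery use 20 seeds of
20,000-patient registries with N = 100 control replicates; the
directionality type-I check uses 400 symmetric-null replicates of 60
patients; trajectory-oracle equivalence uses 100 random instances of up
to ~320 patients and 10 codes; the Monte-Carlo RR check uses one
100,000-patient registry.  The acceptance script
(`scripts/acceptance.py`) re-runs the same computations from scratch and
additionally one 50,000-patient end-to-end demonstration, where the
planted chain accrues enough followers to surface as a length-3
trajectory under the minimum-20 rule.

## Known limitations

- The pre-filter's conservatism costs power against weak effects
  (multipliers near 1–5 on rare codes will not reach 1.21 × 10⁻⁹ at
  these cohort sizes); the published thresholds assume a cohort three
  orders of magnitude larger.
- Matched pools in small registries rely on the documented fallback
  chain; matching fidelity degrades gracefully but measurably below a
  few thousand patients.
- Per-seed RR estimates for rare targets carry ~20–30% control-side
  sampling noise at N = 100; medians over seeds are stable.
- The trajectory builder enumerates all qualifying chains; on pair
  graphs far denser than significance testing produces (hundreds of
  interlinked pairs), enumeration grows combinatorially.
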