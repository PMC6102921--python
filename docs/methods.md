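# Methods

## Decision problem and model structure

The model evaluates prosthetic treatment of a single missing lower first
molar from a Japanese public-payer perspective.  A cohort enters at age 50
in the initial state of one of three strategies — single implant (Implant),
insurance-covered fixed dental prosthesis (IFDP) or privately funded fixed
dental prosthesis (PFDP) — and is followed for 30 annual cycles.

Nine mutually exclusive states are modelled: `Implant`, `secondImplant`,
`IFDP`, `secondIFDP`, `PFDP`, `secondPFDP`, `RPD` (removable partial
denture), `MT` (missing tooth left untreated) and `dead`.  Re-treatment
with the same prosthesis type is allowed exactly once, encoded directly in
the state graph rather than with a counter: a failed first prosthesis is
replaced by its `second…` counterpart, a failed second prosthesis leads to
an RPD, and an abandoned RPD leads to MT, which is absorbing apart from
death.  A failed implant is re-treated with a second implant and, failing
that, with an insured bridge; a failed private bridge is *not* re-treated
with an insured one.

## Transition dynamics

Within a cycle death competes first and prosthesis failure applies to
survivors (the ordering is a modelling choice; the two events are
compounded multiplicatively):

* `P(s → dead) = q(age)`
* `P(s → d) = (1 − q(age)) · f_s · a_{s,d}` for each allocation destination
* `P(s → s) += (1 − q(age)) · (1 − f_s)`

with `f_s` the annual failure rate and `a_{s,d}` the allocation split.
Annual failure rates (%/year): Implant 0.52, second implant 2, IFDP 11,
second IFDP 15, PFDP 4.4, second PFDP 8.4, RPD 16.8.  Allocations: first
prostheses go to their second counterpart (bridges with a 0.2 % direct
RPD leak), second prostheses to RPD, RPD to MT.  Failure rates and
allocation splits carry no published uncertainty and are treated as fixed
in the PSA; a config hook (an optional distribution bound to
`annual_failure_rate`) exists for analysts who wish to sample them.

## Mortality

Annual mortality is anchored at q(50) = 0.0016 and q(80) = 0.0252 from an
abridged national life table.  Intervening integer ages are filled by
log-linear (Gompertz) interpolation `q(a) = q(50)·exp(b·(a−50))` with
`b = ln(q(80)/q(50))/30 ≈ 0.0919/yr`, which is the standard shape for adult
mortality; any interior anchor supplied in the config overrides the
interpolated value exactly at its own age.  The interpolator gives
q(51) = 0.001754; an empirical abridged table prints 0.0017 at that age,
i.e. the Gompertz fill is accurate to about half of the final printed
digit at the low-age end.  The life table is replaceable wholesale via
`life_table: {kind: table, q: {...}}`.

## Effectiveness and costs

Effectiveness is the GOHAI oral-health QOL score.  Raw totals (12–60) are
rescaled linearly, `(G − 12)/48`, onto [0, 1]; the per-cycle accrual is the
occupancy-weighted state QOL, so totals are "GOHAI-scaled years" with a
maximum of one per year alive.  State values (mean ± SD on the converted
scale): implant states 0.88 ± 0.14, all bridge states 0.83 ± 0.13, RPD
0.71 ± 0.23, MT 0.70 ± 0.18.  Utilities reported for a *lost* implant
(0.71 ± 0.23) and a *lost* bridge (0.68 ± 0.17) are stored on the states
as `failure_qol` but not accrued by default, because failures are modelled
as instantaneous transitions; setting `use_failure_qol: true` accrues them
for the failing flow in the cycle of failure.

Costs are in euros at €1 = ¥114.60.  Entry (treatment) costs: implant
€2 744 ± 274.4, insured bridge €420 ± 42, private bridge €2 618 ± 261.8,
RPD €368 ± 36.8; the full entry cost of the destination state is charged
to the flow entering it, including replacements (no published re-treatment
tariff exists, so a replacement costs the same as the first treatment).
Maintenance: €261.8 ± 26.2 per cycle for implant, bridge and MT states
(the published maintenance row covers all three), €305 ± 43.6 for RPD,
nothing for `dead`.

## Accrual and discounting conventions

Costs and effects are discounted at 2 %/year with `v(t) = 1.02^(−t)`.
Defaults (each is a config switch):

* occupancy-based accrual uses start-of-cycle occupancy, cycle 0
  undiscounted, cycles 0…29;
* no half-cycle correction (`half_cycle_correction: true` reweights the
  boundary cycles by ½ and adds a cycle-30 half term);
* entry costs are event-based: charged to the transition flow and
  discounted at the arrival cycle, including arrivals at the cycle-30
  boundary (the replacement happens inside the 30-year window);
* maintenance is charged for every cycle a state is occupied, including
  the cycle in which the prosthesis fails.

## Base-case results and their sensitivity to structure

With these conventions the packaged model gives, per cohort member over 30
discounted years: IFDP €6 801.3 / 16.72, Implant €8 694.2 / 18.98, PFDP
€9 943.7 / 17.40; Implant vs IFDP ΔC = €1 892.9, ΔE = 2.257, ICER = €838.7
per GOHAI-scaled year; PFDP is strictly dominated by Implant, so the
frontier is IFDP → Implant.  (These are the numbers the test suite and
`scripts/acceptance.py` recompute.)

The incremental effectiveness is driven almost entirely by how long the
bridge cohort spends in the RPD and MT states: at the modelled failure
rates the IFDP cohort accumulates ≈ 9.4 discounted years there (QOL
deficit ≈ 0.12 vs a functioning bridge), while the implant cohort barely
leaves its initial state.  ΔE is therefore very sensitive to the bridge
and RPD failure rates, and the PFDP classification (strictly vs extended
dominated) flips with the replacement-cost convention: charging
replacements at full price makes the private bridge costlier than the
implant.  Users comparing against other implementations of this decision
problem should check these two structural choices first.

## Probabilistic sensitivity analysis

Each of the (default) 5 000 iterations draws all twelve parameters
independently — QOL from the fitted betas, costs from the fitted gammas —
and records total discounted cost and effectiveness per strategy.  The
method-of-moments fits reproduce the published means and SDs exactly, so
the PSA means estimate the base-case totals (asserted within 3 Monte-Carlo
SEs).  Because sampled parameters do not enter the transition structure by
default, the occupancy trace is identical across draws and per-draw totals
are evaluated as linear functionals of the sampled cost/QOL vectors
(discounted state-years and discounted entry inflows from a single trace
per strategy); a test asserts exact equality with per-draw engine reruns.
If a failure-rate distribution is configured, the PSA transparently falls
back to a full rerun per draw.

The CEAC is evaluated on a willingness-to-pay grid of €0–5 000 in steps of
€100 (covering the region where all three strategies exchange rank); the
optimum is the maximum net monetary benefit, exact ties split equally.
There is no correlation structure (none is published) and the life table
is not resampled.

## One-way sensitivity analysis

The tornado varies each sampled parameter to mean ± 1 SD (configurable
multiple or explicit bounds), holding the rest at baseline, and recomputes
the Implant-vs-IFDP ICER with two cohort runs per bound.  Bounds outside a
parameter's domain are clamped (e.g. implant QOL 0.88 + 0.14 → 1.0) with a
logged warning.  When a bound moves ΔE across zero the ICER changes sign;
entries are ranked by the absolute swing and such sign-flipping entries
(implant QOL at −1 SD does this) should be interpreted on the net-benefit
scale.  With the default ranges the leading drivers are implant QOL,
bridge QOL and the untreated-tooth (MT) QOL, consistent with the MT
occupancy noted above; the lost-prosthesis utilities and the private-bridge
cost have zero swing because they do not enter this comparison.

## Synthetic survey data

The QOL parameters originate from a 12-item GOHAI questionnaire
(items 1–5, total 12–60) administered to six clinical groups (implant 168,
lost implant 32, bridge 65, lost bridge 66, RPD 45, MT 184 patients).
Patient-level data are not published, so `generate_survey` draws each
patient's converted score from the beta distribution moment-matched to the
group mean ± SD, snaps it to the 49-point raw grid and decomposes the raw
total into twelve bounded item scores by a random composition.  Snapping
perturbs the moments by less than the grid spacing (1/48 ≈ 0.02), which the
recovery tests' tolerances account for; item-level patterns are arbitrary
and must not be analysed as if they were behavioural data.  What passing
recovery tests show is that the estimation pipeline (convert → mean/SD →
moment fit) is consistent; they say nothing about how real patients answer
individual items, nor about non-beta features (e.g. ceiling clumping) of
real score distributions.

## Numerical and degenerate-input choices

* Moment fits validate feasibility (`0 < sd² < mean(1−mean)` for a beta,
  positive mean and SD for a gamma) and round-trip to 1e−9 relative.
* Occupancy rows sum to 1 within 1e−12 at every cycle (asserted).
* Frontier ties: equal effectiveness is resolved by cost; exact
  (cost, effectiveness) twins are both kept, classified together and
  flagged `equivalent`; extended dominance is removed iteratively until
  consecutive ICERs are strictly increasing, and the result is checked
  against a brute-force net-benefit oracle on random strategy sets.
* A single-patient survey group has a defined mean and an undefined (NaN)
  SD.
* All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline derives independent sub-seeds per stage from the user seed via
  `SeedSequence` and records them in the manifest.

## Known limitations

* Cohort-level model: no individual heterogeneity, no tunnel states, no
  within-cycle sojourn time.
* Failure rates are age-invariant and, by default, not sampled in the PSA;
  their uncertainty is unpublished.
* The GOHAI rescaling is linear; the model is a cost-effectiveness (not
  cost-utility) analysis and its effectiveness unit is not a QALY.
* The Gompertz life-table fill is an approximation between two anchors of
  an empirical table it cannot fully reconstruct.
* Base-case totals depend materially on the replacement-cost and
  failure-pathway structure discussed above; both are exposed in the
  config so alternative conventions can be run without code changes.
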