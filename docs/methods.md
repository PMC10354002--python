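# Methods

## Uptake translation

The choice model is a conditional logit: the probability of picking
alternative *i* in a task is `exp(β'x_i) / Σ_j exp(β'x_j)`. Attribute
levels are reference-coded against the baseline service configuration
(clinic location, morning hours, unfriendly staff, no confidentiality, no
incentives), so the baseline bundle has utility 0 and each coefficient
reads as a log-odds shift.

Translating a bundle into uptake uses a **two-alternative contrast**:
modified service versus status quo, with the status-quo utility anchored
so that its choice probability equals the clinic's observed baseline
uptake share (30.60% of all clinic users in the bundled data). The
projected change is `Δp = 100·[expit(logit(p₀) + β'x) − p₀]` percentage
points. This is a deliberate design choice: the original experiment's full
choice-set design is not available, and the quantity of interest is a
change from an observed baseline probability, which the binary contrast
represents exactly.

Combined bundles use the **sum of component coefficients** (no interaction
terms — none are estimable from a published coefficient table), and the SE
of a combined utility is the root-sum-of-squares of the component SEs
(independence assumed; a full coefficient covariance matrix can be
supplied to `utility_std_error` when available). CIs are symmetric on the
percentage-point scale with z = 1.959964. The delta-method SE
`100·p(1−p)·se(β'x)` is evaluated at the shifted probability p.

Two caveats about the bundled projection table, both inherited from its
source and handled by treating the printed deltas as authoritative inputs
rather than recomputing them: (i) the printed per-attribute deltas (e.g.
0.19 → 18.54 pp) are not reproducible from the printed two-decimal
coefficients under any baseline probability, so the logit translation is
exercised and tested on exact synthetic coefficients instead; (ii) printed
combined-row coefficients (e.g. Wi-Fi and food = 0.11) are not the sum of
the printed components (0.03 + 0.02) — the combined rows were estimated,
not derived, upstream.

## Headcount arithmetic

`additional = round(N_base × Δp/100)` with half-away-from-zero rounding —
the only rule consistent with every internally consistent published count
(1531×0.0271 = 41.49 → 41; 1531×0.23 = 352.1 → 352; 1808×0.23 = 415.8 →
416). The delta multiplies the **baseline adolescent count**, not total
clinic headcount (the alternative contradicts every published cell).
Negative projections (possible at the lower CI bound) clamp to 0 by
default; a `floor=1` compatibility option reproduces published sensitivity
tables that never report fewer than one additional adolescent (their floor
is undocumented; a zero floor is the defensible default). Unrounded counts
are carried alongside for cost-per-patient arithmetic. Annual figures are
12× monthly.

## Costing

Only incremental costs of a modification are counted, allocated to the
additional adolescents it attracts, at 14 ZAR per USD (2019 mid-year rate,
configurable). Allocation rules per line: none_incremental (assets — no
new assets needed), per_visit (supplies at a per-visit unit cost),
shared_all_patients (utilities/overheads diluted over headcount +
additional), extra_room_overhead (a counselling-room share of overheads,
charged only to scenarios needing extra space: youth-only or afternoon),
afternoon_staff_time (a fraction of monthly staff spend, afternoon
scenarios only), all_adolescents_billed_to_additional (food: ZAR 10 per
adolescent for **all** adolescents, billed to the additional ones), and
fixed_monthly (the whole monthly amount when the gating attribute is
present — the Wi-Fi supply contract). Every attribute-tied rule is gated:
it contributes 0 to scenarios without that attribute.

Two config parameters have no published value and were fixed once from the
published per-category aggregates for Clinic B:
`afternoon_hours_fraction = 0.016` (the marginal afternoon roster ≈ 1.6%
of monthly staff expenditure, consistent with ≈$61 staff cost per
additional adolescent at 15 additional) and `room_share = 0.015` (one
average counselling room ≈ 1.5% of facility overheads, consistent with the
≈$116/month youth-only overhead cell). The bundled Clinic B workbook is a
**synthetic reconstruction** (marked as such in its header): the original
line-level workbooks are unpublished, so the costing module is validated
by unit oracles and scaling/gating properties, not by regenerating the
published per-category table (several of whose cells are misaligned).
Cost-per-additional uses the unrounded count and is reported as undefined
(NaN) when a positive cost meets zero additional adolescents.

## Dominance engine

Strategies are (effect, cost) points; a zero-cost, zero-effect
"do nothing" baseline is always included. Strict dominance removes any
strategy with a competitor at least as effective and no more costly (one
comparison strict). Extended dominance then iteratively removes any
strategy whose ICER versus the next-cheaper survivor is ≥ the ICER of the
next-more-effective survivor versus it; the survivors are exactly the
strict vertices of the lower-left convex hull, and their ICER ladder is
strictly increasing. Ties: exact (cost, effect) duplicates keep the
lexicographically first name; collinear points are removed (the ≥ rule),
keeping the ladder strictly increasing. Effects enter at the integer
(rounded) scale by default to match published tables; `use_unrounded=True`
switches to full precision. The first ICER is anchored on the do-nothing
baseline; no willingness-to-pay threshold is applied.

**Known divergence from the published Clinic A table.** By Clinic A's own
printed columns, Wi-Fi+food ($1705.92, 168 additional; $10.15 per
adolescent from the origin) delivers effect more cheaply than
Wi-Fi+youth-only ($1465.56, 138; $10.62), so a complete extended-dominance
pass excludes Wi-Fi+youth-only — yet the published table keeps it on the
frontier (ICER $9.78 versus the Wi-Fi-only strategy) and labels
Wi-Fi+food weakly dominated. No dominance rule consistent with the
printed numbers reproduces that labelling; it is an incomplete
extended-dominance pass upstream. The engine follows the definitions and
*surfaces* the disagreement (engine labels sit next to the printed-status
column of the fixtures); the published pairwise ICERs ($9.78, and $10.45
for adding food to Wi-Fi+youth-only) remain exactly reproducible via
`pairwise_icer` between the named strategies. Clinic B's published
frontier coincides with the hull; its middle/top rung ICERs recompute to
9.37/14.40 from the printed columns versus printed 9.32/14.45 (unprinted
precision upstream), with the first rung $7.01 exact.

## Sensitivity analysis

`run_sensitivity` substitutes the chosen CI bound (lower/upper/point) for
every scenario's delta and re-runs projection, costing and the frontier.
`bound="point"` is the identity. The published lower-bound tables are
shipped as reference fixtures only: their percent columns disagree with
the CI bounds they claim to use and their cost columns are visibly
misaligned, so no numeric check pins them.

## Synthetic choice data and estimation

`generate_design` draws uniformly random level assignments per attribute
per alternative (reference level included in the draw), resampling any
task whose alternatives are identical; random rather than D-optimal
designs suffice for recovery testing. `simulate_choices` samples from the
softmax at the true coefficients. The fitter maximizes the
conditional-logit likelihood by Newton-Raphson with analytic gradient and
Hessian, step-halving for global stability, convergence at gradient
max-norm < 1e-6, and SEs from the inverse observed information. Rank
deficiency raises an error naming the collinear columns; estimates running
past |β| = 15 raise a separation error instead of silently diverging (a
genuine conditional-logit coefficient of 15 corresponds to odds shifts of
e^15 ≈ 3×10⁶ — far outside anything estimable from survey-scale data).
Defaults mirror the motivating survey's scale: 805 respondents × 8
binary-choice tasks (tasks-per-respondent and alternatives are not
published; 8 and 2 are conventional and configurable). One master seed
fans out to design/simulation/replicate streams via `SeedSequence.spawn`.

What the generator does *not* emulate: preference heterogeneity (mixed
logit), respondent covariates, serial correlation within respondents, and
D-efficient designs. Passing recovery tests therefore show the estimator
and translation are internally correct at the stated scale — not that
stated preferences predict real-world uptake.

## Problem sizes used in tests

The recovery acceptance check runs one full-scale fit (805×8 tasks) plus
200 replicates at the same scale (~10 s total); the dominance engine is
checked against an independent willingness-to-pay sweep oracle on 1,000
random strategy sets of ≤10 strategies. These sizes were chosen as the
smallest that exercise the study-scale conditions directly.

## Known limitations

- Linear cost scale-up is assumed (as upstream); no saturation or
  congestion effects, no seasonal trends.
- The "challenging to modify" attributes (friendliness, confidentiality)
  are projected but not costed — no generalizable intervention exists to
  price.
- The costing decomposition is validated by properties, not by cell-level
  regeneration of the published per-category table.
- CI coverage of the frontier itself (probabilistic sensitivity analysis)
  is out of scope; only CI-bound substitution is implemented.
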