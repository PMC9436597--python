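# Methods

This note documents the model implemented by `copdcea`, the conventions it
fixes where the source analysis left them unstated, the numerical choices,
and what the synthetic generators and tests do and do not demonstrate.

## Cohort model

Four states in canonical order (C, B, A, DEATH): moderate COPD
(50% ≤ predicted FEV₁ < 80%), severe (30–50%), very severe (<30%), and
absorbing death. The cohort is propagated by row-stochastic 4×4 matrices at
quarterly cycles; the transition into cycle 1 uses the "base" matrix, every
later cycle the "new" matrix (the two-phase structure of the input tables).
Allowed moves are stay, worsen by one severity step, and die from any
state; improvement transitions are structural zeros. Probability
conservation and monotone death occupancy are asserted at every cycle, not
just tested.

Per-cycle rewards are linear in occupancy: drug and management costs,
expectation-valued exacerbation costs (expected events per patient-quarter
times the unit cost of a severe/non-severe event), expected adverse-event
costs (probability × unit cost per event type, over the alive mass), and
utility accrual (annual weight × 0.25 years). Exacerbations and adverse
events carry costs only — the source parameterizes no disutility or excess
mortality for them. An event type with a unit cost but no incidence in
either arm (oropharyngeal pain in the bundled tables) is flagged inactive
at load time and excluded from expected cost rather than silently priced.

Cycle-length conversion of probabilities uses the constant-rate identity
r = −ln(1−P₁)/t₁, P₂ = 1−exp(−r t₂), exposed as `rescale_probability`; a
certain event stays certain over any positive duration.

## Conventions and the replication findings

The source report does not state its reward accrual, discount indexing, or
half-cycle handling, and three of its headline outputs turn out to be
mutually inconsistent. All conventions are therefore explicit flags,
recorded in every run manifest:

* `half_cycle` — accrue on the mean of entry and exit occupancy (on in the
  bundled configuration) or on entry occupancy alone;
* `discount_offset` — cycle k discounted by (1.01)^−(k−offset); offset 1
  (bundled) leaves the first cycle undiscounted;
* `cycle0_accrual` — optional extra accrual at model entry (off);
* `gold_state_mapping` — how baseline GOLD stage counts map to states.

The last flag is the decisive one. Mapping stages by severity
(II→C, III→B, IV→A) yields per-arm totals around $4,120/1.73 QALYs —
nowhere near the published $5,070.82/1.545. Mapping the stage-ordered
counts onto the state list positionally (II→A, III→B, IV→C), combined with
half-cycle correction, reproduces all four published per-arm totals to
within 0.8% / 0.002 QALYs and the $765.67 saving to 0.4%. The bundled
configuration therefore uses the positional assignment: the original
model evidently bound the stage-ordered counts to its state list in
written order. `initial_distribution()` defaults to the severity mapping,
which is what a fresh analysis should use.

Two further published figures are consistent only with the *severity*
mapping, not with the published totals:

* the headline ICER of −$397,468.04/QALY sits within ~4% of the
  severity-mapping, state-at-entry run (−$415,000), while the
  totals-matching convention gives −$328,721; no single convention
  reproduces both, and the published rounded deltas themselves imply yet
  another value (−765.67/0.002 = −$382,835). The package reports the
  unrounded-delta ICER under the totals-matching convention, and the
  corresponding acceptance test is deliberately left failing rather than
  tuned;
* the tornado ordering (utility 50–80% > utility 30–50% > TIO drug cost)
  emerges exactly under the severity mapping with ±20% ranges applied to
  every parameter and transition rows held fixed — hence
  `run_owsa(range_source="pct20", include_transitions=False)` for
  replication, while the default follows the stated rule (95% interval of
  the sampling distribution where one exists, ±20% otherwise).

The source also states both a 5% annual discount and a 1% quarterly
discount (inconsistent: 5%/yr ≈ 1.23%/quarter). The quarterly 1% figure its
tables footnote is used and is configurable.

One input-table artifact: the TIO new-phase C row's Dirichlet counts
(0, 23, 829, 23) total 875 where every other TIO row totals 874, and
829/875 = 0.9474 vs the printed 0.948. The count-consistency validation
tolerance is 1e-3 (rather than the 5e-4 the other rows meet) so the
verbatim table loads; the point probabilities, which sum to exactly 1,
drive the deterministic engine. Printed gamma scale parameters are rounded
to 4 dp (one rounds to 0.0000), so scales are reconstructed as
point/shape, which reproduces every printed incidence exactly.

## Sensitivity analyses

**OWSA.** Each scalar input is set to the ends of its range with all others
at point values and both arms re-run; entries are ranked by the absolute
spread of the chosen outcome (ICER by default; NMB, ΔC, ΔE available), ties
broken by parameter identifier. Utilities, unit costs and exacerbation
counts are shared between arms and perturb both; drug costs, adverse-event
incidences and transition rows are arm-specific. A perturbed transition
probability renormalizes the remaining non-structural destinations of its
row, preserving row-stochasticity. If a perturbed run leaves the ICER
undefined (ΔE = 0), the entry falls back to the NMB spread and is flagged.

**PSA.** Second-order Monte Carlo with 1,000 iterations by default:
Dirichlet transition rows from their counts (structural zeros preserved),
beta utilities, gamma adverse-event incidences truncated to [0, 1] with the
truncated fraction reported (0 for the bundled magnitudes), uniform costs
and exacerbation counts. The correlation structure is switchable: shared
mode draws the health-state block once per iteration for both arms;
arm-specific mode draws every distribution independently per arm. The
published 61.6% probability of cost-effectiveness at $31,554/QALY is
reproduced only by the arm-specific mode (seeds 1–5 give 61.5–63.1% at
n = 1000; shared mode gives 76–79%), so arm-specific is the bundled
default. NMB ties count as cost-effective (a measure-zero convention). The
default acceptability-curve grid spans 0 to 3×WTP in 64 uniform steps and
always contains the threshold itself. All sampling flows through one
`numpy.random.Generator`; a seed fully determines scatter, CEAC and
summaries.

## Meta-analysis

Binary two-arm outcomes become log relative risks with delta-method
standard errors √(1/a − 1/n₁ + 1/c − 1/n₂); a study with any zero cell
gets 0.5 added to all four of its cells and is flagged. Pooling is
inverse-variance fixed-effect or DerSimonian–Laird random-effects
(τ² = max(0, (Q − df)/(Σw − Σw²/Σw)) on fixed-effect weights), with
heterogeneity always reported from the fixed-effect weights and the
selection rule "random iff heterogeneity P < 0.1 or I² > 50%" (fixed by
convention for a single study). Continuous endpoints (mean, SD, n per arm)
pool as raw mean differences through the same machinery, so either shape
of trial summary is representable. Per-study outcome counts for the three
source RCTs are not published, so their pooled estimates are not
reproduction targets; the module is validated against hand arithmetic and
an independent R implementation on synthetic tables instead.

## Synthetic data and oracles

`gen_meta_studies` draws study-level log relative risks from
N(ln RR, τ²) around a fixed comparator risk and binomial event counts per
arm — heterogeneity on the log-RR scale, baseline risk held constant across
studies. `gen_model_parameters` builds random but structurally valid
parameter sets by drawing integer Dirichlet counts first and defining
probabilities as counts/total, so every count-consistency invariant holds
exactly; utilities are ordered, cost bounds are exactly ±20%.
`microsim_oracle` replays the same matrices and reward conventions on
independent individual trajectories and returns empirical occupancy,
costs and QALYs with standard errors; the cohort engine must agree within
3 SEs at n = 2×10⁵, which the suite enforces.

What the generators do not emulate: patient-level FEV₁ trajectories,
treatment switching or escalation to triple therapy, exacerbation-driven
mortality, or correlated baseline risks across studies. Passing tests
therefore certify the arithmetic of the models, not the clinical realism
of the inputs.

## Problem sizes and numerics

Defaults used by the test suite and the reproduction script: 12-cycle
horizon; 1,000 PSA draws (five seeds for the stability check); 2×10⁵
microsimulated patients; 2,000 replicates for the meta-analysis coverage
check (fixed-effect CI covers the true RR in 95.6% of homogeneous
scenarios); 400 replicates for the type-I rate of the model-selection
rule. Row sums are validated to 1e-9, beta/gamma moment consistency to
5e-4, Dirichlet count consistency to 1e-3 (see above), cost-bound
consistency to 1e-3 absolute. Equivalence of arms uses a 1e-12 tolerance
on both deltas; ICERs are computed from unrounded deltas. Degenerate PSA
distributions (all supports collapsed) reproduce the deterministic base
case to float precision.

## Known limitations

* The published ICER and tornado are internally inconsistent with the
  published totals; the package reproduces each under its own documented
  convention but cannot reconcile them, and does not try to.
* No currency conversion or inflation machinery beyond a scalar; no EVPI,
  two-way or scenario analyses; no survival extrapolation beyond the
  transition matrices; plotting is left to the exported tables.
* The Markov engine is expectation-valued: exacerbation and adverse-event
  counts enter as means, so second-order (parameter) uncertainty is
  propagated by the PSA but first-order (sampling) variability only
  appears in the microsimulation oracle.
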