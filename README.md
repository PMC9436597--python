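# copdcea

Cost-effectiveness analysis of umeclidinium/vilanterol (UMEC/VI, 62.5/25 µg)
versus tiotropium (TIO, 18 µg) as maintenance bronchodilation in symptomatic
COPD, from the Chinese healthcare-system perspective, as a tested, reusable
Python package. It is aimed at health economists and methodologists who want
to re-run, audit or perturb the published-table analysis rather than trust a
spreadsheet: every input is validated, every convention is an explicit flag,
and every stochastic stage is seeded.

## The model

A Markov cohort model with four health states — moderate COPD
(50% ≤ predicted FEV₁ < 80%, state C), severe (30–50%, B), very severe
(<30%, A) and absorbing death — quarterly cycles and a 3-year horizon
(12 cycles, configurable 1–100). Patients stay, progress one severity step,
or die; the transition into cycle 1 uses a "base" matrix and all later
cycles a "new" matrix. Per cycle, occupancy `w_s` accrues

* drug cost (per-arm quarterly prescription),
* management cost (per state),
* expected exacerbation cost `n_sev(s)·c_sev + n_nonsev(s)·c_nonsev`,
* expected adverse-event cost `Σ_e p_e·c_e` over the alive mass,
* utility `u_s · 0.25` QALYs,

discounted at 1% per quarter. Arms are compared by incremental cost ΔC,
incremental QALYs ΔE, the ICER ΔC/ΔE with dominance classification, and net
monetary benefit `NMB(λ) = λ·ΔE − ΔC` at the willingness-to-pay threshold
λ = 3 × per-capita GDP = $31,554/QALY.

Around the deterministic engine sit:

* **OWSA** — one-way ranges (95% distribution intervals where available,
  otherwise ±20%), ranked by outcome spread for a tornado diagram;
* **PSA** — second-order Monte Carlo (Dirichlet transition rows, beta
  utilities, gamma adverse-event probabilities truncated to [0, 1], uniform
  costs and exacerbation counts), 1,000 seeded iterations, CE-plane and
  cost-effectiveness acceptability curves;
* **meta-analysis** — two-arm binary outcomes pooled as relative risks with
  inverse-variance (fixed) or DerSimonian–Laird (random) weights, Q/I²/τ²
  heterogeneity, and the selection rule "random effects iff P < 0.1 or
  I² > 50%"; continuous endpoints pool as mean differences;
* **synthetic data** — seeded generators for multi-study binomial trials and
  valid random Markov parameter sets, plus a patient-level microsimulation
  oracle used to cross-check the cohort engine.

The input tables ship as a bundled, named configuration (`umec-vi-tio`);
your own model is a YAML document with the same sections.

## Worked example

```
$ copdcea base-case --out-dir out
Strategy      Cost (US$)  Effect (QALYs)
TIO              5795.54           1.542
UMEC_VI          5033.12           1.544
Increment: cost -762.42, QALY 0.002, ICER Dominant (unrounded -328720.85 US$/QALY)
NMB at WTP 31554: 835.61
```

UMEC/VI costs $762 less and yields 0.002 more QALYs per patient over three
years, so it dominates TIO: no trade-off price per QALY needs to be paid,
and the positive NMB says the same thing at the $31,554/QALY threshold. The
published totals ($5070.82/1.545 vs $5836.49/1.543, savings $765.67) are
reproduced within 0.8% on costs and 0.001 on QALYs; `out/` receives both
per-cycle traces, a results document and a manifest recording the
convention flags.

```
$ copdcea psa --n-draws 1000 --seed 1 --out-dir out
P(UMEC/VI cost-effective at WTP 31554) = 62.9% (1000 draws, seed 1)
```

Parameter uncertainty leaves UMEC/VI the preferred strategy in about 62% of
draws (published figure: 61.6%), with the acceptability curve written to
`out/ceac.csv`. `copdcea owsa`, `copdcea meta` and `copdcea synth` drive the
tornado, pooling and generator stages; `copdcea replay out/manifest.json`
re-runs any recorded analysis bit-for-bit.

Library use mirrors the CLI:

```python
import copdcea as cea

params = cea.load_fixture("umec-vi-tio")
result = cea.compute_icer(
    cea.evaluate_arm(params, cea.Arm.UMEC_VI),
    cea.evaluate_arm(params, cea.Arm.TIO),
    params.wtp_per_qaly,
)
print(result.delta_cost, result.delta_qaly, result.dominance)
```

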