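# teer-cea

Cost-effectiveness model of transcatheter edge-to-edge mitral valve repair
(MitraClip) plus optimal medical therapy (OMT) versus OMT alone, for heart
failure patients with secondary mitral regurgitation, from a Chinese
healthcare-payer perspective.

The package is aimed at health-economics analysts: it implements the full
modelling pipeline — a 30-day decision tree feeding a lifetime Markov cohort
model — as a tested, config-driven library with report writers, a CLI and an
independent patient-level simulator, so every number in the analysis can be
recomputed, perturbed and validated.

## Model

Patients enter one of two strategies. The intervention arm incurs the
one-time MitraClip-related costs (device 322,000 CNY plus procedure,
diagnosis, medicine, complications, ward, nursing and other costs; 395,659
CNY in total) and the one-time procedure and complication disutilities
during a 30-day decision-tree stage; both arms then enter a Markov cohort
model over the live states NYHA I–IV plus an absorbing dead state, cycling
monthly for 336 cycles (age 72 to 100) with half-cycle correction. Each
live month accrues OMT drug cost (428 CNY), a state utility
(0.065/0.065/0.060/0.055 per month for NYHA I–IV), and — with a per-state
monthly probability — an HF hospitalization costing 10,926 CNY with a 0.1
disutility. Costs and QALYs are discounted at 5%/year, compounded monthly.

For strategies `i` (MitraClip) and `c` (OMT),

    ICER = (C_i − C_c) / (E_i − E_c)   [CNY/QALY]
    NMB(λ) = λ·ΔE − ΔC,   λ = WTP = 3 × per-capita GDP = 242,928 CNY/QALY

The intervention is cost-effective when ICER < λ, equivalently NMB(λ) > 0.
Uncertainty is handled by one-way analysis over each parameter's 95%
interval (tornado), and by probabilistic sensitivity analysis (gamma costs,
beta utilities and transition probabilities, 10,000 Monte Carlo draws)
summarised as a scatter plot and cost-effectiveness acceptability curve.

Two inputs are not published and are produced by the package's calibration
operation against the reported lifetime outcomes: the post-30-day NYHA
distribution of each arm, and the per-state monthly hospitalization
probabilities. See `docs/methods.md`.

## Worked example

```python
from teer_cea import default_parameters, evaluate

params = default_parameters()          # shipped, calibrated base case
outcome = evaluate(params)
mc, omt = outcome.arms["mitraclip"], outcome.arms["omt"]
print(f"MitraClip: {mc.lifetime_cost:,.0f} CNY, {mc.lifetime_qaly:.2f} QALY")
print(f"OMT:       {omt.lifetime_cost:,.0f} CNY, {omt.lifetime_qaly:.2f} QALY")
print(f"ICER: {outcome.cea.icer:,.0f} CNY/QALY "
      f"({outcome.cea.icer_wtp_ratio:.1f} x WTP)")
```

prints

```
MitraClip: 423,728 CNY, 2.30 QALY
OMT:       28,148 CNY, 1.78 QALY
ICER: 754,842 CNY/QALY (3.1 x WTP)
```

i.e. MitraClip gains about 0.52 QALY per patient at an incremental cost of
about 395,600 CNY; the ICER is roughly three times the willingness-to-pay
threshold, so MitraClip is not cost-effective at the current Chinese device
price. The same pipeline is exposed on the command line
(`teer-cea run|scenario|dsa|psa|calibrate`), and the numbered scripts in
`analysis/` walk through the full study: calibration, base case,
device-price scenarios (the cost-effective device price is ≈54,000 CNY,
about 17% of the current price), tornado, PSA (≈0% probability of
cost-effectiveness at the threshold; acceptability reaches 50% near 750,000
CNY/QALY) and a microsimulation cross-check of the cohort engine.

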