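# escc-cea

Cost-effectiveness analysis of **serplulimab + chemotherapy vs chemotherapy
alone** as first-line treatment for PD-L1-positive advanced esophageal squamous
cell carcinoma (ESCC), from the Chinese health-care payer perspective.

The package is aimed at health-economics analysts who want a reproducible,
tested implementation of a standard oncology cost-utility pipeline: a
three-state Markov cohort model (progression-free → progressed → death) with
monthly cycles over a 10-year horizon, Weibull-extrapolated survival, 5 %/year
discounting, and ICER/INMB decision rules at a willingness-to-pay (WTP)
threshold of $37,663.26/QALY (3× China's per-capita GDP).

## Model core

For each arm, fitted Weibull curves S(t) = exp(−λt^γ) for progression-free
survival (PFS) and overall survival (OS) define state occupancy by partitioned
survival:

    pfs(t) = S_PFS(t),  death(t) = 1 − S_OS(t),  pd(t) = max(0, S_OS(t) − S_PFS(t))

equivalent to the per-cycle exit probability P(t,u) = 1 − exp{λ(t−u)^γ − λt^γ}.
Discounted costs (per-cycle treatment components in PFS, subsequent-therapy
cost in PD) and QALYs (utilities 0.68 PFS / 0.42 PD) are accrued with a
half-cycle correction, and compared via

    ICER = ΔCost / ΔQALYs        INMB = ΔQALYs × WTP − ΔCost.

Also included: Kaplan-Meier digitization → pseudo individual-patient-data
reconstruction → Weibull maximum-likelihood fitting (the survival front end),
one-way ±20 % sensitivity analysis with tornado ranking, 1000-draw
probabilistic sensitivity analysis (gamma costs, beta utilities) with
cost-effectiveness acceptability curves, drug-donation cost schedules, and a
synthetic two-arm trial generator for end-to-end testing. See
`docs/methods.md` for assumptions and parameter provenance.

## Worked example

```python
import escc_cea as cea

config = cea.default_config()          # published base-case parameter set
result = cea.evaluate_population(config, "cps_ge1")
print(f"intervention: ${result.arm_a.cost:,.2f}, {result.arm_a.qalys:.4f} QALYs")
print(f"comparator:   ${result.arm_b.cost:,.2f}, {result.arm_b.qalys:.4f} QALYs")
print(f"ICER ${result.icer:,.2f}/QALY, INMB ${result.inmb:,.2f}, "
      f"cost-effective: {result.cost_effective}")
```

prints

```
intervention: $43,471.39, 0.7807 QALYs
comparator:   $13,910.26, 0.6186 QALYs
ICER $182,377.14/QALY, INMB $-23,456.38, cost-effective: False
```

i.e. adding serplulimab gains 0.162 discounted QALYs for an extra $29,561 over
ten years — about $182k per QALY, far above the $37,663.26/QALY threshold, so
the combination is not cost-effective at Chinese WTP (the published totals are
$43,427.43 / 0.78 and $13,879.55 / 0.62, ICER $184,674.25/QALY).

The same analyses from a shell:

```bash
escc-cea base-case --population cps_ge1 --outdir results
escc-cea owsa      --population cps_ge1 --outdir results --plot
escc-cea psa       --population cps_ge1 --seed 2023 --outdir results --plot
escc-cea simulate  --seed 7 --outdir results
escc-cea fit results/km.csv --n-total 368
```

Populations: `cps_ge1` (all PD-L1 CPS ≥ 1), `cps_1to10`, `cps_ge10` (see
`docs/methods.md` for a caveat on the shipped CPS≥10 comparator parameters).

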