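# Methods

## Decision problem and model structure

The package evaluates whether adding serplulimab (a PD-1 inhibitor) to
cisplatin/5-FU chemotherapy is cost-effective as first-line therapy for
PD-L1-positive (CPS ≥ 1) advanced esophageal squamous cell carcinoma from the
Chinese health-care payer perspective. A cohort moves through three mutually
exclusive states — progression-free (PFS), progressed disease (PD), death —
in monthly cycles over a 10-year horizon (120 cycles). Everyone starts in PFS.

State occupancy is computed by the partitioned-survival identity from two
independently fitted Weibull curves per arm:

    pfs(t) = S_PFS(t),   death(t) = 1 − S_OS(t),   pd(t) = max(0, S_OS(t) − S_PFS(t)),

with S(t) = exp(−λ t^γ), t in months, λ in month^−γ. This is the unique
occupancy consistent with both curves and with the per-cycle exit probability
P(t, u) = 1 − exp{λ(t−u)^γ − λ t^γ}; `trace_transition_check` verifies the
identity pfs(t) = pfs(t−1)·(1 − P(t,1)) to < 10⁻¹⁰ on every run. The
PFS→PD vs PFS→death split is defined residually — no source specifies it, and
no downstream quantity depends on it. If the fitted curves cross (S_PFS > S_OS),
the implied negative PD occupancy is clamped to zero with the mass assigned to
death, preserving row sums of 1; occurrences are logged. No crossing occurs
within the horizon for any shipped parameter set.

## Costs, utilities, discounting

All treatment-phase cost components (serplulimab, chemotherapy backbone,
antiemetics, tests, adverse-event management, hospitalization) accrue per cycle
while in PFS, with no cap on treatment duration; the subsequent-therapy cost
accrues per cycle while in PD. Costs are USD per monthly cycle (converted at
$1 = ¥6.77 upstream of the configuration; the conversion is not re-applied),
dosing at the standard 1.72 m² / 65 kg. Utilities are 0.68 (PFS), 0.42 (PD),
0 (death); each cycle contributes occupancy × utility / 12 QALYs. Both streams
are discounted at 5 %/year by elapsed months, d(t) = 1.05^(−t/12).

**Half-cycle correction (default: on).** Accrual uses trapezoid weights over
cycle boundaries 0..120 (half weight at both ends). This is the package's own
calibration of an unstated convention: with boundary-only accrual the CPS≥1
base case gives 0.752/0.590 QALYs and $41,073/$13,337, while the trapezoid
convention gives 0.781/0.619 QALYs and $43,471/$13,910 — matching the
published totals (0.78/0.62, $43,427/$13,880) to ≲0.2 %. The original model
was built in TreeAge, whose Markov engine applies a half-cycle correction by
default, which explains the fit. The switch `settings.half_cycle_correction`
restores boundary evaluation.

Decision statistics: ICER = ΔC/ΔE (undefined when ΔE = 0, reported as NaN with
dominance labelling), INMB = ΔE·WTP − ΔC, cost-effective ⟺ INMB > 0; WTP
defaults to $37,663.26/QALY (3× per-capita GDP).

**Donation schedules.** `donation_schedule_cost` expresses patient-assistance
programmes (e.g. pay 600 mg / receive 600 mg free / pay 600 mg / free until
progression, ≤ 2 years) as per-cycle multipliers in [0,1] on the drug component
with a hard cap. The published figure for this scenario ($96,535.81/QALY)
depends on unstated dose-rounding and block-timing assumptions, so the package
treats it only qualitatively: any schedule with multipliers ≤ 1 lowers the ICER
relative to base case (asserted in tests), but no specific value is reproduced.

## Survival front end

For populations where only a published KM figure exists, the pipeline is:
digitized coordinates → pseudo individual-patient data → Weibull MLE.

*Reconstruction* (`reconstruct_ipd`) uses the interval form of the
published-KM inversion methods: survival drops are converted to event counts by
product-limit inversion; when a numbers-at-risk table is available, the censor
count per inter-risk-time interval is chosen to reconcile the published number
at risk and censor times are spread uniformly within the interval (two passes:
events assuming no interior censoring, then interleaved re-allocation);
without a risk table, censoring is assumed to occur only at the final
follow-up time, so a terminal plateau maps to administratively censored
subjects. Round-trip accuracy (KM of the reconstruction vs the input curve) is
required to be < 0.02 absolute survival for n ≥ 200 — the digitization noise
floor — and achieves ~0.001–0.005 in tests.

*Fitting* (`fit_weibull_mle`) maximizes the right-censored Weibull
log-likelihood Σ_events[log λ + log γ + (γ−1)log t] − λΣ_all t^γ in
(log λ, log γ) space (unconstrained, scale-stable), initialized from a
least-squares fit of log(−log S_KM) against log t, refined by Nelder-Mead then
BFGS with tight tolerances, so the result is deterministic for a given input.
Standard errors come from the numerically differentiated observed information
via the delta method. `fix_gamma=1` recovers the closed-form exponential MLE
(events / total exposure). Whether the original analysis fitted the
reconstructed-IPD likelihood or least squares on the curves is not stated; MLE
on pseudo-IPD is implemented, and the published λ/γ table is taken as the
authoritative input to the economic model either way.

## Sensitivity analysis

*OWSA*: each parameter is set to base·(1±20 %) with everything else fixed and
the full model re-run; entries are ranked by |INMB(high) − INMB(low)|
(tornado order, invariant to the INMB sign convention). Varied parameters are
every cost component and both utilities; Weibull parameters are excluded (they
are treated as fixed throughout). The "PFS-phase cost" of an arm is implemented
as joint ±20 % scaling of all that arm's treatment-phase components, matching
the aggregated tornado labels of the source analysis. Utilities are capped at
their logical bounds (u_pfs ≤ 1, u_pd ≤ u_pfs) when scaled up.

*PSA*: 1000 Monte Carlo iterations resample every cost component from
moment-matched gamma distributions (shape = mean²/se², rate = mean/se²) and
both utilities from moment-matched beta distributions (α = mean·ν,
β = (1−mean)·ν, ν = mean(1−mean)/se² − 1), utilities drawn once per iteration
and shared across arms; survival parameters stay fixed, so each arm's trace is
built once. Standard errors are not published; the default is se = 20 % of the
mean for every sampled parameter, mirroring the OWSA span (configurable via
`psa.se_fraction`). A single seeded `numpy` generator drives the run; the seed
is recorded in the output metadata and identical seeds give byte-identical
CSVs. The CEAC reports, over a WTP grid ($0–$250,000 in $2,500 steps by
default, covering the $100k/$200k discussion thresholds), the fraction of
draws with ΔE·WTP − ΔC > 0.

## Synthetic trial generator

`simulate_trial` emulates a two-arm first-line trial: 2:1 allocation (368/184
by default), Weibull PFS/OS event times by inverse transform, administrative
censoring at 15 months (the reported ~14.9-month median follow-up). PFS and OS
are comonotone — one uniform draw per subject drives both inverse transforms,
plus a min() clamp — so PFS ≤ OS holds for every subject while both marginals
remain exactly the specified Weibulls wherever the PFS curve lies below the OS
curve (true to ~t ≈ 2750 months for the shipped parameter sets). A shared
latent-death construction with an independent progression time was rejected
because taking minima adds the hazards and contaminates the PFS marginal,
defeating parameter-recovery testing. Consequences: the generator's perfect
rank correlation between endpoints is stronger than real trial data, and
curve-crossing handling in the Markov engine is exercised only via directly
specified parameters, not via simulated cohorts. `make_digitized_fixture`
emulates plot digitization: evenly spaced time samples, truncated Gaussian
survival noise (default sd 0.005, a typical plot-extraction error), and a
running-minimum to restore monotonicity.

What passing the end-to-end recovery test (simulate → KM → digitize →
reconstruct → fit, within 2 SE at n = 500) shows: the front end is internally
consistent under idealized digitization. It does not validate against real
pixel-level digitization artifacts (axis skew, curve overplotting), informative
censoring, or non-Weibull hazards.

## Known limitations and flagged inputs

- The shipped CPS≥10 chemotherapy-arm Weibull parameters imply an OS median of
  ~4.8 months, inconsistent with that subgroup's reported trial median (13.9
  months) and with the published per-arm QALYs; they look like a transcription
  error in the source table but are shipped as printed. Full-model totals are
  therefore asserted only for CPS≥1 and 1≤CPS<10; for CPS≥10 only the
  worked-example arithmetic (ICER/INMB from printed ΔC, ΔE) is checked.
- Two published INMB values (−$29,547.88 overall, −$28,420.65 for 1≤CPS<10)
  equal −ΔC rather than ΔE·WTP − ΔC; the third (−$26,196.62, CPS≥10) follows
  the formula. The package always applies the formula (overall INMB
  −$23,521.76 from the printed ΔC/ΔE) and documents the discrepancy rather
  than reproducing it.
- Non-Weibull survival models, model selection by information criteria,
  societal costs, value-of-information analysis and multi-way sensitivity
  analysis are out of scope.

## Problem sizes and numerics

Deterministic runs evaluate 121 cycle boundaries per arm (milliseconds). PSA
uses 1000 iterations; distribution moment checks use 10⁵ draws at 1 %
tolerance; MLE recovery tests use n = 2000 (direct) and n = 500 (end-to-end,
2-SE criterion); round-trip reconstruction tests use n = 200–500. Conservation
of trace occupancy is enforced at 10⁻¹⁰, the transition-recursion identity at
10⁻¹⁰, mean-survival closed form vs quadrature at 10⁻⁴ relative. Ties in MLE
optimization are avoided by the deterministic two-stage optimizer; degenerate
inputs (all-censored data, zero-length intervals, empty parameter lists,
negative rates) raise typed validation errors rather than propagating NaNs.
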