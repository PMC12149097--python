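# Methods

## Decision problem and model structure

The package compares two first-line strategies for high-volume
metastatic hormone-sensitive prostate cancer (mHSPC) in China:
rezvilutamide + ADT versus bicalutamide + ADT. A cohort Markov model
with three health states — progression-free (PFS), progressed disease
(PD) and Death (absorbing) — tracks a cohort that starts entirely in
PFS. Patients leave PFS by progression or death; PD patients remain or
die.

Cycle length is 28 days (matching the 4-week dosing cycle); the horizon
is 13 years, i.e. `floor(13 × 365.25 / 28) = 169` complete cycles
(12.96 years), chosen to carry a cohort with median age ~69 to the
national life expectancy. Costs and QALYs are discounted at 5 % per
year, varied 0–8 % in sensitivity analysis. Willingness-to-pay is fixed
at $37,256.3/QALY (3× 2023 per-capita GDP); it is taken as a given
input rather than recomputed from GDP series.

### Transition probabilities from survival curves

The model's only clinical inputs are a PFS and an OS curve per arm.
Transitions are derived by *marginal matching*: whenever feasible the
boundary occupancies reproduce the partitioned-survival identity
π_PFS(t) = S_PFS(t), π_Death(t) = 1 − S_OS(t), π_PD = S_OS − S_PFS.
Over cycle [t, t+1]:

- p(PFS→PFS) = S_PFS(t+1)/S_PFS(t);
- total new deaths d = S_OS(t) − S_OS(t+1); the PFS exit flow assigns
  deaths at the marginal OS hazard d/S_OS(t), capped so p(PFS→PD) ≥ 0;
- p(PD→Death) absorbs the remaining deaths so cumulative mortality
  tracks 1 − S_OS exactly.

Infeasible cells (possible when curves cross or PD is empty) are
clamped to [0,1] with the row renormalised and a diagnostic logged;
S_PFS > S_OS is clipped to S_OS (progression-free patients are alive).
With exponential test curves the boundary occupancies match the closed
forms to ~1e−16 (tested at 1e−10); with log-normal curves the
discounted QALYs match direct numerical integration of the
partitioned-survival areas to ≈0.2 % (tested at 0.5 %), the residual
being the within-cycle discretisation of the discount factor.

Half-cycle correction (outcome accumulation on the average of start-
and end-of-cycle occupancy) is on by default; the source analysis is
silent on it, and it is a flag. A one-time end-of-life cost hook exists
and defaults to $0 (no value is published).

## Survival inputs

### Pseudo-IPD reconstruction (Guyot interval algorithm)

Digitized curve coordinates plus the numbers-at-risk table are inverted
into per-patient records. Within each risk-table interval the number of
censorings is solved iteratively: censor times are spread uniformly
across the interval (the standard assumption), events at each
coordinate follow from the KM step given the running at-risk count
(with a largest-remainder carry so integer rounding does not
accumulate), and the censoring count is adjusted until the implied
number at risk at the next interval start matches the published one.
Because no total-death count is published, the unconstrained variant is
used: the final interval assumes no interim censoring, and everyone
still at risk after the last coordinate is censored there. Residual
mismatches within digitization rounding (≤ max(2, 2 % of n)) are
accepted; larger ones raise an error naming the interval. The
reconstruction is deterministic.

A cleaning pass precedes reconstruction: survival clipped to [0,1],
monotone non-increasing staircase enforced by a running-minimum clip,
duplicate times deduplicated (last reading kept), and a (0, 1) anchor
inserted if the digitizer missed it.

On synthetic 326-patient arms digitized on a 0.5-month grid with exact
6-monthly risk tables, the KM curve of the reconstruction matches the
input coordinates to sup-norm ≈0.005 (tested at 0.02), and refitting
recovers the generating log-normal parameters within 5 %. That 5 % at
n = 326 is ≈1.3 sampling standard deviations for σ, so the check is a
joint test of algorithm and sampling noise, not of the algorithm alone.

### Parametric fitting and selection

Five families are fitted by maximum likelihood under right censoring
(`ll = Σ_events log f + Σ_censored log S`): exponential (rate),
Weibull (shape, scale), log-normal (μ, σ), log-logistic (shape, scale)
and Gompertz, parameterised h(t) = a·e^{bt} with a > 0 and b
unrestricted so decreasing hazards are allowed. Optimisation runs on
log-transformed positive parameters (Gompertz b untransformed) with
moment-based multi-starts, Nelder–Mead polished by BFGS; the fitting
code is cross-checked against lifelines' Weibull and log-normal fitters
in the test suite. Selection minimises AIC = 2k − 2ll (or
BIC = k·ln n − 2ll), ties broken by fewer parameters then by the fixed
family order exponential < Weibull < log-normal < log-logistic <
Gompertz. On log-normal data at n = 5,000 AIC selects log-normal in
≥95 % of seeds (observed: 100/100).

Time is handled internally in months; the cycle grid converts via
1 month = 365.25/12 days.

## Costs and utilities

All costs are 2024 USD (converted at 7.1954 CNY/USD) and live in
`src/mhspc_cea/data/params.yaml` with value / low / high / distribution
per item. Per-cycle PFS cost = first-line drug ($823.03 rezvilutamide,
$120.75 bicalutamide) + ADT backbone ($148.55, the average across the
four LHRH agents) + monitoring. PD cost = uptake-weighted subsequent
therapy + supportive care ($117.1/cycle) for the remainder +
follow-up. Grade ≥3 adverse events (hypertension, hypertriglyceridemia)
are charged once at model entry as incidence × unit cost (7 %/2 % in
the rezvilutamide arm, 8 %/7 % with bicalutamide). Utilities: PFS 0.76,
PD 0.68.

Choices the published inputs leave open, fixed here as configurable
defaults:

- **Subsequent-therapy uptake**: 27 % mapped to the rezvilutamide arm
  and 62 % to the bicalutamide arm (sentence order matches arm order);
  a config field because the source sentence is ambiguous.
- **Basket composition**: equal thirds abiraterone (+prednisone),
  enzalutamide, docetaxel — the explicitly listed options; apalutamide
  and darolutamide prices are carried in the file but unweighted.
- **Monitoring schedule** (only unit prices are published):
  testosterone + PSA every cycle and CT every third cycle in PFS;
  follow-up every cycle in PD; the routine-treatment/checklist item is
  priced but disabled.
- **AE costs are one-time**, since the incidences are trial-level, not
  per-cycle.

## Economic evaluation

ΔC, ΔQ, ICER = ΔC/ΔQ (only when ΔQ > 0 and ΔC > 0; dominance flagged
otherwise) and NMB = λΔQ − ΔC, with internal arithmetic unrounded and
rounding (cents, 2-decimal QALYs) confined to the reporting layer —
necessary because published tables that round first produce
inconsistent increments (e.g. an incremental-QALY figure that appears
as 2.15 or 2.16 depending on where the rounding happens).

The threshold price solves NMB(price) = 0 by bisection to $0.01. NMB is
strictly decreasing in the price (the intervention arm's cost is
affine-increasing in it), so this is equivalent to ICER = λ wherever
the ICER is defined and remains well-posed when the lower bound makes
the intervention dominant. If even the upper bound is cost-effective
the upper bound is returned (any price acceptable); if even a free drug
is not, the solve raises with the boundary ICERs.

## Sensitivity analysis

One-way: every cost item ±20 %, utilities ±10 %, discount rate 0–8 %,
each re-evaluated at its bounds with everything else at base, ranked by
ICER spread. Parameters the model never reads produce zero-width bars
and are kept in the table. Model failures at an extreme flag the row
rather than dropping it.

Probabilistic: 10,000 replicates, each drawing all parameters
independently — gamma for costs (shape = (base/se)², rate = base/se²),
beta for utilities and the discount rate (method of moments) — with
se = (high − low)/3.92, i.e. the one-way range read as a 95 % interval.
Moment matching makes every sampled mean equal its base value. The CEAC
reports the fraction of draws with positive NMB on a λ grid that always
includes $37,256.3. Survival-curve parameter uncertainty is *not*
sampled (the published distribution table lists only costs, utilities
and discounting); state occupancies are therefore fixed across draws,
which also keeps each replicate to a pair of dot products. A PSA
mean-ΔC check against the deterministic ΔC is meaningful only for
parameters the model is ~linear in (costs; utilities never enter ΔC) —
the discount rate enters convexly and would bias the comparison by
construction, so it is held at base for that check.

## Synthetic trial generator

The generator emulates the structure of the source trial: two arms of
326, reference (bicalutamide) PFS log-normal with median 25.1 months
and σ = 0.9; OS = PFS + an independent post-progression survival (PPS)
draw, log-normal median 30 months, σ = 0.8 — realistic for progression
to castration resistance followed by second-line therapy, and
guaranteeing PFS ≤ OS per patient. The treated arm is an
accelerated-failure-time scaling: PFS times ×1.9033 and PPS ×0.7991,
calibrated once by bisection on large simulated samples (n = 120,000,
Cox fits) so the *marginal* hazard ratios hit the trial's 0.44 (PFS)
and 0.58 (OS) — an AFT coupling is needed because the log-normal family
has no proportional-hazards representation. The PPS factor lands below
1: the PFS benefit alone pushes the marginal OS hazard ratio under
0.58, so matching both ratios requires somewhat worse post-progression
survival in the treated arm. Administrative censoring is exponential at
0.01/month truncated at 48 months of follow-up; both are free
parameters (nothing is published about the trial's censoring), chosen
to give event fractions typical of an interim-maturity readout.

What the generator does **not** emulate: the real trial's accrual
pattern and calendar censoring, covariate structure, treatment
discontinuation/crossover, and any deviation of the true curves from
the log-normal family. Passing tests therefore demonstrate that the
pipeline recovers known generating truths and published-table
arithmetic — not that the synthetic base case reproduces the published
base case, which depends on unpublished digitized coordinates and
fitted parameters. Indeed the synthetic extrapolation lands on the
cost-effective side of the threshold while the published analysis lands
marginally on the other side; both agree the rezvilutamide price is the
dominant lever.

## Numerical and reproducibility notes

- One global seed fans out to per-stage child seeds via
  `numpy.random.SeedSequence.spawn` (stage order: trial, PSA), so
  stages can be re-run in isolation; all seeds stay below 2³¹.
- Occupancy conservation is asserted at every cycle (tolerance 1e−12);
  Death occupancy is monotone by construction (absorbing state).
- Problem sizes used by the shipped analyses: 326 patients/arm,
  0.5-month digitization grid, 6-month risk tables, 169 cycles,
  10,000 PSA draws, 100 seeds for the selection-consistency study.
- Degenerate inputs: equal PFS/OS curves yield exactly zero progression
  probability; all-censored arms give a flat KM curve but cannot be
  reconstructed (no events) or fitted (<2 events), by design.

## Known limitations

- Transition derivation from marginal curves is not unique; marginal
  matching is one defensible construction (it reproduces both published
  curves exactly when feasible), but other splits of the death flow
  between PFS and PD are possible and would shift state-time, hence
  costs.
- The unconstrained Guyot variant cannot disentangle events from
  censoring beyond the last risk-table entry; heavy unreported
  censoring would bias reconstructed tails.
- Gompertz fits with strongly negative b imply defective distributions
  (a surviving fraction); selection by AIC can still prefer them on
  immature data, which is why visual-inspection judgement is left to
  the analyst when curves are supplied externally.
- No treatment-duration cap, dose adjustment, drug wastage, or societal
  costs; subsequent-therapy duration equals PD state-time.
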