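# Methods

## The decision problem

Locally advanced gastric cancer with no radiographic metastases is treated
with curative-intent gastrectomy — unless free cancer cells are found in
peritoneal washings (positive peritoneal cytology, CY1), which upgrades the
disease to M1 and makes systemic chemotherapy, not resection, the
recommended treatment.  The model compares three ways of resolving the
unknown cytology status of a 56-year-old Chinese cohort:

* **LPL** — intraoperative laparoscopic peritoneal lavage (the guideline
  approach): sensitive (84.6% for occult peritoneal metastases, OPM) but
  expensive ($2,213) and requiring general anaesthesia;
* **PPL** — preoperative percutaneous peritoneal lavage: cheap ($246) and
  bedside, but less sensitive (75.9%), with every PPL-negative patient
  proceeding to an exploratory laparotomy with intraoperative cytology;
* **ELNC** — exploratory laparotomy with no cytology (common practice in
  resource-limited regions): finds all visible implants but necessarily
  misses cytology-only disease (CY1P0, prevalence 6.4%).

Specificity is modelled as 1 throughout (false-positive cytology is not
observed in the source studies), so every test error is a false negative.

## Model structure

A short-term decision tree resolves the staging procedure, its
complications (cost-only, no utility decrement: the complicated fraction
pays a 3-fold procedure cost) and perioperative mortality, then hands each
survivor stratum to one of three monthly-cycle Markov models — curative
resection, palliative (non-curative) resection for missed OPM, and
chemotherapy for detected OPM — each with three states (disease- or
progression-free survival, progressive disease, death) run for 40 years.

One structural choice deserves emphasis.  The perioperative mortality of
exploratory laparotomy (1.5%) is applied to **every** patient who is
surgically opened in the PPL and ELNC arms — including those who proceed to
gastrectomy in the same operation (gastrectomy mortality, 2.7%, is then
applied sequentially to the resected).  An open exploration carries its
operative risk whether or not resection follows, and this risk on the large
OPM-free stratum is precisely what PPL and ELNC trade against LPL's safer
(0.07% mortality) but costlier laparoscopic staging.  It is also the only
attribution under which laparotomy mortality can be an influential
parameter at all: confined to the small nontherapeutic subset (~5% of the
cohort) it would move the strategies' QALYs in the fourth decimal, whereas
applied to all laparotomies it produces the observed ~0.07 QALY gap between
LPL and PPL and a laparotomy-mortality threshold (~0.9%) close below its
base value.

### Transition probabilities

Disease transitions come from parametric survival curves refit to published
trial Kaplan-Meier data (time in months):

| transition | arm | family | parameters |
|---|---|---|---|
| DFS→PD, curative | adjuvant-chemo gastrectomy (CLASSIC) | Weibull | λ=0.0132, γ=0.8454 |
| PFS→PD, palliative surgery | gastrectomy+chemo (REGATTA) | log-logistic | a=0.0142, b=2.0360 |
| PFS→PD, chemotherapy | chemo-alone (REGATTA) | log-logistic | a=0.0069, b=2.3024 |
| PD→death | docetaxel (COUGAR-02) | Weibull | λ=0.0654, γ=1.3663 |

with S(t)=exp(−λt^γ) and S(t)=1/(1+at^b).  Per-cycle probabilities are
p_t = 1 − S(t+1)/S(t), which telescopes exactly back to S (tested to
1e-10).  Background mortality in the front state uses an annual life table
converted monthly, 1−(1−qx)^(1/12); death from progressive disease is the
maximum of the trial-based PD hazard and background mortality.  The PD→death
clock runs on time since PD entry, tracked exactly (at monthly resolution)
by per-entry-cycle sub-cohorts rather than by a single memoryless PD state.
Competing risks in the front state allocate background death first, then
progression among survivors: p_dead = p_bg, p_pd = (1−p_bg)·p_prog, which
avoids double-counting deaths already present in the trial curves.

### Costs and utilities

Costs are 2019 US$ (¥6.75/$), societal perspective, as annual blocks
(direct medical + indirect + direct non-medical) accrued monthly:

* curative arm: surgery block ($10,601/yr) during months 1–12 plus
  adjuvant chemotherapy $2,635/cycle in months 1–6; disease-free months
  beyond the first year accrue no further cost (no surveillance costs are
  charged — none are published);
* palliative-surgery arm: the same first-year schedule as the curative arm
  — surgery block plus the six adjuvant-chemotherapy cycles — because this
  arm is a resection followed by postoperative chemotherapy ("gastrectomy
  plus chemotherapy"); the chemotherapy block ($5,256/yr) applies while
  progression-free thereafter;
* chemotherapy arm: chemotherapy block throughout PFS;
* progressive disease (all arms): palliative-therapy block ($4,331/yr).

Utilities: 0.68 during adjuvant months (<6 m), 0.81 post-gastrectomy,
0.54 after palliative resection, 0.66 on chemotherapy, 0.40 in progressive
disease.  QALYs and costs are discounted at 3%/yr, (1.03)^(−cycle/12);
accruals are taken at cycle start with no half-cycle correction (a
trapezoidal flag exists but is off by default).  The number of adjuvant
cycles (6) is inferred from the "<6 m" utility window; it is not printed
anywhere as a cycle count.

### The life table

No usable accession exists for the life table behind the published model, so
the default is a synthetic Gompertz–Makeham stand-in,
qx(age) = 1 − exp(−(A + B·c^age)) with A=5·10⁻⁵, B=3.5·10⁻⁵, c=1.094
(qx(56)≈0.0054, qx(80)≈0.045), ages 0–100 with qx(100)=1.  Any real table
can be supplied as an `age,qx` CSV.  Background mortality is a second-order
influence here (most model deaths are disease deaths), but the undiscounted
life-expectancy-driven totals are the quantities most sensitive to it.

## Decision analysis

ICERs are incremental cost per QALY along the efficiency frontier after
strict- and extended-dominance pruning; the willingness-to-pay threshold is
$29,313/QALY (three times the 2018 per-capita GDP of $9,770.85).  Net
monetary benefit (wtp·QALY − cost) backs the probabilistic results; at any
WTP the max-NMB strategy coincides with the ICER-rule choice (property
tested on random outcome triples).

One-way sensitivity analysis re-runs the pipeline at each parameter's range
ends (ranges are read uniformly as 95% central intervals); threshold
analysis bisects on the NMB difference of LPL vs PPL, whose root equals the
ICER = WTP crossing while remaining defined where one strategy dominates
(bracket tolerance 1e-6, max 200 iterations).  The PSA draws all parameters
independently — beta for probabilities/utilities, gamma for costs, normal
for the cost fold, moment-matched with mean = base and SD = (high−low)/3.92
— in 1,000 Monte Carlo draws; draws violating structural invariants
(p_cy1p0 > p_opm, fold < 1) are redrawn and counted.  Acceptability curves
report, per WTP on a $0–60,000 grid (step $500), the fraction of draws in
which each strategy attains maximal NMB, ties split equally.

Because the trial survival parameters and the life table are structural
constants (not Table-style uncertain inputs), the three cohort traces are
computed once and reused: every OWSA/threshold/PSA re-evaluation reduces to
decision-tree arithmetic plus accruals that are linear in the varied
utilities and costs.  This is an exact factorisation, not an approximation,
and it keeps a full 1,000-draw PSA under two seconds on one core.

## Survival refitting stage

Published curves enter as digitized (time, survival) points.  Fitting is
weighted nonlinear least squares on the survival scale (weights ∝ the
initial at-risk hint, uniform otherwise), with deterministic closed-form
starts (exponential rate from the terminal point; Weibull seeded at γ=1;
log-logistic at b=1 with a from the median crossing; log-normal μ from the
median, σ=1).  The reported log-likelihood is the Gaussian profile
likelihood of the residuals, from which AIC = 2k − 2ℓ and
BIC = k·ln(n) − 2ℓ; model selection takes the lowest-BIC converged fit,
ties broken by AIC and then a fixed family order.  This is a curve-refit
surrogate — digitized points carry no individual-level information, so
these are not true data likelihoods, and the criteria are comparable only
across families fit to the same points.

## Synthetic data generator

`simulate_km` emulates the digitization pipeline from known ground truth:
inverse-CDF event times for any of the four families, independent
exponential censoring at a monthly rate, a Kaplan–Meier step estimate
(lifelines), an equally spaced reading grid over (0, t at S=0.05], and
additive Gaussian "operator" noise (SD 0.01 by default, the scale of
reading error off a published plot) clipped to [0,1] and monotonized by
running minimum.  Defaults: 1,000 subjects, 60 grid points.  What it does
not emulate: dependent censoring, number-at-risk tables, axis-calibration
bias, or the within-curve correlation structure of a real digitizer trace
beyond what the KM step process induces — so passing recovery tests show
correctness of the fitting machinery under honest sampling noise, not
digitizer-grade fidelity.

A known limitation follows from that correlation: under the least-squares
BIC surrogate, noisy pseudo-digitized curves do not reliably separate the
exponential from the Weibull that nests it (the autocorrelated noise gives
the extra Weibull parameter more gain than the χ²(1) the penalty assumes),
nor the log-logistic from the log-normal, whose survival functions differ
by less than the noise scale at these parameter values.  Measured recovery
at n=1,000/noise 0.01 over 50 seeds: Weibull 100%, log-normal ~90%,
exponential ~30–50%, log-logistic ~45–50%.  Noiseless curves recover the
generating family and its parameters exactly (tested for all four).

## Problem sizes and numerics

Deterministic analyses run the full 480-cycle horizon; the PSA uses 1,000
draws; recovery experiments use 50 seeds × 4 families at 1,000 subjects —
all chosen to match the study design the model reproduces.  Occupancy is
conserved to 1e-10 per cycle; the engine matches an independent brute-force
enumeration (plain-Python dict of PD entry cohorts, closed-form survival)
to 1e-8 on a 24-cycle toy.  Degenerate inputs are handled explicitly:
S(t)=0 saturates the transition probability at 1 with a warning; ages
beyond the life table clamp to its last row; a beta whose matched variance
is infeasible for its mean falls back to uniform on the range; fits that
fail to converge are flagged, never raised, and excluded from selection.

## Known limitations

* Several costing details of the original model are unpublished
  (surveillance, adjuvant cycle count, the palliative arm's schedule); the
  choices above are disclosed and produce base-case outcomes within a few
  percent of the published table, but exact reproduction is not expected.
* The CY1PX/CY0P1 split within OPM is unpublished, so PPL sensitivity is
  applied to all OPM rather than to the cytology-positive subset.
* Parameters are drawn independently in the PSA; any correlation among the
  three cost sub-components of a block is ignored.
* Neoadjuvant chemotherapy and conversion surgery are outside the model:
  cytology-positive patients cannot convert to resectability.
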