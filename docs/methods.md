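# Methods

`isocal` implements the analysis chain for indirect-calorimetry studies of
isolator-housed mice with defined microbiota status (germ-free GF,
gnotobiotic OLIGO carrying a 12-strain community, conventionally raised
SPF): datapoint quality control, gas-exchange and energy-expenditure
computation, circadian summarization, covariate normalization, and
energy-balance accounting with propagated uncertainty. Because raw data
from such systems are rarely shareable, the package ships a synthetic-study
generator with the same statistical structure, so every stage is testable
and parameter recovery is demonstrable end to end.

## Time base and phases

All clock times are converted to Zeitgeber time (ZT): hours since the most
recent lights-on event, modulo 24. ZT 0–12 is the light (resting) phase and
ZT 12–24 the dark (active) phase; phase membership is half-open, so ZT 12.0
belongs to the dark phase. The lights-on wall-clock time is a required
dialect parameter, not a default — it is a property of the animal room and
there is no safe guess. Records are kept on a fixed daily grid anchored at
each mouse's first ZT 0; anything recorded before that instant is
discarded, because a partial pseudo-day would bias circadian summaries.

## Quality control

Faults in long-running cage systems have recognisable signatures, removed
in a fixed order so that attribution is unambiguous (each record counts
toward the first rule it triggers, making
`input = surviving + Σ removals` an exact invariant):

1. **Food sentinel** — a reading equal to 0.01 g per interval is balance
   noise; matched within half the balance resolution (default ±0.005 g)
   because stored floats carry formatting noise.
2. **Negativity** — negative food, water, dO₂ or dCO₂ are physically
   impossible under the sign conventions below.
3. **High intake outliers** — food or water above Q75 + 1.5·IQR per mouse
   (leaky bottles, dropped pellets).
4. **Low gas outliers** — dO₂ or dCO₂ below Q25 − 1.5·IQR per mouse
   (unsealed cages, clogged pre-analyzer filters).

Quartiles are type-7 (linear interpolation) and are pooled over all days of
a mouse, computed once on the records surviving rules 1–2. Re-estimating
them after removal is deliberately avoided: a single clean-up pass is the
documented contract, and the thresholds are part of the QC report, so
re-applying the QC with those recorded thresholds removes nothing
(fixed-threshold idempotence). Mice with fewer than four eligible records
get no quartile thresholds and are flagged.

Finally, any mouse-day in which strictly more than 20 % of the expected
daily grid (60 records at the 24-min cadence) was lost is discarded
entirely: a 12/60 day is retained, a 13/60 day is dropped. The denominator
is the expected grid, not the observed count, so ingest-level rejections
count toward the same budget.

## Gas exchange

Sign conventions: `d_o2 = reference − cage` (consumption positive) and
`d_co2 = cage − reference` (production positive). With outlet flow F_out
equal to the configured extraction flow and cage fractions
Fe_O2 = ref_O2 − d_o2, Fe_CO2 = ref_CO2 + d_co2, inert-gas (N₂)
conservation F_in·(1 − ref_O2 − ref_CO2) = F_out·(1 − Fe_O2 − Fe_CO2)
fixes the inlet flow (the Haldane transformation), giving

    VO2  = F_in·ref_O2  − F_out·Fe_O2
    VCO2 = F_out·Fe_CO2 − F_in·ref_CO2

implemented in an algebraically identical but cancellation-free form
expressed through the differentials directly. Reference-air fractions
default to 0.2095 / 0.0004 and are configurable. Energy expenditure uses
Weir's abbreviated equation, EE = 3.941·VO2 + 1.106·VCO2 (kcal, volumes in
litres), without the urinary-nitrogen term — standard for metabolic cages,
where no nitrogen data exist. Air is assumed dry at the sensors (upstream
dehumidification); no STP or humidity correction is applied. RER is
VCO2/VO2, undefined (propagated as missing) when VO2 = 0. The hydrogen
production rate is the H₂ differential times flow (ppm·L/min).

## Circadian summarization

Per-phase energy expenditure is the trapezoid AUC of the instantaneous EE
over half-open windows [t0, t1), with window-edge values obtained by linear
interpolation; this makes light + dark = full-day exact, and QC gaps are
spanned by a single trapezoid (the documented choice for missing data —
no imputation). Food intake over a window is cumulative; RER is averaged
pointwise. The final recorded day has no closing grid point, so its AUC is
short by one cadence interval (0.4 h of 24, ≈1.7 %); per-mouse summaries
exclude the last day by default.

For curves whose continuous evolution matters (RER, gross hydrogen),
values are first averaged at each time point within each mouse — mice, not
records, are the unit — and a penalized cubic regression spline is fitted
to the means: cubic B-spline basis (default dimension 10, cyclic over the
24-h period by default since the schedule is periodic), second-order
difference penalty, and smoothing parameter chosen by generalized
cross-validation (GCV = n·RSS/(n − edf)², λ on a log grid from 1e−10 to
1e6). With noiseless data GCV drives the penalty to its smallest grid
value and recovers any curve in the spline space essentially exactly; a
rank-deficient design triggers basis reduction with a warning. No cosinor
or period estimation is attempted — the light schedule fixes 24 h.

## Covariate normalization

Dividing energy expenditure by body mass is biased whenever groups differ
in metabolically inert mass: a GF mouse carries up to ~10 % of its body
mass as cecal content (water, largely), which spends no energy but
inflates the denominator. The regression-based alternative fits

    EE ~ lean mass + dissected fat mass + group

with group as a qualitative covariate and a single slope per covariate (no
interactions), then replaces each value by its residual plus the model
prediction at the covariate grand means with the mouse's own group
coefficient retained. Group contrasts on adjusted values therefore equal
the ANCOVA adjusted means, and genuine group effects survive adjustment.
Grand means are mouse-weighted (pooled over all mice rather than averaged
per group); this is recorded in the fit notes. The fat covariate is the
sum of the dissected depots (iBAT + iWAT + vWAT), not an MRI readout,
because cecal content corrupts MRI fat estimates in GF mice. Hydrogen
production is adjusted analogously with cecal mass (a proxy for total gut
microbiota mass) as the single covariate; GF mice produce no microbial
hydrogen and are excluded from that fit. Classical ratios (per total mass,
total mass without cecum, or lean mass) are provided for comparison; no
allometric exponent is fitted.

Group comparisons use one-way ANOVA with Tukey's honest significance test
(Tukey–Kramer for unbalanced designs), applied to per-mouse summaries —
no repeated-measures modelling. Applying Tukey to ANCOVA-adjusted values
mirrors the two-step adjust-then-compare practice and is statistically
approximate: the covariate-fit degrees of freedom are not carried into the
comparison, which makes the test slightly liberal at small n (measured
family-wise error ≈0.05–0.065 at n = 10/group in the calibration test).

## Energy balance and uncertainty

Group-level inputs enter as mean ± SEM over mice, treated as independent
Gaussian sources, and all derived quantities propagate uncertainty by the
first-order Taylor method (u(x±y) = √(u_x²+u_y²), u(xy) = √((y·u_x)² +
(x·u_y)²), division analogous); correlations are unsupported and would
require a covariance-aware substrate. Reported intervals are mean ± 1.96u.
The bookkeeping: input = intake × 3.94 kcal/g chow; excretion = fecal dry
mass × bomb energy density; extraction = input − excretion (exact in the
means); percent extraction = 100·(input − excretion)/input with partials
100·y/x² and −100/x.

**Validity envelope.** First-order propagation matches a 10⁶-draw Monte
Carlo SD to well under 2 % for sums, differences and products at input
relative uncertainties up to 10 %. For reciprocal-containing operations
(division, percent extraction) the first-order result systematically
understates the sampled spread as the denominator's relative uncertainty
approaches 10 % (≈3 % deviation at exactly 10 %, stable across MC seeds) —
a second-order property, aggravated by the fact that the variance of a
ratio with a Gaussian denominator is formally divergent. The acceptance
test asserts the 2 % agreement at 2 %, 5 % and 10 % relative uncertainty
per operation; the two reciprocal cases at 10 % fail by this margin and
are left failing as an honest statement of the envelope. In the actual
energy-balance inputs (SEM-scale uncertainties of a few percent) the
approximation is comfortably inside 2 %.

The microbial contribution to fecal energy density is cell density ×
2.26e−13 g dry mass/cell × 4.58 kcal/g dry mass; with measured cecal
densities of 1.1e11 (OLIGO) and 1.6e11 (SPF) cells/g this gives 0.11 and
0.17 kcal/g. Note the estimator applies a per-gram-of-cecal-content
density to per-gram-of-dry-feces energy; the two denominators are not
identical, so the function emits a warning and the result should be read
as an order-of-magnitude bound. Cecal metabolite pools are concentration ×
group cecal mass with the same propagation.

## Cytometry

Absolute bacterial density from bead-normalized counts:
cells/g = (bacterial events / bead events) × bead concentration × mix
volume ÷ aliquot volume × homogenate volume ÷ sample mass. Defaults:
4.55e3 beads/µL, 2 µL of a 1 mL homogenate, 200 µL stained mix (the mix
volume is a required assay parameter chosen here for round numbers — every
factor of the dimensional chain is exposed rather than hard-coded).
Germ-free samples define the blank; a sample at or below the blank count
is flagged rather than reported as a positive density. Counts are taken as
already gated; no FCS parsing or flow-rate model.

## Synthetic studies

The generator emits complete studies in raw sensor space: latent daily EE
per mouse (intercept 3.0 kcal/day + 0.30 kcal/day per g lean mass +
configurable group effect + N(0, 0.25) mouse scatter, ≈9 kcal/day at 20 g
lean) modulated sinusoidally over the day (relative amplitude 0.3, peak ZT
18; the modulation integrates to zero over 24 h), converted to VO2/VCO2
through the group×phase RER profile and then inverted through the Haldane
mass balance to dO₂/dCO₂ — so the pipeline's forward computation is
exercised nontrivially, and with noise and faults off the pipeline
recovers latent EE to <0.5 %. Defaults encode the targeted study
conditions: cecal masses 3.0/1.5/0.5 g (GF/OLIGO/SPF), GF intake ≈15 %
above colonized (4.0 vs 3.5 g/day), fecal energy density 3.7 (GF) vs 4.0
(colonized) kcal/g, fecal dry mass set so every group extracts ≈9
kcal/day, colonized cecal densities 1.1e11/1.6e11 cells/g, RER profiles
ordered GF < OLIGO < SPF in the light phase and GF < OLIGO ≈ SPF in the
dark, hydrogen as a dark-phase peak scaled by cecal mass (with a higher
per-gram rate in OLIGO) and pure blank noise in GF, 24-min cadence at 0.4
L/min, n = 10 per group for 10 days. Feeding is modelled as frequent small
bouts (Bernoulli per slot, dark-heavy, gamma amounts rounded to the 0.01 g
balance resolution). Fault injection reproduces the QC taxonomy (sentinel,
negatives, intake spikes, collapsed gas differentials) at a combined
default rate of ≈9.5 % of records, with a ground-truth log; sentinel and
negativity faults are caught with recall 1 by construction, quantile-based
faults with recall ≥0.9 (their thresholds are estimated from the
contaminated data).

What the generator does **not** emulate: sensor drift and autocorrelated
noise, cage-to-cage crosstalk, meal-structure physiology (RER responding
to individual bouts), day-to-day variation in latent EE, microbiome
dynamics, or mechanistic SCFA kinetics (metabolite tables are group-mean ±
SD draws). Passing tests therefore demonstrate correctness of the
computations and the statistical behaviour of the pipeline under the
stated model, not robustness to every failure mode of real hardware.

## Problem sizes and numerical choices

The analysis drivers and acceptance checks run a 30-mouse × 10-day cohort
(18,000 records) for the main pipeline, a 4-day identical-latent-EE cohort
for the normalization-artifact demonstration, 200 simulated cohorts at the
per-mouse summary level (lean-mass-driven EE, n = 10/group) for effect
recovery, and 1,000 null replicates for Tukey calibration — sizes chosen
so the whole chain reruns in minutes while keeping Monte-Carlo error well
below the tolerances tested. Degenerate inputs are handled explicitly:
constant covariates drop out of ANCOVA (adjustment becomes identity),
zero-variance Tukey inputs return p = 1, IQR = 0 makes the outlier fences
collapse to exact equality (nothing strictly exceeds them), and AUC
windows with fewer than two support points report missing.
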