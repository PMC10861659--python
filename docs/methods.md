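# Methods

## Scope

`hairscreen` implements two connected analyses for hair-based doping
control. The first is experimental: given multi-matrix concentration data
from a repeated-dose study, estimate each substance's hair incorporation
degree (hair concentration divided by plasma AUC) with proper handling of
censoring and calibration. The second is in silico: train a random-forest
classifier on a labelled drug panel and screen arbitrary substance lists
for hair detectability inside a range-based applicability domain. Because
no real study data ship with the package, a synthetic-study generator
produces data with the statistical structure the analysis assumes; the
test suite uses it for parameter-recovery experiments.

## Study design defaults

The default `StudyDesign` encodes a four-group rat protocol: vehicle plus
three dose groups of ten animals at 1, 2 and 4 mg/kg, oral gavage
(5 mL/kg) once every 24 h for 7 days. Plasma is sampled densely on day 7
(pre-dose trough plus 0.5, 0.75, 1, 1.5, 3, 6, 9 and 12 h post-dose) and
once on days 0, 10, 14 and 28; 24-h urine and faeces collections fall on
days 0, 7, 10, 14 and 28; hair is shaved at days 0 and 28. Whether the
dense day-7 grid includes a pre-dose point was an open design choice; we
include t = 0 as the trough so the trapezoid covers the full 0–12 h
window. Excreta amounts are converted to concentrations with fixed
collection constants (15 mL urine and 10 g faeces per 24 h, 0.25 kg body
mass), stored in the design so the conversion is explicit and
configurable.

## Generating model

Plasma follows a one-compartment model with first-order absorption,
superposed over the dosing schedule:

C(t) = Σ_{tᵢ ≤ t} (D·ka) / (V/F·(ka − ke)) · (e^(−ke(t−tᵢ)) − e^(−ka(t−tᵢ)))

This is the minimal model that reproduces the observed concentration–time
shapes; the package never fits it to data — it is purely the generator.
Per-substance presets give short (ka 1.5/h, ke 0.35/h; half-life ≈ 2 h,
detectable ≤ 12 h post-dose), medium (letrozole-like, ke 0.06/h) and long
(clenbuterol/GW1516-like, ke 0.02/0.012/h) plasma windows. The degenerate
case ka = ke is rejected rather than special-cased; callers perturb a
rate.

Urine and faeces receive fixed fractions (`f_urine`, `f_faeces`, defined
relative to the absorbed amount) of each dose under an
instantaneous-absorption approximation, valid for ka ≫ ke; the unabsorbed
fraction (1 − `f_abs`, default `f_abs` = 0.9) transits to faeces with a
one-day lag. Mass balance over an infinite horizon is therefore
D_abs·(f_urine + f_faeces) + D·(1 − f_abs), asserted to 0.5% in the tests.

Hair receives `incorporation_coeff` × plasma AUC × exp(ε). The AUC basis
is configurable: the default, "day7", uses the analytic AUC over the dense
day-7 window, which puts the generating coefficient on exactly the scale
of the recovered degree; "block" uses the total AUC of the dosing block to
an effectively infinite horizon, for users who prefer a whole-exposure
deposition model (the two differ by a substance-dependent factor of
roughly the number of doses). ε is Normal(−σ²/2, σ²) — lognormal with
mean one — so the coefficient is the population mean deposition per unit
exposure, i.e. the estimand of the pooled mean degree. Clearance gets an
independent median-one lognormal multiplier per animal.

Measurements live at the internal-standard response-ratio level:
ratio = slope·C·(1 + cv·z) + Normal(0, blank_sd). Incurred study samples
use `proportional_cv` (default 0.20, analytical plus matrix/biological
error); spiked calibrators, blanks and QCs in pooled blank matrix use
`calibration_cv` (default 0.05, analytical repeatability — the level at
which calibration r² ≥ 0.99 holds, as the quantitation tests verify). No
chromatograms or raw signals are simulated.

## Quantitation

Calibration is an unweighted OLS line of response ratio on nominal
concentration over 15 levels geometrically spaced on 0.01–500 (matrix
units), requiring at least six usable levels. Unweighted OLS is the
package default deliberately, although proportional noise over four
decades would normally motivate weighting; a `1/x2` option is provided,
and the recovery experiments use it because it is the correct variance
model for the generator's noise. The LOD is the lowest calibrator whose
response ratio reaches three times the standard deviation of blank
response ratios (an S/N ≥ 3 rule operationalised at the response level,
since no chromatographic noise definition applies); if no level qualifies
the curve is flagged not-detectable with an infinite-LOD sentinel. The
linear range runs from the LOD-qualified lowest calibrator to the top
level; back-calculations outside it are extrapolated and flagged, not
refused. Non-positive back-calculations clamp to zero and are censored;
values below the LOD are censored to zero. Curves with r² < 0.99 are
flagged rather than rejected — the 0.99 figure describes expected
linearity, not a hard gate.

## Exposure and incorporation

AUC₀₋₁₂ uses the linear trapezoid over the day-7 grid with no
extrapolation to infinity; censored points enter as zero (conservative
"not detected" semantics). On the default short-elimination preset the
sparse grid reproduces the closed-form AUC to within about 2% (tested at
5%), and refinement converges monotonically.

The degree is computed per animal and only when both inputs are
detections; a drug seen in hair but not plasma (or vice versa) raises
`Incalculable` rather than contributing zero. Degrees are pooled across
the three treated dose groups (legitimate because the degree is
dose-independent under linear PK — asserted on noise-free simulation) into
mean ± SEM (sample SD, n − 1, over √n), with per-dose means also emitted
and the n actually used reported, since animals with censored hair values
drop out per substance. The unit convention, (pg/mg)/(ng·h/mL), is printed
in every report header.

The recovery experiment (`recover_incorporation`) is the package's
validation instrument: 30 treated animals per replicate, full
quantitation, at the generator's noise defaults. Its replicate-level
standard deviation decomposes as hair measurement (20%/√30 ≈ 3.7%),
between-animal variability (≈ 3.8%), per-animal AUC noise (≈ 1.6%) and
two calibration slopes (≈ 2% each) — about 6% in total, so individual
replicates land within 10% of the generating coefficient roughly 9 times
in 10, and the mean over 100 replicates is within ~2%.

## QSAR screen

Descriptors are restricted to the families known to govern hair
incorporation — lipophilicity, charge/basicity and molecular mass:
Crippen logP, TPSA, molecular weight, H-bond donor/acceptor counts,
SMARTS-based acidic (carboxylic acid, sulfonamide N–H) and basic
(non-amide, non-sulfonylated, non-aromatic amine) group counts, and their
difference as a net-charge-at-pH-7.4 proxy. External descriptor CSVs
bypass computation bit-exactly for parity studies against other backends.
Unparseable structures are excluded and logged, never silently imputed.

The useless-feature filter drops numeric features with zero variance
(relative tolerance 10⁻¹²) and categorical features whose distinct-value
count exceeds 99% of the row count (identifier-like); it preserves column
order and is idempotent. The forest uses 500 trees, √p features per
split, bagging, and a fixed seed (20240115) for stability on a 17 × p
table. The screening score is the fraction of trees voting positive
(vote fraction, not a calibrated probability); "detectable" means score
≥ 0.5 (majority vote) and "high confidence" means strictly above 0.9.
Cross-validation is stratified 10-fold — with only 3 negatives in 17
rows, unstratified folds would frequently contain no negative at all —
with metrics pooled over held-out predictions and fold assignment
deterministic per seed.

The applicability domain is the closed per-feature min–max box of the
training rows. Membership is inclusive at the boundary, invariant to
feature order, and a missing feature is an error rather than silently
out-of-domain. Out-of-AD substances carry no score and are excluded from
the detectable/undetectable counts, which therefore partition the input
exactly.

The training labels come from the embedded panel: 14 hair-positive drugs
and 3 negatives (terbutaline, salbutamol, chlorothiazide). The negative
class follows the hair-detection statements; chlorothiazide is negative
in both hair and plasma.

## What the generator does and does not emulate

The generator reproduces: dose-proportional exposure across the 1/2/4
mg/kg groups; short/medium/long plasma detection windows; censoring at an
estimated LOD; AUC-proportional hair deposition with between-animal
spread; and matched calibration sets per matrix. It does not emulate:
metabolite formation (real urine detections are often metabolite-only,
which is why several parent drugs are urine-negative in practice);
nonlinear PK, enterohepatic recirculation or tissue accumulation;
chromatographic interferences or matrix-specific LOD differences; hair
growth kinetics, melanin binding or cosmetic-treatment losses. Passing
recovery tests therefore show that the *statistical pipeline* is unbiased
and correctly calibrated under the assumed structure — not that the
one-compartment model or deposition law is true of any real substance.

## Problem sizes and numerical choices

The shipped experiments use 30 treated animals per replicate, 100
replicates per recovery experiment, 200 replicates for calibration
quality, and 400-replicate characterisation runs during development;
these sizes give Monte-Carlo standard errors comfortably below the
tolerances they are tested against. Ties and degenerate inputs are
resolved explicitly: ka = ke rejected; single-timepoint AUC rejected;
n = 1 group SEM reported as undefined rather than zero; empty descriptor
tables allowed; single-class training rejected. All randomness derives
from one integer seed through CRC32-named substreams per stage, so adding
draws to one stage never perturbs another.

## Known limitations

- The 17-row training table cannot support more than a coarse
  detectability split; the 10-fold CV accuracy (~0.94, negative recall
  2/3) is the honest performance estimate, and the perfect training
  accuracy is expected of a 500-tree forest on 17 rows rather than
  evidence of generalisation.
- The range-based AD is a box: it ignores correlations between
  descriptors and admits corner regions never seen in training.
- Descriptor values are backend-specific (Crippen logP is not a measured
  logP); screening lists computed with other tools should be supplied as
  external CSVs rather than mixed.
- Urine/faeces detection labels for the panel are unknown in the fixture;
  the detection grid for those matrices is only meaningful for simulated
  studies.
- The human segmental report is fixture-driven (printed values only) and
  performs no growth-rate modelling beyond the 2 cm ≈ 2 months reading
  order.
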