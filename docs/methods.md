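# Methods

## Dose model

The red-marrow absorbed dose is computed at the organ level (MIRD
formalism): `D(BM←source) = S(BM←source) · Ã_source`, with the
time-integrated activity (TIA) `Ã` obtained by fitting a washout model to
sparse measurements and integrating analytically from injection to
infinity. Three constituents are assembled:

* **Blood self-dose.** Without specific marrow or blood-cell binding the
  marrow self-dose is carried by the activity in the marrow extracellular
  fluid, in equilibrium with the blood plasma. The blood
  activity-concentration curve is fitted bi-exponentially (fast
  distribution phase plus slow washout) and converted with the
  red-marrow-to-blood concentration ratio RMBLR: `RMECFF/(1 − HCT)` for
  PSMA-617 (extracellular-fluid fraction RMECFF = 0.19, haematocrit HCT
  patient-specific) and 1 for Octreotate, where marrow uptake is taken
  equal to blood concentration.
* **Organ cross-doses.** Kidneys for both therapies; liver and spleen
  additionally for Octreotate. Organ TIAs come from mono-exponential fits
  to the three SPECT time points; liver tumour VOIs are subtracted from the
  healthy-liver activity (they then remain inside the remainder of body).
* **Remainder-of-body (ROB) cross-dose.** `Ã_ROB` is the whole-body TIA
  minus the marrow blood term and the explicit organ TIAs. All tumours stay
  inside the ROB — per-lesion S values do not exist for arbitrary tumour
  geometry. The ROB S value is the whole-body conversion minus the
  marrow-self and organ shares, each term mass-scaled.

**Mass scaling.** Phantom S values are adjusted to the patient with the
non-linear exponents a (marrow self term), b (whole-body mass ratio) and
c (marrow mass ratio in the ROB bracket): a = 1.001/0.992, b = 0.896/0.894,
c = 0.963/0.970 for the male/female phantom. Patient marrow mass defaults
to linear body-mass scaling of the phantom marrow mass
(`m_BM,pat = m_BM,ph · m_WB,pat/m_WB,ph`), and the patient ROB mass to
whole body minus marrow minus explicit organs; both are overridable — no
published derivation is universal here, so the simplest defensible default
was chosen and documented.

**Units.** Times in hours post-injection; activities in Bq; blood
concentrations in Bq/ml; masses stored in kg and converted to grams inside
the equations with 1 ml of blood ≡ 1 g, so `[Ã_blood]·RMBLR·m_BM` is in
Bq·h. Doses are reported in Gy and normalised to mGy/GBq of injected
activity.

**S values are configuration, not code.** Public tabulations are phantom-
and source-specific; the package reads them from a YAML/JSON file. The
packaged `phantom_illustrative.yaml` is a synthetic set with plausible
magnitudes for Lu-177 — sufficient for every relative statement the tests
make (recoveries, deviations, identities), not for absolute clinical doses.

## Curve fitting

* **Mono-exponential** (whole-body, organ, abdominal series; three points at
  24/48/72 h): unweighted least squares on log-transformed values — exact
  for two points, deterministic, standard practice. A weighted variant
  exists but is off by default. A fitted decay constant ≤ 1e−12/h raises a
  non-physical-kinetics error (the series does not wash out); the threshold
  absorbs floating-point noise on constant series.
* **Bi-exponential** (blood; five points at 0.5, 1.33, 24, 48, 72 h):
  bounded non-linear least squares on the linear scale, multi-started from
  a fixed grid of five (fast, slow) half-life pairs because five-point
  bi-exponential fits are ill-conditioned; best residual wins, so the fit
  is deterministic. An amplitude collapsing below 1e−6 of the total flags
  the fit degenerate (effectively mono-exponential) rather than failing.
* **Integration.** `Ã = A0/λ` (mono) or `Σ A_i/λ_i` (bi), verified against
  adaptive quadrature to ≤ 0.01% in tests and in the acceptance script.
* Measurements are treated as *not* decay-corrected, so fitted constants
  are effective (biological + physical) and the integrals are effective
  TIAs — the dose integral runs over the measured curve.

## Image quantification

* **TEW scatter correction** uses the trapezoidal estimator
  `(C_low/w_low + C_up/w_up)·w_peak/2` with absolute widths 25.5/31.2/24.0
  keV for the 170/208/240 keV windows (15/15/10% fractional); negative
  corrected pixels are floored at zero.
* **HU→μ calibration** is bilinear with the two segments constrained to
  meet at HU = 0, solved as one linear least-squares system; evaluation
  clamps to the calibrated HU range (−688, 1127) — extrapolating the air or
  metal regimes without calibration support is worse than clamping.
* **μ-projection**: path-integrated μ along the ventral axis; body segments
  outside CT coverage (arms, legs, head) take per-segment default optical
  depths; the map is blurred with the camera resolution (FWHM 11 mm,
  σ = FWHM/2.355) using a generous 8σ kernel truncation so the discrete
  kernel preserves integral mass to ~1e−12.
* **Conjugate view**: `sqrt(ant·post)/duration · exp(depth/2)`; symmetric in
  the two views by construction.
* **Planar calibration** anchors each whole-body planar image on the
  same-session quantitative SPECT: `C = A_SPECT/x_planar` in Bq/cps.
* **VOIs** are percent-of-regional-maximum isocontours; defaults 0.35 for
  kidneys/spleen, 0.125 for liver (metastatic livers are heterogeneous, a
  low threshold captures the organ), 0.40 for tumours — midpoints of the
  clinically used ranges, overridable per organ.
* Dead-time and partial-volume corrections are deliberately not applied.

## Hybrid protocol

`λ_SPECT` is fitted to the three abdominal SPECT field-of-view totals
(organs and tumours included, no subtraction — the module exposes no option
to exclude them) and anchored at the measured planar whole-body activity at
t\* ∈ {24, 48, 72} h. The anchor uses the *measured* value by default; the
synthetic machinery can also place it on-curve for deterministic studies.
Exact identities hold and are property-tested: if λ_SPECT equals the
whole-body constant and the anchor lies on the reference fit, the hybrid
TIA, ROB dose and total dose equal the reference to machine precision; for
any mono-exponential pair, intercept-ratio × half-life-ratio equals the TIA
ratio exactly. When the abdominal washout is slower than the whole-body
washout (the typical case), the early anchor overestimates the dose and the
gap shrinks monotonically towards the 72 h anchor — the directional
behaviour the cohort tests check. Blood and organ constituents are
byte-identical between protocols.

## Comparison statistics

Percentage contribution `100·D_i/D_total`; absolute percentage deviation
`100·|D_HP − D_RP|/D_RP`; cohort medians with (min–max) ranges (mean of the
central pair for even n; clinical cohorts here are n = 5); Pearson r with
the two-sided p from the t-transform at n−2 degrees of freedom. Rounding
(doses to 0.1 mGy/GBq, percentages and half-lives to integers, ratios to
one decimal) is applied only at serialisation, never in computation. The
published summary values shipped as fixtures contain one internal
inconsistency (a prostate-cohort reference median printed as 10.8 mGy/GBq
whose own column medians to 10.2); the package always recomputes medians
from per-patient values.

## Synthetic virtual patients

A virtual patient is a set of closed-form curves: mono-exponential
whole-body, abdominal and organ washouts and a bi-exponential blood
concentration, so every TIA and dose truth is analytic (no sampling in the
truth path). Presets mirror the two therapy profiles: "octreotate-like"
(whole-body T½ 43 h, abdominal 61 h, blood slow phase 25 h, moderate tumour
load) and "psma-like" (31/42/14 h, high tumour load, kidneys-only organ
model); every field is overridable. Noise is multiplicative log-normal
(default σ = 5%) on sampled activities — quantification error dominates
counting statistics at therapy activities — with optional Poisson counts
for the planar projection fixture. The blood curve places the injected
activity in a 5 l blood pool with an 80% fast phase (T½ 1.5 h); this is a
kinetic shape choice, not a clinical calibration.

What the generator does *not* emulate: anatomically realistic activity
distributions, planar organ overlap, SPECT reconstruction artefacts,
misregistration between time points, or dead-time/partial-volume effects.
Passing recovery tests therefore demonstrates correctness of the estimation
chain under the model's own assumptions, not clinical accuracy on real
images. Absolute synthetic dose levels are higher than typical clinical
values because the synthetic whole-body and blood curves retain more
activity than real patients (no early excretion phase before the first
measurement) and the S values are illustrative; all verification statements
are relative, so this does not affect them.

Problem sizes used by the test suite and acceptance script: cohorts of 5
virtual patients; 200 noisy replicates for the bias estimate; 1000
parameter draws for the quadrature checks; 64×32-pixel projection fixtures.
These sizes give stable statistics while keeping the full run in seconds.

## Degenerate inputs and failure policy

Constant or rising activity series raise non-physical-kinetics errors
carrying the fitted constant; a negative ROB TIA raises an inconsistency
error by default (it signals a calibration fault) with an explicit opt-in
clamp-to-zero mode; a non-positive ROB S-value bracket reports each term.
In cohort runs one patient's failure is recorded as a structured failure
entry and never aborts the remaining patients. Every intermediate (fit
parameters, TIAs) is written to a machine-readable audit file sufficient to
recompute any report value by hand.

## Known limitations

* Organ-level S values cannot capture patient-specific 3D anatomy or
  heterogeneous ROB activity; photon cross-dose errors up to the order of
  100% have been reported for standardised S values in unfavourable cases.
* The marrow-mass derivation (linear body-mass scaling) is an assumption;
  marrow-mass models differ and directly scale the blood self-dose.
* Anchors later than 72 h are out of scope (no such acquisitions exist in
  the protocol being modelled); multi-bed SPECT extensions are not
  implemented.
* Slow-phase blood half-lives recovered from five points depend on the
  fitter's weighting; no attempt is made to match published per-cohort
  blood half-life medians.
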