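# Methods

## The measurement chain

synerkit models a coupled colorimetric enzyme-inhibition assay of the
DCIP/DHODH type. Substrate oxidation is stoichiometric with dye reduction,
so the reaction is read as a decline in absorbance (A600) over a short
kinetic window during which the signal is linear in time. The reaction
velocity of a well is the ordinary-least-squares slope of A600 on time
(dA/min). Wells without inhibitor define the uninhibited velocity, and

    inhibition% = (slope_control − slope_sample) / slope_control × 100.

Dividing by 100 gives the fraction affected, fa. Replicate wells are
aggregated by averaging slopes first and converting the mean slope to
inhibition — equivalent to a velocity from the pooled linear region, and
stable under replicate ordering — rather than averaging per-replicate
inhibition values. Negative inhibition (apparent activation) and values
above 100% are reported as computed with a warning, never clamped: silent
clamping hides assay problems.

### Velocity window

The default window policy is `full`: the assay design is a short read
(0–5 min at one-minute intervals) chosen to be linear throughout. For
noisier traces the `auto` policy selects, among all contiguous windows of
length ≥ max(3, ⌈n/2⌉), the one maximising r², with ties resolved toward
the earlier and then the longer window. The half-trace floor prevents the
selector from collapsing onto a tiny, trivially linear segment.

## The median-effect model

Single-agent dose–effect data follow the mass-action median-effect
equation

    fa / fu = (D / Dm)^m,     fu = 1 − fa,

with Dm the median-effect dose (the dose giving 50% effect; equivalent to
IC50/ED50) and m the sigmoidicity. Its linearisation, the median-effect
plot, is

    log(fa/fu) = m·log D − m·log Dm,

and Dm, m and r are *defined* through this plot: m is the OLS slope,
log Dm the x-intercept, and r the Pearson correlation of the transformed
points. The fit is therefore unweighted OLS on the transformed
coordinates, not nonlinear least squares on fa — the two estimators answer
different questions, and the plot-based definition is the one the
combination indices below are built on. Base 10 is used for plot
coordinates; m and r are base-invariant and Dm is base-consistent, so the
choice only fixes the plot scale.

Points with fa outside the clip window (default 0.005–0.995) never enter
a fit: the transform is undefined at fa ∈ {0, 1} and near-boundary points
dominate the regression. Flagged points are retained in reports. Fitting
requires at least two fittable points at distinct doses from a single
agent and unit.

A conventional logistic (Hill) fit,

    inhibition% = bottom + (top − bottom) / (1 + (IC50/D)^h),

is provided separately for the IC50 route, with bottom and top fixed at 0
and 100 by default (two free parameters, needing ≥ 3 points; ≥ 5 when all
four are free). It is solved by Levenberg–Marquardt least squares on a
log-IC50 parameterisation, multi-started from the dose quartiles and a
linearised median-effect guess; the convergence flag reports the
optimiser's own status. When bottom = 0 and top = 100 this logistic *is*
the median-effect curve, so on noiseless mass-action data the two routes
agree (this equivalence is asserted in the tests to 1e-6).

## Combination analysis

At an effect level fa, with single-agent equipotent doses
(Dx)a = dose_for_effect(fit_a, fa) and (Dx)b likewise, a combination
delivering component doses (Da, Db) at that effect has

    CI  = Da/(Dx)a + Db/(Dx)b          (combination index)
    DRI = (Dx)/D(in combination)       (per-agent dose-reduction index)

so CI = 1/DRI_a + 1/DRI_b identically. The two-term ("mutually
exclusive") CI form is used throughout; no third product term. CI < 1 is
synergism, CI > 1 antagonism, and values within a configurable additive
band (default ±0.05) are labelled additive — published practice labels
CI = 1.03 additive but 1.09 antagonistic, so strict equality is not what
is actually practiced. Normalised isobologram coordinates are
(Da/(Dx)a, Db/(Dx)b); since their sum is the CI, the side-of-line call
("below/on/above" with the same band) can never disagree with the CI
label.

Fixed-ratio fa–CI profiles derive component doses from the mixture's own
median-effect fit: at each fa the total mixture dose is
Dc = dose_for_effect(fit_combo, fa), split by the design's ratio
fractions (defaulting to the agents' Dm proportions, i.e. an
IC50-equivalent fixed ratio). Published combination tables of this kind
sometimes print per-level dose columns whose ratios drift across effect
levels and match neither a fixed ratio nor the single-agent Dx values;
such columns are not used as inputs here — CI is reproduced through the
DRI identity and the mixture-fit route instead.

### The Loewe-additive null

`solve_loewe_mixture` inverts the additivity condition
p·Dc/Dx_a(fa) + q·Dc/Dx_b(fa) = 1 for fa by bisection on
(1e-9, 1 − 1e-9); the left side is strictly decreasing in fa for m > 0,
so the root is unique. Bisection was chosen over derivative-based solvers
for robustness on this monotone target; the iteration tolerance is 1e-12
absolute on fa (bracketing failures are reported with both endpoints).

A Loewe-additive mixture of two median-effect agents is itself exactly a
median-effect curve only when the agents share m (then m_mix = m and
1/Dm_mix = p/Dm_a + q/Dm_b). The end-to-end additivity null in the test
suite — simulate an additive mixture, refit it, and require CI = 1 to
1e-4 across effect levels — therefore uses a shared slope; with unequal
slopes the mixture curve is not exactly log-linear and a refit introduces
small, purely structural CI wobble that is not evidence of interaction. A
separate qualitative test covers the unequal-slope case.

## Plant-score aggregation of docking hits

For virtual-screening tables, a compound is an active hit when its
docking score (kcal/mol; more negative is better) is at or below a
user-supplied cutoff. Because plants contribute different numbers of
compounds to a screened database, the per-plant statistic weights the
summed hit scores by the hit fraction:

    plant score = (Σ hit scores) × (n_hits / total compounds in database),

ranked ascending (most negative first, ties alphabetical). The hit cutoff
is a required input — no universally valid default exists, and the
worked examples use −10 kcal/mol purely for illustration. Each plant
table is scored independently; compounds shared between plants count for
every plant listing them.

## Synthetic data generator

`synthetic_data` emulates the statistical structure the analysis assumes
and nothing more: each well's absorbance declines linearly with velocity
v(dose) = control_velocity × (1 − fa(dose)), fa following the agent's
median-effect curve (fa = 0 at dose 0), with i.i.d. Gaussian noise added
to each absorbance read. Noise enters the *measured* quantity, so it
propagates through slope estimation exactly as on a plate. Defaults:
timepoints 0–5 min at 1-min intervals; control velocity −0.010 AU/min
from an initial absorbance of 1.0 AU; two replicates per dose (the usual
duplicate-well design); noise_sd 0.002 AU — replicate-level scatter in
published kinetic reads of this assay type is unreported, so this is a
plausible plate-reader figure rather than a calibrated one. All
randomness flows from a single recorded seed through one generator, so
identical seeds give byte-identical bundles.

What the generator does **not** emulate: substrate depletion or curvature
of the kinetic trace, dye re-oxidation, plate-position effects,
between-day drift, or heteroscedastic noise. Passing round-trip tests
therefore show that the estimators are correct under the model's own
assumptions — not that real plates satisfy those assumptions.

The module also bundles, as plain data, a published reference dataset of
a fixed-ratio hDHODH inhibition study (brequinar, Allium sativum extract,
silymarin, silibinin): per-agent dose tables at effect levels
0.10–0.90, the corresponding published median-effect parameters, and the
published CI/DRI tables of the three binary combinations with brequinar.
Two internal consistencies of that dataset are worth knowing:

- The dose tables imply Dm values exactly 2× the published Dm for every
  agent, while reproducing the published m to five decimals and r to
  ~1e-5 — a uniform dose-scale factor that leaves the slope and
  correlation untouched (the fit is scale-equivariant). Dm is therefore
  never asserted against those tables.
- Two of the fifteen published CI/DRI rows are internally inconsistent:
  both print CI = 1.14 where their own DRI pairs give 1/DRI_a + 1/DRI_b =
  1.16 and 1.18. The identity is exact algebra, so the corresponding
  acceptance tests fail honestly on exactly those two rows and pass on
  the other thirteen.

## Numerical choices

- fa from dose is computed through a logistic, expit(m·ln(D/Dm)), which
  is overflow-safe at extreme doses; the inverse uses the closed form
  Dm·(fa/fu)^(1/m). The pair inverts to ≤ 1e-10 over fa ∈ [0.01, 0.99].
- A zero-variance (flat) trace fits a zero-slope line perfectly and is
  assigned r² = 1; window ties in `auto` are compared with a 1e-12
  tolerance before the positional tie-breaks apply.
- Classification applies a 1e-12 slack to the additive band edge so a CI
  sitting exactly on the boundary is not reclassified by floating-point
  representation.
- Reports store full-precision values plus a formatted mirror at the
  configured precision (default 2 decimals, matching how such tables are
  usually printed); the numeric payload is deterministic (sorted keys, no
  timestamps — the run manifest carries the timestamp separately).

## Problem sizes

The bundled analyses are small by nature (five-point dose series, five
effect levels). The Monte-Carlo slope-bias check uses 500 seeded
replicates of a five-dose, duplicate-well study at noise_sd 0.002 AU and
requires the median fitted m to sit within 0.05 of the generating value;
the grid-search oracle for the Loewe inversion uses 10^6 candidate effect
levels. Both run in seconds.

## Known limitations

- Two-agent combinations only; no three-drug designs, and no Bliss/HSA/
  ZIP or response-surface alternatives to Loewe additivity.
- No confidence intervals on Dm or m; the plot-based estimator has no
  standard error theory attached here, and none is reported.
- Units are opaque labels: consistency within an agent is enforced, but
  no conversion between units is attempted (CI and DRI are unitless, so
  none is needed).
- The kinetic model is strictly linear in time; assays whose traces
  curve within the read window need the `auto` window at minimum, and
  possibly a different tool.
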