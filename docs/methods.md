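# Methods

`pentafit` implements the quantitative pipeline used to decide whether an
α/β heteropentameric nicotinic receptor contains two or three copies of its
α subunit, from four kinds of evidence: reporter-mutation EC50 shifts,
agonist potency ratios, Zn²⁺ modulation, and single-channel
conductance/burst signatures. All concentrations are µM, all logs base 10.

## Dose-response model and fitting

Whole-cell peak currents are fitted with the Hill equation

    I(A) = I_max · A^nH / (A^nH + EC50^nH)

by equal-weight least squares (`scipy.optimize.least_squares`, trust-region
reflective) with EC50 fitted on the log10 scale for conditioning. Starts:
I_max at the largest observed response, EC50 at the concentration whose
response is nearest half-max, nH ∈ {1.5, 1.0, 2.5}; a wider start grid is
tried only if no primary start converges. A fit whose optimum sits on a
parameter bound is flagged failed rather than clipped. Standard errors come
from the Gauss–Newton covariance at the optimum (delta method for EC50).

**Rundown correction.** A standard near-EC20 application of the reference
agonist is interleaved every third response. Standard responses are
interpolated linearly in application index; each test response is
multiplied by (first standard)/(interpolated standard). This linear rule is
a documented stand-in: the original correction procedure lives in prior
work that the recordings' description only cites. At least two standards
bracketing the tests are required; otherwise correction must be skipped
explicitly.

**Parallel fits and dose ratios.** Each cell's curve is normalized to its
own fitted maximum and pooled per receptor set; the pooled curves are then
fitted simultaneously with a single shared Hill slope, per-curve maxima,
and each non-reference EC50 parameterized as `reference_ec50 × dose_ratio`
(ratios fitted on the log scale). The potency ratio reported in the tables
is the reciprocal dose ratio. A lack-of-parallelism diagnostic refits every
curve with a free slope and compares residuals by an extra-sum-of-squares F
test; strongly non-parallel curves (e.g. slopes 0.9 vs 2.4) still fit, but
the diagnostic flags them.

Whether the original analysis pooled normalized points (as described) or
used per-cell curves with shared parameters is not fully specified;
pooled-normalized is what is implemented.

**Profile-likelihood ("2.01-unit") intervals.** For a Gaussian model with
the noise variance profiled out, the drop in profile log-likelihood at a
fixed dose ratio d is (n/2)·ln(RSS(d)/RSS_min). The interval collects d
with drop ≤ δ (default δ = 2.01 ≈ z²/2 for z = 2, i.e. ±2 SD). The search
doubles its step outward from the estimate until the threshold is crossed,
then brackets the crossing with Brent's method; a side that never crosses
inside the parameter bounds is flagged open. Note a small-sample caveat:
the δ-threshold is anti-conservative when the fit has few points per
parameter (measured coverage ~0.86–0.93 at n ≈ 16 points for 5 parameters,
where the exact pivot would be an F quantile). At the pooled-curve sizes
the pipeline actually uses (≈ 48 points per curve, 5–8 cells), measured
coverage is 0.95–0.96 under 5% multiplicative noise.

## Potency ratios from partial curves

At concentrations well below the EC50 the Hill curve is a power law, so
one cell's panel of agonists (2–3 low concentrations each, responses under
~10% of maximum) is fitted as parallel lines in log-log space: one common
slope s, per-agonist intercepts c_a, equal weights, responses ≤ 0 dropped
before the log transform with a logged count. The potency ratio of agonist
a relative to the standard (ACh) is 10^((c_a − c_std)/s). Confidence
intervals for the exponent (a ratio of jointly normal estimates) use
Fieller's theorem with the t quantile at the cell's residual degrees of
freedom; g ≥ 1 yields an unbounded-interval flag, not an error. Free-slope
fits per agonist provide the parallelism check (the free slope tends to nH
as concentrations → 0). Across cells, potency ratios are combined as
unweighted mean ± SEM; per-cell Fieller bounds are combined by averaging
the bounds on the log scale and are reported alongside the SEM without
asserting the two are equivalent (how the original bracketed ranges were
combined is not stated).

## Stoichiometry from per-copy EC50 shifts

A 9′ Leu→Thr reporter mutation multiplies agonist potency by roughly a
constant factor r per mutant copy, so a subunit present in n copies shifts
the EC50 r^n-fold and log10(EC50) is linear in copy number with slope
−log10 r. `per_copy_shift` takes the n-th root of a potency ratio
(intervals transformed endpoint-wise); `fit_copy_line` is closed-form OLS
of log10 EC50 on copies with R². `infer_stoichiometry` scores the two
pentameric candidates (α,β) ∈ {(2,3),(3,2)} by the log-scale discrepancy
|log r_α − log r_β| between the per-copy factors implied by the α- and
β-mutant ratios, and picks the smaller; ties are flagged ambiguous.
Consistency is scored on the log scale because the shifts are
multiplicative (free-energy-like). Other stoichiometries (4:1, 5:0) are
outside the hypothesis space and rejected at input. When ratio intervals
are supplied, the transformed per-copy intervals and their overlap are
reported; no formal test is invented. Because the wild-type EC50 itself
differs between the two receptor forms, panels from different expression
contexts are fitted separately and never merged.

## Zn²⁺ modulation

Responses to a fixed near-EC20 ACh concentration co-applied with Zn²⁺ are
normalized to the ACh-alone control. Two nested models in x = log10[Zn²⁺]:

* inhibition-only: I = 1 + min_effect·L(x; IC50, nH), min_effect ∈ [−1.5, 0];
* biphasic: I = 1 + w·(Max − 1)·L(x; EC50, nH1) + (1 − w)·Min·L(x; IC50, nH2),

with L(x; c50, n) = 1/(1 + 10^(n(log10 c50 − x))) rising 0 → 1, so both
are anchored at the control response 1. The exact printed form of the
original two-component equation is not legible in the source; this
parameterization satisfies every stated constraint and is isolated behind
`biphasic_response` so it can be swapped. Only the amplitude products
w·(Max−1) and (1−w)·Min enter the curve, so w, Max and Min are not
separately identifiable: the fit estimates the two amplitudes and reports
w/Max/Min under a w = 0.5 convention. Classification as biphasic requires
both a significant extra-sum-of-squares F test (default α = 0.05) over the
single-logistic model and fitted peak enhancement above a margin (default
+10%). The per-curve EC50 of the enhancing limb is a right-skewed
estimator at realistic noise; the recovery checks therefore pool several
cells' curves before fitting (as the pooled-curve analysis does) and
assess bias of concentration parameters on their natural log scale.

## Single-channel analysis

Inputs are idealized event lists (alternating open/shut, durations in ms,
open amplitudes in pA) with holding potential, filter cutoff and imposed
resolution as metadata; idealization itself (time-course fitting) is out
of scope. Openings enter amplitude analysis only if longer than twice the
filter rise time, T_r = 0.3321/f_c — the Gaussian-response constant, an
adequate approximation for an 8-pole Bessel at this precision, and
configurable. The amplitude list (floor: 100 openings) is fitted by a
maximum-likelihood Gaussian mixture (scikit-learn, 5 EM restarts), k = 1–3
chosen by BIC when not fixed; ML on the fitted amplitudes replaces the
histogram least squares used for display in the original figures. Chord
conductance assumes a 0 mV reversal potential: g (pS) = i (pA) / |V_hold −
V_rev| (mV) × 1000.

Bursts are openings separated by shut gaps shorter than a critical time
tcrit; a gap ≥ tcrit ends the burst. Burst duration runs from first
opening start to last opening end, so total open time and opening count
are conserved for every tcrit and burst count is non-increasing in tcrit.
tcrit is not stated in the source analysis; the default 5 ms sits well
between the sub-ms within-burst gaps and the ≥100 ms between-burst gaps of
these channels, is always recorded in the output, and is overridable. Each
burst is assigned to the mixture component with the highest posterior
density at its mean open amplitude; a burst more than 4 SD from every
component is "unassigned" (how the original analysis assigned overlapping
amplitudes is not stated). Direct transitions between conductance classes
are counted as a diagnostic, not assumed absent.

## Synthetic data

The generators produce every input the pipeline consumes, with the
structure the analysis assumes:

* dose-response: Hill truth × geometric rundown per application (default
  2%, must be < 10%) × multiplicative lognormal noise with unit mean
  (default cv 5%) — peak currents are positive and heteroscedastic;
  standards near the EC20 interleaved every third application and closing
  the protocol so they bracket the tests; descending dose order; default
  6 cells per set and 8 concentrations spanning 3 decades around the EC50.
* mutation panels: mutant EC50 = wild-type EC50 / r^copies under a chosen
  (α,β) assignment, everything else shared.
* partial curves: top concentration set so noiseless responses stay below
  8% of maximum, 3 half-log-spaced points per agonist, cv 2%.
* zinc: model truth (biphasic: enhancement amplitude 0.7 with EC50
  168.2 µM, slope 1.8; inhibition amplitude −1 with IC50 3.2 mM, slope
  2.1; inhibition-only: IC50 400 µM, slope 1.4) × lognormal noise.
* single channel: bursts drawn per class frequency; opening counts
  geometric, durations exponential, amplitudes Gaussian (low class: 2.6 ±
  0.5 pA, ~100 ms bursts of ~10 openings; high class: 3.9 ± 0.4 pA, ~14 ms
  bursts of ~3 openings; 500 ms mean between-burst gaps); the stated
  resolution is imposed by absorbing sub-resolution intervals into the
  preceding interval (duration-weighted amplitudes on concatenation),
  which can never create non-positive durations.

Every generator emits a ground-truth sidecar; recovery tests read truth
only from there. What the generators do **not** emulate: desensitization
and agonist self-block, receptor-mixture macroscopic curves, multi-state
burst kinetics, series-resistance and junction-potential errors, and any
correlation of noise across applications beyond rundown. Passing recovery
tests therefore show the estimators are correct for data matching the
analysis's own assumptions, not that those assumptions hold for any given
recording.

## Problem sizes used in the validation suite

Replicate counts were chosen to keep Monte-Carlo error small relative to
the tolerance being checked: 100 replicate Hill fits and 200 replicate
parallel fits (48 points per pooled curve) for bias/coverage, 60 pooled
(5-cell) zinc fits and 200 classification replicates per truth, 50
mixture fits, and 500 end-to-end mutation-panel replicates with r drawn
uniformly in [1.5, 6]. Oracle comparisons use a 600-point profile grid, a
10⁵-draw parametric bootstrap for Fieller bounds, and hand-enumerated
event lists.

## Known limitations

* The profile-interval δ-threshold is anti-conservative for small fits
  (see above); a future option is an exact-F threshold.
* The biphasic zinc model's w/Max/Min are reported by convention only.
* Burst-class assignment ignores within-burst amplitude heterogeneity.
* The rundown stand-in assumes rundown linear in application index
  between standards; strongly non-linear rundown would leave residual
  trend.
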