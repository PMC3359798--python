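# Methods

This note records the modeling assumptions, numerical choices and known
limitations of `braincm`, at the level of detail a user needs to judge
what a passing test suite does and does not establish.

## Model equations and assumptions

All times are minutes, concentrations mM, first-order rates 1/min;
`c_in` and `k_in'` are concentration rates (mM/min).  All initial
concentrations are zero.  The models describe the Gd-shortened-T1 spin
population only; exchange of unaffected spins is neglected, and the
contrast agent is assumed extracellular (it never enters the IES, whose
signal arises from magnetization exchange at rates `k_pi`, `k_ip`).

* Blood pool: `AIF(t) = c_in·t·e^(−k_out·t)`; whole-blood concentration
  `(1 − Hct)·AIF`.  The single hematocrit factor applies wherever
  `C_BLOOD` appears — in tissue and CSF voxels too — because the blood
  compartment is defined once.
* Tissue voxel: blood / EES / IES / NOW with
  `v_blood + v_ees + v_ies + v_now = 1` (enforced to 1e-12 at
  construction); linear two-stage exchange cascade driven by `C_BLOOD`.
* CSF voxel: blood / CSF, `v_blood + v_csf = 1`;
  `CSFIF(t) = k_in'·t·e^(−k_out'·t)`.  The paper-level description of a
  CSF voxel does not spell out a mixing rule; this package mirrors the
  tissue mixture, `v_blood·C_BLOOD + v_csf·CSFIF`, and applies no
  (1−Hct)-like factor to the CSFIF (its rate constant is taken to absorb
  any such factor).  Both choices are documented assumptions.
* Infusion window: the ramp-times-exponential input describes the
  during-infusion period.  An optional `t_end` on `BloodParams` switches
  the blood pool to pure mono-exponential elimination at `k_out`
  afterwards, continuous at `t_end`; all downstream solutions handle the
  piecewise forcing (closed form for the EES, two-phase propagation for
  the IES, segment-wise integration in the numerical oracle).

## Numerical evaluation

The EES solution is evaluated as

    C_EES(t) = k_trans·A·t²·e^(−k_out·t)·g((k_ep − k_out)·t),
    A = (1 − Hct)·c_in,   g(x) = (x − 1 + e^(−x))/x²,

which is uniformly stable: `g` switches to a 5-term Taylor series below
|x| < 1e-2 (truncation ~4e-15 there, versus ~1e-12 cancellation in the
direct form), and `g(0) = 1/2` reproduces the equal-rate degenerate
limit `t²/2·e^(−k_out·t)` exactly, with no accuracy cliff anywhere.

The IES solution is a second convolution and its textbook closed form
carries a `1/(k_ep − k_out)²` cancellation.  The primary evaluator uses
the stable closed form (scaled exponential differences via `exprel`)
while `|k_ep − k_out| ≥ 1e-4·max(1, k_ep, k_out)`, and otherwise
propagates the augmented linear system
`x = (C_EES, C_IES, e^(−k_out·t), t·e^(−k_out·t))` with matrix
exponentials, `x(t) = exp(Mt)·x(0)` — exact for every rate coincidence
and branch-free.  Measured agreement between the two paths and against
the independent ODE oracle is ~1e-11 relative or better on both sides
of the switch.

`solve_numeric` integrates the same ODEs with DOP853 at rtol 1e-10 /
atol 1e-14 and exists purely as an independent oracle; it raises on
solver failure rather than falling back silently.

Quasi-steady behavior: for `k_ep ≫ k_out`,
`C_EES → k_trans·C_BLOOD/k_ep` with a relative correction ≈ 1/(k_ep·t)
(the forcing is ramp-like, so the correction decays algebraically, not
like `e^(−k_ep·t)`); the 1% band is reached for `t ≳ 100/k_ep`.

## Fitting

Two-stage: blood-pool `(c_in, k_out)` from a blood-ROI curve with Hct
supplied (Hct and `c_in` are perfectly confounded); tissue and CSF fits
are conditional on the fitted `BloodParams` and never modify them.  Each
fit runs bounded trust-region-reflective least squares from five
deterministic starts (data-driven peak heuristics plus fixed
physiological anchors), then polishes the best solution with a 3-point
Jacobian at ftol 1e-12 / xtol 1e-10.  The coarse stage is capped at 250
residual evaluations per start and the polish at 600; multistart exits
early once a start's RSS falls below 1e-10 of the data's sum of squares
(an exact-model optimum).  Noiseless exact-model curves are recovered to
~1e-10 relative; the polish stage is what reaches it (2-point
finite-difference gradients floor out near 1e-3 on this problem's flat
valleys).  Volume closure is structural: the free parameterization
derives the dependent fraction, so every returned parameter set sums to
one exactly.  Fitted transfer rates below 1e-6 1/min are reported as
exactly 0; a `k_trans` at the lower bound sets the `blood_only` flag
(intact-BBB signature).

### Identifiability

Two structural facts shape the default parameterization:

1. `C_IES` is strictly proportional to `k_pi` and enters the signal only
   as `v_ies·C_IES`, so `(v_ies, k_pi)` are identifiable only through
   their product.  The default fit therefore fixes `v_now` (default
   0.03) along with the conventional `v_ees = 0.20`, deriving
   `v_ies = 1 − v_ees − v_now − v_blood`; this breaks the ridge and
   makes all five free parameters (`k_trans, k_ep, k_pi, k_ip,
   v_blood`) identifiable.  Passing `v_now_fixed=None` frees `v_ies`
   and accepts the ridge: the product `v_ies·k_pi` and the remaining
   parameters are still recovered, the split between `v_ies` and `k_pi`
   is not.
2. The CSF voxel is a two-term mixture of `t·e^(−k_out·t)` and
   `t·e^(−k_out'·t)`: it becomes rank-deficient as `k_out' → k_out`, and
   `v_blood`/`k_in'` trade off.  The synthetic defaults keep the CSF
   evacuation rate (mean 0.05 1/min, sd 0.005) separated from the blood
   elimination range (0.028–0.034 1/min) so the mixture stays well
   conditioned; fits of real voxels where the two rates coincide should
   be interpreted through the `bounds_hit`/`rss` diagnostics.

At realistic noise the tissue objective is additionally multi-modal:
large `k_pi/k_ep` amplification ratios can mimic a small-`k_trans`
accumulation signal, so noisy `k_trans` estimates scatter widely even
when the global optimum is found.  A Fisher-information calculation at
the default design (61 samples, 0–60 min, σ = 0.002 mM,
k_trans = 5e-4 1/min) bounds the sd of any unbiased `k_trans` estimator
above ~2e-4 1/min *even with all other parameters known*, and ~1.6e-2
with all five free.  Detecting transfer rates at the 1e-4 1/min
granularity therefore requires higher SNR, longer acquisitions, or
stronger priors than this design provides; the detectability experiment
in the acceptance suite measures this honestly rather than asserting it
away.

## Synthetic data

The generator emulates everything downstream of image reconstruction.
Defaults are chosen once from the physiologically reported ranges and
are the package's reference study conditions:

| quantity | default | basis |
|---|---|---|
| time grid | 0–60 min, 1-min frames (61 samples) | slow-infusion acquisition |
| blood `c_in` | truncnorm(0.069, 0.013) mM/min | reported range 0.0427–0.0956 |
| blood `k_out` | truncnorm(0.031, 0.0016) 1/min | reported range 0.0281–0.0344 |
| Hct | 0.45 | adult normal |
| tissue `k_trans` | 0–5e-4 1/min | reported range (intact BBB) |
| tissue volumes | 0.05 / 0.20 / 0.72 / 0.03 | v_ees conventionally 20% |
| CSF `k_in'` | truncnorm(0.06, 0.012) mM/min | same order as blood input |
| CSF `k_out'` | truncnorm(0.05, 0.005) 1/min | chosen distinct from blood `k_out` (conditioning, above) |
| CSF `v_blood` | truncnorm(0.13, 0.02) | reported range 9.4–16.5% |
| noise sd | 0.005 mM (0.002 in tissue-recovery experiments) | additive, zero-mean |

Parameter draws are normals truncated at zero (ranges, not
distributions, are what is reported; truncation keeps rates physical).
Noise is additive i.i.d. Gaussian on concentration.  Real DCE-MRI noise
is Rician on the complex signal and only approximately Gaussian on
converted concentrations at high SNR; the generator also omits the
signal→concentration conversion (T1 mapping, relaxivity), AIF
dispersion/delay, motion, and anatomical geometry.  Passing recovery
tests therefore demonstrate correctness of the estimation machinery
under the model's own assumptions — not robustness to conversion bias
or structured artifacts.  Phantoms are per-class-constant 4D images
with parameter truth maps, exported as NIfTI-1 with the frame period in
the temporal zoom.

## IOF

Stage means are unweighted arithmetic means over subjects (per-subject
fits, not pooled curves).  Control normalization divides each
(region, stage) mean by the same-region control mean, so the control
stage yields IOF = 1.0 exactly in floating point (`x/x`).  The
input/output classification uses a configurable balanced band of
half-width 1e-9 around 1; at 0 the strict binary rule is recovered.
1/IOF is reported whenever IOF < 1.  IOF is invariant under common
rescaling of all rates in a region and antisymmetric (reciprocal) under
exchanging the input/output roles.

## Degenerate inputs and error policy

Identically-zero or too-short curves raise `DegenerateInputError`;
negative times, invalid fractions, broken volume closure and unknown
model ids raise `ValueError` at construction; a zero control mean raises
at normalization; ODE solver failure raises, never silently falls back.
YAML configs reject unknown keys (a typo in a rate name must not become
a silent default).

## Problem sizes

The shipped experiments use 61-sample curves; 100-replicate Monte-Carlo
runs for recovery statistics; 200 random parameter draws for the
closed-form/ODE equivalence sweep; and cohorts of up to 200 subjects
per stage for pipeline-level IOF checks.  These sizes give Monte-Carlo
errors comfortably below the tolerances they are tested against.
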