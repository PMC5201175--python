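# Methods

`bst1map` implements a complete quantitative-MRI analysis chain: mapping
the radiofrequency transmit field (B1) from the Bloch–Siegert phase shift,
using that map to correct variable-flip-angle (VFA) T1 estimates, and
validating accuracy and test–retest reproducibility against
inversion-recovery (IR) gold-standard fits.  Everything runs on synthetic
digital phantoms, so the full chain is testable without any acquisition.

## Signal models

**Spoiled gradient echo (VFA).**  At repetition time TR and prescribed flip
angle α, with TE ≪ T2* so transverse decay is absorbed into the scaling
constant,

    S(α) = S0 · sin(f·α) · (1 − E1) / (1 − E1·cos(f·α)),   E1 = exp(−TR/T1)

where S0 lumps proton density and receiver gain and f is the per-voxel
flip-angle correction factor (actual/prescribed angle; f = 1 for the
uncorrected fit).  The default protocol acquires 10 angles, 2°–20° in 2°
steps, at TR = 7.9 ms.

**Inversion recovery (IR-TSE).**  With inversion flip α_inv (nominally
180°), inversion time TI, and a finite predelay TD between repetitions,

    S(TI) = S0 · | cos(α_inv)·(1 − exp(−TD/T1))·exp(−TI/T1) + 1 − exp(−TI/T1) |

fitted directly as a magnitude model with no polarity restoration.  The
default protocol uses 12 TIs from 25 to 10 000 ms and TD = 2500 ms.  Note
that at TD = 2500 ms the finite predelay shifts the signal null away from
the textbook TI = T1·ln 2 to TI = T1·ln(2 − exp(−TD/T1)); for
fibroglandular-tissue T1 ≈ 1290 ms the TI = 500 ms image therefore carries
a small negative-recovery magnitude rather than a perfect null.  The
synthetic nulling image uses the model-implied value, and the adipose
threshold segmentation works on the resulting intensity contrast rather
than assuming an exact zero.

## Bloch–Siegert B1 mapping

An off-resonant pulse (default: 2 ms Fermi envelope, ±8 kHz offset,
2.29 µT RMS amplitude; constant, Gaussian and linearly frequency-swept
envelopes are also available) imparts a phase on transverse magnetization
proportional, to leading order, to B1²/offset without exciting it.  Two
acquisitions at opposite offsets isolate that phase: the per-voxel angle
of `img₊ · conj(img₋)` cancels B0, receiver and sequence phase.

The phase→B1 relation is obtained by simulating the actual pulse with a
hard-pulse (piecewise-constant rotation) Bloch integrator — 2000 steps
over the pulse by default, exact 3×3 rotations so |M| is conserved by
construction — on a B1 grid from 0 to 2.5× nominal (64 points), and
inverted by piecewise-linear interpolation.  Construction fails if the
tabulated phase difference is not strictly increasing (the pulse has left
its design regime), and mapping flags voxels whose measured phase falls
outside the table rather than extrapolating.  A pulse that excites more
than 1% of the transverse magnitude raises an error; a spec whose offset
is below 10×γB1 warns.

Two numerical conventions are worth recording.  First, because every
hard-pulse rotation axis lies in the transverse plane, the accrued
transverse phase is invariant under the sign of the rotation (the ±γ
convention); the sign of the phase relative to the offset sign is
therefore a receiver convention, chosen here so that a positive offset
accrues positive phase and the lookup table increases.  Second, the
far-off-resonance analytic shift φ = (2πγB1)²·T/(2·2π·f_off) is used only
as a test oracle (the simulator matches it within 2% for constant pulses);
the pipeline itself always uses the simulated table, so simulation and
inversion share one pulse model and the mapping is exact up to
interpolation error (≤0.5% end to end on noiseless phantoms).

The nominal transmit amplitude corresponding to f = 1 is a configuration
input defaulting to the pulse's RMS amplitude (2.29 µT).

## Voxelwise fitting

Both fits minimize the per-voxel residual sum of squares in (T1, S0) with
a batched Levenberg–Marquardt solver (`bst1map.fitting.lm_fit`): analytic
Jacobians, per-voxel damping, box bounds by projection (T1 ∈ [1, 10000] ms
by default), and monotone acceptance so the final residual never exceeds
the initialization's.  Initializations are deterministic and data-derived:
the classic linearized regression of S/sin(fα) on S/tan(fα) for VFA, and
the signal-null heuristic T1 ≈ TI_min-signal/ln 2 with S0 from the
longest-TI sample for IR.  Convergence is declared at a relative cost
decrease below 1e-10 (or when damping saturates); voxels below the signal
floor, with invalid correction factors, or non-convergent are NaN with a
false validity flag and can never enter an ROI mean.  The inversion flip
angle is fixed at the protocol value by default; `FitOptions(fit_inv_flip=True)`
frees it as a third parameter.

Magnitude (Rician) noise bias is deliberately not modeled in the fits —
they are plain least squares on magnitude data, faithful to the stated
models — and this is a known limitation at low SNR.

A useful closed form for the uncorrected bias: expanding the SPGR model to
third order in the angle shows that data acquired at true factor f but
fitted assuming f = 1 yield an apparent T1 ≈ f²·T1 (under-flipping biases
T1 low).  The package's tests verify this law within 5% and, more
stringently, verify the fit against an exhaustive T1 grid search on the
same signals.

## Synthetic phantoms and noise

*Gel phantom*: 8 circular tubes (radius auto-sized to the grid, default
96×96 single slice) with reference T1 values {322, 328, 835, 843, 1004,
1478, 1500, 1558} ms spanning the 300–1600 ms calibration range.

*Breast phantom*: an elliptical adipose body (T1 = 420 ms) enclosing
blob-shaped fibroglandular tissue (T1 = 1290 ms) at a configurable volume
fraction (default 0.25); blobs are the upper quantile of a smooth random
field inside an inner ellipse, so an adipose shell always encloses them.
Tissue T1 defaults sit at the means reported for healthy breast tissue at
3 T.

*Transmit field*: uniform, a left–right linear ramp (default f ∈
[0.8, 1.1], the pattern reported for bilateral breast imaging at 3 T), or
a radial quadratic bowl.  The ramp hits its endpoints exactly at the
lateral edge columns.

*Noise*: magnitude series receive Rician noise (complex Gaussian of SD σ
added in quadrature, then modulus); the Bloch–Siegert pair receives
complex Gaussian noise.  All generators are pure functions of
(spec, seed); independent but reproducible streams per series and session
derive from one seed.  The default study condition is σ = 1.25 at
S0 = 1000, i.e. SNR ≈ 50 at the peak VFA signal — the in vivo SNR of the
reference acquisitions is unreported, so this is a package choice, and
tests use it together with the noiseless regime rather than claiming to
match any scanner.

What the phantoms do **not** emulate: partial-volume mixing at tissue
boundaries, chemical-shift/off-resonance effects in fat (the Bloch–Siegert
phase is simulated for on-resonance spins; B0 coupling is exposed only as
a validation sweep, not corrected), coil sensitivity profiles, anatomical
geometry, or through-plane motion.  Passing tests therefore demonstrate
the correctness of the mapping/fitting/statistics chain under its own
models, not robustness to those physical effects.

## Studies

*Phantom study*: simulate (or load) VFA/IR/BS data, fit the three maps,
and report per-tube mean ± SD with integer-rounded percent error of each
VFA method against IR on the central slice.

*Cohort study* (default conditions): 16 subjects, of which 3 carry only a
token amount of fibroglandular tissue and are excluded from the FGT
analyses (13 FGT subjects — the same cohort split that makes the
small-sample t multipliers 2.131 at n = 16 and 2.179 at n = 13).
Per-subject tissue T1s are drawn N(420, 30²) / N(1290, 100²) ms; each
session gets its own B1 ramp with endpoints jittered by ±0.05 and the
second session is translated by ±1 voxel in-plane, emulating
repositioning.  Per session the full pipeline runs; adipose tissue is
segmented by Otsu's threshold on the TI = 500 ms IR image within the body
mask (the manual skin/chest-wall exclusion is replaced by the supplied
body mask), fibroglandular tissue is its complement.  Accuracy (percent
error, Lin's concordance correlation with population moments, and the
subject-level bootstrap of the mean absolute-deviation difference with
1000 percentile resamples) and reproducibility (rMSD, t-based 95% CI of
the mean difference, wSD = rMSD/√2, repeatability r = 2.77·wSD, and the
per-subject coefficient of variation) are reported per tissue and method.
The reported "mean difference" is the mean absolute difference between
sessions, the reading consistent with the accompanying CI columns.

*Patient study*: three synthetic patients with a tumor disk (T1 defaults
1364/1374/1101 ms) embedded at the fibroglandular centroid; ROI tables
mirror the phantom table format.

Problem sizes were chosen so the full acceptance sweep (noiseless phantom
study plus 20 cohort replicates) completes in a few minutes on one core:
48×48 single-slice subject grids, 96×96 phantom grid.  Statistics are
ROI-level, so grid size affects only the within-ROI averaging, not the
estimators.

## Design choices and conventions

- Sample SD (n−1) everywhere a "± SD" is reported; Lin's CCC uses
  population moments (÷n), switchable via `ddof`.
- Bootstrap CI flavor is percentile, resampling whole subjects (both
  sessions travel together).
- d = scan1 − scan2; all reported reproducibility quantities use |d| or
  d², so the sign convention is immaterial.
- The difference-vector pre-checks (Shapiro–Wilk, Wilcoxon signed-rank,
  Kendall's tau of |d| against the per-subject mean) delegate to
  scipy.stats; degenerate inputs resolve by convention (all-zero d →
  Wilcoxon p = 1; tied |d| → tau = 0, p = 1).
- Index convention (slice, row, col), 0-based; all derived maps share the
  exact grid of their source series; nothing resamples.  Slice
  correspondence between a multi-slice VFA stack and a single-slice IR
  acquisition is by index (the central slice).
- Complex images are stored in NIfTI's native complex dtype.
- Invalid voxels are NaN + false mask everywhere; ROI summaries always
  filter on the mask.

## Known limitations

- No magnitude-bias correction in the fits (acceptable at the SNR of the
  study conditions, biased at low SNR).
- The IR magnitude model is fitted without polarity restoration; near the
  null the magnitude model's gradient is discontinuous, which is handled
  but can slow convergence for voxels sampled exactly at the null.
- B0/chemical-shift coupling of the Bloch–Siegert phase is not corrected.
- Two sessions per subject only; no mixed-effects repeatability model.
- The breast phantom is geometric, not anatomical; segmentation results
  on it say nothing about skin/chest-wall removal, which is accepted as
  an input mask.
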