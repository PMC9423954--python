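# Methods

This note documents the models implemented in `acupilot`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Perspective hand-eye calibration

The camera observes the robot's x-y travel plane obliquely, so the map
between image pixels and robot millimetres on one plane is an 8-parameter
projective transform (bottom-right matrix entry fixed to 1). It is fitted
by minimizing the *algebraic* residual of the linearized system — each
correspondence contributes the two rows `X(gx+hy+1) = ax+by+c` and
`Y(gx+hy+1) = dx+ey+f` — rather than the geometric transfer error; the
overdetermined solve is closed-form and, for noiseless data generated by a
representable map, exact. Both point sets are Hartley-normalized
(centroid to origin, mean radius √2) before the solve because raw pixel
coordinates (~10²) against projective terms (~10⁻⁴) condition the design
matrix badly. Degeneracy is reported when the design matrix loses rank
(e.g. collinear sources with n = 4); singularity is declared at
`|det| < 1e-12` for the unit-normalized matrix, and projective
denominators below `1e-9` raise a horizon-point error rather than
returning unbounded coordinates.

### Height fine-tuning

A target above the calibration plane appears shifted in the image; the
correction transform `F` (image at +1 cm -> image at base height) is
fitted from a second reference set, and intermediate or extrapolated
heights use the entrywise interpolation `H(k) = k F + (1 − k) I`, applied
before the base map `T`. This reading was chosen because it is the unique
operator form consistent with both endpoints: `H(0) = I` (no correction on
the calibration plane) and `H(1) = F` (the fitted one-step correction).
`k` is signed and measured in units of the calibration offset (1 cm by
default), so points below the plane use `k < 0` and intermediate heights
use fractional `k`.

For a camera exactly at nadir, `F` is a pure scaling about the principal
point and the linear interpolation is *exact at every height*. The
default synthetic camera is therefore given a small lateral offset
(~3 cm), making its view slightly off-nadir as on any physical mount: the
interpolation then remains exact at `k = 0` and `k = 1` but acquires a
genuine (micron-scale at 2 cm) extrapolation residual, which the height
evaluation measures separately. This residual is also why the "all noise
zero" end-to-end error has a floor of a few microns rather than machine
epsilon.

## Acupoint localization

The localization chain treats acupoint transfer as an image deformation
problem: align an annotated reference hand to the image, project its
acupoints, and warp them by the discrepancy between projected and detected
landmarks.

* **Consensus filtering.** Detected landmarks are matched to model
  landmarks by name; random-sample consensus over six-point samples fits a
  full 3×4 projection matrix (DLT) and counts reprojection inliers, with
  adaptive early stopping at 99% confidence. The classification threshold
  is a 3 px floor that follows the robust residual scale
  (2.5 × 1.4826 × median residual) upward: a fixed 3 px cut rejects
  honest σ ≈ 4 px detection noise wholesale, while the adaptive threshold
  still isolates a 50 px gross outlier (whose residual sits far outside
  any plausible noise scale) in effectively every trial.
* **Pose estimation.** Initialization tries both a projective DLT and a
  planar-homography decomposition on the best-fit landmark plane; the hand
  is nearly flat (depth relief ~30 mm against a 300 mm viewing distance),
  which makes the pure DLT ill-conditioned, and the planar init is the
  reliable fallback exactly there. The better initialization by
  reprojection RMS is refined by damped Gauss–Newton on the mean squared
  reprojection error (analytic Jacobian, left-multiplicative rotation
  increments, step halving when a step worsens the fit, termination at
  step norm < 1e-10 or 50 iterations).
* **MLS deformation.** Affine moving least squares with weights
  `w_i = 1/(d² + ε)^α`, α = 1, ε = 1e-8 px². Affine MLS reproduces any
  global affine map of the controls exactly and interpolates control
  displacements up to the ε regularization; the affine (rather than
  similarity or rigid) family was chosen because the residual between a
  posed reference hand and an individual hand is dominated by anisotropic
  shape difference, which similarity MLS cannot absorb.
* **Sides.** Each image is tagged `back` or `palm` and only same-side
  acupoints are returned; the reference model annotates 13 back-of-hand
  and 5 palm acupoints.

A useful exactness property follows from the construction: with noiseless
detections the pose is exact, projection lands on the ground truth, the
MLS controls coincide with their destinations, and localization error is
zero to numerical tolerance for every pose in the sampled family. The
chain is also exactly equivariant under in-plane image rotation (a camera
roll). It is *not* exactly equivariant under uniform image scaling —
scaling is an effective focal-length change, which a rigid pose with fixed
intrinsics cannot represent — so a 15% scale perturbs estimates at the
0.3 px level via the deformation stage.

## PPG analysis

* **Peak detection** follows the two-moving-average event scheme: 0.5–8 Hz
  zero-phase band-pass (2nd-order Butterworth, necessary because 25 Hz
  sampling leaves little room above the pulse harmonics), clip negatives,
  square, compare a 111 ms "peak" moving average against a 667 ms "beat"
  moving average plus an offset of 0.02 × mean squared signal, keep blocks
  wider than the peak window, and take the block argmax. Flat or
  too-short (< 5 s) input yields an empty result, not an error.
* **PP gating**: intervals outside 250–2000 ms or deviating more than 30%
  from the 5-beat local median are flagged and excluded from spectra —
  missed beats otherwise alias into enormous spurious low-frequency power.
* **Sub-sample peak timing.** At 25 Hz, integer-sample peak indices
  quantize beat times to 40 ms; that alone injects roughly 10% spurious
  power into the HF band of a 50 ms modulation. When the raw signal is
  available the peak times are refined on an 8× band-limited polyphase
  upsampling (with a final fine-grid parabola). A plain 3-point parabola
  on the raw samples was rejected: its phase-dependent bias acts as a
  gain < 1 on small beat-to-beat timing variations and visibly attenuates
  low-amplitude PP modulations.
* **PRV HF power**: valid PP intervals are cubic-spline interpolated onto
  a uniform 4 Hz grid (linear interpolation attenuates a 0.25 Hz tone
  sampled at ~1 Hz beat rate by ~15% in power), mean-detrended, and the
  Welch spectrum (Hann, 120 s segments, 50% overlap) is integrated over
  0.15–0.4 Hz, in ms². Pulse amplitude is peak minus the minimum of the
  preceding half-PP window, which makes it invariant to any constant
  baseline.

Known limitation: the sub-sample refinement leaves a timing noise floor
of 1–2 ms; HF estimates of modulations below ~15 ms depth (HF < ~100 ms²)
on clean 25 Hz signals are biased low by tens of percent, and white
sensor noise at SNR ≤ 20 dB adds a broadband tachogram floor that can
dominate small HF powers. Recovery within a few percent holds for
25–50 ms modulations on clean signals, which is the regime the
stimulation-response comparison targets.

## Synthetic generators

The generators are pure functions of their seed and parameters.

* **Hand model**: a stylized, skeleton-proportioned 21-landmark hand
  (wrist + 4 joints per finger) of length 180 mm, with a small seeded
  shape jitter (σ = 0.01 hand units ≈ 1.8 mm) so different seeds give
  different individuals. Knuckle arching gives the landmark cloud ~30 mm
  of depth relief — enough non-planarity to exercise 3D pose estimation
  while remaining hand-like. The 18 acupoints are convex combinations of
  landmarks (guaranteeing they stay inside the landmark footprint) with a
  vertical offset: back points on the dorsal surface, palm points one
  hand-thickness below. The geometry is *not* anatomically scanned; it
  exercises the projective and deformation math at realistic magnitudes,
  nothing more.
* **Scene**: world frame = robot frame (z = 0 is the calibration plane,
  mm). The camera sits 300 mm above the hand with focal length 640 px at
  640×480, chosen so the 180 mm hand spans ~60% of the frame. Landmark
  "detections" are the true projections plus iid Gaussian pixel noise and
  optional planted outliers. Robot ground truth comes from the analytic
  plane-to-pixel homographies of the scene's projection matrix.
* **Calibration sets**: 13 base points (pixel ↔ robot mm, mm noise on the
  robot side) and 13 offset points on the +1 cm plane (pixel ↔ base-plane
  pixel, pixel noise), drawn uniformly over a ±80 mm workspace.
* **PPG**: asymmetric Gaussian pulses (rise σ = 0.10 PP, fall σ = 0.22 PP)
  at beat times generated by PP(t) = 60000/HR + depth·sin(2πft) ms, plus
  white noise at a specified SNR. Defaults are a 5-minute recording at
  25 Hz. Real PPG morphology (dicrotic notch, baseline wander, motion
  artefacts) is deliberately absent — passing tests demonstrate the
  correctness of the detection/spectral chain, not robustness to
  real-world artefact.

Because every stage has exact synthetic ground truth, the repository's
master integration property is *closure*: noiseless generator output fed
through the corresponding analysis stage recovers the stored truth to
numerical tolerance.

## Evaluation and the error budget

Component errors are measured on seeded scene ensembles (default 15–20
scenes, which keeps the full evaluation under a few seconds while putting
the Monte-Carlo error of the reported means well under the differences
that matter). Pixel errors are converted to millimetres with the scene's
projective scale at the hand surface (camera depth / focal length,
≈ 0.49 mm/px at default geometry).

The realistic noise preset (`evaluation.PAPER_NOISE`: landmark σ = 4.1 px,
correspondence σ = 0.8 mm, offset σ = 0.47 px) was calibrated once by
simulation so the three component error means land at ≈ 2 mm, ≈ 0.55 mm
and ≈ 0.15 mm respectively — the operating regime of a physical
smartphone-above-hand rig — and is frozen.

Attribution uses one-at-a-time ablation: each noise source is zeroed in
turn with identical random streams (zero-σ draws still consume the same
random variates, so the other sources' realizations are unchanged), and
the marginal reduction in mean error, clipped at zero, is normalized into
fractions summing to one per acupoint. Ablation was preferred over a
variance decomposition because the chain is nonlinear and the one-at-a-time
marginals are directly interpretable as "what would fixing this component
buy". With all sources at zero the decomposition is undefined and flagged
rather than normalized. Under the realistic preset, acupoint estimation
dominates (> 60% share) for essentially all acupoints — the vision-side
error, not the robot-side calibration, limits end-to-end accuracy.
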