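# Methods

## ASL quantification model

The FAIR difference signal is modelled with the single-compartment
pulsed-ASL equation: after global inversion (tag) the inflowing blood is
inverted, after slice-selective inversion (control) it is fresh, so at
inversion time TI the averaged control-minus-tag difference ΔM relates
to flow f (ml/g/s) by

    ΔM = 2 f M0 TI exp(−TI/T1) / λ,

inverted pixelwise as f = λ ΔM exp(TI/T1) / (2 M0 TI) and scaled by
6000 to ml/100 g/min. Assumptions: immediate exchange of labelled blood
water into tissue, transit delays neglected, one global tissue T1, full
inversion efficiency, and no flow-related correction of the steady-state
readout. No image registration is applied (a hook exists in the
pipeline for data that need it).

Parameters, with defaults and units:

| parameter | default | unit | meaning |
|---|---|---|---|
| `ti` | 1.2 | s | inversion (inflow) time |
| `t1` | 1.14 | s | tissue longitudinal relaxation time (renal cortex at 3 T) |
| `lambda_bt` | 0.8 | ml/g | blood–tissue water partition coefficient |
| `unit_factor` | 6000 | — | ml/g/s → ml/100 g/min |
| `m0_floor` | 5% of robust M0 max | signal | background exclusion threshold |

The mask rule (`m0_floor`) is a package choice: the ΔM/M0 ratio diverges
in air, so pixels whose M0 is below 5% of the 99.5th percentile of the
M0 image are excluded. Negative flows are retained in the map and in
ROI means (no clipping).

## DCE quantification model

Tracer mass balance during the first pass gives
C_T(t) = (C_A ⊛ h)(t) with h(t) = f_s·R(t), where R is the residue
function (R(0) = 1, non-increasing) and f_s the flow in 1/s; hence
RBF = 6000·max h. Signal is assumed proportional to concentration with
the same constant in blood and tissue; because that constant multiplies
both sides of the convolution it cancels, so curves remain in
baseline-subtracted signal units and the flow estimate is invariant to
it (and to any global signal scaling).

Discretisation uses the rectangle rule at the volume spacing dt, giving
the lower-triangular Toeplitz system A h = c_T with A[i,j] = dt·C_A[i−j].
The solve is a truncated SVD: singular values below
`threshold_fraction × σ_max` are discarded. The matrix is severely
ill-conditioned (the baseline samples of the AIF are zero and the bolus
is smooth), so some truncation is always required on noisy data;
`threshold_fraction = 0.15` is the field-standard default for in-vivo
noise levels, while noise-free synthetic recovery uses a nominal 1e-12
(only the exactly-zero singular values are dropped, and recovery is
exact to rounding because the simulator uses the same discretisation).
No negative-lobe clipping is applied to h before taking its maximum.
Bolus delay/dispersion between aorta and kidney is not fitted; aorta
and tissue share one time axis.

Processing defaults follow the acquisition they model: dt = 0.9 s,
15 pre-contrast baseline volumes subtracted per pixel, first-pass
truncation to 50 volumes (60 for late washout), AIF as the mean curve
of an aortic ROI, per-slice pixelwise maps and the mean of the three
slice ROI means as the reported cortical value.

### Estimator bias under noise, and the ROI-level estimator

`max h` is a nonlinear statistic. On a noisy per-pixel response the
maximum is upward-biased when regularisation is weak (the max selects
positive noise excursions) and downward-biased when it is strong
(truncation smooths the peak of h). Both biases are systematic — they
do not average out over pixels or replicates — so a pixelwise map,
while the right surface for *display* and for intra-map contrast, is
not an unbiased ROI estimator at finite SNR. For ROI-level flow
estimates the package therefore also provides
`dce.roi_concentration_curve`: the concentration curves are averaged
over the ROI (and slices) *before* deconvolution, which suppresses the
noise ahead of the nonlinear max by ~√(N pixels) and leaves the
estimate unbiased at weak truncation. The Monte-Carlo recovery
experiments use this estimator with `threshold_fraction = 1e-3`, chosen
from the effective noise of the ROI-averaged curve (~0.02% of peak
enhancement at 1% per-pixel noise); the pixelwise default stays 0.15.

## Synthetic phantom

The phantom emulates a single 4 mm axial slice through a rat abdomen
imaged at 0.5 mm in-plane resolution on a 128×128 grid: two elliptical
kidneys (26×17 pixel semi-axes, 5-pixel cortical ring) and a 3-pixel
radius aortic cross-section cranial to them. Ground-truth cortical
flows default to 316 (left, injured) and 416 (right, healthy)
ml/100 g/min — representative of unilateral ischaemia-reperfusion
injury, which roughly halves cortical perfusion — and medullary flow to
120 ml/100 g/min, well below cortical as in vivo.

The ASL forward model emits interleaved M0/ssIR/nsIR frames (30 of each
by default, 90 frames) whose difference equals the model-implied ΔM
exactly; the inversion-prepared frames share the static term
M0(1 − 2exp(−TI/T1)). This inverse-by-construction design makes the
quantification stage exactly testable; it does not simulate the
steady-state readout physics. The DCE forward model uses a
gamma-variate AIF (shape α = 3, scale β = 1.5 s, arrival at the end of
the 15-volume baseline, peak ~4.5 s later — a first-pass bolus
contained well inside the 50-volume window) and an exponential residue
with 4 s mean transit time, plausible for renal cortex
(≈ blood volume / flow).

Noise is additive zero-mean Gaussian per frame/volume, seeded
(`numpy.random.default_rng`); identical spec + seed reproduce series
bit-exactly. The simulated difference and enhancement signals sit far
above the noise floor, where Rician magnitude noise is effectively
Gaussian. The stochastic experiments set the ASL per-frame sigma so the
30-pair averaged ΔM image carries 1% relative noise in healthy cortex,
and the DCE sigma to 1% of the peak cortical enhancement
(peak-enhancement SNR 100) — realistic for these acquisitions.

Features of real data the phantom does not emulate: respiratory motion,
inversion-slab imperfections and incomplete labelling, partial-volume
effects, view-sharing temporal blur, AIF dispersion, B0/B1
inhomogeneity, and spatial heterogeneity within compartments. Passing
recovery tests therefore demonstrates correctness of the quantification
chain under its own model assumptions, not robustness to those
confounds.

## Agreement statistics

Group summaries use the sample SD (ddof 1); paired-difference and
repeatability summaries use the population SD (ddof 0) — both
conventions are exposed because reported renal-perfusion tables mix
them. The paired t-test is two-sided, t = mean(d)/(sd(d)/√n) with n−1
degrees of freedom. Bland–Altman limits of agreement are
mean ± 1.96 × population SD. Subjects with two healthy kidneys
contribute both kidneys to the healthy group and are excluded from
paired differences and injury statistics. Report rounding is
print-style (half away from zero): integer flows, 2-decimal ratios,
p-values in percent with 2 decimals.

## Numerical and design choices

- Rectangle-rule convolution/deconvolution keeps simulator and solver
  on the same discrete operator, so noise-free recovery is exact up to
  regularisation; a higher-order quadrature would introduce a
  discretisation mismatch instead.
- Time origin: volume i is at t = i·dt (0-based); bolus arrival t0
  defaults to n_baseline·dt so the gamma-variate is identically zero
  through the baseline window.
- Degenerate inputs raise rather than warn: missing preparation labels,
  empty ROIs, bolus-free arterial curves, zero-variance t-tests,
  truncation windows that leave no dynamics.
- Per-pixel deconvolution reuses one pseudo-inverse of A per slice
  (the AIF is shared), making the pixelwise map a single matrix
  multiplication.
- Simulation problem sizes in the test-suite and reproduction script —
  128×128 (or 64×64 for unit tests) grids, 100 Monte-Carlo replicates,
  1000 t-test null replicates — were chosen to make Monte-Carlo error
  small relative to the tolerances being checked.

## Known limitations

- Absolute DCE flow values on real data depend on the regularisation
  choice; only relative contrast and synthetic recovery are promised.
- Single global T1 in the ASL model biases flow where cortical T1
  deviates (e.g. in injured tissue).
- No hematocrit correction, no relaxivity-based signal-to-concentration
  conversion, no pharmacokinetic (filtration) modelling.
- NIfTI is the only ingest format; DICOM series must be converted
  upstream.
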