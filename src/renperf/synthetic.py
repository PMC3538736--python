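"""Synthetic renal-perfusion phantoms and forward simulation.

A digital phantom of a single axial slice through a rat abdomen: two
elliptical kidneys, each a cortical ring around a medullary core, plus a
small circular aorta cross-section.  Each compartment carries a known
ground-truth perfusion, so parameter recovery by the quantification
stages can be checked exactly.

Two forward models are provided:

* ``simulate_asl`` emits an interleaved FAIR series (M0 / ssIR / nsIR
  frames) whose control-minus-tag difference is the exact algebraic
  inverse of the single-compartment quantification formula at the
  ground-truth flow.  With zero noise the ASL chain is therefore an
  exact round trip — the quantification stage has a noise-free oracle.
* ``simulate_dce`` emits a dynamic contrast series: per pixel,
  baseline + (f/6000) x (C_A convolved with R), discretised with the same
  rectangle rule the deconvolution stage inverts.  The aorta carries the
  gamma-variate input function itself.  An experimental unilateral
  kidney injury is emulated by a lower cortical flow on the affected
  side (ischaemia-reperfusion injury roughly halves cortical perfusion).

Noise is additive zero-mean Gaussian per frame/volume and fully seeded;
the difference and enhancement signals simulated here sit well above the
noise floor, where the Rician magnitude distribution is effectively
Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .asl import ASLSeries, QuantConstants
from .dce import AIF, ConcentrationCurve, DCESeries

__all__ = [
    "Ellipse",
    "PhantomSpec",
    "GroundTruth",
    "AIFModel",
    "ResidueModel",
    "make_phantom",
    "simulate_asl",
    "gamma_variate_aif",
    "residue_function",
    "simulate_dce",
]


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in pixel coordinates: centre (row, col) and
    semi-axes (row, col)."""

    center: tuple[float, float]
    axes: tuple[float, float]

    def contains(self, rows: np.ndarray, cols: np.ndarray, shrink: float = 0.0) -> np.ndarray:
        """Boolean interior mask, with both semi-axes reduced by ``shrink``."""
        ar, ac = self.axes[0] - shrink, self.axes[1] - shrink
        if ar <= 0 or ac <= 0:
            raise ValueError("shrink leaves a degenerate ellipse")
        return (
            ((rows - self.center[0]) / ar) ** 2
            + ((cols - self.center[1]) / ac) ** 2
        ) <= 1.0


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, ground truth and noise model of the digital phantom.

    Perfusion values are in ml/100 g/min.  The defaults place two
    kidneys side by side on a 128 x 128 grid (0.5 mm pixels) with the
    aorta cranial to them, a diseased left cortex at 316 and a healthy
    right cortex at 416 ml/100 g/min — representative cortical flows for
    an injured and a healthy rat kidney — and medullary flow well below
    cortical.  ``m0_tissue`` is the equilibrium signal of tissue pixels
    (arbitrary units) and ``noise_sigma`` the per-frame additive noise
    standard deviation in the same units.
    """

    grid_shape: tuple[int, int] = (128, 128)
    pixel_size: float = 0.5  # mm
    kidney_left: Ellipse = Ellipse(center=(72.0, 38.0), axes=(26.0, 17.0))
    kidney_right: Ellipse = Ellipse(center=(72.0, 90.0), axes=(26.0, 17.0))
    cortex_thickness: float = 5.0  # pixels
    f_cortex_left: float = 316.0
    f_cortex_right: float = 416.0
    f_medulla: float = 120.0
    m0_tissue: float = 1.0
    t1_tissue: float = 1.14  # s
    noise_sigma: float = 0.0
    seed: int = 0
    aorta_center: tuple[float, float] = (24.0, 64.0)
    aorta_radius: float = 3.0  # pixels

    def __post_init__(self) -> None:
        if min(self.grid_shape) <= 0:
            raise ValueError("grid_shape must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for name in ("f_cortex_left", "f_cortex_right", "f_medulla"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for kidney in (self.kidney_left, self.kidney_right):
            if self.cortex_thickness <= 0 or self.cortex_thickness >= min(kidney.axes):
                raise ValueError(
                    "cortex_thickness must be positive and strictly smaller "
                    "than both kidney semi-axes"
                )
        if self.m0_tissue <= 0:
            raise ValueError("m0_tissue must be positive")
        if self.t1_tissue <= 0:
            raise ValueError("t1_tissue must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclass
class GroundTruth:
    """Phantom ground truth: perfusion map plus compartment masks."""

    perfusion_map: np.ndarray
    cortex_left: np.ndarray
    cortex_right: np.ndarray
    medulla_left: np.ndarray
    medulla_right: np.ndarray
    aorta: np.ndarray

    def __post_init__(self) -> None:
        masks = self.mask_dict()
        total = sum(m.astype(int) for m in masks.values())
        if np.any(total > 1):
            raise ValueError("compartment masks overlap")
        if np.any(self.perfusion_map < 0):
            raise ValueError("perfusion_map must be >= 0 everywhere")

    def mask_dict(self) -> dict[str, np.ndarray]:
        return {
            "cortex_left": self.cortex_left,
            "cortex_right": self.cortex_right,
            "medulla_left": self.medulla_left,
            "medulla_right": self.medulla_right,
            "aorta": self.aorta,
        }

    @property
    def tissue(self) -> np.ndarray:
        """All kidney pixels (cortex plus medulla, both sides)."""
        return (
            self.cortex_left | self.cortex_right
            | self.medulla_left | self.medulla_right
        )


def make_phantom(spec: PhantomSpec) -> GroundTruth:
    """Rasterise the phantom geometry into masks and a perfusion map."""
    rows, cols = np.indices(spec.grid_shape, dtype=float)
    outer_l = spec.kidney_left.contains(rows, cols)
    outer_r = spec.kidney_right.contains(rows, cols)
    if np.any(outer_l & outer_r):
        raise ValueError("kidney ellipses overlap")
    medulla_l = spec.kidney_left.contains(rows, cols, shrink=spec.cortex_thickness)
    medulla_r = spec.kidney_right.contains(rows, cols, shrink=spec.cortex_thickness)
    cortex_l = outer_l & ~medulla_l
    cortex_r = outer_r & ~medulla_r
    aorta = (
        (rows - spec.aorta_center[0]) ** 2 + (cols - spec.aorta_center[1]) ** 2
    ) <= spec.aorta_radius**2
    if np.any(aorta & (outer_l | outer_r)):
        raise ValueError("aorta overlaps a kidney")
    perfusion = np.zeros(spec.grid_shape)
    perfusion[cortex_l] = spec.f_cortex_left
    perfusion[cortex_r] = spec.f_cortex_right
    perfusion[medulla_l | medulla_r] = spec.f_medulla
    return GroundTruth(
        perfusion_map=perfusion,
        cortex_left=cortex_l,
        cortex_right=cortex_r,
        medulla_left=medulla_l,
        medulla_right=medulla_r,
        aorta=aorta,
    )


def fair_delta_m(
    perfusion: np.ndarray,
    m0: np.ndarray,
    ti: float,
    t1: float,
    lambda_bt: float,
    unit_factor: float = 6000.0,
) -> np.ndarray:
    """Exact control-minus-tag difference implied by the quantification
    model: the algebraic inverse of the single-compartment FAIR formula,

        dM = 2 (f / unit_factor) M0 ti exp(-ti/T1) / lambda.
    """
    return (
        2.0 * (perfusion / unit_factor) * m0 * ti * np.exp(-ti / t1) / lambda_bt
    )


def simulate_asl(
    truth: GroundTruth,
    spec: PhantomSpec,
    ti: float = 1.2,
    n_pairs: int = 30,
    lambda_bt: float = 0.8,
    noise_sigma: float | None = None,
    seed: int | None = None,
    inter_image_time: float = 6.0,
) -> ASLSeries:
    """Forward-simulate an interleaved FAIR series.

    Emits ``3 * n_pairs`` frames in repeating (M0, ssIR, nsIR) order —
    30 pairs plus 30 equilibrium images, 90 frames, at the defaults.
    The inversion-prepared frames share the static tissue signal
    ``M0 (1 - 2 exp(-ti/T1))`` and differ exactly by the model-implied
    perfusion-weighted difference, so quantification inverts the
    simulation identically when ``noise_sigma = 0``.
    """
    if ti <= 0:
        raise ValueError("ti must be positive")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if noise_sigma is None:
        noise_sigma = spec.noise_sigma
    if seed is None:
        seed = spec.seed
    m0_map = np.where(truth.tissue, spec.m0_tissue, 0.0)
    dm = fair_delta_m(truth.perfusion_map, m0_map, ti, spec.t1_tissue, lambda_bt)
    base_ir = m0_map * (1.0 - 2.0 * np.exp(-ti / spec.t1_tissue))
    frame_for = {"M0": m0_map, "ssIR": base_ir + dm, "nsIR": base_ir}
    labels = np.array(["M0", "ssIR", "nsIR"] * n_pairs)
    frames = np.stack([frame_for[lab] for lab in labels])
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)
    return ASLSeries(
        frames=frames, labels=labels, ti=ti, inter_image_time=inter_image_time
    )


@dataclass(frozen=True)
class AIFModel:
    """Gamma-variate arterial bolus:
    ``c(t) = amplitude ((t - t0)/beta)^alpha exp(-(t - t0)/beta)`` for
    ``t >= t0``, zero before arrival.  Peak at ``t0 + alpha beta``.

    ``t0 = None`` means "resolve to n_baseline x dt at simulation time"
    so aorta and tissue share a time origin with the pre-contrast
    baseline.
    """

    t0: float | None = None
    alpha: float = 3.0
    beta: float = 1.5  # s
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


def gamma_variate_aif(model: AIFModel, times: np.ndarray) -> AIF:
    """Evaluate the gamma-variate bolus on a time grid."""
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (len(times) >= 2 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be a 1D ascending vector")
    t0 = 0.0 if model.t0 is None else model.t0
    shifted = times - t0
    conc = np.zeros_like(times)
    pos = shifted > 0
    x = shifted[pos] / model.beta
    conc[pos] = model.amplitude * x**model.alpha * np.exp(-x)
    return AIF(
        curve=ConcentrationCurve(times=times, conc=conc),
        source_roi="gamma-variate model",
    )


@dataclass(frozen=True)
class ResidueModel:
    """Tissue residue function R(t): fraction of tracer remaining ``t``
    seconds after an ideal arterial impulse.  ``R(0) = 1``, monotone
    non-increasing.  ``tc`` is the mean transit time in seconds for the
    exponential form, the plateau length for the boxcar."""

    form: str = "exponential"
    tc: float = 4.0  # s

    def __post_init__(self) -> None:
        if self.form not in ("exponential", "boxcar"):
            raise ValueError(f"unknown residue form {self.form!r}")
        if self.tc <= 0:
            raise ValueError("tc must be positive")


def residue_function(model: ResidueModel, times: np.ndarray) -> np.ndarray:
    """Evaluate R(t) on a time grid (times >= 0)."""
    times = np.asarray(times, dtype=float)
    if model.form == "exponential":
        return np.exp(-times / model.tc)
    return (times < model.tc).astype(float)


def simulate_dce(
    truth: GroundTruth,
    aif_model: AIFModel,
    residue: ResidueModel,
    dt: float = 0.9,
    n_baseline: int = 15,
    n_volumes: int = 50,
    n_slices: int = 3,
    m0_tissue: float = 1.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DCESeries:
    """Forward-simulate a dynamic contrast series on the phantom grid.

    Per tissue pixel the signal is ``baseline + (f/6000) (C_A conv R)(t)``
    with the convolution discretised by the rectangle rule at step
    ``dt``; the aorta carries the input function itself; the bolus
    arrives after the ``n_baseline`` pre-contrast volumes.  The 2D slice
    is replicated over ``n_slices`` slices (each with independent
    noise), matching a thin multislice readout through the same
    phantom.
    """
    if n_baseline < 1:
        raise ValueError("n_baseline must be >= 1")
    if n_volumes <= n_baseline:
        raise ValueError("n_volumes must exceed n_baseline")
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    times = np.arange(n_volumes) * dt
    if aif_model.t0 is None:
        aif_model = replace(aif_model, t0=n_baseline * dt)
    ca = gamma_variate_aif(aif_model, times).curve.conc
    r = residue_function(residue, times)
    conv = dt * np.convolve(ca, r)[:n_volumes]  # rectangle rule
    signal = np.zeros((*truth.perfusion_map.shape, n_volumes))
    signal += (truth.perfusion_map / 6000.0)[..., None] * conv[None, None, :]
    signal[truth.aorta] = ca
    baseline = np.where(truth.tissue | truth.aorta, m0_tissue, 0.0)
    signal += baseline[..., None]
    volumes = np.repeat(signal[:, :, None, :], n_slices, axis=2)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        volumes = volumes + rng.normal(0.0, noise_sigma, size=volumes.shape)
    return DCESeries(volumes=volumes, dt=dt, n_baseline=n_baseline)
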