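"""FAIR-ASL perfusion quantification.

A pulsed-ASL acquisition with flow-sensitive alternating inversion recovery
(FAIR) interleaves three magnetic preparations: unprepared equilibrium
images (``M0``), slice-selective inversion recovery (``ssIR``, the control)
and non-selective global inversion (``nsIR``, the tag).  Inverted water in
inflowing arterial blood acts as an endogenous tracer: after the inflow
time TI the tag image is slightly darker than the control wherever tissue
is perfused, and the averaged difference image

    dM = <ssIR> - <nsIR>

is proportional to blood flow.  Under the single-compartment FAIR model —
instantaneous exchange of blood water into tissue, transit delays
neglected, a single tissue T1 — the pixelwise flow is

    f = unit_factor * lambda * dM * exp(TI / T1) / (2 * M0 * TI)

where ``lambda`` is the blood-tissue water partition coefficient (ml/g)
and ``unit_factor = 6000`` converts ml/g/s to the conventional
ml/100 g/min (x60 s->min, x100 per-g -> per-100 g).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PREPARATIONS",
    "ASLSeries",
    "QuantConstants",
    "PerfusionMap",
    "average_by_preparation",
    "delta_m",
    "quantify_fair",
    "roi_mean",
]

logger = logging.getLogger(__name__)

#: Frame preparation labels, in canonical interleaving order.
PREPARATIONS = ("M0", "ssIR", "nsIR")


@dataclass
class ASLSeries:
    """Interleaved FAIR series with per-frame preparation labels.

    Parameters
    ----------
    frames
        Stack of 2D signal images, shape ``(n_frames, rows, cols)``,
        arbitrary units.
    labels
        Per-frame preparation tag, each one of :data:`PREPARATIONS`.
    ti
        Inversion (inflow) time in seconds; the delay between the
        inversion pulse and the readout.
    inter_image_time
        Time between consecutive frames in seconds (long enough for full
        longitudinal relaxation; metadata only).
    """

    frames: np.ndarray
    labels: np.ndarray
    ti: float
    inter_image_time: float = 6.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, rows, cols), got shape {self.frames.shape}"
            )
        if len(self.labels) != len(self.frames):
            raise ValueError(
                f"{len(self.labels)} labels for {len(self.frames)} frames"
            )
        unknown = set(self.labels.tolist()) - set(PREPARATIONS)
        if unknown:
            raise ValueError(f"unknown preparation labels: {sorted(unknown)}")
        for prep in PREPARATIONS:
            if not np.any(self.labels == prep):
                raise ValueError(f"no frames labelled {prep!r}")
        if self.ti <= 0:
            raise ValueError(f"ti must be positive, got {self.ti}")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class QuantConstants:
    """Constants of the single-compartment FAIR model.

    ``lambda_bt`` is the blood-tissue water partition coefficient in ml/g
    (0.8 ml/g for kidney), ``t1`` the longitudinal relaxation time of the
    tissue in seconds (1.14 s for renal cortex at 3 T), and
    ``unit_factor`` converts ml/g/s to the reporting unit
    (6000 -> ml/100 g/min; 1 -> ml/g/s).
    """

    lambda_bt: float = 0.8
    t1: float = 1.14
    unit_factor: float = 6000.0

    def __post_init__(self) -> None:
        if self.lambda_bt <= 0:
            raise ValueError("lambda_bt must be positive")
        if self.t1 <= 0:
            raise ValueError("t1 must be positive")
        if self.unit_factor <= 0:
            raise ValueError("unit_factor must be positive")


@dataclass
class PerfusionMap:
    """Per-pixel blood-flow map with a validity mask.

    ``values`` are in the unit implied by the quantification's
    ``unit_factor`` (ml/100 g/min by default); ``mask`` flags pixels where
    the estimate is defined (sufficient M0 signal, finite result);
    ``provenance`` records the producing modality (``"ASL"`` or ``"DCE"``).
    """

    values: np.ndarray
    mask: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must share a shape")
        if self.provenance not in ("ASL", "DCE"):
            raise ValueError(f"provenance must be 'ASL' or 'DCE', got {self.provenance!r}")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite values inside the mask")


def average_by_preparation(
    series: ASLSeries,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average the frames of each magnetic preparation.

    Returns the pixelwise mean M0, ss-IR and ns-IR images (in that
    order).  Frame order within a preparation is irrelevant.
    """
    means = {}
    for prep in PREPARATIONS:
        sel = series.labels == prep
        if not np.any(sel):
            raise ValueError(f"no frames labelled {prep!r}")
        means[prep] = series.frames[sel].mean(axis=0)
    return means["M0"], means["ssIR"], means["nsIR"]


def delta_m(ssir_mean: np.ndarray, nsir_mean: np.ndarray) -> np.ndarray:
    """Perfusion-weighted difference image: control minus tag.

    Positive in perfused tissue (fresh, uninverted blood raises the
    control signal relative to the globally inverted tag).
    """
    ssir_mean = np.asarray(ssir_mean, dtype=float)
    nsir_mean = np.asarray(nsir_mean, dtype=float)
    if ssir_mean.shape != nsir_mean.shape:
        raise ValueError(
            f"shape mismatch: {ssir_mean.shape} vs {nsir_mean.shape}"
        )
    return ssir_mean - nsir_mean


def default_m0_floor(m0_map: np.ndarray, fraction: float = 0.05) -> float:
    """Signal floor excluding background pixels from quantification.

    A fraction of the robust maximum (99.5th percentile) of M0, so that
    air/background pixels — where the dM/M0 ratio diverges — are masked
    without clipping tissue.
    """
    robust_max = float(np.percentile(m0_map, 99.5))
    return fraction * robust_max


def quantify_fair(
    delta_m_map: np.ndarray,
    m0_map: np.ndarray,
    consts: QuantConstants,
    ti: float,
    m0_floor: float | None = None,
) -> PerfusionMap:
    """Pixelwise single-compartment FAIR quantification.

    Applies ``f = unit_factor * lambda * dM * exp(ti/T1) / (2 * M0 * ti)``
    on every pixel whose M0 exceeds ``m0_floor`` (default: 5% of the
    robust M0 maximum).  Negative flows are retained in the map; masking
    is purely an M0-signal criterion.
    """
    delta_m_map = np.asarray(delta_m_map, dtype=float)
    m0_map = np.asarray(m0_map, dtype=float)
    if delta_m_map.shape != m0_map.shape:
        raise ValueError(
            f"shape mismatch: {delta_m_map.shape} vs {m0_map.shape}"
        )
    if ti <= 0:
        raise ValueError(f"ti must be positive, got {ti}")
    if m0_floor is None:
        m0_floor = default_m0_floor(m0_map)
    mask = m0_map > m0_floor
    values = np.zeros_like(delta_m_map)
    np.divide(
        consts.unit_factor * consts.lambda_bt * delta_m_map * np.exp(ti / consts.t1),
        2.0 * m0_map * ti,
        out=values,
        where=mask,
    )
    bad = mask & ~np.isfinite(values)
    if np.any(bad):
        logger.warning("masking %d non-finite pixels", int(bad.sum()))
        mask = mask & ~bad
        values[bad] = 0.0
    logger.debug(
        "quantify_fair: ti=%g s, t1=%g s, lambda=%g ml/g, unit_factor=%g, "
        "m0_floor=%g (%d pixels in mask)",
        ti, consts.t1, consts.lambda_bt, consts.unit_factor, m0_floor,
        int(mask.sum()),
    )
    return PerfusionMap(values=values, mask=mask, provenance="ASL")


def roi_mean(pmap: PerfusionMap, roi: np.ndarray) -> float:
    """Mean flow over the intersection of an ROI with the validity mask."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != pmap.values.shape:
        raise ValueError(f"roi shape {roi.shape} != map shape {pmap.values.shape}")
    sel = roi & pmap.mask
    if not np.any(sel):
        raise ValueError("ROI does not intersect the valid mask")
    return float(pmap.values[sel].mean())
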