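"""Shared I/O: NIfTI series/masks/maps, frame-label CSVs, YAML config.

Conventions: arrays are indexed (row, column, slice, time), 0-based;
masks share the grid of their series exactly (no resampling); NIfTI is
the canonical volume format with an isotropic-in-plane affine derived
from the phantom pixel size.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .asl import ASLSeries, PerfusionMap
from .dce import DCESeries
from .synthetic import GroundTruth

__all__ = [
    "MASK_LABELS",
    "save_asl_series",
    "load_asl_series",
    "save_dce_series",
    "load_dce_series",
    "save_masks",
    "load_masks",
    "save_perfusion_map",
    "load_perfusion_map",
    "save_aif_csv",
    "RunConfig",
    "load_config",
    "config_hash",
]

logger = logging.getLogger(__name__)

#: Integer codes of the mask label volume.
MASK_LABELS = {
    "cortex_left": 1,
    "cortex_right": 2,
    "medulla_left": 3,
    "medulla_right": 4,
    "aorta": 5,
}


def _affine(pixel_size: float = 0.5, slice_thickness: float = 4.0) -> np.ndarray:
    return np.diag([pixel_size, pixel_size, slice_thickness, 1.0])


def save_asl_series(
    series: ASLSeries,
    nii_path: str | Path,
    labels_path: str | Path,
    pixel_size: float = 0.5,
) -> None:
    """Write an ASL series as one 4D NIfTI (rows, cols, 1, frames) plus a
    sidecar CSV of frame labels (frame_index, preparation)."""
    data = np.moveaxis(series.frames, 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(data, _affine(pixel_size)), str(nii_path))
    pd.DataFrame(
        {"frame_index": np.arange(series.n_frames), "preparation": series.labels}
    ).to_csv(labels_path, index=False)


def load_asl_series(
    nii_path: str | Path,
    labels_path: str | Path,
    ti: float,
    inter_image_time: float = 6.0,
) -> ASLSeries:
    """Read a 4D NIfTI + frame-label CSV back into an ASL series."""
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI, got shape {data.shape}")
    if data.shape[2] != 1:
        raise ValueError("ASL series must be single-slice (third axis of length 1)")
    frames = np.moveaxis(data[:, :, 0, :], -1, 0)
    labels_df = pd.read_csv(labels_path)
    if "preparation" not in labels_df.columns:
        raise ValueError("label CSV must have a 'preparation' column")
    if len(labels_df) != len(frames):
        raise ValueError(
            f"label CSV has {len(labels_df)} rows for {len(frames)} frames"
        )
    order = labels_df.sort_values("frame_index") if "frame_index" in labels_df else labels_df
    return ASLSeries(
        frames=frames,
        labels=order["preparation"].to_numpy(),
        ti=ti,
        inter_image_time=inter_image_time,
    )


def save_dce_series(
    series: DCESeries, nii_path: str | Path, pixel_size: float = 0.5
) -> None:
    """Write a DCE series as one 4D NIfTI (rows, cols, slices, time)."""
    data = series.volumes
    if data.ndim == 3:
        data = data[:, :, None, :]
    nib.save(nib.Nifti1Image(data, _affine(pixel_size)), str(nii_path))


def load_dce_series(
    nii_path: str | Path, dt: float | None, n_baseline: int
) -> DCESeries:
    """Read a 4D NIfTI into a DCE series; ``dt`` must come from config."""
    if dt is None:
        raise ValueError(
            "volume spacing dt is not stored in the NIfTI: set 'dt' in the "
            "DCE config (e.g. dt: 0.9)"
        )
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI, got shape {data.shape}")
    return DCESeries(volumes=data, dt=dt, n_baseline=n_baseline)


def save_masks(
    truth: GroundTruth, nii_path: str | Path, pixel_size: float = 0.5
) -> None:
    """Write the phantom masks as one integer label volume."""
    labels = np.zeros(truth.perfusion_map.shape, dtype=np.int16)
    for name, code in MASK_LABELS.items():
        labels[truth.mask_dict()[name]] = code
    nib.save(
        nib.Nifti1Image(labels[:, :, None], _affine(pixel_size)), str(nii_path)
    )


def load_masks(nii_path: str | Path) -> dict[str, np.ndarray]:
    """Read a label volume back into named boolean masks (2D)."""
    img = nib.load(str(nii_path))
    labels = np.asarray(img.dataobj)
    if labels.ndim == 3:
        labels = labels[:, :, 0]
    return {name: labels == code for name, code in MASK_LABELS.items()}


def save_perfusion_map(
    pmap: PerfusionMap, nii_path: str | Path, pixel_size: float = 0.5
) -> None:
    """Write a perfusion map (masked-out pixels as NaN) to NIfTI."""
    data = np.where(pmap.mask, pmap.values, np.nan)
    nib.save(nib.Nifti1Image(data[:, :, None], _affine(pixel_size)), str(nii_path))


def load_perfusion_map(nii_path: str | Path, provenance: str) -> PerfusionMap:
    img = nib.load(str(nii_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[:, :, 0]
    mask = np.isfinite(data)
    return PerfusionMap(
        values=np.where(mask, data, 0.0), mask=mask, provenance=provenance
    )


def save_aif_csv(times: np.ndarray, conc: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"time_s": times, "conc": conc}).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything a reproducible pipeline run needs.

    Defaults are the study conditions: TI 1.2 s, tissue T1 1.14 s,
    partition coefficient 0.8 ml/g for ASL; 0.9 s volume spacing, 15
    baseline volumes and a 50-volume first pass for DCE.
    """

    seed: int = 0
    out_dir: str = "renperf_out"
    # ASL constants
    ti: float = 1.2
    t1: float = 1.14
    lambda_bt: float = 0.8
    # DCE constants
    dt: float = 0.9
    n_baseline: int = 15
    first_pass_volumes: int = 50
    threshold_fraction: float = 0.15
    # stats options
    ddof_groups: int = 1
    ddof_diffs: int = 0
    # phantom (simulation) options
    noise_sigma: float = 0.0
    dce_noise_sigma: float = 0.0
    n_pairs: int = 30
    n_volumes: int = 120
    n_slices: int = 3
    # optional input paths (pre-existing series instead of simulation)
    asl_series: str | None = None
    asl_labels: str | None = None
    dce_series: str | None = None
    masks: str | None = None

    def __post_init__(self) -> None:
        for name in ("ti", "t1", "lambda_bt", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_baseline < 1 or self.first_pass_volumes < self.n_baseline + 2:
            raise ValueError("invalid DCE volume counts")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config (flat keys matching :class:`RunConfig` fields);
    keyword overrides win over the file, which wins over defaults."""
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a YAML mapping")
        unknown = set(loaded) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**values)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonicalised config, for provenance."""
    canonical = yaml.safe_dump(asdict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
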