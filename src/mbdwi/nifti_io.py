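"""Volume-level plumbing: 4D DWI NIfTI input, FSL-style bval sidecars,
voxel-wise map fitting, and lesion feature extraction from ROI masks.

Affines are passed through untouched (no resampling); parameter maps are
written one 3D volume per metric.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import FitConfig, SignalDecay, fit_all_models, roi_aggregate
from .models import METRICS, BValueScheme
from .synthetic import generate_decay

__all__ = [
    "read_bvals", "write_bvals", "read_dwi", "fit_volume", "write_maps",
    "extract_lesion_features", "synthesize_dwi_volume",
]


def read_bvals(path) -> BValueScheme:
    """FSL convention: one whitespace-separated row of b-values."""
    text = Path(path).read_text().split()
    return BValueScheme(tuple(float(v) for v in text))


def write_bvals(scheme: BValueScheme, path) -> None:
    Path(path).write_text(" ".join(f"{b:g}" for b in scheme.b_values) + "\n")


def read_dwi(dwi_path, bval_path):
    """Load a 4D DWI volume and its b-value sidecar.

    Returns (data, scheme, affine); the 4th axis must match the scheme
    length.
    """
    img = nib.load(str(dwi_path))
    data = np.asarray(img.dataobj, dtype=float)
    scheme = read_bvals(bval_path)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D volume, got shape {data.shape}")
    if data.shape[3] != len(scheme.b_values):
        raise ValueError(
            f"volume has {data.shape[3]} b-frames but sidecar lists "
            f"{len(scheme.b_values)} b-values")
    return data, scheme, img.affine


def fit_volume(data: np.ndarray, mask: np.ndarray, scheme: BValueScheme,
               config: FitConfig | None = None):
    """Independent voxel-wise fits inside a mask.

    Returns (maps, voxel_metrics): ``maps`` maps each metric to a 3D
    array (NaN outside the mask or for non-converged fits);
    ``voxel_metrics`` is the list of per-voxel 18-metric dicts in mask
    order, for ROI aggregation.
    """
    config = config or FitConfig()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != data.shape[:3]:
        raise ValueError("mask shape must match the volume's spatial shape")
    if not mask.any():
        raise ValueError("mask is empty")
    maps = {m: np.full(mask.shape, np.nan) for m in METRICS}
    voxel_metrics = []
    for idx in zip(*np.nonzero(mask)):
        sig = data[idx]
        decay = SignalDecay(scheme, tuple(np.maximum(sig, 1e-12)))
        fit = fit_all_models(decay, config)
        vm = fit.metrics
        voxel_metrics.append(vm)
        for m, v in vm.items():
            maps[m][idx] = v
    return maps, voxel_metrics


def write_maps(maps: dict, affine: np.ndarray, out_dir) -> list:
    """One 3D NIfTI per metric; '/' in metric names is not an issue but
    spaces are avoided.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for m, vol in maps.items():
        safe = m.replace("-", "_")
        path = out_dir / f"{safe}.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
        paths.append(path)
    return paths


def extract_lesion_features(data: np.ndarray, mask: np.ndarray,
                            scheme: BValueScheme,
                            config: FitConfig | None = None) -> dict:
    """Voxel-wise fit then ROI mean: the lesion's 18-metric vector."""
    _, voxel_metrics = fit_volume(data, mask, scheme, config)
    return roi_aggregate(voxel_metrics)


def synthesize_dwi_volume(params, shape: tuple, scheme: BValueScheme,
                          snr: float = 50.0, seed: int = 0):
    """Uniform synthetic phantom: every voxel decays with ``params`` plus
    independent Rician noise.  Returns (data4d, mask)."""
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    data = np.empty((nx, ny, nz, len(scheme.b_values)))
    for idx in np.ndindex(nx, ny, nz):
        data[idx] = generate_decay(params, scheme, snr, rng)
    return data, np.ones(shape, dtype=bool)
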