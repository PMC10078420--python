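"""File-format plumbing: HDF5 for k-space series, NIfTI for maps, YAML for
configuration.  Every writer round-trips through its reader to an equal
in-memory object."""

from __future__ import annotations

import numpy as np

from .phantom import KSpaceSeries
from .schedule import AveragingSchedule
from .signal_model import SequenceParams

__all__ = [
    "save_kspace",
    "load_kspace",
    "save_map",
    "load_map",
    "save_config",
    "load_config",
]

_SEQ_FIELDS = (
    "alpha_nominal", "TR_alpha", "TE", "TR_max", "n_slices", "t_sat", "t_line", "sat_angle",
)

VOXEL_MM = 3.0  # native in-plane voxel spacing


def save_kspace(path, ks: KSpaceSeries) -> None:
    """Write a k-space series to an HDF5 container (one dataset per block)."""
    import h5py

    with h5py.File(path, "w") as f:
        for i, arr in enumerate(ks.data):
            f.create_dataset(f"blocks/{i:03d}", data=arr)
        f.create_dataset("line_mask", data=ks.line_mask)
        f.create_dataset("times", data=ks.times)
        f.attrs["noise_sd"] = ks.noise_sd
        f.attrs["seed"] = -1 if ks.seed is None else ks.seed
        f.attrs["schedule_blocks"] = np.asarray(ks.schedule.blocks)
        f.attrs["schedule_TR_alpha"] = ks.schedule.TR_alpha
        f.attrs["schedule_n_points_max"] = ks.schedule.n_points_max
        for name in _SEQ_FIELDS:
            f.attrs[f"seq_{name}"] = getattr(ks.seq, name)


def load_kspace(path) -> KSpaceSeries:
    import h5py

    with h5py.File(path, "r") as f:
        blocks = [f[f"blocks/{k}"][()] for k in sorted(f["blocks"])]
        seq = SequenceParams(**{
            name: (int if name == "n_slices" else float)(f.attrs[f"seq_{name}"])
            for name in _SEQ_FIELDS
        })
        schedule = AveragingSchedule(
            blocks=tuple(tuple(int(v) for v in b) for b in f.attrs["schedule_blocks"]),
            TR_alpha=float(f.attrs["schedule_TR_alpha"]),
            n_points_max=int(f.attrs["schedule_n_points_max"]),
        )
        seed = int(f.attrs["seed"])
        return KSpaceSeries(
            data=blocks,
            schedule=schedule,
            seq=seq,
            line_mask=f["line_mask"][()].astype(bool),
            noise_sd=float(f.attrs["noise_sd"]),
            seed=None if seed < 0 else seed,
        )


def save_map(path, values: np.ndarray, units: str = "ms", valid: np.ndarray | None = None) -> None:
    """Write a quantitative map as float32 NIfTI (units noted in the header);
    invalid pixels are stored as NaN when a validity mask is given."""
    import nibabel as nib

    data = np.asarray(values, dtype=np.float32)
    if valid is not None:
        data = data.copy()
        data[~np.asarray(valid, bool)] = np.nan
    # axes: (slice, x, y) -> NIfTI (x, y, slice)
    if data.ndim == 3:
        data = np.moveaxis(data, 0, -1)
    affine = np.diag([VOXEL_MM, VOXEL_MM, 20.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header["descrip"] = f"units={units}".encode()
    nib.save(img, str(path))


def load_map(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a map written by :func:`save_map`; returns ``(values, valid)``."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = np.moveaxis(data, -1, 0)
    valid = np.isfinite(data)
    return np.nan_to_num(data), valid


def save_config(path, config: dict) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)
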