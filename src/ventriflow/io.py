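"""Readers and writers for the on-disk layout.

Volumes are NIfTI-1 (optionally gzipped): velocity as three 4D files
(``*_vx/_vy/_vz.nii.gz``, m/s) or one 5D file (x, y, z, t, component);
multi-point magnitudes as ``*_s0.._s3``; masks as uint8 4D. Geometry and
timing live in a JSON sidecar::

    {"spacing_mm": [..], "frame_times_s": [..], "venc_ms": v,
     "rr_s": r, "hr_bpm": h, "origin_mm": [..]}

``venc_ms`` is the velocity-encoding limit in m/s. NIfTI stores arrays
spatial-first; in memory everything is time-major (see :mod:`.datamodel`).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .datamodel import MAGNITUDE_KEYS, FlowDataset, LVMaskSeries
from .errors import ConfigError, FormatError

SIDEREQ = ("spacing_mm", "frame_times_s", "venc_ms", "rr_s")


def read_sidecar(path: str | Path) -> dict:
    try:
        raw = json.loads(Path(path).read_text())
    except FileNotFoundError as exc:
        raise ConfigError(f"sidecar not found: {path}") from exc
    for key in SIDEREQ:
        if key not in raw:
            raise ConfigError(f"sidecar {path} missing required key {key!r}")
    return raw


def write_sidecar(path: str | Path, *, spacing, frame_times, venc, rr, hr=None,
                  origin=None, extra: dict | None = None) -> None:
    doc = {
        "spacing_mm": list(np.asarray(spacing, float)),
        "frame_times_s": list(np.asarray(frame_times, float)),
        "venc_ms": float(venc),
        "rr_s": float(rr),
        "hr_bpm": float(hr) if hr is not None else 60.0 / float(rr),
    }
    if origin is not None:
        doc["origin_mm"] = list(np.asarray(origin, float))
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = np.asarray(origin, float) + 0.5 * np.asarray(spacing, float)
    return aff


def _save_nii(path, data_spatial_first: np.ndarray, spacing, origin, dtype=None):
    arr = data_spatial_first if dtype is None else data_spatial_first.astype(dtype)
    img = nib.Nifti1Image(arr, _affine(spacing, origin))
    img.header.set_zooms(tuple(spacing) + (1.0,) * (arr.ndim - 3))
    nib.save(img, str(path))


def _load_nii(path) -> np.ndarray:
    try:
        img = nib.load(str(path))
    except FileNotFoundError as exc:
        raise FormatError(f"volume not found: {path}") from exc
    return np.asarray(img.dataobj)


def _scalar_to_time_major(arr: np.ndarray, name: str) -> np.ndarray:
    if arr.ndim != 4:
        raise FormatError(f"{name}: expected 4D NIfTI, got {arr.ndim}D")
    return np.moveaxis(arr, 3, 0)  # (x,y,z,t) -> (t,x,y,z)


def save_flow_dataset(ds: FlowDataset, out_dir: str | Path, basename: str = "flow") -> dict:
    """Write velocity (3 files), optional magnitudes, and the sidecar.

    Returns a dict of written paths keyed ``vx/vy/vz``, ``s0..s3``, ``sidecar``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for axis, suffix in enumerate(("vx", "vy", "vz")):
        p = out / f"{basename}_{suffix}.nii.gz"
        comp = np.moveaxis(ds.velocity[..., axis], 0, 3)  # (t,x,y,z)->(x,y,z,t)
        _save_nii(p, comp, ds.spacing, ds.origin, dtype=np.float64)
        paths[suffix] = p
    if ds.magnitudes is not None:
        for key in MAGNITUDE_KEYS:
            if key in ds.magnitudes:
                p = out / f"{basename}_{key}.nii.gz"
                _save_nii(p, np.moveaxis(ds.magnitudes[key], 0, 3), ds.spacing,
                          ds.origin, dtype=np.float64)
                paths[key] = p
    sc = out / f"{basename}_sidecar.json"
    write_sidecar(sc, spacing=ds.spacing, frame_times=ds.frame_times, venc=ds.venc,
                  rr=ds.rr_interval, hr=ds.heart_rate, origin=ds.origin)
    paths["sidecar"] = sc
    return paths


def load_flow_dataset(
    velocity_paths: Sequence[str | Path] | str | Path,
    sidecar_path: str | Path,
    magnitude_paths: Sequence[str | Path] | None = None,
) -> FlowDataset:
    """Load a :class:`FlowDataset` from NIfTI volumes plus a JSON sidecar.

    ``velocity_paths`` is either three 4D component files (x, y, z order) or a
    single 5D file. Velocity samples exceeding the VENC trigger a warning
    (possible residual aliasing), not an error.
    """
    side = read_sidecar(sidecar_path)
    if isinstance(velocity_paths, (str, Path)):
        arr = _load_nii(velocity_paths)
        if arr.ndim != 5 or arr.shape[-1] != 3:
            raise FormatError(
                f"single velocity file must be 5D (x,y,z,t,3), got {arr.shape}"
            )
        vel = np.moveaxis(arr, 3, 0)  # (t,x,y,z,3)
    else:
        if len(velocity_paths) != 3:
            raise FormatError("expected three velocity component files")
        comps = []
        for p in velocity_paths:
            comps.append(_scalar_to_time_major(_load_nii(p), str(p)))
        shapes = {c.shape for c in comps}
        if len(shapes) != 1:
            raise FormatError(f"velocity component shapes differ: {sorted(shapes)}")
        vel = np.stack(comps, axis=-1)

    n_frames = len(side["frame_times_s"])
    if vel.shape[0] != n_frames:
        raise FormatError(
            f"velocity has {vel.shape[0]} frames but sidecar declares {n_frames}"
        )

    mags = None
    if magnitude_paths is not None:
        if len(magnitude_paths) != 4:
            raise FormatError("expected four magnitude files (s0..s3)")
        mags = {}
        for key, p in zip(MAGNITUDE_KEYS, magnitude_paths):
            grid = _scalar_to_time_major(_load_nii(p), str(p))
            if grid.shape != vel.shape[:4]:
                raise FormatError(
                    f"magnitude {key} shape {grid.shape} != velocity {vel.shape[:4]}"
                )
            mags[key] = grid

    ds = FlowDataset(
        velocity=vel,
        spacing=side["spacing_mm"],
        frame_times=side["frame_times_s"],
        venc=side["venc_ms"],
        rr_interval=side["rr_s"],
        magnitudes=mags,
        heart_rate=side.get("hr_bpm"),
        origin=side.get("origin_mm", np.zeros(3)),
    )
    n_alias = int(np.count_nonzero(np.abs(ds.velocity) > ds.venc))
    if n_alias:
        warnings.warn(
            f"{n_alias} velocity samples exceed VENC={ds.venc} m/s "
            "(possible residual aliasing)",
            UserWarning,
            stacklevel=2,
        )
    return ds


def save_mask_series(masks: LVMaskSeries, path: str | Path,
                     sidecar_path: str | Path | None = None) -> None:
    """Write masks as uint8 4D NIfTI; optionally write a sidecar alongside."""
    _save_nii(path, np.moveaxis(masks.masks.astype(np.uint8), 0, 3),
              masks.spacing, masks.origin)
    if sidecar_path is not None:
        extra = {}
        if masks.ed_frame is not None:
            extra = {"ed_frame": int(masks.ed_frame), "es_frame": int(masks.es_frame)}
        write_sidecar(sidecar_path, spacing=masks.spacing,
                      frame_times=masks.frame_times, venc=1.0,
                      rr=masks.rr_interval, origin=masks.origin, extra=extra)


def load_mask_series(path: str | Path, sidecar_path: str | Path) -> LVMaskSeries:
    side = read_sidecar(sidecar_path)
    grid = _scalar_to_time_major(_load_nii(path), str(path))
    return LVMaskSeries(
        masks=grid > 0,
        spacing=side["spacing_mm"],
        frame_times=side["frame_times_s"],
        rr_interval=side["rr_s"],
        origin=side.get("origin_mm", np.zeros(3)),
        ed_frame=side.get("ed_frame"),
        es_frame=side.get("es_frame"),
    )


def save_scalar_field(field: np.ndarray, path: str | Path, spacing, origin=None) -> None:
    """Write a time-major scalar field (T, nx, ny, nz) as 4D NIfTI."""
    if origin is None:
        origin = np.zeros(3)
    _save_nii(path, np.moveaxis(np.asarray(field, float), 0, 3), spacing, origin)


def load_scalar_field(path: str | Path) -> np.ndarray:
    return _scalar_to_time_major(_load_nii(path), str(path))
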