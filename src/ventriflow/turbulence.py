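"""Turbulent kinetic energy from multi-point PC-MRI magnitude data.

The intravoxel velocity fluctuation intensity sigma_i (m/s) along each of
three orthogonal motion-encoding directions is estimated from the attenuation
of the encoded magnitude |S_i| relative to the reference magnitude |S|:

    sigma_i = (1 / kv) * sqrt(2 * ln(|S| / |S_i|)),     kv = pi / VENC

assuming a Gaussian intravoxel velocity distribution. The TKE density is

    TKE = 1/2 * rho * (sigma_1^2 + sigma_2^2 + sigma_3^2)   [J/m^3]

with rho the blood density (default 1060 kg/m^3). Noise can push
|S_i| >= |S|; those voxels are clamped to sigma_i = 0 (nonnegativity), as are
voxels with no signal (|S| = 0). The TKE field is optionally denoised with a
3x3x3 spatial median filter applied per frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .datamodel import FlowDataset
from .errors import DataError, DomainError, SizeError


@dataclass
class TurbulenceMaps:
    """Per-voxel sigma fields and TKE density.

    sigma : (T, nx, ny, nz, 3) m/s; tke_density : (T, nx, ny, nz) J/m^3.
    """

    sigma: np.ndarray
    tke_density: np.ndarray
    kv: float          # motion sensitivity, s/m
    rho: float         # blood density used, kg/m^3
    filtered: bool     # whether the median filter was applied
    clamp_fraction: float = 0.0  # fraction of voxels hit by the noise-floor clamp


def compute_kv(venc: float) -> float:
    """Motion sensitivity kv = pi / VENC, in s/m (VENC in m/s)."""
    if venc <= 0:
        raise DomainError(f"venc must be > 0, got {venc}")
    return float(np.pi / venc)


def estimate_sigma(s_ref: np.ndarray, s_enc: np.ndarray, kv: float) -> np.ndarray:
    """Velocity fluctuation intensity (m/s) from a magnitude pair.

    Wherever ``s_enc >= s_ref`` (noise floor) or ``s_ref == 0`` (no signal) the
    estimate is clamped to zero.
    """
    s_ref = np.asarray(s_ref, dtype=float)
    s_enc = np.asarray(s_enc, dtype=float)
    if kv <= 0:
        raise DomainError(f"kv must be > 0, got {kv}")
    if np.any(s_ref < 0) or np.any(s_enc < 0):
        raise DataError("magnitudes must be nonnegative")
    sigma = np.zeros(np.broadcast_shapes(s_ref.shape, s_enc.shape))
    valid = (s_ref > 0) & (s_enc > 0) & (s_enc < s_ref)
    ratio = np.divide(s_ref, s_enc, out=np.ones_like(sigma), where=valid)
    sigma[valid] = np.sqrt(2.0 * np.log(ratio[valid])) / kv
    # s_enc == 0 with s_ref > 0: signal fully attenuated, the log diverges;
    # no finite estimate exists, so those voxels are also left at zero.
    return sigma


def compute_tke_density(sigma: np.ndarray, rho: float) -> np.ndarray:
    """TKE density 1/2 * rho * sum_i sigma_i^2 (J/m^3); sigma (..., 3) in m/s."""
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape[-1] != 3:
        raise DataError(f"sigma must have a trailing axis of 3, got {sigma.shape}")
    if np.any(sigma < 0):
        raise DataError("sigma must be nonnegative")
    if rho <= 0:
        raise DomainError(f"rho must be > 0, got {rho}")
    return 0.5 * rho * np.sum(sigma * sigma, axis=-1)


def median_filter_tke(tke: np.ndarray) -> np.ndarray:
    """3x3x3 spatial median filter, per frame, edge-repeat padding at boundaries."""
    tke = np.asarray(tke, dtype=float)
    if tke.ndim == 3:
        frames = tke[None]
        squeeze = True
    elif tke.ndim == 4:
        frames = tke
        squeeze = False
    else:
        raise DataError(f"tke must be 3D or 4D, got {tke.ndim}D")
    if min(frames.shape[1:]) < 3:
        raise SizeError(
            f"each spatial dimension must be >= 3 for a 3x3x3 filter, got "
            f"{frames.shape[1:]}"
        )
    out = np.stack(
        [ndimage.median_filter(f, size=3, mode="reflect") for f in frames]
    )
    return out[0] if squeeze else out


def compute_turbulence_maps(
    ds: FlowDataset, rho: float = 1060.0, median_filter: bool = True
) -> TurbulenceMaps:
    """Full magnitude-to-TKE chain for a dataset carrying |S|, |S1..3|."""
    if ds.magnitudes is None:
        raise DataError("dataset has no magnitude volumes")
    for key in ("s0", "s1", "s2", "s3"):
        if key not in ds.magnitudes:
            raise DataError(f"magnitude volume {key!r} missing")
    kv = compute_kv(ds.venc)
    s_ref = ds.magnitudes["s0"]
    sigma = np.stack(
        [estimate_sigma(s_ref, ds.magnitudes[f"s{i}"], kv) for i in (1, 2, 3)],
        axis=-1,
    )
    clamped = sum(
        int(np.count_nonzero(ds.magnitudes[f"s{i}"] >= s_ref)) for i in (1, 2, 3)
    )
    tke = compute_tke_density(sigma, rho)
    if median_filter:
        tke = median_filter_tke(tke)
    return TurbulenceMaps(
        sigma=sigma,
        tke_density=tke,
        kv=kv,
        rho=rho,
        filtered=bool(median_filter),
        clamp_fraction=clamped / (3 * s_ref.size),
    )
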