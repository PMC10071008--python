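"""In-memory containers for 4D flow data and LV segmentations.

Conventions
-----------
* Arrays are time-major: velocity ``(T, nx, ny, nz, 3)`` in m/s, masks
  ``(T, nx, ny, nz)`` boolean.
* Voxel indices are 0-based; the physical center of voxel ``(i, j, k)`` is
  ``origin + (i + 1/2, j + 1/2, k + 1/2) * spacing`` in mm.
* The cardiac cycle is periodic: the frame after the last one is frame 0
  (retrospective gating covers a full cycle), so diastole may wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    AlignmentError,
    DataError,
    DegenerateInputError,
    FormatError,
    GeometryError,
    SizeError,
)

MAGNITUDE_KEYS = ("s0", "s1", "s2", "s3")


def _as_float_vec(x, n, name) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise FormatError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass
class FlowDataset:
    """Time-resolved 3D three-component velocity field with geometry/timing.

    Parameters
    ----------
    velocity : ndarray, shape (T, nx, ny, nz, 3)
        Phase-averaged velocity in m/s.
    spacing : array-like of 3 floats
        Voxel edge lengths in mm.
    frame_times : array-like of T floats
        Acquisition time of each reconstructed frame, seconds from cycle start;
        strictly increasing, all within ``[0, rr_interval)``.
    venc : float
        Velocity-encoding limit in m/s (sets the motion sensitivity kv).
    rr_interval : float
        Cardiac cycle length in seconds.
    magnitudes : dict or None
        Optional four-point magnitude volumes keyed ``s0`` (reference, no
        motion-sensitivity encoding) and ``s1..s3`` (encoded), each
        ``(T, nx, ny, nz)``, nonnegative, arbitrary signal units.
    heart_rate : float or None
        Beats per minute; defaults to ``60 / rr_interval``.
    origin : array-like of 3 floats
        Physical position (mm) of the corner of voxel (0,0,0).
    """

    velocity: np.ndarray
    spacing: np.ndarray
    frame_times: np.ndarray
    venc: float
    rr_interval: float
    magnitudes: dict[str, np.ndarray] | None = None
    heart_rate: float | None = None
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.velocity = np.asarray(self.velocity, dtype=float)
        if self.velocity.ndim != 5 or self.velocity.shape[-1] != 3:
            raise FormatError(
                f"velocity must be (T, nx, ny, nz, 3), got {self.velocity.shape}"
            )
        self.spacing = _as_float_vec(self.spacing, 3, "spacing")
        if np.any(self.spacing <= 0):
            raise FormatError("spacing must be positive")
        self.origin = _as_float_vec(self.origin, 3, "origin")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.n_frames,):
            raise FormatError(
                f"frame_times length {self.frame_times.size} != {self.n_frames} frames"
            )
        if np.any(np.diff(self.frame_times) <= 0):
            raise FormatError("frame_times must be strictly increasing")
        if self.rr_interval <= 0:
            raise FormatError("rr_interval must be positive")
        if self.frame_times[0] < 0 or self.frame_times[-1] >= self.rr_interval:
            raise FormatError("frame_times must lie in [0, rr_interval)")
        if self.venc <= 0:
            raise FormatError("venc must be positive")
        if self.heart_rate is None:
            self.heart_rate = 60.0 / self.rr_interval
        if self.magnitudes is not None:
            for key in self.magnitudes:
                if key not in MAGNITUDE_KEYS:
                    raise FormatError(f"unknown magnitude key {key!r}")
            for key, grid in self.magnitudes.items():
                grid = np.asarray(grid, dtype=float)
                if grid.shape != self.grid_shape_t:
                    raise FormatError(
                        f"magnitude {key} shape {grid.shape} != velocity grid "
                        f"{self.grid_shape_t}"
                    )
                if np.any(grid < 0):
                    raise DataError(f"magnitude {key} contains negative values")
                self.magnitudes[key] = grid

    # --- geometry helpers -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.velocity.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.velocity.shape[1:4]

    @property
    def grid_shape_t(self) -> tuple[int, int, int, int]:
        return self.velocity.shape[:4]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_m3(self) -> float:
        return self.voxel_volume_mm3 * 1e-9

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical bounding box: rows (low, high) per axis, mm."""
        low = self.origin
        high = self.origin + np.asarray(self.grid_shape) * self.spacing
        return np.stack([low, high])

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Physical centers (mm) of all voxels, or of ``mask`` voxels, (N, 3)."""
        if mask is None:
            idx = np.stack(
                np.meshgrid(*[np.arange(n) for n in self.grid_shape], indexing="ij"),
                axis=-1,
            ).reshape(-1, 3)
        else:
            idx = np.argwhere(mask)
        return self.origin + (idx + 0.5) * self.spacing


def voxel_centers_of(indices: np.ndarray, spacing, origin) -> np.ndarray:
    return np.asarray(origin, float) + (np.asarray(indices, float) + 0.5) * np.asarray(
        spacing, float
    )


@dataclass
class LVMaskSeries:
    """Time-resolved binary LV segmentation with per-frame volumes.

    ``ed_frame``/``es_frame`` default to the argmax/argmin of the volume curve;
    they may be given explicitly for datasets (e.g. constant-volume phantoms)
    where the volume curve does not determine them.
    """

    masks: np.ndarray
    spacing: np.ndarray
    frame_times: np.ndarray
    rr_interval: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ed_frame: int | None = None
    es_frame: int | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks).astype(bool)
        if self.masks.ndim != 4:
            raise FormatError(f"masks must be 4D (T, nx, ny, nz), got {self.masks.shape}")
        self.spacing = _as_float_vec(self.spacing, 3, "spacing")
        if np.any(self.spacing <= 0):
            raise FormatError("spacing must be positive")
        self.origin = _as_float_vec(self.origin, 3, "origin")
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.frame_times.shape != (self.n_frames,):
            raise FormatError("frame_times length does not match mask frames")
        if np.any(np.diff(self.frame_times) <= 0):
            raise FormatError("frame_times must be strictly increasing")
        if self.rr_interval <= 0:
            raise FormatError("rr_interval must be positive")
        counts = self.masks.reshape(self.n_frames, -1).sum(axis=1)
        if np.any(counts == 0):
            raise DataError("mask is empty at one or more frames")
        self._counts = counts
        if (self.ed_frame is None) != (self.es_frame is None):
            raise FormatError("ed_frame and es_frame must be given together")
        if self.ed_frame is not None:
            for name, f in (("ed_frame", self.ed_frame), ("es_frame", self.es_frame)):
                if not 0 <= f < self.n_frames:
                    raise FormatError(f"{name}={f} out of range")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.masks.shape[1:4]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    @property
    def volumes_ml(self) -> np.ndarray:
        """Per-frame LV volume in ml (voxel count x voxel volume)."""
        return self._counts * self.voxel_volume_ml

    def _extremum_frames(self) -> tuple[int, int]:
        vols = self.volumes_ml
        if np.ptp(vols) == 0:
            raise DegenerateInputError(
                "constant volume curve: ED/ES undefined (pass ed_frame/es_frame)"
            )
        return int(np.argmax(vols)), int(np.argmin(vols))

    def get_ed_es(self) -> tuple[int, int]:
        """(ed_frame, es_frame): explicit if given, else volume-curve extrema."""
        if self.ed_frame is not None:
            return int(self.ed_frame), int(self.es_frame)
        return self._extremum_frames()

    def extent_mm(self) -> np.ndarray:
        low = self.origin
        high = self.origin + np.asarray(self.grid_shape) * self.spacing
        return np.stack([low, high])


@dataclass(frozen=True)
class VentricularMetrics:
    """Standard volumetric LV function indices."""

    edv: float              # end-diastolic volume, ml
    esv: float              # end-systolic volume, ml
    sv: float               # stroke volume, ml
    ef: float               # ejection fraction, %
    cardiac_output: float   # l/min
    diastolic_length: float  # s, ES -> ED (wrapping)
    heart_rate: float       # bpm
    ed_frame: int
    es_frame: int


def compute_ventricular_metrics(
    masks: LVMaskSeries, rr_interval: float | None = None
) -> VentricularMetrics:
    """EDV/ESV/SV/EF/CO and diastolic length from the mask volume curve.

    ED and ES are the frames of largest and smallest LV volume. The diastolic
    length is the time from ES to ED, wrapping past the end of the cycle.
    """
    if masks.n_frames < 3:
        raise SizeError(f"need >= 3 frames, got {masks.n_frames}")
    rr = masks.rr_interval if rr_interval is None else float(rr_interval)
    ed, es = masks._extremum_frames()
    vols = masks.volumes_ml
    edv = float(vols[ed])
    esv = float(vols[es])
    sv = edv - esv
    ef = 100.0 * sv / edv
    hr = 60.0 / rr
    co = sv * hr / 1000.0
    diast = float((masks.frame_times[ed] - masks.frame_times[es]) % rr)
    return VentricularMetrics(
        edv=edv, esv=esv, sv=sv, ef=ef, cardiac_output=co,
        diastolic_length=diast, heart_rate=hr, ed_frame=ed, es_frame=es,
    )


# --------------------------------------------------------------------------
# Mask resampling
# --------------------------------------------------------------------------

def _signed_distance(mask3d: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance (mm), positive inside the mask."""
    inside = ndimage.distance_transform_edt(mask3d, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask3d, sampling=spacing)
    return inside - outside


def resample_mask_series(
    masks: LVMaskSeries,
    target: "FlowDataset | LVMaskSeries",
) -> LVMaskSeries:
    """Resample a mask series onto the grid and frame times of ``target``.

    Spatial resampling is nearest-neighbour on the signed-distance transform of
    each source frame; temporal resampling linearly interpolates the
    signed-distance samples between the two bracketing source frames
    (cyclically), thresholding the result at zero. This preserves topology and
    yields a smooth volume curve.
    """
    t_spacing = np.asarray(target.spacing, float)
    t_origin = np.asarray(target.origin, float)
    t_shape = target.grid_shape
    t_times = np.asarray(target.frame_times, float)
    rr = masks.rr_interval

    # require physical overlap
    src_ext = masks.extent_mm()
    low = np.maximum(src_ext[0], t_origin)
    high = np.minimum(src_ext[1], t_origin + np.asarray(t_shape) * t_spacing)
    if np.any(high <= low):
        raise GeometryError("source and target grids have disjoint physical extents")

    # fast path: identical grid and timing -> identity
    same_grid = (
        masks.grid_shape == tuple(t_shape)
        and np.allclose(masks.spacing, t_spacing)
        and np.allclose(masks.origin, t_origin)
    )
    if same_grid and masks.frame_times.shape == t_times.shape and np.allclose(
        masks.frame_times, t_times
    ):
        return LVMaskSeries(
            masks=masks.masks.copy(), spacing=t_spacing, frame_times=t_times,
            rr_interval=rr, origin=t_origin,
            ed_frame=masks.ed_frame, es_frame=masks.es_frame,
        )

    sdts = np.stack([_signed_distance(m, masks.spacing) for m in masks.masks])

    # target voxel centers -> fractional source indices
    centers = np.stack(
        np.meshgrid(*[np.arange(n) for n in t_shape], indexing="ij"), axis=-1
    ).astype(float)
    pos = t_origin + (centers + 0.5) * t_spacing
    src_idx = (pos - masks.origin) / masks.spacing - 0.5
    coords = np.moveaxis(src_idx, -1, 0)  # (3, nx, ny, nz)

    src_times = masks.frame_times
    n_src = masks.n_frames
    out = np.empty((t_times.size,) + tuple(t_shape), dtype=bool)
    # cache spatially resampled SDTs per needed source frame
    sampled: dict[int, np.ndarray] = {}

    def sample(f: int) -> np.ndarray:
        if f not in sampled:
            sampled[f] = ndimage.map_coordinates(
                sdts[f], coords, order=0, mode="nearest"
            )
        return sampled[f]

    for ti, t in enumerate(t_times):
        tau = t % rr
        f1 = int(np.searchsorted(src_times, tau, side="right")) - 1
        if f1 < 0:  # before first source frame: bracket is (last, first) across wrap
            f0, fnxt = n_src - 1, 0
            t0 = src_times[-1] - rr
            t1 = src_times[0]
        else:
            f0 = f1
            fnxt = (f1 + 1) % n_src
            t0 = src_times[f0]
            t1 = src_times[f0 + 1] if f1 + 1 < n_src else src_times[0] + rr
        w = 0.0 if t1 == t0 else (tau - t0) / (t1 - t0)
        sdt = (1.0 - w) * sample(f0) + w * sample(fnxt)
        out[ti] = sdt > 0

    ed = es = None
    if masks.ed_frame is not None and t_times.size == masks.n_frames and np.allclose(
        t_times, masks.frame_times
    ):
        ed, es = masks.ed_frame, masks.es_frame
    result = LVMaskSeries(
        masks=out, spacing=t_spacing, frame_times=t_times, rr_interval=rr,
        origin=t_origin, ed_frame=ed, es_frame=es,
    )
    return result


def require_same_grid(a, b, what: str = "inputs") -> None:
    """Raise AlignmentError unless two gridded objects share geometry and timing."""
    if tuple(a.grid_shape) != tuple(b.grid_shape):
        raise AlignmentError(f"{what}: grid shapes differ {a.grid_shape} vs {b.grid_shape}")
    if not (np.allclose(a.spacing, b.spacing) and np.allclose(a.origin, b.origin)):
        raise AlignmentError(f"{what}: grid geometry differs")
    if a.frame_times.shape != b.frame_times.shape or not np.allclose(
        a.frame_times, b.frame_times
    ):
        raise AlignmentError(f"{what}: frame times differ")
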