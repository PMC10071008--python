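"""Whole-LV kinetic-energy time series and diastolic indices.

MKE is summed over the segmented LV as ``sum_i 1/2 rho V_i |v_i|^2`` (J) and
TKE as ``sum_i TKE_density_i V_i``; both are volume-normalized by the current
LV volume to J/m^3 so chambers of different size are comparable. Diastole is
the frame window from end-systole to end-diastole (wrapping past the end of
the cycle); the E- and A-wave time points are the two highest local maxima of
the volume-normalized MKE within that window; time integrals use the
trapezoidal rule on the physical frame times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import FlowDataset, LVMaskSeries, require_same_grid
from .errors import DataError, DegenerateInputError, DomainError, SizeError
from .turbulence import TurbulenceMaps


@dataclass
class EnergeticsSeries:
    """Per-frame global energetics plus diastolic summary indices."""

    frame_times: np.ndarray     # s
    lv_volume_ml: np.ndarray
    mke_total: np.ndarray       # J
    tke_total: np.ndarray       # J
    mke_v: np.ndarray           # J/m^3
    tke_v: np.ndarray           # J/m^3
    diastole: np.ndarray        # ordered frame indices, ES..ED (may wrap)
    e_frame: int
    a_frame: int
    mke_v_integral: float       # J*s/m^3 over diastole
    tke_v_integral: float
    tke_ke_peak_e: float
    tke_ke_peak_a: float
    tke_ke_integral: float


def compute_mke_series(
    flow: FlowDataset, masks: LVMaskSeries, rho: float = 1060.0
) -> tuple[np.ndarray, np.ndarray]:
    """(mke_total [J], mke_v [J/m^3]) per frame over the LV mask."""
    require_same_grid(flow, masks, "flow vs masks")
    if rho <= 0:
        raise DomainError("rho must be > 0")
    speed2 = np.sum(flow.velocity**2, axis=-1)  # (T, nx, ny, nz), (m/s)^2
    vvox = flow.voxel_volume_m3
    totals = np.empty(flow.n_frames)
    for f in range(flow.n_frames):
        sel = masks.masks[f]
        if not sel.any():
            raise DataError(f"empty mask at frame {f}")
        totals[f] = 0.5 * rho * vvox * float(speed2[f][sel].sum())
    lv_m3 = masks.volumes_ml * 1e-6
    return totals, totals / lv_m3


def compute_tke_series(
    tke: TurbulenceMaps, masks: LVMaskSeries
) -> tuple[np.ndarray, np.ndarray]:
    """(tke_total [J], tke_v [J/m^3]) per frame over the LV mask."""
    density = tke.tke_density
    if density.shape != masks.masks.shape:
        raise DataError(
            f"TKE grid {density.shape} does not match masks {masks.masks.shape}"
        )
    vvox = masks.voxel_volume_mm3 * 1e-9
    totals = np.empty(density.shape[0])
    for f in range(density.shape[0]):
        sel = masks.masks[f]
        if not sel.any():
            raise DataError(f"empty mask at frame {f}")
        totals[f] = vvox * float(density[f][sel].sum())
    lv_m3 = masks.volumes_ml * 1e-6
    return totals, totals / lv_m3


def detect_diastole(masks: LVMaskSeries) -> np.ndarray:
    """Ordered frame indices from ES to ED inclusive, wrapping if needed."""
    ed, es = masks.get_ed_es()
    if ed == es:
        raise DegenerateInputError("ED and ES coincide: no diastolic window")
    n = masks.n_frames
    length = (ed - es) % n
    return (es + np.arange(length + 1)) % n


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of local maxima; plateaus contribute their first index.

    Endpoints qualify with a one-sided comparison, so a monotone decreasing
    series has its single maximum at index 0.
    """
    v = np.asarray(values, float)
    n = v.size
    out: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        left_ok = i == 0 or v[i - 1] < v[i]
        right_ok = j == n - 1 or v[j + 1] < v[i]
        if left_ok and right_ok:
            out.append(i)
        i = j + 1
    return out


def detect_ea_peaks(
    mke_v: np.ndarray,
    window: np.ndarray,
    fallback_fraction: float = 0.30,
) -> tuple[int, int]:
    """E- and A-wave frames from the diastolic MKE_V course.

    Among the local maxima of ``mke_v`` restricted to ``window`` (frame
    indices), the two highest values are the candidate peaks; E is the earlier
    and A the later. When the waves have merged into a single maximum (high
    heart rate), E is that maximum and A falls back to the frame of maximal
    MKE_V within the final ``fallback_fraction`` of the window, strictly after
    E. Returns absolute frame indices.
    """
    window = np.asarray(window, int)
    m = window.size
    if m < 4:
        raise SizeError(f"diastole window must span >= 4 frames, got {m}")
    values = np.asarray(mke_v, float)[window]
    maxima = _local_maxima(values)
    if len(maxima) >= 2:
        ranked = sorted(maxima, key=lambda i: (-values[i], i))
        top2 = sorted(ranked[:2])
        return int(window[top2[0]]), int(window[top2[1]])
    e_pos = maxima[0] if maxima else int(np.argmax(values))
    tail = max(1, int(np.ceil(fallback_fraction * m)))
    start = max(m - tail, e_pos + 1)
    if start >= m:
        raise DegenerateInputError("no frames after the E peak for the A fallback")
    a_pos = start + int(np.argmax(values[start:]))
    return int(window[e_pos]), int(window[a_pos])


def window_times(
    window: np.ndarray, frame_times: np.ndarray, rr_interval: float
) -> np.ndarray:
    """Monotone times (s) for an ordered, possibly wrapping frame window."""
    window = np.asarray(window, int)
    t = np.asarray(frame_times, float)[window]
    wraps = np.cumsum(np.concatenate([[0], (np.diff(window) < 0).astype(int)]))
    return t + wraps * rr_interval


def integrate_diastole(
    series: np.ndarray,
    window: np.ndarray,
    frame_times: np.ndarray,
    rr_interval: float,
) -> float:
    """Trapezoidal time integral of a per-frame series over the window."""
    t = window_times(window, frame_times, rr_interval)
    y = np.asarray(series, float)[np.asarray(window, int)]
    return float(np.trapezoid(y, t))


def tke_ke_ratio(tke, mke):
    """TKE / (TKE + MKE): the turbulent fraction of total kinetic energy."""
    tke = np.asarray(tke, float)
    mke = np.asarray(mke, float)
    if np.any(tke < 0) or np.any(mke < 0):
        raise DataError("energies must be nonnegative")
    total = tke + mke
    if np.any(total == 0):
        raise DegenerateInputError("TKE and MKE both zero: ratio undefined")
    out = tke / total
    return float(out) if out.ndim == 0 else out


def compute_global_energetics(
    flow: FlowDataset,
    masks: LVMaskSeries,
    turbulence: TurbulenceMaps,
    rho: float = 1060.0,
    a_wave_fallback_fraction: float = 0.30,
) -> EnergeticsSeries:
    """Assemble the full whole-LV energetics summary."""
    mke_total, mke_v = compute_mke_series(flow, masks, rho)
    tke_total, tke_v = compute_tke_series(turbulence, masks)
    window = detect_diastole(masks)
    e_frame, a_frame = detect_ea_peaks(mke_v, window, a_wave_fallback_fraction)
    mke_int = integrate_diastole(mke_v, window, flow.frame_times, flow.rr_interval)
    tke_int = integrate_diastole(tke_v, window, flow.frame_times, flow.rr_interval)
    return EnergeticsSeries(
        frame_times=flow.frame_times.copy(),
        lv_volume_ml=masks.volumes_ml,
        mke_total=mke_total,
        tke_total=tke_total,
        mke_v=mke_v,
        tke_v=tke_v,
        diastole=window,
        e_frame=e_frame,
        a_frame=a_frame,
        mke_v_integral=mke_int,
        tke_v_integral=tke_int,
        tke_ke_peak_e=tke_ke_ratio(tke_v[e_frame], mke_v[e_frame]),
        tke_ke_peak_a=tke_ke_ratio(tke_v[a_frame], mke_v[a_frame]),
        tke_ke_integral=tke_ke_ratio(tke_int, mke_int),
    )
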