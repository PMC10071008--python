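"""Lagrangian pathline emission, tracing, flow-component classification, QC.

Pathlines are emitted from the center of every LV voxel at end-diastole and
traced backward to the previous end-systole and forward to the next one
through the time-resolved velocity field (4th-order Runge-Kutta; trilinear
interpolation in space, linear in time, cyclic in the cardiac phase).
Positions are stored at every reconstructed frame time across the traced
interval. Each seed is then classified by its LV membership at the two
end-systoles:

================  =================  ==============================
at ES (backward)  at ES (forward)    component
================  =================  ==============================
outside           outside            direct flow (DF)
outside           inside             retained inflow (RI)
inside            outside            delayed ejection flow (DE)
inside            inside             residual volume (RV)
================  =================  ==============================

Pathlines that leave the computational grid (frozen at the exit point) or
whose LV-membership sequence alternates through more than one exit/entry —
inconsistent with a single valve transit, the signature of trajectories
drifting through the wall — are labelled non-physiological (NP). Data-quality
gates: a dataset is flagged when NP exceeds a threshold (default 15%) or when
the LV inflow (DF + RI) and outflow (DF + DE) volumes disagree by more than a
threshold (default 15%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import FlowDataset, LVMaskSeries, require_same_grid
from .errors import AlignmentError, DataError, DegenerateInputError
from .interp import inside_box, nearest_voxel, trilinear
from .phantom import DE, DF, LABEL_NAMES, NP, RI, RV  # shared label codes


@dataclass
class PathlineSet:
    """Trajectories of all ED seeds sampled at reconstructed frame times.

    positions : (N, S, 3) mm with S = n_frames + 1 samples running from the
    previous end-systole (sample 0) through ED to the next end-systole
    (sample S-1). ``sample_frames[s]`` is the cyclic frame index of sample s
    and ``sample_times[s]`` its unwrapped time in seconds.
    """

    positions: np.ndarray
    sample_frames: np.ndarray
    sample_times: np.ndarray
    seeds: np.ndarray            # (N, 3) mm
    voxel_volume_ml: float
    ed_frame: int
    es_frame: int
    ed_sample: int               # index of the ED sample within the trajectory
    exited: np.ndarray = field(default=None)  # (N,) True if frozen at grid exit
    frozen: np.ndarray = field(default=None)  # (N, S) True once a seed is frozen

    @property
    def n_seeds(self) -> int:
        return self.positions.shape[0]


@dataclass
class QCReport:
    np_percent: float
    inflow_volume_ml: float
    outflow_volume_ml: float
    io_discrepancy_percent: float
    excluded: bool
    reasons: list[str]


def seed_points(masks: LVMaskSeries) -> tuple[np.ndarray, float]:
    """Seed positions (mm) at the ED-mask voxel centers, plus voxel volume (ml)."""
    ed, _ = masks.get_ed_es()
    idx = np.argwhere(masks.masks[ed])
    if idx.size == 0:
        raise DataError("ED mask is empty")
    seeds = masks.origin + (idx + 0.5) * masks.spacing
    return seeds, masks.voxel_volume_ml


class _FieldSampler:
    """Velocity sampling in mm/s with cyclic linear time interpolation."""

    def __init__(self, flow: FlowDataset):
        self.vel = flow.velocity
        self.times = flow.frame_times
        self.rr = flow.rr_interval
        self.spacing = flow.spacing
        self.origin = flow.origin
        self.shape = flow.grid_shape
        self.n = flow.n_frames
        if not np.isfinite(self.vel).all():
            raise DataError("velocity field contains non-finite values")

    def frame_pair(self, t: float) -> tuple[int, int, float]:
        tau = t % self.rr
        f = int(np.searchsorted(self.times, tau, side="right")) - 1
        if f < 0:
            t0 = self.times[-1] - self.rr
            t1 = self.times[0]
            f0, f1 = self.n - 1, 0
        else:
            f0 = f
            f1 = (f + 1) % self.n
            t0 = self.times[f0]
            t1 = self.times[f + 1] if f + 1 < self.n else self.times[0] + self.rr
        w = 0.0 if t1 == t0 else (tau - t0) / (t1 - t0)
        return f0, f1, w

    def __call__(self, pos_mm: np.ndarray, t: float) -> np.ndarray:
        f0, f1, w = self.frame_pair(t)
        v0 = trilinear(self.vel[f0], pos_mm, self.spacing, self.origin)
        if w == 0.0:
            v = v0
        else:
            v1 = trilinear(self.vel[f1], pos_mm, self.spacing, self.origin)
            v = (1.0 - w) * v0 + w * v1
        return v * 1000.0  # m/s -> mm/s


def _rk4_span(
    sampler: _FieldSampler,
    pos: np.ndarray,
    active: np.ndarray,
    t_start: float,
    t_end: float,
    substeps: int,
) -> None:
    """Advance ``pos`` in place from t_start to t_end (either direction) with
    ``substeps`` RK4 steps; deactivates (freezes) seeds that exit the grid."""
    h = (t_end - t_start) / substeps
    for k in range(substeps):
        if not active.any():
            return
        t = t_start + k * h
        p = pos[active]
        k1 = sampler(p, t)
        k2 = sampler(p + 0.5 * h * k1, t + 0.5 * h)
        k3 = sampler(p + 0.5 * h * k2, t + 0.5 * h)
        k4 = sampler(p + h * k3, t + h)
        new = p + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        inside = inside_box(new, sampler.shape, sampler.spacing, sampler.origin)
        idx = np.flatnonzero(active)
        pos[idx[inside]] = new[inside]
        # frozen at the last in-grid position; flagged by the caller via active
        active[idx[~inside]] = False


def trace(
    flow: FlowDataset,
    seeds: np.ndarray,
    from_frame: int,
    to_frame: int,
    direction: str,
    substeps: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trace seeds between two frames; returns (positions, exited, frozen).

    positions : (N, K+1, 3) sampled at the frame times from ``from_frame`` to
    ``to_frame`` walking forward or backward cyclically; exited : (N,) flags
    seeds frozen at a grid exit at any point; frozen : (N, K+1) marks the
    samples at which a seed was already frozen.
    """
    if substeps < 1:
        raise DataError("substeps must be >= 1")
    if direction not in ("forward", "backward"):
        raise DataError(f"direction must be 'forward' or 'backward', got {direction!r}")
    sampler = _FieldSampler(flow)
    n = flow.n_frames
    step = 1 if direction == "forward" else -1
    span = (to_frame - from_frame) * step % n
    frames = [(from_frame + step * i) % n for i in range(span + 1)]
    # unwrapped times along the walk
    times = [flow.frame_times[from_frame]]
    for i in range(1, span + 1):
        prev_f, cur_f = frames[i - 1], frames[i]
        dt = (flow.frame_times[cur_f] - flow.frame_times[prev_f]) * step % flow.rr_interval
        times.append(times[-1] + step * dt)
    pos = np.array(seeds, dtype=float, copy=True)
    active = np.ones(len(pos), dtype=bool)
    out = np.empty((len(pos), span + 1, 3))
    frozen = np.zeros((len(pos), span + 1), dtype=bool)
    out[:, 0] = pos
    for i in range(1, span + 1):
        _rk4_span(sampler, pos, active, times[i - 1], times[i], substeps)
        out[:, i] = pos
        frozen[:, i] = ~active
    return out, ~active, frozen


def trace_pathlines(
    flow: FlowDataset,
    masks: LVMaskSeries,
    substeps: int = 10,
) -> PathlineSet:
    """Emit seeds at ED and trace to both adjacent end-systoles.

    The trajectory has ``n_frames + 1`` samples covering one full cycle from
    ES (previous) to ES (next), with the ED sample shared by both passes.
    """
    require_same_grid(flow, masks, "flow vs masks")
    ed, es = masks.get_ed_es()
    if ed == es:
        raise DegenerateInputError("ED and ES coincide")
    seeds, vvox_ml = seed_points(masks)
    n = flow.n_frames
    back, exited_b, frozen_b = trace(flow, seeds, ed, es, "backward", substeps)
    fwd, exited_f, frozen_f = trace(flow, seeds, ed, es, "forward", substeps)
    n_back = back.shape[1] - 1  # frames ES..ED
    n_fwd = fwd.shape[1] - 1    # frames ED..ES(next)
    positions = np.concatenate([back[:, ::-1][:, :-1], fwd], axis=1)
    frozen = np.concatenate([frozen_b[:, ::-1][:, :-1], frozen_f], axis=1)
    sample_frames = np.array(
        [(es + i) % n for i in range(n_back)] + [(ed + i) % n for i in range(n_fwd)]
        + [es]
    )
    # unwrapped times along the cyclic frame sequence
    sample_times = [float(flow.frame_times[es])]
    for i in range(1, sample_frames.size):
        f_prev, f_cur = sample_frames[i - 1], sample_frames[i]
        dt = (flow.frame_times[f_cur] - flow.frame_times[f_prev]) % flow.rr_interval
        sample_times.append(sample_times[-1] + dt)
    return PathlineSet(
        positions=positions,
        sample_frames=sample_frames,
        sample_times=np.asarray(sample_times),
        seeds=seeds,
        voxel_volume_ml=vvox_ml,
        ed_frame=ed,
        es_frame=es,
        ed_sample=n_back,
        exited=exited_b | exited_f,
        frozen=frozen,
    )


def _membership(pset: PathlineSet, masks: LVMaskSeries) -> np.ndarray:
    """(N, S) boolean: nearest-voxel LV membership of every sample."""
    n_seeds, n_samp, _ = pset.positions.shape
    member = np.zeros((n_seeds, n_samp), dtype=bool)
    shape = np.asarray(masks.grid_shape)
    for s in range(n_samp):
        f = int(pset.sample_frames[s])
        if f >= masks.n_frames:
            raise AlignmentError("trajectory frames exceed mask frames")
        idx = nearest_voxel(pset.positions[:, s], masks.spacing, masks.origin)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        sel = np.flatnonzero(ok)
        member[sel, s] = masks.masks[f][tuple(idx[sel].T)]
    return member


def classify(
    pset: PathlineSet,
    masks: LVMaskSeries,
    check_np_transits: bool = True,
) -> np.ndarray:
    """Flow-component labels (codes into :data:`LABEL_NAMES`) per seed.

    Membership is tested at the two end-systolic endpoints by nearest-voxel
    lookup. NP overrides the four-way split for grid-exit-frozen trajectories
    and (optionally) for membership sequences with more than a single
    entry/exit transit.
    """
    member = _membership(pset, masks)
    in_prev = member[:, 0]
    in_next = member[:, -1]
    labels = np.full(pset.n_seeds, RV, dtype=np.int64)
    labels[~in_prev & ~in_next] = DF
    labels[~in_prev & in_next] = RI
    labels[in_prev & ~in_next] = DE
    if pset.exited is not None:
        labels[pset.exited] = NP
    if check_np_transits:
        m = member.astype(np.int8)
        entries = np.sum((np.diff(m, axis=1) > 0), axis=1)
        exits = np.sum((np.diff(m, axis=1) < 0), axis=1)
        labels[(entries > 1) | (exits > 1)] = NP
    return labels


def component_volumes(labels: np.ndarray, voxel_volume_ml: float) -> pd.DataFrame:
    """Per-component volume (ml) and fraction of EDV (%), NP included."""
    labels = np.asarray(labels)
    total = labels.size
    rows = []
    for code, name in enumerate(LABEL_NAMES):
        cnt = int(np.count_nonzero(labels == code))
        rows.append(
            {
                "component": name,
                "count": cnt,
                "volume_ml": cnt * voxel_volume_ml,
                "fraction_pct": 100.0 * cnt / total,
            }
        )
    return pd.DataFrame(rows).set_index("component")


def qc(
    labels: np.ndarray,
    voxel_volume_ml: float,
    np_threshold: float = 15.0,
    io_threshold: float = 15.0,
) -> QCReport:
    """Exclusion gates on the NP fraction and the inflow/outflow discrepancy.

    inflow = DF + RI volume, outflow = DF + DE volume; the discrepancy is
    their absolute difference over their mean, in percent. Gates are strict
    inequalities: exactly 15% does not exclude.
    """
    labels = np.asarray(labels)
    total = labels.size
    np_pct = 100.0 * np.count_nonzero(labels == NP) / total
    vol = lambda code: np.count_nonzero(labels == code) * voxel_volume_ml
    inflow = vol(DF) + vol(RI)
    outflow = vol(DF) + vol(DE)
    if inflow + outflow == 0:
        raise DegenerateInputError("no inflow or outflow volume: discrepancy undefined")
    disc = 100.0 * abs(inflow - outflow) / ((inflow + outflow) / 2.0)
    reasons = []
    if np_pct > np_threshold:
        reasons.append("non-physiological flow")
    if disc > io_threshold:
        reasons.append("inflow/outflow discrepancy")
    return QCReport(
        np_percent=np_pct,
        inflow_volume_ml=inflow,
        outflow_volume_ml=outflow,
        io_discrepancy_percent=disc,
        excluded=bool(reasons),
        reasons=reasons,
    )


# --------------------------------------------------------------------------
# optional exports
# --------------------------------------------------------------------------

def save_pathlines_h5(pset: PathlineSet, labels: np.ndarray, path) -> None:
    """HDF5 layout: /positions (N, S, 3 mm), /labels, /frame_times, attrs."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions", data=pset.positions, compression="gzip")
        h5.create_dataset("labels", data=np.asarray(labels, np.int64))
        h5.create_dataset("frame_times", data=pset.sample_times)
        h5.create_dataset("sample_frames", data=pset.sample_frames)
        h5.attrs["label_names"] = ",".join(LABEL_NAMES)
        h5.attrs["voxel_volume_ml"] = pset.voxel_volume_ml
        h5.attrs["ed_frame"] = pset.ed_frame
        h5.attrs["es_frame"] = pset.es_frame


def save_pathlines_vtk(pset: PathlineSet, labels: np.ndarray, path) -> None:
    """Legacy ASCII VTK polydata of the trajectories, component code as scalar."""
    n, s, _ = pset.positions.shape
    pts = pset.positions.reshape(-1, 3)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nventriflow pathlines\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        fh.write(f"LINES {n} {n * (s + 1)}\n")
        for i in range(n):
            ids = " ".join(str(i * s + j) for j in range(s))
            fh.write(f"{s} {ids}\n")
        fh.write(f"CELL_DATA {n}\nSCALARS component int 1\nLOOKUP_TABLE default\n")
        for lab in np.asarray(labels, int):
            fh.write(f"{lab}\n")
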