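"""Synthetic 4D flow phantoms with analytic ground truth.

Three phantom families stand in for in-vivo acquisitions:

``plug_flow``
    A fixed rectangular "chamber" inside a larger grid, with a spatially
    uniform axial velocity ``u(t) * z_hat``. The cycle starts at end-systole
    (frame 0): diastolic filling is the sum of two raised-cosine pulses (the
    E- and A-waves), followed by a systolic ejection pulse. Because transport
    is a pure axial shift, the flow-component label of every seed follows in
    closed form from the cumulative displacement, which makes this phantom the
    oracle for pathline classification.

``affine_deform`` / ``rigid_rotation``
    Velocity ``v(x, t) = dA/dt A(t)^-1 (x - c)`` for a smooth invertible
    matrix schedule ``A(t)`` (isotropic "breathing" diagonal, or a rotation
    about z). The exact pathline is ``x(t) = c + A(t) A(t0)^-1 (x0 - c)``; the
    mask is the image of a reference ellipsoid under ``A(t)``. These are the
    oracles for pathline tracing accuracy and for the MKE sums.

The phantom's continuous-time velocity waveform is *defined* as the
piecewise-linear interpolation of its frame samples — the same continuous-time
model any tracer of frame-sampled data assumes — so analytic displacements are
exact integrals of that waveform.

Turbulence is prescribed as a sigma plateau (per-direction fluctuation
intensity) on an axial sub-band of the plug chamber, and is forward-encoded
into four-point magnitude volumes with optional Rician noise, matching the
inversion implemented in :mod:`.turbulence`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .datamodel import FlowDataset, LVMaskSeries
from .errors import PhantomSpecError
from .turbulence import compute_kv

LABEL_NAMES = ("DF", "RI", "DE", "RV", "NP")
DF, RI, DE, RV, NP = range(5)


@dataclass
class PhantomSpec:
    """Parameters of a synthetic dataset; defaults give a rest-like cycle."""

    kind: str = "plug_flow"  # plug_flow | affine_deform | rigid_rotation
    grid: tuple[int, int, int] = (48, 48, 64)
    spacing: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_frames: int = 40
    rr_interval: float = 1.0  # s
    venc: float = 1.4         # m/s
    s0: float = 100.0         # baseline magnitude signal
    noise_sd: float = 0.0     # Rician noise level, signal units
    seed: int = 0
    rho: float = 1060.0       # kg/m^3, used only for tabulated truth series

    # cycle structure (frame 0 = end-systole; diastole first, then systole)
    systolic_fraction: float = 0.375
    e_peak_frame: int = 9
    a_peak_frame: int = 21
    e_width_frames: float = 10.0
    a_width_frames: float = 6.0
    systolic_width_frames: float = 12.0
    jet_speed: float = 0.22        # E-wave plug speed amplitude, m/s
    a_ratio: float = 0.5           # A-wave amplitude as a fraction of jet_speed
    systolic_amplitude: float = 0.24  # ejection plug speed, m/s

    # plug chamber geometry (voxel indices on the grid)
    chamber_margin_xy: int = 8  # inset of the chamber cross-section in x and y
    chamber_z0: int = 22        # first axial chamber voxel
    chamber_len: int = 20       # axial chamber extent, voxels

    # prescribed turbulence: per-direction sigma plateau on an axial band
    sigma_amplitude: float = 0.3          # m/s, each of sigma_1..3
    sigma_band: tuple[float, float] = (0.0, 0.5)  # axial fractions of the chamber

    # affine / rotation schedules
    deform_amplitude: float = 0.2   # isotropic contraction depth of a(t)
    rotation_cycles: float = 1.0    # revolutions per cardiac cycle
    ellipsoid_radii_mm: tuple[float, float, float] = (35.0, 35.0, 45.0)

    def __post_init__(self) -> None:
        if self.kind not in ("plug_flow", "affine_deform", "rigid_rotation"):
            raise PhantomSpecError(f"unknown phantom kind {self.kind!r}")
        if self.n_frames < 8:
            raise PhantomSpecError("n_frames must be >= 8")
        if not 0 < self.systolic_fraction < 1:
            raise PhantomSpecError("systolic_fraction must be in (0, 1)")
        if self.kind == "plug_flow":
            ed = self.ed_frame
            if not (0 < self.e_peak_frame < self.a_peak_frame < ed):
                raise PhantomSpecError(
                    "need 0 < e_peak_frame < a_peak_frame < ed_frame "
                    f"(= {ed}) for a biphasic diastole"
                )
        if self.noise_sd > 0:
            bound = (self.venc / np.pi) * np.sqrt(
                2.0 * np.log(self.s0 / self.noise_sd)
            )
            if self.sigma_amplitude >= bound:
                raise PhantomSpecError(
                    f"sigma_amplitude {self.sigma_amplitude} not invertible above "
                    f"the noise floor (bound {bound:.3f} m/s)"
                )

    @property
    def ed_frame(self) -> int:
        """End-diastolic frame: end of the filling phase (cycle starts at ES)."""
        return int(round(self.n_frames * (1.0 - self.systolic_fraction)))

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.rr_interval / self.n_frames


@dataclass
class PhantomTruth:
    """Closed-form ground truth accompanying a generated dataset."""

    seeds: np.ndarray          # (N, 3) mm, voxel centers of the ED mask
    labels: np.ndarray         # (N,) int codes into LABEL_NAMES
    pathline: Callable[[np.ndarray, float, float], np.ndarray]
    # pathline(x0, t0, t): exact positions (mm) at time t of points at x0 at t0
    mke_v: np.ndarray          # (T,) J/m^3, exact summation over the mask
    tke_v: np.ndarray          # (T,) J/m^3, exact summation over the mask
    volumes_ml: np.ndarray     # (T,)
    ed_frame: int
    es_frame: int
    e_frame: int | None = None
    a_frame: int | None = None
    component_fractions: dict[str, float] = field(default_factory=dict)  # % of EDV
    displacement_diastole_mm: float = 0.0
    displacement_systole_mm: float = 0.0
    boundary_distance_mm: np.ndarray | None = None  # per-seed margin to a band edge


# --------------------------------------------------------------------------
# magnitude encoding (forward model of the turbulence inversion)
# --------------------------------------------------------------------------

def encode_magnitudes(
    sigma_fields: np.ndarray,
    venc: float,
    s0: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> dict[str, np.ndarray]:
    """Four-point magnitude volumes from prescribed sigma fields.

    ``|S| = s0`` and ``|S_i| = s0 * exp(-kv^2 sigma_i^2 / 2)`` with
    ``kv = pi / venc``; optional Rician noise
    ``m -> sqrt((m + n1)^2 + n2^2)``, ``n1, n2 ~ N(0, noise_sd)``, is applied
    to all four volumes with the given seed.
    """
    sigma_fields = np.asarray(sigma_fields, float)
    if sigma_fields.shape[-1] != 3:
        raise PhantomSpecError("sigma_fields must have a trailing axis of 3")
    if np.any(sigma_fields < 0):
        raise PhantomSpecError("sigma must be nonnegative")
    if s0 <= 0:
        raise PhantomSpecError("s0 must be positive")
    kv = compute_kv(venc)
    mags = {"s0": np.full(sigma_fields.shape[:-1], float(s0))}
    for i in range(3):
        mags[f"s{i + 1}"] = s0 * np.exp(-0.5 * (kv * sigma_fields[..., i]) ** 2)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        for key in ("s0", "s1", "s2", "s3"):
            m = mags[key]
            n1 = rng.normal(0.0, noise_sd, m.shape)
            n2 = rng.normal(0.0, noise_sd, m.shape)
            mags[key] = np.sqrt((m + n1) ** 2 + n2**2)
    return mags


# --------------------------------------------------------------------------
# plug flow
# --------------------------------------------------------------------------

def _raised_cosine(f: np.ndarray, center: float, width: float) -> np.ndarray:
    """Raised-cosine pulse in frame units: support [center - w/2, center + w/2]."""
    x = (np.asarray(f, float) - center) / width
    out = np.where(np.abs(x) <= 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * x)), 0.0)
    return out


def plug_speed_samples(spec: PhantomSpec) -> np.ndarray:
    """Axial plug speed u (m/s) at the frame times."""
    f = np.arange(spec.n_frames, dtype=float)
    u = spec.jet_speed * _raised_cosine(f, spec.e_peak_frame, spec.e_width_frames)
    u += spec.jet_speed * spec.a_ratio * _raised_cosine(
        f, spec.a_peak_frame, spec.a_width_frames
    )
    s_center = 0.5 * (spec.ed_frame + spec.n_frames)
    u += spec.systolic_amplitude * _raised_cosine(
        f, s_center, spec.systolic_width_frames
    )
    return u


def _piecewise_linear_integral(u: np.ndarray, dt: float, t: np.ndarray) -> np.ndarray:
    """Exact integral from 0 to t of the piecewise-linear waveform through
    samples ``u`` at times ``k * dt``, extended cyclically (u[n] = u[0])."""
    u_ext = np.append(u, u[0])
    s_knots = np.concatenate([[0.0], np.cumsum(0.5 * (u_ext[:-1] + u_ext[1:]) * dt)])
    t = np.asarray(t, float)
    i = np.clip((t // dt).astype(int), 0, len(u) - 1)
    theta = t / dt - i
    du = u_ext[i + 1] - u_ext[i]
    return s_knots[i] + dt * (u_ext[i] * theta + 0.5 * du * theta**2)


def generate_plug_flow(spec: PhantomSpec):
    """Plug-flow phantom: returns (FlowDataset, LVMaskSeries, PhantomTruth)."""
    if spec.kind != "plug_flow":
        raise PhantomSpecError(f"generate_plug_flow requires kind='plug_flow'")
    nx, ny, nz = spec.grid
    sp = np.asarray(spec.spacing, float)
    n = spec.n_frames
    dt = spec.rr_interval / n
    times = spec.frame_times
    u = plug_speed_samples(spec)  # m/s

    # chamber voxel box
    m = spec.chamber_margin_xy
    c0, clen = spec.chamber_z0, spec.chamber_len
    if not (0 < m < nx // 2 and 0 < m < ny // 2):
        raise PhantomSpecError("chamber_margin_xy inconsistent with grid")
    if not (0 < c0 and c0 + clen < nz):
        raise PhantomSpecError("chamber axial extent exceeds grid")
    mask3 = np.zeros((nx, ny, nz), dtype=bool)
    mask3[m:nx - m, m:ny - m, c0:c0 + clen] = True
    masks = np.broadcast_to(mask3, (n, nx, ny, nz)).copy()

    # velocity: uniform axial plug on the whole grid (traceable past the wall)
    vel = np.zeros((n, nx, ny, nz, 3))
    vel[..., 2] = u[:, None, None, None]

    # displacement bookkeeping (mm); the continuous waveform is the
    # piecewise-linear interpolation of the frame samples
    s_frames = _piecewise_linear_integral(u, dt, times) * 1000.0
    # exact full-cycle integral (u[n] = u[0] by periodicity)
    u_ext = np.append(u, u[0])
    s_end = float(np.sum(0.5 * (u_ext[:-1] + u_ext[1:]) * dt)) * 1000.0
    ed = spec.ed_frame
    d_b = float(s_frames[ed] - s_frames[0])        # diastolic filling displacement
    d_f = float(s_end - s_frames[ed])              # systolic ejection displacement

    z_in = c0 * sp[2]                # physical inlet face, mm
    z_out = (c0 + clen) * sp[2]      # physical outlet face, mm
    # every traced position must stay on the grid
    if z_in - d_b < 0 or z_out + d_f > nz * sp[2]:
        raise PhantomSpecError(
            "cycle displacement exceeds the grid margin around the chamber"
        )

    # seeds and closed-form labels
    seeds_idx = np.argwhere(mask3)
    seeds = (seeds_idx + 0.5) * sp
    z0 = seeds[:, 2]
    entered = z0 - d_b < z_in     # outside the chamber at backward end-systole
    leaves = z0 + d_f > z_out     # outside the chamber at forward end-systole
    labels = np.full(len(seeds), RV, dtype=np.int64)
    labels[entered & leaves] = DF
    labels[entered & ~leaves] = RI
    labels[~entered & leaves] = DE

    L = z_out - z_in
    frac = {
        "DF": max(0.0, min(d_b, L) + min(d_f, L) - L) / L,
        "RI": (min(d_b, L) - max(0.0, min(d_b, L) + min(d_f, L) - L)) / L,
        "DE": (min(d_f, L) - max(0.0, min(d_b, L) + min(d_f, L) - L)) / L,
    }
    frac["RV"] = 1.0 - frac["DF"] - frac["RI"] - frac["DE"]
    fractions = {k: 100.0 * v for k, v in frac.items()}
    fractions["NP"] = 0.0

    enter_edge = z_in + d_b   # seeds below this z entered during diastole
    leave_edge = z_out - d_f  # seeds above this z leave during systole
    boundary = np.minimum(np.abs(z0 - enter_edge), np.abs(z0 - leave_edge))

    # prescribed turbulence: per-direction plateau on an axial chamber band
    sigma = np.zeros((n, nx, ny, nz, 3))
    b0 = c0 + int(np.floor(spec.sigma_band[0] * clen))
    b1 = c0 + int(np.ceil(spec.sigma_band[1] * clen))
    if spec.sigma_amplitude > 0 and b1 > b0:
        band = np.zeros((nx, ny, nz), dtype=bool)
        band[m:nx - m, m:ny - m, b0:b1] = True
        sigma[:, band, :] = spec.sigma_amplitude
    mags = encode_magnitudes(sigma, spec.venc, spec.s0, spec.noise_sd, spec.seed)

    ds = FlowDataset(
        velocity=vel, spacing=sp, frame_times=times, venc=spec.venc,
        rr_interval=spec.rr_interval, magnitudes=mags,
    )
    mask_series = LVMaskSeries(
        masks=masks, spacing=sp, frame_times=times, rr_interval=spec.rr_interval,
        ed_frame=ed, es_frame=0,
    )

    vvox_m3 = float(np.prod(sp)) * 1e-9
    n_mask = int(mask3.sum())
    mke_v = 0.5 * spec.rho * u**2  # uniform speed: density is the mean
    tke_density = 0.5 * spec.rho * np.sum(sigma**2, axis=-1)
    tke_v = np.array(
        [float(tke_density[f][mask3].sum()) * vvox_m3 for f in range(n)]
    ) / (n_mask * vvox_m3)
    volumes_ml = np.full(n, n_mask * float(np.prod(sp)) / 1000.0)

    def pathline(x0: np.ndarray, t0: float, t: float) -> np.ndarray:
        disp = (
            _piecewise_linear_integral(u, dt, np.array([float(t)]))
            - _piecewise_linear_integral(u, dt, np.array([float(t0)]))
        )[0] * 1000.0
        out = np.array(x0, float, copy=True)
        out[..., 2] += disp
        return out

    truth = PhantomTruth(
        seeds=seeds, labels=labels, pathline=pathline, mke_v=mke_v, tke_v=tke_v,
        volumes_ml=volumes_ml, ed_frame=ed, es_frame=0,
        e_frame=spec.e_peak_frame, a_frame=spec.a_peak_frame,
        component_fractions=fractions,
        displacement_diastole_mm=d_b, displacement_systole_mm=d_f,
        boundary_distance_mm=boundary,
    )
    return ds, mask_series, truth


# --------------------------------------------------------------------------
# affine / rotation
# --------------------------------------------------------------------------

def _affine_schedule(spec: PhantomSpec):
    """Return (A(t), dA/dt(t)) callables for the configured kind."""
    rr = spec.rr_interval
    if spec.kind == "affine_deform":
        amp = spec.deform_amplitude
        if not 0 < amp < 1:
            raise PhantomSpecError("deform_amplitude must be in (0, 1)")

        def A(t):
            a = 1.0 - 0.5 * amp * (1.0 - np.cos(2.0 * np.pi * t / rr))
            return np.diag([a, a, a])

        def Adot(t):
            da = -amp * np.pi / rr * np.sin(2.0 * np.pi * t / rr)
            return np.diag([da, da, da])

        return A, Adot
    if spec.kind == "rigid_rotation":
        omega = 2.0 * np.pi * spec.rotation_cycles / rr

        def A(t):
            th = omega * t
            c, s = np.cos(th), np.sin(th)
            return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

        def Adot(t):
            th = omega * t
            c, s = np.cos(th), np.sin(th)
            return omega * np.array([[-s, -c, 0.0], [c, -s, 0.0], [0.0, 0.0, 0.0]])

        return A, Adot
    raise PhantomSpecError(f"not an affine kind: {spec.kind!r}")


def generate_affine_flow(spec: PhantomSpec):
    """Affine-deformation or rigid-rotation phantom with exact pathlines."""
    if spec.kind not in ("affine_deform", "rigid_rotation"):
        raise PhantomSpecError("generate_affine_flow requires an affine kind")
    nx, ny, nz = spec.grid
    sp = np.asarray(spec.spacing, float)
    n = spec.n_frames
    times = spec.frame_times
    center = 0.5 * np.asarray(spec.grid) * sp
    radii = np.asarray(spec.ellipsoid_radii_mm, float)
    A, Adot = _affine_schedule(spec)

    centers = np.stack(
        np.meshgrid(*[np.arange(k) for k in spec.grid], indexing="ij"), axis=-1
    )
    pos = (centers + 0.5) * sp
    rel = (pos - center).reshape(-1, 3)

    vel = np.empty((n, nx, ny, nz, 3))
    masks = np.empty((n, nx, ny, nz), dtype=bool)
    dets = np.empty(n)
    for f, t in enumerate(times):
        At = A(t)
        Ainv = np.linalg.inv(At)
        if not np.isfinite(Ainv).all():
            raise PhantomSpecError(f"A(t) singular at frame {f}")
        dets[f] = np.linalg.det(At)
        grad = Adot(t) @ Ainv  # velocity gradient, 1/s
        vel[f] = (rel @ grad.T).reshape(nx, ny, nz, 3) / 1000.0  # mm -> m/s
        ref = rel @ Ainv.T
        masks[f] = (np.sum((ref / radii) ** 2, axis=1) <= 1.0).reshape(nx, ny, nz)

    explicit = None
    if np.ptp(dets) < 1e-12:  # volume-preserving schedule: fix ED/ES by hand
        explicit = (0, n // 2)
    mask_series = LVMaskSeries(
        masks=masks, spacing=sp, frame_times=times, rr_interval=spec.rr_interval,
        ed_frame=None if explicit is None else explicit[0],
        es_frame=None if explicit is None else explicit[1],
    )

    vvox_ml = float(np.prod(sp)) / 1000.0
    counts = masks.reshape(n, -1).sum(axis=1)
    volumes_ml = counts * vvox_ml
    speeds2 = np.sum(vel**2, axis=-1)
    mke_v = np.array(
        [float(speeds2[f][masks[f]].sum()) / counts[f] for f in range(n)]
    ) * 0.5 * spec.rho
    tke_v = np.zeros(n)

    ds = FlowDataset(
        velocity=vel, spacing=sp, frame_times=times, venc=spec.venc,
        rr_interval=spec.rr_interval, magnitudes=None,
    )

    ed, es = mask_series.get_ed_es()
    seeds = ds.voxel_centers(masks[ed])

    def pathline(x0: np.ndarray, t0: float, t: float) -> np.ndarray:
        M = A(t) @ np.linalg.inv(A(t0))
        return center + (np.asarray(x0, float) - center) @ M.T

    truth = PhantomTruth(
        seeds=seeds, labels=np.full(len(seeds), RV, dtype=np.int64),
        pathline=pathline, mke_v=mke_v, tke_v=tke_v, volumes_ml=volumes_ml,
        ed_frame=ed, es_frame=es,
    )
    return ds, mask_series, truth


def generate(spec: PhantomSpec):
    """Dispatch on ``spec.kind``."""
    if spec.kind == "plug_flow":
        return generate_plug_flow(spec)
    return generate_affine_flow(spec)
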