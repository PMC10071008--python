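# Methods

This note documents the models, numerical choices, and validation strategy
behind ventriflow, in the spirit of the methods documentation of packages
like msprime or statsmodels: what is computed, under which assumptions, and
what the synthetic validation does and does not demonstrate.

## Turbulence estimation from multi-point magnitudes

With asymmetric four-point flow encoding, the reference magnitude |S| and the
three motion-sensitized magnitudes |Sᵢ| are related — under the assumption of
a Gaussian intravoxel velocity distribution — by
|Sᵢ| = |S| · exp(−½ k_v² σᵢ²), with motion sensitivity k_v = π/VENC (s/m).
The inversion

    σᵢ = (1/k_v) √(2 ln(|S|/|Sᵢ|))

is exact for the noiseless forward model, and the package's phantom encoder
implements precisely that forward model so the pair is self-consistent.
Numerical notes:

* **Noise-floor clamp.** Noise can push |Sᵢ| ≥ |S|; the estimate is clamped
  to σᵢ = 0 there (rather than NaN) to preserve nonnegativity. Voxels with
  |S| = 0 (no signal) are likewise zero. The fraction of clamped voxels is
  reported in `TurbulenceMaps.clamp_fraction`.
* **Precision floor.** The derivative dσ/d(ln ratio) diverges as σ → 0⁺, so
  double precision recovers σ exactly (≲10⁻¹³ m/s absolute) only down to
  about 10⁻⁴ m/s; smaller nonzero intensities are physically meaningless at
  MR signal SNRs anyway.
* **TKE density** is ½ ρ Σσᵢ² (J/m³) with blood density ρ = 1060 kg/m³ by
  default (configurable). The TKE field — not σ — is optionally denoised with
  a 3×3×3 *spatial* median filter per frame, edge-repeat padding at the
  volume boundary.

## Global energetics

MKE is summed voxelwise over the (resampled) LV mask, ½ ρ V_voxel |v|², and
TKE density is integrated the same way; both are divided by the current LV
volume (J/m³) so ventricles of different size are comparable. ED and ES are
the frames of largest and smallest mask volume; diastole is the ES→ED frame
window, wrapping past the end of the cycle (retrospective gating covers a
full R–R interval). Time integrals use the trapezoidal rule on the physical
frame times (exact for piecewise-linear series; the frame times of wrapped
windows are unwrapped by adding the RR interval).

**E/A detection.** The E- and A-wave time points are the two highest *local
maxima* of volume-normalized MKE within diastole (strict inequality against
neighbours; plateaus take their first frame; window endpoints qualify with a
one-sided comparison). At high heart rate the A-wave can merge into the
E-wave tail, leaving a single maximum; the fallback then takes E at that
maximum and A at the frame of maximal MKE_V within the final 30% of diastole
strictly after E. The 30% fraction is configurable
(`AnalysisConfig.a_wave_fallback_fraction`). "Two highest samples" versus
"two highest local maxima" is genuinely ambiguous for merged waves; local
maxima were chosen because two high samples on one peak's flanks are not two
filling waves.

## Pathlines and flow components

Pathlines are emitted from the center of every LV voxel at ED and traced
backward and forward to the adjacent end-systoles with classical RK4,
Δt = (frame interval)/substeps (default 10 substeps per frame). Velocity is
interpolated trilinearly in space and linearly in time, cyclically across
the cycle boundary; backward tracing integrates with a negative step.
Positions are recorded at each reconstructed frame time. A pathline whose
integration step would leave the computational grid is frozen at its last
in-grid position and flagged.

Classification tests LV membership (nearest-voxel lookup of the binary mask;
ties on voxel boundaries round half-down, i.e. to the lower index) at the two
end-systolic endpoints: out/out → direct flow, out/in → retained inflow,
in/out → delayed ejection, in/in → residual volume. The four combinations
are exhaustive, so non-physiological flow (NP) is operationalized as
(a) grid-exit-frozen trajectories and (b) trajectories whose LV-membership
sequence shows more than one exit→entry alternation over the traced interval
— the signature of pathlines drifting through the myocardial wall, the
practical source of NP in noisy in-vivo data. Check (b) can be disabled
(`check_np_transits=False`). Residual volume's "resident for at least two
cycles" is inferred from in/in membership over the single traced cycle, not
from multi-cycle tracing.

QC gates flag (never silently drop) a dataset when NP exceeds 15% of seeds
or when inflow (DF+RI) and outflow (DF+DE) volumes disagree by more than 15%
(|in−out| over their mean); both thresholds are strict inequalities and
configurable.

Nearest-voxel membership (rather than interpolating the mask) keeps the
binary boundary crisp; the cost is a half-voxel uncertainty band around
component boundaries, which is exactly the band excluded in the phantom
validation below.

## Energy mapping onto pathlines

Each pathline point receives an energy sampled from a density field over the
8 voxel centers spanning the grid cell containing it:

    E = Σⱼ wⱼ Vⱼ ρⱼ / Σⱼ wⱼ,   wⱼ = exp(−(pⱼ − d)²/(d/2)²)

with d the voxel diagonal and pⱼ the center distance. The weight peaks at
pⱼ = d — an unusual shape for an interpolant (voxel centers at distance d
get more weight than the nearest corner) — but it is implemented verbatim as
specified, and a standard trilinear mode is available behind
`AnalysisConfig.gaussian_weight_sampling=False` for sensitivity analysis.
Key properties: for a uniform density c the energy is exactly c·V_voxel
anywhere; points exactly on a cell face use the lower cell; frozen NP
trajectories contribute no energy after their exit sample.

The same sampling is applied to two channels: the measured TKE density and
the MKE density ½ ρ |v|², keeping per-component TKE and MKE methodologically
symmetric. Per-component values divide the summed point energies of a
component's seeds by the component volume (J/m³); instantaneous values are
reported at the E and A frames, and diastolic time integrals are trapezoidal
over the ES→ED samples of the trajectory. Both the diastolic and whole-cycle
integrals are computable; the diastolic window is the default reported
output. Component sums reproduce whole-LV totals exactly when the density is
spatially uniform, and to within a few percent otherwise (the residual is
interpolation/partition error, not a bug; exact equality is not claimed).

## Statistics

Paired rest-vs-stress comparison per variable: Shapiro–Wilk on the paired
differences (the quantity the t-test assumes normal; a per-condition gate is
available via `normality_gate="conditions"`); paired t when normal, Wilcoxon
signed-rank otherwise (exact null distribution up to n = 25, normal
approximation with continuity correction above; zero differences dropped,
ties mid-ranked); two-sided p-values; significance at α = 0.05 without
multiple-testing correction. Summaries are "mean ± SD" (one decimal) when
normal, "median [Q1; Q3]" otherwise with quartiles linearly interpolated
between order statistics.

## Synthetic phantoms and ground truth

No suitable public in-vivo dataset accompanies this analysis, so validation
uses three phantom families whose truth is closed-form:

* **Plug flow** — a fixed rectangular chamber in a larger grid with a
  spatially uniform axial velocity u(t): biphasic raised-cosine diastolic
  filling (E and A pulses at prescribed frames) followed by a systolic
  ejection pulse; the cycle starts at ES. Transport is a pure axial shift
  s(t) = ∫u dt, so every seed's flow-component label follows from two
  numbers (the diastolic and systolic displacements) and band arithmetic;
  the generator reports per-seed labels, analytic band fractions, and each
  seed's distance to the nearest band edge. A σ plateau (default 0.3 m/s per
  direction over the inlet half of the chamber, constant in time) is
  forward-encoded into four-point magnitudes, with optional seeded Rician
  noise √((m+n₁)² + n₂²). Default geometry: 48×48×64 voxels at 2.5 mm, 40
  frames, 20,480 seeds; displacements ≈ 36 mm against a 50 mm chamber give
  DF/RI/DE ≈ 40/30/30% (a pure plug cannot populate all four components at
  once: residual volume is nonempty only when the transit bands do not
  overlap, i.e. when DF is empty).
* **Affine deformation** — v(x,t) = Ȧ A⁻¹(x−c) for an isotropic "breathing"
  diagonal schedule; the mask is the image of a reference ellipsoid under
  A(t), so the volume curve tracks det A(t) (within voxelization error,
  ≈1% at 3 mm), and MKE_V truth is tabulated by exact summation over the
  generated mask.
* **Rigid rotation** — the same construction with A(t) a rotation about z;
  pathlines are circular orbits known in closed form, providing the
  integrator oracle. Volume is constant, so ED/ES are set explicitly.

**Continuous-time convention.** The phantoms *define* their continuous-time
velocity as the piecewise-linear interpolation of the frame samples — the
same model any tracer of frame-sampled data must assume — and analytic
displacements are exact integrals of that waveform. RK4 with substeps nested
inside frame intervals integrates a piecewise-linear-in-time, linear-in-space
field exactly (to rounding), which is why plug-flow classification recovers
the analytic labels for *every* seed outside the half-voxel membership band,
and why the rotation phantom (time-constant field) exhibits the clean
4th-order convergence of the integrator itself.

**What the phantoms do not show.** They contain no vortex rings, no valve
geometry, no wall motion coupled to the flow (the plug chamber is static; the
velocity field is defined on the whole grid so boundary-crossing pathlines
remain traceable), no partial-volume effects, and their turbulence is a
prescribed plateau rather than shear-generated fluctuations. Passing these
tests demonstrates the correctness of the estimators, the integrator, the
classifier, and the bookkeeping — not the physiological accuracy of any
in-vivo result. In particular the plug phantom's TKE/KE (~0.9) is far above
in-vivo values because its plug velocity (and hence MKE) is deliberately
small: the whole cross-section moves, so transit speed is capped by the
chamber length per half-cycle, while σ is kept at jet-like intensity.

## Degenerate inputs and tie-breaks

* Constant mask volume curve: ED/ES are undefined from the data;
  `LVMaskSeries` accepts explicit `ed_frame`/`es_frame` (the plug phantom
  sets them), `compute_ventricular_metrics` raises, and the pipeline records
  a note instead of failing.
* Mask resampling: nearest-neighbour sampling of the per-frame signed
  Euclidean distance transform in space, linear interpolation of the sampled
  distances between the two bracketing source frames (cyclically), threshold
  at zero — topology-preserving and smooth in time.
* Velocity samples above VENC on load raise a warning (possible residual
  aliasing), never an error.
* `estimate_sigma`, `tke_ke_ratio`, QC discrepancy and the statistical tests
  each raise typed errors (`DomainError`, `DegenerateInputError`,
  `DataError`, `SizeError`) on undefined inputs rather than returning NaN.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the full pipeline at the
phantom's native scale (48×48×64 × 40 frames, ~20k pathlines, ~40 s on one
CPU) and the integrator checks on a 48³ rotation phantom (2000 seeds for the
error norm, 200 for the convergence sweep at 5/10/20 substeps). Statistical
level checks use 2000 seeded replicates at n = 11 pairs. Unit tests use
smaller variants of the same phantoms (~1000 seeds) chosen to keep the whole
suite under a minute without changing any default study condition.
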