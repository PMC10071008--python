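# ventriflow

Diastolic left-ventricular (LV) kinetic-energy analysis for 4D flow MRI.

4D flow MRI acquires time-resolved, three-directional velocity fields of the
beating heart. With a multi-point (asymmetric four-point) flow encoding, the
same acquisition also yields the *intravoxel standard deviation* of velocity,
so the total kinetic energy of LV blood can be split into

* **MKE** — mean kinetic energy of the phase-averaged velocity field,
  `MKE = Σ_i ½ ρ V_i |v_i|²` over the segmented LV, and
* **TKE** — turbulent kinetic energy of the sub-voxel velocity fluctuations,
  `TKE = ½ ρ (σ₁² + σ₂² + σ₃²)` per unit volume, with the fluctuation
  intensity estimated from magnitude attenuation,
  `σᵢ = (1/k_v) √(2 ln(|S|/|Sᵢ|))`, `k_v = π / VENC`.

The ratio `TKE/KE = TKE/(TKE+MKE)` is the fraction of kinetic energy carried
by turbulent fluctuations — an index of flow inefficiency. ventriflow
computes these quantities for the whole LV and mapped onto Lagrangian
pathlines partitioned into the four classical flow components (direct flow,
retained inflow, delayed ejection flow, residual volume), with E-/A-wave peak
values, diastolic time integrals, data-quality gates, and paired
rest-vs-stress statistics (Shapiro–Wilk-gated paired t / Wilcoxon
signed-rank).

It is intended for researchers in cardiovascular MR flow physiology who want
a tested, scriptable implementation of this analysis chain — plus synthetic
phantoms with analytic ground truth (plug flow, affine deformation, rigid
rotation) for validating every stage.

## Worked example

```python
import ventriflow as vf

spec = vf.PhantomSpec()          # 48 x 48 x 64 grid, 40 frames, ~20k seeds
ds, masks, truth = vf.generate_plug_flow(spec)
bundle = vf.run_analysis(ds, masks, vf.AnalysisConfig())

e = bundle.energetics
print(f"E-wave frame {e.e_frame}, A-wave frame {e.a_frame}")
print(f"peak-E MKE_V = {e.mke_v[e.e_frame]:.1f} J/m^3, "
      f"peak-E TKE_V = {e.tke_v[e.e_frame]:.1f} J/m^3")
print(f"diastolic TKE/KE = {e.tke_ke_integral:.3f}")
print(bundle.component_volumes[["count", "volume_ml", "fraction_pct"]])
```

prints

```
E-wave frame 9, A-wave frame 21
peak-E MKE_V = 25.7 J/m^3, peak-E TKE_V = 69.6 J/m^3
diastolic TKE/KE = 0.940
           count  volume_ml  fraction_pct
component
DF          8192      128.0          40.0
RI          6144       96.0          30.0
DE          6144       96.0          30.0
RV             0        0.0           0.0
NP             0        0.0           0.0
```

The phantom fills and ejects a rectangular chamber with a biphasic diastolic
plug flow: the E- and A-wave peaks land on the prescribed frames (9 and 21),
every emitted pathline is classified, the component volumes sum exactly to
the end-diastolic volume, and the direct-flow fraction (40%) matches the
analytic overlap of the inflow and outflow transit bands. The prescribed
turbulence plateau (σᵢ = 0.3 m/s over half the chamber) is recovered from the
encoded magnitude volumes; because the plug phantom's transit velocities are
deliberately low, its TKE/KE ratio is far higher than in-vivo values.

On real data, the same analysis runs from NIfTI velocity/magnitude volumes,
a time-resolved LV segmentation, and a JSON sidecar (spacing, frame times,
VENC, RR interval):

```
ventriflow run --flow data/ --mask lv.nii.gz --mask-sidecar lv.json --out results/
```

Subcommands `phantom`, `tke`, `pathlines`, and `stats` expose the individual
stages; outputs are per-frame CSV series, per-component tables, a QC report,
and a JSON summary.

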