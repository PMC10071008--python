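"""Shared fixtures: small phantoms exercised across the suite."""

import numpy as np
import pytest

import ventriflow as vf


def small_plug_spec(**overrides) -> vf.PhantomSpec:
    """A fast plug-flow phantom (~1000 seeds) with all four bands populated."""
    base = dict(
        grid=(20, 20, 32),
        spacing=(2.5, 2.5, 2.5),
        n_frames=20,
        chamber_margin_xy=5,
        chamber_z0=11,
        chamber_len=10,
        e_peak_frame=4,
        a_peak_frame=10,
        e_width_frames=5.0,
        a_width_frames=3.0,
        systolic_width_frames=6.0,
        systolic_fraction=0.4,
        jet_speed=0.12,
        systolic_amplitude=0.14,
    )
    base.update(overrides)
    return vf.PhantomSpec(**base)


@pytest.fixture(scope="session")
def small_plug():
    spec = small_plug_spec()
    ds, masks, truth = vf.generate_plug_flow(spec)
    return spec, ds, masks, truth


@pytest.fixture(scope="session")
def low_flow_plug():
    """Displacements below chamber length: DF empty, RV populated."""
    spec = small_plug_spec(jet_speed=0.05, systolic_amplitude=0.06)
    ds, masks, truth = vf.generate_plug_flow(spec)
    return spec, ds, masks, truth


@pytest.fixture(scope="session")
def small_rotation():
    spec = vf.PhantomSpec(
        kind="rigid_rotation",
        grid=(24, 24, 24),
        spacing=(4.0, 4.0, 4.0),
        n_frames=20,
        ellipsoid_radii_mm=(28.0, 28.0, 32.0),
    )
    ds, masks, truth = vf.generate_affine_flow(spec)
    return spec, ds, masks, truth


@pytest.fixture(scope="session")
def small_deform():
    spec = vf.PhantomSpec(
        kind="affine_deform",
        grid=(32, 32, 32),
        spacing=(3.0, 3.0, 3.0),
        n_frames=20,
        deform_amplitude=0.2,
        ellipsoid_radii_mm=(30.0, 30.0, 36.0),
    )
    ds, masks, truth = vf.generate_affine_flow(spec)
    return spec, ds, masks, truth


@pytest.fixture(scope="session")
def small_plug_bundle(small_plug):
    """Full in-memory analysis of the small plug phantom (unfiltered TKE)."""
    _, ds, masks, _ = small_plug
    cfg = vf.AnalysisConfig(median_filter=False)
    return vf.run_analysis(ds, masks, cfg)


def assert_partition(labels: np.ndarray) -> None:
    counts = np.bincount(labels, minlength=5)
    assert counts.sum() == labels.size
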