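"""Shared fixtures: phantom scenes and expensive pipeline runs.

The heavyweight fixtures (tube-grid tracking, bead calibration, the 20-tube
benchmark) are session-scoped so the unit tests and the acceptance tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import vesseltrace as vt
from vesseltrace.phantoms import (PhantomSpec, TubeSpec, BeadPhantomSpec,
                                  make_paired_phantom, render_bead_phantom,
                                  render_vessel_phantom, random_vessel_spec,
                                  straight_tube_spec)

PSF_EX = vt.PSFModel(lateral_fwhm=1.0, axial_fwhm_intercept=3.4,
                     axial_fwhm_slope=(7.5 - 3.4) / 1000.0)
PSF_IN = vt.PSFModel(lateral_fwhm=1.0, axial_fwhm_intercept=3.4,
                     axial_fwhm_slope=0.0)


@pytest.fixture(scope="session")
def psf_ex():
    """Cleared-tissue PSF: axial FWHM 3.4 μm at the surface, 7.5 μm at 1 mm."""
    return PSF_EX


@pytest.fixture(scope="session")
def psf_in():
    """In vivo PSF: depth-invariant, axial FWHM 3.4 μm."""
    return PSF_IN


def render_single_tube(diameter, depth, psf, noise="none", **kw):
    spec = straight_tube_spec(diameter=diameter, depth=depth,
                              noise_model=noise, **kw)
    return render_vessel_phantom(spec, psf)


@pytest.fixture(scope="session")
def tube_grid_tracked(psf_ex):
    """Straight tubes d ∈ {3,4,6,8,10} μm at depths {0,300,600,900} μm,
    rendered with the depth-varying PSF, tracked with the same (correct)
    PSF, and re-measured under the constant surface PSF.

    Returns a list of dicts with keys d, depth, net (tracked), net_const
    (radii re-fit with the depth-invariant model), truth.
    """
    from vesseltrace.tracking import recompute_diameters, track_image

    out = []
    for d in (3.0, 4.0, 6.0, 8.0, 10.0):
        for depth in (0.0, 300.0, 600.0, 900.0):
            vol, truth = render_single_tube(d, depth, psf_ex)
            cfg = vt.TrackerConfig(psf=psf_ex, seed_threshold=200.0)
            net = track_image(vol, psf_ex, cfg)
            net_const = recompute_diameters(net, vol, PSF_IN)
            out.append({"d": d, "depth": depth, "net": net,
                        "net_const": net_const, "truth": truth, "vol": vol})
    return out


@pytest.fixture(scope="session")
def small_tube_grid_tracked(psf_ex):
    """Small vessels d ∈ {2.5,3,4,5} μm, depths 0–1000 μm, tracked with the
    depth-varying PSF and re-measured under the constant assumption."""
    from vesseltrace.tracking import recompute_diameters, track_image

    out = []
    for d in (2.5, 3.0, 4.0, 5.0):
        for depth in (0.0, 250.0, 500.0, 750.0, 1000.0):
            vol, truth = render_single_tube(d, depth, psf_ex)
            cfg = vt.TrackerConfig(psf=psf_ex, seed_threshold=200.0)
            net = track_image(vol, psf_ex, cfg)
            net_const = recompute_diameters(net, vol, PSF_IN)
            out.append({"d": d, "depth": depth, "net": net,
                        "net_const": net_const})
    return out


@pytest.fixture(scope="session")
def benchmark_scene(psf_in):
    """The 20-tube benchmark: default generator conditions (5% Gaussian
    noise), non-local-means denoised, tracked. Returns (net, truth)."""
    from vesseltrace.preprocess import denoise_nlm
    from vesseltrace.tracking import track_image

    spec = random_vessel_spec(n_tubes=20, seed=7)
    vol, truth = render_vessel_phantom(spec, psf_in)
    vol = denoise_nlm(vol)
    net = track_image(vol, psf_in, vt.TrackerConfig(psf=psf_in))
    return net, truth


@pytest.fixture(scope="session")
def bead_calibration(psf_ex):
    """40 noiseless beads spanning 0–1000 μm: render, pre-blur, fit, calibrate.

    Returns (fitted PSFModel, OLS summary, bead table).
    """
    from vesseltrace.preprocess import blur_xy
    from vesseltrace.psf_model import calibrate_psf_depth_model, fit_bead_fwhm

    spec = BeadPhantomSpec(n_beads=40, psf=psf_ex, rng_seed=5)
    vol, table = render_bead_phantom(spec)
    vol = blur_xy(vol, 1.5)
    fits = []
    for _, row in table.iterrows():
        guess = row[["x_um", "y_um", "z_um"]].to_numpy(float)
        fx = fit_bead_fwhm(vol, guess, "x")
        fz = fit_bead_fwhm(vol, guess, "z")
        fx.fwhm_z = fz.fwhm_z
        fits.append(fx)
    model, summary = calibrate_psf_depth_model(fits)
    return model, summary, table


def build_paired_scene(warp=None, cap_scale=0.87, pen_scale=0.66, seed=2):
    """A paired in vivo / ex vivo scene: 2 vertical penetrating vessels and 8
    capillaries, ex vivo geometry warped and diameters shrunk per class."""
    rng = np.random.default_rng(seed)
    tubes = []
    for x in (40.0, 100.0):
        tubes.append(TubeSpec(np.array(
            [[x, 70 + rng.uniform(-5, 5), 10.0],
             [x + rng.uniform(-6, 6), 70 + rng.uniform(-5, 5), 130.0]]),
            11.0, 1000.0))
    for i in range(8):
        y = 12.0 + i * 16.0
        z = rng.uniform(20, 120)
        tubes.append(TubeSpec(np.array(
            [[12.0, y, z],
             [128.0, y + rng.uniform(-6, 6), z + rng.uniform(-8, 8)]]),
            rng.uniform(3.5, 6.0), 1000.0))
    spec = PhantomSpec(volume_shape=(95, 95, 95), voxel_size=(1.5, 1.5, 1.5),
                       tubes=tubes, noise_model="none", rng_seed=seed + 1)
    if warp is None:
        def warp(p):
            p = np.atleast_2d(p)
            return p + np.stack([4 * np.sin(p[:, 1] / 40),
                                 3 * np.cos(p[:, 0] / 50),
                                 2 * np.sin(p[:, 0] / 60 + p[:, 1] / 80)],
                                axis=1)

    def dscale(d):
        return cap_scale * d if d < 8 else pen_scale * d

    return spec, make_paired_phantom(spec, warp, dscale)


@pytest.fixture(scope="session")
def paired_scene():
    spec, bundle = build_paired_scene()
    return spec, bundle
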