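"""Shared fixtures: a fast low-axial-resolution optical model for module
tests and a full-depth model for the acceptance suite."""

import numpy as np
import pytest

from bfsim import bgfilter, optics, simulate


@pytest.fixture(scope="session")
def fast_config():
    """Coarse z grid (11 slices) — cheap but structurally complete."""
    return optics.OpticalConfig(
        em_wavelength_nm=488.0,
        na=1.4,
        refractive_index=1.5,
        pixel_nm=65.0,
        z_step_nm=400.0,
        z_halfrange_nm=2000.0,
        infocus_halfrange_nm=400.0,
        psf_size_px=64,
    )


@pytest.fixture(scope="session")
def fast_psf(fast_config):
    return optics.generate_psf3d(fast_config)


@pytest.fixture(scope="session")
def full_depth_config():
    """Full-depth z grid: ±4 µm at 100 nm, in-focus ±0.4 µm."""
    return optics.OpticalConfig(psf_size_px=128)


@pytest.fixture(scope="session")
def full_depth_psf(full_depth_config):
    return optics.generate_psf3d(full_depth_config)


@pytest.fixture(scope="session")
def otf128(fast_config, fast_psf):
    return optics.otf_pair_on_grid(
        fast_psf,
        fast_config.infocus_halfrange_nm,
        (128, 128),
        k_cutoff_cycles_per_px=fast_config.k_cutoff_cycles_per_px,
    )


@pytest.fixture(scope="session")
def filt128(otf128):
    return bgfilter.build_filter(otf128)


@pytest.fixture(scope="session")
def patterns(fast_config):
    return simulate.make_pattern_set(k_cutoff=fast_config.k_cutoff_cycles_per_px)


@pytest.fixture(scope="session")
def filament_stack(fast_config, fast_psf, patterns):
    """Noiseless model-consistent (g_out = g_in) raw stack on a 128 grid."""
    phantom = simulate.make_filament_phantom((128, 128), 5, rng_seed=1)
    stack = simulate.simulate_raw_stack(
        phantom,
        patterns,
        fast_psf,
        fast_config.infocus_halfrange_nm,
        None,
        k_cutoff=fast_config.k_cutoff_cycles_per_px,
    )
    return phantom, stack


def oracle_infocus_frame(phantom, pattern, phase, otf_pair):
    """Direct convolution oracle: [g_in · I] ⊗ h_in via the in-focus OTF."""
    illum = pattern.field(phantom.shape, phase)
    return np.fft.ifft2(np.fft.fft2(phantom.g_in * illum) * otf_pair.h_in).real
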