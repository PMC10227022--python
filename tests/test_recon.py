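import numpy as np
import pytest
from scipy.stats import pearsonr

from bfsim import bgfilter, optics, recon, simulate
from bfsim.errors import (
    ConditioningError,
    PatternNotFoundError,
    StageError,
    ValidationError,
)

PHASES = simulate.DEFAULT_PHASES


@pytest.fixture(scope="module")
def filtered_bands(patterns, otf128, filt128, filament_stack):
    _, stack = filament_stack
    fstack = bgfilter.filter_stack(stack, filt128)
    out = []
    for a in range(3):
        out.append(recon.separate_bands(fstack.frames[a], patterns[a].phases_rad))
    return out


class TestSeparateBands:
    def test_zero_modulation_collapses_to_mean(self):
        rng = np.random.default_rng(1)
        frame = rng.random((64, 64))
        frames = np.stack([frame, frame, frame])
        c0, cp, cm = recon.separate_bands(frames, PHASES)
        assert np.abs(cp).max() < 1e-9 * np.abs(c0).max()
        assert np.abs(cm).max() < 1e-9 * np.abs(c0).max()
        assert np.allclose(c0, np.fft.fft2(frame))

    def test_forward_model_oracle(self, fast_config, fast_psf, patterns, otf128,
                                  filament_stack):
        # C+ must equal dc·(m/2)·FT{g·e^{2πi k·r}}·(H_in + H_out)
        phantom, stack = filament_stack
        pat = patterns[0]
        y, x = np.arange(128), np.arange(128)
        carrier = np.exp(2j * np.pi * (pat.k_vec[0] * x[None, :] + pat.k_vec[1] * y[:, None]))
        den = otf128.h_in + otf128.h_out
        cp_oracle = pat.dc * (pat.modulation / 2) * np.fft.fft2(phantom.g_in * carrier) * den
        _, cp, _ = recon.separate_bands(stack.frames[0], pat.phases_rad)
        assert np.abs(cp - cp_oracle).max() <= 1e-8 * np.abs(cp_oracle).max()

    def test_permutation_invariance(self, filament_stack):
        _, stack = filament_stack
        frames = stack.frames[0]
        c = recon.separate_bands(frames, PHASES)
        perm = [2, 0, 1]
        cperm = recon.separate_bands(frames[perm], [PHASES[i] for i in perm])
        for a, b in zip(c, cperm):
            assert np.allclose(a, b, atol=1e-9 * np.abs(a).max())

    def test_degenerate_phases_rejected(self):
        frames = np.zeros((3, 16, 16))
        with pytest.raises(ConditioningError):
            recon.separate_bands(frames, (0.0, 0.0, 2.0))

    def test_wrong_frame_count_rejected(self):
        with pytest.raises(ValidationError):
            recon.separate_bands(np.zeros((4, 8, 8)), PHASES)

    def test_conjugate_band_relation(self, filtered_bands):
        # order −1 equals the conjugate reflection of order +1 for real input
        c0, cp, cm = filtered_bands[0]
        n = cp.shape[0]
        idx = (-np.arange(n)) % n
        assert np.allclose(cm, np.conj(cp[np.ix_(idx, idx)]), atol=1e-9 * np.abs(cp).max())


class TestEstimatePattern:
    def test_noiseless_recovery(self, fast_config, patterns, otf128, filtered_bands):
        kc = fast_config.k_cutoff_cycles_per_px
        for (c0, cp, cm), pat in zip(filtered_bands, patterns):
            est = recon.estimate_pattern(c0, cp, otf128.h_in, cm, k_cutoff=kc)
            assert np.hypot(*(est.k_vec - pat.k_vec)) * 128 <= 0.1
            assert abs(est.phases_rad[0]) <= 0.05
            assert est.modulation == pytest.approx(pat.modulation, rel=0.05)

    def test_integer_k_exact_integer_peak(self, fast_config, fast_psf, otf128, filt128):
        kc = fast_config.k_cutoff_cycles_per_px
        pat = simulate.IlluminationPattern(np.array([40 / 128, 0.0]))
        ph = simulate.make_filament_phantom((128, 128), 5, rng_seed=1)
        stack = simulate.simulate_raw_stack(ph, [pat], fast_psf, 400.0, k_cutoff=kc)
        fstack = bgfilter.filter_stack(stack, filt128)
        c0, cp, cm = recon.separate_bands(fstack.frames[0], pat.phases_rad)
        est = recon.estimate_pattern(c0, cp, otf128.h_in, cm, k_cutoff=kc)
        assert est.k_vec[0] * 128 == pytest.approx(40.0, abs=0.02)
        assert est.k_vec[1] * 128 == pytest.approx(0.0, abs=0.02)

    def test_modulation_invariant_to_scaling(self, fast_config, otf128, filtered_bands):
        kc = fast_config.k_cutoff_cycles_per_px
        c0, cp, cm = filtered_bands[0]
        est1 = recon.estimate_pattern(c0, cp, otf128.h_in, cm, k_cutoff=kc)
        est2 = recon.estimate_pattern(10 * c0, 10 * cp, otf128.h_in, 10 * cm, k_cutoff=kc)
        assert est2.modulation == pytest.approx(est1.modulation, rel=1e-6)

    def test_unusable_data_rejected(self, fast_config, otf128):
        # a single hot pixel yields a flat correlation magnitude whose peak
        # cannot clear the 4x-median significance gate
        img = np.zeros((128, 128))
        img[40, 60] = 1000.0
        spec = np.fft.fft2(img)
        with pytest.raises(PatternNotFoundError):
            recon.estimate_pattern(spec, spec, otf128.h_in,
                                   k_cutoff=fast_config.k_cutoff_cycles_per_px)


class TestWienerCombine:
    def test_zero_modulation_is_wiener_widefield(self, otf128):
        rng = np.random.default_rng(5)
        img = rng.random((128, 128))
        wf = np.fft.ifft2(np.fft.fft2(img) * otf128.h_in).real
        c0 = np.fft.fft2(wf)
        pat = simulate.IlluminationPattern(np.array([0.3, 0.0]), (0.0,), 0.5, 1.0)
        pat.modulation = 0.0  # degenerate widefield path
        bs = recon.BandSet(c0, np.zeros_like(c0), np.zeros_like(c0), pat)
        params = recon.ReconParams(apodization="none")
        res = recon.wiener_combine([bs], otf128.h_in, params,
                                   k_cutoff=otf128.k_cutoff_cycles_per_px)
        # oracle: direct Wiener deconvolution on the upsampled grid
        otfn = otf128.h_in / otf128.h_in[0, 0]
        big_c = recon._embed_spectrum(c0, 2)
        big_o = np.fft.fft2(np.fft.ifft2(recon._embed_spectrum(otfn, 2)))
        kyf = np.fft.fftfreq(256)[:, None] * 2
        kxf = np.fft.fftfreq(256)[None, :] * 2
        kcm = np.hypot(kyf, kxf) <= otf128.k_cutoff_cycles_per_px + 1.0 / 128
        big_o = big_o * kcm
        oracle = np.fft.ifft2(np.conj(big_o) * big_c / (np.abs(big_o) ** 2 + 0.05**2)).real * 4
        assert np.abs(res.sr_image - oracle).max() <= 1e-9 * np.abs(oracle).max()
        # effective OTF support limited to the widefield cutoff
        kr = np.hypot(kyf, kxf)
        sup = kr[res.effective_otf > 1e-9 * res.effective_otf.max()]
        assert sup.max() <= otf128.k_cutoff_cycles_per_px + 2.0 / 128

    def test_upsampled_shape_and_real(self, fast_config, otf128, patterns, filtered_bands):
        bsets = []
        for (c0, cp, cm), pat in zip(filtered_bands, patterns):
            est = recon.estimate_pattern(c0, cp, otf128.h_in, cm,
                                         k_cutoff=fast_config.k_cutoff_cycles_per_px)
            bsets.append(recon.BandSet(c0, cp, cm, est))
        res = recon.wiener_combine(bsets, otf128.h_in, recon.ReconParams(),
                                   k_cutoff=otf128.k_cutoff_cycles_per_px)
        assert res.sr_image.shape == (256, 256)
        assert np.isfinite(res.sr_image).all()
        # conjugate-symmetric spectrum: real output by construction, verify
        # the combined spectrum's Hermitian residue
        spec = np.fft.fft2(res.sr_image)
        n = 256
        idx = (-np.arange(n)) % n
        assert np.abs(spec - np.conj(spec[np.ix_(idx, idx)])).max() <= 1e-9 * np.abs(spec).max()

    def test_nan_band_rejected(self, otf128, patterns):
        c = np.full((128, 128), np.nan, dtype=complex)
        pat = simulate.IlluminationPattern(np.array([0.3, 0.0]), (0.0,), 0.8, 1.0)
        bs = recon.BandSet(c, c, c, pat)
        with pytest.raises(ValidationError):
            recon.wiener_combine([bs], otf128.h_in, recon.ReconParams())

    def test_modulation_floor(self, otf128):
        c = np.zeros((128, 128), dtype=complex)
        pat = simulate.IlluminationPattern(np.array([0.3, 0.0]), (0.0,), 0.05, 1.0)
        bs = recon.BandSet(c, c, c, pat)
        with pytest.raises(PatternNotFoundError):
            recon.wiener_combine([bs], otf128.h_in, recon.ReconParams())


class TestReconstruct:
    def test_end_to_end_exactness_anchor(self, fast_config, fast_psf, patterns,
                                         otf128, filament_stack):
        # BF commutes with the pipeline under the model: reconstructing the
        # filtered full scene equals reconstructing a directly simulated
        # in-focus-only stack through the identical combination stage
        phantom, stack = filament_stack
        kc = fast_config.k_cutoff_cycles_per_px
        ph_in = simulate.Phantom(phantom.g_in, np.zeros_like(phantom.g_in), 65.0)
        stack_in = simulate.simulate_raw_stack(ph_in, patterns, fast_psf, 400.0, k_cutoff=kc)
        res_bf = recon.reconstruct(stack, otf128, recon.ReconParams(use_bf=True))
        filt = bgfilter.build_filter(otf128)
        h_eff = otf128.h_in * (1.0 - filt.w)
        res_in = recon.reconstruct(stack_in, otf128, recon.ReconParams(use_bf=False),
                                   otf_z0=h_eff)
        diff = np.abs(res_bf.sr_image - res_in.sr_image).max()
        assert diff <= 1e-6 * np.abs(res_in.sr_image).max()

    def test_clean_scene_bf_invariance(self, fast_config, fast_psf, otf128):
        # integer-bin wave-vectors so band placement is grid-exact; the
        # remaining on/off difference then isolates the filter's effect
        kc = fast_config.k_cutoff_cycles_per_px
        pats = [
            simulate.IlluminationPattern(np.array([38 / 128, 0.0])),
            simulate.IlluminationPattern(np.array([0.0, 38 / 128])),
            simulate.IlluminationPattern(np.array([27 / 128, 27 / 128])),
        ]
        ph = simulate.make_filament_phantom((128, 128), 8, rng_seed=4)
        ph0 = simulate.Phantom(ph.g_in, np.zeros_like(ph.g_in), 65.0)
        stack = simulate.simulate_raw_stack(ph0, pats, fast_psf, 400.0, k_cutoff=kc)
        a = recon.reconstruct(stack, otf128, recon.ReconParams(use_bf=True)).sr_image
        b = recon.reconstruct(stack, otf128, recon.ReconParams(use_bf=False),
                              otf_z0=otf128.h_in).sr_image
        r, _ = pearsonr(a.ravel(), b.ravel())
        assert r >= 0.999

    def test_stage_error_wrapping(self, otf128, filament_stack):
        _, stack = filament_stack
        frames = stack.frames.copy()
        frames[0, 0, 0, 0] = np.nan
        bad = simulate.RawSIMStack(frames, 65.0)
        with pytest.raises(StageError):
            recon.reconstruct(bad, otf128, recon.ReconParams(use_bf=True))

    def test_deterministic_and_planewise_independent(self, otf128, filament_stack):
        # repeated calls (as in plane-by-plane z-stack processing) are
        # bit-identical and independent of call order
        _, stack = filament_stack
        params = recon.ReconParams(use_bf=True)
        a = recon.reconstruct(stack, otf128, params).sr_image
        b = recon.reconstruct(stack, otf128, params).sr_image
        assert np.array_equal(a, b)


class TestNotchBaseline:
    def test_zero_strength_identity(self, fast_config, otf128, patterns, filtered_bands):
        kc = fast_config.k_cutoff_cycles_per_px
        bsets = []
        for (c0, cp, cm), pat in zip(filtered_bands, patterns):
            est = recon.estimate_pattern(c0, cp, otf128.h_in, cm, k_cutoff=kc)
            bsets.append(recon.BandSet(c0, cp, cm, est))
        plain = recon.wiener_combine(bsets, otf128.h_in, recon.ReconParams(), k_cutoff=kc)
        notched = recon.notch_attenuation_baseline(bsets, otf128.h_in, 0.0, 0.05,
                                                   k_cutoff=kc)
        assert np.abs(plain.sr_image - notched.sr_image).max() <= 1e-12 * np.abs(
            plain.sr_image).max()

    def test_continuity_in_strength(self, fast_config, otf128, patterns, filtered_bands):
        kc = fast_config.k_cutoff_cycles_per_px
        bsets = []
        for (c0, cp, cm), pat in zip(filtered_bands, patterns):
            est = recon.estimate_pattern(c0, cp, otf128.h_in, cm, k_cutoff=kc)
            bsets.append(recon.BandSet(c0, cp, cm, est))
        a = recon.notch_attenuation_baseline(bsets, otf128.h_in, 0.50, 0.05, k_cutoff=kc)
        b = recon.notch_attenuation_baseline(bsets, otf128.h_in, 0.50 + 1e-4, 0.05,
                                             k_cutoff=kc)
        scale = np.abs(a.sr_image).max()
        assert np.abs(a.sr_image - b.sr_image).max() <= 1e-2 * scale

    def test_total_suppression_rejected(self, otf128):
        with pytest.raises(ValidationError):
            recon.NotchSpec(1.0, 0.05)
        with pytest.raises(ValidationError):
            recon.notch_attenuation_baseline([], otf128.h_in, 1.2, 0.05)
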