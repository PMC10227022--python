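"""Wiener 2D-SIM reconstruction with optional background pre-filtering.

Pipeline per angle: solve the 3-phase mixing system for the three spectral
orders, estimate the illumination wave-vector / phase / modulation by
cross-correlation of the overlapping bands, then shift every order onto a
2×-upsampled grid and merge them with a generalized Wiener filter

    S(k) = Σ_b conj(OTF_b)·C_b / ( Σ_b |OTF_b|² + w² ),

followed by apodization and an inverse FFT.  A Gaussian notch that
attenuates each band's OTF at its own centre is available as the
attenuation-style comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize

from .bgfilter import build_filter, filter_stack
from .errors import (
    ConditioningError,
    PatternNotFoundError,
    StageError,
    ValidationError,
)
from .optics import OTFPair
from .simulate import DEFAULT_PHASES, IlluminationPattern, RawSIMStack

__all__ = [
    "BandSet",
    "NotchSpec",
    "ReconParams",
    "ReconstructionResult",
    "separate_bands",
    "estimate_pattern",
    "wiener_combine",
    "reconstruct",
    "notch_attenuation_baseline",
]

_APODIZATIONS = ("triangle", "gaussian", "none")


@dataclass(frozen=True)
class NotchSpec:
    """Gaussian attenuation of each band's OTF at its own centre."""

    att_strength: float
    att_fwhm_cycles: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.att_strength < 1.0:
            raise ValidationError(
                f"att_strength must lie in [0, 1), got {self.att_strength} "
                "(total suppression is disallowed)"
            )
        if not self.att_fwhm_cycles > 0:
            raise ValidationError("att_fwhm_cycles must be positive")


@dataclass(frozen=True)
class ReconParams:
    wiener_w: float = 0.05
    apodization: str = "triangle"
    upsample: int = 2
    use_bf: bool = True
    notch: NotchSpec | None = None
    offset: float = 0.0
    modulation_floor: float = 0.1
    # Weight bands by the full chain response H_in·(1 − W) instead of H_in
    # alone, so that a scene with no defocused content reconstructs
    # identically with the filter on or off (the filter's in-band
    # attenuation is divided back out by the Wiener step).
    bf_compensate: bool = True

    def __post_init__(self) -> None:
        if not self.wiener_w > 0:
            raise ValidationError("wiener_w must be positive")
        if self.upsample != 2:
            raise ValidationError("only 2x upsampling is supported")
        if self.apodization not in _APODIZATIONS:
            raise ValidationError(f"apodization must be one of {_APODIZATIONS}")


@dataclass
class BandSet:
    """Separated orders (0, +1, −1) for one pattern angle."""

    c0: np.ndarray
    cp: np.ndarray
    cm: np.ndarray
    pattern: IlluminationPattern


@dataclass
class ReconstructionResult:
    sr_image: np.ndarray
    effective_otf: np.ndarray
    patterns: list
    params: ReconParams
    provenance: list = field(default_factory=list)


def separate_bands(frames, phases):
    """Unmix three phase frames into spectral orders (C0, C+, C−).

    Solves, per Fourier coefficient, ``D_j = C0 + e^{iφ_j}·C+ + e^{−iφ_j}·C−``
    (the modulation amplitude stays folded into C± at this stage).
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.shape[0] != 3 or len(phases) != 3:
        raise ValidationError("exactly 3 frames and 3 phases are required")
    phases = np.asarray(phases, dtype=np.float64)
    m = np.stack(
        [np.ones(3, dtype=np.complex128), np.exp(1j * phases), np.exp(-1j * phases)], axis=1
    )
    det = np.linalg.det(m)
    if abs(det) < 1e-6:
        raise ConditioningError(
            f"phase mixing matrix is singular (|det| = {abs(det):.3e}); phases {phases} degenerate"
        )
    minv = np.linalg.inv(m)
    d = np.fft.fft2(frames, axes=(-2, -1))
    c = np.tensordot(minv, d, axes=([1], [0]))
    return c[0], c[1], c[2]


def _kgrid_px(shape):
    """Signed frequency coordinates in cycles per image (index units)."""
    qy = np.fft.fftfreq(shape[0]) * shape[0]
    qx = np.fft.fftfreq(shape[1]) * shape[1]
    return qy, qx


def _xcorr_value(prod, qy, qx):
    """|Σ_r prod(r)·e^{−2πi q·r/N}| evaluated at a non-integer bin (qy, qx)."""
    ny, nx = prod.shape
    ey = np.exp(-2j * np.pi * qy * np.arange(ny) / ny)
    ex = np.exp(-2j * np.pi * qx * np.arange(nx) / nx)
    return ey @ prod @ ex


def _smooth_mask(mask: np.ndarray, sigma_bins: float) -> np.ndarray:
    """Gaussian-taper a binary frequency mask (smoothed in shifted layout)."""
    return np.fft.ifftshift(
        gaussian_filter(np.fft.fftshift(mask.astype(float)), sigma_bins, mode="constant")
    )


def estimate_pattern(
    c0: np.ndarray,
    cp: np.ndarray,
    otf: np.ndarray,
    cm: np.ndarray | None = None,
    *,
    k_cutoff: float | None = None,
    min_k_bins: float = 5.0,
    otf_support_rel: float = 0.05,
    taper_sigma_bins: float = 2.0,
    significance: float = 4.0,
) -> IlluminationPattern:
    """Recover the illumination wave-vector, global phase and modulation.

    The integer-bin peak of the cross-correlation between the 0th and +1st
    order (both Wiener-equalised) locates the wave-vector; it is refined
    to sub-pixel precision by maximising the continuous cross-correlation
    magnitude of the OTF-compensated joint-overlap product, whose value at
    the optimum is the complex pattern amplitude ``(m/2)·e^{iφ0}``.
    Passing the −1 order ``cm`` as well averages two bands with
    independent noise and tightens every estimate.
    """
    shape = c0.shape
    ny, nx = shape
    otf = np.asarray(otf, dtype=np.complex128)
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.fftfreq(nx)[None, :]
    kr = np.hypot(ky, kx)

    # Wiener-equalised weighting: approximately divides the OTF out of both
    # bands on its support (flat common spectrum), which keeps the carrier
    # peak from being doubly attenuated, while damping amplified noise;
    # out-of-band frequencies carry no pattern information and are dropped.
    otfn = otf / np.abs(otf).max()
    weq = np.conj(otfn) / (np.abs(otfn) ** 2 + 0.1**2)
    if k_cutoff is not None:
        # strictly inside the passband: between k_c and ~1.05 k_c the
        # transfer-function pair nearly cancels and the background filter
        # amplifies noise there enormously
        weq = weq * (kr <= k_cutoff)
    i0 = np.fft.ifft2(c0 * weq)
    i1 = np.fft.ifft2(cp * weq)
    prod = i1 * np.conj(i0)
    corr = np.fft.fft2(prod)
    mag = np.abs(corr)

    qy, qx = _kgrid_px(shape)
    qr = np.hypot(qy[:, None], qx[None, :])
    valid = qr >= min_k_bins
    if k_cutoff is not None:
        # physical SIM patterns sit at a large fraction of the cutoff; the
        # DC-proximal region instead collects signal autocorrelation and
        # correlated shot-noise terms
        valid &= (qr >= 0.25 * k_cutoff * min(ny, nx)) & (
            qr <= 1.05 * k_cutoff * min(ny, nx)
        )
    if not valid.any():
        raise PatternNotFoundError("no admissible wave-vector search region")
    mag_masked = np.where(valid, mag, -np.inf)
    flat = int(np.argmax(mag_masked))  # ties: lowest index, deterministic
    iy, ix = np.unravel_index(flat, shape)
    peak = mag[iy, ix]
    baseline = float(np.median(mag[valid]))
    if peak < significance * baseline:
        raise PatternNotFoundError(
            f"correlation peak {peak:.3g} below {significance}× median {baseline:.3g}; "
            "pattern unusable"
        )

    res = minimize(
        lambda q: -abs(_xcorr_value(prod, q[0], q[1])),
        np.array([qy[iy], qx[ix]]),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 200},
    )
    qy1, qx1 = res.x
    k_vec = np.array([qx1 / nx, qy1 / ny])  # (kx, ky) cycles/px

    # Complex pattern amplitude on the joint overlap.  Each band is divided
    # by the OTF over the overlap of its support with the 0th order's and
    # restricted by a *smoothly tapered*, |OTF|-weighted version of that
    # overlap (a hard mask edge, offset by the fractional part of the shift
    # between the bands, would bias both the refined peak and the phase).
    # The demodulated product then satisfies q1·conj(q0) ≈ α·|g̃|²·carrier
    # with α = (m/2)·e^{iφ0} and |g̃|² real non-negative, so its continuous
    # cross-correlation magnitude peaks at the wave-vector and its value
    # there is α.  The norm Σ|q0|² is corrected for the band's noise floor
    # (measured beyond the passband) before forming the modulation ratio.
    amax = np.abs(otf).max()
    mask = np.abs(otf) > otf_support_rel * amax
    sy = int(round(k_vec[1] * ny))
    sx = int(round(k_vec[0] * nx))
    safe_otf = np.where(mask, otf, 1.0)
    abs_h = np.abs(otf)
    var_c0 = 0.0
    if k_cutoff is not None:
        outside = kr > 1.1 * k_cutoff
        if outside.any():
            # median-based: robust against the few bins the background
            # filter amplifies near transfer-function zero crossings
            var_c0 = float(np.median(np.abs(c0[outside]) ** 2) / np.log(2.0))

    # Exclude DC-proximal bins from the overlap: residual (defocus or
    # offset) background is concentrated there and would inflate the
    # 0th-order norm, biasing the modulation low.
    qr_bins = kr * min(ny, nx)
    dc_guard = qr_bins >= max(min_k_bins, 0.15 * np.hypot(float(sy), float(sx)))

    def _band_product(c_band, s):
        """Demodulated overlap product and noise-corrected norm for one order."""
        joint = mask & np.roll(mask, (-s[0], -s[1]), axis=(0, 1)) & dc_guard
        if not joint.any():
            raise PatternNotFoundError("band overlap region is empty")
        weight = _smooth_mask(joint, taper_sigma_bins) * np.sqrt(
            abs_h * np.roll(abs_h, (-s[0], -s[1]), axis=(0, 1))
        )
        q0b = np.fft.ifft2(np.where(mask, c0 / safe_otf, 0.0) * weight)
        q1b = np.fft.ifft2(
            np.where(mask, c_band / safe_otf, 0.0) * np.roll(weight, s, axis=(0, 1))
        )
        norm = float(np.sum(np.abs(q0b) ** 2))
        norm -= var_c0 * float(np.sum(np.abs(np.where(mask, weight / safe_otf, 0.0)) ** 2)) / (
            ny * nx
        )
        return q1b * np.conj(q0b), max(norm, 1e-30)

    prod2, norm = _band_product(cp, (sy, sx))
    if cm is not None:
        prod_m, norm_m = _band_product(cm, (-sy, -sx))
        # cm ≈ conj(α)·G(k+k_p)·H, so conjugating its product restores the
        # +k_p carrier; independent noise halves the estimator variance.
        prod2 = prod2 + np.conj(prod_m)
        norm += norm_m
    res2 = minimize(
        lambda q: -abs(_xcorr_value(prod2, q[0], q[1])),
        np.array([qy1, qx1]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-16, "maxiter": 300},
    )
    qy2, qx2 = res2.x
    k_vec = np.array([qx2 / nx, qy2 / ny])
    alpha = _xcorr_value(prod2, qy2, qx2) / norm
    modulation = float(min(2.0 * np.abs(alpha), 1.0))
    phase = float(np.angle(alpha))
    return IlluminationPattern(k_vec, phases_rad=(phase,), modulation=modulation, dc=1.0)


def _embed_spectrum(c: np.ndarray, upsample: int) -> np.ndarray:
    """Zero-pad an unshifted spectrum onto an upsampled grid."""
    ny, nx = c.shape
    big = np.zeros((ny * upsample, nx * upsample), dtype=np.complex128)
    cs = np.fft.fftshift(c)
    r0 = (ny * upsample - ny) // 2
    c0 = (nx * upsample - nx) // 2
    big[r0 : r0 + ny, c0 : c0 + nx] = cs
    return np.fft.ifftshift(big)


def wiener_combine(
    bandsets: list[BandSet],
    otf: np.ndarray | OTFPair,
    params: ReconParams,
    *,
    k_cutoff: float | None = None,
) -> ReconstructionResult:
    """Shift all separated orders onto the 2× grid and merge them.

    ``otf`` is the detection transfer function the bands were imaged
    through (an ``OTFPair``'s in-focus member may be passed directly).  It
    is normalised to unit DC so ``wiener_w`` has a scale-free meaning.
    A band with modulation 0 contributes its 0th order only (degenerate
    widefield path); modulations between 0 and the floor raise
    ``PatternNotFoundError``.
    """
    if isinstance(otf, OTFPair):
        if k_cutoff is None:
            k_cutoff = otf.k_cutoff_cycles_per_px
        otf = otf.h_in
    otf = np.asarray(otf, dtype=np.complex128)
    otf = otf / otf[0, 0]
    kc = k_cutoff if k_cutoff is not None else _support_radius(otf)
    u = params.upsample
    ny, nx = otf.shape
    big_shape = (ny * u, nx * u)
    num = np.zeros(big_shape, dtype=np.complex128)
    den = np.zeros(big_shape, dtype=np.float64)

    yy = np.arange(big_shape[0])[:, None]
    xx = np.arange(big_shape[1])[None, :]
    kyf = np.fft.fftfreq(big_shape[0])[:, None] * u  # cycles per original px
    kxf = np.fft.fftfreq(big_shape[1])[None, :] * u
    otf_big_real = np.fft.ifft2(_embed_spectrum(otf, u))

    k_mags = []
    for bs in bandsets:
        if np.any(~np.isfinite(bs.c0)) or np.any(~np.isfinite(bs.cp)) or np.any(~np.isfinite(bs.cm)):
            raise ValidationError("NaN/Inf in separated bands (stage: wiener_combine)")
        pat = bs.pattern
        m = pat.modulation
        phi0 = pat.phases_rad[0] if pat.phases_rad else 0.0
        kx, ky = pat.k_vec
        if m == 0.0:
            orders = [(0, bs.c0, 1.0)]
        else:
            if m < params.modulation_floor:
                raise PatternNotFoundError(
                    f"modulation {m:.3f} below floor {params.modulation_floor}"
                )
            k_mags.append(float(np.hypot(kx, ky)))
            coeff = 0.5 * m * np.exp(1j * phi0)
            orders = [(0, bs.c0, 1.0), (1, bs.cp, coeff), (-1, bs.cm, np.conj(coeff))]
        for order, c, coeff in orders:
            u_r = np.fft.ifft2(_embed_spectrum(c, u)) / coeff
            if order == 0:
                s_b = np.fft.fft2(u_r)
                otf_b = np.fft.fft2(otf_big_real)
            else:
                # shift the band spectrum by −order·k_p via a real-space ramp
                ramp = np.exp(
                    -2j * np.pi * order * ((kx / u) * xx + (ky / u) * yy)
                )
                s_b = np.fft.fft2(u_r * ramp)
                otf_b = np.fft.fft2(otf_big_real * ramp)
            # restrict the band OTF to its theoretical support (cutoff disk
            # around −order·k_p): the fractional-shift ramp otherwise leaves
            # Dirichlet ringing across the whole extended grid
            rho2 = (kxf + order * kx) ** 2 + (kyf + order * ky) ** 2
            margin = 1.0 / min(ny, nx)
            otf_b = otf_b * (rho2 <= (kc + margin) ** 2)
            if params.notch is not None:
                sigma = params.notch.att_fwhm_cycles / 2.355
                otf_b = otf_b * (
                    1.0 - params.notch.att_strength * np.exp(-rho2 / (2.0 * sigma**2))
                )
            num += np.conj(otf_b) * s_b
            den += np.abs(otf_b) ** 2

    spectrum = num / (den + params.wiener_w**2)
    k_ext = kc + (max(k_mags) if k_mags else 0.0)
    kr = np.hypot(kyf, kxf)
    if params.apodization == "triangle":
        apod = np.clip(1.0 - kr / k_ext, 0.0, None)
    elif params.apodization == "gaussian":
        apod = np.exp(-(kr**2) / (2.0 * (k_ext / 3.0) ** 2))
    else:
        apod = 1.0
    spectrum = spectrum * apod
    sr_c = np.fft.ifft2(spectrum) * (u * u)
    sr = sr_c.real
    prov = [
        {"stage": "wiener_combine", "wiener_w": params.wiener_w, "apodization": params.apodization,
         "k_ext_cycles_per_px": k_ext,
         "notch": None if params.notch is None else
         {"att_strength": params.notch.att_strength, "att_fwhm_cycles": params.notch.att_fwhm_cycles}}
    ]
    return ReconstructionResult(sr, den, [bs.pattern for bs in bandsets], params, prov)


def _support_radius(otf: np.ndarray, rel_tol: float = 1e-4) -> float:
    mag = np.abs(otf)
    ky = np.fft.fftfreq(otf.shape[0])[:, None]
    kx = np.fft.fftfreq(otf.shape[1])[None, :]
    kr = np.hypot(ky, kx)
    sup = kr[mag > rel_tol * mag.max()]
    return float(sup.max()) if sup.size else 0.5


def reconstruct(
    stack: RawSIMStack,
    otf_pair: OTFPair,
    params: ReconParams,
    *,
    otf_z0: np.ndarray | None = None,
    phases=None,
) -> ReconstructionResult:
    """Full pipeline: (background filter) → unmix → estimate → combine.

    With ``use_bf`` the frames are background-filtered first and the bands
    are weighted against the in-focus transfer function (the filtered
    data's true OTF); without it, weighting uses the focal-plane OTF
    ``otf_z0`` when provided (falling back to the in-focus OTF).
    """
    phases = tuple(phases) if phases is not None else DEFAULT_PHASES[: stack.n_phases]
    if stack.n_phases != 3:
        raise ValidationError("reconstruction requires exactly 3 phases per angle")
    prov: list[dict] = []
    if params.use_bf:
        try:
            filt = build_filter(otf_pair)
            work = filter_stack(stack, filt, offset=params.offset)
        except Exception as exc:  # noqa: BLE001 - wrapped with stage name
            raise StageError("background_filter", exc) from exc
        det_otf = otf_pair.h_in
        if params.bf_compensate:
            det_otf = det_otf * (1.0 - filt.w)
        prov.append({"stage": "background_filter", "w_dc": filt.dc_fraction,
                     "offset": params.offset, "bf_compensate": params.bf_compensate})
    else:
        frames = stack.frames - params.offset
        work = RawSIMStack(frames, stack.pixel_nm, stack.patterns_truth, dict(stack.meta))
        det_otf = otf_z0 if otf_z0 is not None else otf_pair.h_in
        prov.append({"stage": "offset_subtract", "offset": params.offset,
                     "detection_otf": "z0" if otf_z0 is not None else "in_focus_fallback"})

    bandsets = []
    for a in range(work.n_angles):
        try:
            c0, cp, cm = separate_bands(work.frames[a], phases)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"separate_bands[angle={a}]", exc) from exc
        try:
            pat = estimate_pattern(c0, cp, det_otf, cm, k_cutoff=otf_pair.k_cutoff_cycles_per_px)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"estimate_pattern[angle={a}]", exc) from exc
        bandsets.append(BandSet(c0, cp, cm, pat))
    try:
        result = wiener_combine(
            bandsets, det_otf, params, k_cutoff=otf_pair.k_cutoff_cycles_per_px
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("wiener_combine", exc) from exc
    result.provenance = prov + result.provenance
    return result


def notch_attenuation_baseline(
    bandsets: list[BandSet],
    otf: np.ndarray | OTFPair,
    att_strength: float,
    att_fwhm_cycles: float,
    params: ReconParams | None = None,
    k_cutoff: float | None = None,
) -> ReconstructionResult:
    """Attenuation-style comparator: same pipeline, notched band OTFs."""
    base = params or ReconParams()
    notched = replace(base, notch=NotchSpec(att_strength, att_fwhm_cycles))
    return wiener_combine(bandsets, otf, notched, k_cutoff=k_cutoff)
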