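"""Fourier-domain estimation and subtraction of defocused background.

The filtered frame is ``d_in = d − iFT{ D(k) · W(k) }`` with the fixed,
parameter-free kernel ``W(k) = H_out / (H_in + H_out)`` built from the
in-focus / out-of-focus transfer-function pair.  Unlike data-dependent
attenuation schemes, this is a strictly linear shift-invariant filter:
for a purely in-focus scene each Fourier coefficient is attenuated by
exactly ``H_in / (H_in + H_out)``, and for a scene matching the two-term
forward model the background is removed identically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidOpticsError, ValidationError
from .optics import OTFPair
from .simulate import RawSIMStack

__all__ = ["FilterSpec", "BackgroundFilter", "build_filter", "filter_image", "filter_stack"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """How the 0/0 regions outside the OTF support are handled.

    The ratio kernel is left unregularised inside the support (``eps = 0``)
    and defined as 0 outside it, so data beyond the passband — pure noise —
    is passed through untouched for downstream Wiener handling.  The
    support tolerance sits at the numerical-cancellation level: a looser
    mask (e.g. 1e-6) zeroes bins that still carry real transfer, breaking
    the exact-removal identity at the ~1e-6 level on the full z grid.
    """

    eps: float = 0.0
    support_mask_rel_tol: float = 1e-9
    clamp_negative: bool = False
    restrict_to_passband: bool = False

    def __post_init__(self) -> None:
        if self.eps < 0:
            raise ValidationError("eps must be non-negative")
        if not 0.0 < self.support_mask_rel_tol < 1.0:
            raise ValidationError("support_mask_rel_tol must lie in (0, 1)")


@dataclass
class BackgroundFilter:
    """The real, even kernel W(k) on the shared unshifted frequency grid."""

    w: np.ndarray
    k_cutoff_cycles_per_px: float
    spec: FilterSpec = FilterSpec()

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.ndim != 2:
            raise ValidationError("filter kernel must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.w.shape

    @property
    def dc_fraction(self) -> float:
        """W(0): the fraction of total flux attributed to background."""
        return float(self.w[0, 0])


def build_filter(otf: OTFPair, spec: FilterSpec | None = None) -> BackgroundFilter:
    """Construct W = H_out / (H_in + H_out + eps) on the OTF support, 0 outside.

    The kernel is *not* clipped: on an adequately sampled PSF it stays
    within a few percent of [0, 1] inside the passband (the defocused OTF
    has small negative lobes), and leaving it exact preserves the
    background-removal identity.  With ``restrict_to_passband`` the kernel
    is additionally forced to zero beyond ``k_cutoff``, where an ideal OTF
    pair would vanish but a finite-window one carries truncation leakage;
    the default keeps the ratio there so the identity stays machine-exact.
    """
    spec = spec or FilterSpec()
    h_in = otf.h_in.real
    h_out = otf.h_out.real
    if not np.any(np.abs(h_in) > 0):
        raise InvalidOpticsError("H_in is identically zero; optics are unusable")
    if not np.any(np.abs(h_out) > 0):
        warnings.warn(
            "H_out is identically zero; background filter is an identity", UserWarning
        )
    denom = h_in + h_out
    dc = denom[0, 0]
    support = np.abs(denom) > spec.support_mask_rel_tol * abs(dc)
    passband = otf.k_radius() <= otf.k_cutoff_cycles_per_px
    if spec.restrict_to_passband:
        support &= passband
    w = np.zeros_like(denom)
    np.divide(h_out, denom + spec.eps, out=w, where=support)
    w_in = w[passband]
    if spec.eps == 0.0 and (w_in.min() < -0.5 or w_in.max() > 1.5):
        raise InvalidOpticsError(
            f"background kernel escapes [0, 1] by more than 0.5 inside the passband "
            f"(range {w_in.min():.3g}..{w_in.max():.3g}); PSF looks undersampled or truncated"
        )
    return BackgroundFilter(w, otf.k_cutoff_cycles_per_px, spec)


def filter_image(
    d: np.ndarray, filt: BackgroundFilter, clamp_negative: bool | None = None
) -> np.ndarray:
    """Subtract the modelled background from one frame.

    Returns ``iFT{ FT{d} · (1 − W) }``, which equals ``d − iFT{FT{d}·W}``.
    With ``clamp_negative`` the (noise-induced) negative values are zeroed
    *after* the subtraction and the clamped flux fraction is logged.
    """
    d = np.asarray(d, dtype=np.float64)
    if d.shape != filt.shape:
        raise ValidationError(f"image shape {d.shape} does not match filter grid {filt.shape}")
    if not np.all(np.isfinite(d)):
        raise ValidationError("input frame contains NaN or Inf")
    if clamp_negative is None:
        clamp_negative = filt.spec.clamp_negative
    out_c = np.fft.ifft2(np.fft.fft2(d) * (1.0 - filt.w))
    out = out_c.real
    if clamp_negative:
        neg = out < 0
        if np.any(neg):
            clipped = -out[neg].sum()
            total = np.abs(out).sum()
            log.debug("clamped %.3g of flux (fraction %.3g)", clipped, clipped / max(total, 1e-30))
            out = np.where(neg, 0.0, out)
    return out


def filter_stack(
    stack: RawSIMStack,
    filt: BackgroundFilter,
    offset: float = 0.0,
    clamp_negative: bool = False,
) -> RawSIMStack:
    """Apply the background filter to every frame of a raw stack.

    The camera offset is removed first — a constant offset would otherwise
    be scaled by ``1 − W(0)`` and corrupt intensity linearity.
    """
    out = np.empty_like(stack.frames)
    for a in range(stack.n_angles):
        for p in range(stack.n_phases):
            try:
                out[a, p] = filter_image(stack.frames[a, p] - offset, filt, clamp_negative)
            except ValidationError as exc:
                raise ValidationError(f"frame (angle={a}, phase={p}): {exc}") from exc
    meta = dict(stack.meta)
    meta["background_filter"] = {
        "w_dc": filt.dc_fraction,
        "offset_subtracted": offset,
        "clamp_negative": clamp_negative,
    }
    return RawSIMStack(out, stack.pixel_nm, patterns_truth=stack.patterns_truth, meta=meta)
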