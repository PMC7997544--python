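"""Theoretical PSF construction, Richardson-Lucy deconvolution and Z projection.

The point-spread function is modelled as a separable Gaussian discretized on
the voxel grid, with widths set by the standard diffraction-limited
approximations

    sigma_lateral = 0.21 * lambda / NA
    sigma_axial   = 0.66 * lambda * n / NA**2

where ``lambda`` is the emission wavelength, ``NA`` the numerical aperture
and ``n`` the refractive index of the immersion medium.  This is adequate for
isolated sub-diffraction puncta such as single virions on glass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as spfft
from scipy.special import erf

__all__ = ["PSFModel", "theoretical_psf", "richardson_lucy", "max_project"]


def _pixel_integrated_gaussian(sigma_px: float, radius: int, center: float = 0.0) -> np.ndarray:
    """1-D Gaussian mass integrated over unit pixels centred on integers.

    Returns weights for offsets -radius..radius relative to ``center``
    (in pixel units).  Integrating over the pixel extent rather than sampling
    the density keeps total flux exact for any sub-pixel ``center``.
    """
    i = np.arange(-radius, radius + 1, dtype=float)
    s = max(float(sigma_px), 1e-6) * np.sqrt(2.0)
    return 0.5 * (erf((i + 0.5 - center) / s) - erf((i - 0.5 - center) / s))


@dataclass(frozen=True)
class PSFModel:
    """Discretized 3-D Gaussian PSF with its physical parameters."""

    numerical_aperture: float
    emission_wavelength_um: float
    pixel_size_um: float
    z_step_um: float
    sigma_lateral_um: float
    sigma_axial_um: float
    kernel: np.ndarray = field(repr=False)  # (Z, Y, X), non-negative, sums to 1

    @property
    def sigma_lateral_px(self) -> float:
        return self.sigma_lateral_um / self.pixel_size_um

    @property
    def sigma_axial_planes(self) -> float:
        return self.sigma_axial_um / self.z_step_um


def theoretical_psf(
    numerical_aperture: float,
    emission_wavelength_um: float,
    pixel_size_um: float,
    z_step_um: float,
    refractive_index: float = 1.515,
    truncate: float = 3.0,
    shape_limit: tuple[int, int, int] | None = None,
) -> PSFModel:
    """Build a diffraction-limited Gaussian PSF on the voxel grid.

    Parameters
    ----------
    numerical_aperture : objective NA; must be below ``refractive_index``.
    emission_wavelength_um : emission wavelength in micrometres (0.3-0.8).
    pixel_size_um, z_step_um : voxel pitch.
    refractive_index : immersion medium index (oil default).
    truncate : kernel half-width in sigmas per axis.
    shape_limit : optional (Z, Y, X) support limit, e.g. the image shape;
        the kernel is truncated to fit and renormalized.  A limit too small
        to hold even a minimal 3-voxel support is refused.
    """
    if not 0 < numerical_aperture < refractive_index:
        raise ValueError(
            f"numerical_aperture must lie in (0, {refractive_index}); got {numerical_aperture}"
        )
    if not 0.3 < emission_wavelength_um < 0.8:
        raise ValueError(f"emission wavelength {emission_wavelength_um} um outside (0.3, 0.8)")
    if pixel_size_um <= 0 or z_step_um <= 0:
        raise ValueError("voxel pitch must be positive")

    sigma_lat = 0.21 * emission_wavelength_um / numerical_aperture
    sigma_ax = 0.66 * emission_wavelength_um * refractive_index / numerical_aperture**2

    s_xy = sigma_lat / pixel_size_um
    s_z = sigma_ax / z_step_um
    r_xy = max(1, int(np.ceil(truncate * s_xy)))
    r_z = max(1, int(np.ceil(truncate * s_z)))
    if shape_limit is not None:
        lim_z, lim_y, lim_x = shape_limit
        if min(lim_z, lim_y, lim_x) < 3:
            raise ValueError(f"kernel support cannot fit in image shape {shape_limit}")
        r_z = min(r_z, (lim_z - 1) // 2)
        r_xy = min(r_xy, (min(lim_y, lim_x) - 1) // 2)

    wx = _pixel_integrated_gaussian(s_xy, r_xy)
    wz = _pixel_integrated_gaussian(s_z, r_z)
    kernel = wz[:, None, None] * wx[None, :, None] * wx[None, None, :]
    kernel = np.clip(kernel, 0.0, None)
    kernel /= kernel.sum()

    return PSFModel(
        numerical_aperture=numerical_aperture,
        emission_wavelength_um=emission_wavelength_um,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        sigma_lateral_um=sigma_lat,
        sigma_axial_um=sigma_ax,
        kernel=kernel,
    )


def _centered_otf(kernel: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Embed a small centred kernel into ``shape`` and return its rFFT."""
    padded = np.zeros(shape, dtype=np.float64)
    slices = tuple(slice(0, s) for s in kernel.shape)
    padded[slices] = kernel
    # shift kernel centre to the origin so convolution is centred
    shifts = tuple(-(s // 2) for s in kernel.shape)
    padded = np.roll(padded, shifts, axis=tuple(range(padded.ndim)))
    return spfft.rfftn(padded)


def richardson_lucy(image: np.ndarray, psf, n_iter: int = 15) -> np.ndarray:
    """Richardson-Lucy restoration with reflective boundary padding.

    The multiplicative update is applied on an image padded reflectively by
    one kernel radius per axis, which suppresses edge ringing; the pad is
    stripped before returning.  Convolutions run in Fourier space with the
    kernel transform computed once.

    Parameters
    ----------
    image : non-negative photon-count array (2-D or 3-D), same rank as PSF.
    psf : :class:`PSFModel` or raw kernel array.
    n_iter : number of multiplicative updates (>= 1).
    """
    kernel = psf.kernel if isinstance(psf, PSFModel) else np.asarray(psf, dtype=float)
    img = np.asarray(image, dtype=np.float64)
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if kernel.ndim != img.ndim:
        raise ValueError(f"PSF rank {kernel.ndim} does not match image rank {img.ndim}")
    ksum = kernel.sum()
    if ksum <= 0:
        raise ValueError("PSF must have positive sum")
    if np.any(np.asarray(kernel.shape) > np.asarray(img.shape)):
        raise ValueError(f"PSF support {kernel.shape} exceeds image size {img.shape}")
    if img.min() < 0:
        raise ValueError("image must be non-negative")
    kernel = kernel / ksum

    # reflective pad by one kernel radius, extended to FFT-friendly sizes
    pad = []
    for n, s in zip(img.shape, kernel.shape):
        lo = s // 2
        total = spfft.next_fast_len(n + 2 * lo, real=True)
        pad.append((lo, total - n - lo))
    padded = np.pad(img, pad, mode="reflect").astype(np.float32)
    otf = _centered_otf(kernel, padded.shape).astype(np.complex64)
    otf_conj = np.conj(otf)  # mirror kernel for a real PSF

    eps = np.float32(1e-9)
    est = padded.copy()
    for _ in range(n_iter):
        conv = spfft.irfftn(spfft.rfftn(est) * otf, s=padded.shape)
        ratio = padded / np.maximum(conv, eps)
        est *= spfft.irfftn(spfft.rfftn(ratio) * otf_conj, s=padded.shape)
        np.clip(est, 0.0, None, out=est)

    core = tuple(slice(p[0], est.shape[i] - p[1]) for i, p in enumerate(pad))
    return est[core].astype(np.float64)


def max_project(stack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection along Z (axis 0 of a Z,Y,X stack)."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack.copy()
    if stack.ndim != 3:
        raise ValueError(f"expected a (Z, Y, X) stack, got rank {stack.ndim}")
    return stack.max(axis=0)
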