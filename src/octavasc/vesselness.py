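"""Multi-scale Hessian enhancement of tubular structures.

Bright tubes in a 3D image have a characteristic second-derivative
signature at a Gaussian scale matched to their radius: one eigenvalue of
the Hessian near zero (along the axis) and two strongly negative
eigenvalues (across the lumen). The classic ridge functional combines
three geometric ratios of the |.|-sorted eigenvalues |l1| <= |l2| <= |l3|:

    R_A = |l2| / |l3|            plate vs line discrimination
    R_B = |l1| / sqrt(|l2 l3|)   blob discrimination
    S   = sqrt(l1^2 + l2^2 + l3^2)   structure strength

    V = 0                                     if l2 > 0 or l3 > 0
    V = (1 - exp(-R_A^2 / 2 a^2))
        * exp(-R_B^2 / 2 b^2)
        * (1 - exp(-S^2 / 2 c^2))             otherwise

evaluated over a ladder of physical scales; the response is the maximum
over scales and ``best_scale`` records the argmax (ties broken toward the
smallest scale). Anisotropic voxels are handled by per-axis Gaussian
sigmas in voxel units (sigma_axis = sigma_um / spacing_axis), with
gamma = 2 normalization (Hessian multiplied by sigma^2) so responses are
comparable across scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .reconstruction import OCTAVolume

__all__ = ["VesselnessVolume", "hessian_eigenvalues", "multiscale_vesselness"]

DEFAULT_SCALES_UM = (7.5, 15.0, 30.0, 60.0)


@dataclass
class VesselnessVolume:
    """Multi-scale tubularity response in [0, 1] with the per-voxel best scale."""

    response: np.ndarray
    best_scale: np.ndarray
    scales_used: tuple[float, ...]
    voxel_size: tuple[float, float, float]


def hessian_eigenvalues(
    volume: np.ndarray,
    voxel_size: tuple[float, float, float],
    sigma_um: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigenvalues of the scale-normalized Hessian, sorted by magnitude.

    The Hessian is computed from Gaussian-derivative smoothing at physical
    scale ``sigma_um`` (per-axis sigma in voxels = sigma_um / spacing),
    converted to physical second derivatives (1/um^2) and multiplied by
    sigma_um^2 (gamma = 2 normalization).  Returns (l1, l2, l3) with
    |l1| <= |l2| <= |l3| at every voxel.

    Raises if ``sigma_um`` is smaller than the largest voxel dimension
    (the derivative would be undersampled).
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError("expected a 3D volume")
    spacing = np.asarray(voxel_size, dtype=float)
    if sigma_um < spacing.max():
        raise ValueError(
            f"sigma {sigma_um} um is below the largest voxel dimension "
            f"{spacing.max()} um; the derivative kernel would be undersampled"
        )
    sig_vox = sigma_um / spacing

    axes = ((0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2))
    H = np.empty(volume.shape + (3, 3), dtype=np.float64)
    smooth0 = None
    for i, j in axes:
        order = [0, 0, 0]
        order[i] += 1
        order[j] += 1
        d = ndimage.gaussian_filter(volume, sigma=sig_vox, order=order, mode="nearest")
        if i == j:
            # the truncated order-2 kernel does not sum exactly to zero,
            # which leaks a multiple of the smoothed volume into the
            # second derivative (nonzero Hessian on constants); subtract it
            if smooth0 is None:
                smooth0 = ndimage.gaussian_filter(volume, sigma=sig_vox, mode="nearest")
            d -= _second_derivative_kernel_sum(sig_vox[i]) * smooth0
        d /= spacing[i] * spacing[j]  # voxel-index derivative -> physical 1/um^2
        d *= sigma_um * sigma_um  # gamma = 2 scale normalization
        H[..., i, j] = d
        H[..., j, i] = d

    eig = np.linalg.eigvalsh(H)  # ascending by value
    order = np.argsort(np.abs(eig), axis=-1)
    eig = np.take_along_axis(eig, order, axis=-1)
    return eig[..., 0], eig[..., 1], eig[..., 2]


def _second_derivative_kernel_sum(sigma_vox: float) -> float:
    """Sum of scipy's truncated 1D order-2 Gaussian derivative kernel."""
    n = max(int(4.0 * sigma_vox + 0.5), 1)
    ones = np.ones(4 * n + 1)
    resp = ndimage.gaussian_filter1d(ones, sigma=sigma_vox, order=2, mode="nearest")
    return float(resp[2 * n])


def _frangi_response(l1, l2, l3, alpha, beta, c):
    """Bright-tube vesselness from |.|-sorted eigenvalues; safe at l3 = 0."""
    a2 = np.abs(l2)
    a3 = np.abs(l3)
    # absolute floor: second derivatives at machine-noise level (e.g. a
    # constant volume) must not be normalized up by the data-adaptive c
    structured = a3 > 1e-10
    a3_safe = np.where(structured, a3, 1.0)
    ra2 = (a2 / a3_safe) ** 2
    rb2 = l1 * l1 / np.where(structured, a2 * a3, 1.0)
    s2 = l1 * l1 + l2 * l2 + l3 * l3
    if c is None or (isinstance(c, str) and c == "auto"):
        smax = np.sqrt(s2.max())
        c_val = smax / 2.0 if smax > 0 else 1.0
    else:
        c_val = float(c)
    v = (
        (1.0 - np.exp(-ra2 / (2.0 * alpha * alpha)))
        * np.exp(-rb2 / (2.0 * beta * beta))
        * (1.0 - np.exp(-s2 / (2.0 * c_val * c_val)))
    )
    v = np.where((l2 > 0) | (l3 > 0) | ~structured, 0.0, v)
    return v


def multiscale_vesselness(
    octa: OCTAVolume | np.ndarray,
    scales_um=DEFAULT_SCALES_UM,
    alpha: float = 0.5,
    beta: float = 0.5,
    c="auto",
    voxel_size=None,
) -> VesselnessVolume:
    """Maximum bright-tube vesselness over a ladder of physical scales.

    Parameters
    ----------
    octa : OCTAVolume or ndarray
        Input volume (the flow decorrelation map in the standard
        pipeline). A bare array requires ``voxel_size``.
    scales_um : sequence of float
        Gaussian scales in micrometers; each must be at least the largest
        voxel dimension.
    alpha, beta : float
        Sensitivities of the plate and blob discriminants.
    c : float or "auto"
        Structure-strength sensitivity; "auto" uses half the maximum
        structure norm S observed in the volume at each scale.
    """
    if isinstance(octa, OCTAVolume):
        data = octa.decorrelation
        voxel_size = octa.voxel_size
    else:
        data = np.asarray(octa, dtype=float)
        if voxel_size is None:
            raise ValueError("voxel_size required when passing a bare array")
    scales = tuple(float(s) for s in scales_um)
    if len(scales) == 0:
        raise ValueError("scale list must be non-empty")

    response = np.zeros(data.shape, dtype=np.float64)
    best_scale = np.full(data.shape, min(scales), dtype=np.float64)
    for s in sorted(scales):
        l1, l2, l3 = hessian_eigenvalues(data, voxel_size, s)
        v = _frangi_response(l1, l2, l3, alpha, beta, c)
        better = v > response  # strict: ties keep the smaller scale
        best_scale[better] = s
        np.maximum(response, v, out=response)
    np.clip(response, 0.0, 1.0, out=response)
    return VesselnessVolume(
        response=response,
        best_scale=best_scale,
        scales_used=scales,
        voxel_size=tuple(float(v) for v in voxel_size),
    )
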