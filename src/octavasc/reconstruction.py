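"""OCT angiography reconstruction from repeated intensity scans.

A 4D OCT acquisition records the same volume N times; static tissue
produces a nearly identical speckle pattern in every frame, whereas voxels
containing moving scatterers (blood) decorrelate between consecutive
frames. The angiogram is the per-voxel mean amplitude decorrelation

    D = (1/(N-1)) * sum_n [ 1 - 2*I_n*I_{n+1} / (I_n^2 + I_{n+1}^2) ]

over the N-1 consecutive frame pairs. Each pairwise term lies in [0, 1]
(it is 1 minus a normalized product of the two intensities), is invariant
to a global intensity rescaling, and equals 0 for identical frames and 1
when one frame of a pair is dark while the other is bright.

Dark voxels carry no usable flow information, so voxels whose time-mean
intensity falls below a noise floor (a percentile of the time-mean
distribution) are flagged and forced to zero decorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["OCTVolume4D", "OCTAVolume", "estimate_noise_floor", "compute_decorrelation"]


@dataclass
class OCTVolume4D:
    """Time-resolved OCT intensity scan.

    Parameters
    ----------
    data : ndarray, shape (t, z, y, x)
        Non-negative intensities; at least two frames.
    voxel_size : tuple of float
        Physical voxel spacing (dz, dy, dx) in micrometers.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (t, z, y, x) data, got ndim={self.data.ndim}")
        if self.data.shape[0] < 2:
            raise ValueError("need at least 2 frames for decorrelation")
        if np.any(self.data < 0):
            raise ValueError("OCT intensities must be non-negative")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive spacings (dz, dy, dx)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]


@dataclass
class OCTAVolume:
    """Flow decorrelation map with low-SNR suppression.

    ``decorrelation`` is in [0, 1] for every voxel and is forced to 0
    wherever ``low_snr_mask`` is set (time-mean intensity below
    ``noise_floor``).
    """

    decorrelation: np.ndarray
    low_snr_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        self.decorrelation = np.asarray(self.decorrelation, dtype=float)
        self.low_snr_mask = np.asarray(self.low_snr_mask, dtype=bool)
        if self.decorrelation.shape != self.low_snr_mask.shape:
            raise ValueError("decorrelation and low_snr_mask shapes differ")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)


def estimate_noise_floor(volume: OCTVolume4D, percentile: float = 0.5) -> float:
    """Intensity threshold below which decorrelation is unreliable.

    Returns the given percentile (fraction in (0, 1), linear-interpolation
    convention) of the distribution of per-voxel time-mean intensities.

    A constant-zero volume yields 0 with a warning.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must lie strictly between 0 and 1")
    tmean = volume.data.mean(axis=0)
    if not np.any(tmean > 0):
        warnings.warn("volume is identically zero; noise floor set to 0", stacklevel=2)
        return 0.0
    return float(np.quantile(tmean, percentile))


def compute_decorrelation(volume: OCTVolume4D, noise_floor: float = 0.0) -> OCTAVolume:
    """Mean pairwise amplitude decorrelation across consecutive frames.

    A pair with both intensities zero contributes 0 (no evidence of flow).
    Voxels with time-mean intensity strictly below ``noise_floor`` are
    flagged in ``low_snr_mask`` and their decorrelation is set to 0.
    """
    frames = np.asarray(volume.data, dtype=np.float64)
    n = frames.shape[0]
    a = frames[:-1]
    b = frames[1:]
    denom = a * a + b * b
    with np.errstate(divide="ignore", invalid="ignore"):
        pair = 1.0 - np.where(denom > 0, 2.0 * a * b / np.where(denom > 0, denom, 1.0), 1.0)
    d = pair.sum(axis=0) / (n - 1)
    np.clip(d, 0.0, 1.0, out=d)

    tmean = frames.mean(axis=0)
    low_snr = tmean < noise_floor
    d[low_snr] = 0.0
    return OCTAVolume(
        decorrelation=d,
        low_snr_mask=low_snr,
        voxel_size=volume.voxel_size,
        noise_floor=float(noise_floor),
    )
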