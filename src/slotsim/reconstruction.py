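"""Filtered back projection of rotational projection series.

Standard parallel-beam FBP: each sinogram row is convolved (in the
frequency domain) with a ramp-family kernel, the filtered projections are
smeared back across the slice over all angles, and the sum is scaled by
π/(2·n_angles).  The discrete ramp kernel follows the classical
band-limited construction (unit-area central tap 1/4, odd taps −1/(π n)²),
which removes the DC component and restores amplitudes so that
FBP(Radon(f)) ≈ f.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import sparse

from .acquisition import ProjectionSeries, Sinogram

FILTERS = ("ramp", "shepp-logan", "none")


@dataclass(frozen=True)
class ReconstructedVolume:
    """A stack of FBP-reconstructed transverse slices, top slice first."""

    data: np.ndarray  # (detector_height, W, W)
    voxel_pitch: float  # mm
    time: float  # h
    channel: str
    filter_name: str

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.shape[1] != self.data.shape[2]:
            raise ValueError("reconstructed volume must be (n_slices, W, W)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("reconstructed volume must be finite")


def fourier_ramp_filter(width: int, filter_name: str = "ramp") -> np.ndarray:
    """Frequency response (length ``width``) of the chosen ramp-family filter."""
    if filter_name not in FILTERS:
        raise ValueError(f"filter must be one of {FILTERS}")
    if filter_name == "none":
        return np.ones(width)
    # real-space band-limited ramp kernel
    n = np.concatenate(
        (np.arange(1, width / 2 + 1, 2, dtype=int), np.arange(width / 2 - 1, 0, -2, dtype=int))
    )
    f = np.zeros(width)
    f[0] = 0.25
    f[1::2] = -1.0 / (np.pi * n) ** 2
    response = 2.0 * np.real(np.fft.fft(f))
    if filter_name == "shepp-logan":
        omega = np.pi * np.fft.fftfreq(width)[1:]
        response[1:] *= np.sin(omega) / omega
    return response


def _padded_width(width: int) -> int:
    return max(64, int(2 ** np.ceil(np.log2(2 * width))))


def _filter_rows(rows: np.ndarray, filter_name: str) -> np.ndarray:
    """Convolve the last axis of ``rows`` with the chosen kernel via FFT."""
    width = rows.shape[-1]
    if filter_name == "none":
        return np.asarray(rows, dtype=np.float64)
    padded = _padded_width(width)
    response = fourier_ramp_filter(padded, filter_name)
    spectrum = np.fft.fft(rows, n=padded, axis=-1) * response
    return np.real(np.fft.ifft(spectrum, axis=-1))[..., :width]


def filter_sinogram(sino: Sinogram, filter_name: str = "ramp") -> Sinogram:
    """Ramp-family filter each angle's projection; ``none`` is the identity."""
    if filter_name not in FILTERS:
        raise ValueError(f"filter must be one of {FILTERS}")
    return Sinogram(
        data=_filter_rows(sino.data, filter_name),
        angles_deg=sino.angles_deg,
        slice_index=sino.slice_index,
    )


@lru_cache(maxsize=8)
def _backprojection_matrix(width: int, angles_key: tuple[float, ...]) -> sparse.csr_matrix:
    """Sparse operator mapping a flat (n_angles·W) filtered sinogram to a flat (W²) slice.

    Each output pixel at offset (x, y) from the slice center samples every
    angle's filtered projection (linear interpolation) at detector
    coordinate ``x·cosφ + y·sinφ`` — the adjoint of the forward projector's
    convention; the π/(2·n_angles) scale is folded into the weights.
    """
    n_angles = len(angles_key)
    center = (width - 1) / 2.0
    offsets = np.arange(width) - center
    x = offsets[None, :]
    y = offsets[:, None]
    pixel_rows = np.arange(width * width)
    scale = np.pi / (2.0 * n_angles)
    rows_all, cols_all, data_all = [], [], []
    for i, ang in enumerate(angles_key):
        phi = np.deg2rad(ang)
        s = (x * np.cos(phi) + y * np.sin(phi) + center).ravel()
        inside = (s >= 0) & (s <= width - 1)
        lo = np.clip(np.floor(s).astype(np.int64), 0, width - 1)
        hi = np.clip(lo + 1, 0, width - 1)
        frac = np.clip(s - lo, 0.0, 1.0)
        for idx, w in ((lo, 1.0 - frac), (hi, frac)):
            valid = inside & (w > 0)
            rows_all.append(pixel_rows[valid])
            cols_all.append(i * width + idx[valid])
            data_all.append(scale * w[valid])
    mat = sparse.coo_matrix(
        (
            np.concatenate(data_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(width * width, n_angles * width),
    )
    return mat.tocsr()


def _backproject_stack(filtered: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Backproject (..., n_angles, W) filtered sinograms to (..., W, W) slices."""
    n_angles = len(angles_deg)
    if n_angles == 0:
        raise ValueError("at least one projection angle is required")
    width = filtered.shape[-1]
    mat = _backprojection_matrix(width, tuple(float(a) for a in angles_deg))
    lead = filtered.shape[:-2]
    flat = np.asarray(filtered, dtype=np.float64).reshape(-1, n_angles * width)
    recon = (mat @ flat.T).T
    return recon.reshape(lead + (width, width))


def backproject(filtered: Sinogram) -> np.ndarray:
    """Backproject one filtered sinogram into a square (W × W) slice."""
    return _backproject_stack(filtered.data, filtered.angles_deg)


def fbp_slice(sino: Sinogram, filter_name: str = "ramp") -> np.ndarray:
    """Convenience: filter then backproject one sinogram."""
    return backproject(filter_sinogram(sino, filter_name))


def _circle_mask(width: int) -> np.ndarray:
    center = (width - 1) / 2.0
    offsets = np.arange(width) - center
    return offsets[None, :] ** 2 + offsets[:, None] ** 2 <= (width / 2.0) ** 2


def reconstruct_volume(
    series: ProjectionSeries,
    filter_name: str = "ramp",
    clamp_negative: bool = True,
) -> ReconstructedVolume:
    """FBP-reconstruct every transverse slice of a projection series.

    Slice ``h`` of the output is ``backproject(filter_sinogram(...))`` of
    detector row ``h``.  Values outside the inscribed reconstruction circle
    are set to 0; negative values are clamped to 0 by default (emission
    intensities are non-negative), switchable via ``clamp_negative``.
    """
    g = series.geometry
    # (n_angles, H, W) -> (H, n_angles, W) so the FFT batches over slices
    sinos = np.ascontiguousarray(np.moveaxis(series.data, 1, 0))
    filtered = _filter_rows(sinos, filter_name)
    volume = _backproject_stack(filtered, g.angles_deg)
    volume *= _circle_mask(g.detector_width)
    if clamp_negative:
        np.maximum(volume, 0.0, out=volume)
    return ReconstructedVolume(
        data=volume.astype(np.float32),
        voxel_pitch=g.pixel_pitch,
        time=series.time,
        channel=series.channel,
        filter_name=filter_name,
    )
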