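"""Rotational parallel-beam projection of emission volumes.

Image formation model: the sample rotates about the implant axis while the
detector records, for each angle, the line integral of emission along
parallel rays (no attenuation, no depth-dependent point-spread function).
Detector row ``h`` sees transverse slice ``h``; the detector coordinate of a
point at transverse offset (x, y) from the rotation axis is
``s = x·cosφ + y·sinφ`` at rotation angle φ (degrees, counter-clockwise,
0° along +x, with x the column offset and y the row offset of the slice).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
from scipy import sparse

from .config import AcquisitionGeometry
from .phantom import EmissionVolume


@dataclass(frozen=True)
class Sinogram:
    """Projections of one transverse slice, rows ordered by angle."""

    data: np.ndarray  # (n_angles, detector_width)
    angles_deg: np.ndarray
    slice_index: int = 0

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.angles_deg):
            raise ValueError("sinogram rows must match the angle list")


@dataclass(frozen=True)
class ProjectionSeries:
    """One channel's projection stack: (n_angles, detector_height, detector_width)."""

    data: np.ndarray
    geometry: AcquisitionGeometry
    channel: str
    time: float  # h

    def __post_init__(self) -> None:
        g = self.geometry
        expected = (g.n_angles, g.detector_height, g.detector_width)
        if self.data.shape != expected:
            raise ValueError(f"projection stack shape {self.data.shape} != {expected}")

    def sinogram(self, slice_index: int) -> Sinogram:
        """The sinogram of one transverse slice (one detector row)."""
        return Sinogram(
            data=np.ascontiguousarray(self.data[:, slice_index, :]),
            angles_deg=self.geometry.angles_deg,
            slice_index=slice_index,
        )


@lru_cache(maxsize=8)
def _projection_matrix(width: int, angles_key: tuple[float, ...]) -> sparse.csr_matrix:
    """Sparse operator mapping a flat (W²) slice to a flat (n_angles·W) sinogram.

    For angle φ and detector bin s the ray {x·cosφ + y·sinφ = s} is sampled
    at W points with unit step; each sample contributes its four bilinear
    neighbor weights.  Precomputing the operator makes projecting a whole
    volume a single sparse mat-mat product, reused across channels and
    time points.
    """
    center = (width - 1) / 2.0
    offsets = np.arange(width) - center
    s_grid = offsets[None, :]  # detector coordinate
    u_grid = offsets[:, None]  # position along the ray
    rows_all, cols_all, data_all = [], [], []
    for i, ang in enumerate(angles_key):
        phi = np.deg2rad(ang)
        xs = (s_grid * np.cos(phi) - u_grid * np.sin(phi) + center).ravel()
        ys = (s_grid * np.sin(phi) + u_grid * np.cos(phi) + center).ravel()
        det_rows = i * width + np.broadcast_to(np.arange(width)[None, :], (width, width)).ravel()
        ix0 = np.floor(xs).astype(np.int64)
        iy0 = np.floor(ys).astype(np.int64)
        fx = xs - ix0
        fy = ys - iy0
        for dy, dx, w in (
            (0, 0, (1 - fy) * (1 - fx)),
            (0, 1, (1 - fy) * fx),
            (1, 0, fy * (1 - fx)),
            (1, 1, fy * fx),
        ):
            iy, ix = iy0 + dy, ix0 + dx
            valid = (ix >= 0) & (ix < width) & (iy >= 0) & (iy < width) & (w > 0)
            rows_all.append(det_rows[valid])
            cols_all.append(iy[valid] * width + ix[valid])
            data_all.append(w[valid])
    mat = sparse.coo_matrix(
        (
            np.concatenate(data_all),
            (np.concatenate(rows_all), np.concatenate(cols_all)),
        ),
        shape=(len(angles_key) * width, width * width),
    )
    return mat.tocsr()


def _project(volume_or_slice: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Discrete line-integral projections (bilinear ray sampling).

    A point at transverse offset (x, y) from the slice center appears at
    detector coordinate ``x·cosφ + y·sinφ`` for rotation angle φ.  Works on
    a 2D slice or a (nz, ny, nx) volume; returns (n_angles, width) or
    (n_angles, nz, width).
    """
    arr = np.asarray(volume_or_slice, dtype=np.float64)
    width = arr.shape[-1]
    mat = _projection_matrix(width, tuple(float(a) for a in angles_deg))
    flat = arr.reshape(-1, width * width)  # (n_slices, W²)
    sino = mat @ flat.T  # (n_angles·W, n_slices)
    n_angles = len(angles_deg)
    if arr.ndim == 2:
        return sino[:, 0].reshape(n_angles, width).astype(np.float32)
    nz = arr.shape[0]
    return np.ascontiguousarray(
        sino.reshape(n_angles, width, nz).transpose(0, 2, 1)
    ).astype(np.float32)


def project_slice(slice_2d: np.ndarray, angles_deg) -> Sinogram:
    """Sinogram of one square transverse slice with the rotation axis at its center."""
    slice_2d = np.asarray(slice_2d)
    if slice_2d.ndim != 2 or slice_2d.shape[0] != slice_2d.shape[1]:
        raise ValueError("slice must be square with the rotation axis at its center")
    angles = np.asarray(angles_deg, dtype=float)
    return Sinogram(data=_project(slice_2d, angles), angles_deg=angles)


def acquire_projections(
    live: EmissionVolume,
    dead: EmissionVolume,
    geometry: AcquisitionGeometry,
    rng: np.random.Generator | None = None,
) -> dict[str, ProjectionSeries]:
    """Project both channels; returns {"live": ..., "dead": ...}.

    Detector row ``h`` holds the sinogram of transverse slice ``h``.  Noise,
    if enabled in the geometry, is applied per channel with a generator
    derived from ``geometry.rng_seed`` unless one is passed in.
    """
    out: dict[str, ProjectionSeries] = {}
    if rng is None and geometry.noise_model != "none":
        rng = np.random.default_rng(np.random.SeedSequence(geometry.rng_seed).spawn(1)[0])
    for volume in (live, dead):
        nz, ny, nx = volume.data.shape
        if nx != geometry.detector_width or ny != geometry.detector_width:
            raise ValueError(
                f"transverse extent {ny}×{nx} does not match detector width "
                f"{geometry.detector_width}"
            )
        if nz != geometry.detector_height:
            raise ValueError(f"axial extent {nz} does not match detector height")
        series = ProjectionSeries(
            data=_project(volume.data, geometry.angles_deg),
            geometry=geometry,
            channel=volume.channel,
            time=volume.time,
        )
        if geometry.noise_model != "none":
            series = apply_noise(series, geometry, rng=rng)
        out[volume.channel] = series
    return out


def apply_noise(
    series: ProjectionSeries,
    geometry: AcquisitionGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> ProjectionSeries:
    """Apply the geometry's shot/readout noise model to a projection stack.

    ``poisson`` replaces each pixel by a Poisson draw with that pixel's mean;
    ``poisson+gaussian`` adds zero-mean Gaussian readout noise of
    ``gaussian_sigma`` on top.  Output is clamped at 0.
    """
    geometry = geometry or series.geometry
    if np.any(series.data < 0):
        raise ValueError("noise model requires non-negative projection values")
    if geometry.noise_model == "none":
        return series
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(geometry.rng_seed).spawn(1)[0])
    noisy = rng.poisson(series.data.astype(np.float64)).astype(np.float32)
    if geometry.noise_model == "poisson+gaussian":
        noisy = noisy + rng.normal(0.0, geometry.gaussian_sigma, size=noisy.shape).astype(
            np.float32
        )
    return replace(series, data=np.maximum(noisy, 0.0))
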