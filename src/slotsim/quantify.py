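"""Maximum intensity projections and width-averaged axial profiles.

The readout mimics the study's quantification: a side-view maximum
intensity projection (MIP) of each reconstructed volume, an axial profile
obtained by averaging the MIP over the full implant width, and a single
max-to-1 normalization applied per channel across the whole time series
(so that the dead-stain profiles can grow toward the live-stain
distribution over time instead of each being rescaled independently).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.filters import threshold_otsu

from .config import ScenarioConfig


@dataclass(frozen=True)
class AxialProfile:
    """Width-averaged intensity versus top-down axial position."""

    positions: np.ndarray  # mm, uniformly spaced from 0, top-down
    intensities: np.ndarray  # a.u. >= 0
    channel: str
    time: float  # h

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.intensities):
            raise ValueError("positions and intensities must have equal length")
        if len(self.positions) and (
            self.positions[0] != 0.0 or np.any(np.diff(self.positions) <= 0)
        ):
            raise ValueError("positions must increase strictly from 0")


@dataclass(frozen=True)
class ProfileSeries:
    """One channel's axial profiles over time on a common position grid."""

    times: np.ndarray  # h, strictly increasing
    positions: np.ndarray  # mm
    intensities: np.ndarray  # (n_times, n_positions)
    channel: str
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.intensities.shape != (len(self.times), len(self.positions)):
            raise ValueError("intensity matrix shape must be (n_times, n_positions)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def profile(self, i: int) -> AxialProfile:
        return AxialProfile(self.positions, self.intensities[i], self.channel, float(self.times[i]))

    @classmethod
    def from_profiles(cls, profiles: list[AxialProfile], normalized: bool = False) -> "ProfileSeries":
        if not profiles:
            raise ValueError("at least one profile is required")
        positions = profiles[0].positions
        for p in profiles[1:]:
            if len(p.positions) != len(positions) or not np.allclose(p.positions, positions):
                raise ValueError("profiles must share one position grid")
            if p.channel != profiles[0].channel:
                raise ValueError("profiles must share one channel")
        return cls(
            times=np.array([p.time for p in profiles], dtype=float),
            positions=np.asarray(positions, dtype=float),
            intensities=np.stack([p.intensities for p in profiles]).astype(float),
            channel=profiles[0].channel,
            normalized=normalized,
        )


def max_intensity_projection(volume: np.ndarray, axis: int = 1) -> np.ndarray:
    """Per-pixel maximum of a 3D volume along ``axis``.

    The default axis 1 collapses one transverse horizontal direction of a
    (z, y, x) volume, giving the (height × width) side view used for the
    axial profiles.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.size == 0:
        raise ValueError("a non-empty 3D volume is required")
    return volume.max(axis=axis)


def implant_roi(mip: np.ndarray, config: ScenarioConfig) -> tuple[int, int]:
    """Half-open column interval [lo, hi) spanning the implant diameter.

    Derived from the known geometry: center column ``floor(W/2)``,
    half-width ``round(radius / pitch)`` columns.  Requires the implant to
    be centered on the rotation axis and to fit inside the image.
    """
    width = mip.shape[1]
    center = width // 2
    half = int(round(config.implant_radius / config.voxel_pitch))
    lo, hi = center - half, center + half
    if lo >= hi:
        raise ValueError("degenerate implant width (zero-column interval)")
    if lo < 0 or hi > width:
        raise ValueError("implant wider than the image")
    return lo, hi


def implant_roi_otsu(live_mip: np.ndarray) -> tuple[int, int]:
    """Threshold-based ROI fallback for externally produced volumes.

    Otsu-thresholds the live-channel MIP and returns the widest contiguous
    run of foreground columns.
    """
    fg_cols = (live_mip > threshold_otsu(live_mip)).any(axis=0)
    if not fg_cols.any():
        raise ValueError("no foreground columns found")
    best_lo = best_hi = lo = 0
    for i, v in enumerate(np.append(fg_cols, False)):
        if v and (i == 0 or not fg_cols[i - 1]):
            lo = i
        if not v and i > 0 and fg_cols[i - 1] and i - lo > best_hi - best_lo:
            best_lo, best_hi = lo, i
    return best_lo, best_hi


def axial_profile(
    mip: np.ndarray,
    roi: tuple[int, int],
    pixel_pitch: float,
    channel: str = "dead",
    time: float = 0.0,
) -> AxialProfile:
    """Average the MIP over the implant-width columns, top-down.

    Row ``h`` of the image maps to axial position ``h · pixel_pitch``.
    """
    lo, hi = roi
    if lo >= hi or lo < 0 or hi > mip.shape[1]:
        raise ValueError("ROI must be a non-empty column interval inside the image")
    return AxialProfile(
        positions=np.arange(mip.shape[0]) * pixel_pitch,
        intensities=mip[:, lo:hi].mean(axis=1),
        channel=channel,
        time=time,
    )


def normalize_series(series: ProfileSeries) -> ProfileSeries:
    """Scale a channel's whole time series so its global maximum is 1.

    A single maximum over all profiles and positions is used (not one per
    time point), so relative growth between time points is preserved.
    Idempotent; raises on an all-zero series.
    """
    peak = float(series.intensities.max(initial=0.0))
    if peak <= 0.0:
        raise ValueError("cannot normalize an all-zero profile series")
    return replace(series, intensities=series.intensities / peak, normalized=True)
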