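"""Time-resolved two-channel emission phantom of a cell-colonized implant.

Cells adhere to the lateral surface of a cylindrical implant standing on the
grid's central vertical axis.  Every cell emits in the live channel; once its
membrane is compromised by the toxicant it additionally emits in the dead
channel, attenuated by a photobleaching factor ``b`` for every dead-channel
exposure it has already experienced.

Coordinate convention: z = 0 at the implant top, increasing downward; voxel
``i`` spans the half-open interval [i·pitch, (i+1)·pitch) with its center at
(i + 0.5)·pitch.  Volumes are indexed ``(z, y, x)`` so that page 0 of an
exported stack is the top transverse slice.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, special

from .config import ScenarioConfig

CHANNELS = ("live", "dead")


@dataclass(frozen=True)
class EmissionVolume:
    """One channel's 3D emission intensity grid at one time point."""

    data: np.ndarray  # (nz, ny, nx), a.u. >= 0
    channel: str
    voxel_pitch: float  # mm
    time: float  # h

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")
        if self.data.ndim != 3:
            raise ValueError("emission grid must be 3-dimensional")
        if np.any(self.data < 0):
            raise ValueError("emission intensities must be non-negative")


@dataclass
class CellPopulation:
    """Surface-adherent cells parameterized by axial and angular position.

    ``compromise_time`` is NaN for live cells; the live→compromised
    transition is absorbing.  ``exposures`` counts dead-channel imaging
    exposures experienced since compromise (drives photobleaching).
    """

    z: np.ndarray  # mm, 0 = implant top
    theta: np.ndarray  # rad
    compromise_time: np.ndarray  # h, NaN = live
    exposures: np.ndarray  # int

    def __post_init__(self) -> None:
        n = len(self.z)
        if not (len(self.theta) == len(self.compromise_time) == len(self.exposures) == n):
            raise ValueError("per-cell arrays must share one length")

    @property
    def n_cells(self) -> int:
        return len(self.z)

    @property
    def compromised(self) -> np.ndarray:
        return ~np.isnan(self.compromise_time)

    def copy(self) -> "CellPopulation":
        return CellPopulation(
            self.z.copy(), self.theta.copy(), self.compromise_time.copy(), self.exposures.copy()
        )


def build_implant_mask(config: ScenarioConfig) -> np.ndarray:
    """Boolean voxel mask of the solid implant cylinder, shape (nz, ny, nx).

    A voxel belongs to the implant when its center lies within
    ``implant_radius`` of the central vertical axis and within the implant's
    axial extent.  An implant longer than the grid is cropped at the grid
    bottom.
    """
    nx, ny, nz = config.grid_shape
    pitch = config.voxel_pitch
    cx, cy = config.axis_center_mm
    x = (np.arange(nx) + 0.5) * pitch - cx
    y = (np.arange(ny) + 0.5) * pitch - cy
    z = (np.arange(nz) + 0.5) * pitch
    r2 = y[None, :, None] ** 2 + x[None, None, :] ** 2
    inside_r = r2 <= config.implant_radius**2
    inside_z = z <= config.implant_length
    return inside_r & inside_z[:, None, None]


def seed_cells(config: ScenarioConfig, rng: np.random.Generator | None = None) -> CellPopulation:
    """Place cells uniformly at random on the lateral cylinder surface.

    The count is Poisson with mean ``density · 2π r L``; all cells start
    live.  Reproducible for a fixed scenario seed (cell-seeding stream).
    """
    if config.cell_surface_density < 0:
        raise ValueError("cell_surface_density must be >= 0")
    if rng is None:
        rng = config.rng_streams()[0]
    area = 2.0 * np.pi * config.implant_radius * config.implant_length
    n = int(rng.poisson(config.cell_surface_density * area))
    z = rng.uniform(0.0, config.implant_length, size=n)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return CellPopulation(
        z=z,
        theta=theta,
        compromise_time=np.full(n, np.nan),
        exposures=np.zeros(n, dtype=np.int64),
    )


def toxicant_concentration(config: ScenarioConfig, z, t) -> np.ndarray | float:
    """Toxicant concentration (µM) at depth ``z`` (mm) and time ``t`` (h).

    diffusion mode: one-dimensional diffusion into a semi-infinite medium
    with a constant source C0 held at z = 0, i.e. C(z, t) = C0·erfc(z / (2√(D t))).
    constant_velocity mode: C0 behind the front (z ≤ v·t), 0 ahead of it.
    homogeneous_control mode: 0 everywhere.
    """
    z_arr = np.asarray(z, dtype=float)
    t_arr = np.asarray(t, dtype=float)
    if np.any(z_arr < 0) or np.any(t_arr < 0):
        raise ValueError("z and t must be non-negative")
    c0 = config.source_concentration
    if config.front_mode == "homogeneous_control":
        out = np.zeros(np.broadcast_shapes(z_arr.shape, t_arr.shape))
    elif config.front_mode == "constant_velocity":
        out = np.where(z_arr <= config.front_velocity * t_arr, c0, 0.0)
    elif config.front_mode == "diffusion":
        with np.errstate(divide="ignore", invalid="ignore"):
            arg = z_arr / (2.0 * np.sqrt(config.diffusion_coefficient * t_arr))
        # t = 0: concentration is C0 at the source plane, 0 below it
        arg = np.where((t_arr == 0) & (z_arr > 0), np.inf, arg)
        arg = np.where(np.isnan(arg), 0.0, arg)  # z = 0, t = 0
        out = c0 * special.erfc(arg)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"unknown front_mode {config.front_mode!r}")
    if np.isscalar(z) and np.isscalar(t):
        return float(out)
    return out


def update_cell_states(
    cells: CellPopulation,
    config: ScenarioConfig,
    t: float,
    rng: np.random.Generator | None = None,
) -> CellPopulation:
    """Advance membrane state to time ``t`` (absorbing live→compromised).

    Threshold kinetics: a live cell is compromised at ``t`` when the local
    toxicant concentration reaches ``death_threshold``.  In
    ``homogeneous_control`` mode each live cell instead dies with
    probability ``p_control`` per update (uniformly over the implant).
    """
    out = cells.copy()
    live = ~out.compromised
    if config.front_mode == "homogeneous_control":
        if rng is None:
            rng = config.rng_streams()[1]
        dies = live & (rng.random(out.n_cells) < config.p_control)
    else:
        conc = toxicant_concentration(config, out.z, float(t))
        dies = live & (np.asarray(conc) >= config.death_threshold)
    out.compromise_time[dies] = float(t)
    return out


def _deposit(config: ScenarioConfig, z, theta, weights) -> np.ndarray:
    """Accumulate per-cell point emissions into a (nz, ny, nx) grid.

    Cells past the grid bottom (possible when the implant is a fraction of
    a voxel longer than the grid) are folded into the bottom voxel row.
    """
    nx, ny, nz = config.grid_shape
    pitch = config.voxel_pitch
    cx, cy = config.axis_center_mm
    r = config.implant_radius
    x = cx + r * np.cos(theta)
    y = cy + r * np.sin(theta)
    ix = np.clip((x / pitch).astype(np.int64), 0, nx - 1)
    iy = np.clip((y / pitch).astype(np.int64), 0, ny - 1)
    iz = np.clip((z / pitch).astype(np.int64), 0, nz - 1)
    grid = np.zeros((nz, ny, nx), dtype=np.float64)
    np.add.at(grid, (iz, iy, ix), weights)
    return grid


def render_emission(
    cells: CellPopulation, config: ScenarioConfig, t: float
) -> tuple[EmissionVolume, EmissionVolume]:
    """Render the live and dead emission volumes at time ``t``.

    Every cell deposits ``live_intensity`` into the live channel; every
    compromised cell deposits ``dead_intensity · b**exposures`` into the
    dead channel.  Co-located deposits add.  An optional isotropic Gaussian
    blur (``blur_sigma_mm``) is applied per channel.
    """
    live_grid = _deposit(config, cells.z, cells.theta, np.full(cells.n_cells, config.live_intensity))
    dead = cells.compromised
    dead_weights = config.dead_intensity * config.bleach_factor ** cells.exposures[dead]
    dead_grid = _deposit(config, cells.z[dead], cells.theta[dead], dead_weights)
    if config.blur_sigma_mm > 0:
        sigma = config.blur_sigma_mm / config.voxel_pitch
        live_grid = ndimage.gaussian_filter(live_grid, sigma)
        dead_grid = ndimage.gaussian_filter(dead_grid, sigma)
    pitch = config.voxel_pitch
    return (
        EmissionVolume(live_grid.astype(np.float32), "live", pitch, float(t)),
        EmissionVolume(dead_grid.astype(np.float32), "dead", pitch, float(t)),
    )


def generate_timeseries(
    config: ScenarioConfig,
) -> list[tuple[float, EmissionVolume, EmissionVolume]]:
    """Simulate the full imaging time series.

    The live channel is imaged once (before the first dead-channel
    exposure) and reused at every time point; the dead channel is rendered
    at each time point, after which the exposure counter of every
    compromised cell is incremented — newly compromised cells therefore
    appear at full intensity and bleach on subsequent exposures.
    Deterministic for a fixed scenario seed.
    """
    seed_rng, control_rng, _ = config.rng_streams()
    cells = seed_cells(config, rng=seed_rng)
    live_volume: EmissionVolume | None = None
    series: list[tuple[float, EmissionVolume, EmissionVolume]] = []
    for t in config.time_points:
        cells = update_cell_states(cells, config, t, rng=control_rng)
        live, dead = render_emission(cells, config, t)
        if live_volume is None:
            live_volume = live
        cells.exposures[cells.compromised] += 1
        series.append((float(t), live_volume, dead))
    return series
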