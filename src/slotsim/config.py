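"""Scenario and acquisition configuration.

All lengths are millimetres, times are hours, concentrations are micromolar
and intensities are arbitrary units unless stated otherwise.  The default
scenario describes a Ø 3 mm × 30 mm titanium cylinder colonized by
fibroblast-like cells, embedded along the axis of a glass tube, with a
cytotoxic chlorhexidine bolus (400 µM) applied at the top at t = 0 and the
dead-stain channel imaged every 7 h from 0 to 63 h.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

FRONT_MODES = ("constant_velocity", "diffusion", "homogeneous_control")
NOISE_MODELS = ("none", "poisson", "poisson+gaussian")

#: default imaging cadence: every 7 h from 0 to 63 h (10 exposures)
DEFAULT_TIME_POINTS = tuple(float(t) for t in range(0, 64, 7))


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of one synthetic monitoring experiment.

    Parameters
    ----------
    implant_radius, implant_length
        Geometry of the cylindrical implant (mm).  A zero radius is the
        degenerate empty cylinder.
    tube_radius
        Radius of the surrounding sample tube (mm); only used for the
        sanity check ``implant_radius < tube_radius``.
    voxel_pitch
        Isotropic voxel edge length (mm/voxel).
    grid_shape
        ``(nx, ny, nz)`` voxel counts; the implant axis is the grid's
        central vertical (z) axis.
    cell_surface_density
        Mean surface density of adherent cells (cells/mm²).
    time_points
        Imaging times in hours, strictly increasing, first element 0.
    front_mode
        ``constant_velocity`` (sharp front moving at ``front_velocity``),
        ``diffusion`` (semi-infinite constant-source erfc profile with a
        concentration threshold), or ``homogeneous_control`` (no toxicant;
        spatially uniform random death at rate ``p_control`` per interval).
    source_concentration
        Toxicant concentration C0 maintained at the implant top (µM).
    diffusion_coefficient
        Toxicant diffusivity D in the hydrogel (mm²/h), diffusion mode.
    death_threshold
        Concentration above which a cell's membrane is compromised (µM).
    live_intensity, dead_intensity
        Emitted intensity per cell and channel (a.u./cell).
    bleach_factor
        Multiplicative dead-stain intensity retention per imaging exposure,
        0 < b ≤ 1 (b = 1 disables photobleaching).
    p_control
        Per-imaging-interval death probability of each live cell in
        ``homogeneous_control`` mode.
    blur_sigma_mm
        Optional isotropic Gaussian blur applied to each rendered channel
        (mm); 0 disables it.
    rng_seed
        Scenario seed; all stochastic draws derive from it (see
        :func:`ScenarioConfig.rng_streams`).
    """

    implant_radius: float = 1.5
    implant_length: float = 30.0
    tube_radius: float = 7.5
    voxel_pitch: float = 0.078
    grid_shape: tuple[int, int, int] = (96, 96, 384)
    cell_surface_density: float = 150.0
    time_points: tuple[float, ...] = DEFAULT_TIME_POINTS
    front_mode: str = "constant_velocity"
    front_velocity: float = 0.2
    source_concentration: float = 400.0
    diffusion_coefficient: float = 0.36
    death_threshold: float = 72.0
    live_intensity: float = 1.0
    dead_intensity: float = 1.0
    bleach_factor: float = 0.9
    p_control: float = 0.03
    blur_sigma_mm: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "time_points", tuple(float(t) for t in self.time_points))
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        if self.implant_radius < 0:
            raise ValueError("implant_radius must be >= 0")
        if self.implant_length <= 0 or self.tube_radius <= 0 or self.voxel_pitch <= 0:
            raise ValueError("implant_length, tube_radius and voxel_pitch must be > 0")
        if self.implant_radius >= self.tube_radius:
            raise ValueError("implant_radius must be smaller than tube_radius")
        if len(self.grid_shape) != 3 or any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be three positive voxel counts")
        nx, ny, nz = self.grid_shape
        half_extent = min(nx, ny) * self.voxel_pitch / 2.0
        if self.implant_radius > half_extent:
            raise ValueError(
                f"implant radius {self.implant_radius} mm exceeds the transverse "
                f"grid half-extent {half_extent:.3f} mm"
            )
        if len(self.time_points) < 1 or self.time_points[0] != 0.0:
            raise ValueError("time_points must start at 0")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time_points must be strictly increasing")
        if self.front_mode not in FRONT_MODES:
            raise ValueError(f"front_mode must be one of {FRONT_MODES}")
        if not 0.0 < self.bleach_factor <= 1.0:
            raise ValueError("bleach_factor must satisfy 0 < b <= 1")
        if self.cell_surface_density < 0:
            raise ValueError("cell_surface_density must be >= 0")
        if not 0.0 <= self.p_control <= 1.0:
            raise ValueError("p_control must be a probability")

    # -- derived geometry -------------------------------------------------

    @property
    def axis_center_mm(self) -> tuple[float, float]:
        """(x, y) of the rotation/implant axis, mm from the grid corner."""
        nx, ny, _ = self.grid_shape
        return nx * self.voxel_pitch / 2.0, ny * self.voxel_pitch / 2.0

    @property
    def axial_extent_mm(self) -> float:
        return self.grid_shape[2] * self.voxel_pitch

    def rng_streams(self) -> tuple[np.random.Generator, np.random.Generator, np.random.Generator]:
        """Derive the scenario's independent RNG streams.

        Stream-splitting rule: ``SeedSequence(rng_seed)`` is spawned into
        three children used, in order, for (0) cell seeding, (1) control-mode
        death draws, (2) acquisition noise.
        """
        children = np.random.SeedSequence(self.rng_seed).spawn(3)
        return tuple(np.random.default_rng(c) for c in children)  # type: ignore[return-value]

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["time_points"] = list(self.time_points)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Rotational parallel-beam acquisition parameters.

    The full-scale instrument acquires 1200 projections per 360° turn at
    8.5 µm/pixel on a 1000 × 3079 detector; the desk-scale default uses 120
    angles on a detector matched to the default scenario grid.
    """

    n_angles: int = 120
    detector_width: int = 96
    detector_height: int = 384
    pixel_pitch: float = 0.078
    noise_model: str = "none"
    gaussian_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be > 0")
        if self.detector_width < 1 or self.detector_height < 1:
            raise ValueError("detector dimensions must be >= 1")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"noise_model must be one of {NOISE_MODELS}")

    @property
    def angles_deg(self) -> np.ndarray:
        """Uniform angles over [0°, 360°), counter-clockwise."""
        return np.arange(self.n_angles) * (360.0 / self.n_angles)

    @classmethod
    def for_scenario(cls, config: ScenarioConfig, **overrides) -> "AcquisitionGeometry":
        """Geometry whose detector matches the scenario grid one-to-one."""
        nx, ny, nz = config.grid_shape
        if nx != ny:
            raise ValueError("scenario grid must be square in the transverse plane")
        defaults = dict(
            detector_width=nx,
            detector_height=nz,
            pixel_pitch=config.voxel_pitch,
            rng_seed=config.rng_seed,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def full_scale_geometry() -> AcquisitionGeometry:
    """The instrument-scale geometry (config constants, not a test default)."""
    return AcquisitionGeometry(
        n_angles=1200, detector_width=1000, detector_height=3079, pixel_pitch=0.0085
    )
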