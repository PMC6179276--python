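"""File formats: multi-page TIFF volumes, sidecar metadata, CSV tables.

Volumes and projection stacks travel as 32-bit float multi-page TIFF
(page 0 = top transverse slice, or first angle for projection stacks) with
a small YAML sidecar holding acquisition metadata.  Profiles, tracks and
assay tables are plain CSV; fit records and run manifests are JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .front import FrontTrack, VelocityFit
from .quantify import ProfileSeries

VOLUME_FILENAME = "{scenario}_{channel}_t{hours:03d}.tif"


def write_volume(path: str | Path, data: np.ndarray, metadata: dict | None = None) -> None:
    """Write a 3D grid as a 32-bit float multi-page TIFF, top slice first."""
    data = np.asarray(data)
    if data.ndim != 3 or data.shape[0] == 0:
        raise ValueError("a non-empty 3D grid (pages, rows, cols) is required")
    if not np.all(np.isfinite(data)):
        raise ValueError("volume contains non-finite values; refusing to write")
    # record the page count so truncated files are detectable on read
    meta = {"n_pages": int(data.shape[0]), **(metadata or {})}
    tifffile.imwrite(
        path, data.astype(np.float32), photometric="minisblack", description=json.dumps(meta)
    )


def read_volume(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF back into a (pages, rows, cols) float array.

    A corrupt or truncated file raises an error naming the failing page.
    """
    with tifffile.TiffFile(path) as tif:
        if len(tif.pages) == 0:
            raise ValueError(f"{path}: TIFF contains no pages")
        pages = []
        for i, page in enumerate(tif.pages):
            try:
                pages.append(page.asarray())
            except Exception as exc:  # pragma: no cover - depends on corruption kind
                raise IOError(f"{path}: failed reading page {i}: {exc}") from exc
        meta: dict = {}
        desc = tif.pages[0].tags.get("ImageDescription")
        if desc is not None:
            try:
                parsed = json.loads(desc.value)
                if isinstance(parsed, dict):
                    meta = parsed
            except (TypeError, ValueError):
                pass
    data = np.stack(pages)
    if data.ndim == 2:
        data = data[None]
    expected = meta.pop("n_pages", None)
    if expected is not None and data.shape[0] != expected:
        raise IOError(
            f"{path}: truncated volume — page {data.shape[0]} of {expected} missing"
        )
    return data, meta


def volume_path(outdir: str | Path, scenario: str, channel: str, hours: float) -> Path:
    return Path(outdir) / VOLUME_FILENAME.format(
        scenario=scenario, channel=channel, hours=int(round(hours))
    )


def write_sidecar(path: str | Path, metadata: dict) -> None:
    """YAML sidecar (angles, pitch, seed, ...) next to a projection stack."""
    Path(path).write_text(yaml.safe_dump(metadata, sort_keys=True))


def read_sidecar(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def profiles_to_csv(series_list: list[ProfileSeries], path: str | Path) -> pd.DataFrame:
    """Long-format profile table: time_h, position_mm, intensity, channel, normalized."""
    frames = []
    for series in series_list:
        t_grid, p_grid = np.meshgrid(series.times, series.positions, indexing="ij")
        frames.append(
            pd.DataFrame(
                {
                    "time_h": t_grid.ravel(),
                    "position_mm": p_grid.ravel(),
                    "intensity": series.intensities.ravel(),
                    "channel": series.channel,
                    "normalized": series.normalized,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False)
    return df


def profiles_from_csv(path: str | Path) -> list[ProfileSeries]:
    df = pd.read_csv(path)
    out = []
    for (channel, normalized), group in df.groupby(["channel", "normalized"], sort=False):
        pivot = group.pivot(index="time_h", columns="position_mm", values="intensity")
        out.append(
            ProfileSeries(
                times=pivot.index.to_numpy(dtype=float),
                positions=pivot.columns.to_numpy(dtype=float),
                intensities=pivot.to_numpy(dtype=float),
                channel=str(channel),
                normalized=bool(normalized),
            )
        )
    return out


def track_to_csv(track: FrontTrack, path: str | Path) -> None:
    pd.DataFrame({"time_h": track.times, "peak_mm": track.positions}).to_csv(path, index=False)


def track_from_csv(path: str | Path) -> FrontTrack:
    df = pd.read_csv(path)
    return FrontTrack(
        times=df["time_h"].to_numpy(dtype=float), positions=df["peak_mm"].to_numpy(dtype=float)
    )


def fit_record(fit: VelocityFit, label: str) -> dict:
    return {
        "slope_mm_per_h": fit.slope,
        "intercept_mm": fit.intercept,
        "r_squared": fit.r_squared,
        "n_points": fit.n_points,
        "label": label,
    }


def write_json(path: str | Path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
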