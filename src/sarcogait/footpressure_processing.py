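"""Plantar-pressure series to single-channel average images, plus augmentation.

The classification input is the time-averaged pressure image of a walking
sequence: one channel, non-negative values.  Training-time augmentation is
a horizontal flip with probability 0.5 and a rotation about the image
center (default: angle drawn from {-45, 0, +45} degrees; a fixed 45-degree
mode is available).  Validation/test images are never augmented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "PressureSeries",
    "PressureImage",
    "average_pressure",
    "augment_flip",
    "augment_rotate",
    "augment_image",
    "normalize_image",
    "read_pressure_series",
    "write_pressure_series",
    "write_pressure_image",
    "read_pressure_image_csv",
]


@dataclass
class PressureSeries:
    """``T x H x W`` non-negative pressure frames on a fixed sensor grid."""

    frames: np.ndarray
    grid_spacing_mm: float = 10.0
    participant_id: str = ""
    sequence_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be T x H x W, got {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise ValueError("series must contain at least one frame")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if np.any(self.frames < 0):
            raise ValueError("pressure values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape


@dataclass
class PressureImage:
    """Single-channel ``H x W`` non-negative pressure image."""

    pixels: np.ndarray
    label: str | None = None
    meta: dict = field(default_factory=dict)
    channel_count: int = 1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be H x W, got {self.pixels.shape}")
        if self.channel_count != 1:
            raise ValueError("pressure images are single-channel")
        if np.any(self.pixels < 0) or not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite and non-negative")


def average_pressure(series: PressureSeries) -> PressureImage:
    """Arithmetic mean over time of the series frames."""
    return PressureImage(
        pixels=series.frames.mean(axis=0),
        meta={"participant_id": series.participant_id,
              "sequence_id": series.sequence_id},
    )


def augment_flip(img: PressureImage, rng: np.random.Generator) -> PressureImage:
    """Mirror left-right with probability 0.5, driven by the supplied rng."""
    if rng.random() < 0.5:
        return replace(img, pixels=img.pixels[:, ::-1].copy())
    return replace(img, pixels=img.pixels.copy())


def augment_rotate(img: PressureImage, angle_deg: float = 45.0) -> PressureImage:
    """Rotate about the image center (bilinear, zero fill, same H x W)."""
    if angle_deg % 360 == 0:
        return replace(img, pixels=img.pixels.copy())
    if angle_deg % 90 == 0 and img.pixels.shape[0] == img.pixels.shape[1]:
        # exact lattice rotation for squares: no interpolation loss
        k = int(angle_deg // 90) % 4
        return replace(img, pixels=np.rot90(img.pixels, k=k).copy())
    out = _sk_rotate(img.pixels, angle_deg, resize=False, order=1,
                     mode="constant", cval=0.0, preserve_range=True)
    return replace(img, pixels=np.clip(out, 0.0, None))


def augment_image(
    img: PressureImage,
    rng: np.random.Generator,
    rotation_mode: str = "choice",  # "choice" over {-45, 0, +45} | "fixed"
    angle_deg: float = 45.0,
) -> PressureImage:
    """Training-time augmentation: seeded flip then rotation."""
    out = augment_flip(img, rng)
    if rotation_mode == "fixed":
        angle = angle_deg
    elif rotation_mode == "choice":
        angle = float(rng.choice([-angle_deg, 0.0, angle_deg]))
    else:
        raise ValueError(f"unknown rotation_mode {rotation_mode!r}")
    return augment_rotate(out, angle)


def normalize_image(img: PressureImage) -> PressureImage:
    """Divide by the image maximum; all-zero images pass through unchanged."""
    peak = img.pixels.max()
    if peak <= 0:
        return replace(img, pixels=img.pixels.copy())
    return replace(img, pixels=img.pixels / peak)


# ---------------------------------------------------------------------------
# file interfaces


def write_pressure_series(series: PressureSeries, out_dir: str | Path) -> None:
    """One CSV per frame (H rows x W cols) under ``out_dir``, plus meta CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for t in range(series.frames.shape[0]):
        np.savetxt(out_dir / f"frame_{t:04d}.csv", series.frames[t],
                   delimiter=",", fmt="%.6g")
    pd.DataFrame(
        [{"grid_spacing_mm": series.grid_spacing_mm,
          "participant_id": series.participant_id,
          "sequence_id": series.sequence_id,
          "n_frames": series.frames.shape[0]}]
    ).to_csv(out_dir / "meta.csv", index=False)


def read_pressure_series(in_dir: str | Path) -> PressureSeries:
    in_dir = Path(in_dir)
    frame_files = sorted(in_dir.glob("frame_*.csv"))
    if not frame_files:
        raise FileNotFoundError(f"no frame_*.csv files in {in_dir}")
    frames = np.stack([np.loadtxt(f, delimiter=",", ndmin=2) for f in frame_files])
    meta_path = in_dir / "meta.csv"
    kw = {}
    if meta_path.exists():
        row = pd.read_csv(meta_path, dtype={"participant_id": str, "sequence_id": str}).iloc[0]
        kw = {"grid_spacing_mm": float(row["grid_spacing_mm"]),
              "participant_id": str(row["participant_id"]),
              "sequence_id": str(row["sequence_id"])}
    return PressureSeries(frames=frames, **kw)


def write_pressure_series_npz(series: PressureSeries, path: str | Path) -> None:
    """Single 3-D array file alternative to the per-frame CSV directory."""
    np.savez_compressed(
        path, frames=series.frames,
        grid_spacing_mm=series.grid_spacing_mm,
        participant_id=series.participant_id,
        sequence_id=series.sequence_id)


def read_pressure_series_npz(path: str | Path) -> PressureSeries:
    with np.load(path, allow_pickle=False) as z:
        return PressureSeries(
            frames=z["frames"],
            grid_spacing_mm=float(z["grid_spacing_mm"]),
            participant_id=str(z["participant_id"]),
            sequence_id=str(z["sequence_id"]))


def write_pressure_image(img: PressureImage, path: str | Path) -> None:
    """Write a CSV of raw values and a 16-bit grayscale PNG rendering."""
    path = Path(path)
    np.savetxt(path.with_suffix(".csv"), img.pixels, delimiter=",", fmt="%.6g")
    peak = img.pixels.max()
    scaled = img.pixels / peak if peak > 0 else img.pixels
    iio.imwrite(path.with_suffix(".png"),
                (scaled * 65535).round().astype(np.uint16))


def read_pressure_image_csv(path: str | Path) -> PressureImage:
    return PressureImage(pixels=np.loadtxt(path, delimiter=",", ndmin=2))
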