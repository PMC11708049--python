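"""Image sets and fluorescence cross-section profiles.

The spatial assays quantify reporter induction along a straight line that
starts inside a producer colony and runs into the surrounding reporter
material (a lawn or a neighbouring colony).  This module holds the two
containers those measurements live in — :class:`ImageSet` (registered
per-channel rasters with a µm/pixel calibration) and
:class:`CrossSectionProfile` (ordered distance/intensity samples with a
validity mask) — plus the operations that produce and transform them:
reading per-channel TIFFs, sampling a line with bilinear interpolation,
locating the producer-colony edge on the mCherry channel, shifting the
distance origin, and masking the agar gap between non-contacting colonies.

All distances are in micrometres.  Channel rasters are stored as written
(typically ``uint16``); profile intensities are float.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import map_coordinates

__all__ = [
    "ImageSet",
    "CrossSectionProfile",
    "read_image_set",
    "write_image_set",
    "extract_cross_section",
    "detect_producer_edge",
    "align_profile",
    "mask_gap",
    "write_profile_csv",
    "read_profile_csv",
    "read_session_file",
]

#: canonical channel order used for CSV serialization
CHANNELS = ("CFP", "YFP", "mCherry")


@dataclass
class ImageSet:
    """Registered per-channel 2-D intensity rasters with a µm/px calibration."""

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm per pixel
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if not self.channels:
            raise ValueError("ImageSet needs at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        ref_name, ref_shape = next(iter(shapes.items()))
        for name, shape in shapes.items():
            if len(shape) != 2:
                raise ValueError(f"channel {name!r} is not a 2-D raster")
            if shape != ref_shape:
                raise ValueError(
                    f"channel {name!r} shape {shape} does not match "
                    f"{ref_name!r} shape {ref_shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) spanned by pixel centres, in µm."""
        rows, cols = self.shape
        return ((cols - 1) * self.pixel_size, (rows - 1) * self.pixel_size)


@dataclass
class CrossSectionProfile:
    """Ordered (distance, intensity) samples along a marked line.

    ``distances`` are strictly increasing, in µm, measured from the line
    start (or from the alignment origin after :func:`align_profile`).
    ``mask`` flags valid samples; masked-out samples keep their intensity
    values but are ignored by downstream statistics.
    """

    distances: np.ndarray
    intensities: dict[str, np.ndarray]
    mask: np.ndarray
    origin_kind: str | None = None  # "yfp-peak" | "mcherry-edge" | None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n = self.distances.size
        if self.mask.size != n:
            raise ValueError("mask length does not match distances")
        for name, arr in self.intensities.items():
            arr = np.asarray(arr, dtype=float)
            if arr.size != n:
                raise ValueError(f"channel {name!r} length does not match distances")
            self.intensities[name] = arr
        if n > 1 and not np.all(np.diff(self.distances) > 0):
            raise ValueError("distances must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.intensities[name]
        except KeyError:
            raise KeyError(
                f"profile has no channel {name!r}; available: "
                f"{sorted(self.intensities)}"
            ) from None

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# I/O


def read_image_set(paths: Mapping[str, str | Path], pixel_size: float) -> ImageSet:
    """Read per-channel TIFF files into a registered :class:`ImageSet`.

    Missing optional channels are simply absent from ``paths``.  All files
    must decode to 2-D rasters of one shape; a mismatch raises a
    ``ValueError`` naming the offending channel.
    """
    channels: dict[str, np.ndarray] = {}
    for name, path in paths.items():
        path = Path(path)
        try:
            arr = tifffile.imread(path)
        except (OSError, ValueError) as exc:
            raise ValueError(f"cannot read channel {name!r} from {path}: {exc}") from exc
        channels[name] = np.asarray(arr)
    return ImageSet(channels=channels, pixel_size=pixel_size,
                    metadata={"paths": {k: str(v) for k, v in paths.items()}})


def write_image_set(img: ImageSet, directory: str | Path, scene: str) -> dict[str, Path]:
    """Write each channel as ``<scene>_<channel>.tif``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, arr in img.channels.items():
        path = directory / f"{scene}_{name}.tif"
        tifffile.imwrite(path, np.asarray(arr))
        paths[name] = path
    return paths


_CSV_NAMES = {"CFP": "cfp", "YFP": "yfp", "mCherry": "mcherry"}
_CSV_NAMES_INV = {v: k for k, v in _CSV_NAMES.items()}


def write_profile_csv(profile: CrossSectionProfile, path: str | Path) -> None:
    """Serialize a profile as CSV (distance_um, cfp, yfp, mcherry, mask)."""
    data: dict[str, np.ndarray] = {"distance_um": profile.distances}
    for name, arr in profile.intensities.items():
        data[_CSV_NAMES.get(name, name.lower())] = arr
    data["mask"] = profile.mask.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)


def read_profile_csv(path: str | Path) -> CrossSectionProfile:
    df = pd.read_csv(path)
    intensities = {
        _CSV_NAMES_INV.get(col, col): df[col].to_numpy(dtype=float)
        for col in df.columns
        if col not in ("distance_um", "mask")
    }
    return CrossSectionProfile(
        distances=df["distance_um"].to_numpy(dtype=float),
        intensities=intensities,
        mask=df["mask"].to_numpy(dtype=bool),
    )


def read_session_file(path: str | Path) -> dict:
    """Read a line-marking session file (structured YAML text).

    A session records what an operator would mark interactively: the scene
    id, the line endpoints ``p0``/``p1`` in µm, and optional colony-edge
    marks (``edges``, µm distances along the line).
    """
    with open(path) as fh:
        session = yaml.safe_load(fh)
    for key in ("scene", "p0", "p1"):
        if key not in session:
            raise ValueError(f"session file missing required key {key!r}")
    session["p0"] = tuple(float(v) for v in session["p0"])
    session["p1"] = tuple(float(v) for v in session["p1"])
    if "edges" in session and session["edges"] is not None:
        session["edges"] = [float(v) for v in session["edges"]]
    return session


# ---------------------------------------------------------------------------
# Extraction and geometry


def extract_cross_section(
    img: ImageSet,
    p0: tuple[float, float],
    p1: tuple[float, float],
    step: float | None = None,
) -> CrossSectionProfile:
    """Sample all channels along the segment from ``p0`` to ``p1``.

    Points are (x, y) positions in µm; pixel (row r, column c) sits at
    x = c·pixel_size, y = r·pixel_size.  Samples are taken at arithmetic
    spacing ``step`` (default: one pixel equivalent) starting at ``p0``;
    intensities come from bilinear interpolation.  If ``step`` exceeds the
    segment length the two endpoints are returned.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if step is None:
        step = img.pixel_size
    if step <= 0:
        raise ValueError("step must be positive")
    length = float(np.hypot(*(p1 - p0)))
    if length == 0:
        raise ValueError("zero-length cross-section line")

    rows, cols = img.shape
    for pt, label in ((p0, "p0"), (p1, "p1")):
        x, y = pt / img.pixel_size
        if not (0 <= x <= cols - 1 and 0 <= y <= rows - 1):
            raise ValueError(f"{label} at {tuple(pt)} µm lies outside the image")

    distances = np.arange(0.0, length + step * 1e-9, step)
    if distances.size < 2:
        distances = np.array([0.0, length])
    direction = (p1 - p0) / length
    points = p0[None, :] + distances[:, None] * direction[None, :]
    # map_coordinates wants (row, col) = (y, x) in pixel units
    coords = np.vstack([points[:, 1], points[:, 0]]) / img.pixel_size

    intensities = {
        name: map_coordinates(np.asarray(arr, dtype=float), coords, order=1)
        for name, arr in img.channels.items()
    }
    return CrossSectionProfile(
        distances=distances,
        intensities=intensities,
        mask=np.ones(distances.size, dtype=bool),
        metadata={"p0": tuple(p0), "p1": tuple(p1), "step": step},
    )


def detect_producer_edge(
    profile: CrossSectionProfile,
    channel: str = "mCherry",
    n_tail: int = 20,
    contrast_factor: float = 5.0,
) -> float:
    """Locate the producer-colony edge as the half-maximum crossing of a
    constitutive producer channel (default mCherry).

    The channel is expected to show a high plateau (inside the colony)
    followed by a decay to a far-field level.  The edge is the first
    crossing of the level halfway between plateau (channel maximum) and
    far field (mean of the last ``n_tail`` samples), scanning outward from
    the maximum, with linear interpolation between the bracketing samples.

    Raises ``ValueError`` ("no colony on section") when the plateau-to-far-
    field contrast falls below ``contrast_factor`` times the far-field
    standard deviation (with a tiny absolute floor so flat sections always
    fail).
    """
    y = profile.channel(channel)
    d = profile.distances
    if y.size < max(n_tail, 2):
        raise ValueError("profile too short for edge detection")
    far = y[-n_tail:]
    far_level = float(np.mean(far))
    far_sd = float(np.std(far, ddof=1)) if far.size > 1 else 0.0
    plateau = float(np.max(y))
    floor = max(contrast_factor * far_sd, 1e-9)
    if plateau - far_level <= floor:
        raise ValueError(f"no colony on section: {channel} contrast below floor")
    half = 0.5 * (plateau + far_level)
    i0 = int(np.argmax(y))
    for i in range(i0, y.size - 1):
        if y[i] >= half > y[i + 1]:
            t = (y[i] - half) / (y[i] - y[i + 1])
            return float(d[i] + t * (d[i + 1] - d[i]))
    raise ValueError("no colony on section: no half-maximum crossing found")


def align_profile(
    profile: CrossSectionProfile, origin: float, origin_kind: str
) -> CrossSectionProfile:
    """Shift distances so ``origin`` maps to 0; mask samples at negative
    distances.  Intensities are untouched.  Idempotent for origin 0."""
    d = profile.distances
    if not (d.min() <= origin <= d.max()):
        raise ValueError(
            f"origin {origin} µm outside profile range [{d.min()}, {d.max()}]"
        )
    new_d = d - origin
    new_mask = profile.mask & (new_d >= -1e-9)
    return dataclasses.replace(
        profile,
        distances=new_d,
        intensities={k: v.copy() for k, v in profile.intensities.items()},
        mask=new_mask,
        origin_kind=origin_kind,
    )


def mask_gap(
    profile: CrossSectionProfile, gap_start: float, gap_end: float
) -> CrossSectionProfile:
    """Mask samples in the closed interval [gap_start, gap_end] µm.

    Used for non-contacting colony pairs, where positions on the agar
    between the two colonies carry no reporter material and must be
    ignored.  Values are never altered, only validity flags.
    """
    if gap_start >= gap_end:
        raise ValueError("gap_start must be below gap_end")
    in_gap = (profile.distances >= gap_start) & (profile.distances <= gap_end)
    return dataclasses.replace(
        profile,
        distances=profile.distances.copy(),
        intensities={k: v.copy() for k, v in profile.intensities.items()},
        mask=profile.mask & ~in_gap,
    )
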