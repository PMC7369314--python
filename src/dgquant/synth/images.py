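"""Synthetic fluorescence micrographs with pixel-level ground truth.

The generator emulates the images the automated counter was designed for:
bright, quasi-circular immunoreactive cells over an uneven background, with
Gaussian sensor noise and both sub-cellular ("small") and super-cellular
("large") bright artifacts that a size filter must reject.  Cells are rendered
as truncated Gaussian spots (sigma = radius / 2) rather than hard disks —
smoother and closer to real out-of-focus somata.

Lengths are in pixels throughout: the counting algorithm's parameters (disk
radius, size bounds) are pixel-based and no physical pixel size is assumed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = ["ImageSpec", "GroundTruth", "generate_micrograph"]

#: margin (px) between the image border and the rectangular ROI trace; kept
#: comfortably larger than the opening disk so the background estimate is
#: free of border effects inside the ROI, as a real freehand trace would be
ROI_MARGIN_PX = 25

#: fraction of the nominal cell area pi*r^2 below/above which an artifact
#: qualifies as "small" / "large" — straddles the counter's size-filter bounds
SMALL_ARTIFACT_AREA_FRAC = 0.10
LARGE_ARTIFACT_AREA_FRAC = 3.0

_PLACEMENT_TRIES = 2000


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic micrograph.

    Defaults describe the nominal imaging condition the counter is tuned for:
    cells of ~10 px radius (matching the 10 px structuring element), a
    moderate linear shading gradient, and mild sensor noise.
    """

    width_px: int = 512
    height_px: int = 512
    n_cells: int = 20
    cell_radius_px: float = 10.0
    radius_jitter_frac: float = 0.10
    cell_peak_intensity: float = 200.0
    background_level: float = 40.0
    gradient_amplitude: float = 30.0
    noise_sd: float = 8.0
    n_small_artifacts: int = 2
    n_large_artifacts: int = 1
    min_center_separation_px: float = 40.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be non-negative")
        if self.cell_radius_px <= 0:
            raise ValueError("cell_radius_px must be positive")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be in [0, 255]")
        if not 0 <= self.cell_peak_intensity <= 255:
            raise ValueError("cell_peak_intensity must be in [0, 255]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.min_center_separation_px < 0:
            raise ValueError("min_center_separation_px must be non-negative")
        if self.cell_peak_intensity <= self.background_level + self.gradient_amplitude / 2:
            raise ValueError(
                "cells must be brighter than the local background: require "
                "cell_peak_intensity > background_level + gradient_amplitude/2"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ImageSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class GroundTruth:
    """What was actually placed in a generated micrograph."""

    cell_centers: list[tuple[float, float]]  # (x, y) pixel coordinates
    artifact_regions: list[np.ndarray] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_centers)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_cells": self.n_cells,
            "cell_centers": [[float(x), float(y)] for x, y in self.cell_centers],
            "artifact_regions": [r.tolist() for r in self.artifact_regions],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


class PlacementError(RuntimeError):
    """Raised when the pairwise-separation constraint cannot be satisfied."""


def _place_points(
    rng: np.random.Generator,
    n: int,
    lo_x: float,
    hi_x: float,
    lo_y: float,
    hi_y: float,
    min_sep: float,
    existing: list[tuple[float, float]],
) -> list[tuple[float, float]]:
    """Rejection-sample ``n`` points with pairwise separation ``min_sep``."""
    if hi_x <= lo_x or hi_y <= lo_y:
        raise PlacementError("placement window is empty for the requested radius")
    placed: list[tuple[float, float]] = []
    all_pts = list(existing)
    for _ in range(n):
        for _try in range(_PLACEMENT_TRIES):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if all(np.hypot(x - px, y - py) >= min_sep for px, py in all_pts):
                placed.append((x, y))
                all_pts.append((x, y))
                break
        else:
            raise PlacementError(
                f"could not place point {len(placed) + 1}/{n} with pairwise "
                f"separation >= {min_sep} px after {_PLACEMENT_TRIES} tries; "
                "the field is too crowded for min_center_separation_px"
            )
    return placed


def _render_gaussian_spot(
    field_: np.ndarray, x: float, y: float, radius: float, amplitude: float
) -> None:
    """Add a truncated Gaussian spot (sigma = radius/2, cut at 3 sigma) in place."""
    sigma = radius / 2.0
    cut = 3.0 * sigma
    h, w = field_.shape
    x0, x1 = max(0, int(x - cut)), min(w, int(x + cut) + 1)
    y0, y1 = max(0, int(y - cut)), min(h, int(y + cut) + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx - x) ** 2 + (yy - y) ** 2
    spot = amplitude * np.exp(-d2 / (2.0 * sigma**2))
    spot[d2 > cut**2] = 0.0
    field_[y0:y1, x0:x1] += spot


def _render_disk(
    field_: np.ndarray, x: float, y: float, radius: float, level: float
) -> np.ndarray:
    """Set a hard disk to ``level`` in place; return its (row, col) indices."""
    h, w = field_.shape
    x0, x1 = max(0, int(x - radius)), min(w, int(x + radius) + 1)
    y0, y1 = max(0, int(y - radius)), min(h, int(y + radius) + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - x) ** 2 + (yy - y) ** 2 <= radius**2
    sub = field_[y0:y1, x0:x1]
    sub[inside] = np.maximum(sub[inside], level)
    rows, cols = np.nonzero(inside)
    return np.column_stack([rows + y0, cols + x0])


def generate_micrograph(
    spec: ImageSpec,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Generate one 8-bit micrograph, its ROI mask, and the ground truth.

    Returns
    -------
    image : uint8 array (height, width)
        Background level + horizontal linear gradient + Gaussian cell spots +
        artifacts + Gaussian noise, clamped to [0, 255].
    roi : bool array (height, width)
        Rectangular region-of-interest trace inset from the border; all cells
        are placed inside it.
    truth : GroundTruth
        Every placed cell center (x, y) and artifact pixel region.

    Identical spec (including seed) yields a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    # uneven illumination: flat level plus a horizontal linear ramp
    x_ramp = np.linspace(0.0, 1.0, w)[None, :]
    field_ = np.broadcast_to(
        spec.background_level + spec.gradient_amplitude * x_ramp, (h, w)
    ).astype(np.float64).copy()

    roi = np.zeros((h, w), dtype=bool)
    m = min(ROI_MARGIN_PX, (min(h, w) - 1) // 2)
    roi[m : h - m, m : w - m] = True

    amplitude = spec.cell_peak_intensity - spec.background_level
    nominal_area = np.pi * spec.cell_radius_px**2
    small_r = np.sqrt(SMALL_ARTIFACT_AREA_FRAC * nominal_area / np.pi) * 0.8
    large_r = np.sqrt(LARGE_ARTIFACT_AREA_FRAC * nominal_area / np.pi) * 1.3

    # artifacts go down first, while the field is empty; cells then keep
    # their separation from them
    artifact_regions: list[np.ndarray] = []
    placed_so_far: list[tuple[float, float]] = []
    for n_art, art_r, level in (
        (spec.n_small_artifacts, small_r, spec.cell_peak_intensity),
        (
            spec.n_large_artifacts,
            large_r,
            # big dim blob: survives the opening, hence subtracted away
            spec.background_level + amplitude * 0.5,
        ),
    ):
        if not n_art:
            continue
        art_pad = m + art_r + 2
        sep = art_r + 2.0 * spec.cell_radius_px
        art_centers = _place_points(
            rng, n_art, art_pad, w - art_pad, art_pad, h - art_pad,
            sep, existing=placed_so_far,
        )
        placed_so_far.extend(art_centers)
        for x, y in art_centers:
            artifact_regions.append(_render_disk(field_, x, y, art_r, level))

    # keep whole somata inside the ROI trace
    pad = m + 1.5 * spec.cell_radius_px
    try:
        centers = _place_points(
            rng,
            spec.n_cells,
            pad,
            w - pad,
            pad,
            h - pad,
            spec.min_center_separation_px,
            existing=placed_so_far,
        )
    except PlacementError as err:
        raise PlacementError(
            f"{err} (n_cells={spec.n_cells}, field {w}x{h} px)"
        ) from err

    for x, y in centers:
        r = spec.cell_radius_px * (
            1.0 + spec.radius_jitter_frac * rng.uniform(-1.0, 1.0)
        )
        _render_gaussian_spot(field_, x, y, r, amplitude)

    if spec.noise_sd > 0:
        field_ += rng.normal(0.0, spec.noise_sd, size=(h, w))

    image = np.clip(np.rint(field_), 0, 255).astype(np.uint8)
    return image, roi, GroundTruth(cell_centers=centers, artifact_regions=artifact_regions)


def write_micrograph(
    path: str | Path, image: np.ndarray, roi: np.ndarray | None = None
) -> None:
    """Write an 8-bit grayscale TIFF and, if given, a 0/255 PNG ROI mask."""
    path = Path(path)
    tifffile.imwrite(path, image.astype(np.uint8))
    if roi is not None:
        iio.imwrite(
            path.with_suffix(".roi.png"), (roi.astype(np.uint8) * 255)
        )
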