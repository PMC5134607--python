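"""Timestamped camera imagery, polygon ROIs and chromatic-coordinate extraction.

Cameras record 8-bit RGB digital numbers (DN, 0-255 per channel). Greenness
is summarized by the green chromatic coordinate

    GCC = G_DN / (R_DN + G_DN + B_DN)

with RCC and BCC defined analogously, so GCC + RCC + BCC = 1 for every
retained sample. Pixel coordinates are 0-based (row, col) with origin at the
top-left; a pixel belongs to an ROI polygon when its center lies inside or on
the polygon boundary. Timestamps are local camera time (fixed clock, no DST).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import shapely
from PIL import Image, UnidentifiedImageError
from shapely.geometry import Polygon

logger = logging.getLogger(__name__)

SERIES_COLUMNS = ["timestamp", "doy", "roi", "gcc", "rcc", "bcc", "n_pixels"]


class EmptyInputError(ValueError):
    """Raised when an operation receives no usable input."""


@dataclass
class TimestampedImage:
    """One camera frame: acquisition time plus an (H, W, 3) uint8 DN array."""

    timestamp: datetime
    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be (H, W, 3), got {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("digital numbers must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def doy(self) -> int:
        return self.timestamp.timetuple().tm_yday

    @property
    def fractional_doy(self) -> float:
        t = self.timestamp
        return self.doy + (t.hour + t.minute / 60.0) / 24.0


@dataclass
class LoadReport:
    """Outcome of reading an image directory: what loaded, what was skipped."""

    n_loaded: int = 0
    n_skipped_timestamp: int = 0
    n_skipped_corrupt: int = 0
    skipped: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return self.n_skipped_timestamp + self.n_skipped_corrupt


def parse_timestamp(filename: str | Path, pattern: str) -> datetime:
    """Parse an acquisition time from a filename stem via a strptime pattern.

    ``pattern`` may include literal text, e.g. ``"site_%Y_%m_%d_%H%M"``
    matches ``site_2015_05_07_1200.jpg``.
    """
    return datetime.strptime(Path(filename).stem, pattern)


def load_image_series(
    paths: Iterable[str | Path],
    timestamp_pattern: str = "%Y_%m_%d_%H%M",
) -> tuple[list[TimestampedImage], LoadReport]:
    """Load and time-sort camera frames; skip (and count) unusable files.

    Files whose names do not match ``timestamp_pattern`` or that cannot be
    decoded as 3-channel images are skipped with a logged count, never fatal.
    An empty path list raises :class:`EmptyInputError`.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise EmptyInputError("no image files supplied")
    report = LoadReport()
    images: list[TimestampedImage] = []
    for p in paths:
        try:
            ts = parse_timestamp(p, timestamp_pattern)
        except ValueError:
            report.n_skipped_timestamp += 1
            report.skipped.append(str(p))
            continue
        try:
            with Image.open(p) as im:
                px = np.asarray(im.convert("RGB"), dtype=np.uint8)
        except (OSError, UnidentifiedImageError):
            report.n_skipped_corrupt += 1
            report.skipped.append(str(p))
            continue
        images.append(TimestampedImage(ts, px, source_id=p.stem))
    images.sort(key=lambda im: im.timestamp)
    report.n_loaded = len(images)
    if report.n_skipped:
        logger.warning("skipped %d of %d files (%d bad timestamp, %d undecodable)",
                       report.n_skipped, len(paths),
                       report.n_skipped_timestamp, report.n_skipped_corrupt)
    return images, report


@dataclass
class ROI:
    """A named polygon over the camera frame with its rasterized mask."""

    name: str
    vertices: list[tuple[float, float]]  # (row, col)
    mask: np.ndarray  # (H, W) bool

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) half-open bounds of the true mask region."""
        rows, cols = np.nonzero(self.mask)
        return int(rows.min()), int(rows.max()) + 1, int(cols.min()), int(cols.max()) + 1


def build_roi_mask(
    vertices: Sequence[tuple[float, float]],
    image_height: int,
    image_width: int,
    name: str = "roi",
) -> ROI:
    """Rasterize a polygon into a pixel mask.

    A pixel (r, c) is inside when its center point lies inside or on the
    polygon boundary. Degenerate (zero-area) polygons raise ``ValueError``.
    """
    verts = [(float(r), float(c)) for r, c in vertices]
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    for r, c in verts:
        if not (0 <= r <= image_height - 1 and 0 <= c <= image_width - 1):
            raise ValueError(f"vertex ({r}, {c}) outside image bounds")
    poly = Polygon(verts)
    if poly.area == 0:
        raise ValueError("degenerate polygon (zero area)")
    mask = np.zeros((image_height, image_width), dtype=bool)
    # restrict the point-in-polygon test to the polygon bounding box
    minr, minc, maxr, maxc = poly.bounds
    r0, r1 = int(np.floor(minr)), int(np.ceil(maxr))
    c0, c1 = int(np.floor(minc)), int(np.ceil(maxc))
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    pts = shapely.points(np.column_stack([rr.ravel(), cc.ravel()]).astype(float))
    inside = shapely.covers(poly, pts).reshape(rr.shape)
    mask[r0:r1 + 1, c0:c1 + 1] = inside
    if not mask.any():
        raise ValueError("polygon covers no pixel centers")
    return ROI(name=name, vertices=verts, mask=mask)


def save_roi(roi: ROI, path: str | Path) -> None:
    """Write a plain-text ROI file: a name header then ``row,col`` lines."""
    lines = [roi.name]
    lines += [f"{r!r},{c!r}" for r, c in roi.vertices]
    Path(path).write_text("\n".join(lines) + "\n")


def load_roi(path: str | Path, image_height: int, image_width: int) -> ROI:
    """Read a plain-text ROI file and rebuild its mask deterministically."""
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 4:
        raise ValueError(f"ROI file {path} needs a name and >= 3 vertices")
    name = lines[0].strip()
    verts = []
    for ln in lines[1:]:
        r, c = ln.split(",")
        verts.append((float(r), float(c)))
    return build_roi_mask(verts, image_height, image_width, name=name)


def chromatic_coordinates(pixels: np.ndarray) -> np.ndarray:
    """Per-pixel (gcc, rcc, bcc) for an (..., 3) DN array; NaN where R+G+B=0."""
    px = np.asarray(pixels, dtype=float)
    total = px.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        cc = px / total
    cc[np.broadcast_to(total == 0, cc.shape)] = np.nan
    return cc[..., [1, 0, 2]]  # order: gcc, rcc, bcc


def extract_chromatic(
    image: TimestampedImage,
    roi: ROI,
    scope: str = "roi-average",
    convention: str = "ratio-of-means",
):
    """Chromatic coordinates of one frame within an ROI.

    scope="roi-average" returns a dict with one (gcc, rcc, bcc) triple;
    scope="per-pixel" returns a dict of arrays over the masked pixels.

    Pixels with R+G+B = 0 carry no chromatic information and are excluded
    (the excluded count is reported); if every masked pixel is zero the
    sample is missing (gcc is NaN, n_pixels 0).

    The ROI average follows the ratio-of-means convention by default: the
    chromatic coordinate of the per-channel mean DN. This is robust to dark
    pixels, which would dominate a mean of per-pixel ratios.
    convention="mean-of-ratios" averages per-pixel coordinates instead.
    """
    if roi.mask.shape != image.pixels.shape[:2]:
        raise ValueError("ROI mask shape does not match image")
    px = image.pixels[roi.mask].astype(float)  # (N, 3) in R, G, B order
    nonzero = px.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.debug("%s: excluded %d zero-DN pixels (%.2f%%)", image.source_id,
                     n_excluded, 100.0 * n_excluded / len(px))
    if scope == "per-pixel":
        cc = chromatic_coordinates(px)
        rows, cols = np.nonzero(roi.mask)
        return {
            "rows": rows, "cols": cols,
            "gcc": cc[:, 0], "rcc": cc[:, 1], "bcc": cc[:, 2],
            "n_excluded": n_excluded,
        }
    if scope != "roi-average":
        raise ValueError(f"unknown scope {scope!r}")
    valid = px[nonzero]
    if len(valid) == 0:
        return {"gcc": np.nan, "rcc": np.nan, "bcc": np.nan,
                "n_pixels": 0, "n_excluded": n_excluded}
    if convention == "ratio-of-means":
        mean_dn = valid.mean(axis=0)
        gcc, rcc, bcc = chromatic_coordinates(mean_dn)
    elif convention == "mean-of-ratios":
        cc = chromatic_coordinates(valid)
        gcc, rcc, bcc = np.nanmean(cc, axis=0)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return {"gcc": float(gcc), "rcc": float(rcc), "bcc": float(bcc),
            "n_pixels": int(len(valid)), "n_excluded": n_excluded}


def extract_series(
    images: Sequence[TimestampedImage],
    rois: Sequence[ROI] | ROI,
    convention: str = "ratio-of-means",
) -> pd.DataFrame:
    """ROI-averaged sub-daily chromatic series for one or more ROIs.

    Returns a DataFrame with columns timestamp, doy, roi, gcc, rcc, bcc,
    n_pixels, sorted by (roi, timestamp). Frames where every masked pixel has
    zero DN are dropped (missing samples).
    """
    if isinstance(rois, ROI):
        rois = [rois]
    if not images:
        raise EmptyInputError("no images to extract from")
    rows = []
    for roi in rois:
        for im in images:
            rec = extract_chromatic(im, roi, convention=convention)
            if rec["n_pixels"] == 0:
                continue
            rows.append({
                "timestamp": im.timestamp, "doy": im.doy, "roi": roi.name,
                "gcc": rec["gcc"], "rcc": rec["rcc"], "bcc": rec["bcc"],
                "n_pixels": rec["n_pixels"],
            })
    if not rows:
        warnings.warn("all frames produced missing samples")
    df = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    return df.sort_values(["roi", "timestamp"], kind="stable").reset_index(drop=True)


def write_series_csv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_series_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", parse_dates=["timestamp"])
    return df
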