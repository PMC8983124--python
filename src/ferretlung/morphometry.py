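"""Alveolar airspace morphometry on 2D histology-like images.

Airspaces (low-stain regions) are binarised, labelled, and measured;
enlargement is expressed as the surface-area-to-perimeter ratio (SA/P,
um) per airspace, then averaged per lobe and per animal (unweighted mean
of lobe means).  A user-supplied exclusion mask stands in for the trained
investigator who removes conducting airways: any labelled region that
overlaps it is dropped entirely.

Perimeter estimation uses the length of the simplified marching-squares
contour (Douglas-Peucker tolerance 0.8 px).  The raw marching-squares
polyline is accurate for axis-aligned edges but overestimates smooth
boundaries by ~5% through staircase excursions; simplification removes
the staircase while preserving true corners, keeping both rectangles and
disks within ~1% of their analytic perimeter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import InputError, DegenerateAnalysisError

#: Douglas-Peucker tolerance (px) for contour simplification.
CONTOUR_TOLERANCE_PX = 0.8

LOBES = ("LUL", "LLL", "RUL", "RML", "RLL", "accessory")


@dataclass
class AirspaceImage:
    """A 2D grayscale or binary image with physical pixel size."""

    pixels: np.ndarray
    pixel_size_um: float
    exclusion: np.ndarray | None = None
    lobe: str | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise InputError(f"image must be 2D, got shape {self.pixels.shape}")
        if self.pixel_size_um <= 0:
            raise InputError(f"pixel size must be positive, got {self.pixel_size_um}")
        if self.exclusion is not None:
            self.exclusion = np.asarray(self.exclusion, dtype=bool)
            if self.exclusion.shape != self.pixels.shape:
                raise InputError("exclusion mask shape differs from image")


@dataclass
class AirspaceLabelMap:
    """Integer-labelled airspace regions (labels contiguous from 1)."""

    labels: np.ndarray
    pixel_size_um: float
    min_size_px: int
    lobe: str | None = None
    n_border_removed: int = 0

    @property
    def count(self) -> int:
        return int(self.labels.max())


@dataclass
class MorphometryResult:
    """Lobe-level and animal-level SA/P summaries."""

    lobe_means_um: pd.Series
    animal_mean_um: float
    pooled_lobe_ratios_um: pd.Series | None = None
    per_region: pd.DataFrame | None = None


def label_airspaces(
    image: AirspaceImage,
    binarize: str = "auto",
    min_size_px: int = 10,
    exclude_border: bool = True,
) -> AirspaceLabelMap:
    """Binarise and label airspace regions.

    For grayscale input the foreground (airspace) is the bright, low-stain
    side of an Otsu split (``binarize="auto"``); boolean input is used as
    is.  Regions overlapping the exclusion mask by even one pixel are
    removed, as are regions smaller than ``min_size_px`` and (by default)
    regions touching the image border, whose SA/P would be biased by the
    missing part.
    """
    px = image.pixels
    if px.dtype == bool:
        fg = px
    elif binarize == "auto":
        if px.max() == px.min():
            raise InputError("flat image - cannot binarise")
        fg = px > threshold_otsu(px)
    elif binarize == "fixed":
        fg = px > 0
    else:
        raise InputError(f"unknown binarize mode {binarize!r}")
    if not fg.any():
        raise InputError("empty foreground after binarisation")

    labels = measure.label(fg, connectivity=2)  # 8-connected
    drop = set()
    if image.exclusion is not None:
        drop.update(np.unique(labels[image.exclusion & (labels > 0)]).tolist())
    n_border = 0
    if exclude_border:
        border = np.zeros_like(fg)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        border_labels = set(np.unique(labels[border & (labels > 0)]).tolist())
        n_border = len(border_labels - drop)
        drop.update(border_labels)
    sizes = np.bincount(labels.ravel())
    drop.update(np.flatnonzero(sizes < min_size_px).tolist())
    drop.discard(0)
    if drop:
        labels[np.isin(labels, list(drop))] = 0
    # relabel contiguously from 1
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return AirspaceLabelMap(
        labels=out,
        pixel_size_um=image.pixel_size_um,
        min_size_px=min_size_px,
        lobe=image.lobe,
        n_border_removed=n_border,
    )


def region_perimeter_px(mask: np.ndarray, tolerance_px: float = CONTOUR_TOLERANCE_PX) -> float:
    """Boundary length of a binary region in pixels.

    Sum of simplified marching-squares contour lengths (outer boundary
    plus any hole boundaries).
    """
    padded = np.pad(mask.astype(float), 1)
    total = 0.0
    for contour in measure.find_contours(padded, 0.5):
        poly = measure.approximate_polygon(contour, tolerance_px)
        d = np.diff(poly, axis=0)
        total += float(np.sqrt((d**2).sum(axis=1)).sum())
    return total


def airspace_metrics(label_map: AirspaceLabelMap) -> pd.DataFrame:
    """Per-airspace area, perimeter, and SA/P in physical units.

    Area is pixel count times (pixel size)^2; perimeter is the simplified
    contour length times pixel size.  Degenerate zero-perimeter regions
    are skipped with a warning.
    """
    if label_map.count < 1:
        raise InputError("label map contains no regions")
    px = label_map.pixel_size_um
    rows = []
    for rp in measure.regionprops(label_map.labels):
        sl = rp.slice
        mask = label_map.labels[sl] == rp.label
        perim_px = region_perimeter_px(mask)
        if perim_px == 0:
            warnings.warn(f"region {rp.label} has zero perimeter - skipped")
            continue
        area = rp.area * px**2
        perim = perim_px * px
        rows.append(
            {
                "label": rp.label,
                "lobe": label_map.lobe,
                "area_um2": float(area),
                "perimeter_um": float(perim),
                "sa_p_um": float(area / perim),
            }
        )
    return pd.DataFrame(rows, columns=["label", "lobe", "area_um2", "perimeter_um", "sa_p_um"])


def summarize_lobes(per_region: pd.DataFrame) -> MorphometryResult:
    """Lobe means of per-airspace SA/P, and the animal mean of lobe means.

    ``per_region`` is the concatenation of :func:`airspace_metrics`
    outputs over all images of an animal, with the ``lobe`` column set.
    Lobes with zero airspaces are simply absent; if no lobe has data a
    :class:`DegenerateAnalysisError` is raised.  The pooled alternative
    (total area / total perimeter per lobe) is reported alongside.
    """
    if per_region.empty:
        raise DegenerateAnalysisError("no airspaces in any lobe")
    if per_region["lobe"].isna().any():
        raise InputError("per-region table has rows without a lobe label")
    lobe_means = per_region.groupby("lobe", sort=True)["sa_p_um"].mean()
    pooled = per_region.groupby("lobe", sort=True).apply(
        lambda g: g["area_um2"].sum() / g["perimeter_um"].sum(), include_groups=False
    )
    return MorphometryResult(
        lobe_means_um=lobe_means,
        animal_mean_um=float(lobe_means.mean()),
        pooled_lobe_ratios_um=pooled,
        per_region=per_region,
    )
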