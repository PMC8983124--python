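"""Quantitative-CT emphysema scoring.

The stages mirror a standard inspiratory-CT analysis chain: threshold the
volume to find low-attenuation tissue, drop exterior air by
border-connectivity, extract the airway tree by seeded region growing
with leak control, subtract it and clean the lung mask morphologically,
then express emphysema burden as %LAA - the percentage of lung voxels at
or below each Hounsfield threshold.  A final cross-subject regression
relates %LAA to airflow obstruction (FEV_0.4:FVC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError, NoLungFoundError, DegenerateAnalysisError
from .types import CTVolume, BinaryMask3D

#: 26-connectivity structuring element for 3D component labelling.
_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Standard %LAA thresholds (HU).  Comparison is inclusive (<=).
DEFAULT_LAA_THRESHOLDS = (-950, -910, -900, -870)


@dataclass
class LAAProfile:
    """%LAA per HU threshold for one subject.

    ``percents[i]`` is 100 * (# lung voxels with HU <= thresholds[i]) /
    denominator.  Non-decreasing in the threshold by construction.
    """

    thresholds_hu: tuple[int, ...]
    percents: tuple[float, ...]
    denominator: int
    subject: str | None = None

    def percent_at(self, threshold: int) -> float:
        return self.percents[self.thresholds_hu.index(threshold)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject,
                "threshold_hu": self.thresholds_hu,
                "percent": self.percents,
                "denominator": self.denominator,
            }
        )


@dataclass
class EmphysemaFunctionFit:
    """Per-threshold OLS of %LAA on the FEV_0.4:FVC ratio across subjects."""

    table: pd.DataFrame  # columns: threshold_hu, slope, intercept, r_squared, n

    def slope_at(self, threshold: int) -> float:
        row = self.table[self.table["threshold_hu"] == threshold]
        return float(row["slope"].iloc[0])


def _border_connected(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` connected (26-conn) to any face of the grid."""
    labels, _ = ndimage.label(mask, structure=_CONN26)
    border_labels = set()
    for axis in range(3):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            border_labels.update(np.unique(face[face > 0]).tolist())
    if not border_labels:
        return np.zeros_like(mask)
    return np.isin(labels, list(border_labels))


def segment_lungs(
    volume: CTVolume,
    lung_threshold: float = -320.0,
    keep_components: int = 2,
) -> BinaryMask3D:
    """Threshold-based lung segmentation.

    Candidate voxels are those with HU <= ``lung_threshold``.  Components
    touching the grid border (exterior air, and any airway opening at a
    face) are removed; of the remainder, the largest ``keep_components``
    components are kept (left and right lungs may or may not fuse at the
    carina).  Airway lumen inside the chest may still be present at this
    stage; it is removed by :func:`refine_lung_mask`.
    """
    candidate = volume.hu <= lung_threshold
    if not candidate.any():
        raise NoLungFoundError(
            f"no voxel at or below {lung_threshold} HU - no lung candidate found"
        )
    candidate &= ~_border_connected(candidate)
    if not candidate.any():
        raise NoLungFoundError(
            "all low-attenuation voxels are border-connected exterior air"
        )
    labels, n = ndimage.label(candidate, structure=_CONN26)
    sizes = ndimage.sum_labels(candidate, labels, index=np.arange(1, n + 1))
    keep = np.argsort(sizes)[::-1][:keep_components] + 1
    mask = np.isin(labels, keep)
    return BinaryMask3D(mask, role="lung", spacing=volume.spacing)


def _auto_seed(volume: CTVolume, grow_threshold: float) -> tuple[int, int, int]:
    """Locate a trachea seed: the darkest candidate component that opens
    at the top face but does not touch any lateral face (which would be
    exterior air)."""
    candidate = volume.hu <= grow_threshold
    labels, n = ndimage.label(candidate, structure=_CONN26)
    if n == 0:
        raise InputError(f"no voxel at or below {grow_threshold} HU to seed airway growth")
    side_labels = set()
    for axis in (1, 2):
        for sl in (0, -1):
            face = np.take(labels, sl, axis=axis)
            side_labels.update(np.unique(face[face > 0]).tolist())
    top = labels[0]
    top_labels = [l for l in np.unique(top[top > 0]) if l not in side_labels]
    if not top_labels:
        raise InputError("no airway opening found at the top face")
    sizes = {l: int((labels == l).sum()) for l in top_labels}
    best = max(sizes, key=sizes.get)
    coords = np.argwhere(top == best)
    centroid = coords.mean(axis=0)
    y, x = coords[np.argmin(np.linalg.norm(coords - centroid, axis=1))]
    return (0, int(y), int(x))


def segment_airways(
    volume: CTVolume,
    seed_voxel: tuple[int, int, int] | None = None,
    grow_threshold: float = -950.0,
    leak_factor: float = 2.0,
    step_hu: float = 10.0,
    max_threshold: float = -500.0,
) -> BinaryMask3D:
    """Airway extraction by seeded region growing with leak control.

    Starting from the (given or auto-detected) trachea seed, the
    26-connected component of voxels at or below the growth threshold is
    extracted.  The threshold is then relaxed in ``step_hu`` increments;
    if the region volume jumps by more than ``leak_factor`` between steps
    the growth has broken into parenchyma, and the pre-leak region is
    returned.  Otherwise relaxation stops at ``max_threshold``.
    """
    if seed_voxel is None:
        seed_voxel = _auto_seed(volume, grow_threshold)
    seed_voxel = tuple(int(v) for v in seed_voxel)
    shape = volume.shape
    if any(not (0 <= seed_voxel[a] < shape[a]) for a in range(3)):
        raise InputError(f"seed voxel {seed_voxel} outside volume of shape {shape}")
    if volume.hu[seed_voxel] > grow_threshold:
        raise InputError(
            f"seed voxel HU {volume.hu[seed_voxel]:.0f} is above the growth "
            f"threshold {grow_threshold:.0f}"
        )

    region = None
    threshold = grow_threshold
    max_threshold = max(max_threshold, grow_threshold)
    while threshold <= max_threshold + 1e-9:
        candidate = volume.hu <= threshold
        labels, _ = ndimage.label(candidate, structure=_CONN26)
        grown = labels == labels[seed_voxel]
        size = int(grown.sum())
        if region is not None and size > leak_factor * int(region.sum()):
            break  # leak into parenchyma: keep the pre-leak region
        region = grown
        threshold += step_hu
    return BinaryMask3D(region, role="airway", spacing=volume.spacing)


def refine_lung_mask(
    lung: BinaryMask3D,
    airway: BinaryMask3D,
    close_radius_mm: float = 2.0,
) -> BinaryMask3D:
    """Subtract the airway, smooth by physical-radius closing, fill holes.

    Closing uses a ball of ``close_radius_mm`` realised through Euclidean
    distance transforms with the mask's anisotropic spacing, so the
    physical radius is honoured per axis.  The airway is subtracted again
    after closing so the result is guaranteed disjoint from it.
    """
    if lung.shape != airway.shape:
        raise InputError(f"mask shapes differ: {lung.shape} vs {airway.shape}")
    mask = lung.mask & ~airway.mask
    if close_radius_mm > 0 and mask.any():
        spacing = lung.spacing
        dilated = ndimage.distance_transform_edt(~mask, sampling=spacing) <= close_radius_mm
        mask = ndimage.distance_transform_edt(dilated, sampling=spacing) > close_radius_mm
    mask = ndimage.binary_fill_holes(mask)
    mask &= ~airway.mask
    return BinaryMask3D(mask, role="refined-lung", spacing=lung.spacing)


def laa_profile(
    volume: CTVolume,
    refined_lung: BinaryMask3D,
    thresholds=DEFAULT_LAA_THRESHOLDS,
    subject: str | None = None,
) -> LAAProfile:
    """%LAA: percent of lung voxels at or below each HU threshold."""
    if volume.shape != refined_lung.shape:
        raise InputError("volume and mask shapes differ")
    lung_hu = volume.hu[refined_lung.mask]
    denom = lung_hu.size
    if denom == 0:
        raise InputError("empty lung mask - cannot compute %LAA")
    thresholds = tuple(sorted(int(t) for t in thresholds))
    percents = tuple(
        float(100.0 * np.count_nonzero(lung_hu <= t) / denom) for t in thresholds
    )
    return LAAProfile(
        thresholds_hu=thresholds, percents=percents, denominator=denom, subject=subject
    )


def laa_function_slope(records) -> EmphysemaFunctionFit:
    """Regress %LAA on FEV_0.4:FVC across subjects, per threshold.

    ``records`` is an iterable of ``(subject, LAAProfile, fev_ratio)``.
    Returns the OLS slope (%-points per unit ratio), intercept, and R^2
    for each threshold shared by all profiles.
    """
    records = list(records)
    if len(records) < 2:
        raise DegenerateAnalysisError(
            f"need at least 2 subjects to fit a slope, got {len(records)}"
        )
    ratios = np.array([r[2] for r in records], dtype=float)
    if np.ptp(ratios) == 0:
        raise DegenerateAnalysisError(
            "all FEV:FVC ratios identical - regression slope undefined"
        )
    thresholds = records[0][1].thresholds_hu
    rows = []
    for t in thresholds:
        y = np.array([r[1].percent_at(t) for r in records], dtype=float)
        slope, intercept = np.polyfit(ratios, y, 1)
        y_hat = slope * ratios + intercept
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        ss_res = float(np.sum((y - y_hat) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        rows.append(
            {
                "threshold_hu": t,
                "slope": float(slope),
                "intercept": float(intercept),
                "r_squared": r2,
                "n": len(records),
            }
        )
    return EmphysemaFunctionFit(table=pd.DataFrame(rows))


def qct_pipeline(
    volume: CTVolume,
    lung_threshold: float = -320.0,
    grow_threshold: float = -950.0,
    leak_factor: float = 2.0,
    close_radius_mm: float = 2.0,
    thresholds=DEFAULT_LAA_THRESHOLDS,
    subject: str | None = None,
) -> tuple[BinaryMask3D, BinaryMask3D, LAAProfile]:
    """Full QCT chain: lungs, airways, refinement, %LAA profile."""
    lung = segment_lungs(volume, lung_threshold=lung_threshold)
    airway = segment_airways(
        volume, grow_threshold=grow_threshold, leak_factor=leak_factor
    )
    refined = refine_lung_mask(lung, airway, close_radius_mm=close_radius_mm)
    profile = laa_profile(volume, refined, thresholds=thresholds, subject=subject)
    return refined, airway, profile
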