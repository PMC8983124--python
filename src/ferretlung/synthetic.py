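"""Synthetic inputs with attached ground truth for every pipeline stage.

Every generator is a pure function of its spec and seed, so downstream
estimates can be validated against exact (or analytically known) truth:

* :func:`make_ct_phantom` - a chest-CT-like HU volume containing a body,
  an ellipsoidal lung with a tunable emphysematous voxel fraction, and a
  walled bifurcating airway tree opening at the cranial face.
* :func:`make_expiration_trace` - mono-/multi-exponential forced
  expirations with analytic FEV_x truth.
* :func:`make_pv_loop` - single-exponential quasistatic loops
  ``V(P) = A - B * exp(-K * P)`` with optional hysteresis and noise.
* :func:`make_airspace_image` - binary airspace images built from
  non-overlapping squares and disks with analytic area/perimeter truth.
* :func:`make_cohort` - longitudinal IC/Ln cohorts with per-animal random
  intercepts, sex intercepts, and genotype-specific age slopes.
* :func:`make_inhibition_curve` - protease residual-activity curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .types import CTVolume, BinaryMask3D, FlowVolumeTrace, PVLoop, ManeuverSegment

# --------------------------------------------------------------------------
# CT phantom
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the CT phantom generator.

    HU distributions are (mean, SD) Gaussians per tissue compartment.  The
    defaults place the %LAA thresholds (-950...-870 HU) between the normal
    parenchyma mode and the emphysema mode, so threshold behaviour is
    informative.  Airway lumen noise is truncated at 2 SD: the lumen is
    homogeneous air and should never stray into parenchymal densities.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.5)  # mm, (z, y, x)
    emphysema_fraction: float = 0.0
    parenchyma_hu: tuple[float, float] = (-700.0, 60.0)
    emphysema_hu: tuple[float, float] = (-930.0, 30.0)
    airway_hu: tuple[float, float] = (-1000.0, 5.0)
    soft_tissue_hu: tuple[float, float] = (40.0, 20.0)
    exterior_hu: float = -1000.0
    airway_depth: int = 3  # trachea + (depth-1) bifurcation levels
    airway_radius_mm: float = 1.25
    wall_thickness_mm: float = 1.0
    emphysema_mode: str = "bernoulli"  # or "blobs"
    blob_radius_mm: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.emphysema_fraction <= 1.0):
            raise InputError(
                f"emphysema_fraction must be in [0, 1], got {self.emphysema_fraction}"
            )
        if any(n <= 0 for n in self.shape) or len(self.shape) != 3:
            raise InputError(f"shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be positive, got {self.spacing}")
        for name in ("parenchyma_hu", "emphysema_hu", "airway_hu", "soft_tissue_hu"):
            if getattr(self, name)[1] < 0:
                raise InputError(f"{name} SD must be >= 0")
        if self.emphysema_mode not in ("bernoulli", "blobs"):
            raise InputError(f"unknown emphysema_mode {self.emphysema_mode!r}")


@dataclass
class PhantomTruth:
    """Ground-truth masks aligned with the generated volume."""

    lung: BinaryMask3D
    airway: BinaryMask3D
    emphysema: BinaryMask3D


def _mark_tube(lumen, p0, p1, radius_mm, spacing):
    """Set voxels within radius_mm of segment p0-p1 (voxel coords) to True."""
    sp = np.asarray(spacing, dtype=float)
    p0 = np.asarray(p0, dtype=float) * sp  # physical mm
    p1 = np.asarray(p1, dtype=float) * sp
    lo_mm = np.minimum(p0, p1) - radius_mm
    hi_mm = np.maximum(p0, p1) + radius_mm
    lo = np.maximum(np.floor(lo_mm / sp).astype(int), 0)
    hi = np.minimum(np.ceil(hi_mm / sp).astype(int) + 1, np.array(lumen.shape))
    if np.any(lo >= hi):
        return
    grids = np.meshgrid(
        *[np.arange(lo[a], hi[a]) * sp[a] for a in range(3)], indexing="ij"
    )
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sub = lumen[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub |= dist <= radius_mm


def _airway_tree(spec: PhantomSpec, lung_center, lung_semi):
    """Voxelize a symmetric bifurcating tube tree opening at the top face."""
    nz, ny, nx = spec.shape
    lumen = np.zeros(spec.shape, dtype=bool)
    cz, cy, cx = lung_center
    r_mm = spec.airway_radius_mm
    # trachea: from the top face down to just above the lung centre
    carina = np.array([cz - 0.30 * lung_semi[0], cy, cx])
    _mark_tube(lumen, (0.0, cy, cx), carina, r_mm, spec.spacing)
    parents = [(carina, np.array([1.0, 0.0, 0.0]))]
    length = 0.35 * lung_semi[0]
    for level in range(1, spec.airway_depth):
        r_mm *= 0.75
        children = []
        for start, _ in parents:
            # alternate branching plane between y and x by level
            axis = 1 if level % 2 == 1 else 2
            for sign in (-1.0, 1.0):
                direction = np.array([1.0, 0.0, 0.0])
                direction[axis] = sign
                direction = direction / np.linalg.norm(direction)
                end = start + direction * length
                _mark_tube(lumen, start, end, r_mm, spec.spacing)
                children.append((end, direction))
        parents = children
        length *= 0.7
    return lumen


def _dilate_mm(mask, radius_mm, spacing):
    """Morphological dilation by a physical-radius ball via the EDT."""
    if radius_mm <= 0 or not mask.any():
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return dist <= radius_mm


def make_ct_phantom(spec: PhantomSpec) -> tuple[CTVolume, PhantomTruth]:
    """Generate a CT phantom and its ground-truth masks.

    Geometry (z axis runs cranial->caudal, z=0 is the top face): a
    soft-tissue elliptic-cylinder body spans the top 92% of the grid and is
    surrounded by exterior air that touches the lateral and caudal borders.
    Inside the body sits an ellipsoidal lung; a walled airway tree descends
    from the top face through the body into the lung.  The airway wall is
    soft tissue, so lumen and parenchyma never touch - region growing can
    be validated without incidental leaks.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape

    zz, yy, xx = np.meshgrid(
        np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"
    )
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    body = ((yy - cy) / (0.42 * ny)) ** 2 + ((xx - cx) / (0.42 * nx)) ** 2 <= 1.0
    body &= zz <= 0.92 * nz

    lung_center = (0.58 * nz, cy, cx)
    lung_semi = (0.30 * nz, 0.30 * ny, 0.30 * nx)
    lung_region = (
        ((zz - lung_center[0]) / lung_semi[0]) ** 2
        + ((yy - lung_center[1]) / lung_semi[1]) ** 2
        + ((xx - lung_center[2]) / lung_semi[2]) ** 2
    ) <= 1.0

    lumen = _airway_tree(spec, lung_center, lung_semi)
    wall = _dilate_mm(lumen, spec.wall_thickness_mm, spec.spacing) & ~lumen
    lung = lung_region & ~lumen & ~wall

    emphysema = np.zeros(spec.shape, dtype=bool)
    f = spec.emphysema_fraction
    if f > 0:
        if spec.emphysema_mode == "bernoulli":
            emphysema[lung] = rng.random(int(lung.sum())) < f
        else:  # blobs: union of random spheres until the target fraction
            target = f * lung.sum()
            r_vox = max(1, int(round(spec.blob_radius_mm / min(spec.spacing))))
            idx = np.argwhere(lung)
            while emphysema.sum() < target and idx.size:
                c = idx[rng.integers(len(idx))]
                lo = np.maximum(c - r_vox, 0)
                hi = np.minimum(c + r_vox + 1, np.array(spec.shape))
                sz, sy, sx = [np.arange(lo[a], hi[a]) for a in range(3)]
                gz, gy, gx = np.meshgrid(sz, sy, sx, indexing="ij")
                ball = (gz - c[0]) ** 2 + (gy - c[1]) ** 2 + (gx - c[2]) ** 2 <= r_vox**2
                sub = emphysema[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
                sub |= ball
            emphysema &= lung

    hu = np.full(spec.shape, spec.exterior_hu, dtype=np.float32)

    def _fill(mask, mean, sd, truncate_sd=None):
        n = int(mask.sum())
        if n == 0:
            return
        z = rng.standard_normal(n)
        if truncate_sd is not None:
            z = np.clip(z, -truncate_sd, truncate_sd)
        hu[mask] = mean + sd * z

    _fill(body, *spec.soft_tissue_hu)
    _fill(lung & ~emphysema, *spec.parenchyma_hu)
    _fill(emphysema, *spec.emphysema_hu)
    _fill(wall, *spec.soft_tissue_hu)
    _fill(lumen, *spec.airway_hu, truncate_sd=2.0)

    volume = CTVolume(hu=hu, spacing=spec.spacing)
    truth = PhantomTruth(
        lung=BinaryMask3D(lung, role="lung", spacing=spec.spacing),
        airway=BinaryMask3D(lumen, role="airway", spacing=spec.spacing),
        emphysema=BinaryMask3D(emphysema, role="emphysema", spacing=spec.spacing),
    )
    return volume, truth


# --------------------------------------------------------------------------
# Forced-expiration traces
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TracePreset:
    """Mono-/multi-exponential forced-expiration preset.

    Cumulative exhaled volume follows
    ``V(t) = FVC * sum_i a_i * (1 - exp(-(t - t_onset) / tau_i))`` for
    ``t >= t_onset`` and 0 before.  Noise is added to the flow channel
    only; the volume channel is the noiseless analytic truth, so FEV_x
    truth stays exact.
    """

    fvc_ml: float = 30.0
    fractions: tuple[float, ...] = (1.0,)
    taus_s: tuple[float, ...] = (0.2,)
    t_onset_s: float = 0.1
    dt_s: float = 0.001
    duration_s: float = 4.0
    noise_sd_ml_s: float = 0.0
    recruitment_delta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fvc_ml <= 0:
            raise InputError(f"FVC must be positive, got {self.fvc_ml}")
        if len(self.fractions) != len(self.taus_s):
            raise InputError("fractions and taus must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise InputError(f"compartment fractions must sum to 1, got {sum(self.fractions)}")
        if any(t <= 0 for t in self.taus_s):
            raise InputError(f"time constants must be positive, got {self.taus_s}")
        if self.dt_s <= 0:
            raise InputError(f"dt must be positive, got {self.dt_s}")


def analytic_volume(preset: TracePreset, t):
    """Noiseless cumulative exhaled volume at time(s) t (trace clock)."""
    t = np.asarray(t, dtype=float)
    dt_on = np.maximum(t - preset.t_onset_s, 0.0)
    v = np.zeros_like(dt_on)
    for a, tau in zip(preset.fractions, preset.taus_s):
        v += a * (1.0 - np.exp(-dt_on / tau))
    return preset.fvc_ml * v


def analytic_fev(preset: TracePreset, x_seconds: float) -> float:
    """Closed-form FEV_x (volume exhaled in the first x seconds)."""
    return float(
        preset.fvc_ml
        * sum(
            a * (1.0 - math.exp(-x_seconds / tau))
            for a, tau in zip(preset.fractions, preset.taus_s)
        )
    )


def make_expiration_trace(preset: TracePreset) -> FlowVolumeTrace:
    """Sample a forced-expiration trace from an analytic preset."""
    rng = np.random.default_rng(preset.seed)
    t = np.arange(0.0, preset.duration_s, preset.dt_s)
    volume = analytic_volume(preset, t)
    dt_on = np.maximum(t - preset.t_onset_s, 0.0)
    flow = np.zeros_like(t)
    started = t >= preset.t_onset_s
    for a, tau in zip(preset.fractions, preset.taus_s):
        flow[started] += preset.fvc_ml * a / tau * np.exp(-dt_on[started] / tau)
    if preset.noise_sd_ml_s > 0:
        flow = flow + rng.normal(0.0, preset.noise_sd_ml_s, size=flow.size)
    meta = {
        "fvc_ml": preset.fvc_ml,
        "t_onset_s": preset.t_onset_s,
        "fractions": tuple(preset.fractions),
        "taus_s": tuple(preset.taus_s),
        "preset": preset,
    }
    return FlowVolumeTrace(time_s=t, flow_ml_s=flow, volume_ml=volume, meta=meta)


# --------------------------------------------------------------------------
# PV loops and multistroke maneuvers
# --------------------------------------------------------------------------


def salazar_knowles_volume(pressure, a_ml: float, b_ml: float, k_per_cmh2o: float):
    """Single-exponential PV relation ``V(P) = A - B * exp(-K * P)``."""
    return a_ml - b_ml * np.exp(-k_per_cmh2o * np.asarray(pressure, dtype=float))


def make_pv_loop(
    a_ml: float = 60.0,
    b_ml: float = 55.0,
    k_per_cmh2o: float = 0.1,
    noise_sd_ml: float = 0.0,
    hysteresis_ml: float = 0.0,
    p_range: tuple[float, float] = (3.0, 30.0),
    n_points: int = 20,
    seed: int = 0,
) -> PVLoop:
    """Sample inflation and deflation limbs of a quasistatic PV loop.

    The deflation limb is offset upward by ``hysteresis_ml`` at every
    shared pressure.
    """
    if k_per_cmh2o < 0:
        raise InputError(f"K must be >= 0, got {k_per_cmh2o}")
    p_min, p_max = p_range
    if not (a_ml > b_ml * math.exp(-k_per_cmh2o * p_min) >= 0):
        raise InputError(
            "invalid PV parameters: require A > B*exp(-K*P_min) >= 0 "
            f"(A={a_ml}, B={b_ml}, K={k_per_cmh2o}, P_min={p_min})"
        )
    rng = np.random.default_rng(seed)
    p_up = np.linspace(p_min, p_max, n_points)
    p_down = p_up[::-1]
    v_up = salazar_knowles_volume(p_up, a_ml, b_ml, k_per_cmh2o)
    v_down = salazar_knowles_volume(p_down, a_ml, b_ml, k_per_cmh2o) + hysteresis_ml
    if noise_sd_ml > 0:
        v_up = v_up + rng.normal(0, noise_sd_ml, size=v_up.size)
        v_down = v_down + rng.normal(0, noise_sd_ml, size=v_down.size)
    pressure = np.concatenate([p_up, p_down])
    volume = np.concatenate([v_up, v_down])
    limb = np.array(["inflation"] * n_points + ["deflation"] * n_points)
    meta = {"a_ml": a_ml, "b_ml": b_ml, "k_per_cmh2o": k_per_cmh2o, "hysteresis_ml": hysteresis_ml}
    return PVLoop(pressure_cmh2o=pressure, volume_ml=volume, limb=limb, meta=meta)


def make_multistroke_segments(
    pv_volume,
    delta: float = 0.0,
    pressures: tuple[float, float, float] = (3.0, 15.0, 30.0),
) -> tuple[ManeuverSegment, ManeuverSegment]:
    """Simulate the two-stroke IC maneuver from a monotone PV relation.

    ``pv_volume`` maps pressure (cmH2O) to absolute lung volume (mL).  The
    recruitment offset ``delta`` inflates the second stroke's delivered
    volume such that the summed maneuver overreads the true single-stroke
    IC by the factor ``(1 + delta)`` - mirroring the empirical multistroke
    overestimate, which the analysis-side correction divides back out.
    """
    p0, p1, p2 = pressures
    v0, v1, v2 = (float(pv_volume(p)) for p in pressures)
    stroke1 = v1 - v0
    true_ic = v2 - v0
    stroke2 = (v2 - v1) + delta * true_ic
    return (
        ManeuverSegment(start_cmh2o=p0, end_cmh2o=p1, volume_ml=stroke1),
        ManeuverSegment(start_cmh2o=p1, end_cmh2o=p2, volume_ml=stroke2),
    )


# --------------------------------------------------------------------------
# Airspace images
# --------------------------------------------------------------------------


def make_airspace_image(
    shapes: list[dict],
    canvas: tuple[int, int] = (512, 512),
    pixel_size_um: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render non-overlapping squares/disks as a binary airspace image.

    Each shape dict is ``{"kind": "square", "size": px, "center": (r, c)}``
    or ``{"kind": "disk", "radius": px, "center": (r, c)}``.  Returns the
    boolean image (airspace = True) and a truth table with analytic area
    and perimeter in pixel units.

    Raises :class:`InputError` on overlapping shapes or shapes that exceed
    the canvas.
    """
    img = np.zeros(canvas, dtype=bool)
    rows = []
    for i, sh in enumerate(shapes):
        mask = np.zeros(canvas, dtype=bool)
        r0, c0 = sh["center"]
        if sh["kind"] == "square":
            s = int(sh["size"])
            top, left = int(round(r0 - s / 2)), int(round(c0 - s / 2))
            if top < 0 or left < 0 or top + s > canvas[0] or left + s > canvas[1]:
                raise InputError(f"shape {i} exceeds canvas")
            mask[top : top + s, left : left + s] = True
            area, perim = float(s * s), float(4 * s)
        elif sh["kind"] == "disk":
            rad = float(sh["radius"])
            if r0 - rad < 0 or c0 - rad < 0 or r0 + rad >= canvas[0] or c0 + rad >= canvas[1]:
                raise InputError(f"shape {i} exceeds canvas")
            rr, cc = np.meshgrid(np.arange(canvas[0]), np.arange(canvas[1]), indexing="ij")
            mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
            area, perim = math.pi * rad**2, 2 * math.pi * rad
        else:
            raise InputError(f"unknown shape kind {sh['kind']!r}")
        if (img & mask).any():
            raise InputError(f"shape {i} overlaps a previous shape")
        img |= mask
        rows.append(
            {
                "shape": i,
                "kind": sh["kind"],
                "area_px2": area,
                "perimeter_px": perim,
                "sa_p_px": area / perim,
            }
        )
    truth = pd.DataFrame(rows, columns=["shape", "kind", "area_px2", "perimeter_px", "sa_p_px"])
    return img, truth


# --------------------------------------------------------------------------
# Longitudinal cohorts
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortPreset:
    """Generating model for a longitudinal IC/Ln cohort.

    ``value = sex_intercept + animal_intercept + beta * age + noise`` with
    per-animal random intercepts ~ N(0, random_intercept_sd^2) and i.i.d.
    residuals ~ N(0, residual_sd^2).  The three named presets carry the
    genotype-specific age slopes used as recovery targets.
    """

    genotype: str = "PiMM"
    n_animals: int = 19
    visit_ages_days: tuple[float, ...] = tuple(np.linspace(100, 1000, 6))
    beta_ml_cm_day: float = 0.000093
    sex_intercepts: dict = field(default_factory=lambda: {"F": 0.75, "M": 1.05})
    random_intercept_sd: float = 0.08
    residual_sd: float = 0.05
    body_length_cm: dict = field(default_factory=lambda: {"F": 38.0, "M": 44.0})
    seed: int = 0

    def __post_init__(self):
        if self.n_animals < 1:
            raise InputError("cohort needs at least 1 animal")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise InputError("SDs must be >= 0")
        if len(self.visit_ages_days) == 0:
            raise InputError("visit schedule is empty")
        ages = np.asarray(self.visit_ages_days)
        if np.any(np.diff(ages) <= 0):
            raise InputError("visit ages must be strictly increasing")


COHORT_PRESETS: dict[str, CohortPreset] = {
    "PiMM": CohortPreset(
        genotype="PiMM",
        n_animals=19,
        visit_ages_days=tuple(np.linspace(100, 1000, 6)),
        beta_ml_cm_day=0.000093,
    ),
    "PiZZ": CohortPreset(
        genotype="PiZZ",
        n_animals=6,
        visit_ages_days=tuple(np.linspace(100, 700, 6)),
        beta_ml_cm_day=0.00043,
    ),
    "AAT-KO": CohortPreset(
        genotype="AAT-KO",
        n_animals=13,
        visit_ages_days=tuple(np.linspace(100, 1100, 7)),
        beta_ml_cm_day=0.00036,
    ),
}


def make_cohort(preset: CohortPreset, seed: int | None = None) -> pd.DataFrame:
    """Generate a tidy longitudinal cohort table.

    One row per animal-visit with columns ``animal, genotype, sex,
    age_days, body_length_cm, ic_per_ln``.  Sexes alternate so cohorts are
    balanced.  Generating parameters are echoed in ``df.attrs``.
    """
    if seed is not None:
        preset = replace(preset, seed=seed)
    rng = np.random.default_rng(preset.seed)
    rows = []
    for i in range(preset.n_animals):
        sex = "F" if i % 2 == 0 else "M"
        intercept = preset.sex_intercepts[sex] + rng.normal(0, preset.random_intercept_sd)
        length = preset.body_length_cm[sex] + rng.normal(0, 1.0)
        for age in preset.visit_ages_days:
            value = (
                intercept
                + preset.beta_ml_cm_day * age
                + rng.normal(0, preset.residual_sd)
            )
            rows.append(
                {
                    "animal": f"{preset.genotype}-{i:02d}",
                    "genotype": preset.genotype,
                    "sex": sex,
                    "age_days": float(age),
                    "body_length_cm": float(length),
                    "ic_per_ln": float(value),
                }
            )
    df = pd.DataFrame(rows)
    df.attrs["generating_beta_ml_cm_day"] = preset.beta_ml_cm_day
    df.attrs["preset"] = preset
    return df


# --------------------------------------------------------------------------
# NE-inhibition curves
# --------------------------------------------------------------------------


def make_inhibition_curve(
    volumes_ul,
    slope_per_ul: float | None = None,
    saturating: tuple[float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Residual protease activity vs sample volume.

    Either ``slope_per_ul`` (linear decay, clipped to [0, 1]) or
    ``saturating = (floor, tau_ul)`` (exponential approach to ``floor``)
    must be given.  Activity at volume 0 is exactly 1 by the assay's
    normalisation to the no-sample control well.
    """
    volumes = np.asarray(volumes_ul, dtype=float)
    if np.any(volumes < 0):
        raise InputError("volumes must be non-negative")
    if len(np.unique(volumes)) != len(volumes):
        raise InputError("duplicate volumes in inhibition curve")
    if (slope_per_ul is None) == (saturating is None):
        raise InputError("specify exactly one of slope_per_ul or saturating")
    order = np.argsort(volumes)
    volumes = volumes[order]
    if slope_per_ul is not None:
        activity = np.clip(1.0 - slope_per_ul * volumes, 0.0, 1.0)
    else:
        floor, tau = saturating
        activity = floor + (1.0 - floor) * np.exp(-volumes / tau)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        activity = np.clip(activity + rng.normal(0, noise_sd, size=activity.size), 0.0, 1.0)
    activity[volumes == 0] = 1.0  # normalisation anchor
    return pd.DataFrame({"volume_ul": volumes, "activity": activity})
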