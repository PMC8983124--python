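"""Shared in-memory containers for volumes, masks, and respiratory signals.

Conventions
-----------
* CT volumes are stored as arrays of Hounsfield units (HU).  The default
  axis order is ``zyx`` with ``z=0`` the cranial (top) face; spacing is
  millimetres per axis in the same order.  Physical coordinates are
  ``index * spacing`` (0-based indices).
* Masks share their volume's grid exactly and carry a ``role`` tag so
  downstream stages can assert they were handed the right one.
* Respiratory traces are uniformly sampled; cumulative exhaled volume is
  referenced to the start of the recording (zero before exhalation onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class CTVolume:
    """A 3D grid of Hounsfield units with physical voxel spacing."""

    hu: np.ndarray
    spacing: tuple[float, float, float]
    axis_order: str = "zyx"

    def __post_init__(self):
        self.hu = np.asarray(self.hu)
        if self.hu.ndim != 3:
            raise InputError(f"CT volume must be 3D, got shape {self.hu.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.hu)):
            raise InputError("CT volume contains non-finite HU values")

    @property
    def shape(self):
        return self.hu.shape

    def permuted(self, order: tuple[int, int, int]) -> "CTVolume":
        """Relabel axes (spacing permuted accordingly); %LAA is invariant."""
        return CTVolume(
            hu=np.transpose(self.hu, order),
            spacing=tuple(self.spacing[a] for a in order),
            axis_order="".join(self.axis_order[a] for a in order),
        )


@dataclass
class BinaryMask3D:
    """Boolean grid aligned to a CTVolume, tagged with its role."""

    mask: np.ndarray
    role: str  # "lung" | "airway" | "refined-lung" | ...
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise InputError(f"mask must be 3D, got shape {self.mask.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self):
        return self.mask.shape

    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class FlowVolumeTrace:
    """Uniformly sampled forced-expiration signals.

    ``volume_ml`` is cumulative exhaled volume (mL); ``flow_ml_s`` is
    expiratory flow (mL/s, positive during exhalation).
    """

    time_s: np.ndarray
    flow_ml_s: np.ndarray
    volume_ml: np.ndarray
    pressure_cmh2o: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.flow_ml_s = np.asarray(self.flow_ml_s, dtype=float)
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        n = self.time_s.size
        if self.flow_ml_s.size != n or self.volume_ml.size != n:
            raise InputError("trace columns must have equal length")
        if n < 2:
            raise InputError("trace needs at least 2 samples")
        dts = np.diff(self.time_s)
        if np.any(dts <= 0):
            bad = int(np.argmax(dts <= 0))
            raise InputError(f"time must be strictly increasing (violation at sample {bad + 1})")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.time_s)))


@dataclass
class PVLoop:
    """Quasistatic pressure-volume loop with labelled limbs."""

    pressure_cmh2o: np.ndarray
    volume_ml: np.ndarray
    limb: np.ndarray  # "inflation" | "deflation" per sample
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pressure_cmh2o = np.asarray(self.pressure_cmh2o, dtype=float)
        self.volume_ml = np.asarray(self.volume_ml, dtype=float)
        self.limb = np.asarray(self.limb)
        if not (self.pressure_cmh2o.size == self.volume_ml.size == self.limb.size):
            raise InputError("PV-loop columns must have equal length")

    def limb_points(self, which: str):
        """Return (pressure, volume) of one limb sorted by ascending pressure."""
        sel = self.limb == which
        p = self.pressure_cmh2o[sel]
        v = self.volume_ml[sel]
        order = np.argsort(p)
        return p[order], v[order]


@dataclass
class ManeuverSegment:
    """One inflation stroke: pressure range and delivered volume."""

    start_cmh2o: float
    end_cmh2o: float
    volume_ml: float

    def __post_init__(self):
        if self.end_cmh2o <= self.start_cmh2o:
            raise InputError(
                f"segment end pressure ({self.end_cmh2o}) must exceed start ({self.start_cmh2o})"
            )
        if self.volume_ml <= 0:
            raise InputError(f"segment volume must be positive, got {self.volume_ml}")
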