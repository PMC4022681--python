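"""Data containers, NIfTI volume I/O, and protocol timing arithmetic.

All containers carry voxel size explicitly so physical units never depend on
header conventions.  Voxel indices are 0-based with axis order ``(x, y, z)``
and, for multi-TSL series, ``(x, y, z, TSL)``.  Spin-lock-time metadata lives
in a YAML sidecar keyed ``tsl_ms`` because NIfTI has no TSL field.

Invalid voxels in derived maps are stored as NaN; zeroing for display is a
separate, explicit step (:func:`t1rhomap.mapping.apply_display_rules`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

logger = logging.getLogger(__name__)

#: Gyromagnetic ratio of 1H in MHz/T; ppm -> Hz conversion uses this times field strength.
GAMMA_MHZ_PER_T = 42.5764

# Integer label codes shared by RegionMask producers/consumers.
LABEL_BACKGROUND = 0
LABEL_DEEP = 1
LABEL_MIDDLE = 2
LABEL_SUPERFICIAL = 3
LABEL_FLUID = 4
LABEL_BONE = 5

SIDE_NONE = 0
SIDE_MEDIAL = 1
SIDE_LATERAL = 2

CARTILAGE_LABELS = (LABEL_DEEP, LABEL_MIDDLE, LABEL_SUPERFICIAL)


@dataclass
class TslSeries:
    """Stack of magnitude volumes indexed by spin-lock time.

    Parameters
    ----------
    volumes : ndarray, shape (x, y, z, n_tsl)
        Magnitude signal in arbitrary units; must be non-negative.
    tsl_ms : sequence of float
        Spin-lock durations in ms, strictly increasing, first >= 0.
    voxel_size_mm : 3-sequence of float
    field_T : float
        Static field strength in Tesla.
    b1sl_hz : float
        Spin-lock amplitude in Hz.
    """

    volumes: np.ndarray
    tsl_ms: list[float]
    voxel_size_mm: tuple[float, float, float] = (0.3125, 0.3125, 3.0)
    field_T: float = 7.0
    b1sl_hz: float = 500.0

    def __post_init__(self) -> None:
        self.volumes = np.asarray(self.volumes, dtype=float)
        self.tsl_ms = [float(t) for t in self.tsl_ms]
        if self.volumes.ndim != 4:
            raise ValueError("volumes must be 4D (x, y, z, TSL)")
        if self.volumes.shape[3] != len(self.tsl_ms):
            raise ValueError(
                f"number of volumes ({self.volumes.shape[3]}) does not match "
                f"length of tsl_ms ({len(self.tsl_ms)})"
            )
        diffs = np.diff(self.tsl_ms)
        if len(self.tsl_ms) == 0 or self.tsl_ms[0] < 0 or np.any(diffs <= 0):
            raise ValueError("tsl_ms must be strictly increasing with first element >= 0")
        if np.any(self.volumes < 0):
            raise ValueError("magnitude signal must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.volumes.shape[:3]

    @property
    def n_tsl(self) -> int:
        return len(self.tsl_ms)


@dataclass
class FieldMap:
    """Scalar per-voxel map: B0 offset in Hz (``b0_hz``) or relative B1 (``b1rel``)."""

    values: np.ndarray
    kind: str
    voxel_size_mm: tuple[float, float, float] = (0.3125, 0.3125, 3.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("b0_hz", "b1rel"):
            raise ValueError(f"unknown field-map kind {self.kind!r}")
        if self.values.ndim != 3:
            raise ValueError("FieldMap values must be 3D")
        defined = np.isfinite(self.values)
        if self.kind == "b1rel" and np.any(self.values[defined] <= 0):
            raise ValueError("b1rel values must be > 0 where defined")


@dataclass
class RegionMask:
    """Integer label volume for cartilage zones plus a medial/lateral side code.

    ``labels`` uses the module-level codes (background 0, deep 1, middle 2,
    superficial 3, fluid 4, bone 5).  ``side`` is 0 outside cartilage and
    medial/lateral (1/2) on cartilage voxels once a divider has been applied.
    """

    labels: np.ndarray
    side: np.ndarray | None = None
    voxel_size_mm: tuple[float, float, float] = (0.3125, 0.3125, 3.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            self.labels = self.labels.astype(np.int16)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.side is None:
            self.side = np.zeros_like(self.labels)
        else:
            self.side = np.asarray(self.side).astype(self.labels.dtype)
            if self.side.shape != self.labels.shape:
                raise ValueError("side must match labels shape")

    @property
    def cartilage(self) -> np.ndarray:
        """Boolean mask of all cartilage voxels (any zone)."""
        return np.isin(self.labels, CARTILAGE_LABELS)


@dataclass
class ProtocolSpec:
    """Acquisition protocol description used for timing/resolution arithmetic.

    Defaults reproduce the 7T knee protocol: 5 TSLs, 10 slice encodes,
    2 shots per slice encode, 5 s shot TR, FOV 140x140 mm, matrix 448x224,
    and the seven named protocol segments (localizer, shim/prescan,
    structural, SVS, axial T1rho, SVS, coronal T1rho) in minutes.
    """

    n_tsl: int = 5
    n_slice_encodes: int = 10
    shots_per_slice_encode: int = 2
    shot_tr_s: float = 5.0
    segment_minutes: list[float] = field(
        default_factory=lambda: [0.5, 1.0, 4.0, 2.0, 8.3, 2.0, 8.3]
    )
    fov_mm: tuple[float, float] = (140.0, 140.0)
    matrix: tuple[int, int] = (448, 224)

    def __post_init__(self) -> None:
        for name in ("n_tsl", "n_slice_encodes", "shots_per_slice_encode"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.shot_tr_s <= 0:
            raise ValueError("shot_tr_s must be > 0")
        if any(s <= 0 for s in self.segment_minutes):
            raise ValueError("segment durations must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def scan_time_s(p: ProtocolSpec) -> float:
    """Total acquisition time of one multi-TSL 3D set, in seconds.

    One shot is played per (TSL, slice encode, shot) combination, so the time
    is the plain product ``n_tsl * n_slice_encodes * shots * shot_TR``.
    """
    return p.n_tsl * p.n_slice_encodes * p.shots_per_slice_encode * p.shot_tr_s


def protocol_total_minutes(p: ProtocolSpec) -> float:
    """Sum of all named protocol segment durations in minutes."""
    if not p.segment_minutes:
        raise ValueError("segment_minutes is empty")
    return float(sum(p.segment_minutes))


def inplane_voxel_area_mm2(p: ProtocolSpec) -> float:
    """In-plane voxel area (mm^2) = (FOVx/Nx) * (FOVy/Ny)."""
    nx, ny = p.matrix
    if nx == 0 or ny == 0:
        raise ValueError("matrix dimensions must be nonzero")
    return (p.fov_mm[0] / nx) * (p.fov_mm[1] / ny)


# ---------------------------------------------------------------------------
# NIfTI I/O


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".yaml")
    return path.with_suffix(".yaml")


def write_volume(obj, path: str | Path) -> Path:
    """Write a container to NIfTI (plus a YAML sidecar for series metadata).

    ``TslSeries`` writes its TSL list, field strength and lock amplitude to a
    sidecar next to the image.  ``FieldMap`` records its kind, ``RegionMask``
    its side codes.  NaN (invalid) voxels are preserved as NaN.
    """
    path = Path(path)
    if isinstance(obj, TslSeries):
        img = nib.Nifti1Image(obj.volumes.astype(np.float64), _affine(obj.voxel_size_mm))
        nib.save(img, path)
        sidecar = {
            "tsl_ms": list(obj.tsl_ms),
            "field_T": float(obj.field_T),
            "b1sl_hz": float(obj.b1sl_hz),
        }
        with open(_sidecar_path(path), "w") as fh:
            yaml.safe_dump(sidecar, fh)
    elif isinstance(obj, FieldMap):
        img = nib.Nifti1Image(obj.values.astype(np.float64), _affine(obj.voxel_size_mm))
        img.header["descrip"] = obj.kind.encode()
        nib.save(img, path)
    elif isinstance(obj, RegionMask):
        img = nib.Nifti1Image(obj.labels.astype(np.int16), _affine(obj.voxel_size_mm))
        nib.save(img, path)
        if np.any(obj.side):
            side_path = path.with_name("side_" + path.name)
            nib.save(nib.Nifti1Image(obj.side.astype(np.int16), _affine(obj.voxel_size_mm)), side_path)
    elif isinstance(obj, np.ndarray):
        nib.save(nib.Nifti1Image(obj.astype(np.float64), np.eye(4)), path)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    return path


def read_volume(path: str | Path, kind: str | None = None) -> TslSeries | FieldMap | RegionMask:
    """Read a NIfTI volume back into the matching container.

    4D images require a ``tsl_ms`` sidecar (written by :func:`write_volume`)
    and return a :class:`TslSeries`; the function fails rather than guessing
    spin-lock times.  3D images return a :class:`FieldMap` when ``kind`` is
    ``"b0_hz"``/``"b1rel"`` (or recorded in the header), a :class:`RegionMask`
    when ``kind="labels"`` or the data are integer-valued.
    """
    path = Path(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    if data.ndim == 4:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise FileNotFoundError(
                f"4D series {path} needs a sidecar {sidecar.name} with key 'tsl_ms'"
            )
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh)
        if "tsl_ms" not in meta:
            raise KeyError(f"sidecar {sidecar} missing required key 'tsl_ms'")
        return TslSeries(
            volumes=data,
            tsl_ms=meta["tsl_ms"],
            voxel_size_mm=voxel,
            field_T=meta.get("field_T", 7.0),
            b1sl_hz=meta.get("b1sl_hz", 500.0),
        )
    if data.ndim != 3:
        raise ValueError(f"expected 3D or 4D image, got {data.ndim}D")
    if kind is None:
        descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(errors="ignore")
        if descrip in ("b0_hz", "b1rel"):
            kind = descrip
        elif np.issubdtype(data.dtype, np.integer):
            kind = "labels"
        else:
            raise ValueError(
                f"cannot infer container kind for {path}; pass kind='b0_hz', 'b1rel' or 'labels'"
            )
    if kind == "labels":
        side_path = path.with_name("side_" + path.name)
        side = None
        if side_path.exists():
            side = np.asanyarray(nib.load(side_path).dataobj)
        return RegionMask(labels=data, side=side, voxel_size_mm=voxel)
    return FieldMap(values=data, kind=kind, voxel_size_mm=voxel)
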