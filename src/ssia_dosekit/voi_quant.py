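"""Volume-of-interest quantification on 3-D SUV PET volumes.

Volumes are NIfTI images (nibabel) or ``(array, spacing)`` pairs already
calibrated to SUV.  Coordinates are world millimetres (RAS); sphere VOIs
include a voxel when its *center* lies inside the sphere, threshold VOIs are
the 26-connected supra-cutoff component containing a seed (so a tumour-local
mask is obtained even when distant organs also exceed the cutoff), and masks
are stored in the voxel index space of the reference scan, which makes
propagation across co-registered same-grid scans a no-op on the mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

__all__ = [
    "SuvVolume",
    "SphereVoi",
    "MaskVoi",
    "VoiStats",
    "EmptyVoiError",
    "GridMismatchError",
    "as_suv_volume",
    "voi_stats",
    "threshold_voi",
    "propagate_voi",
    "mirror_background_voi",
    "voi_to_json",
    "voi_from_json",
]


class EmptyVoiError(ValueError):
    """The VOI does not intersect the image grid / contains no voxels."""


class GridMismatchError(ValueError):
    """Two scans do not share a common voxel grid."""


@dataclass(frozen=True)
class SuvVolume:
    """A 3-D SUV image with its voxel-to-world affine (mm)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def voxel_volume_ml(self) -> float:
        return abs(float(np.linalg.det(self.affine[:3, :3]))) / 1000.0

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of voxel centers."""
        idx = np.indices(self.data.shape, dtype=float)
        ijk = np.stack([idx[0], idx[1], idx[2]], axis=-1)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, point_mm: Sequence[float]) -> tuple[int, int, int]:
        inv = np.linalg.inv(self.affine)
        ijk = inv[:3, :3] @ np.asarray(point_mm, dtype=float) + inv[:3, 3]
        return tuple(int(round(c)) for c in ijk)

    def same_grid(self, other: "SuvVolume") -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )


def as_suv_volume(volume) -> SuvVolume:
    """Coerce a nibabel spatial image or ``(array, spacing)`` to SuvVolume."""
    if isinstance(volume, SuvVolume):
        return volume
    if hasattr(volume, "get_fdata") and hasattr(volume, "affine"):
        return SuvVolume(np.asarray(volume.get_fdata(), dtype=float), np.asarray(volume.affine))
    if isinstance(volume, tuple) and len(volume) == 2:
        data, spacing = volume
        affine = np.diag(list(np.asarray(spacing, dtype=float)) + [1.0])
        return SuvVolume(np.asarray(data, dtype=float), affine)
    raise TypeError("expected SuvVolume, nibabel image, or (array, spacing) tuple")


@dataclass(frozen=True)
class SphereVoi:
    """A spherical VOI given by world-mm center and diameter."""

    center_mm: tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("sphere diameter must be positive")

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def volume_ml(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm**3 / 1000.0


@dataclass(frozen=True)
class MaskVoi:
    """An explicit voxel mask in the index space of a reference grid."""

    mask: np.ndarray  # boolean, same shape as the reference volume
    cutoff: Optional[float] = None  # set when derived from a threshold

    def __post_init__(self) -> None:
        if self.mask.dtype != bool:
            object.__setattr__(self, "mask", self.mask.astype(bool))
        if not self.mask.any():
            raise EmptyVoiError("mask VOI contains no voxels")


Voi = Union[SphereVoi, MaskVoi]


@dataclass(frozen=True)
class VoiStats:
    suv_max: float
    suv_mean: float
    volume_ml: float
    n_voxels: int

    def __post_init__(self) -> None:
        if not self.suv_max >= self.suv_mean:
            raise ValueError("suv_max must be >= suv_mean")


def _voi_mask(vol: SuvVolume, voi: Voi) -> np.ndarray:
    if isinstance(voi, MaskVoi):
        if voi.mask.shape != vol.data.shape:
            raise GridMismatchError(
                f"mask shape {voi.mask.shape} does not match volume {vol.data.shape}"
            )
        return voi.mask
    centers = vol.voxel_centers_mm()
    d2 = np.sum((centers - np.asarray(voi.center_mm)) ** 2, axis=-1)
    return d2 <= voi.radius_mm**2


def voi_stats(volume, voi: Voi) -> VoiStats:
    """SUVmax, SUVmean and volume over the voxels whose centers fall in the VOI."""
    vol = as_suv_volume(volume)
    mask = _voi_mask(vol, voi)
    n = int(mask.sum())
    if n == 0:
        raise EmptyVoiError("VOI does not contain any voxel center")
    values = vol.data[mask]
    return VoiStats(
        suv_max=float(values.max()),
        suv_mean=float(values.mean()),
        volume_ml=n * vol.voxel_volume_ml,
        n_voxels=n,
    )


_CONN26 = np.ones((3, 3, 3), dtype=int)


def threshold_voi(
    volume,
    cutoff: float = 2.0,
    seed_mm: Optional[Sequence[float]] = None,
) -> tuple[MaskVoi, float]:
    """Supra-cutoff VOI: 26-connected component containing the seed.

    Without a seed the component containing the hottest voxel is used.
    Returns the mask VOI and its uptake volume in mL.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    vol = as_suv_volume(volume)
    above = vol.data >= cutoff
    if not above.any():
        raise EmptyVoiError(f"no voxel reaches the SUV cutoff {cutoff}")
    labels, _ = ndimage.label(above, structure=_CONN26)
    if seed_mm is None:
        seed_idx = np.unravel_index(int(np.argmax(vol.data)), vol.data.shape)
    else:
        seed_idx = vol.world_to_voxel(seed_mm)
        if not all(0 <= c < s for c, s in zip(seed_idx, vol.data.shape)):
            raise EmptyVoiError(f"seed {seed_mm} lies outside the image grid")
    component = labels[seed_idx]
    if component == 0:
        raise EmptyVoiError("seed voxel is below the cutoff")
    mask = labels == component
    voi = MaskVoi(mask=mask, cutoff=cutoff)
    return voi, float(mask.sum()) * vol.voxel_volume_ml


def propagate_voi(voi: Voi, from_scan, to_scan) -> Voi:
    """Copy a VOI from one scan to a co-registered scan on the same grid."""
    src = as_suv_volume(from_scan)
    dst = as_suv_volume(to_scan)
    if not src.same_grid(dst):
        raise GridMismatchError(
            "scans do not share a grid: "
            f"shapes {src.data.shape} vs {dst.data.shape}, affines differ by "
            f"{np.abs(src.affine - dst.affine).max():g} mm"
        )
    return voi


def mirror_background_voi(
    tumour_voi: SphereVoi, midline_x_mm: float = 0.0
) -> SphereVoi:
    """Equal-volume sphere reflected across the sagittal midline plane.

    The tumour sphere must lie fully on one side of the plane; a straddling
    VOI raises, and the caller must supply an explicit background VOI
    (e.g. a cranio-caudal placement) instead.
    """
    offset = tumour_voi.center_mm[0] - midline_x_mm
    if abs(offset) <= tumour_voi.radius_mm:
        raise ValueError(
            "tumour VOI straddles the midline; supply an explicit background VOI"
        )
    mirrored = (
        midline_x_mm - offset,
        tumour_voi.center_mm[1],
        tumour_voi.center_mm[2],
    )
    return SphereVoi(center_mm=mirrored, diameter_mm=tumour_voi.diameter_mm)


# ---------------------------------------------------------------------------
# JSON (de)serialisation, run-length encoding for masks


def _rle_encode(flat: np.ndarray) -> list[int]:
    # counts of alternating runs, starting with zeros
    changes = np.nonzero(np.diff(flat.astype(np.int8)))[0] + 1
    edges = np.concatenate([[0], changes, [len(flat)]])
    runs = np.diff(edges).tolist()
    if flat[0]:
        runs = [0] + runs
    return [int(r) for r in runs]


def voi_to_json(voi: Voi) -> str:
    if isinstance(voi, SphereVoi):
        return json.dumps(
            {"kind": "sphere", "center_mm": list(voi.center_mm), "diameter_mm": voi.diameter_mm}
        )
    return json.dumps(
        {
            "kind": "mask",
            "shape": list(voi.mask.shape),
            "rle": _rle_encode(voi.mask.ravel()),
            "cutoff": voi.cutoff,
        }
    )


def voi_from_json(text: str) -> Voi:
    obj = json.loads(text)
    if obj["kind"] == "sphere":
        return SphereVoi(center_mm=tuple(obj["center_mm"]), diameter_mm=obj["diameter_mm"])
    if obj["kind"] == "mask":
        flat = np.zeros(int(np.prod(obj["shape"])), dtype=bool)
        pos, value = 0, False
        for run in obj["rle"]:
            if value:
                flat[pos : pos + run] = True
            pos += run
            value = not value
        return MaskVoi(mask=flat.reshape(obj["shape"]), cutoff=obj.get("cutoff"))
    raise ValueError(f"unknown VOI kind {obj.get('kind')!r}")
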