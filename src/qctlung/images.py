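"""Grid-aligned image containers and NIfTI I/O.

Conventions
-----------
Arrays are indexed ``(i, j, k)``; voxel ``(i, j, k)`` sits at world position
``origin + (i, j, k) * spacing`` in mm.  Displacement fields are stored as a
trailing length-3 axis in the same (i, j, k) world frame, in mm, and map a
point on the *expiration* grid to its corresponding *inspiration*-space
location ``x + u(x)``.

NIfTI files are written with a diagonal affine built from spacing and origin;
orientation flips/rotations from external data are not interpreted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

#: Canonical lobe labels: left/right upper, right middle, left/right lower.
LOBE_LABELS: dict[str, int] = {"LUL": 1, "LLL": 2, "RUL": 3, "RML": 4, "RLL": 5}


@dataclass
class ImageVolume:
    """A 3-D scalar grid (HU or derived fractions) with mm spacing."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"ImageVolume requires a 3-D array, got ndim={self.data.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "ImageVolume | LobeMask | DisplacementField") -> bool:
        return (
            tuple(self.data.shape[:3]) == tuple(other.data.shape[:3])
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data, self.spacing, self.origin)


#: A FractionMap is an ImageVolume whose values are volume fractions in [0, 1]
#: (NaN marks voxels invalidated by out-of-domain warping).
FractionMap = ImageVolume


@dataclass
class LobeMask:
    """Integer lobe-label grid aligned to an :class:`ImageVolume`.

    Label 0 is background; nonzero labels follow :data:`LOBE_LABELS` unless a
    custom ``labels`` mapping is supplied.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: dict[str, int] = field(default_factory=lambda: dict(LOBE_LABELS))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"LobeMask requires a 3-D array, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int16)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def lung(self) -> np.ndarray:
        """Boolean mask of all labelled (nonzero) voxels."""
        return self.data > 0

    def lobe(self, name: str) -> np.ndarray:
        if name not in self.labels:
            raise KeyError(f"unknown lobe {name!r}; known: {sorted(self.labels)}")
        return self.data == self.labels[name]


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) in mm on the expiration grid.

    ``data`` has shape ``(nx, ny, nz, 3)``; the mapping is ``x -> x + u(x)``
    from expiration-grid world coordinates into inspiration space.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise ValueError(
                f"DisplacementField requires shape (nx, ny, nz, 3), got {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape[:3]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def write_volume(volume: ImageVolume | LobeMask | DisplacementField, path: str) -> None:
    """Write a scalar volume, label mask or 3-component field as NIfTI-1."""
    data = volume.data
    if isinstance(volume, LobeMask):
        data = data.astype(np.int16)
    img = nib.Nifti1Image(data, _affine(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, path)


def read_volume(path: str) -> ImageVolume:
    """Read a 3-D scalar NIfTI volume; round-trips voxel data bit-exactly."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D scalar payload, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def read_lobe_mask(path: str, labels: dict[str, int] | None = None) -> LobeMask:
    vol = read_volume(path)
    return LobeMask(
        np.rint(vol.data).astype(np.int16),
        vol.spacing,
        vol.origin,
        labels=dict(labels or LOBE_LABELS),
    )


def read_field(path: str) -> DisplacementField:
    """Read a displacement field stored as a 4-D (x, y, z, 3) NIfTI."""
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a (nx, ny, nz, 3) vector payload, got {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DisplacementField(data, spacing, origin)


def asdict_config(obj) -> dict:
    """Dataclass -> JSON-serialisable dict (numpy scalars/arrays unwrapped)."""

    def clean(v):
        if isinstance(v, np.ndarray):
            return v.tolist()
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        return v

    return clean(dataclasses.asdict(obj))
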