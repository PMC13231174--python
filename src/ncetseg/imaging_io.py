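"""NIfTI input/output and the label convention shared by the whole pipeline.

All volumes handled here are assumed to be preprocessed upstream: co-registered,
skull-stripped and resampled to a common (typically 1 mm isotropic) grid.
Anatomical tumor labels follow the BraTS-style convention; the output label map
adds code 3 for the putative non-contrast-enhancing tumor (nCET) subregion:

====  =========================
code  tissue
====  =========================
0     background
1     necrosis
2     edema (vasogenic on output)
3     nCET (output only)
4     contrast-enhancing tumor
====  =========================
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

BACKGROUND = 0
NECROSIS = 1
EDEMA = 2
NCET = 3  # output-only code
CET = 4

ANATOMY_CODES = frozenset({BACKGROUND, NECROSIS, EDEMA, CET})
OUTPUT_CODES = frozenset({BACKGROUND, NECROSIS, EDEMA, NCET, CET})

#: tolerances for grid comparison (mm for spacing, absolute for affines)
SPACING_ATOL = 1e-4
AFFINE_ATOL = 1e-3


class GridMismatchError(ValueError):
    """Raised when volumes that must share a voxel grid do not."""


@dataclass
class IntensityVolume:
    """A 3D scalar image on a regular grid with physical voxel spacing.

    Parameters
    ----------
    data
        3D array of intensities (arbitrary units).
    spacing
        Voxel edge lengths in mm, one per axis.
    affine
        4x4 voxel-to-world transform.
    """

    data: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    name: str = "volume"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)
        if self.data.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got shape {self.data.shape} for {self.name!r}"
            )
        if min(self.data.shape) < 1:
            raise ValueError(f"empty volume {self.name!r}")
        if np.any(self.spacing <= 0):
            raise ValueError(f"non-positive voxel spacing {self.spacing} for {self.name!r}")
        n_nan = int(np.isnan(self.data).sum())
        if n_nan:
            raise ValueError(f"{self.name!r} contains {n_nan} NaN voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class AnatomyLabelMap:
    """Per-voxel categorical map with BraTS-style codes {0,1,2,4}."""

    labels: np.ndarray
    spacing: np.ndarray
    affine: np.ndarray
    name: str = "anatomy"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = np.rint(self.labels).astype(np.int32)
            if not np.allclose(self.labels, as_int, atol=1e-6):
                raise ValueError(f"label map {self.name!r} holds non-integer values")
            self.labels = as_int
        self.labels = self.labels.astype(np.uint8)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.affine = np.asarray(self.affine, dtype=np.float64).reshape(4, 4)
        if self.labels.ndim != 3:
            raise ValueError(
                f"expected 3D label map, got shape {self.labels.shape} for {self.name!r}"
            )
        codes = set(np.unique(self.labels).tolist())
        if not codes <= ANATOMY_CODES:
            raise ValueError(
                f"label map {self.name!r} holds unexpected codes {sorted(codes - ANATOMY_CODES)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def edema_mask(self) -> np.ndarray:
        return self.mask(EDEMA)

    @property
    def cet_mask(self) -> np.ndarray:
        return self.mask(CET)

    @property
    def necrosis_mask(self) -> np.ndarray:
        return self.mask(NECROSIS)

    @property
    def lesion_mask(self) -> np.ndarray:
        return self.labels != BACKGROUND


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got shape {data.shape} in {path}")
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=np.float64)
    return data, spacing, np.asarray(img.affine, dtype=np.float64)


def read_volume(path: str | Path, name: str | None = None) -> IntensityVolume:
    """Read a 3D NIfTI intensity volume.

    Raises on missing file, non-3D images and NaN voxels (naming the count).
    """
    data, spacing, affine = _load_nifti(path)
    return IntensityVolume(
        data=np.asarray(data, dtype=np.float64),
        spacing=spacing,
        affine=affine,
        name=name or Path(path).name,
    )


def read_labelmap(path: str | Path, name: str | None = None) -> AnatomyLabelMap:
    """Read a BraTS-style anatomical label map from NIfTI."""
    data, spacing, affine = _load_nifti(path)
    return AnatomyLabelMap(
        labels=data, spacing=spacing, affine=affine, name=name or Path(path).name
    )


def write_volume(vol: IntensityVolume, path: str | Path) -> Path:
    """Write an intensity volume to NIfTI (float32)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.spacing))
    nib.save(img, str(path))
    return path


def check_same_grid(items: list[IntensityVolume | AnatomyLabelMap]) -> None:
    """Verify that all items share one voxel grid (shape, spacing, affine).

    Passes silently iff every shape matches, spacings agree within 1e-4 mm and
    affines within 1e-3; otherwise raises :class:`GridMismatchError` naming the
    offending input.
    """
    if not items:
        raise ValueError("check_same_grid needs a non-empty list")
    ref = items[0]
    for item in items[1:]:
        if item.shape != ref.shape:
            raise GridMismatchError(
                f"{item.name!r} shape {item.shape} != {ref.name!r} shape {ref.shape}"
            )
        if not np.allclose(item.spacing, ref.spacing, atol=SPACING_ATOL, rtol=0):
            raise GridMismatchError(
                f"{item.name!r} spacing {item.spacing} != {ref.name!r} spacing {ref.spacing}"
            )
        if not np.allclose(item.affine, ref.affine, atol=AFFINE_ATOL, rtol=0):
            raise GridMismatchError(f"{item.name!r} affine differs from {ref.name!r}")


def write_labelmap(split, anatomy: AnatomyLabelMap, path: str | Path) -> Path:
    """Write the output label map with codes {0,1,2,3,4}; code 3 marks nCET.

    ``split`` is an :class:`~ncetseg.postprocess.EdemaSplit`; its nCET and
    vasogenic masks must partition the anatomy's edema label exactly.
    """
    edema = anatomy.edema_mask
    ncet = np.asarray(split.ncet_mask, dtype=bool)
    vasog = np.asarray(split.vasogenic_mask, dtype=bool)
    if ncet.shape != anatomy.shape:
        raise GridMismatchError("nCET mask is not on the anatomy grid")
    if np.any(ncet & ~edema):
        raise ValueError("nCET mask extends outside the edema label")
    if np.any(ncet & vasog) or not np.array_equal(ncet | vasog, edema):
        raise ValueError("nCET/vasogenic masks do not partition the edema label")
    out = anatomy.labels.copy()
    out[ncet] = NCET
    path = Path(path)
    img = nib.Nifti1Image(out.astype(np.uint8), anatomy.affine)
    img.header.set_zooms(tuple(anatomy.spacing))
    nib.save(img, str(path))
    return path
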