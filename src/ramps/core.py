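"""Core volume containers and the resection-specification type.

All images are carried as thin dataclasses around a 3D numpy array plus a
NIfTI affine (voxel -> world, mm).  Three kinds are distinguished so that
interpolation policy is unambiguous everywhere downstream: scalar
intensities (:class:`Volume`, linear), integer region/lobe codes
(:class:`LabelVolume`, nearest) and boolean masks (:class:`BinaryMask`,
linear-then-threshold-0.5).  Masks and labels produced by the pipeline are
always stored in pre-operative voxel space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "LabelVolume",
    "BinaryMask",
    "ResectionSpec",
    "GridMismatchError",
    "LOBE_CODES",
    "LOBE_NAMES",
    "EXCLUDED",
    "HEMISPHERES",
]


class GridMismatchError(ValueError):
    """Two volumes that must share a voxel grid do not."""


# Lobe-atlas coding: left-hemisphere lobes 1..6, right-hemisphere +10,
# regions where a resection cannot occur (ventricles, brainstem,
# cerebellum, extra-cerebral CSF) collapse to a single Excluded code.
LOBE_CODES: dict[str, int] = {
    "Frontal-L": 1,
    "Parietal-L": 2,
    "Temporal-L": 3,
    "Occipital-L": 4,
    "Insula-L": 5,
    "SubCortical-L": 6,
    "Frontal-R": 11,
    "Parietal-R": 12,
    "Temporal-R": 13,
    "Occipital-R": 14,
    "Insula-R": 15,
    "SubCortical-R": 16,
    "Excluded": 99,
}
LOBE_NAMES: dict[int, str] = {v: k for k, v in LOBE_CODES.items()}
EXCLUDED = LOBE_CODES["Excluded"]
HEMISPHERES = ("L", "R")

_LOBE_INITIALS = {
    "T": "Temporal",
    "F": "Frontal",
    "O": "Occipital",
    "P": "Parietal",
}


def _check_3d(data: np.ndarray) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D array, got shape {data.shape}")


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


@dataclass
class _Grid:
    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        _check_3d(self.data)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be positive on every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel size in mm per axis."""
        return _spacing_from_affine(self.affine)

    def same_grid(self, other: "_Grid") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def require_same_grid(self, other: "_Grid", what: str = "volumes") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"{what} must share shape and affine "
                f"(got {self.shape} vs {other.shape})"
            )


@dataclass
class Volume(_Grid):
    """3D scalar image with voxel spacing and voxel->world affine."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        super().__post_init__()
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy())

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=np.float32), img.affine)


@dataclass
class LabelVolume(_Grid):
    """3D integer-coded region map with a code -> name legend."""

    legend: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = np.round(self.data).astype(np.int32)
        self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label codes must be non-negative")
        super().__post_init__()
        self.legend = dict(self.legend)

    def codes(self) -> np.ndarray:
        c = np.unique(self.data)
        return c[c != 0]

    def validate_legend(self) -> None:
        missing = [int(c) for c in self.codes() if int(c) not in self.legend]
        if missing:
            raise ValueError(f"codes missing from legend: {missing}")

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.affine.copy(), dict(self.legend))

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path, legend: Mapping[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        lv = cls(np.round(data).astype(np.int32), img.affine, legend or {})
        if not lv.legend:
            lv.legend = {int(c): str(int(c)) for c in lv.codes()}
        return lv


@dataclass
class BinaryMask(_Grid):
    """Boolean 3D mask (resection masks, brain masks, lobe filters)."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0.5
        super().__post_init__()

    @property
    def volume_mm3(self) -> float:
        return float(self.data.sum()) * float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.data.sum())

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.data.copy(), self.affine.copy())

    def save(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "BinaryMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) > 0.5, img.affine)


@dataclass(frozen=True)
class ResectionSpec:
    """User's prior knowledge of where the resection occurred.

    ``hemisphere`` is ``"L"``, ``"R"`` or ``"both"`` (default: search both
    hemispheres).  ``lobes`` is a subset of the initials ``T, F, O, P`` or
    ``"all"`` (default).  The temporal filter deliberately also includes the
    sub-cortical and insula territories, since temporal-lobe resections
    routinely involve the hippocampus, amygdala and adjacent insula.
    """

    hemisphere: str = "both"
    lobes: frozenset[str] | str = "all"

    def __post_init__(self) -> None:
        hemi = str(self.hemisphere)
        if hemi.upper() in ("L", "R"):
            hemi = hemi.upper()
        elif hemi.lower() == "both":
            hemi = "both"
        else:
            raise ValueError(
                f"hemisphere must be L, R or both, got {self.hemisphere!r}"
            )
        object.__setattr__(self, "hemisphere", hemi)
        lobes = self.lobes
        if isinstance(lobes, str) and lobes.lower() == "all":
            object.__setattr__(self, "lobes", "all")
            return
        if isinstance(lobes, str):
            lobes = frozenset(lobes)
        lobes = frozenset(str(l).upper() for l in lobes)
        bad = sorted(lobes - set(_LOBE_INITIALS))
        if bad:
            raise ValueError(
                f"unknown lobe initial(s) {bad}; valid codes are T, F, O, P"
            )
        object.__setattr__(self, "lobes", "all" if not lobes else lobes)

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return HEMISPHERES if self.hemisphere == "both" else (self.hemisphere,)

    def lobe_names(self) -> frozenset[str]:
        """Selected lobe territory names after temporal expansion."""
        if self.lobes == "all":
            names = {"Frontal", "Parietal", "Temporal", "Occipital",
                     "Insula", "SubCortical"}
        else:
            names = {_LOBE_INITIALS[l] for l in self.lobes}
            if "Temporal" in names:
                names |= {"SubCortical", "Insula"}
        return frozenset(names)

    def selected_codes(self) -> frozenset[int]:
        """Lobe-atlas codes covered by this specification."""
        codes = set()
        for hemi in self.hemispheres:
            for name in self.lobe_names():
                codes.add(LOBE_CODES[f"{name}-{hemi}"])
        return frozenset(codes)
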