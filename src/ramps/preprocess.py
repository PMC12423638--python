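"""Data preparation: grid standardization, bias correction, intensity
clamping, lobe-atlas assembly and hemisphere/lobe filter masks.

Brain extraction and regional segmentation are *not* performed here: the
pipeline consumes an integer region :class:`~ramps.core.LabelVolume`
(SynthSeg/FreeSurfer-coded in real use, phantom-provided in tests).  The
packaged ``data/lobe_map.tsv`` maps those region codes onto the six lobe
territories per hemisphere plus a single ``Excluded`` code covering the
regions in which a resection cannot occur (ventricles, brainstem,
cerebellum, extra-cerebral CSF).  Region codes whose lobe column reads
``WhiteMatter`` are brain tissue without a lobe of their own; they stay
unlabelled in the grey-matter atlas and are filled by
:func:`dilate_atlas_through_wm`.
"""

from __future__ import annotations

import csv
import warnings
from importlib import resources
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import (
    EXCLUDED,
    LOBE_CODES,
    LOBE_NAMES,
    BinaryMask,
    LabelVolume,
    ResectionSpec,
    Volume,
)

__all__ = [
    "load_lobe_mapping",
    "normalize_resolution",
    "correct_bias",
    "clamp_top_percentile",
    "build_lobe_atlas",
    "mask_brain",
    "dilate_atlas_through_wm",
    "split_resection_lobes",
]

_UNLABELLED_BRAIN = "WhiteMatter"


def load_lobe_mapping(path: str | Path | None = None) -> dict[int, tuple[str, str]]:
    """Read a region-code -> (lobe, hemisphere) table.

    Defaults to the packaged SynthSeg/FreeSurfer table.  The TSV needs the
    columns ``code``, ``lobe`` and ``hemisphere``.
    """
    if path is None:
        src = resources.files("ramps.data") / "lobe_map.tsv"
        text = src.read_text()
    else:
        text = Path(path).read_text()
    mapping: dict[int, tuple[str, str]] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        mapping[int(row["code"])] = (row["lobe"], row["hemisphere"])
    return mapping


# ---------------------------------------------------------------------------
# Step 1: resolution/FOV normalization
# ---------------------------------------------------------------------------

def _resample_to_grid(data: np.ndarray, in_affine: np.ndarray,
                      out_affine: np.ndarray, out_shape, order: int,
                      cval: float = 0.0) -> np.ndarray:
    # voxel_out -> world -> voxel_in
    M = np.linalg.inv(in_affine) @ out_affine
    return ndimage.affine_transform(
        data, M[:3, :3], offset=M[:3, 3], output_shape=tuple(out_shape),
        order=order, mode="constant", cval=cval)


def normalize_resolution(vol, target_spacing: float | tuple = 1.0,
                         target_shape: tuple[int, int, int] = (256, 256, 256)):
    """Resample onto an isotropic grid (default 1 mm, 256^3) centred on the
    input field of view, keeping the image in its original world space.

    Intensity volumes are interpolated linearly, labels nearest-neighbour,
    masks linearly then thresholded at 0.5.  If the input FOV exceeds the
    target FOV on any axis a warning is issued and the image is
    centre-cropped.
    """
    spacing = np.broadcast_to(np.asarray(target_spacing, float), 3).astype(float)
    out_shape = np.asarray(target_shape, int)
    in_aff = np.asarray(vol.affine, float)
    in_shape = np.asarray(vol.shape, float)

    in_fov = vol.spacing * in_shape
    if np.any(in_fov > spacing * out_shape + 1e-6):
        warnings.warn("input field of view exceeds the target grid; "
                      "centre-cropping", stacklevel=2)

    direction = in_aff[:3, :3] / vol.spacing  # unit columns
    out3 = direction * spacing
    center_world = in_aff @ np.append((in_shape - 1) / 2.0, 1.0)
    out_aff = np.eye(4)
    out_aff[:3, :3] = out3
    out_aff[:3, 3] = center_world[:3] - out3 @ ((out_shape - 1) / 2.0)

    if isinstance(vol, BinaryMask):
        res = _resample_to_grid(vol.data.astype(np.float32), in_aff, out_aff,
                                out_shape, order=1)
        return BinaryMask(res > 0.5, out_aff)
    if isinstance(vol, LabelVolume):
        res = _resample_to_grid(vol.data, in_aff, out_aff, out_shape, order=0)
        return LabelVolume(res, out_aff, vol.legend)
    res = _resample_to_grid(vol.data, in_aff, out_aff, out_shape, order=1)
    return Volume(res, out_aff)


# ---------------------------------------------------------------------------
# Step 2: bias-field correction and top-percentile clamp
# ---------------------------------------------------------------------------

def _poly_design(shape, points_idx: tuple[np.ndarray, ...], order: int) -> np.ndarray:
    coords = [2.0 * idx / max(n - 1, 1) - 1.0
              for idx, n in zip(points_idx, shape)]
    cols = []
    for i in range(order + 1):
        for j in range(order + 1 - i):
            for k in range(order + 1 - i - j):
                cols.append(coords[0] ** i * coords[1] ** j * coords[2] ** k)
    return np.stack(cols, axis=1)


def _kmeans_1d(values: np.ndarray, k: int = 3, iters: int = 15) -> np.ndarray:
    """Deterministic 1D k-means; returns per-value class means."""
    centers = np.percentile(values, np.linspace(15, 90, k))
    for _ in range(iters):
        assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        for c in range(k):
            sel = assign == c
            if sel.any():
                centers[c] = values[sel].mean()
        centers.sort()
    assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
    return centers[assign]


def correct_bias(vol: Volume, brain: BinaryMask, order: int = 3,
                 n_iter: int = 5) -> tuple[Volume, Volume]:
    """Estimate and remove a smooth multiplicative intensity bias field.

    A low-order 3D polynomial is fitted to the log-intensities within the
    brain, iterated against a piecewise-constant 3-class tissue estimate
    (the polynomial absorbs smooth variation; the class means absorb
    anatomy).  The returned field has mean 1 over the brain and the
    corrected volume equals ``input / field`` exactly.
    """
    vol.require_same_grid(brain, "volume and brain mask")
    if brain.count() == 0:
        raise ValueError("brain mask is empty")
    data = vol.data.astype(float)
    if not np.any(data != 0):
        raise ValueError("cannot bias-correct an all-zero volume")

    idx = np.nonzero(brain.data)
    vals = data[idx]
    floor = max(np.percentile(vals[vals > 0], 1) * 0.05, 1e-6)
    logv = np.log(np.maximum(vals, floor))

    X = _poly_design(vol.shape, idx, order)
    field_log = np.zeros(logv.shape)
    for _ in range(n_iter):
        corrected = logv - field_log
        class_log = _kmeans_1d(corrected)
        resid = logv - class_log
        coef, *_ = np.linalg.lstsq(X, resid, rcond=None)
        field_log = X @ coef

    full_idx = np.nonzero(np.ones(vol.shape, bool))
    Xf = _poly_design(vol.shape, full_idx, order)
    field = np.exp(Xf @ coef).reshape(vol.shape)
    field /= field[brain.data].mean()
    corrected_vol = Volume(vol.data / field, vol.affine)
    return corrected_vol, Volume(field, vol.affine)


def clamp_top_percentile(vol: Volume, brain: BinaryMask, pct: float = 1.0) -> Volume:
    """Replace the brightest ``pct`` percent of brain voxels by the brain
    median, suppressing residual hyper-intensities after bias correction."""
    vol.require_same_grid(brain, "volume and brain mask")
    if brain.count() == 0:
        raise ValueError("brain mask is empty")
    vals = vol.data[brain.data]
    thr = np.percentile(vals, 100.0 - pct)
    med = np.median(vals)
    out = vol.data.copy()
    out[brain.data & (vol.data >= thr)] = med
    return Volume(out, vol.affine)


# ---------------------------------------------------------------------------
# Step 4: lobe-atlas assembly and brain masking
# ---------------------------------------------------------------------------

def build_lobe_atlas(regions: LabelVolume,
                     mapping: dict[int, tuple[str, str]] | None = None
                     ) -> LabelVolume:
    """Merge region codes into the grey-matter lobe atlas.

    Regions mapped to a lobe territory get the hemisphere-crossed lobe
    code; ventricles/brainstem/cerebellum collapse to ``Excluded``;
    white-matter-like codes stay 0 (in-brain, unlabelled).
    """
    if mapping is None:
        mapping = load_lobe_mapping()
    codes = regions.codes()
    unmapped = [int(c) for c in codes if int(c) not in mapping]
    if unmapped:
        raise ValueError(f"region code(s) not in the lobe mapping: {unmapped}")

    lut_size = int(codes.max()) + 1 if codes.size else 1
    lut = np.zeros(lut_size, np.int32)
    for code in codes:
        lobe, hemi = mapping[int(code)]
        if lobe == "Excluded":
            lut[code] = EXCLUDED
        elif lobe == _UNLABELLED_BRAIN:
            lut[code] = 0
        else:
            key = f"{lobe}-{hemi}"
            if key not in LOBE_CODES:
                raise ValueError(
                    f"region {int(code)} maps to unknown lobe cell {key!r}")
            lut[code] = LOBE_CODES[key]
    atlas = lut[regions.data]
    legend = {int(c): LOBE_NAMES[int(c)] for c in np.unique(atlas) if c}
    return LabelVolume(atlas, regions.affine, legend)


def mask_brain(vol: Volume, atlas: LabelVolume) -> tuple[Volume, BinaryMask]:
    """Zero all intensities outside the binarized segmentation atlas."""
    vol.require_same_grid(atlas, "volume and atlas")
    brain = atlas.data > 0
    if not brain.any():
        raise ValueError("atlas is empty; cannot derive a brain mask")
    out = vol.data.copy()
    out[~brain] = 0.0
    return Volume(out, vol.affine), BinaryMask(brain, vol.affine)


# ---------------------------------------------------------------------------
# Step 5: atlas dilation through white matter and lobe splitting
# ---------------------------------------------------------------------------

def dilate_atlas_through_wm(atlas: LabelVolume, brain: BinaryMask) -> LabelVolume:
    """Propagate lobe labels through unlabelled brain (white matter).

    Every brain voxel without a grey-matter lobe label receives the code of
    its nearest labelled voxel (Euclidean distance transform per lobe
    code).  ``Excluded`` regions keep their code and are never a source.
    Distance ties break toward the lowest lobe code, which makes the
    operation deterministic.
    """
    atlas.require_same_grid(brain, "atlas and brain mask")
    data = atlas.data
    src_codes = sorted(int(c) for c in np.unique(data)
                       if c not in (0, EXCLUDED))
    if not src_codes:
        raise ValueError("atlas has no grey-matter lobe labels to dilate")
    fill = brain.data & (data == 0)
    out = data.copy()
    if fill.any():
        fidx = np.nonzero(fill)
        dists = np.empty((len(src_codes), fidx[0].size))
        for i, code in enumerate(src_codes):
            d = ndimage.distance_transform_edt(data != code)
            dists[i] = d[fidx]
        # argmin returns the first (lowest-code) minimizer: the tie-break
        choice = np.argmin(dists, axis=0)
        out[fidx] = np.asarray(src_codes, np.int32)[choice]
    legend = {int(c): LOBE_NAMES[int(c)] for c in np.unique(out) if c}
    return LabelVolume(out, atlas.affine, legend)


def split_resection_lobes(full_atlas: LabelVolume, spec: ResectionSpec
                          ) -> tuple[BinaryMask, BinaryMask]:
    """Split the dilated atlas into the resected-lobe mask selected by the
    user's hemisphere/lobe prior and the complementary non-resected mask.

    The two outputs are disjoint and together cover the non-Excluded brain.
    """
    selected = spec.selected_codes()
    data = full_atlas.data
    target = np.isin(data, list(selected))
    if not target.any():
        raise ValueError(
            f"specification {spec} selects an empty region of the atlas")
    others = (data > 0) & (data != EXCLUDED) & ~target
    return (BinaryMask(target, full_atlas.affine),
            BinaryMask(others, full_atlas.affine))
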