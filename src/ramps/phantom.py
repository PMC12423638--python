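"""Synthetic pre/post-operative brain phantoms with known ground truth.

The phantom emulates the conditions a resection-delineation pipeline faces:
a layered ellipsoidal "brain" (WM core, GM shell, CSF rim, ventricles) with
lobe-parcellated cortex in two hemispheres; surgery carves an ellipsoidal
cavity filled with CSF-like intensity; tissue then sags into the cavity via
a smooth radial displacement field; a low-order multiplicative bias field,
additive Gaussian noise and a rigid pre/post misalignment complete the
picture.  Every corrupting process is recorded in a :class:`PhantomTruth`
so each pipeline stage can be tested against exact ground truth.

The geometry is deliberately crude (no cortical folding); it exists to make
every stage of the pipeline testable, not to be biofidelic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import BinaryMask, LabelVolume, Volume

__all__ = [
    "PhantomConfig",
    "PhantomTruth",
    "generate_pre",
    "apply_surgery",
    "generate_case",
    "make_fixture_suite",
    "FIXTURE_PRESETS",
    "TISSUE_CODES",
    "REGION_LEGEND",
]

# Tissue-label codes used in PhantomTruth.tissue_labels.
TISSUE_CODES = {"background": 0, "CSF": 1, "ventricle": 2, "GM": 3, "WM": 4}

# Region codes follow the SynthSeg/FreeSurfer convention so the packaged
# code->lobe table applies to phantom and real segmentations alike.
REGION_LEGEND = {
    2: "Left-Cerebral-White-Matter",
    41: "Right-Cerebral-White-Matter",
    4: "Left-Lateral-Ventricle",
    43: "Right-Lateral-Ventricle",
    10: "Left-Thalamus",
    49: "Right-Thalamus",
    16: "Brain-Stem",
    24: "CSF",
    1011: "ctx-lh-lateraloccipital",
    2011: "ctx-rh-lateraloccipital",
    1028: "ctx-lh-superiorfrontal",
    2028: "ctx-rh-superiorfrontal",
    1029: "ctx-lh-superiorparietal",
    2029: "ctx-rh-superiorparietal",
    1030: "ctx-lh-superiortemporal",
    2030: "ctx-rh-superiortemporal",
    1035: "ctx-lh-insula",
    2035: "ctx-rh-insula",
}

_CTX_SECTOR = {  # (lh_code, rh_code) per angular sector, see _parcellate
    "Frontal": (1028, 2028),
    "Parietal": (1029, 2029),
    "Occipital": (1011, 2011),
    "Temporal": (1030, 2030),
}


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic pre/post pair.

    Intensities are arbitrary T1-like units obeying CSF < GM < WM.
    ``noise_sigma`` is the additive Gaussian scale as a fraction of the WM
    mean; ``bias_amplitude`` the peak deviation of the multiplicative bias
    field from 1; ``sagging_magnitude`` the peak inward tissue displacement
    at the cavity wall in voxels; ``rigid_offset`` the pre/post
    misalignment as (tx, ty, tz) mm + (rx, ry, rz) degrees applied to the
    post-operative volume.  Geometry is expressed in voxel coordinates and
    scales with ``grid_shape`` (cavity fields default relative to a 96^3
    grid).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissue_means: tuple[float, float, float, float] = (0.0, 150.0, 450.0, 750.0)
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.15
    cavity_center: tuple[float, float, float] | None = None
    cavity_radii: tuple[float, float, float] | None = None
    sagging_magnitude: float = 2.0
    sagging_tau: float = 3.0
    rigid_offset: tuple[float, float, float, float, float, float] = (
        0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        bg, csf, gm, wm = self.tissue_means
        if not (bg < csf < gm < wm):
            raise ValueError("tissue means must satisfy background < CSF < GM < WM")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.sagging_magnitude < 0:
            raise ValueError("sagging_magnitude must be >= 0")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")

    # -- derived geometry ------------------------------------------------
    @property
    def center(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, float) - 1.0) / 2.0

    @property
    def brain_radii(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * np.array([0.42, 0.40, 0.38])

    def cavity_geometry(self) -> tuple[np.ndarray, np.ndarray]:
        scale = np.asarray(self.grid_shape, float) / 96.0
        if self.cavity_center is None:
            center = self.center + self.brain_radii * np.array([-0.62, 0.35, -0.30])
        else:
            center = np.asarray(self.cavity_center, float)
        if self.cavity_radii is None:
            radii = np.array([10.0, 9.0, 8.0]) * scale
        else:
            radii = np.asarray(self.cavity_radii, float)
        return center, radii

    def validate_cavity(self) -> None:
        center, _ = self.cavity_geometry()
        rho = np.sqrt((((center - self.center) / self.brain_radii) ** 2).sum())
        if rho >= 1.0:
            raise ValueError(
                "cavity center lies outside the brain envelope "
                f"(normalized radius {rho:.2f} >= 1)")


@dataclass
class PhantomTruth:
    """Ground truth recorded while building a phantom pair."""

    tissue_labels: LabelVolume          # pre-space {bg, CSF, ventricle, GM, WM}
    lobe_labels: LabelVolume            # pre-space GM lobe atlas (lobe codes)
    region_labels: LabelVolume          # pre-space SynthSeg-style regions
    resection_mask: BinaryMask | None = None   # pre-space, pre-deformation
    bias_field: Volume | None = None
    sagging_field: np.ndarray | None = None    # (3, *grid) voxel displacements
    rigid_transform: tuple[float, ...] | None = None  # tx,ty,tz (mm), rx,ry,rz (deg)
    region_labels_post: LabelVolume | None = None     # post-space regions


def _affine(config: PhantomConfig) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = config.voxel_spacing
    return aff


def _ellipsoid_rho(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    acc = np.zeros(shape, float)
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return np.sqrt(acc)


def _parcellate(config: PhantomConfig, gm: np.ndarray) -> np.ndarray:
    """Assign cortical GM to angular-sector lobe parcels per hemisphere.

    The sector angle lives in the sagittal (y, z) plane: anterior-superior
    -> Frontal, posterior-superior -> Parietal, posterior-inferior ->
    Occipital, anterior-inferior -> Temporal.
    """
    shape = config.grid_shape
    c = config.center
    yy, zz = np.meshgrid(np.arange(shape[1], dtype=float),
                         np.arange(shape[2], dtype=float), indexing="ij")
    theta = np.arctan2(zz - c[2], yy - c[1])  # (-pi, pi], 0 = anterior
    sector = np.empty(theta.shape, dtype="U9")
    sector[(theta >= 0) & (theta < np.pi / 2)] = "Frontal"
    sector[theta >= np.pi / 2] = "Parietal"
    sector[theta < -np.pi / 2] = "Occipital"
    sector[(theta >= -np.pi / 2) & (theta < 0)] = "Temporal"

    xs = np.arange(shape[0], dtype=float)[:, None, None]
    left = np.broadcast_to(xs < c[0], shape)
    out = np.zeros(shape, np.int32)
    for name, (lh, rh) in _CTX_SECTOR.items():
        in_sector = np.broadcast_to((sector == name)[None, :, :], shape)
        out[gm & in_sector & left] = lh
        out[gm & in_sector & ~left] = rh
    return out


def _bias_field(config: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field: product of low-order 1D polynomials,
    normalized to mean 1 and scaled so max |field - 1| = bias_amplitude."""
    shape = config.grid_shape
    if config.bias_amplitude == 0:
        return np.ones(shape)
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    field_log = np.zeros(shape)
    for axis, x in enumerate(coords):
        coef = rng.uniform(-1.0, 1.0, size=3)  # degrees 1..3 per axis
        poly = coef[0] * x + coef[1] * x**2 + coef[2] * x**3
        sh = [1, 1, 1]
        sh[axis] = shape[axis]
        field_log = field_log + poly.reshape(sh)
    field_log -= field_log.mean()
    peak = np.abs(field_log).max()
    if peak > 0:
        field_log *= np.log1p(config.bias_amplitude) / peak
    field = np.exp(field_log)
    return field / field.mean()


def generate_pre(config: PhantomConfig) -> tuple[Volume, PhantomTruth]:
    """Build the pre-operative volume and its ground-truth labellings."""
    config.validate_cavity()
    shape = config.grid_shape
    aff = _affine(config)
    rng = np.random.default_rng(config.seed)

    rho = _ellipsoid_rho(shape, config.center, config.brain_radii)
    brain = rho <= 1.0
    csf_rim = brain & (rho > 0.93)
    gm_shell = brain & (rho > 0.80) & (rho <= 0.93)
    wm_core = brain & (rho <= 0.80)

    c = config.center
    scale = np.asarray(shape, float) / 96.0
    vent = np.zeros(shape, bool)
    vent_sides = {}
    for side, sx in (("L", -1.0), ("R", 1.0)):
        vc = c + np.array([sx * 9.0, -2.0, 2.0]) * scale
        vr = np.array([4.0, 9.0, 5.0]) * scale
        m = _ellipsoid_rho(shape, vc, vr) <= 1.0
        vent_sides[side] = m
        vent |= m
    subcort = np.zeros(shape, bool)
    for side, sx in (("L", -1.0), ("R", 1.0)):
        vc = c + np.array([sx * 9.0, -2.0, 2.0]) * scale
        vr = np.array([8.0, 13.0, 9.0]) * scale
        subcort |= _ellipsoid_rho(shape, vc, vr) <= 1.0
    subcort &= wm_core & ~vent
    insula = np.zeros(shape, bool)
    for side, sx in (("L", -1.0), ("R", 1.0)):
        vc = c + np.array([sx * 9.0, -2.0, 2.0]) * scale
        vr = np.array([10.5, 15.5, 11.5]) * scale
        insula |= _ellipsoid_rho(shape, vc, vr) <= 1.0
    insula &= wm_core & ~vent & ~subcort
    stem = _ellipsoid_rho(
        shape, c + np.array([0.0, -4.0, -30.0]) * scale,
        np.array([6.0, 7.0, 12.0]) * scale) <= 1.0
    stem &= brain
    vent &= ~stem
    subcort &= ~stem
    insula &= ~stem

    # tissue labels
    codes = TISSUE_CODES
    tissue = np.zeros(shape, np.int32)
    tissue[csf_rim] = codes["CSF"]
    tissue[gm_shell] = codes["GM"]
    tissue[wm_core] = codes["WM"]
    tissue[insula] = codes["GM"]
    tissue[subcort] = codes["GM"]    # deep grey
    tissue[stem] = codes["WM"]
    tissue[vent] = codes["ventricle"]

    # region labels (SynthSeg-style)
    gm_ctx = gm_shell.copy()
    regions = np.zeros(shape, np.int32)
    regions[wm_core] = 2
    xs = np.arange(shape[0], dtype=float)[:, None, None]
    left = np.broadcast_to(xs < c[0], shape)
    regions[wm_core & ~left] = 41
    regions[csf_rim] = 24
    ctx = _parcellate(config, gm_ctx)
    regions[gm_ctx] = ctx[gm_ctx]
    regions[insula & left] = 1035
    regions[insula & ~left] = 2035
    regions[subcort & left] = 10
    regions[subcort & ~left] = 49
    regions[stem] = 16
    regions[vent_sides["L"] & ~stem] = 4
    regions[vent_sides["R"] & ~stem] = 43

    # GM lobe atlas ground truth via the packaged region->lobe mapping
    from .preprocess import build_lobe_atlas  # local import: avoid cycle

    region_lv = LabelVolume(regions, aff, REGION_LEGEND)
    lobe_lv = build_lobe_atlas(region_lv)

    # tissue code -> mean: bg->bg, CSF/ventricle->CSF, GM->GM, WM->WM
    mean_lut = np.array([
        config.tissue_means[0],  # background
        config.tissue_means[1],  # CSF
        config.tissue_means[1],  # ventricle (CSF-filled)
        config.tissue_means[2],  # GM
        config.tissue_means[3],  # WM
    ])
    clean = mean_lut[tissue]

    bias = _bias_field(config, rng)
    data = clean * bias
    if config.noise_sigma > 0:
        data = data + rng.normal(
            0.0, config.noise_sigma * config.tissue_means[3], size=shape)

    truth = PhantomTruth(
        tissue_labels=LabelVolume(tissue, aff,
                                  {v: k for k, v in codes.items() if v}),
        lobe_labels=lobe_lv,
        region_labels=region_lv,
        bias_field=Volume(bias, aff),
    )
    return Volume(data.astype(np.float32), aff), truth


def _carve_mask(config: PhantomConfig, truth: PhantomTruth) -> np.ndarray:
    """Ellipsoidal cavity intersected with resectable tissue (GM/WM/deep
    grey, not ventricles/rim CSF/background), largest connected component."""
    center, radii = config.cavity_geometry()
    ell = _ellipsoid_rho(config.grid_shape, center, radii) <= 1.0
    tissue = truth.tissue_labels.data
    resectable = (tissue == TISSUE_CODES["GM"]) | (tissue == TISSUE_CODES["WM"])
    cav = ell & resectable
    if not cav.any():
        raise ValueError("cavity does not intersect resectable brain tissue")
    lab, n = ndimage.label(cav, structure=np.ones((3, 3, 3), int))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
        cav = lab == (1 + int(np.argmax(sizes)))
    return cav


def _sagging_displacement(config: PhantomConfig,
                          cavity: np.ndarray) -> np.ndarray:
    """Radial sampling displacement (voxels) producing inward tissue sag.

    Magnitude s * exp(-d / tau) with d the unsigned distance to the cavity
    wall; direction away from the cavity centroid, so resampling pulls
    outer tissue toward (and into) the cavity.
    """
    shape = cavity.shape
    s = config.sagging_magnitude
    if s == 0:
        return np.zeros((3,) + shape)
    d_out = ndimage.distance_transform_edt(~cavity)
    d_in = ndimage.distance_transform_edt(cavity)
    d = np.where(cavity, d_in, d_out)
    mag = s * np.exp(-d / config.sagging_tau)
    centroid = np.array(ndimage.center_of_mass(cavity))
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                        indexing="ij")
    vec = np.stack([g - cc for g, cc in zip(grids, centroid)])
    norm = np.sqrt((vec**2).sum(axis=0))
    norm[norm == 0] = 1.0
    return mag * vec / norm


def _rigid_matrix(params, spacing, center_vox) -> tuple[np.ndarray, np.ndarray]:
    """Voxel-space sampling map for a rigid move: returns (A, b) with
    sample_coord = A @ x + b.  params = tx,ty,tz (mm), rx,ry,rz (deg),
    rotation about the grid center."""
    t = np.asarray(params[:3], float) / np.asarray(spacing, float)  # mm -> vox
    rx, ry, rz = np.deg2rad(params[3:6])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    R = Rz @ Ry @ Rx
    c = np.asarray(center_vox, float)
    b = c - R @ c + R @ t
    return R, b


def apply_surgery(pre: Volume, truth: PhantomTruth,
                  config: PhantomConfig) -> tuple[Volume, BinaryMask]:
    """Carve the cavity, sag tissue into it, add bias/noise and misalign.

    Returns the post-operative volume and the pre-space ground-truth
    resection mask (the carved voxels *before* any deformation).  Also
    fills ``truth.resection_mask``, ``truth.sagging_field``,
    ``truth.rigid_transform`` and ``truth.region_labels_post``.
    """
    config.validate_cavity()
    shape = config.grid_shape
    aff = _affine(config)
    rng = np.random.default_rng(config.seed + 1)

    cav = _carve_mask(config, truth)
    mean_lut = np.array([
        config.tissue_means[0], config.tissue_means[1],
        config.tissue_means[1], config.tissue_means[2],
        config.tissue_means[3]])
    tissue_post = truth.tissue_labels.data.copy()
    tissue_post[cav] = TISSUE_CODES["CSF"]
    regions_post = truth.region_labels.data.copy()
    regions_post[cav] = 24
    clean_post = mean_lut[tissue_post].astype(float)

    disp = _sagging_displacement(config, cav)
    if config.sagging_magnitude > 0:
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                            indexing="ij")
        coords = [g + d for g, d in zip(grids, disp)]
        clean_post = ndimage.map_coordinates(clean_post, coords, order=1,
                                             mode="nearest")
        tissue_post = ndimage.map_coordinates(tissue_post, coords, order=0,
                                              mode="nearest")
        regions_post = ndimage.map_coordinates(regions_post, coords, order=0,
                                               mode="nearest")

    bias = truth.bias_field.data if truth.bias_field is not None else 1.0
    data = clean_post * bias
    if config.noise_sigma > 0:
        data = data + rng.normal(
            0.0, config.noise_sigma * config.tissue_means[3], size=shape)

    if any(abs(p) > 0 for p in config.rigid_offset):
        A, b = _rigid_matrix(config.rigid_offset, config.voxel_spacing,
                             config.center)
        data = ndimage.affine_transform(data, A, offset=b, order=1,
                                        mode="constant", cval=0.0)
        regions_post = ndimage.affine_transform(
            regions_post, A, offset=b, order=0, mode="constant", cval=0)

    truth.resection_mask = BinaryMask(cav, aff)
    truth.sagging_field = disp
    truth.rigid_transform = tuple(float(p) for p in config.rigid_offset)
    truth.region_labels_post = LabelVolume(regions_post, aff, REGION_LEGEND)
    return Volume(data.astype(np.float32), aff), truth.resection_mask


def generate_case(config: PhantomConfig) -> tuple[Volume, Volume, PhantomTruth]:
    """Convenience: pre volume, post volume, and the complete truth."""
    pre, truth = generate_pre(config)
    post, _ = apply_surgery(pre, truth, config)
    return pre, post, truth


_SMALL_RADII = (3.5, 3.0, 3.0)      # lesionectomy-sized, < 5% of default volume
_OFFSET_4MM_3DEG = (4.0, -2.0, 1.5, 3.0, -2.0, 1.5)

FIXTURE_PRESETS: dict[str, dict] = {
    # (a) aligned, noiseless
    "a": dict(noise_sigma=0.0, bias_amplitude=0.0, sagging_magnitude=0.0),
    # (b) noise + bias only
    "b": dict(sagging_magnitude=0.0),
    # (c) sagging only
    "c": dict(noise_sigma=0.0, bias_amplitude=0.0),
    # (d) rigid misalignment only
    "d": dict(noise_sigma=0.0, bias_amplitude=0.0, sagging_magnitude=0.0,
              rigid_offset=_OFFSET_4MM_3DEG),
    # (e) sagging + misalignment + bias + noise
    "e": dict(rigid_offset=_OFFSET_4MM_3DEG),
    # (f) small lesionectomy: a clearly visible small cavity (tissue
    # collapse into a lesionectomy-sized cavity is minimal) under mild
    # noise, bias and misalignment
    "f": dict(sagging_magnitude=0.5,
              rigid_offset=(2.0, -1.0, 1.0, 1.5, -1.0, 0.5)),
}


def preset_config(preset: str, seed: int = 0,
                  grid_shape: tuple[int, int, int] = (96, 96, 96)) -> PhantomConfig:
    if preset not in FIXTURE_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from "
                         f"{sorted(FIXTURE_PRESETS)}")
    kw = dict(FIXTURE_PRESETS[preset])
    if preset == "f":
        scale = np.asarray(grid_shape, float) / 96.0
        kw["cavity_radii"] = tuple(np.asarray(_SMALL_RADII) * scale)
    return PhantomConfig(grid_shape=grid_shape, seed=seed, **kw)


def make_fixture_suite(seed: int = 0,
                       grid_shape: tuple[int, int, int] = (96, 96, 96),
                       presets: str = "abcdef",
                       ) -> list[tuple[Volume, Volume, PhantomTruth]]:
    """Graded battery of phantom cases (a)..(f), easiest to hardest."""
    suite = []
    for i, p in enumerate(presets):
        cfg = preset_config(p, seed=seed + i, grid_shape=grid_shape)
        suite.append(generate_case(cfg))
    return suite
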