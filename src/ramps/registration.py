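"""Rigid + deformable alignment of the post-operative volume into
pre-operative space.

The rigid stage minimizes the masked mean-squared intensity difference
over 6 parameters (Euler rotations + translations about the fixed-volume
centre) with a deterministic multi-resolution Powell search — appropriate
for same-modality T1-T1 alignment.  The deformable stage is a demons-style
iterative scheme: an intensity-difference-driven force, Gaussian fluid
smoothing of the update and Gaussian diffusion smoothing of the field,
run coarse-to-fine with a fixed iteration schedule.  Both stages are fully
deterministic (no stochastic sampling).

The deformable stage is deliberately conservative: the resection cavity is
a *genuine* pre/post difference, and an aggressive (or very coarse-level)
deformable fit "heals" it by dragging surrounding tissue inward, which
destroys the subtraction-image signal the cavity-classification steps rely
on.  The schedule therefore runs only at 2x and 1x with few iterations —
enough to correct post-surgical sagging of a few voxels, not enough to
close a cavity.

A ``backend`` seam on :func:`register` lets deployments substitute an
external registration; the built-in implementation is the tested default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize

from .core import BinaryMask, GridMismatchError, LabelVolume, Volume

__all__ = [
    "RigidTransform",
    "DisplacementField",
    "TransformChain",
    "register_rigid",
    "register_deformable",
    "register",
    "apply_chain",
]


# ---------------------------------------------------------------------------
# transform types
# ---------------------------------------------------------------------------

def _euler_matrix(rot_rad: np.ndarray) -> np.ndarray:
    rx, ry, rz = rot_rad
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


@dataclass
class RigidTransform:
    """6-parameter rigid map of world coordinates (fixed -> moving space).

    ``y = R (x - center) + center + translation`` with rotations in
    radians and translations/center in mm.
    """

    rotations: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    translations: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, float).reshape(3)
        self.translations = np.asarray(self.translations, float).reshape(3)
        self.center = np.asarray(self.center, float).reshape(3)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate map."""
        R = _euler_matrix(self.rotations)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = self.center - R @ self.center + self.translations
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, center: np.ndarray) -> "RigidTransform":
        R = M[:3, :3]
        ry = np.arcsin(np.clip(-R[2, 0], -1.0, 1.0))
        rx = np.arctan2(R[2, 1], R[2, 2])
        rz = np.arctan2(R[1, 0], R[0, 0])
        center = np.asarray(center, float)
        t = M[:3, 3] - center + R @ center
        return cls(np.array([rx, ry, rz]), t, center)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: returns T with T(x) = self(other(x))."""
        return RigidTransform.from_matrix(self.matrix() @ other.matrix(),
                                          self.center)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.matrix()),
                                          self.center)

    def to_dict(self) -> dict:
        return {"rotations_rad": self.rotations.tolist(),
                "translations_mm": self.translations.tolist(),
                "center_mm": self.center.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.array(d["rotations_rad"]),
                   np.array(d["translations_mm"]),
                   np.array(d["center_mm"]))


@dataclass
class DisplacementField:
    """Dense per-voxel displacement (mm) on the fixed grid; the sampling
    position for fixed voxel x is x + u(x) (world-aligned axes)."""

    data: np.ndarray              # (3, nx, ny, nz)
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 4 or self.data.shape[0] != 3:
            raise ValueError("displacement field must have shape (3, nx, ny, nz)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("displacement field must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    def magnitude(self) -> np.ndarray:
        return np.sqrt((self.data ** 2).sum(axis=0))


@dataclass
class TransformChain:
    """Ordered rigid -> deformable map defined on the fixed grid."""

    fixed_affine: np.ndarray
    fixed_shape: tuple[int, int, int]
    rigid: RigidTransform | None = None
    field: DisplacementField | None = None

    def sampling_coords(self, moving_affine: np.ndarray) -> np.ndarray:
        """Moving-volume voxel coordinates at which to sample, per fixed
        voxel: x -> inv(A_mov) . T_rigid . A_fix . (x + u(x))."""
        shape = self.fixed_shape
        grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape],
                            indexing="ij")
        coords = np.stack(grids)                      # (3, ...)
        if self.field is not None:
            spacing = np.sqrt((np.asarray(self.fixed_affine)[:3, :3] ** 2
                               ).sum(axis=0))
            coords = coords + self.field.data / spacing[:, None, None, None]
        M = np.asarray(self.fixed_affine, float)
        if self.rigid is not None:
            M = self.rigid.matrix() @ M
        M = np.linalg.inv(np.asarray(moving_affine, float)) @ M
        flat = coords.reshape(3, -1)
        out = M[:3, :3] @ flat + M[:3, 3:4]
        return out.reshape(coords.shape)


def apply_chain(payload, chain: TransformChain):
    """Resample a payload from moving space onto the fixed grid.

    Interpolation: linear for intensities, nearest for labels, linear then
    threshold-0.5 for masks.
    """
    if payload.data.ndim != 3:
        raise GridMismatchError("payload must be a 3D volume")
    coords = chain.sampling_coords(payload.affine)
    out_affine = np.asarray(chain.fixed_affine, float)
    if isinstance(payload, LabelVolume):
        res = ndimage.map_coordinates(payload.data, coords, order=0,
                                      mode="constant", cval=0)
        return LabelVolume(res, out_affine, payload.legend)
    if isinstance(payload, BinaryMask):
        res = ndimage.map_coordinates(payload.data.astype(np.float32), coords,
                                      order=1, mode="constant", cval=0.0)
        return BinaryMask(res > 0.5, out_affine)
    res = ndimage.map_coordinates(payload.data, coords, order=1,
                                  mode="constant", cval=0.0)
    return Volume(res, out_affine)


# ---------------------------------------------------------------------------
# pyramids
# ---------------------------------------------------------------------------

def _block_mean(data: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return np.asarray(data, float)
    shape = [(s // f) * f for s in data.shape]
    d = np.asarray(data[: shape[0], : shape[1], : shape[2]], float)
    d = d.reshape(shape[0] // f, f, shape[1] // f, f, shape[2] // f, f)
    return d.mean(axis=(1, 3, 5))


def _down_affine(affine: np.ndarray, f: int) -> np.ndarray:
    if f == 1:
        return np.asarray(affine, float)
    out = np.asarray(affine, float).copy()
    out[:3, :3] = affine[:3, :3] * f
    out[:3, 3] = affine[:3, 3] + affine[:3, :3] @ np.full(3, (f - 1) / 2.0)
    return out


def _rescale_unit(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    vals = data[mask] if mask.any() else data
    lo, hi = np.percentile(vals, [1, 99])
    if hi <= lo:
        return np.zeros_like(data, dtype=float)
    return np.clip((data - lo) / (hi - lo), 0.0, 1.0)


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------

def register_rigid(fixed: Volume, moving: Volume, fixed_mask: BinaryMask,
                   levels: tuple[int, ...] = (4, 2, 1),
                   maxiter: tuple[int, ...] = (100, 50, 25),
                   ) -> RigidTransform:
    """Multi-resolution masked-MSD rigid registration (moving -> fixed).

    Deterministic: identity initialization, fixed Powell iteration budget
    per level, no sampling.  Returns the world-space transform such that
    resampling ``moving`` through it matches ``fixed``.
    """
    fixed.require_same_grid(fixed_mask, "fixed volume and mask")
    f_unit = _rescale_unit(fixed.data, fixed_mask.data)
    m_unit = _rescale_unit(moving.data, moving.data > 0)

    center_vox = (np.asarray(fixed.shape, float) - 1) / 2.0
    center_world = (fixed.affine @ np.append(center_vox, 1.0))[:3]

    params = np.zeros(6)  # rx, ry, rz (deg), tx, ty, tz (mm)
    for level, itmax in zip(levels, maxiter):
        f_l = _block_mean(f_unit, level)
        m_l = _block_mean(m_unit, level)
        mask_l = _block_mean(fixed_mask.data.astype(float), level) > 0.5
        aff_f = _down_affine(fixed.affine, level)
        aff_m = _down_affine(moving.affine, level)
        if not mask_l.any():
            continue
        midx = np.nonzero(mask_l)
        fvals = f_l[midx]

        def loss(p, _f=f_l, _m=m_l, _aff_f=aff_f, _aff_m=aff_m,
                 _midx=midx, _fvals=fvals, _shape=f_l.shape):
            T = RigidTransform(np.deg2rad(p[:3]), p[3:], center_world)
            M = np.linalg.inv(_aff_m) @ T.matrix() @ _aff_f
            pts = np.stack([c.astype(float) for c in _midx])
            mov_pts = M[:3, :3] @ pts + M[:3, 3:4]
            w = ndimage.map_coordinates(_m, mov_pts, order=1,
                                        mode="constant", cval=0.0)
            r = w - _fvals
            val = float(np.mean(r * r))
            if not np.isfinite(val):
                raise FloatingPointError("non-finite registration loss")
            return val

        res = optimize.minimize(loss, params, method="Powell",
                                options={"maxiter": itmax, "xtol": 1e-4,
                                         "ftol": 1e-8})
        if not res.success and res.status not in (1, 2):
            warnings.warn(f"rigid level {level}x did not converge: "
                          f"{res.message}; keeping best iterate",
                          stacklevel=2)
        params = res.x

    return RigidTransform(np.deg2rad(params[:3]), params[3:], center_world)


# ---------------------------------------------------------------------------
# deformable (demons) registration
# ---------------------------------------------------------------------------

def _warp_voxel(data: np.ndarray, u: np.ndarray, order: int = 1) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in data.shape],
                        indexing="ij")
    coords = np.stack(grids) + u
    return ndimage.map_coordinates(data, coords, order=order,
                                   mode="nearest")


def register_deformable(fixed: Volume, moving_rigid: Volume,
                        fixed_mask: BinaryMask,
                        levels: tuple[int, ...] = (1,),
                        iters: tuple[int, ...] = (5,),
                        sigma_fluid: float = 1.0,
                        sigma_diffusion: float = 0.0,
                        sigma_image: float = 1.0,
                        sigma_reject: float = 0.2,
                        step: float = 0.5,
                        mask_margin: int = 3) -> DisplacementField:
    """Demons-style deformable registration on the fixed grid.

    ``moving_rigid`` must already be resampled into fixed space.  The
    update force is Gaussian-regularized (fluid model, ``sigma_fluid``)
    and, optionally, the accumulated field is diffusion-smoothed
    (``sigma_diffusion``; 0 disables).  Images are pre-smoothed by
    ``sigma_image`` so that sub-voxel corrections at sharp interfaces are
    cheap.  The force is additionally down-weighted by
    ``exp(-(diff/sigma_reject)^2)``: a large coherent pre/post intensity
    difference is genuine tissue change (the resection cavity), not
    misalignment, and must not be "healed" away by the deformation.

    The returned field is zero outside ``fixed_mask`` dilated by
    ``mask_margin`` voxels.  If the masked MSD stops improving the best
    iterate is returned with a warning.
    """
    fixed.require_same_grid(moving_rigid, "fixed and rigid-aligned moving")
    fixed.require_same_grid(fixed_mask, "fixed volume and mask")
    f_unit = _rescale_unit(fixed.data, fixed_mask.data)
    m_unit = _rescale_unit(moving_rigid.data, fixed_mask.data)
    spacing = fixed.spacing

    u = None  # voxel units, on the current level grid
    for level, itmax in zip(levels, iters):
        f_l = _block_mean(f_unit, level)
        m_l = _block_mean(m_unit, level)
        if sigma_image > 0:
            f_l = ndimage.gaussian_filter(f_l, sigma_image)
            m_l = ndimage.gaussian_filter(m_l, sigma_image)
        mask_l = _block_mean(fixed_mask.data.astype(float), level) > 0.25
        support = ndimage.binary_dilation(
            mask_l, iterations=max(1, int(np.ceil(mask_margin / level))))
        if u is None:
            u = np.zeros((3,) + f_l.shape)
        else:
            zoom = [t / s for t, s in zip(f_l.shape, u.shape[1:])]
            u = np.stack([ndimage.zoom(u[a], zoom, order=1) * zoom[a]
                          for a in range(3)])
            # zoom may be off by a voxel; pad/crop to the level grid
            u = _fit_shape(u, f_l.shape)

        best_u, best_msd = u.copy(), np.inf
        bad_streak = 0
        for _ in range(itmax):
            warped = _warp_voxel(m_l, u)
            diff = f_l - warped
            msd = float(np.mean((diff[mask_l]) ** 2))
            if msd < best_msd - 1e-12:
                best_msd, best_u = msd, u.copy()
                bad_streak = 0
            else:
                bad_streak += 1
                if bad_streak >= 5:
                    warnings.warn("deformable stage stopped early "
                                  "(no MSD improvement); returning best "
                                  "iterate", stacklevel=2)
                    u = best_u
                    break
            grad = np.stack(np.gradient(warped))
            gnorm2 = (grad ** 2).sum(axis=0)
            denom = gnorm2 + diff ** 2 + 1e-12
            force = diff * grad / denom
            if sigma_reject > 0:
                force = force * np.exp(-((diff / sigma_reject) ** 2))
            force = np.stack([ndimage.gaussian_filter(force[a], sigma_fluid)
                              for a in range(3)])
            u = u + step * force
            if sigma_diffusion > 0:
                u = np.stack([ndimage.gaussian_filter(u[a], sigma_diffusion)
                              for a in range(3)])
            u *= support
        else:
            warped = _warp_voxel(m_l, u)
            msd = float(np.mean(((f_l - warped)[mask_l]) ** 2))
            if msd > best_msd:
                u = best_u
        last_level = level

    if last_level > 1:  # finest processed level was still downsampled
        u = np.stack([ndimage.zoom(u[a], last_level, order=1) * last_level
                      for a in range(3)])
    u = _fit_shape(u, fixed.shape)
    support_full = ndimage.binary_dilation(fixed_mask.data,
                                           iterations=mask_margin)
    u *= support_full
    u_mm = u * spacing[:, None, None, None]
    return DisplacementField(u_mm, fixed.affine)


def _fit_shape(u: np.ndarray, shape) -> np.ndarray:
    out = np.zeros((3,) + tuple(shape))
    sl = tuple(slice(0, min(a, b)) for a, b in zip(u.shape[1:], shape))
    out[(slice(None),) + sl] = u[(slice(None),) + sl]
    return out


def register(fixed: Volume, moving: Volume, fixed_mask: BinaryMask,
             backend=None, **kwargs) -> TransformChain:
    """Full rigid + deformable registration returning a TransformChain.

    ``backend``, if given, is a callable with this same signature returning
    a :class:`TransformChain`; it replaces the built-in implementation.
    """
    if backend is not None:
        return backend(fixed, moving, fixed_mask, **kwargs)
    rigid = register_rigid(fixed, moving, fixed_mask)
    chain_r = TransformChain(fixed.affine, fixed.shape, rigid=rigid)
    moving_rigid = apply_chain(moving, chain_r)
    fld = register_deformable(fixed, moving_rigid, fixed_mask,
                              **kwargs)
    return TransformChain(fixed.affine, fixed.shape, rigid=rigid, field=fld)
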