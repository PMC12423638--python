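"""Cavity classification: delineate the resection cavity in registered
post-operative space and expand it to the pre-operative tissue boundary.

The sequence mirrors the mask-creation part of the pipeline:

7.  rescale both images to [0, 1] so CSF/GM/WM take comparable values;
8.  prior-guided two-class Gaussian-mixture EM (ventricle prior -> CSF
    class, non-resected-lobe tissue prior -> tissue class) segments the
    cavity within the resected lobe of the aligned post-operative image;
9.  a no-prior 2-means split within that cavity isolates its CSF core
    from damaged in-between tissue;
10. the post-operative image is subtracted from the pre-operative one —
    same tissue class cancels, pre-operative tissue overlying post-
    operative CSF leaves a positive residue;
11. a second prior-guided EM expands the CSF core through the subtraction
    image, keeping the largest connected component in the resected lobe;
12. erosion + cluster-checked constrained dilation removes thin
    misalignment spurs;
13. a directional boundary dilation extends the mask to nearby CSF (and
    only toward CSF, never into intact tissue);
14. closing, hole-filling, lobe filtering and resampling to the original
    pre-operative grid finish the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage

from .core import BinaryMask, GridMismatchError, LabelVolume, ResectionSpec, Volume
from . import preprocess as prep
from . import registration as reg

__all__ = [
    "RescaledVolume",
    "PriorSet",
    "CavityState",
    "CavityNotFoundError",
    "VENTRICLE_CODES",
    "rescale_unit",
    "prior_mixture_segment",
    "kmeans2_csf",
    "subtract_images",
    "expand_cavity",
    "remove_misalignment_spurs",
    "directional_boundary_dilation",
    "finalize_mask",
    "run_cavity_pipeline",
]

VENTRICLE_CODES = (4, 5, 14, 15, 43, 44, 72)

_STRUCT_26 = np.ones((3, 3, 3), bool)
_STRUCT_6 = ndimage.generate_binary_structure(3, 1)


class CavityNotFoundError(RuntimeError):
    """No cavity could be delineated; carries a machine-readable code."""

    def __init__(self, message: str, code: str = "no_cavity_found"):
        super().__init__(message)
        self.code = code


class RescaledVolume(Volume):
    """Volume whose brain intensities have been mapped into [0, 1]."""


@dataclass
class PriorSet:
    """Spatial priors for the cavity EM: ventricular CSF, intact tissue,
    and the lobe in which to search."""

    csf_prior: BinaryMask
    tissue_prior: BinaryMask
    search_region: BinaryMask

    def __post_init__(self) -> None:
        self.csf_prior.require_same_grid(self.tissue_prior, "priors")
        self.csf_prior.require_same_grid(self.search_region, "priors")
        if self.csf_prior.count() == 0 or self.tissue_prior.count() == 0:
            raise ValueError("prior masks must be nonempty")
        if np.any(self.csf_prior.data & self.tissue_prior.data):
            raise ValueError("CSF and tissue priors must be disjoint")
        if np.any(self.search_region.data & self.tissue_prior.data):
            raise ValueError("search region must be disjoint from the "
                             "tissue prior")


@dataclass
class CavityState:
    """All intermediates of the cavity stage, for audit."""

    postop_cavity: BinaryMask | None = None      # step 8
    cavity_csf: BinaryMask | None = None         # step 9
    diff_image: Volume | None = None             # step 10
    expanded_mask: BinaryMask | None = None      # step 11
    cleaned_mask: BinaryMask | None = None       # step 12
    dilated_mask: BinaryMask | None = None       # step 13
    final_mask: BinaryMask | None = None         # step 14
    warnings: list[str] = dc_field(default_factory=list)

    def counts(self) -> dict[str, int | None]:
        return {name: (getattr(self, name).count()
                       if getattr(self, name) is not None else None)
                for name in ("postop_cavity", "cavity_csf", "expanded_mask",
                             "cleaned_mask", "dilated_mask", "final_mask")}


# ---------------------------------------------------------------------------
# step 7: rescale
# ---------------------------------------------------------------------------

def rescale_unit(vol: Volume, brain: BinaryMask) -> RescaledVolume:
    """Robust min-max rescale: the 1st/99th percentiles of brain
    intensities map to 0/1, values outside are clipped; background stays 0.
    """
    vol.require_same_grid(brain, "volume and brain mask")
    if brain.count() == 0:
        raise ValueError("brain mask is empty")
    vals = vol.data[brain.data]
    lo, hi = np.percentile(vals, [1, 99])
    if hi <= lo:
        raise ValueError("brain intensities are constant; cannot rescale")
    data = np.clip((vol.data - lo) / (hi - lo), 0.0, 1.0)
    data[~brain.data] = 0.0
    return RescaledVolume(data, vol.affine)


# ---------------------------------------------------------------------------
# two-class Gaussian EM (the finite-mixture work-horse of steps 8 and 11)
# ---------------------------------------------------------------------------

def _em_two_class(values: np.ndarray, fixed: np.ndarray,
                  init_means: tuple[float, float],
                  init_sds: tuple[float, float],
                  max_iter: int = 100, tol: float = 1e-5,
                  fix_proportions: bool = False) -> np.ndarray:
    """EM for a 2-component Gaussian mixture with partially fixed
    memberships.

    ``fixed`` holds -1 for free voxels, 0/1 for voxels whose class is
    known (prior voxels).  With ``fix_proportions`` the mixing weights
    stay at 1/2 — used when one class is a small object inside a large
    search region and must not be swamped by the other's mass.  Returns
    the class-0 posterior per voxel.
    """
    mu = np.array(init_means, float)
    sd = np.maximum(np.array(init_sds, float), 1e-4)
    pi = np.array([0.5, 0.5])
    r0 = np.where(fixed == 0, 1.0, np.where(fixed == 1, 0.0, 0.5))
    free = fixed == -1
    for _ in range(max_iter):
        prev = np.concatenate([mu, sd, pi])
        if free.any():
            logp = np.empty((2, values.size))
            for k in range(2):
                logp[k] = (np.log(pi[k] + 1e-300)
                           - 0.5 * ((values - mu[k]) / sd[k]) ** 2
                           - np.log(sd[k]))
            m = logp.max(axis=0)
            p = np.exp(logp - m)
            post0 = p[0] / (p[0] + p[1])
            r0 = np.where(free, post0, r0)
        w0 = r0
        w1 = 1.0 - r0
        for k, w in ((0, w0), (1, w1)):
            tot = w.sum()
            if tot < 1e-12:
                continue
            mu[k] = (w * values).sum() / tot
            sd[k] = np.sqrt((w * (values - mu[k]) ** 2).sum() / tot)
            sd[k] = max(sd[k], 1e-4)
            if not fix_proportions:
                pi[k] = tot / values.size
        pi /= pi.sum()
        if np.max(np.abs(np.concatenate([mu, sd, pi]) - prev)) < tol:
            break
    return r0


def prior_mixture_segment(vol: RescaledVolume, priors: PriorSet) -> BinaryMask:
    """Prior-initialized finite-mixture segmentation of the resection
    cavity (step 8).

    The CSF class is seeded from ventricle intensities, the tissue class
    from cerebral tissue in the non-resected lobes; prior voxels keep a
    fixed membership throughout EM.  Returns the search-region voxels
    assigned to the CSF/cavity class.
    """
    data = vol.data
    sel = priors.search_region.data | priors.csf_prior.data | priors.tissue_prior.data
    idx = np.nonzero(sel)
    values = data[idx].astype(float)
    fixed = np.full(values.size, -1, np.int8)
    fixed[priors.csf_prior.data[idx]] = 0
    fixed[priors.tissue_prior.data[idx]] = 1

    csf_vals = data[priors.csf_prior.data]
    tis_vals = data[priors.tissue_prior.data]
    pooled_sd = np.sqrt((csf_vals.var() + tis_vals.var()) / 2.0)
    if abs(csf_vals.mean() - tis_vals.mean()) < 0.5 * max(pooled_sd, 1e-6):
        warnings.warn("CSF and tissue prior intensity distributions overlap "
                      "heavily; segmentation may be unreliable", stacklevel=2)
    post0 = _em_two_class(
        values, fixed,
        init_means=(float(csf_vals.mean()), float(tis_vals.mean())),
        init_sds=(float(csf_vals.std()), float(tis_vals.std())))
    out = np.zeros(vol.shape, bool)
    out[idx] = (post0 > 0.5) & priors.search_region.data[idx]
    return BinaryMask(out, vol.affine)


# ---------------------------------------------------------------------------
# step 9: K-means CSF split
# ---------------------------------------------------------------------------

def kmeans2_csf(vol: RescaledVolume, cavity: BinaryMask,
                min_separation: float = 0.1) -> BinaryMask:
    """No-prior 2-means split within the step-8 cavity; the cluster with
    the lower median intensity is CSF.

    If the two cluster medians differ by less than ``min_separation``
    (rescaled units) the cavity is unimodal — there is no distinct
    damaged-tissue mode, the split is merely cutting noise in half — and
    the whole cavity is returned.  Ties break toward the lower mean, then
    toward the cluster containing the minimum intensity.  A cavity with a
    single distinct intensity is returned whole, with a warning.
    """
    vol.require_same_grid(cavity, "volume and cavity")
    if cavity.count() < 2:
        raise ValueError("cavity must contain at least 2 voxels")
    vals = vol.data[cavity.data].astype(float)
    if np.unique(vals).size == 1:
        warnings.warn("cavity has a single distinct intensity; returning "
                      "the whole cavity as CSF", stacklevel=2)
        return cavity.copy()
    centers = np.percentile(vals, [25, 75]).astype(float)
    if centers[0] == centers[1]:
        centers[1] = vals.max()
        centers[0] = vals.min()
    for _ in range(100):
        assign = np.abs(vals - centers[0]) > np.abs(vals - centers[1])
        new = np.array([vals[~assign].mean() if (~assign).any() else centers[0],
                        vals[assign].mean() if assign.any() else centers[1]])
        if np.allclose(new, centers, atol=1e-12):
            break
        centers = new
    assign = np.abs(vals - centers[0]) > np.abs(vals - centers[1])
    groups = [~assign, assign]
    med = [np.median(vals[g]) if g.any() else np.inf for g in groups]
    if np.all(np.isfinite(med)) and abs(med[0] - med[1]) < min_separation:
        # unimodal cavity: the 2-means split is only cutting noise in
        # half; there is no distinct damaged-tissue mode to discard
        return cavity.copy()
    if med[0] != med[1]:
        low = int(np.argmin(med))
    else:
        mean = [vals[g].mean() if g.any() else np.inf for g in groups]
        if mean[0] != mean[1]:
            low = int(np.argmin(mean))
        else:
            low = 0 if vals[groups[0]].min() <= vals[groups[1]].min() else 1
    out = np.zeros(vol.shape, bool)
    idx = np.nonzero(cavity.data)
    out[tuple(i[groups[low]] for i in idx)] = True
    return BinaryMask(out, vol.affine)


# ---------------------------------------------------------------------------
# step 10: subtraction image
# ---------------------------------------------------------------------------

def subtract_images(pre: RescaledVolume, post_aligned: RescaledVolume,
                    pre_brain: BinaryMask) -> Volume:
    """pre - post difference masked to the pre-operative brain: same-class
    voxels cancel; pre-operative tissue over post-operative CSF leaves a
    positive residue marking resected (or sagged-away) tissue."""
    pre.require_same_grid(post_aligned, "pre and aligned post")
    pre.require_same_grid(pre_brain, "pre and brain mask")
    diff = (pre.data - post_aligned.data) * pre_brain.data
    return Volume(diff, pre.affine)


# ---------------------------------------------------------------------------
# step 11: expansion through the subtraction image
# ---------------------------------------------------------------------------

def expand_cavity(diff: Volume, cavity_seed: BinaryMask,
                  resected_lobe: BinaryMask,
                  free_band: int = 4) -> BinaryMask:
    """Expand the CSF seed through the subtraction image by prior-guided
    EM; keep the largest 26-connected component in the resected lobe.

    The seed keeps a fixed cavity membership; lobe voxels farther than
    ``free_band`` voxels from the seed keep a fixed no-difference
    membership (and initialize that class); the band in between is free.
    The band bounds how far a single expansion can reach, which keeps
    distant misalignment residue from joining the cavity, while a band of
    a few voxels comfortably covers the sagged-tissue rim.
    """
    diff.require_same_grid(cavity_seed, "diff and seed")
    diff.require_same_grid(resected_lobe, "diff and lobe")
    if cavity_seed.count() == 0:
        raise CavityNotFoundError("cavity seed is empty: no cavity found")
    seed = cavity_seed.data
    lobe = resected_lobe.data
    bg_prior = lobe & ~ndimage.binary_dilation(seed, _STRUCT_26,
                                               iterations=free_band)
    sel = lobe | seed
    idx = np.nonzero(sel)
    values = diff.data[idx].astype(float)
    fixed = np.full(values.size, -1, np.int8)
    fixed[seed[idx]] = 0
    fixed[bg_prior[idx] & ~seed[idx]] = 1

    seed_vals = diff.data[seed]
    bg_vals = diff.data[bg_prior] if bg_prior.any() else np.array([0.0])
    post0 = _em_two_class(
        values, fixed,
        init_means=(float(seed_vals.mean()), float(bg_vals.mean())),
        init_sds=(float(seed_vals.std()), float(bg_vals.std())),
        fix_proportions=True)
    cls1 = np.zeros(diff.shape, bool)
    cls1[idx] = post0 > 0.5
    cls1 &= lobe
    if not cls1.any():
        raise CavityNotFoundError("expansion produced no cavity voxels: "
                                  "no cavity found")
    lab, n = ndimage.label(cls1, structure=_STRUCT_26)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=range(1, n + 1))
    out = lab == (1 + int(np.argmax(sizes)))
    return BinaryMask(out, diff.affine)


# ---------------------------------------------------------------------------
# step 12: misalignment-spur removal
# ---------------------------------------------------------------------------

def remove_misalignment_spurs(mask: BinaryMask, erosion_radius: int = 1,
                              n_dilations: int = 3,
                              cluster_threshold: int | None = None
                              ) -> BinaryMask:
    """Erode, keep the main body, then re-grow inside the original mask,
    discarding small re-entry clusters (poor-alignment spurs).

    After each constrained dilation round, newly reached voxels are
    grouped into 26-connected clusters; clusters smaller than
    ``cluster_threshold`` (default max(10, 1% of the mask volume)) are
    removed and barred from later rounds.  If erosion would empty the
    mask (small lesionectomies) it is skipped with a warning.
    """
    if mask.count() == 0:
        raise ValueError("mask is empty")
    original = mask.data
    if cluster_threshold is None:
        cluster_threshold = max(10, int(0.01 * original.sum()))
    # Chebyshev ball: a 1-voxel bridge voxel whose face-neighbours are
    # all masked still erodes away via its corner neighbours
    eroded = ndimage.binary_erosion(original, _STRUCT_26,
                                    iterations=erosion_radius)
    if not eroded.any():
        warnings.warn("erosion empties the mask; skipping spur removal to "
                      "protect a small cavity", stacklevel=2)
        return mask.copy()
    lab, n = ndimage.label(eroded, structure=_STRUCT_26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=range(1, n + 1))
        eroded = lab == (1 + int(np.argmax(sizes)))
    current = eroded
    forbidden = np.zeros_like(original)
    for _ in range(n_dilations):
        grown = ndimage.binary_dilation(current, _STRUCT_26)
        grown &= original & ~forbidden
        new = grown & ~current
        if not new.any():
            break
        lab, n = ndimage.label(new, structure=_STRUCT_26)
        for comp in range(1, n + 1):
            sel = lab == comp
            if sel.sum() < cluster_threshold:
                forbidden |= sel
            else:
                current = current | sel
    return BinaryMask(current, mask.affine)


# ---------------------------------------------------------------------------
# step 13: directional boundary dilation toward CSF
# ---------------------------------------------------------------------------

def _bresenham_between(b: np.ndarray, c: np.ndarray) -> list[tuple[int, ...]]:
    """Voxels strictly between b and c on the discrete 3D line segment."""
    n = int(np.max(np.abs(c - b)))
    if n <= 1:
        return []
    ts = np.arange(1, n) / n
    pts = np.round(b[None, :] + ts[:, None] * (c - b)[None, :]).astype(int)
    return [tuple(p) for p in pts]


def directional_boundary_dilation(mask: BinaryMask, csf: BinaryMask,
                                  max_dist: int = 3,
                                  metric: str = "chebyshev") -> BinaryMask:
    """Extend the mask from its boundary toward nearby CSF (step 13).

    For every boundary voxel with a CSF voxel within ``max_dist``
    (Chebyshev by default, Euclidean via ``metric='euclidean'``), the
    voxels on the discrete segment to the *nearest* such CSF voxel are
    added.  Growth is therefore possible only toward CSF — never into
    intact tissue.  CSF voxels already inside the mask are not targets.
    """
    mask.require_same_grid(csf, "mask and CSF")
    if metric not in ("chebyshev", "euclidean"):
        raise ValueError("metric must be 'chebyshev' or 'euclidean'")
    data = mask.data
    targets = csf.data & ~data
    if not targets.any():
        return mask.copy()
    boundary = data & ~ndimage.binary_erosion(data, _STRUCT_6)
    out = data.copy()
    shape = data.shape
    m = max_dist
    for b in np.argwhere(boundary):
        lo = np.maximum(b - m, 0)
        hi = np.minimum(b + m + 1, shape)
        win = targets[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        if not win.any():
            continue
        cand = np.argwhere(win) + lo
        delta = cand - b
        cheb = np.abs(delta).max(axis=1)
        eucl2 = (delta ** 2).sum(axis=1)
        if metric == "euclidean":
            ok = eucl2 <= m * m
            if not ok.any():
                continue
            cand, cheb, eucl2 = cand[ok], cheb[ok], eucl2[ok]
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0],
                                cheb, eucl2))
        else:
            order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0],
                                eucl2, cheb))
        c = cand[order[0]]
        for p in _bresenham_between(b, c):
            out[p] = True
    return BinaryMask(out, mask.affine)


# ---------------------------------------------------------------------------
# step 14: closing, hole fill, lobe filter, resample
# ---------------------------------------------------------------------------

def finalize_mask(mask: BinaryMask, resected_lobe_pre: BinaryMask,
                  original_grid: tuple[np.ndarray, tuple[int, int, int]] | None = None
                  ) -> BinaryMask:
    """Morphological closing + internal hole fill, lobe filtering, and
    resampling back to the original pre-operative grid.

    Hole filling floods the 6-connected background from the volume border;
    unreached background components are interior holes and are filled.
    The largest 26-connected component is kept so the final mask is a
    single object.
    """
    if mask.count() == 0:
        raise CavityNotFoundError("mask is empty before finalization")
    mask.require_same_grid(resected_lobe_pre, "mask and lobe")
    closed = ndimage.binary_closing(mask.data, _STRUCT_6, iterations=1)
    closed |= mask.data
    filled = ndimage.binary_fill_holes(closed, _STRUCT_6)
    filtered = filled & resected_lobe_pre.data
    if not filtered.any():
        raise CavityNotFoundError("cavity outside specified lobe",
                                  code="cavity_outside_lobe")
    lab, n = ndimage.label(filtered, structure=_STRUCT_26)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab,
                                   index=range(1, n + 1))
        filtered = lab == (1 + int(np.argmax(sizes)))
    out = BinaryMask(filtered, mask.affine)
    if original_grid is not None:
        affine, shape = original_grid
        if tuple(shape) != out.shape or not np.allclose(affine, out.affine,
                                                        atol=1e-6):
            M = np.linalg.inv(out.affine) @ np.asarray(affine, float)
            res = ndimage.affine_transform(
                out.data.astype(np.float32), M[:3, :3], offset=M[:3, 3],
                output_shape=tuple(shape), order=1, mode="constant", cval=0.0)
            out = BinaryMask(res > 0.5, affine)
            if not out.data.any():
                raise CavityNotFoundError("mask vanished on resampling",
                                          code="no_cavity_found")
    return out


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _ventricle_mask(regions: LabelVolume) -> BinaryMask:
    return BinaryMask(np.isin(regions.data, VENTRICLE_CODES), regions.affine)


def run_cavity_pipeline(pre: Volume, post: Volume,
                        labels_pre: LabelVolume, labels_post: LabelVolume,
                        spec: ResectionSpec = ResectionSpec(),
                        lobe_mapping: dict | None = None,
                        registration_kwargs: dict | None = None,
                        csf_level: float = 0.2,
                        ) -> tuple[BinaryMask, CavityState, dict]:
    """Full pipeline: data preparation, registration, cavity steps 7-14.

    ``labels_pre``/``labels_post`` are region segmentations of each image
    on its own grid (external segmenter in real use; phantom ground truth
    in tests).  Returns the final pre-operative-space resection mask, the
    audit trail of intermediates, and a JSON-serializable report.
    """
    report: dict = {"spec": {"hemisphere": spec.hemisphere,
                             "lobes": sorted(spec.lobes)
                             if spec.lobes != "all" else "all"},
                    "steps": {}, "warnings": []}
    state = CavityState()
    original_grid = (pre.affine.copy(), pre.shape)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # ---- step 1: common 1 mm isotropic working grid ----
        iso = (np.allclose(pre.spacing, 1.0, atol=0.01)
               and np.allclose(post.spacing, 1.0, atol=0.01)
               and pre.same_grid(post))
        if not iso:
            fov = np.maximum(np.asarray(pre.shape) * pre.spacing,
                             np.asarray(post.shape) * post.spacing)
            shape = tuple(int(min(np.ceil(f), 256)) for f in fov)
            pre = prep.normalize_resolution(pre, 1.0, shape)
            post = prep.normalize_resolution(post, 1.0, shape)
            labels_pre = prep.normalize_resolution(labels_pre, 1.0, shape)
            labels_post = prep.normalize_resolution(labels_post, 1.0, shape)
            report["steps"]["working_grid"] = list(shape)

        # ---- Part A: preparation (both images, pre-space atlas) ----
        atlas_pre = prep.build_lobe_atlas(labels_pre, lobe_mapping)
        pre_masked, brain_pre = prep.mask_brain(pre, labels_pre)
        post_masked, brain_post = prep.mask_brain(post, labels_post)
        pre_corr, _ = prep.correct_bias(pre_masked, brain_pre)
        post_corr, _ = prep.correct_bias(post_masked, brain_post)
        pre_prep = prep.clamp_top_percentile(pre_corr, brain_pre)
        post_prep = prep.clamp_top_percentile(post_corr, brain_post)
        full_atlas = prep.dilate_atlas_through_wm(atlas_pre, brain_pre)
        target_lobe, other_lobes = prep.split_resection_lobes(full_atlas, spec)
        report["steps"]["resected_lobe_voxels"] = target_lobe.count()

        # ---- Part B: registration (post -> pre space) ----
        chain = reg.register(pre_prep, post_prep, brain_pre,
                             **(registration_kwargs or {}))
        post_in_pre = reg.apply_chain(post_prep, chain)
        report["steps"]["rigid_params"] = chain.rigid.to_dict()

        # ---- Part C: cavity classification ----
        pre_r = rescale_unit(pre_prep, brain_pre)
        post_r = rescale_unit(post_in_pre, brain_pre)

        vent = _ventricle_mask(labels_pre)
        if other_lobes.count() > 0:
            tissue_prior = other_lobes
            search = target_lobe
        else:
            # no prior knowledge (search everything): a provisional CSF
            # estimate seeded by the ventricles alone stands in for the
            # missing "non-resected lobes"; intact tissue is whatever
            # lies away from that estimate
            sel = target_lobe.data | vent.data
            idx = np.nonzero(sel)
            vals = post_r.data[idx].astype(float)
            fixed = np.full(vals.size, -1, np.int8)
            fixed[vent.data[idx]] = 0
            other_vals = post_r.data[target_lobe.data & ~vent.data]
            prov0 = _em_two_class(
                vals, fixed,
                init_means=(float(post_r.data[vent.data].mean()),
                            float(other_vals.mean())),
                init_sds=(float(post_r.data[vent.data].std()),
                          float(other_vals.std())))
            provisional = np.zeros(pre.shape, bool)
            provisional[idx] = prov0 > 0.5
            blocked = ndimage.binary_dilation(
                provisional | vent.data, _STRUCT_26, iterations=2)
            tissue_prior = BinaryMask(
                brain_pre.data & ~blocked & target_lobe.data, pre.affine)
            search = BinaryMask(target_lobe.data & ~tissue_prior.data,
                                pre.affine)
        priors = PriorSet(vent, tissue_prior, search)
        state.postop_cavity = prior_mixture_segment(post_r, priors)
        if state.postop_cavity.count() == 0:
            raise CavityNotFoundError(
                "no cavity voxels found in the search region")
        state.cavity_csf = kmeans2_csf(post_r, state.postop_cavity)
        state.diff_image = subtract_images(pre_r, post_r, brain_pre)
        state.expanded_mask = expand_cavity(state.diff_image,
                                            state.cavity_csf, target_lobe)
        state.cleaned_mask = remove_misalignment_spurs(state.expanded_mask)
        csf_union = BinaryMask(
            state.cavity_csf.data
            | (brain_pre.data & (pre_r.data < csf_level)),
            pre.affine)
        state.dilated_mask = directional_boundary_dilation(
            state.cleaned_mask, csf_union)
        state.final_mask = finalize_mask(
            state.dilated_mask,
            BinaryMask(target_lobe.data & brain_pre.data, pre.affine),
            original_grid=original_grid)

    state.warnings = [str(w.message) for w in caught]
    report["warnings"] = state.warnings
    report["steps"].update(state.counts())
    return state.final_mask, state, report
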