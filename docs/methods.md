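# Methods

This note documents the models, algorithms and numerical choices behind
`ramps`, what the synthetic phantoms do and do not emulate, and the known
limitations.

## The problem

A resection mask labels, on the **pre-operative** T1w grid, the voxels of
tissue that surgery subsequently removed.  Two effects make this harder
than outlining the cavity on the post-operative scan: the pre and post
images live in different coordinate frames (head placement, scanner), and
after surgery the surrounding brain *sags* into the cavity, so the
post-operative CSF-filled cavity is smaller than, and displaced relative
to, the removed pre-operative tissue.

## Synthetic phantoms

The phantom generator (`ramps.phantom`) builds the study conditions every
test and the acceptance script run under.

**Geometry.** A layered ellipsoidal head: WM core (normalized radius
ρ ≤ 0.80 of the brain envelope), GM shell (0.80 < ρ ≤ 0.93), CSF rim
(0.93 < ρ ≤ 1), two ellipsoidal lateral ventricles, deep-grey
(thalamus-coded) and insula shells around them, and a brainstem blob.
Cortical GM is parcellated into Frontal / Parietal / Occipital / Temporal
by angular sector in the sagittal plane, per hemisphere (mid-sagittal
split).  Region labels use the SynthSeg/FreeSurfer integer codes so the
packaged `lobe_map.tsv` applies to phantom and real segmentations alike.

**Surgery.** An ellipsoidal cavity (default radii 10×9×8 voxels at 96³,
centred in the left temporal territory, touching the cortical surface as
real resections do) is carved to the CSF intensity.  The ground-truth
mask is the carved tissue *before* any deformation — exactly the
pre-operative tissue that was removed.

**Corruptions**, chosen once as plausible T1 acquisition/surgery
conditions and then left alone:

| parameter | default | meaning |
|---|---|---|
| grid | 96³ voxels, 1 mm | test-scale volume (160³ for demos) |
| tissue means | 0 / 150 / 450 / 750 | background / CSF / GM / WM, arbitrary units |
| `noise_sigma` | 0.03 × WM mean | additive Gaussian noise |
| `bias_amplitude` | 0.15 | peak deviation of the multiplicative bias field from 1 |
| `sagging_magnitude` | 2 voxels | peak inward displacement at the cavity wall |
| `sagging_tau` | 3 voxels | exponential decay length of the sag with distance from the wall |
| `rigid_offset` | 4 mm / 3° | pre/post misalignment (fixture cases d and e) |

Sagging is modelled as a radial sampling displacement of magnitude
`s·exp(−d/τ)` (d = distance to the cavity wall) away from the cavity
centroid, so resampling pulls outer tissue into the cavity.  The bias
field is the exponential of a sum of per-axis cubics, normalized to mean
1.  Noise is Gaussian (not Rician); phantom realism is a means, not an
end.  The fixture battery grades difficulty: (a) aligned/noiseless,
(b) noise+bias, (c) sagging, (d) rigid misalignment, (e) everything,
(f) a small lesionectomy (radii 3.5×3×3 voxels, < 5 % of the default
cavity volume).  Case (f) uses sagging 0.5 voxels: collapse into a
lesionectomy-sized cavity is physically minimal, and the case exists to
probe small-cavity behaviour, not sag erasure — a 1-voxel sag would fill
two-thirds of such a cavity and remove the image evidence that a visible
lesionectomy cavity by definition has.

**What the phantoms do not emulate:** cortical folding, Rician noise,
multi-contrast acquisitions, partial-volume mixtures beyond interpolation,
heterogeneous tissue texture, LiTT ablations, or multi-focal resections.
Passing tests therefore demonstrate algorithmic correctness under
controlled geometry, not clinical-grade accuracy on patient data.

## Data preparation

* **Resampling**: linear for intensities, nearest for labels, linear +
  0.5 threshold for masks; the working grid is 1 mm isotropic (default
  FOV 256³, phantoms pass through unchanged when already 1 mm).
* **Bias correction**: an order-3 3D polynomial is fitted to the brain
  log-intensities, iterated 5 times against a 3-class piecewise-constant
  tissue estimate (deterministic 1-D k-means).  The estimated field is
  normalized to mean 1 over the brain and divided out exactly.  This is a
  polynomial stand-in for B-spline N4 with the same low-frequency
  assumption; its contract is field recovery on phantoms (relative RMSE
  < 0.05), not equivalence with any particular tool.
* **Clamping**: the top 1 % of brain voxels are set to the brain median,
  within the brain only (background zeros would distort both the
  percentile and the median).
* **Lobe atlas**: region codes → lobe cells per the packaged TSV;
  ventricles/brainstem/cerebellum/extra-cerebral CSF collapse to a single
  `Excluded` code in which resection cannot occur.  White matter is
  filled by nearest-labelled-voxel propagation (per-code Euclidean
  distance transforms); distance ties break to the lowest lobe code,
  making the fill deterministic.  The nearest-source rule also settles
  behaviour at the mid-sagittal plane without an explicit barrier: a
  voxel adopts whichever hemisphere's label is closest.
* **Resection spec**: hemisphere L/R/both (default both) × lobes
  T/F/O/P (default all); T expands to Temporal ∪ SubCortical ∪ Insula
  because temporal-lobe surgery routinely removes hippocampus, amygdala
  and adjacent insula.

## Registration

The rigid stage optimizes 6 parameters (Euler angles + translations
about the volume centre) by Powell search on the masked mean-squared
difference of unit-rescaled images, over a 3-level pyramid (4×, 2×, 1×
block-mean downsampling; 100/50/25 iterations).  MSD is appropriate for
same-modality T1–T1 pairs and keeps the stage fully deterministic.  On
misalignment-only phantoms it recovers offsets up to 6 mm/5° within
0.1 mm / 0.1°.

The deformable stage is demons-like: force
`(f−m)∇m / (|∇m|² + (f−m)²)`, Gaussian fluid smoothing of the update
(σ = 1 voxel), images pre-smoothed by σ = 1 voxel, step 0.5, a fixed
budget of 5 iterations at full resolution, and the field zeroed outside
the brain mask dilated by 3 voxels.  Two choices here are deliberate and
differ from a generic registration:

1. **Robust force weighting.** The update is multiplied by
   `exp(−(diff/0.2)²)`.  A large coherent pre/post difference *is the
   resection*, not misalignment; without this weight the demons "heals"
   the cavity — it drags surrounding tissue inward to make the post image
   match the pre image, which destroys the subtraction-image signal the
   cavity steps depend on.
2. **No coarse level, few iterations.** At coarse pyramid levels the
   cavity spans only a few voxels and is healed wholesale; and because
   the resected tissue has no correspondence in the post image, longer
   optimization can only continue healing.  Five fine-level iterations
   correct smooth misalignment of a few voxels — the scale of
   post-surgical sagging — while leaving the cavity essentially intact.
   Field-diffusion smoothing is available (`sigma_diffusion`) but off by
   default: on piecewise-constant phantoms it displaces razor-sharp
   interfaces that carry no mismatch and raises the MSD.

A registration cannot, even in principle, "un-sag" the tissue: the
correspondence of the sagged rim is with pre-operative tissue that was
removed.  Recovering that rim is the job of the subtraction-image
expansion and the boundary dilation below.  `register()` accepts a
`backend` callable so a deployment can substitute an external
registration; the built-in stages are the tested default.

## Cavity classification

Steps, all deterministic:

7. **Rescale** both images to [0, 1] by the robust 1st/99th brain
   percentiles (clipped), so tissue classes take comparable values
   across scans.
8. **Prior-guided mixture.** Two-class Gaussian EM over the resected
   lobe plus priors; ventricle voxels are held in the CSF class and
   non-resected-lobe voxels in the tissue class throughout (fixed
   membership); convergence at max parameter change < 1e-5 or 100
   iterations; no MRF/spatial smoothing term.  When the user supplies no
   hemisphere/lobe information the search region is all non-Excluded
   brain and the tissue prior is derived from a provisional EM seeded by
   the ventricles alone.
9. **CSF core.** 2-means (deterministic 25th/75th-percentile
   initialization) inside the step-8 cavity; the lower-median cluster is
   CSF.  If the two cluster medians differ by < 0.1 the cavity is
   unimodal — there is no damaged-tissue mode and the split would only
   cut noise in half — so the whole cavity is kept.  Ties break to the
   lower mean, then to the cluster containing the minimum.
10. **Subtraction image** `pre − post`, masked to the pre-operative
    brain: matched classes cancel; pre-operative tissue over
    post-operative CSF leaves a positive residue.
11. **Expansion.** A second two-class EM on the subtraction image: the
    CSF core keeps a fixed cavity membership, lobe voxels beyond a
    4-voxel band around it keep a fixed no-difference membership, and the
    band in between is free.  Mixing proportions are held at 1/2: the
    no-difference class outnumbers the cavity a hundredfold and free
    proportions let it absorb genuine signal (e.g. the diff ≈ 0.4 of
    grey matter sagged over white matter).  The band bounds any single
    expansion so distant misalignment residue cannot join the mask.
    Largest 26-connected component within the lobe.
12. **Spur removal.** Erode by a radius-1 Chebyshev ball (the 26-
    neighbourhood: a 1-voxel bridge erodes even when its face-neighbours
    are all masked), keep the largest component, then up to 3 rounds of
    26-connected dilation constrained inside the original mask; newly
    reached 26-clusters smaller than max(10, 1 % of the mask) are
    removed and barred from later rounds.  If erosion would empty the
    mask (small lesionectomies) the step is skipped with a warning.
13. **Directional boundary dilation.** Each mask-boundary voxel with CSF
    within 3 voxels (Chebyshev; Euclidean by flag) adds the discrete
    segment to its *nearest* CSF voxel (ties: smaller Euclidean
    distance, then lexicographic voxel order).  The CSF set is the
    step-9 cavity CSF united with pre-operative low-intensity voxels
    (< 0.2 rescaled) in the brain, minus the mask itself — growth is
    possible only toward CSF, never into intact tissue.
14. **Finalize.** 6-connected closing, interior hole fill (6-connected
    background flood from the border), multiplication by the resected
    lobe ∩ brain, largest component (the mask is one object by
    contract), and resampling to the original pre-operative grid.

Connectivity conventions: 26 for objects/clusters, 6 for hole-filling
background.  An empty result at any stage raises
`CavityNotFoundError` with a machine-readable code; the pipeline never
writes a silent empty mask.

## Evaluation statistics

`compare_masks` reads the voxel confusion matrix; `overlap` is the
Jaccard index TP/(TP+FP+FN), which satisfies J = DSC/(2−DSC) exactly
(checked to 1e-12 in tests); a sensitivity reading is available via
`overlap_def="sensitivity"`.  Both-empty comparisons score DSC 1 with a
warning; one-empty score 0.  The DSC rubric assigns boundary values to
the upper bin (0.6 → good, 0.7 → high, 0.8 → excellent).  Cohort
quartiles use linear interpolation.  The paired Wilcoxon signed-rank
test excludes zero differences, midranks ties, and uses the exact null
distribution of W⁺ for n ≤ 25 via generating-function convolution over
the doubled midranks (identical to enumerating all 2ⁿ sign patterns,
which serves as the independent test oracle); larger n use the normal
approximation with tie correction and continuity correction.

## Expected behaviour and limitations

On the fixture battery the pipeline recovers the ground truth with DSC
≈ 0.97 (aligned/noiseless), ≈ 0.85 (sagging + 4 mm/3° misalignment +
bias + noise) and ≈ 0.8 (small lesionectomy), with near-zero miss rate
in the easy case and a characteristic asymmetry under sagging: misses
concentrate in the sagged rim (where the post image genuinely shows
tissue) while false positives stay low.  Run times are well under a
minute per 96³ case on one CPU.

Known limitations: the sagged rim not adjacent to CSF is unrecoverable
from intensities alone (it is recovered only where the boundary dilation
can bridge to CSF); the deformable stage trades registration sharpness
for cavity preservation and is not diffeomorphic or inverse-consistent;
brain extraction and regional segmentation are not performed — the
pipeline requires an external label volume per image; and phantom
results bound what the algorithms can do under idealized geometry, not
what they will do on clinical data.
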