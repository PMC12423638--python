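"""Mask-agreement metrics, the DSC quality rubric, cohort summaries and
paired Wilcoxon pipeline comparisons.

Voxelwise agreement between a manual and an automated binary mask is read
as a confusion matrix: voxels in both masks are true positives, voxels
only in the manual mask false negatives, voxels only in the automated mask
false positives.  From the counts we derive

* ``dsc`` = 2 TP / (2 TP + FP + FN), the Dice similarity coefficient;
* ``overlap`` = TP / (TP + FP + FN), the Jaccard index — related to Dice
  by J = DSC / (2 - DSC);
* ``miss_rate`` = FN / (TP + FN), manual-mask voxels the automation missed;
* ``fdr`` = FP / (TP + FP), automated-mask voxels outside the manual mask.

The Jaccard reading of "overlap" is adopted because it satisfies
J = DSC/(2-DSC) exactly (e.g. DSC 0.86 <-> overlap 0.754, DSC 0.71 <->
0.551); a sensitivity reading is available via ``overlap_def``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import BinaryMask

__all__ = [
    "MaskComparison",
    "CohortSummary",
    "compare_masks",
    "classify_dsc",
    "summarize_cohort",
    "wilcoxon_paired",
    "DSC_CATEGORIES",
]

DSC_CATEGORIES = ("poor", "good", "high", "excellent")
_DSC_EDGES = (0.6, 0.7, 0.8)


@dataclass(frozen=True)
class MaskComparison:
    """Confusion-matrix counts and the derived agreement fractions."""

    tp: int
    fp: int
    fn: int
    tn: int
    dsc: float
    overlap: float
    miss_rate: float
    fdr: float

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("tp", "fp", "fn", "tn", "dsc", "overlap",
                          "miss_rate", "fdr")}


def compare_masks(manual: BinaryMask, auto: BinaryMask,
                  overlap_def: str = "jaccard") -> MaskComparison:
    """Confusion-matrix comparison of a manual and an automated mask.

    Degenerate cases: both masks empty counts as perfect (vacuous)
    agreement with a warning; exactly one empty mask scores dsc = 0.
    """
    manual.require_same_grid(auto, "masks")
    m, a = manual.data, auto.data
    tp = int(np.count_nonzero(m & a))
    fp = int(np.count_nonzero(~m & a))
    fn = int(np.count_nonzero(m & ~a))
    tn = int(m.size) - tp - fp - fn

    if tp + fp + fn == 0:
        warnings.warn("both masks are empty; reporting vacuous perfect "
                      "agreement", stacklevel=2)
        return MaskComparison(tp, fp, fn, tn, 1.0, 1.0, 0.0, 0.0)

    dsc = 2.0 * tp / (2.0 * tp + fp + fn)
    if overlap_def == "jaccard":
        overlap = tp / (tp + fp + fn)
    elif overlap_def == "sensitivity":
        overlap = tp / (tp + fn) if tp + fn else 0.0
    else:
        raise ValueError("overlap_def must be 'jaccard' or 'sensitivity'")
    miss_rate = fn / (tp + fn) if tp + fn else 0.0
    fdr = fp / (tp + fp) if tp + fp else 1.0
    return MaskComparison(tp, fp, fn, tn, dsc, overlap, miss_rate, fdr)


def classify_dsc(dsc: float) -> str:
    """Quality rubric: [0, 0.6) poor, [0.6, 0.7) good, [0.7, 0.8) high,
    [0.8, 1] excellent.  Boundaries belong to the upper bin."""
    if not 0.0 <= dsc <= 1.0:
        raise ValueError(f"DSC must lie in [0, 1], got {dsc}")
    for edge, cat in zip(_DSC_EDGES, DSC_CATEGORIES[:-1]):
        if dsc < edge:
            return cat
    return DSC_CATEGORIES[-1]


@dataclass
class CohortSummary:
    """Per-case metric table with median/IQR and DSC-category counts."""

    table: pd.DataFrame           # one row per (pipeline, case)
    medians: pd.DataFrame         # pipeline x metric
    iqrs: pd.DataFrame            # pipeline x metric
    category_counts: pd.DataFrame  # pipeline x category
    threshold_counts: pd.DataFrame  # pipeline x {n_high (>=0.7), n_poor (<0.6)}


_METRICS = ("dsc", "overlap", "miss_rate", "fdr")


def summarize_cohort(cases: list[MaskComparison] | dict[str, list[MaskComparison]],
                     pipeline_labels: list[str] | None = None) -> CohortSummary:
    """Median, IQR (linear-interpolation quartiles), DSC category and
    threshold counts per pipeline."""
    if isinstance(cases, dict):
        groups = cases
    else:
        label = (pipeline_labels[0] if pipeline_labels else "pipeline")
        groups = {label: list(cases)}
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("summarize_cohort needs at least one case per pipeline")

    rows = []
    for name, comps in groups.items():
        for i, c in enumerate(comps):
            rows.append({"pipeline": name, "case": i, **c.as_dict(),
                         "category": classify_dsc(c.dsc)})
    table = pd.DataFrame(rows)

    med = table.groupby("pipeline")[list(_METRICS)].median()
    q3 = table.groupby("pipeline")[list(_METRICS)].quantile(0.75,
                                                            interpolation="linear")
    q1 = table.groupby("pipeline")[list(_METRICS)].quantile(0.25,
                                                            interpolation="linear")
    iqr = q3 - q1
    cat = (table.groupby("pipeline")["category"]
           .value_counts().unstack(fill_value=0)
           .reindex(columns=list(DSC_CATEGORIES), fill_value=0))
    thr = table.groupby("pipeline")["dsc"].agg(
        n_high=lambda s: int((s >= 0.7).sum()),
        n_poor=lambda s: int((s < 0.6).sum()))
    return CohortSummary(table, med, iqr, cat, thr)


def _exact_sf(ranks2: np.ndarray, w2: int) -> float:
    """P(W+ >= w) under the signed-rank null, by generating-function
    convolution over the (doubled, integer) midranks.  Equivalent to
    enumerating all 2^n sign assignments."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in ranks2:
        nxt = counts.copy()
        nxt[r:] += counts[: total + 1 - r]
        counts = nxt
    counts /= counts.sum()
    return float(counts[w2:].sum())


def wilcoxon_paired(x, y, alternative: str = "greater",
                    exact_threshold: int = 25) -> float:
    """One-tailed Wilcoxon signed-rank p-value for paired metric vectors.

    Zero differences are excluded; tied absolute differences receive
    midranks.  For n <= ``exact_threshold`` retained pairs the exact null
    distribution of W+ is used; above, the normal approximation with tie
    correction.  ``alternative='greater'`` tests x > y (applied to DSC and
    overlap in pipeline comparisons); ``'less'`` tests x < y (miss rate,
    FDR).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 5:
        raise ValueError("need at least 5 pairs")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size

    if n <= exact_threshold:
        ranks2 = np.round(2 * ranks).astype(int)
        w2_plus = int(round(2 * w_plus))
        if alternative == "greater":
            return _exact_sf(ranks2, w2_plus)
        total = int(ranks2.sum())
        # P(W+ <= w) = P(W+' >= total - w) by sign symmetry
        return _exact_sf(ranks2, total - w2_plus)

    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = (n * (n + 1) * (2 * n + 1)
           - (tie_counts**3 - tie_counts).sum() / 2.0) / 24.0
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / np.sqrt(var)
        return float(stats.norm.sf(z))
    z = (w_plus - mean + 0.5) / np.sqrt(var)
    return float(stats.norm.cdf(z))
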