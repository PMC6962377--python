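"""Wound-healing (gap-closure) quantification.

Collective migration is read out as wound closure,

    WC = (Area_initial - Area_final) / Area_initial,

from the cell-free area segmented in matched image pairs, and as the
differential wound closure Delta WC = mean(WC_exp - WC_ctrl) over same-day
matched replicate pairs, reported in percentage points with a one-sided
paired t-test at a Bonferroni-adjusted alpha (0.05 / 5 comparisons = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage.filters import threshold_minimum, threshold_otsu
from skimage.morphology import closing, disk

__all__ = [
    "WoundAreas",
    "ClosureResult",
    "DifferentialClosure",
    "SegmentationError",
    "BONFERRONI_ALPHA",
    "segment_cell_free_area",
    "wound_closure",
    "differential_closure",
    "pair_by_replicate",
    "fold_increase",
]

#: 0.05 / 5 pressure-vs-control comparisons.
BONFERRONI_ALPHA = 0.01


class SegmentationError(ValueError):
    """Image cannot be segmented into cell lawn vs cell-free area."""


@dataclass(frozen=True)
class WoundAreas:
    """Initial/final cell-free areas of one replicate (same units)."""

    area_initial: float
    area_final: float
    replicate_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if self.area_initial <= 0:
            raise ValueError("area_initial must be positive")
        if self.area_final < 0:
            raise ValueError("area_final must be non-negative")


@dataclass(frozen=True)
class ClosureResult:
    wc: float
    replicate_id: str = ""
    condition: str = ""


@dataclass(frozen=True)
class DifferentialClosure:
    delta_wc_mean: float  # percentage points
    delta_wc_sem: float  # percentage points
    n_pairs: int
    p_value: float
    significant: bool
    alpha: float = BONFERRONI_ALPHA


def segment_cell_free_area(image: np.ndarray, pixel_size: float = 1.0) -> float:
    """Area (um^2) of the largest dark connected region of a wound image.

    Global histogram-valley threshold (falling back to Otsu when the
    histogram has no two modes), a binary closing (3-px disk) to despeckle,
    then the largest below-threshold connected component -- the cell-free
    gap.  The valley threshold is used because the gap can occupy a small
    minority of pixels, where Otsu's between-class variance criterion drifts
    into the cell-lawn intensity mode.  Deterministic for a fixed input.

    Raises
    ------
    SegmentationError
        When no threshold separates two intensity classes (uniform image)
        or no dark region remains after cleanup.
    """
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a nonempty 2-D array")
    if np.ptp(img) == 0:
        raise SegmentationError("uniform image: no threshold separates classes")
    # float view: keeps the threshold histogram at 256 bins regardless of
    # integer bit depth
    work = img.astype(float)
    try:
        thresh = threshold_minimum(work)
    except RuntimeError:  # unimodal histogram
        thresh = threshold_otsu(work)
    dark = work < thresh
    if not dark.any() or dark.all():
        raise SegmentationError("thresholding produced a single class")
    dark = closing(dark, disk(3))
    labels, n = ndimage.label(dark)
    if n == 0:
        raise SegmentationError("no dark region after morphological cleanup")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    return float(sizes.max()) * pixel_size**2


def wound_closure(areas: WoundAreas) -> ClosureResult:
    """Fractional closure (Area_i - Area_f) / Area_i."""
    wc = (areas.area_initial - areas.area_final) / areas.area_initial
    return ClosureResult(
        wc=wc, replicate_id=areas.replicate_id, condition=areas.condition
    )


def pair_by_replicate(
    exp: Sequence[ClosureResult], ctrl: Sequence[ClosureResult]
) -> list[tuple[float, float]]:
    """Match experimental and control closures by replicate_id.

    Pairing is explicit, never by row order, so a missing or duplicated
    replicate raises rather than silently misaligning the matched design.
    """
    ctrl_by_id: dict[str, float] = {}
    for c in ctrl:
        if c.replicate_id in ctrl_by_id:
            raise ValueError(f"duplicate control replicate {c.replicate_id!r}")
        ctrl_by_id[c.replicate_id] = c.wc
    pairs = []
    for e in exp:
        if e.replicate_id not in ctrl_by_id:
            raise ValueError(f"no control for replicate {e.replicate_id!r}")
        pairs.append((e.wc, ctrl_by_id[e.replicate_id]))
    return pairs


def differential_closure(
    pairs: Sequence[tuple[float, float]], alpha: float = BONFERRONI_ALPHA
) -> DifferentialClosure:
    """Delta WC over matched (wc_exp, wc_ctrl) pairs, in percentage points.

    The p-value is a one-sided paired t-test of closure exceeding control
    (the direction of the study's post-hoc test).  With zero variance in the
    differences the t statistic is undefined; the degenerate case is mapped
    to p = 0 for a uniformly positive difference and p = 1 otherwise.
    """
    if len(pairs) == 0:
        raise ValueError("need at least one matched pair")
    exp = np.asarray([p[0] for p in pairs], dtype=float)
    ctrl = np.asarray([p[1] for p in pairs], dtype=float)
    diff_pp = (exp - ctrl) * 100.0
    mean = float(diff_pp.mean())
    sem = float(stats.sem(diff_pp)) if len(pairs) > 1 else 0.0
    if np.ptp(diff_pp) == 0:
        p_value = 0.0 if mean > 0 else 1.0
    else:
        p_value = float(stats.ttest_rel(exp, ctrl, alternative="greater").pvalue)
    return DifferentialClosure(
        delta_wc_mean=mean,
        delta_wc_sem=sem,
        n_pairs=len(pairs),
        p_value=p_value,
        significant=bool(p_value < alpha),
        alpha=alpha,
    )


def fold_increase(wc_ctrl: float, delta_wc: float) -> float:
    """Fold change of closure implied by a control closure and Delta WC.

    ``wc_ctrl`` is a fraction, ``delta_wc`` percentage points; the result is
    (100 * wc_ctrl + delta_wc) / (100 * wc_ctrl).
    """
    if wc_ctrl <= 0:
        raise ValueError("control closure must be positive")
    base = wc_ctrl * 100.0
    return (base + delta_wc) / base
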