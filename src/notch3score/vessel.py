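"""Human-tissue scoring variant: NOTCH3 positivity within a vessel mask.

Human sections are double stained (NOTCH3 in brown, the endothelial
marker CD31 in blue) and the vessel region is delineated manually from
the CD31 signal; the mask is supplied to this module as a raster.
Within the vessel region the NOTCH3-positive area is the count of
pixels at or below an intensity threshold of 100.  The score is
reported as the percentage of the vessel area that is positive, which
makes it independent of how generously the ROI was drawn; the raw
positive area is always reported alongside.

Unlike the mouse variant, no unsharp mask and no particle size or
circularity filter are applied by default; both can be switched on for
sensitivity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .enhance import EnhanceParams, unsharp_mask
from .errors import DegenerateInputError, DimensionError
from .particles import ScoreParams, filter_particles, human_score_params, label_components, measure_particles, threshold_mask

__all__ = ["VesselScoreResult", "SubjectScore", "vessel_masked_score", "per_subject_score"]


@dataclass(frozen=True)
class VesselScoreResult:
    """Score of one image restricted to its vessel mask.

    ``score`` is ``100 * positive_area / vessel_area`` (percent);
    areas are in pixel^2.
    """

    vessel_area: int
    positive_area: int
    score: float


@dataclass(frozen=True)
class SubjectScore:
    """Per-subject aggregate over image scores: mean and sample SD."""

    n: int
    mean: float
    sd: float  # NaN when n == 1


def vessel_masked_score(
    img: np.ndarray,
    vessel: np.ndarray,
    params: ScoreParams | None = None,
    *,
    enhance: EnhanceParams | None = None,
    particle_filter: bool = False,
) -> VesselScoreResult:
    """Score an image within a CD31-defined vessel mask.

    Parameters
    ----------
    img : 8-bit grayscale image.
    vessel : boolean mask of the vessel region, same shape as ``img``.
    params : threshold settings; defaults to the human preset
        (threshold 100, dark-positive).
    enhance : optional unsharp-mask settings (off by default).
    particle_filter : if True, apply the size/circularity filter to the
        positive pixels before intersecting with the vessel mask.
    """
    arr = np.asarray(img)
    mask = np.asarray(vessel, dtype=bool)
    if arr.shape != mask.shape:
        raise DimensionError(
            f"vessel mask shape {mask.shape} does not match image shape {arr.shape}"
        )
    vessel_area = int(mask.sum())
    if vessel_area < 1:
        raise DegenerateInputError("vessel mask is empty; score is undefined")

    if params is None:
        params = human_score_params()
    working = unsharp_mask(arr, enhance) if enhance is not None else arr
    positive = threshold_mask(working, params)
    if particle_filter:
        labels, n = label_components(positive, params.connectivity)
        retained = filter_particles(measure_particles(labels, n), params)
        keep = np.isin(labels, [p.label for p in retained])
        positive = positive & keep
    positive_area = int((positive & mask).sum())
    return VesselScoreResult(
        vessel_area=vessel_area,
        positive_area=positive_area,
        score=100.0 * positive_area / vessel_area,
    )


def per_subject_score(scores: list[VesselScoreResult | float]) -> SubjectScore:
    """Aggregate per-image scores to a subject mean and sample SD.

    Accepts :class:`VesselScoreResult` objects or bare numbers.  SD is
    the n-1 sample standard deviation, NaN for a single image.
    """
    values = [s.score if isinstance(s, VesselScoreResult) else float(s) for s in scores]
    if len(values) == 0:
        raise DegenerateInputError("need at least one image score per subject")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else math.nan
    return SubjectScore(n=len(values), mean=mean, sd=sd)
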