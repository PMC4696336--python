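"""Multi-image, multi-subject scoring runs and analysis-ready tables.

The reference study design is 10 representative fields per mouse and 3
mice per strain-age cell; the per-mouse value fed into statistics is the
mean of the per-image scores (a sum is available for strict replication
attempts; the mean keeps subjects with unequal image counts comparable).
Field selection itself is taken as given: the design lists the images.

Outputs are tidy pandas tables -- one row per image and one per subject
-- from which every group summary and every statistical result can be
regenerated, with no hidden state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biostats import GroupSummary
from .enhance import EnhanceParams
from .errors import DegenerateInputError, ParameterError
from .particles import ScoreParams, notch3_score
from .raster import load_image, load_mask, to_gray8
from .vessel import vessel_masked_score

__all__ = [
    "DesignRow",
    "CohortDesign",
    "SubjectResult",
    "score_subject",
    "run_cohort",
    "group_summaries",
]


@dataclass(frozen=True)
class DesignRow:
    """One subject: id, group label, age and its image (and mask) paths."""

    subject: str
    group: str
    age_weeks: float
    images: tuple
    masks: tuple | None = None


@dataclass(frozen=True)
class CohortDesign:
    """A scoring run: subject rows plus the scoring variant.

    ``variant`` is ``"mouse"`` (whole-field particle score) or
    ``"human"`` (vessel-masked score; every image needs a mask).
    """

    rows: tuple
    variant: str = "mouse"

    def __post_init__(self):
        if self.variant not in ("mouse", "human"):
            raise ParameterError(f"unknown variant {self.variant!r}")
        paths = [p for r in self.rows for p in r.images]
        if len(paths) != len(set(paths)):
            raise ParameterError("image paths must be unique across the design")
        if self.variant == "human":
            for r in self.rows:
                if r.masks is None or len(r.masks) != len(r.images):
                    raise ParameterError(
                        f"subject {r.subject!r}: human variant needs one mask per image"
                    )


@dataclass(frozen=True)
class SubjectResult:
    """Per-subject outcome: per-image rows, aggregate, and failures."""

    subject: str
    per_image: pd.DataFrame
    aggregate: float
    n_scored: int
    failures: tuple = field(default=())


def _as_gray(img) -> np.ndarray:
    arr = load_image(img) if isinstance(img, (str,)) or hasattr(img, "__fspath__") else np.asarray(img)
    return to_gray8(arr) if arr.ndim == 3 else arr


def score_subject(
    images,
    *,
    subject: str = "subject",
    enhance: EnhanceParams | None = EnhanceParams(),
    params: ScoreParams = ScoreParams(),
    aggregate: str = "mean",
) -> SubjectResult:
    """Score a subject's images (mouse variant) and aggregate.

    ``images`` may be paths or in-memory arrays.  An unreadable path is
    recorded as a failure and the run continues; the aggregate is then
    over the scored images only.  ``aggregate`` is ``"mean"`` (default)
    or ``"sum"``.
    """
    if aggregate not in ("mean", "sum"):
        raise ParameterError(f"aggregate must be 'mean' or 'sum', got {aggregate!r}")
    if len(images) == 0:
        raise DegenerateInputError("need at least one image per subject")
    rows, failures = [], []
    for i, img in enumerate(images):
        name = str(img) if not isinstance(img, np.ndarray) else f"array[{i}]"
        try:
            res = notch3_score(_as_gray(img), enhance, params)
        except Exception as exc:  # unreadable/corrupt file: log and continue
            failures.append((name, f"{type(exc).__name__}: {exc}"))
            continue
        rows.append(
            {
                "subject": subject,
                "image": name,
                "score": res.score,
                "n_particles_total": res.n_particles_total,
                "n_particles_retained": res.n_particles_retained,
            }
        )
    per_image = pd.DataFrame(
        rows, columns=["subject", "image", "score", "n_particles_total", "n_particles_retained"]
    )
    if len(rows) == 0:
        agg = float("nan")
    elif aggregate == "mean":
        agg = float(per_image["score"].mean())
    else:
        agg = float(per_image["score"].sum())
    return SubjectResult(
        subject=subject,
        per_image=per_image,
        aggregate=agg,
        n_scored=len(rows),
        failures=tuple(failures),
    )


def run_cohort(
    design: CohortDesign,
    *,
    enhance: EnhanceParams | None = EnhanceParams(),
    params: ScoreParams | None = None,
    aggregate: str = "mean",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a whole cohort into tidy per-subject and group-summary tables.

    Returns ``(subjects, summaries)``: one row per subject (subject,
    group, age_weeks, n_images, score) and one per (group, age) cell
    (n, mean, sd).  Deterministic and invariant to design row order up
    to row order of the outputs.
    """
    if len(design.rows) == 0:
        raise DegenerateInputError("empty cohort design")
    sub_rows = []
    for row in design.rows:
        if design.variant == "mouse":
            if params is None:
                params = ScoreParams()
            res = score_subject(
                row.images, subject=row.subject, enhance=enhance,
                params=params, aggregate=aggregate,
            )
            score, n_img = res.aggregate, res.n_scored
        else:
            per_image = []
            for img_path, mask_path in zip(row.images, row.masks):
                v = vessel_masked_score(
                    _as_gray(img_path), load_mask(mask_path), params, enhance=enhance
                )
                per_image.append(v.score)
            score, n_img = float(np.mean(per_image)), len(per_image)
        sub_rows.append(
            {
                "subject": row.subject,
                "group": row.group,
                "age_weeks": row.age_weeks,
                "n_images": n_img,
                "score": score,
            }
        )
    subjects = pd.DataFrame(sub_rows)
    summaries = (
        subjects.groupby(["group", "age_weeks"], sort=True)["score"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1))
        .reset_index()
    )
    return subjects, summaries


def group_summaries(summaries: pd.DataFrame) -> list[GroupSummary]:
    """Convert a (group, age) summary table into GroupSummary records."""
    return [
        GroupSummary(
            label=f"{r.group}@{r.age_weeks:g}w",
            n=int(r.n),
            mean=float(r.mean),
            sd=float(r.sd) if r.n >= 2 else 0.0,
        )
        for r in summaries.itertuples()
    ]
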