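"""The parallelism statistic: orientation order of a skeletonized image.

Every unordered pair of 8-adjacent on-pixels in a skeleton is assigned one
of four orientations — 0, 45, 90 or 135 degrees with respect to the
horizon — from the vector joining the two pixels (rows increase downward,
so the up-right diagonal is 45 degrees).  With pair counts n0, n45, n90,
n135 the parallelism is the doubled-angle orientation order parameter

    P = sqrt((n0 - n90)^2 + (n45 - n135)^2) / (n0 + n45 + n90 + n135)

which is 1 when all pairs share a single orientation and 0 when the four
counts are equal (isotropy).  An ROI is scored by averaging P over its
hemorrhage and hemorrhage-sparse skeletons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import BandpassParams, SkeletonImage, extract_dual_skeletons

__all__ = [
    "OrientationPairCounts",
    "ParallelismScore",
    "UndefinedScoreError",
    "count_orientation_pairs",
    "parallelism_from_counts",
    "skeleton_parallelism",
    "roi_parallelism",
]


class UndefinedScoreError(ValueError):
    """Raised when a skeleton has no adjacent pixel pairs to orient.

    An empty skeleton is never silently scored 0: a 0 score asserts
    isotropy, which is a statement about existing line segments.
    """


@dataclass(frozen=True)
class OrientationPairCounts:
    """Counts of adjacent on-pixel pairs by orientation."""

    n0: int
    n45: int
    n90: int
    n135: int

    def __post_init__(self) -> None:
        for name in ("n0", "n45", "n90", "n135"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n0 + self.n45 + self.n90 + self.n135


@dataclass(frozen=True)
class ParallelismScore:
    """Per-region parallelism of an ROI and the averaged value."""

    p_hemorrhage: float
    p_sparse: float
    counts_hemorrhage: OrientationPairCounts | None = None
    counts_sparse: OrientationPairCounts | None = None

    @property
    def p_mean(self) -> float:
        return 0.5 * (self.p_hemorrhage + self.p_sparse)


def count_orientation_pairs(skel: np.ndarray | SkeletonImage) -> OrientationPairCounts:
    """Count unordered 8-adjacent on-pixel pairs by orientation.

    Each pair is counted exactly once.  Orientations follow the image
    convention of rows increasing downward while angles are reported with
    respect to the conventional horizon: the pair {(r, c), (r-1, c+1)}
    (up and to the right) lies at 45 degrees.
    """
    if isinstance(skel, SkeletonImage):
        skel = skel.pixels
    s = np.asarray(skel, dtype=bool)
    if s.ndim != 2:
        raise ValueError("skeleton must be a 2-D binary image")
    n0 = int(np.count_nonzero(s[:, :-1] & s[:, 1:]))
    n90 = int(np.count_nonzero(s[:-1, :] & s[1:, :]))
    # (r, c) paired with (r-1, c+1): up-right diagonal.
    n45 = int(np.count_nonzero(s[1:, :-1] & s[:-1, 1:]))
    # (r, c) paired with (r-1, c-1): up-left diagonal.
    n135 = int(np.count_nonzero(s[1:, 1:] & s[:-1, :-1]))
    return OrientationPairCounts(n0=n0, n45=n45, n90=n90, n135=n135)


def parallelism_from_counts(counts: OrientationPairCounts) -> float:
    """Orientation order parameter in [0, 1] from the four pair counts."""
    total = counts.total
    if total == 0:
        raise UndefinedScoreError(
            "no adjacent pixel pairs: parallelism is undefined on an empty skeleton"
        )
    return float(
        np.hypot(counts.n0 - counts.n90, counts.n45 - counts.n135) / total
    )


def skeleton_parallelism(skel: np.ndarray | SkeletonImage) -> float:
    """Parallelism of a single skeleton image."""
    return parallelism_from_counts(count_orientation_pairs(skel))


def roi_parallelism(
    roi: np.ndarray, params: BandpassParams | None = None
) -> ParallelismScore:
    """Score an 8-bit grayscale ROI end to end.

    Runs the band-pass / Otsu / skeletonization chain on both polarities
    and averages the parallelism of the hemorrhage and hemorrhage-sparse
    skeletons.  Raises UndefinedScoreError if either skeleton is empty.
    """
    hem, sparse = extract_dual_skeletons(roi, params)
    ch = count_orientation_pairs(hem)
    cs = count_orientation_pairs(sparse)
    return ParallelismScore(
        p_hemorrhage=parallelism_from_counts(ch),
        p_sparse=parallelism_from_counts(cs),
        counts_hemorrhage=ch,
        counts_sparse=cs,
    )
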