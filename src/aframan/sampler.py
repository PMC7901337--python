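"""k-means segmentation of the retained region and Raman point scheduling.

The retained (non-adipose, in-range) pixels are partitioned into K
spatially compact segments by k-means, where K follows from the
user-chosen segment size in pixels (K = round(area / target), at least
1).  Sampling points are then scheduled per segment: every segment gets
at least ``min_points`` points (3 by default) and the remaining
acquisition budget — about 15 minutes at 3.5 s per spectrum — is shared
among segments in proportion to their area.  Within a segment the first
point sits at the centroid (snapped into the segment) and further points
are placed by farthest-point sampling, spreading coverage evenly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans


@dataclass(frozen=True)
class SegmentMap:
    """Segment id per retained pixel (0 = not retained), ids contiguous 1..K."""

    segment_id: np.ndarray
    K: int
    target_segment_px: int
    seed: int
    meta: dict = field(default_factory=dict)

    def pixels_of(self, sid: int) -> np.ndarray:
        """(n, 2) array of (row, col) pixel coordinates of one segment."""
        return np.argwhere(self.segment_id == sid)

    def areas(self) -> np.ndarray:
        return np.bincount(self.segment_id.ravel(), minlength=self.K + 1)[1:]


@dataclass(frozen=True)
class SamplingPlan:
    """Scheduled Raman points under the acquisition-time budget.

    ``allocated_counts`` is what the scheduler assigned per segment
    (always >= ``min_points_per_segment``); ``points`` holds the placed
    points, which can be fewer only for degenerate segments with fewer
    pixels than allocated points (noted in ``degenerate_segments``).
    """

    points: tuple[tuple[int, int, int], ...]
    allocated_counts: dict[int, int]
    t_acq_s: float
    budget_s: float
    min_points_per_segment: int
    budget_exceeded: bool = False
    overrun_s: float = 0.0
    degenerate_segments: tuple[int, ...] = ()
    seed: int = 0

    @property
    def total_time_s(self) -> float:
        return len(self.points) * self.t_acq_s

    def placed_counts(self) -> dict[int, int]:
        out: dict[int, int] = {sid: 0 for sid in self.allocated_counts}
        for _, _, sid in self.points:
            out[sid] += 1
        return out


def segment(
    retained_mask: np.ndarray,
    target_segment_px: int,
    seed: int = 0,
    ratio: np.ndarray | None = None,
    features: str = "spatial",
    ratio_weight: float = 0.1,
) -> SegmentMap:
    """Partition the retained pixels into K ~ area/target segments.

    k-means (k-means++ initialisation, fixed seed) runs on the pixel
    coordinates; with ``features='spatial+ratio'`` the ratio value is
    appended as a third feature scaled to ``ratio_weight`` of the spatial
    spread, keeping segments spatially dominant.  Segment ids are
    relabelled 1..K in order of each segment's lowest pixel index, making
    the labelling canonical.
    """
    retained_mask = np.asarray(retained_mask, bool)
    coords = np.argwhere(retained_mask)
    if coords.shape[0] == 0:
        raise ValueError("nothing to sample: retained region is empty")
    if target_segment_px < 1:
        raise ValueError("target_segment_px must be >= 1")
    if features not in ("spatial", "spatial+ratio"):
        raise ValueError(f"unknown feature space {features!r}")
    K = max(1, round(coords.shape[0] / target_segment_px))
    K = min(K, coords.shape[0])
    X = coords.astype(float)
    if features == "spatial+ratio":
        if ratio is None:
            raise ValueError("ratio image required for spatial+ratio features")
        vals = ratio[retained_mask].astype(float)
        spread = X.std(axis=0).mean()
        vstd = vals.std()
        scale = ratio_weight * spread / vstd if vstd > 0 else 0.0
        X = np.column_stack([X, vals * scale])
    km = KMeans(n_clusters=K, init="k-means++", n_init=1, random_state=seed)
    assign = km.fit_predict(X)
    # canonical relabelling by lowest flat pixel index per cluster
    flat = coords[:, 0] * retained_mask.shape[1] + coords[:, 1]
    first = np.full(K, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(first, assign, flat)
    order = np.argsort(first, kind="stable")
    remap = np.empty(K, dtype=int)
    remap[order] = np.arange(1, K + 1)
    seg = np.zeros(retained_mask.shape, dtype=np.int32)
    seg[retained_mask] = remap[assign]
    within_var = float(
        np.mean(
            [
                np.var(coords[assign == k].astype(float), axis=0).sum()
                for k in range(K)
            ]
        )
    )
    return SegmentMap(
        segment_id=seg,
        K=K,
        target_segment_px=int(target_segment_px),
        seed=seed,
        meta={"features": features, "mean_within_segment_variance_px2": within_var},
    )


def _largest_remainder(extra: int, areas: np.ndarray) -> np.ndarray:
    """Apportion ``extra`` points proportionally to areas (largest remainder)."""
    if extra <= 0:
        return np.zeros(areas.size, dtype=int)
    quota = extra * areas / areas.sum()
    base = np.floor(quota).astype(int)
    rem = extra - base.sum()
    if rem > 0:
        # ties broken by segment id (stable sort of descending remainders)
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def _farthest_points(pixels: np.ndarray, n: int) -> np.ndarray:
    """Centroid-seeded farthest-point subset of pixel coordinates.

    Ties are broken by lowest pixel index; stops early once every pixel
    is used (degenerate segments).
    """
    centroid = pixels.mean(axis=0)
    d0 = np.linalg.norm(pixels - centroid, axis=1)
    chosen = [int(np.argmin(d0))]
    dist = cdist(pixels, pixels[chosen]).ravel()
    while len(chosen) < n:
        far = int(np.argmax(dist))
        if dist[far] <= 0:
            break  # all remaining pixels coincide with chosen ones
        chosen.append(far)
        dist = np.minimum(dist, cdist(pixels, pixels[[far]]).ravel())
    return pixels[chosen]


def plan_sampling(
    seg: SegmentMap,
    min_points: int = 3,
    t_acq_s: float = 3.5,
    budget_s: float = 900.0,
    seed: int = 0,
) -> SamplingPlan:
    """Allocate and place Raman sampling points under the time budget.

    Every segment receives at least ``min_points`` points — the floor is
    never traded away; if K * min_points alone exceeds the budget, the
    plan is produced anyway with ``budget_exceeded`` set and the overrun
    reported.  Budget headroom is apportioned by segment area (largest
    remainder), and points are placed by centroid + farthest-point
    sampling, so the layout is deterministic.
    """
    if min_points < 1:
        raise ValueError("min_points must be >= 1")
    areas = seg.areas()
    K = seg.K
    capacity = math.floor(budget_s / t_acq_s)
    base_total = K * min_points
    budget_exceeded = base_total > capacity
    overrun = max(0.0, base_total * t_acq_s - budget_s)
    counts = np.full(K, min_points, dtype=int)
    if not budget_exceeded:
        counts += _largest_remainder(capacity - base_total, areas)
        # extra points beyond a segment's pixel count would only coincide
        counts = np.maximum(np.minimum(counts, areas), min_points)
    allocated = {sid: int(c) for sid, c in zip(range(1, K + 1), counts)}
    points: list[tuple[int, int, int]] = []
    degenerate: list[int] = []
    for sid in range(1, K + 1):
        pix = seg.pixels_of(sid)
        placed = _farthest_points(pix, allocated[sid])
        if placed.shape[0] < allocated[sid]:
            degenerate.append(sid)
        points.extend((int(r), int(c), sid) for r, c in placed)
    return SamplingPlan(
        points=tuple(points),
        allocated_counts=allocated,
        t_acq_s=float(t_acq_s),
        budget_s=float(budget_s),
        min_points_per_segment=int(min_points),
        budget_exceeded=budget_exceeded,
        overrun_s=float(overrun),
        degenerate_segments=tuple(degenerate),
        seed=seed,
    )
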