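"""Microcolony detection, segmentation and tracking.

Bright-field yeast microcolonies appear as juxtaposed bright and dark
pixels on a homogeneous background.  Detection thresholds each frame at
mean ± k·s.d. (k = 2.2 by default), optionally adding Sobel edge pixels;
segmentation groups detected pixels into connected components after
morphological cleanup; tracking links components frame-to-frame by mutual
nearest centroids, discards frames with anomalous component counts, and
truncates colonies at the frame where they first touch a neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from skimage import filters, measure, morphology

__all__ = [
    "PixelThresholds",
    "FrameComponents",
    "ColonyTrack",
    "detect_cell_pixels",
    "segment_microcolonies",
    "track_colonies",
    "apply_filters",
    "track_stack",
    "tracks_to_frame",
]


@dataclass(frozen=True)
class PixelThresholds:
    """Pixel classification thresholds.

    A pixel is cell-like if its intensity lies beyond mean ± ``k_sd``
    standard deviations of the whole frame.  With ``sobel_enabled`` the
    Sobel gradient magnitude is thresholded too (at ``sobel_threshold``,
    or the frame's 95th gradient percentile when unset) and edge pixels
    are added to the mask.
    """

    k_sd: float = 2.2
    sobel_enabled: bool = False
    sobel_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.k_sd <= 0:
            raise ValueError("k_sd must be > 0")


@dataclass
class FrameComponents:
    """Labeled microcolony candidates in one frame."""

    frame_index: int
    time_h: float
    labels: np.ndarray = field(repr=False)  # labeled image
    centroids: np.ndarray = field(repr=False)  # (n, 2) row/col
    areas: np.ndarray = field(repr=False)  # (n,) pixel counts

    @property
    def n_components(self) -> int:
        return len(self.areas)


@dataclass
class ColonyTrack:
    """One microcolony's trajectory: per-frame centroid and pixel area.

    ``touched_at`` is the frame index where the colony first merged with a
    neighbour; the track is truncated there.  ``discarded_frames`` lists
    frames dropped by the acquisition-anomaly rule (they are absent from
    ``frames``).
    """

    colony_id: int
    frames: list[int] = field(default_factory=list)
    times: list[float] = field(default_factory=list)
    areas: list[float] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)
    touched_at: int | None = None
    discarded_frames: list[int] = field(default_factory=list)
    passed_size_filter: bool | None = None
    passed_growth_filter: bool | None = None

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def initial_area(self) -> float:
        return self.areas[0]

    @property
    def final_area(self) -> float:
        return self.areas[-1]


def detect_cell_pixels(frame: np.ndarray,
                       thresholds: PixelThresholds = PixelThresholds()) -> np.ndarray:
    """Binary mask of cell-like pixels: bright ∪ dark (± k·s.d. of the
    whole-frame mean), optionally ∪ Sobel edges.  A zero-variance frame
    yields an empty mask."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("frame is empty")
    mean, sd = frame.mean(), frame.std()
    if sd == 0:
        return np.zeros(frame.shape, dtype=bool)
    mask = (frame > mean + thresholds.k_sd * sd) | (frame < mean - thresholds.k_sd * sd)
    if thresholds.sobel_enabled:
        grad = filters.sobel(frame)
        cut = (thresholds.sobel_threshold if thresholds.sobel_threshold is not None
               else np.percentile(grad, 95.0))
        mask |= grad > cut
    return mask


def _drop_small_components(mask: np.ndarray, min_size: int) -> np.ndarray:
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def segment_microcolonies(
    mask: np.ndarray,
    closing_radius: int = 3,
    min_size: int = 30,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Group detected pixels into microcolonies.

    Detected pixels are first 8-connected-labeled and components below
    ``min_size`` pixels dropped — isolated threshold-noise pixels form
    only tiny clusters, while a colony's bright/dark speckle is one large
    diagonally-connected component.  A binary closing (radius
    ``closing_radius``) then fills the speckle holes into a solid object
    without eroding the colony boundary, and components are relabeled.

    Returns the labeled image and a frame (label, centroid_row,
    centroid_col, area).  An empty mask gives zero components.
    """
    mask = np.asarray(mask, dtype=bool)
    if min_size > 1:
        mask = _drop_small_components(mask, min_size)
    if closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(closing_radius))
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels)
    table = pd.DataFrame(
        [{"label": p.label,
          "centroid_row": p.centroid[0], "centroid_col": p.centroid[1],
          "area": p.area} for p in props],
        columns=["label", "centroid_row", "centroid_col", "area"],
    )
    return labels, table


def _anomalous_frames(counts: np.ndarray, max_deviation: float = 0.3) -> set[int]:
    """Frames whose component count jumps >30% from the median of up to two
    neighbouring frames on each side (acquisition/processing failures)."""
    bad: set[int] = set()
    n = len(counts)
    for i in range(n):
        # nearest frames first; at least 3 so a single anomalous neighbour
        # cannot swing the median against an edge frame
        order = sorted((j for j in range(n) if j != i), key=lambda j: abs(j - i))
        neighbors = [counts[j] for j in order[:max(3, min(4, n - 1))]]
        med = float(np.median(neighbors))
        if med == 0:
            if counts[i] > 0:
                bad.add(i)
            continue
        if abs(counts[i] - med) / med > max_deviation:
            bad.add(i)
    return bad


def track_colonies(
    frames: list[FrameComponents],
    max_count_deviation: float = 0.3,
    max_link_distance: float | None = None,
) -> list[ColonyTrack]:
    """Link per-frame components into colony tracks.

    Frames whose component count deviates from the median of adjacent
    frames by more than ``max_count_deviation`` are discarded outright
    (tracks bridge across them).  Linking is mutual-nearest-centroid
    between consecutive retained frames; distance ties break toward the
    lowest colony id.  When two or more tracks map onto one component the
    colonies have merged: each is flagged ``touched_at`` that frame and
    truncated there.
    """
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to track")
    counts = np.array([f.n_components for f in frames])
    discarded = sorted(_anomalous_frames(counts, max_count_deviation))
    kept = [f for f in frames if f.frame_index not in
            {frames[i].frame_index for i in discarded}]
    if len(kept) < 2:
        raise ValueError(
            "fewer than 2 frames survive the centroid-count anomaly rule "
            f"(discarded frame indices: {discarded})")

    discarded_idx = [frames[i].frame_index for i in discarded]
    tracks: list[ColonyTrack] = []
    active: dict[int, ColonyTrack] = {}  # colony_id -> track
    next_id = 0

    first = kept[0]
    for i in range(first.n_components):
        tr = ColonyTrack(colony_id=next_id, discarded_frames=list(discarded_idx))
        tr.frames.append(first.frame_index)
        tr.times.append(first.time_h)
        tr.areas.append(float(first.areas[i]))
        tr.centroids.append(tuple(first.centroids[i]))
        tracks.append(tr)
        active[next_id] = tr
        next_id += 1

    for nxt in kept[1:]:
        if not active:
            break
        ids = sorted(active)  # lowest colony_id first -> deterministic ties
        heads = np.array([active[i].centroids[-1] for i in ids], dtype=float)
        if nxt.n_components == 0:
            active.clear()
            continue
        dist = cdist(heads, nxt.centroids)
        nearest_comp = np.argmin(dist, axis=1)
        nearest_head = np.argmin(dist, axis=0)
        # merge detection: >=2 heads share a nearest component
        claim: dict[int, list[int]] = {}
        for hi, ci in enumerate(nearest_comp):
            claim.setdefault(int(ci), []).append(hi)
        merged_heads = {hi for his in claim.values() if len(his) > 1 for hi in his}
        matched_comps: set[int] = set()
        for hi, cid in enumerate(ids):
            ci = int(nearest_comp[hi])
            if hi in merged_heads:
                active[cid].touched_at = nxt.frame_index
                del active[cid]
                continue
            mutual = int(nearest_head[ci]) == hi
            ok_dist = (max_link_distance is None
                       or dist[hi, ci] <= max_link_distance)
            if mutual and ok_dist:
                tr = active[cid]
                tr.frames.append(nxt.frame_index)
                tr.times.append(nxt.time_h)
                tr.areas.append(float(nxt.areas[ci]))
                tr.centroids.append(tuple(nxt.centroids[ci]))
                matched_comps.add(ci)
            else:
                del active[cid]  # colony lost
        for ci in range(nxt.n_components):
            if ci in matched_comps:
                continue
            if len(claim.get(ci, [])) > 1:
                continue  # merge target: do not seed a new track from a blob
            tr = ColonyTrack(colony_id=next_id, discarded_frames=list(discarded_idx))
            tr.frames.append(nxt.frame_index)
            tr.times.append(nxt.time_h)
            tr.areas.append(float(nxt.areas[ci]))
            tr.centroids.append(tuple(nxt.centroids[ci]))
            tracks.append(tr)
            active[next_id] = tr
            next_id += 1
    return tracks


def apply_filters(
    tracks: list[ColonyTrack],
    min_initial_area: float = 50.0,
    min_growth_fold: float = 2.0,
) -> list[ColonyTrack]:
    """Debris filters: keep tracks strictly bigger than ``min_initial_area``
    pixels at the start AND growing strictly more than ``min_growth_fold``
    by the end.  Flags are set on every input track; the retained subset is
    returned."""
    kept = []
    for tr in tracks:
        if tr.n_frames == 0:
            tr.passed_size_filter = tr.passed_growth_filter = False
            continue
        tr.passed_size_filter = tr.initial_area > min_initial_area
        tr.passed_growth_filter = tr.final_area / tr.initial_area > min_growth_fold
        if tr.passed_size_filter and tr.passed_growth_filter:
            kept.append(tr)
    return kept


def track_stack(
    stack: np.ndarray,
    frame_interval_h: float = 1.5,
    thresholds: PixelThresholds = PixelThresholds(),
    closing_radius: int = 3,
    min_size: int = 5,
    max_count_deviation: float = 0.3,
    min_initial_area: float = 50.0,
    min_growth_fold: float = 2.0,
) -> list[ColonyTrack]:
    """Full imaging stage on an in-memory stack: detect, segment, track,
    filter.  Returns the retained colony tracks."""
    frames = []
    for f in range(stack.shape[0]):
        mask = detect_cell_pixels(stack[f], thresholds)
        _, table = segment_microcolonies(mask, closing_radius=closing_radius,
                                         min_size=min_size)
        frames.append(FrameComponents(
            frame_index=f, time_h=f * frame_interval_h,
            labels=np.empty(0),
            centroids=table[["centroid_row", "centroid_col"]].to_numpy(dtype=float),
            areas=table["area"].to_numpy(dtype=float),
        ))
    tracks = track_colonies(frames, max_count_deviation=max_count_deviation)
    return apply_filters(tracks, min_initial_area=min_initial_area,
                         min_growth_fold=min_growth_fold)


def tracks_to_frame(tracks: list[ColonyTrack]) -> pd.DataFrame:
    """Long-format table of tracks (one row per colony per frame)."""
    rows = []
    for tr in tracks:
        for f, t, a, (cr, cc) in zip(tr.frames, tr.times, tr.areas, tr.centroids):
            rows.append({"colony_id": tr.colony_id, "frame": f, "time_h": t,
                         "area_px": a, "centroid_row": cr, "centroid_col": cc,
                         "touched_at": tr.touched_at,
                         "passed_size_filter": tr.passed_size_filter,
                         "passed_growth_filter": tr.passed_growth_filter})
    return pd.DataFrame(rows, columns=["colony_id", "frame", "time_h", "area_px",
                                       "centroid_row", "centroid_col", "touched_at",
                                       "passed_size_filter", "passed_growth_filter"])
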