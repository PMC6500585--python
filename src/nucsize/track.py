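"""Per-slice blob detection linked along z: the tracking approach to nuclear size.

Each optical section is scanned with a Laplacian-of-Gaussian detector tuned to
a nominal blob diameter (default 10 μm). Detections whose x-y centroids
coincide across adjacent slices (within a link distance) are chained into one
track per nucleus. A track yields

* cross-section area  = π·(d_MAX/2)²  from its largest per-slice diameter, and
* volume              = Σᵢ π·(dᵢ/2)²·dz  (a Cavalieri slab sum),

the latter only for tracks spanning at least ``min_slices`` (default 3)
sections, which excludes nuclei clipped at the top or bottom of the stack.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from skimage.feature import blob_log
from skimage.filters import threshold_otsu

from .stack import CalibratedStack

__all__ = ["BlobDetection", "NuclearTrack", "detect_blobs", "filter_quality",
           "link_tracks", "track_area", "track_volume", "run_track_method"]

DEFAULT_DIAMETER_UM = 10.0
MIN_SLICES_FOR_VOLUME = 3


@dataclass(frozen=True)
class BlobDetection:
    """One LoG maximum in one optical section (physical units)."""

    slice_index: int
    centroid: tuple[float, float]  # (y, x) μm
    diameter: float  # μm
    quality: float  # brightness-weighted filter response

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")


@dataclass
class NuclearTrack:
    """A z-linked chain of detections for one nucleus."""

    track_id: int
    detections: list[BlobDetection]

    def __post_init__(self) -> None:
        self.detections = sorted(self.detections, key=lambda b: b.slice_index)
        idx = [b.slice_index for b in self.detections]
        if len(set(idx)) != len(idx):
            raise ValueError("a track may hold at most one detection per slice")

    @property
    def n_slices(self) -> int:
        return len(self.detections)

    @property
    def d_max(self) -> float:
        return max(b.diameter for b in self.detections)

    @property
    def cross_section_area(self) -> float:
        return track_area(self)

    def volume(self, dz: float = 1.5) -> float | None:
        return track_volume(self, dz=dz)


def _refine_diameter(img: np.ndarray, y_px: float, x_px: float, d_px: float,
                     pixel_size: float) -> float:
    """Per-detection size from the half-max support around the LoG maximum.

    The LoG scale gives one nominal size; actual per-section diameters vary,
    so the area above half the local peak within a window is converted back
    to an equivalent-circle diameter.
    """
    half_w = max(2, int(round(d_px)))  # window ~2× radius beyond center
    y0, y1 = int(round(y_px)) - half_w, int(round(y_px)) + half_w + 1
    x0, x1 = int(round(x_px)) - half_w, int(round(x_px)) + half_w + 1
    y0, x0 = max(0, y0), max(0, x0)
    y1, x1 = min(img.shape[0], y1), min(img.shape[1], x1)
    win = img[y0:y1, x0:x1]
    if win.size == 0:
        return d_px * pixel_size
    peak = win.max()
    floor = np.percentile(win, 5)  # local background
    if peak <= floor:
        return d_px * pixel_size
    above = win >= floor + 0.5 * (peak - floor)
    # keep only the connected region containing the detection
    lab, _ = ndimage.label(above)
    lid = lab[int(round(y_px)) - y0, int(round(x_px)) - x0]
    if lid == 0:
        return d_px * pixel_size
    area_px = int((lab == lid).sum())
    return 2.0 * math.sqrt(area_px / math.pi) * pixel_size


def detect_blobs(slice_image: np.ndarray, pixel_size: float,
                 estimated_diameter: float = DEFAULT_DIAMETER_UM,
                 slice_index: int = 0,
                 threshold_rel: float = 0.05) -> list[BlobDetection]:
    """LoG blob detection on one calibrated optical section.

    ``estimated_diameter`` (μm) sets the central detection scale; scales are
    scanned over roughly a 4× range around it so the per-blob best scale plus
    a half-max refinement yields the per-section diameter dᵢ. Quality is the
    image intensity at the detected centroid scaled by the normalized LoG
    response, so brighter nuclei score higher.
    """
    img = np.asarray(slice_image, dtype=np.float64)
    if img.max() <= img.min():
        return []
    norm = (img - img.min()) / (img.max() - img.min())
    nominal_sigma = (estimated_diameter / 2.0) / math.sqrt(2.0) / pixel_size
    blobs = blob_log(norm, min_sigma=max(1.0, nominal_sigma / 2.0),
                     max_sigma=nominal_sigma * 2.0, num_sigma=9,
                     threshold=threshold_rel, overlap=0.5)
    out: list[BlobDetection] = []
    for y_px, x_px, sigma in blobs:
        d_px = 2.0 * math.sqrt(2.0) * sigma
        diameter = _refine_diameter(img, y_px, x_px, d_px, pixel_size)
        response = -ndimage.gaussian_laplace(img, sigma=sigma)[int(y_px), int(x_px)] * sigma ** 2
        brightness = img[int(y_px), int(x_px)]
        out.append(BlobDetection(slice_index=slice_index,
                                 centroid=(y_px * pixel_size, x_px * pixel_size),
                                 diameter=max(diameter, pixel_size),
                                 quality=float(max(response, 0.0) * brightness)))
    return out


def filter_quality(blobs: list[BlobDetection], threshold: float) -> list[BlobDetection]:
    """Keep only detections with quality ≥ threshold (order preserved)."""
    return [b for b in blobs if b.quality >= threshold]


def otsu_quality_threshold(blobs: list[BlobDetection]) -> float:
    """Default quality cut: Otsu split of the per-stack quality distribution."""
    q = np.array([b.quality for b in blobs], dtype=float)
    if q.size < 2 or q.min() == q.max():
        return 0.0
    return float(threshold_otsu(q))


def link_tracks(blobs_by_slice: list[list[BlobDetection]],
                max_link_distance: float = 5.0,
                max_gap: int = 0) -> list[NuclearTrack]:
    """Chain detections with coincident x-y centroids across slices.

    Linking is a per-slice optimal assignment (Hungarian) on centroid
    distance, rejecting links beyond ``max_link_distance`` μm; a track may
    skip up to ``max_gap`` empty slices. Each detection joins at most one
    track; ties resolve to the minimal total distance, then lower slice
    index (the assignment is deterministic).
    """
    active: list[tuple[list[BlobDetection], int]] = []  # (detections, last slice)
    finished: list[list[BlobDetection]] = []
    slices = sorted({b.slice_index for lst in blobs_by_slice for b in lst})
    by_slice = {s: [] for s in slices}
    for lst in blobs_by_slice:
        for b in lst:
            by_slice[b.slice_index].append(b)

    for s in slices:
        dets = by_slice[s]
        # retire tracks whose gap budget is exhausted
        still_active = []
        for tr, last in active:
            if s - last > max_gap + 1:
                finished.append(tr)
            else:
                still_active.append((tr, last))
        active = still_active
        if not dets:
            continue
        if active:
            cost = np.full((len(active), len(dets)), 1e9)
            for i, (tr, _last) in enumerate(active):
                ty, tx = tr[-1].centroid
                for j, d in enumerate(dets):
                    dist = math.hypot(d.centroid[0] - ty, d.centroid[1] - tx)
                    if dist <= max_link_distance:
                        cost[i, j] = dist
            rows, cols = linear_sum_assignment(cost)
            claimed = set()
            for i, j in zip(rows, cols):
                if cost[i, j] < 1e9:
                    active[i][0].append(dets[j])
                    active[i] = (active[i][0], s)
                    claimed.add(j)
        else:
            claimed = set()
        for j, d in enumerate(dets):
            if j not in claimed:
                active.append(([d], s))
    finished.extend(tr for tr, _ in active)
    finished.sort(key=lambda tr: (tr[0].slice_index, tr[0].centroid))
    return [NuclearTrack(track_id=i, detections=tr) for i, tr in enumerate(finished)]


def track_area(track: NuclearTrack) -> float:
    """Equatorial cross-section area π·(d_MAX/2)² from the largest diameter."""
    if not track.detections:
        raise ValueError("track has no detections")
    return math.pi * (track.d_max / 2.0) ** 2


def track_volume(track: NuclearTrack, dz: float = 1.5) -> float | None:
    """Slab-sum (Cavalieri) volume Σᵢ π·(dᵢ/2)²·dz, or None for short tracks.

    Tracks spanning fewer than three optical sections are excluded: they are
    taken to be nuclei only partially captured at the stack boundaries.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    if len(track.detections) < MIN_SLICES_FOR_VOLUME:
        return None
    return sum(math.pi * (b.diameter / 2.0) ** 2 * dz for b in track.detections)


def run_track_method(stack: CalibratedStack,
                     estimated_diameter: float = DEFAULT_DIAMETER_UM,
                     quality_threshold: float | None = None,
                     max_link_distance: float = 5.0,
                     max_gap: int = 0,
                     min_slices: int = MIN_SLICES_FOR_VOLUME) -> pd.DataFrame:
    """Full pipeline: detect per slice → quality cut → link → measure.

    Returns one row per track: track_id, n_slices, centroid (μm), d_max_um,
    area_um2 and volume_um3 (NaN when the ≥ min_slices rule excludes it).
    ``quality_threshold=None`` applies the per-stack Otsu default.
    """
    if stack.dx != stack.dy:
        raise ValueError("lateral pixels must be square for blob detection")
    per_slice = [detect_blobs(stack.voxels[k], pixel_size=stack.dx,
                              estimated_diameter=estimated_diameter, slice_index=k)
                 for k in range(stack.n_slices)]
    all_blobs = [b for lst in per_slice for b in lst]
    thr = otsu_quality_threshold(all_blobs) if quality_threshold is None else quality_threshold
    per_slice = [filter_quality(lst, thr) for lst in per_slice]
    tracks = link_tracks(per_slice, max_link_distance=max_link_distance, max_gap=max_gap)
    rows = []
    for t in tracks:
        vol = None
        if t.n_slices >= min_slices:
            vol = sum(math.pi * (b.diameter / 2.0) ** 2 * stack.dz for b in t.detections)
        eq = max(t.detections, key=lambda b: b.diameter)
        rows.append({
            "track_id": t.track_id,
            "n_slices": t.n_slices,
            "centroid_y_um": eq.centroid[0],
            "centroid_x_um": eq.centroid[1],
            "slice_of_d_max": eq.slice_index,
            "d_max_um": t.d_max,
            "area_um2": track_area(t),
            "volume_um3": np.nan if vol is None else vol,
        })
    df = pd.DataFrame(rows, columns=["track_id", "n_slices", "centroid_y_um",
                                     "centroid_x_um", "slice_of_d_max", "d_max_um",
                                     "area_um2", "volume_um3"])
    df.attrs["quality_threshold"] = thr
    return df
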