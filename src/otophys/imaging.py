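"""Imaging-derived quantifications: GCaMP dF/F bundle responses and
orientation calls, per-neuromast directional magnitudes, synaptic-puncta
size filtering and pre/post pairing, afferent selectivity percentages, and
hair-cell density in measurement ROIs.

Coordinates are in um with the origin at the top-left and y increasing
downward; pixel areas use the half-open convention (a pixel belongs to its
minimum edges).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from shapely.geometry import Point, Polygon
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label, regionprops

__all__ = [
    "StimEpoch", "RoiTrace", "DffTrace", "BundleClassification",
    "PunctaImagePair", "SynapseCounts", "RoiCountSpec",
    "compute_dff", "classify_bundle_orientation", "summarize_neuromast_response",
    "count_synapses", "afferent_selectivity", "hc_density", "volume_rate",
]

#: minimum retained puncta areas, um^2 (presynaptic ribbon / postsynaptic density)
MIN_AREA_PRE = 0.025
MIN_AREA_POST = 0.04


def volume_rate(frame_rate: float, n_planes: int) -> float:
    """Volumetric acquisition rate (Hz) of a swept-field stack: one volume
    per ``n_planes`` frames (e.g. 5 planes at 50 Hz frames -> 10 Hz volumes)."""
    if n_planes < 1 or frame_rate <= 0:
        raise ValueError("need frame_rate > 0 and n_planes >= 1")
    return frame_rate / n_planes


@dataclass
class StimEpoch:
    """One fluid-jet stimulus epoch: direction tag, onset and duration in s."""

    direction: str  # AtoP | PtoA
    onset: float
    duration: float

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class RoiTrace:
    """Fluorescence of one hair-bundle ROI over a stimulus protocol."""

    fluorescence: np.ndarray  # a.u. per volume frame
    volume_rate: float  # Hz
    stim_epochs: list[StimEpoch]
    roi_id: int = 0
    neuromast_id: int = 0

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.volume_rate <= 0:
            raise ValueError("volume_rate must be positive")
        t_end = self.fluorescence.size / self.volume_rate
        for ep in self.stim_epochs:
            if not 0 <= ep.onset < ep.end <= t_end:
                raise ValueError(f"epoch {ep} outside the trace")

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.fluorescence.size) / self.volume_rate


@dataclass
class DffTrace:
    dff: np.ndarray  # unitless per frame
    f0: float  # a.u.
    baseline_window: float  # s
    volume_rate: float
    stim_epochs: list[StimEpoch] = field(default_factory=list)
    roi_id: int = 0
    neuromast_id: int = 0


@dataclass
class BundleClassification:
    orientation: str  # AtoP | PtoA | no_response
    peak_dff: dict[str, float]  # per direction
    roi_id: int = 0
    neuromast_id: int = 0


@dataclass
class PunctaImagePair:
    """Registered pre/post synaptic channels of one neuromast."""

    pre_channel: np.ndarray
    post_channel: np.ndarray
    pixel_size: float  # um/px
    hc_masks: np.ndarray | None = None  # labeled regions, same shape

    def __post_init__(self) -> None:
        if self.pre_channel.shape != self.post_channel.shape:
            raise ValueError("channels must share one shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class SynapseCounts:
    complete_per_hc: dict[int, int]
    unpaired_pre_total: int
    unpaired_post_total: int
    n_retained_pre: int
    n_retained_post: int

    @property
    def complete_total(self) -> int:
        return sum(self.complete_per_hc.values())


@dataclass
class RoiCountSpec:
    """Counting ROI: axis-aligned rectangle (origin + size) or polygon, in um."""

    origin: tuple[float, float] | None = None  # (x, y) of the min corner
    width: float | None = None
    height: float | None = None
    polygon: list[tuple[float, float]] | None = None
    marker: str = ""

    def __post_init__(self) -> None:
        if self.polygon is None and (self.width is None or self.height is None
                                     or self.origin is None):
            raise ValueError("give either origin+width+height or polygon")
        if self.width is not None and (self.width <= 0 or self.height <= 0):
            raise ValueError("ROI must have positive area")

    @property
    def area(self) -> float:
        if self.polygon is not None:
            return float(Polygon(self.polygon).area)
        return float(self.width * self.height)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boundary-inclusive on minimum edges for rectangles; polygon
        membership includes the boundary."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.polygon is not None:
            poly = Polygon(self.polygon)
            return np.array([poly.covers(Point(x, y)) for x, y in pts])
        x0, y0 = self.origin
        return ((pts[:, 0] >= x0) & (pts[:, 0] < x0 + self.width)
                & (pts[:, 1] >= y0) & (pts[:, 1] < y0 + self.height))


def compute_dff(trace: RoiTrace, baseline_window: float) -> DffTrace:
    """dF/F relative to the mean fluorescence over the pre-stimulus baseline.

    ``baseline_window`` (s) must end before the first stimulus epoch; F0 must
    be positive.
    """
    first_onset = min(ep.onset for ep in trace.stim_epochs) if trace.stim_epochs else np.inf
    if baseline_window > first_onset:
        raise ValueError("baseline window must precede the first stimulus epoch")
    n_base = max(int(round(baseline_window * trace.volume_rate)), 1)
    f0 = float(trace.fluorescence[:n_base].mean())
    if f0 <= 0:
        raise ValueError(f"non-positive baseline fluorescence F0={f0}")
    dff = (trace.fluorescence - f0) / f0
    return DffTrace(dff=dff, f0=f0, baseline_window=baseline_window,
                    volume_rate=trace.volume_rate, stim_epochs=trace.stim_epochs,
                    roi_id=trace.roi_id, neuromast_id=trace.neuromast_id)


def _epoch_peak(dff: DffTrace, epoch: StimEpoch) -> float:
    i0 = int(np.floor(epoch.onset * dff.volume_rate))
    i1 = max(int(np.ceil(epoch.end * dff.volume_rate)), i0 + 1)
    return float(np.max(dff.dff[i0:i1]))


def classify_bundle_orientation(dff: DffTrace, responder_k: float = 3.0) -> BundleClassification:
    """Orientation call from direction-specific dF/F responses.

    A direction responds if its within-epoch peak dF/F exceeds
    ``responder_k`` times the baseline SD; the orientation is the responding
    direction (the larger peak if both respond), else no_response.
    """
    directions = {ep.direction for ep in dff.stim_epochs}
    if not {"AtoP", "PtoA"} <= directions:
        raise ValueError("both AtoP and PtoA stimulus epochs are required")
    n_base = max(int(round(dff.baseline_window * dff.volume_rate)), 2)
    base_sd = float(dff.dff[:n_base].std(ddof=1))
    floor = responder_k * max(base_sd, 1e-12)
    peaks = {d: max(_epoch_peak(dff, ep) for ep in dff.stim_epochs if ep.direction == d)
             for d in ("AtoP", "PtoA")}
    responding = [d for d, p in peaks.items() if p > floor]
    if not responding:
        orientation = "no_response"
    else:
        orientation = max(responding, key=lambda d: peaks[d])
    return BundleClassification(orientation=orientation, peak_dff=peaks,
                                roi_id=dff.roi_id, neuromast_id=dff.neuromast_id)


def summarize_neuromast_response(
    dffs: list[DffTrace],
    classifications: list[BundleClassification],
) -> dict[str, dict]:
    """Direction-averaged dF/F across responding bundles and its magnitude.

    Per direction with >= 1 responding bundle: the mean dF/F trace across
    those bundles, and the magnitude = peak of the averaged trace during the
    matching stimulus epoch.  Directions without responders are omitted.
    """
    out: dict[str, dict] = {}
    for direction in ("AtoP", "PtoA"):
        members = [d for d, c in zip(dffs, classifications)
                   if c.orientation == direction]
        if not members:
            continue
        mean_trace = np.mean([m.dff for m in members], axis=0)
        ref = members[0]
        avg = DffTrace(dff=mean_trace, f0=np.nan, baseline_window=ref.baseline_window,
                       volume_rate=ref.volume_rate, stim_epochs=ref.stim_epochs)
        mag = max(_epoch_peak(avg, ep) for ep in ref.stim_epochs
                  if ep.direction == direction)
        out[direction] = {"mean_dff": mean_trace, "magnitude": float(mag),
                          "n_bundles": len(members)}
    return out


def _segment_puncta(
    image: np.ndarray, pixel_size: float, min_area_um2: float,
    threshold: float | None,
) -> list[tuple[float, float]]:
    """Centroids (um, (x, y)) of connected components above the area filter."""
    thr = threshold_otsu(image) if threshold is None else threshold
    labels = sk_label(image > thr)
    px_area = pixel_size**2
    centroids = []
    for region in regionprops(labels):
        if region.area * px_area >= min_area_um2:
            r, c = region.centroid
            centroids.append((c * pixel_size, r * pixel_size))
    return centroids


def count_synapses(
    img: PunctaImagePair,
    min_area_pre: float = MIN_AREA_PRE,
    min_area_post: float = MIN_AREA_POST,
    pair_distance: float = 0.5,
    pre_threshold: float | None = None,
    post_threshold: float | None = None,
) -> SynapseCounts:
    """Complete and unpaired synapse counts from a two-channel puncta image.

    Each channel is thresholded (Otsu by default), connected components below
    the channel's minimum area (um^2) are dropped, and retained pre/post
    puncta are paired one-to-one by greedy nearest-centroid matching within
    ``pair_distance`` um.  Complete synapses are assigned to hair cells via
    ``hc_masks``; leftovers are counted unpaired.  The bookkeeping conserves
    puncta: retained_pre = complete + unpaired_pre (post analogously).
    """
    pre = _segment_puncta(img.pre_channel, img.pixel_size, min_area_pre, pre_threshold)
    post = _segment_puncta(img.post_channel, img.pixel_size, min_area_post, post_threshold)

    pairs: list[tuple[int, int]] = []
    if pre and post and pair_distance > 0:
        dist = cdist(np.asarray(pre), np.asarray(post))
        order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
        used_pre: set[int] = set()
        used_post: set[int] = set()
        for i, j in order:
            if dist[i, j] > pair_distance:
                break
            if i in used_pre or j in used_post:
                continue
            pairs.append((int(i), int(j)))
            used_pre.add(int(i))
            used_post.add(int(j))

    complete_per_hc: dict[int, int] = {}
    for i, _ in pairs:
        if img.hc_masks is None:
            hc = 0
        else:
            x, y = pre[i]
            col = min(int(x / img.pixel_size), img.hc_masks.shape[1] - 1)
            row = min(int(y / img.pixel_size), img.hc_masks.shape[0] - 1)
            hc = int(img.hc_masks[row, col])
        complete_per_hc[hc] = complete_per_hc.get(hc, 0) + 1

    return SynapseCounts(
        complete_per_hc=complete_per_hc,
        unpaired_pre_total=len(pre) - len(pairs),
        unpaired_post_total=len(post) - len(pairs),
        n_retained_pre=len(pre),
        n_retained_post=len(post),
    )


def afferent_selectivity(table: pd.DataFrame) -> tuple[float, float | None, str | None]:
    """Innervation percentage and Emx2 selectivity of one afferent.

    ``table`` has one row per hair cell with columns ``emx2_status``
    (positive | negative) and ``contacted`` (bool).  Returns
    (pct_innervated, selectivity_pct, preferred_class); selectivity is the
    larger of the Emx2+/Emx2- contact fractions among contacted cells, None
    with pct 0 when nothing is contacted.
    """
    if not set(table["emx2_status"]) <= {"positive", "negative"}:
        raise ValueError("emx2_status must be 'positive' or 'negative'")
    n_hc = len(table)
    contacted = table[table["contacted"]]
    n_contacted = len(contacted)
    pct_innervated = 100.0 * n_contacted / n_hc if n_hc else 0.0
    if n_contacted == 0:
        return pct_innervated, None, None
    n_pos = int((contacted["emx2_status"] == "positive").sum())
    n_neg = n_contacted - n_pos
    if n_pos >= n_neg:
        return pct_innervated, 100.0 * n_pos / n_contacted, "positive"
    return pct_innervated, 100.0 * n_neg / n_contacted, "negative"


def hc_density(
    points: np.ndarray,
    roi: RoiCountSpec,
    area: float | None = None,
) -> tuple[int, float]:
    """Marker-positive cells inside the ROI and their density per 1000 um^2.

    ``area`` defaults to the ROI's own area; pass the independently measured
    surface (e.g. total striolar surface) to normalize against it instead.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    count = int(roi.contains(pts).sum()) if pts.size else 0
    norm_area = roi.area if area is None else area
    if norm_area <= 0:
        raise ValueError("normalization area must be positive")
    return count, 1000.0 * count / norm_area
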