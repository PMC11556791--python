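"""Synthetic imaging fixtures: GCaMP bundle ROI traces and two-channel
synaptic-puncta images with known pairing.

ROI traces carry a baseline plus a direction-matched plateau during the
corresponding stimulus epoch (anterior-to-posterior or posterior-to-anterior
fluid-jet push).  Puncta images place disks of specified area at specified
centroids in pre (ribbon) and post (density) channels; ground truth records
which puncta survive the standard size filters and which pre/post pairs form
complete synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..core import GroundTruth
from ..imaging import (
    MIN_AREA_POST, MIN_AREA_PRE, PunctaImagePair, RoiTrace, StimEpoch,
)

__all__ = ["PunctumSpec", "ImagingSimConfig", "simulate_imaging_fixtures", "paired_puncta_spec"]


@dataclass
class PunctumSpec:
    centroid: tuple[float, float]  # um, (x, y)
    area: float  # um^2
    channel: str  # pre | post
    hc_id: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("punctum area must be positive")
        if self.channel not in ("pre", "post"):
            raise ValueError("channel must be pre or post")


def paired_puncta_spec(
    n_complete: int = 5,
    n_unpaired_pre: int = 2,
    n_unpaired_post: int = 1,
    pairing_offset: float = 0.2,
    area_pre: float = 0.06,
    area_post: float = 0.08,
    spacing: float = 2.0,
    start: tuple[float, float] = (1.5, 1.5),
) -> list[PunctumSpec]:
    """Regular grid of puncta: ``n_complete`` pre/post pairs separated by
    ``pairing_offset`` um, plus lone pre and post puncta."""
    specs: list[PunctumSpec] = []
    x0, y0 = start
    k = 0
    for i in range(n_complete):
        c = (x0 + spacing * (k % 5), y0 + spacing * (k // 5))
        specs.append(PunctumSpec(c, area_pre, "pre", hc_id=i + 1))
        specs.append(PunctumSpec((c[0] + pairing_offset, c[1]), area_post, "post", hc_id=i + 1))
        k += 1
    for i in range(n_unpaired_pre):
        c = (x0 + spacing * (k % 5), y0 + spacing * (k // 5))
        specs.append(PunctumSpec(c, area_pre, "pre", hc_id=n_complete + i + 1))
        k += 1
    for i in range(n_unpaired_post):
        c = (x0 + spacing * (k % 5), y0 + spacing * (k // 5))
        specs.append(PunctumSpec(c, area_post, "post",
                                 hc_id=n_complete + n_unpaired_pre + i + 1))
        k += 1
    return specs


@dataclass
class ImagingSimConfig:
    n_bundles_per_orientation: int = 6
    response_amp_AtoP: float = 0.25  # dF/F units (A-to-P responders)
    response_amp_PtoA: float = 0.45  # P-to-A responses are the larger ones
    f0: float = 100.0  # baseline fluorescence, a.u.
    stim_onset: float = 2.0  # s, first (AtoP) epoch
    stim_duration: float = 0.5  # s per push
    inter_stim: float = 2.0  # s between the two epochs
    trace_duration: float = 8.0  # s
    volume_rate: float = 10.0  # Hz
    noise_sd: float = 0.0  # a.u.
    puncta: list[PunctumSpec] = field(default_factory=paired_puncta_spec)
    pixel_size: float = 0.05  # um/px, fine enough to resolve the area filters
    image_shape: tuple[int, int] = (256, 256)  # px, (rows, cols)
    pairing_offset: float = 0.2  # um, pre-to-post centroid displacement
    pair_distance: float = 0.5  # um, distance defining a complete synapse
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        h_um = self.image_shape[0] * self.pixel_size
        w_um = self.image_shape[1] * self.pixel_size
        for p in self.puncta:
            r = np.sqrt(p.area / np.pi)
            x, y = p.centroid
            if not (r <= x <= w_um - r and r <= y <= h_um - r):
                raise ValueError(f"punctum at {p.centroid} um outside image bounds")

    @property
    def epochs(self) -> list[StimEpoch]:
        return [
            StimEpoch("AtoP", self.stim_onset, self.stim_duration),
            StimEpoch("PtoA", self.stim_onset + self.stim_duration + self.inter_stim,
                      self.stim_duration),
        ]


def _render_channel(cfg: ImagingSimConfig, channel: str) -> np.ndarray:
    """Paint each punctum as the round(area / pixel_area) pixels nearest its
    centroid, so the rendered area matches the specified one to half a pixel
    (a naive disk raster overstates areas near the size-filter cutoffs)."""
    img = np.zeros(cfg.image_shape)
    px_area = cfg.pixel_size**2
    rows = np.arange(cfg.image_shape[0])[:, None] + 0.5
    cols = np.arange(cfg.image_shape[1])[None, :] + 0.5
    for p in cfg.puncta:
        if p.channel != channel:
            continue
        n_px = max(int(round(p.area / px_area)), 1)
        x, y = p.centroid
        d2 = (rows - y / cfg.pixel_size) ** 2 + (cols - x / cfg.pixel_size) ** 2
        flat = np.argsort(d2, axis=None, kind="stable")[:n_px]
        img.ravel()[flat] = 1.0
    return img


def _hc_masks(cfg: ImagingSimConfig) -> np.ndarray:
    """Voronoi-like label image: each pixel labeled by the nearest pre punctum's hc_id."""
    pre = [p for p in cfg.puncta if p.channel == "pre"]
    masks = np.zeros(cfg.image_shape, dtype=int)
    if not pre:
        return masks
    rows = (np.arange(cfg.image_shape[0])[:, None] + 0.5) * cfg.pixel_size
    cols = (np.arange(cfg.image_shape[1])[None, :] + 0.5) * cfg.pixel_size
    d2 = np.stack([(rows - p.centroid[1]) ** 2 + (cols - p.centroid[0]) ** 2 for p in pre])
    nearest = np.argmin(d2, axis=0)
    ids = np.array([p.hc_id for p in pre])
    return ids[nearest]


def simulate_imaging_fixtures(
    cfg: ImagingSimConfig,
) -> tuple[list[RoiTrace], PunctaImagePair, GroundTruth]:
    """ROI trace set, puncta image pair, and the scoring ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.trace_duration * cfg.volume_rate))
    epochs = cfg.epochs
    traces: list[RoiTrace] = []
    orientations: dict[int, str] = {}
    roi_id = 0
    for direction, amp in (("AtoP", cfg.response_amp_AtoP), ("PtoA", cfg.response_amp_PtoA)):
        epoch = next(e for e in epochs if e.direction == direction)
        i0 = int(round(epoch.onset * cfg.volume_rate))
        i1 = int(round(epoch.end * cfg.volume_rate))
        for _ in range(cfg.n_bundles_per_orientation):
            f = np.full(n_frames, cfg.f0)
            f[i0:i1] += amp * cfg.f0  # plateau: peak dF/F = amp
            if cfg.noise_sd > 0:
                f = f + rng.normal(0, cfg.noise_sd, n_frames)
            traces.append(RoiTrace(fluorescence=f, volume_rate=cfg.volume_rate,
                                   stim_epochs=epochs, roi_id=roi_id))
            orientations[roi_id] = direction
            roi_id += 1

    pair = PunctaImagePair(pre_channel=_render_channel(cfg, "pre"),
                           post_channel=_render_channel(cfg, "post"),
                           pixel_size=cfg.pixel_size, hc_masks=_hc_masks(cfg))

    retained = {"pre": [], "post": []}
    for p in cfg.puncta:
        min_area = MIN_AREA_PRE if p.channel == "pre" else MIN_AREA_POST
        if p.area >= min_area:
            retained[p.channel].append(p)
    pre_by_hc = {p.hc_id: p for p in retained["pre"]}
    n_complete = 0
    for post in retained["post"]:
        pre = pre_by_hc.get(post.hc_id)
        if pre is None:
            continue
        d = float(np.hypot(pre.centroid[0] - post.centroid[0],
                           pre.centroid[1] - post.centroid[1]))
        if d <= cfg.pair_distance:
            n_complete += 1

    params = asdict(cfg)
    params.update(
        orientations=orientations,
        sub_threshold_puncta=[asdict(p) for p in cfg.puncta
                              if p.area < (MIN_AREA_PRE if p.channel == "pre" else MIN_AREA_POST)],
        n_complete=n_complete,
        n_unpaired_pre=len(retained["pre"]) - n_complete,
        n_unpaired_post=len(retained["post"]) - n_complete,
    )
    truth = GroundTruth(generator="imaging_fixtures", seed=cfg.seed, params=params)
    return traces, pair, truth
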