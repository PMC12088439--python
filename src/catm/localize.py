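"""Initial particle localization.

The assignment pipeline only needs approximate centroids to seed local
matching, so localization is deliberately decoupled from orientation
assignment.  Two pathways are provided:

* a classical matched-filter detector (orientation-pooled NCC maxima with
  an adaptive threshold), which works directly on the tomogram; and
* ingestion of an externally produced segmentation volume (from any
  segmentation tool), reduced to centroids with MeanShift.

Both feed the same downstream machinery, plus a boundary filter that
removes particles near the milled lamella faces or outside the condensate.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from sklearn.cluster import MeanShift

from .matching import NccScorer, _margin_voxels
from .orientation import RotationGrid
from .simulate import ImagingModel
from .volume import Volume

__all__ = ["matched_filter_localize", "meanshift_centroids",
           "filter_boundary_particles", "emulate_segmentation_centroids"]


def matched_filter_localize(tomogram: Volume, template: Volume,
                            imaging: ImagingModel | None = None,
                            angular_step: float = 30.0,
                            threshold: float | str = "adaptive",
                            nsigma: float = 5.0,
                            min_separation_nm: float = 4.0,
                            lowpass_sigma_nm: float = 1.0,
                            with_ctf: bool = True) -> np.ndarray:
    """Candidate centroids from an orientation-pooled matched filter.

    The NCC score map is maximized over a coarse orientation grid, and
    centroids are its local maxima above a threshold, deduplicated at
    ``min_separation_nm``.  The adaptive threshold is median + nsigma*MAD
    of the pooled map, which tracks the noise floor: on a noise-only
    volume it yields almost no detections, while in a condensate the
    particle peaks sit far above it.

    Returns an (n, 3) array of positions in nm, ordered by peak height.
    """
    grid = RotationGrid(angular_step)
    scorer = NccScorer(tomogram, template, imaging, with_ctf, lowpass_sigma_nm)
    pooled = np.full(tomogram.data.shape, -np.inf, dtype=np.float32)
    for rot in grid.orientations:
        np.maximum(pooled, scorer.score_map(rot), out=pooled)
    if threshold == "adaptive":
        med = float(np.median(pooled))
        mad = float(np.median(np.abs(pooled - med))) * 1.4826
        thr = med + nsigma * mad
    else:
        thr = float(threshold)
    peaks = (ndimage.maximum_filter(pooled, size=3) == pooled) & (pooled >= thr)
    m = _margin_voxels(tomogram, template)
    interior = np.zeros_like(peaks)
    interior[m:-m or None, m:-m or None, m:-m or None] = True
    peaks &= interior
    zyx = np.argwhere(peaks)
    scores = pooled[tuple(zyx.T)]
    order = np.argsort(-scores)
    pts = np.array([tomogram.voxel_to_nm(zyx[i][::-1].astype(float))
                    for i in order]).reshape(-1, 3)
    # greedy dedup at min separation, strongest first
    kept: list[np.ndarray] = []
    for p in pts:
        if all(np.linalg.norm(p - q) >= min_separation_nm for q in kept):
            kept.append(p)
    return np.array(kept).reshape(-1, 3)


def emulate_segmentation_centroids(positions: np.ndarray, box_size,
                                   rng: np.random.Generator,
                                   jitter_nm: float = 1.5,
                                   miss_rate: float = 0.02,
                                   extra_rate: float = 0.02,
                                   margin_nm: float = 12.0) -> np.ndarray:
    """Seed centroids with the error profile of a segmentation pipeline.

    Emulates learned-segmentation + mode-finding localization on true
    particle positions: isotropic Gaussian jitter of ``jitter_nm`` total
    RMS, a small fraction of missed particles, and a matching fraction of
    spurious anchors placed uniformly in the interior.  Used by the
    simulation benchmark, where the segmentation stage itself is out of
    scope but its output statistics matter.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    box_size = np.broadcast_to(np.asarray(box_size, dtype=float), (3,))
    keep = rng.random(len(positions)) >= miss_rate
    pts = positions[keep] + rng.normal(0.0, jitter_nm / np.sqrt(3.0),
                                       size=(int(keep.sum()), 3))
    n_extra = rng.binomial(len(positions), extra_rate)
    extras = rng.uniform(margin_nm, box_size - margin_nm, size=(n_extra, 3))
    return np.vstack([pts, extras])


def meanshift_centroids(segmentation: Volume, bandwidth: float = 8.0,
                        prob_threshold: float = 0.5) -> np.ndarray:
    """Centroids of a (probability or binary) segmentation via MeanShift.

    Foreground voxel coordinates (nm) are clustered with a flat kernel of
    the given bandwidth; one centroid is returned per mode.  An empty
    segmentation yields an empty array with a warning.
    """
    fg = np.argwhere(segmentation.data > prob_threshold * segmentation.data.max()
                     if segmentation.data.max() > 0 else segmentation.data > 0)
    if len(fg) == 0:
        warnings.warn("empty segmentation: no centroids")
        return np.zeros((0, 3))
    pts = np.array([segmentation.voxel_to_nm(v[::-1].astype(float)) for v in fg])
    ms = MeanShift(bandwidth=bandwidth, bin_seeding=len(pts) > 2000)
    ms.fit(pts)
    return ms.cluster_centers_


def filter_boundary_particles(points: np.ndarray, lamella_z_range,
                              condensate_surface=None,
                              margin_nm: float = 20.0) -> np.ndarray:
    """Drop points near the lamella faces or outside the condensate.

    Points closer than ``margin_nm`` (default 20 nm) to either z face of
    the lamella are removed; if a fitted condensate surface is supplied,
    points outside it (negative signed depth) are removed too.
    """
    z_lo, z_hi = lamella_z_range
    if not z_hi > z_lo:
        raise ValueError("invalid lamella z range")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    keep = (pts[:, 2] - z_lo >= margin_nm) & (z_hi - pts[:, 2] >= margin_nm)
    if condensate_surface is not None:
        s = condensate_surface
        depth = s.radius - np.linalg.norm(pts - s.center, axis=1)
        keep &= depth >= 0
    return pts[keep]
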