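"""Exhaustive template matching with locally normalized cross-correlation.

The scorer computes, for every voxel, the masked Pearson correlation (CCC)
between the tomogram and a rotated template that has been pushed through
the same degradation as the data (CTF modulation and missing-wedge band
limit).  Normalization is local: the tomogram mean and variance are taken
under the rotated template support mask, so scores live in [-1, 1]
regardless of local contrast.

All correlations run through full-volume FFTs with the template embedded
at the origin, so a score map value at voxel v refers to the template
*centered* at v.  Correlations are circular; callers exclude a margin of
half a template near the volume faces (ground-truth particles never sit
there, so this costs no recall).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import fft as sp_fft
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .orientation import RotationGrid
from .particles import ParticleSet
from .simulate import GroundTruth, ImagingModel, apply_ctf, apply_missing_wedge
from .templates import rotate_volume
from .volume import Volume

__all__ = ["MatchCandidate", "NccScorer", "ncc_score_map", "tm_search",
           "nms_distance_cutoff", "ccc_threshold_sweep"]

_EPS_SUPPORT = 1e-3  # fraction of template max defining the support mask


@dataclass
class MatchCandidate:
    """A scored pose: position (nm), orientation, CCC."""

    position: np.ndarray
    rotation: Rotation
    ccc: float
    orientation_index: int = -1

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.isfinite(self.ccc):
            raise ValueError("ccc must be finite")


def _embed_at_origin(small: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """Place a small cube into a zero array with its center at index (0,0,0)."""
    out = np.zeros(shape, dtype=np.float32)
    c = (np.array(small.shape) - 1) // 2
    out[: small.shape[0], : small.shape[1], : small.shape[2]] = small
    return np.roll(out, -c, axis=(0, 1, 2))


class NccScorer:
    """Masked-NCC score maps of one template against one tomogram.

    Parameters
    ----------
    tomogram, template : Volume
    imaging : ImagingModel or None
        If given, each rotated template is CTF-modulated (optional) and
        wedge-filtered before scoring, matching the degradation of the data.
    with_ctf : bool
        Apply the CTF to the template (on by default).
    lowpass_sigma_nm : float
        If positive, a real-space Gaussian of this sigma is applied to both
        the tomogram and the degraded template before correlation.
    mask_dilation_voxels : int
        Grow the normalization window this many voxels beyond the rotated
        template support.  A shell of surrounding background makes the
        score penalize orientations whose support spills into empty space
        and averages noise over more voxels, at the cost of sensitivity to
        neighboring density inside the window.  0 (the default) scores
        under the bare support mask — appropriate for exhaustive matching
        in crowded volumes; local matching around known centroids benefits
        from a few voxels of context.
    """

    def __init__(self, tomogram: Volume, template: Volume,
                 imaging: ImagingModel | None = None, with_ctf: bool = True,
                 lowpass_sigma_nm: float = 0.0, mask_dilation_voxels: int = 0):
        if any(ts >= vs for ts, vs in zip(template.data.shape, tomogram.data.shape)):
            raise ValueError("template must be smaller than tomogram")
        self.tomogram = tomogram
        self.template = template
        self.imaging = imaging
        self.with_ctf = with_ctf
        self.lowpass_sigma_nm = float(lowpass_sigma_nm)
        self.mask_dilation_voxels = int(mask_dilation_voxels)
        data = tomogram.data.astype(np.float32)
        if self.lowpass_sigma_nm > 0:
            data = ndimage.gaussian_filter(data, self.lowpass_sigma_nm / tomogram.voxel_size)
        self._shape = data.shape
        self._f_data = sp_fft.rfftn(data)
        self._f_data2 = sp_fft.rfftn(data * data)
        self._data_const = float(np.ptp(data)) == 0.0

    def _degraded_template(self, rotation: Rotation) -> tuple[np.ndarray, np.ndarray]:
        """Rotated template after the forward degradation, and its support mask."""
        rot = rotate_volume(self.template, rotation)
        mask = (rot.data > _EPS_SUPPORT * float(self.template.data.max()))
        if self.mask_dilation_voxels:
            mask = ndimage.binary_dilation(mask,
                                           iterations=self.mask_dilation_voxels)
        deg = rot
        if self.imaging is not None:
            if self.with_ctf:
                deg = apply_ctf(deg, self.imaging)
            deg = apply_missing_wedge(deg, self.imaging.tilt_min, self.imaging.tilt_max)
        t = deg.data.astype(np.float32)
        if self.lowpass_sigma_nm > 0:
            t = ndimage.gaussian_filter(t, self.lowpass_sigma_nm / self.template.voxel_size)
        return t, mask.astype(np.float32)

    def score_map(self, rotation: Rotation) -> np.ndarray:
        """Per-voxel CCC of the degraded template at this orientation.

        Zero where the local variance vanishes (flat tomogram regions).
        """
        if self._data_const:
            return np.zeros(self._shape, dtype=np.float32)
        t, mask = self._degraded_template(rotation)
        n_m = float(mask.sum())
        tm = (t - (t * mask).sum() / n_m) * mask
        norm = float(np.sqrt((tm * tm).sum()))
        if norm == 0.0:
            return np.zeros(self._shape, dtype=np.float32)
        tm /= norm
        f_t = sp_fft.rfftn(_embed_at_origin(tm, self._shape))
        f_m = sp_fft.rfftn(_embed_at_origin(mask, self._shape))
        num = sp_fft.irfftn(self._f_data * np.conj(f_t), s=self._shape)
        s1 = sp_fft.irfftn(self._f_data * np.conj(f_m), s=self._shape)
        s2 = sp_fft.irfftn(self._f_data2 * np.conj(f_m), s=self._shape)
        var = s2 - s1 * s1 / n_m
        np.clip(var, 0.0, None, out=var)
        denom = np.sqrt(var, out=var)
        tiny = 1e-6 * float(denom.max()) if denom.max() > 0 else 1.0
        score = np.where(denom > tiny, num / np.maximum(denom, tiny), 0.0)
        return np.clip(score, -1.0, 1.0).astype(np.float32)


def ncc_score_map(tomogram: Volume, template: Volume, orientation: Rotation,
                  imaging: ImagingModel | None = None, with_ctf: bool = True,
                  lowpass_sigma_nm: float = 0.0) -> Volume:
    """Locally normalized cross-correlation map for a single orientation."""
    scorer = NccScorer(tomogram, template, imaging, with_ctf, lowpass_sigma_nm)
    return tomogram.with_data(scorer.score_map(orientation))


def _margin_voxels(tomogram: Volume, template: Volume) -> int:
    return template.data.shape[0] // 2


def tm_search(tomogram: Volume, template: Volume,
              grid: RotationGrid | None = None,
              imaging: ImagingModel | None = None,
              score_floor: float = 0.1, with_ctf: bool = True,
              lowpass_sigma_nm: float = 0.0,
              scorer: NccScorer | None = None) -> list[MatchCandidate]:
    """Exhaustive search: best orientation per voxel, then local maxima.

    Every voxel retains only its highest-CCC orientation; candidates are
    the 3x3x3 local maxima of that best-score map above ``score_floor``,
    excluding a half-template margin at the faces.  Sorted by CCC
    descending.
    """
    if grid is None:
        grid = RotationGrid(15.0)
    if scorer is None:
        scorer = NccScorer(tomogram, template, imaging, with_ctf, lowpass_sigma_nm)
    best = np.full(tomogram.data.shape, -np.inf, dtype=np.float32)
    best_ori = np.zeros(tomogram.data.shape, dtype=np.int16)
    for i, rot in enumerate(grid.orientations):
        s = scorer.score_map(rot)
        upd = s > best
        best[upd] = s[upd]
        best_ori[upd] = i
    peaks = (ndimage.maximum_filter(best, size=3) == best) & (best >= score_floor)
    m = _margin_voxels(tomogram, template)
    interior = np.zeros_like(peaks)
    interior[m:-m or None, m:-m or None, m:-m or None] = True
    peaks &= interior
    zyx = np.argwhere(peaks)
    cands = []
    for z, y, x in zyx:
        pos = tomogram.voxel_to_nm(np.array([x, y, z], dtype=float))
        oi = int(best_ori[z, y, x])
        cands.append(MatchCandidate(pos, grid.orientations[oi],
                                    float(best[z, y, x]), oi))
    cands.sort(key=lambda c: -c.ccc)
    return cands


def nms_distance_cutoff(cands: list[MatchCandidate], cutoff: float = 4.0) -> ParticleSet:
    """Greedy non-maximum suppression by center distance.

    Candidates are visited in descending CCC order; each survivor removes
    all later candidates within ``cutoff`` nm of it (the lower-CCC member
    of any close pair is the one removed).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not cands:
        return ParticleSet()
    order = sorted(range(len(cands)), key=lambda i: -cands[i].ccc)
    pos = np.array([cands[i].position for i in order])
    tree = cKDTree(pos)
    alive = np.ones(len(order), dtype=bool)
    keep = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        keep.append(order[i])
        for j in tree.query_ball_point(pos[i], cutoff):
            if j > i:
                alive[j] = False
    kept = [cands[i] for i in keep]
    return ParticleSet.from_arrays(
        np.array([c.position for c in kept]),
        Rotation.concatenate([c.rotation for c in kept]),
        np.array([c.ccc for c in kept]),
    )


def ccc_threshold_sweep(pred: ParticleSet, gt: GroundTruth | ParticleSet,
                        thresholds, dist_tol: float = 5.5,
                        ang_tol: float | None = None) -> pd.DataFrame:
    """Precision/recall/F1 of thresholded predictions against ground truth.

    One row per threshold plus columns flagging the argmax-F1 row.  With no
    predictions above a threshold, precision and recall are reported as 0
    and ``zero_predictions`` is set.
    """
    from .evaluate import match_particles, precision_recall_f1

    gt_parts = gt.particles if isinstance(gt, GroundTruth) else gt
    gt_nuc = gt_parts.of_kind("nucleosome_disc")
    rows = []
    for thr in thresholds:
        sel = pred.select(pred.scores >= thr)
        if len(sel) == 0:
            rows.append({"threshold": thr, "n_pred": 0, "precision": 0.0,
                         "recall": 0.0, "f1": 0.0, "zero_predictions": True})
            continue
        m = match_particles(gt_nuc, sel, dist_tol=dist_tol, ang_tol=ang_tol)
        p, r, f1 = precision_recall_f1(m)
        rows.append({"threshold": thr, "n_pred": len(sel), "precision": p,
                     "recall": r, "f1": f1, "zero_predictions": False})
    df = pd.DataFrame(rows)
    df["is_max_f1"] = df["f1"] == df["f1"].max()
    return df
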