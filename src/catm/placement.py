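"""Context-aware template matching: local matching plus steric placement.

The algorithm splits assignment into two stages.  Around each seed
centroid, local template matching scores every orientation of the template
(degraded like the data) over a small search ball and keeps *all*
orientations above a retention threshold, not just the best — a candidate
list per particle.  Placement then iterates over particles in descending
order of best CCC, positioning each at its highest-scoring candidate that
does not sterically clash with already-placed particles (mask overlap
beyond a tolerance).  When every candidate of a particle clashes, the
particle is paired with its nearest placed neighbor and the cross product
of both candidate lists is searched for the sterically compatible pair
with the highest summed CCC; if none exists, only the higher-CCC particle
of the pair survives.

The search is deliberately two-body: joint optimization over more
particles grows combinatorially and the pairwise stage already resolves
the stacked-disc ambiguities that defeat distance-cutoff suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .matching import NccScorer
from .occupancy import OccupancyGrid, mask_voxel_indices
from .orientation import RotationGrid
from .particles import ParticleSet
from .simulate import ImagingModel
from .templates import build_steric_mask
from .volume import Volume

__all__ = ["Candidate", "CandidateList", "PlacementState", "local_match",
           "local_match_batch", "clash_check", "greedy_place",
           "run_catm", "merge_assignments", "CatmConfig"]


@dataclass
class Candidate:
    position: np.ndarray  # nm
    rotation: Rotation
    ccc: float


@dataclass
class CandidateList:
    particle_id: int
    anchor: np.ndarray
    candidates: list[Candidate]  # sorted by ccc descending

    @property
    def best_ccc(self) -> float:
        return self.candidates[0].ccc if self.candidates else -np.inf


@dataclass
class PlacementState:
    placed: dict[int, Candidate]
    occupancy: OccupancyGrid
    rejected: list[tuple[int, str]] = field(default_factory=list)


@dataclass
class CatmConfig:
    """Tunables of the local-matching and placement stages."""

    search_radius_nm: float = 5.0
    angular_step: float = 10.0
    retain_threshold: float = 0.3
    clash_tolerance_fraction: float = 0.05
    lowpass_sigma_nm: float = 0.0
    with_ctf: bool = True
    mask_threshold_fraction: float = 0.5
    mask_dilation_voxels: int = 4


# ---------------------------------------------------------------------------
# local matching


def local_match_batch(tomogram: Volume, template: Volume, anchors: np.ndarray,
                      imaging: ImagingModel | None = None,
                      config: CatmConfig | None = None,
                      grid: RotationGrid | None = None,
                      scorer: NccScorer | None = None) -> list[CandidateList]:
    """Candidate lists for many anchors, sharing one orientation sweep.

    For each orientation the full score map is computed once; each anchor
    contributes its best-scoring voxel within the search ball, so every
    anchor retains at most one candidate per orientation.  Candidates below
    the retention threshold are dropped; anchors with no candidate are
    flagged "unassigned" (empty list).
    """
    config = config or CatmConfig()
    grid = grid or RotationGrid(config.angular_step)
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    if scorer is None:
        scorer = NccScorer(tomogram, template, imaging, config.with_ctf,
                           config.lowpass_sigma_nm,
                           config.mask_dilation_voxels)
    r_vox = int(np.floor(config.search_radius_nm / tomogram.voxel_size))
    shape = np.array(tomogram.data.shape)
    # precompute ball offsets
    g = np.arange(-r_vox, r_vox + 1)
    oz, oy, ox = np.meshgrid(g, g, g, indexing="ij")
    ball = np.stack([oz.ravel(), oy.ravel(), ox.ravel()], axis=1)
    ball = ball[np.linalg.norm(ball * tomogram.voxel_size, axis=1)
                <= config.search_radius_nm]
    centers = []
    for a in anchors:
        if not tomogram.contains_nm(a):
            raise ValueError(f"anchor {a} outside tomogram")
        centers.append(np.rint(tomogram.nm_to_voxel(a)).astype(int)[::-1])
    per_anchor: list[list[Candidate]] = [[] for _ in anchors]
    for rot in grid.orientations:
        smap = scorer.score_map(rot)
        for ai, c_zyx in enumerate(centers):
            vox = c_zyx + ball
            ok = np.all((vox >= 0) & (vox < shape), axis=1)
            vox = vox[ok]
            vals = smap[tuple(vox.T)]
            j = int(np.argmax(vals))
            if vals[j] >= config.retain_threshold:
                pos = tomogram.voxel_to_nm(vox[j][::-1].astype(float))
                per_anchor[ai].append(Candidate(pos, rot, float(vals[j])))
    lists = []
    for ai, cands in enumerate(per_anchor):
        cands.sort(key=lambda c: -c.ccc)
        lists.append(CandidateList(ai, anchors[ai], cands))
    return lists


def local_match(tomogram: Volume, template: Volume, anchor,
                search_radius_nm: float = 5.0,
                grid: RotationGrid | None = None,
                imaging: ImagingModel | None = None,
                retain_threshold: float = 0.3,
                lowpass_sigma_nm: float = 0.0,
                with_ctf: bool = True,
                mask_dilation_voxels: int = 4) -> CandidateList:
    """Candidate list for a single anchor (crops the tomogram for speed)."""
    anchor = np.asarray(anchor, dtype=float)
    if not tomogram.contains_nm(anchor):
        raise ValueError("anchor outside tomogram")
    cfg = CatmConfig(search_radius_nm=search_radius_nm,
                     retain_threshold=retain_threshold,
                     lowpass_sigma_nm=lowpass_sigma_nm, with_ctf=with_ctf,
                     mask_dilation_voxels=mask_dilation_voxels)
    # crop a window large enough that circular-FFT wrap cannot reach the
    # scored ball: search radius + one full template per side
    side_t = template.data.shape[0]
    r_vox = int(np.ceil(search_radius_nm / tomogram.voxel_size))
    half = r_vox + side_t
    c = np.rint(tomogram.nm_to_voxel(anchor)).astype(int)[::-1]
    lo = np.maximum(c - half, 0)
    hi = np.minimum(c + half + 1, np.array(tomogram.data.shape))
    crop = Volume(tomogram.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
                  tomogram.voxel_size,
                  tomogram.voxel_to_nm(lo[::-1].astype(float)))
    out = local_match_batch(crop, template, anchor[None, :], imaging, cfg,
                            grid or RotationGrid(cfg.angular_step))[0]
    return out


# ---------------------------------------------------------------------------
# steric placement


class _MaskCache:
    """Rotated-mask voxel indices, memoized per (candidate identity)."""

    def __init__(self, mask: Volume, frame: Volume):
        self.mask = mask
        self.frame = frame
        self.n_mask = int(np.count_nonzero(mask.data))
        self._cache: dict[int, np.ndarray] = {}

    def indices(self, cand: Candidate) -> np.ndarray:
        key = id(cand)
        out = self._cache.get(key)
        if out is None:
            out = mask_voxel_indices(self.mask, cand.rotation, cand.position,
                                     self.frame)
            self._cache[key] = out
        return out


def clash_check(mask: Volume, frame: Volume,
                pos_a, rot_a: Rotation, pos_b, rot_b: Rotation,
                tolerance_voxels: int = 0) -> bool:
    """True iff two placed particles' steric masks share more than
    ``tolerance_voxels`` voxels."""
    ia = mask_voxel_indices(mask, rot_a, np.asarray(pos_a, float), frame)
    ib = mask_voxel_indices(mask, rot_b, np.asarray(pos_b, float), frame)
    return len(np.intersect1d(ia, ib, assume_unique=True)) > tolerance_voxels


def _resolve_pairwise(p: CandidateList, q_id: int, state: PlacementState,
                      cache: _MaskCache, tol: int):
    """Two-body resolution: evaluate p and q jointly with q lifted out.

    With q removed from the occupancy, finds (i) the best sterically
    compatible (cand_p, cand_q) pair — cross product of both candidate
    lists, each candidate also checked against the remaining occupancy —
    and (ii) each particle's best single candidate against that occupancy.
    Returns (best_pair_or_None, best_p_alone_or_None, best_q_alone_or_None).
    """
    lists = state.candidate_lists  # type: ignore[attr-defined]
    q_list = lists[q_id]
    q_old = state.occupancy.remove(q_id)
    try:
        occ = state.occupancy
        p_ok = [(cp, cache.indices(cp)) for cp in p.candidates
                if occ.overlap(cache.indices(cp)) <= tol]
        q_ok = [(cq, cache.indices(cq)) for cq in q_list.candidates
                if occ.overlap(cache.indices(cq)) <= tol]
        best = None
        best_sum = -np.inf
        pairs = sorted(((cp, ip, cq, iq) for cp, ip in p_ok for cq, iq in q_ok),
                       key=lambda t: -(t[0].ccc + t[2].ccc))
        for cp, ip, cq, iq in pairs:
            if cp.ccc + cq.ccc <= best_sum:
                break
            if len(np.intersect1d(ip, iq, assume_unique=True)) <= tol:
                best, best_sum = (cp, cq), cp.ccc + cq.ccc
                break
        return (best,
                p_ok[0][0] if p_ok else None,
                q_ok[0][0] if q_ok else None)
    finally:
        state.occupancy.counts[q_old] += 1
        state.occupancy._placed[q_id] = q_old


def greedy_place(candidate_lists: list[CandidateList], frame: Volume,
                 mask: Volume, clash_tolerance_fraction: float = 0.05
                 ) -> PlacementState:
    """Steric-aware placement of all particles.

    Particles are processed in descending order of their best candidate's
    CCC (ties broken by particle id, so the result is deterministic).  Each
    is placed at its best non-clashing candidate; whenever the top
    candidate is blocked, the two-body resolution against the nearest
    placed neighbor also runs and the higher-scoring of {downgraded single
    placement, jointly re-optimized pair} wins.  If a particle has no
    viable candidate and no compatible pair, the lower-CCC particle of the
    conflicting pair is rejected.
    """
    cache = _MaskCache(mask, frame)
    tol = int(clash_tolerance_fraction * cache.n_mask)
    occ = OccupancyGrid(frame)
    state = PlacementState({}, occ, [])
    lists = {cl.particle_id: cl for cl in candidate_lists}
    state.candidate_lists = lists  # type: ignore[attr-defined]
    order = sorted([cl for cl in candidate_lists if cl.candidates],
                   key=lambda cl: (-cl.best_ccc, cl.particle_id))
    for cl in candidate_lists:
        if not cl.candidates:
            state.rejected.append((cl.particle_id, "unassigned"))
    for cl in order:
        placed_cand = None
        for cand in cl.candidates:
            if occ.overlap(cache.indices(cand)) <= tol:
                placed_cand = cand
                break
        if placed_cand is cl.candidates[0]:
            occ.insert(cl.particle_id, cache.indices(placed_cand))
            state.placed[cl.particle_id] = placed_cand
            continue
        # the top candidate is blocked: escalate to two-body resolution with
        # the nearest placed neighbor, and keep whichever of {downgraded
        # single placement, jointly re-optimized pair} scores higher
        if not state.placed:
            if placed_cand is not None:
                occ.insert(cl.particle_id, cache.indices(placed_cand))
                state.placed[cl.particle_id] = placed_cand
            else:
                state.rejected.append((cl.particle_id, "clash_unresolved"))
            continue
        placed_ids = list(state.placed)
        dists = [np.linalg.norm(state.placed[j].position
                                - cl.candidates[0].position)
                 for j in placed_ids]
        q_id = placed_ids[int(np.argmin(dists))]
        q_cur = state.placed[q_id]
        pair, p_alone, q_alone = _resolve_pairwise(cl, q_id, state, cache, tol)
        # joint two-body decision: best total CCC over the four outcomes
        options = []  # (total, tag)
        if placed_cand is not None:
            options.append((placed_cand.ccc + q_cur.ccc, "single"))
        if pair is not None:
            options.append((pair[0].ccc + pair[1].ccc, "pair"))
        options.append((q_cur.ccc, "drop_p"))
        if p_alone is not None:
            options.append((p_alone.ccc, "drop_q"))
        total, tag = max(options, key=lambda t: t[0])
        if tag == "single":
            occ.insert(cl.particle_id, cache.indices(placed_cand))
            state.placed[cl.particle_id] = placed_cand
        elif tag == "pair":
            cp, cq = pair
            occ.remove(q_id)
            occ.insert(q_id, cache.indices(cq))
            state.placed[q_id] = cq
            occ.insert(cl.particle_id, cache.indices(cp))
            state.placed[cl.particle_id] = cp
        elif tag == "drop_q":
            occ.remove(q_id)
            del state.placed[q_id]
            state.rejected.append((q_id, "displaced_by_higher_ccc"))
            occ.insert(cl.particle_id, cache.indices(p_alone))
            state.placed[cl.particle_id] = p_alone
        else:  # drop_p
            state.rejected.append((cl.particle_id, "clash_unresolved"))
    return state


# ---------------------------------------------------------------------------
# top-level driver and merge


def run_catm(tomogram: Volume, template: Volume, centroids,
             imaging: ImagingModel | None = None,
             config: CatmConfig | None = None,
             grid: RotationGrid | None = None) -> tuple[ParticleSet, dict]:
    """Full context-aware assignment from seed centroids.

    Returns the placed particles (positions nm, ZYZ Euler orientations,
    CCC scores) and a log with per-particle rejections.
    """
    config = config or CatmConfig()
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(centroids) == 0:
        return ParticleSet(), {"n_anchors": 0, "rejected": []}
    lists = local_match_batch(tomogram, template, centroids, imaging, config, grid)
    mask = build_steric_mask(template, config.mask_threshold_fraction)
    state = greedy_place(lists, tomogram, mask,
                         config.clash_tolerance_fraction)
    ids = sorted(state.placed)
    if ids:
        parts = ParticleSet.from_arrays(
            np.array([state.placed[i].position for i in ids]),
            Rotation.concatenate([state.placed[i].rotation for i in ids]),
            np.array([state.placed[i].ccc for i in ids]),
        )
        parts.table["anchor_id"] = ids
    else:
        parts = ParticleSet()
    log = {"n_anchors": len(centroids), "n_placed": len(ids),
           "rejected": state.rejected}
    return parts, log


def merge_assignments(primary: ParticleSet, refined: ParticleSet,
                      mask: Volume, frame: Volume,
                      collapse_radius_nm: float = 2.0,
                      match_radius_nm: float = 5.5,
                      clash_tolerance_fraction: float = 0.05) -> ParticleSet:
    """Merge a refined particle set with the primary (pre-refinement) one.

    Refinement tools treat particles independently and can collapse nearby
    particles onto one position; this de-duplicates the refined set (pairs
    closer than ``collapse_radius_nm`` keep the first by listed order) and
    then restores primary-set particles missing from the refined set,
    provided they introduce no steric clash.
    """
    from scipy.spatial import cKDTree

    cache = _MaskCache(mask, frame)
    tol = int(clash_tolerance_fraction * cache.n_mask)
    # de-duplicate refined
    keep = []
    kept_pos: list[np.ndarray] = []
    for i in range(len(refined)):
        p = refined.positions[i]
        if all(np.linalg.norm(p - q) >= collapse_radius_nm for q in kept_pos):
            keep.append(i)
            kept_pos.append(p)
    dedup = refined.select(np.isin(np.arange(len(refined)), keep))
    occ = OccupancyGrid(frame)
    rots = dedup.rotations
    for i in range(len(dedup)):
        occ.insert(i, mask_voxel_indices(mask, rots[i], dedup.positions[i], frame))
    # restore missing primaries
    tree = cKDTree(dedup.positions) if len(dedup) else None
    extra = []
    prots = primary.rotations
    for i in range(len(primary)):
        p = primary.positions[i]
        if tree is not None and len(tree.query_ball_point(p, match_radius_nm)) > 0:
            continue
        idx = mask_voxel_indices(mask, prots[i], p, frame)
        if occ.overlap(idx) <= tol:
            occ.insert(len(dedup) + len(extra), idx)
            extra.append(i)
    restored = primary.select(np.isin(np.arange(len(primary)), extra))
    return ParticleSet.concat([dedup, restored])
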