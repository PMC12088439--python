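"""Condensate-interface geometry and higher-order organization statistics.

Once particles are assigned, the questions shift from "where is each
nucleosome" to "how is the condensate organized": how particles orient
relative to the condensate-buffer interface, how they contact one another
(the interaction network and its valence heterogeneity), and how they
cluster in space.  This module provides those statistics:

* least-squares sphere fitting of annotated interface perimeters, with
  signed depth and outward surface normal per particle;
* a shape-aware contact graph (edges where steric surfaces approach within
  a gap threshold), its valence distribution, the normalized Shannon
  entropy of that distribution (1 = all valences equally populated,
  0 = a single valence), and categorical attribute assortativity;
* DBSCAN clustering of particle centers with noise labels, cluster-size
  cumulative distributions, and the clustered fraction versus depth below
  the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .particles import ParticleSet

__all__ = ["SphereSurface", "fit_sphere", "fit_plane",
           "surface_distance_and_normal", "build_contact_graph",
           "valence_distribution", "normalized_entropy", "assortativity",
           "dbscan_clusters", "cluster_size_distribution",
           "cluster_fraction_vs_depth"]


# ---------------------------------------------------------------------------
# interface geometry


@dataclass
class SphereSurface:
    """Least-squares sphere: center (nm), radius (nm), rms residual (nm)."""

    center: np.ndarray
    radius: float
    rms_residual: float = 0.0

    def __post_init__(self):
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not self.radius > 0:
            raise ValueError("radius must be positive")


def fit_sphere(points: np.ndarray) -> SphereSurface:
    """Fit a sphere to >= 4 non-coplanar points.

    Algebraic (Coope) linear fit followed by geometric Levenberg-Marquardt
    refinement of the orthogonal residuals.  Raises "sphere underdetermined"
    for degenerate (coplanar or too few) inputs.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise ValueError("sphere underdetermined: need >= 4 points")
    # coplanarity check: rank of centered coordinates
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("sphere underdetermined: points are coplanar")
    a = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = (pts**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))

    def resid(p):
        return np.linalg.norm(pts - p[:3], axis=1) - p[3]

    fit = least_squares(resid, np.r_[center, radius], method="lm")
    c, r = fit.x[:3], float(fit.x[3])
    rms = float(np.sqrt(np.mean(resid(fit.x) ** 2)))
    return SphereSurface(c, abs(r), rms)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through >= 3 points: (point_on_plane, unit normal).

    Used for flat interfaces (e.g. the air-water interface of a blotted
    sample) in place of a sphere fit.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise ValueError("plane underdetermined: need >= 3 points")
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    return c, vt[-1]


def surface_distance_and_normal(p, s: SphereSurface) -> tuple[float, np.ndarray]:
    """Signed depth below the sphere surface and the outward surface normal.

    Depth = radius - |p - center|: positive inside the condensate, zero on
    the surface, negative outside.  The normal is the outward radial unit
    vector at the nearest surface point; undefined at the exact center.
    """
    p = np.asarray(p, dtype=float).reshape(3)
    v = p - s.center
    d = float(np.linalg.norm(v))
    if d == 0.0:
        raise ValueError("surface normal undefined at sphere center")
    return s.radius - d, v / d


# ---------------------------------------------------------------------------
# contact graph


def _cylinder_surface_points(diameter: float, height: float,
                             spacing: float = 0.7) -> np.ndarray:
    """Points sampled on the surface of an axis-aligned cylinder (axis z)."""
    r, h2 = diameter / 2.0, height / 2.0
    pts = []
    # lateral wall: rings of points
    n_z = max(2, int(np.ceil(height / spacing)) + 1)
    n_phi = max(8, int(np.ceil(np.pi * diameter / spacing)))
    phi = np.linspace(0, 2 * np.pi, n_phi, endpoint=False)
    for z in np.linspace(-h2, h2, n_z):
        pts.append(np.stack([r * np.cos(phi), r * np.sin(phi),
                             np.full(n_phi, z)], axis=1))
    # faces: concentric rings
    radii = np.arange(0.0, r, spacing)
    for z in (-h2, h2):
        for rr in radii:
            n = max(1, int(np.ceil(2 * np.pi * rr / spacing))) if rr > 0 else 1
            ph = np.linspace(0, 2 * np.pi, n, endpoint=False)
            pts.append(np.stack([rr * np.cos(ph), rr * np.sin(ph),
                                 np.full(n, z)], axis=1))
    return np.concatenate(pts, axis=0)


def build_contact_graph(particles: ParticleSet, criterion: str = "steric",
                        gap_threshold: float = 1.0,
                        center_threshold: float = 12.0,
                        diameter: float = 11.0, height: float = 5.5,
                        surface_spacing: float = 0.7) -> nx.Graph:
    """Graph of steric contacts between assigned particles.

    criterion="steric" (default): edge (i, j) iff the particles' surfaces
    (oriented discs of the given diameter/height) come within
    ``gap_threshold`` nm of each other, measured as the minimum distance
    between sampled surface point clouds.  criterion="center": edge iff
    center distance <= ``center_threshold`` nm.  The criterion and its
    parameters are recorded in the graph metadata.

    Nodes carry a ``class`` attribute when the particle table has one.
    """
    if len(particles) == 0:
        raise ValueError("empty particle set")
    g = nx.Graph()
    g.graph["criterion"] = criterion
    pos = particles.positions
    if criterion == "steric":
        g.graph["gap_threshold_nm"] = gap_threshold
        base = _cylinder_surface_points(diameter, height, surface_spacing)
        rots = particles.rotations
        mats = np.atleast_3d(rots.as_matrix())
        if mats.shape[0] != len(particles):  # single rotation
            mats = mats.reshape(1, 3, 3)
        clouds = [pos[i] + base @ mats[i].T for i in range(len(particles))]
        trees = [cKDTree(c) for c in clouds]
        bound = np.sqrt((diameter / 2) ** 2 + (height / 2) ** 2)
        pair_cut = 2 * bound + gap_threshold
        center_tree = cKDTree(pos)
        pairs = center_tree.query_pairs(pair_cut)
        g.add_nodes_from(range(len(particles)))
        for i, j in pairs:
            dmin = trees[i].query(clouds[j], k=1)[0].min()
            if dmin <= gap_threshold:
                g.add_edge(i, j)
    elif criterion == "center":
        g.graph["center_threshold_nm"] = center_threshold
        tree = cKDTree(pos)
        g.add_nodes_from(range(len(particles)))
        g.add_edges_from(tree.query_pairs(center_threshold))
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if "class" in particles.table.columns:
        nx.set_node_attributes(
            g, dict(enumerate(particles.table["class"])), "class")
    return g


def valence_distribution(g: nx.Graph) -> pd.Series:
    """P(valence = k) for k = 0..max degree; sums to 1."""
    deg = np.array([d for _, d in g.degree()])
    kmax = int(deg.max()) if len(deg) else 0
    counts = np.bincount(deg, minlength=kmax + 1)
    return pd.Series(counts / counts.sum(),
                     index=pd.RangeIndex(kmax + 1, name="valence"),
                     name="frequency")


def normalized_entropy(dist, support: str = "contiguous") -> float:
    """Shannon entropy of a valence distribution, normalized to [0, 1].

    H = -sum p_k ln p_k / ln K.  With support="contiguous" (default) K
    counts all categories 0..max (including unpopulated ones); with
    "observed" K counts only populated categories.  1 means every valence
    equally populated, 0 a single populated valence; a distribution with
    one category returns 0 by convention.
    """
    p = np.asarray(dist, dtype=float)
    if p.size == 0 or p.sum() <= 0:
        raise ValueError("empty distribution")
    p = p / p.sum()
    if support == "observed":
        p = p[p > 0]
    elif support != "contiguous":
        raise ValueError(f"unknown support convention {support!r}")
    k = p.size
    if k <= 1:
        return 0.0
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / np.log(k)


def assortativity(g: nx.Graph, attribute: str = "class") -> float:
    """Categorical attribute assortativity coefficient in [-1, 1].

    +1: nodes connect only within their class; negative values indicate
    preferential mixing between classes; 0 is random mixing.  Returns NaN
    (with a warning) when a single class is present, where the coefficient
    is undefined.
    """
    attrs = nx.get_node_attributes(g, attribute)
    if len(attrs) < len(g):
        raise ValueError(f"every node needs a {attribute!r} attribute")
    if len(set(attrs.values())) < 2:
        warnings.warn("assortativity undefined with a single class")
        return float("nan")
    return float(nx.attribute_assortativity_coefficient(g, attribute))


# ---------------------------------------------------------------------------
# clustering


def dbscan_clusters(particles: ParticleSet | np.ndarray, eps: float = 12.0,
                    min_pts: int = 3) -> np.ndarray:
    """DBSCAN labels on particle centers; -1 marks noise.

    Defaults (eps 12 nm, min_pts 3) group nucleosomes whose centers sit
    within about one diameter of each other and leave isolated particles
    unclustered.
    """
    if eps <= 0 or min_pts < 1:
        raise ValueError("require eps > 0 and min_pts >= 1")
    pos = particles.positions if isinstance(particles, ParticleSet) \
        else np.atleast_2d(np.asarray(particles, dtype=float))
    return DBSCAN(eps=eps, min_samples=min_pts).fit(pos).labels_


def cluster_size_distribution(labels) -> pd.DataFrame:
    """Cumulative distribution of cluster sizes (noise excluded).

    Columns: size, count, cumulative_fraction.  Empty (no clusters) gives
    an empty frame with a warning.
    """
    labels = np.asarray(labels)
    ids, counts = np.unique(labels[labels >= 0], return_counts=True)
    if len(ids) == 0:
        warnings.warn("no clusters found")
        return pd.DataFrame(columns=["size", "count", "cumulative_fraction"])
    sizes, n_of_size = np.unique(counts, return_counts=True)
    cum = np.cumsum(n_of_size) / n_of_size.sum()
    return pd.DataFrame({"size": sizes, "count": n_of_size,
                         "cumulative_fraction": cum})


def cluster_fraction_vs_depth(particles: ParticleSet | np.ndarray, labels,
                              surface: SphereSurface, bin_width: float = 10.0,
                              min_count: int = 5) -> pd.DataFrame:
    """Fraction of particles in clusters per depth bin below the interface.

    Depth is the signed distance below the fitted sphere surface (positive
    inside).  Bins holding fewer than ``min_count`` particles are flagged
    ``low_count`` rather than reported as unreliable point estimates.
    """
    labels = np.asarray(labels)
    pos = particles.positions if isinstance(particles, ParticleSet) \
        else np.atleast_2d(np.asarray(particles, dtype=float))
    depth = np.array([surface_distance_and_normal(p, surface)[0] for p in pos])
    lo = np.floor(depth.min() / bin_width) * bin_width
    hi = np.ceil(depth.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    rows = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (depth >= a) & (depth < b)
        n = int(m.sum())
        frac = float((labels[m] >= 0).mean()) if n else np.nan
        rows.append({"depth_lo": a, "depth_hi": b, "n": n,
                     "clustered_fraction": frac, "low_count": n < min_count})
    return pd.DataFrame(rows)
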