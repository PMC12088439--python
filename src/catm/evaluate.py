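"""Scoring predicted particle sets against ground truth.

True positives are defined through an optimal one-to-one assignment
(Hungarian algorithm) between ground-truth and predicted particles, so the
counts do not depend on listing order.  A pair is eligible if its center
distance is within ``dist_tol`` and — when an angular tolerance is given —
the symmetry-reduced angle between disc normals is within ``ang_tol``.

The orientation-distribution diagnostic compares the angle between each
disc normal and a fixed axis (the beam axis, z) against the sin(theta)
density expected for uniformly random orientations: for an isotropic
sample the angle theta between a random axis and z has CDF 1 - cos(theta)
on [0, 90] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation
from scipy.stats import ks_1samp

from .orientation import angle_between_axes, normal_axis
from .particles import ParticleSet

__all__ = ["MatchResult", "match_particles", "precision_recall_f1",
           "angle_to_axis", "angle_to_interface", "orientation_distribution"]

_BIG = 1e9


@dataclass
class MatchResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    pairs: pd.DataFrame  # gt_id, pred_id, distance_nm, angular_error_deg


def match_particles(gt: ParticleSet, pred: ParticleSet, dist_tol: float = 5.5,
                    ang_tol: float | None = None) -> MatchResult:
    """Optimal one-to-one matching within tolerances.

    Unmatched ground-truth particles count as false negatives, unmatched
    predictions as false positives.
    """
    if dist_tol <= 0 or (ang_tol is not None and ang_tol <= 0):
        raise ValueError("tolerances must be positive")
    n_gt, n_pred = len(gt), len(pred)
    if n_gt == 0 or n_pred == 0:
        return MatchResult(0, n_pred, n_gt,
                           pd.DataFrame(columns=["gt_id", "pred_id",
                                                 "distance_nm",
                                                 "angular_error_deg"]))
    d = np.linalg.norm(gt.positions[:, None, :] - pred.positions[None, :, :], axis=2)
    ang = angle_between_axes(gt.normals[:, None, :], pred.normals[None, :, :])
    ok = d <= dist_tol
    if ang_tol is not None:
        ok &= ang <= ang_tol
    cost = np.where(ok, d, _BIG)
    rows, cols = linear_sum_assignment(cost)
    matched = ok[rows, cols]
    pairs = pd.DataFrame({
        "gt_id": rows[matched], "pred_id": cols[matched],
        "distance_nm": d[rows, cols][matched],
        "angular_error_deg": ang[rows, cols][matched],
    })
    tp = int(matched.sum())
    return MatchResult(tp, n_pred - tp, n_gt - tp, pairs)


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean; zero-division -> 0."""
    tp, fp, fn = m.true_positives, m.false_positives, m.false_negatives
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def angle_to_axis(orientation: Rotation, axis=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Angle (degrees, in [0, 90]) between the disc normal and a fixed axis.

    Antipodal-invariant: flipping the normal gives the same angle.
    """
    axis = np.asarray(axis, dtype=float)
    n = np.atleast_2d(normal_axis(orientation))
    out = angle_between_axes(n, axis[None, :])
    return out if out.size > 1 else float(out[0])


def angle_to_interface(orientation: Rotation, surface_normals: np.ndarray) -> np.ndarray:
    """Per-particle angle between disc normal and local surface normal."""
    n = np.atleast_2d(normal_axis(orientation))
    s = np.atleast_2d(np.asarray(surface_normals, dtype=float))
    return angle_between_axes(n, s)


def _sine_cdf(theta_deg):
    return 1.0 - np.cos(np.radians(theta_deg))


def orientation_distribution(particles: ParticleSet, axis=(0.0, 0.0, 1.0),
                             bins: int = 9) -> dict:
    """Histogram of normal-to-axis angles with the sinusoidal reference.

    Returns bin edges (degrees, spanning [0, 90]), observed frequencies,
    the reference frequencies for uniformly random orientations
    (integral of sin(theta) per bin), and a one-sample KS test of the
    angles against the analytic CDF 1 - cos(theta).
    """
    if len(particles) == 0:
        raise ValueError("empty particle set")
    theta = np.atleast_1d(angle_to_axis(particles.rotations, axis))
    edges = np.linspace(0.0, 90.0, bins + 1)
    freq, _ = np.histogram(theta, bins=edges)
    freq = freq / freq.sum()
    ref = np.diff(_sine_cdf(edges))
    ks = ks_1samp(theta, _sine_cdf)
    return {"bin_edges": edges, "frequency": freq, "reference": ref,
            "ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
            "angles_deg": theta}
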