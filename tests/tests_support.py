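"""Reference implementations used as independent oracles in tests."""

import numpy as np


def brute_force_dbscan(pts, eps, min_pts):
    """DBSCAN by direct definition: exhaustive neighborhood queries,
    stack-based cluster expansion.  Labels: -1 noise, 0..k clusters."""
    n = len(pts)
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        stack.append(k)
        cid += 1
    return labels
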