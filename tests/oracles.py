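"""Independent brute-force oracles used by the test suite.

These deliberately avoid the libraries the implementation uses:
point-in-polygon by crossing number, entropy by direct histogram
arithmetic, AUC by exhaustive pair comparison, PCA by eigendecomposition
of the sample correlation matrix.
"""
from __future__ import annotations

import numpy as np


def point_in_polygon(px: float, py: float, vertices) -> bool:
    """Boundary-inclusive crossing-number point-in-polygon test."""
    verts = np.asarray(vertices, dtype=float)
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        cross = (px - x1) * (y2 - y1) - (py - y1) * (x2 - x1)
        if (abs(cross) < 1e-9
                and min(x1, x2) - 1e-9 <= px <= max(x1, x2) + 1e-9
                and min(y1, y2) - 1e-9 <= py <= max(y1, y2) + 1e-9):
            return True  # on the boundary counts as inside
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def rasterize_by_oracle(boundaries: dict, shape) -> dict:
    """Region masks by brute-force point-in-polygon over pixel centres."""
    h, w = shape
    cov = {}
    for name, verts in boundaries.items():
        m = np.zeros((h, w), dtype=bool)
        for r in range(h):
            for c in range(w):
                m[r, c] = point_in_polygon(float(c), float(r), verts)
        cov[name] = m
    return {
        "inner": cov["te_inner"],
        "te": cov["zp_te"] & ~cov["te_inner"],
        "zp": cov["zp_outer"] & ~cov["zp_te"],
    }


def disk_histogram_entropy(image: np.ndarray, radius: int,
                           row: int, col: int) -> float:
    """Shannon entropy (bits) of the 256-bin histogram in a pixel's disk."""
    h, w = image.shape
    ys, xs = np.mgrid[0:h, 0:w]
    sel = (ys - row) ** 2 + (xs - col) ** 2 <= radius ** 2
    vals = image[sel].astype(int)
    counts = np.bincount(vals, minlength=256)
    p = counts[counts > 0] / vals.size
    return float(-(p * np.log2(p)).sum())


def pairwise_auc(scores, labels) -> float:
    """AUC by exhaustive positive-negative pair comparison, ties half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def correlation_pca(X: np.ndarray, threshold: float):
    """Explained-variance ratios and minimal k from the correlation matrix."""
    sds = X.std(axis=0, ddof=1)
    Z = (X[:, sds > 0] - X[:, sds > 0].mean(axis=0)) / sds[sds > 0]
    C = (Z.T @ Z) / (len(Z) - 1)
    eig = np.linalg.eigvalsh(C)[::-1]
    eig = np.clip(eig, 0, None)
    ratios = eig / eig.sum()
    k = int(np.searchsorted(np.cumsum(ratios), threshold - 1e-12) + 1)
    return ratios, min(k, len(ratios))
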