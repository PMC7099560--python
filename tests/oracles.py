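"""Independent brute-force reference implementations used only by tests.

These deliberately use naive explicit loops and share no code with the
package's vectorized paths.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def brute_force_pairs(
    values: np.ndarray,
    mask: np.ndarray,
    Ng: int,
    displacement: int,
    stride: int,
    direction: tuple[int, ...],
    symmetrize: bool = True,
    stride_all_axes: bool = False,
) -> np.ndarray:
    """Exhaustive pair enumeration over every origin voxel.

    Origins must lie on the stride grid anchored at the mask bounding-box
    minimum corner (in 3D the slice axis, axis 2, is dense unless
    ``stride_all_axes``); both endpoints must be in-bounds and in-mask.
    """
    shape = values.shape
    ndim = len(shape)
    bbox_min = [min(idx) for idx in np.nonzero(mask)]
    if ndim == 2 or stride_all_axes:
        strided = tuple(range(ndim))
    else:
        strided = (0, 1)
    counts = np.zeros((Ng, Ng), dtype=np.int64)
    for p in itertools.product(*(range(n) for n in shape)):
        if not mask[p]:
            continue
        if any((p[a] - bbox_min[a]) % stride != 0 for a in strided):
            continue
        q = tuple(p[a] + displacement * direction[a] for a in range(ndim))
        if any(not (0 <= q[a] < shape[a]) for a in range(ndim)):
            continue
        if not mask[q]:
            continue
        counts[values[p], values[q]] += 1
    if symmetrize:
        counts = counts + counts.T
    return counts


def classic_glcm_2loop(
    values: np.ndarray, mask: np.ndarray, Ng: int, direction: tuple[int, ...]
) -> np.ndarray:
    """Traditional GLCM (d = s = 1) by a plain double/triple loop."""
    return brute_force_pairs(values, mask, Ng, 1, 1, direction, symmetrize=True)


def naive_measures(p: np.ndarray) -> dict[str, float]:
    """All 30 texture measures by direct elementwise summation loops."""
    Ng = p.shape[0]

    def log0(x: float) -> float:
        return math.log(x) if x > 0 else 0.0

    px = [sum(p[i][j] for j in range(Ng)) for i in range(Ng)]
    py = [sum(p[i][j] for i in range(Ng)) for j in range(Ng)]
    mux = sum(i * px[i] for i in range(Ng))
    muy = sum(j * py[j] for j in range(Ng))
    sx = math.sqrt(sum((i - mux) ** 2 * px[i] for i in range(Ng)))
    sy = math.sqrt(sum((j - muy) ** 2 * py[j] for j in range(Ng)))
    psum = [0.0] * (2 * Ng - 1)
    pdiff = [0.0] * Ng
    for i in range(Ng):
        for j in range(Ng):
            psum[i + j] += p[i][j]
            pdiff[abs(i - j)] += p[i][j]

    out: dict[str, float] = {}
    out["angular_second_moment"] = sum(
        p[i][j] ** 2 for i in range(Ng) for j in range(Ng)
    )
    out["contrast"] = sum(k * k * pdiff[k] for k in range(Ng))
    cov = sum(i * j * p[i][j] for i in range(Ng) for j in range(Ng)) - mux * muy
    out["correlation"] = cov / (sx * sy) if sx * sy > 0 else 0.0
    out["sum_of_squares_variance"] = sum(
        (i - mux) ** 2 * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    out["inverse_difference_moment"] = sum(
        p[i][j] / (1 + (i - j) ** 2) for i in range(Ng) for j in range(Ng)
    )
    sa = sum(k * psum[k] for k in range(2 * Ng - 1))
    out["sum_average"] = sa
    out["sum_variance"] = sum((k - sa) ** 2 * psum[k] for k in range(2 * Ng - 1))
    out["sum_entropy"] = -sum(psum[k] * log0(psum[k]) for k in range(2 * Ng - 1))
    hxy = -sum(p[i][j] * log0(p[i][j]) for i in range(Ng) for j in range(Ng))
    out["entropy"] = hxy
    da = sum(k * pdiff[k] for k in range(Ng))
    out["difference_variance"] = sum((k - da) ** 2 * pdiff[k] for k in range(Ng))
    out["difference_entropy"] = -sum(pdiff[k] * log0(pdiff[k]) for k in range(Ng))
    hx = -sum(px[i] * log0(px[i]) for i in range(Ng))
    hy = -sum(py[j] * log0(py[j]) for j in range(Ng))
    hxy1 = -sum(
        p[i][j] * log0(px[i] * py[j]) for i in range(Ng) for j in range(Ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * log0(px[i] * py[j]) for i in range(Ng) for j in range(Ng)
    )
    hm = max(hx, hy)
    out["information_correlation_1"] = (hxy - hxy1) / hm if hm > 0 else 0.0
    out["information_correlation_2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
    )
    # maximal correlation coefficient via the Q-matrix eigenproblem
    keep_x = [i for i in range(Ng) if px[i] > 0]
    keep_y = [j for j in range(Ng) if py[j] > 0]
    if len(keep_x) < 2 or len(keep_y) < 2:
        out["maximal_correlation_coefficient"] = 0.0
    else:
        q = np.zeros((len(keep_x), len(keep_x)))
        for a, i in enumerate(keep_x):
            for b, j in enumerate(keep_x):
                q[a, b] = sum(
                    p[i][k] * p[j][k] / (px[i] * py[k]) for k in keep_y
                )
        ev = sorted(np.clip(np.linalg.eigvals(q).real, 0, 1), reverse=True)
        out["maximal_correlation_coefficient"] = (
            math.sqrt(ev[1]) if len(ev) > 1 else 0.0
        )
    out["autocorrelation"] = sum(
        i * j * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    out["joint_average"] = sum(i * p[i][j] for i in range(Ng) for j in range(Ng))
    cen = lambda i, j: (i - mux) + (j - muy)
    for name, power in (
        ("cluster_average", 1),
        ("cluster_tendency", 2),
        ("cluster_shade", 3),
        ("cluster_prominence", 4),
    ):
        out[name] = sum(
            cen(i, j) ** power * p[i][j] for i in range(Ng) for j in range(Ng)
        )
    out["dissimilarity"] = sum(
        abs(i - j) * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    out["maximum_probability"] = max(
        p[i][j] for i in range(Ng) for j in range(Ng)
    )
    out["inverse_difference"] = sum(
        p[i][j] / (1 + abs(i - j)) for i in range(Ng) for j in range(Ng)
    )
    out["inverse_difference_normalized"] = sum(
        p[i][j] / (1 + abs(i - j) / Ng) for i in range(Ng) for j in range(Ng)
    )
    out["inverse_difference_moment_normalized"] = sum(
        p[i][j] / (1 + (i - j) ** 2 / Ng**2) for i in range(Ng) for j in range(Ng)
    )
    out["inverse_variance"] = sum(
        p[i][j] / (i - j) ** 2 for i in range(Ng) for j in range(Ng) if i != j
    )
    out["marginal_variance_y"] = sum(
        (j - muy) ** 2 * p[i][j] for i in range(Ng) for j in range(Ng)
    )
    out["marginal_entropy_x"] = hx
    out["marginal_entropy_y"] = hy
    out["homogeneity1"] = sum(pdiff[k] / (1 + k) for k in range(Ng))
    return out


def trapezoid_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC AUC by explicit trapezoidal integration over all thresholds."""
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)[::-1]
    n1 = labels.sum()
    n0 = len(labels) - n1
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        pred = scores >= t
        tpr.append((pred & labels).sum() / n1)
        fpr.append((pred & ~labels).sum() / n0)
    return float(np.trapezoid(tpr, fpr))
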