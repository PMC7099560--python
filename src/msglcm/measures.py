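"""Haralick texture measures and the extended 30-measure roster.

All measures are functionals of the normalized co-occurrence matrix
``p(i, j)`` where the gray levels ``i, j`` are the 0-based quantization
bin indices.  Conventions, applied uniformly:

* natural logarithms, with ``0 * log 0 := 0``;
* when a marginal is degenerate (``sigma_x * sigma_y == 0``),
  correlation-type measures return 0; point-mass distributions have
  entropy 0.  This keeps constant VOIs finite instead of raising.
* sum variance is centered on the sum average (the self-consistent form
  of the second moment of ``p_{x+y}``); sum-of-squares variance is
  centered on ``mu_x``.

The extended roster appends 16 measures to the classic 14.  Two of them
are structural by construction: ``cluster_average``,
``sum((i - mu_x) + (j - mu_y)) * p``, is identically zero for every valid
matrix, and ``homogeneity1`` (computed from the difference distribution)
is analytically equal to ``inverse_difference`` (computed from the joint
matrix).  The retained 28-measure roster drops those two redundant
entries; it is the per-direction feature block used by the descriptor
schemes.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .glcm import CoMatrix

__all__ = [
    "ProbMatrix",
    "MeasureVector",
    "Roster",
    "CLASSIC_14",
    "EXTENDED_30",
    "RETAINED_28",
    "normalize",
    "classic_haralick",
    "extended_haralick",
    "retained_28",
]


class Roster(str, Enum):
    classic14 = "classic14"
    extended30 = "extended30"
    retained28 = "retained28"


CLASSIC_14: tuple[str, ...] = (
    "angular_second_moment",
    "contrast",
    "correlation",
    "sum_of_squares_variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "information_correlation_1",
    "information_correlation_2",
    "maximal_correlation_coefficient",
)

_EXTENSION_16: tuple[str, ...] = (
    "autocorrelation",
    "joint_average",
    "cluster_average",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "dissimilarity",
    "maximum_probability",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "marginal_variance_y",
    "marginal_entropy_x",
    "marginal_entropy_y",
    "homogeneity1",
)

EXTENDED_30: tuple[str, ...] = CLASSIC_14 + _EXTENSION_16

#: The identically-zero measure and one member of the equivalent pair are
#: removed from the descriptor roster.
_DROPPED: tuple[str, str] = ("cluster_average", "homogeneity1")

RETAINED_28: tuple[str, ...] = tuple(m for m in EXTENDED_30 if m not in _DROPPED)


@dataclass(frozen=True)
class ProbMatrix:
    """Normalized co-occurrence matrix with precomputed derived arrays.

    ``p_sum[k]`` is the distribution of ``i + j`` (k = 0 .. 2(Ng-1)) and
    ``p_diff[k]`` the distribution of ``|i - j|`` (k = 0 .. Ng-1).
    """

    p: np.ndarray
    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_sum: np.ndarray
    p_diff: np.ndarray

    @property
    def Ng(self) -> int:
        return self.p.shape[0]

    @classmethod
    def from_probabilities(cls, p: np.ndarray) -> "ProbMatrix":
        p = np.asarray(p, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("p must be a square matrix")
        if (p < 0).any():
            raise ValueError("negative probabilities")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        Ng = p.shape[0]
        levels = np.arange(Ng, dtype=float)
        px = p.sum(axis=1)
        py = p.sum(axis=0)
        mu_x = float(levels @ px)
        mu_y = float(levels @ py)
        sigma_x = float(np.sqrt(max(((levels - mu_x) ** 2) @ px, 0.0)))
        sigma_y = float(np.sqrt(max(((levels - mu_y) ** 2) @ py, 0.0)))
        ii, jj = np.meshgrid(np.arange(Ng), np.arange(Ng), indexing="ij")
        p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * Ng - 1)
        p_diff = np.bincount(
            np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=Ng
        )
        return cls(
            p=p,
            px=px,
            py=py,
            mu_x=mu_x,
            mu_y=mu_y,
            sigma_x=sigma_x,
            sigma_y=sigma_y,
            p_sum=p_sum,
            p_diff=p_diff,
        )


@dataclass(frozen=True)
class MeasureVector:
    names: tuple[str, ...]
    values: np.ndarray
    roster: Roster

    def __post_init__(self) -> None:
        expected = {Roster.classic14: 14, Roster.extended30: 30, Roster.retained28: 28}
        if len(self.names) != expected[self.roster] or len(self.values) != len(
            self.names
        ):
            raise ValueError("measure vector length does not match its roster")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, map(float, self.values)))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


def normalize(cm: CoMatrix) -> ProbMatrix:
    """Divide pair counts by the pair total."""
    if cm.total_pairs == 0:
        raise ValueError("cannot normalize a co-occurrence matrix with zero pairs")
    return ProbMatrix.from_probabilities(cm.counts / cm.total_pairs)


def _xlogx(a: np.ndarray) -> np.ndarray:
    out = np.zeros_like(a)
    nz = a > 0
    out[nz] = a[nz] * np.log(a[nz])
    return out


def _entropy(a: np.ndarray) -> float:
    return float(-_xlogx(a).sum())


def _maximal_correlation(pm: ProbMatrix) -> float:
    """Square root of the second-largest eigenvalue of Haralick's Q matrix.

    Rows/columns with zero marginal mass are removed before forming Q; a
    matrix with fewer than two occupied levels returns 0 (the degenerate
    convention).  Numerically fragile on very sparse matrices, which is
    why the descriptor roster treats it like any other measure but the
    eigenvalues are clipped into [0, 1].
    """
    keep_x = pm.px > 0
    keep_y = pm.py > 0
    p = pm.p[np.ix_(keep_x, keep_y)]
    px = pm.px[keep_x]
    py = pm.py[keep_y]
    if p.shape[0] < 2 or p.shape[1] < 2:
        return 0.0
    # Q[i, j] = sum_k p(i,k) p(j,k) / (px(i) py(k))
    q = (p / px[:, None]) @ (p / py[None, :]).T
    ev = np.linalg.eigvals(q)
    ev = np.sort(np.clip(ev.real, 0.0, 1.0))[::-1]
    if len(ev) < 2:
        return 0.0
    return float(np.sqrt(ev[1]))


def _compute_all(pm: ProbMatrix) -> dict[str, float]:
    Ng = pm.Ng
    levels = np.arange(Ng, dtype=float)
    ii, jj = np.meshgrid(levels, levels, indexing="ij")
    p = pm.p
    k_sum = np.arange(2 * Ng - 1, dtype=float)
    k_diff = np.arange(Ng, dtype=float)

    out: dict[str, float] = {}
    out["angular_second_moment"] = float((p**2).sum())
    out["contrast"] = float((k_diff**2) @ pm.p_diff)
    cov = float((ii * jj * p).sum() - pm.mu_x * pm.mu_y)
    denom = pm.sigma_x * pm.sigma_y
    out["correlation"] = cov / denom if denom > 0 else 0.0
    out["sum_of_squares_variance"] = float((((ii - pm.mu_x) ** 2) * p).sum())
    out["inverse_difference_moment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_avg = float(k_sum @ pm.p_sum)
    out["sum_average"] = sum_avg
    out["sum_variance"] = float(((k_sum - sum_avg) ** 2) @ pm.p_sum)
    out["sum_entropy"] = _entropy(pm.p_sum)
    hxy = _entropy(p)
    out["entropy"] = hxy
    diff_avg = float(k_diff @ pm.p_diff)
    out["difference_variance"] = float(((k_diff - diff_avg) ** 2) @ pm.p_diff)
    out["difference_entropy"] = _entropy(pm.p_diff)
    hx = _entropy(pm.px)
    hy = _entropy(pm.py)
    pxpy = np.outer(pm.px, pm.py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log(pxpy[nz2])).sum())
    hmax = max(hx, hy)
    out["information_correlation_1"] = (hxy - hxy1) / hmax if hmax > 0 else 0.0
    out["information_correlation_2"] = float(
        np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy))))
    )
    out["maximal_correlation_coefficient"] = _maximal_correlation(pm)

    # --- extension measures ---
    out["autocorrelation"] = float((ii * jj * p).sum())
    out["joint_average"] = float((ii * p).sum())
    centered = (ii - pm.mu_x) + (jj - pm.mu_y)
    out["cluster_average"] = float((centered * p).sum())  # identically 0
    out["cluster_tendency"] = float((centered**2 * p).sum())
    out["cluster_shade"] = float((centered**3 * p).sum())
    out["cluster_prominence"] = float((centered**4 * p).sum())
    out["dissimilarity"] = float((np.abs(ii - jj) * p).sum())
    out["maximum_probability"] = float(p.max())
    out["inverse_difference"] = float((p / (1.0 + np.abs(ii - jj))).sum())
    out["inverse_difference_normalized"] = float(
        (p / (1.0 + np.abs(ii - jj) / Ng)).sum()
    )
    out["inverse_difference_moment_normalized"] = float(
        (p / (1.0 + (ii - jj) ** 2 / Ng**2)).sum()
    )
    off = ii != jj
    out["inverse_variance"] = float((p[off] / (ii - jj)[off] ** 2).sum())
    out["marginal_variance_y"] = float((((jj - pm.mu_y) ** 2) * p).sum())
    out["marginal_entropy_x"] = hx
    out["marginal_entropy_y"] = hy
    # same quantity as inverse_difference, accumulated from p_{|i-j|}
    out["homogeneity1"] = float((pm.p_diff / (1.0 + k_diff)).sum())
    return out


def classic_haralick(pm: ProbMatrix) -> MeasureVector:
    """The 14 classic measures of the normalized co-occurrence matrix."""
    vals = _compute_all(pm)
    return MeasureVector(
        names=CLASSIC_14,
        values=np.array([vals[m] for m in CLASSIC_14]),
        roster=Roster.classic14,
    )


def extended_haralick(pm: ProbMatrix) -> MeasureVector:
    """The full 30-measure extended roster (classic 14 + 16 extensions)."""
    vals = _compute_all(pm)
    return MeasureVector(
        names=EXTENDED_30,
        values=np.array([vals[m] for m in EXTENDED_30]),
        roster=Roster.extended30,
    )


def retained_28(pm: ProbMatrix) -> MeasureVector:
    """The 28-measure descriptor block: extended roster minus the
    identically-zero ``cluster_average`` and the duplicate
    ``homogeneity1``."""
    vals = _compute_all(pm)
    return MeasureVector(
        names=RETAINED_28,
        values=np.array([vals[m] for m in RETAINED_28]),
        roster=Roster.retained28,
    )


def degenerate_measures(Ng: int, roster: Roster = Roster.retained28) -> MeasureVector:
    """Measure vector of the convention matrix used when a configuration
    produces zero pairs: a point mass at gray level (0, 0).

    Entropies are 0, ASM and maximum probability are 1, and every
    dispersion measure vanishes — the continuous limit of an empty or
    constant sample.
    """
    p = np.zeros((Ng, Ng))
    p[0, 0] = 1.0
    pm = ProbMatrix.from_probabilities(p)
    fn = {
        Roster.classic14: classic_haralick,
        Roster.extended30: extended_haralick,
        Roster.retained28: retained_28,
    }[roster]
    return fn(pm)
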