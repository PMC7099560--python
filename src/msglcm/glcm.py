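"""Multi-scale gray-level co-occurrence matrices on masked 2D/3D arrays.

The classic co-occurrence matrix counts, for a fixed lattice offset, how
often a voxel of gray level *i* has a partner of gray level *j* at that
offset.  The multi-scale generalization used here adds two knobs:

* ``displacement`` (d) — the partner sits at ``p + d * theta`` instead of
  the nearest neighbour along ``theta``;
* ``stride`` (s) — origin voxels are sampled on a grid of spacing ``s``
  instead of exhaustively, i.e. a down-sampling of the pair population.

With ``s = d = 1`` the matrix reduces exactly to the traditional GLCM.
A pair is counted only when both endpoints lie inside the array *and*
inside the volume-of-interest mask; origins whose partner falls outside
are skipped silently (the classical boundary convention, which avoids
padding artifacts in small lesion VOIs).

The stride grid is anchored at the minimum corner of the mask's bounding
box on each strided axis, so results are invariant to how generously the
VOI was cropped.  In 3D the stride applies to the two in-plane axes
(axes 0 and 1) on every slice while the slice axis (axis 2) is traversed
with step 1; set ``stride_all_axes=True`` to stride all three.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .directions import Direction, DirectionSet, is_canonical

__all__ = [
    "QuantizedVolume",
    "GlcmConfig",
    "CoMatrix",
    "quantize",
    "compute_msglcm",
    "msglcm_batch",
]

logger = logging.getLogger(__name__)

#: Sentinel value carried by voxels outside the mask after quantization.
MASKED_OUT = -1


@dataclass(frozen=True)
class QuantizedVolume:
    """Integer-valued image or volume with a boolean VOI mask.

    ``values`` holds bin indices in ``[0, Ng - 1]`` inside the mask and the
    sentinel ``MASKED_OUT`` outside it.
    """

    values: np.ndarray
    mask: np.ndarray
    Ng: int

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if self.values.ndim not in (2, 3):
            raise ValueError("only 2D and 3D arrays are supported")
        if not self.mask.any():
            raise ValueError("mask is empty")
        inside = self.values[self.mask]
        if inside.min() < 0 or inside.max() >= self.Ng:
            raise ValueError("masked values outside [0, Ng-1]")

    @property
    def ndim(self) -> int:
        return self.values.ndim


@dataclass(frozen=True)
class GlcmConfig:
    """Parameters of one co-occurrence computation."""

    displacement: int
    stride: int
    direction: Direction
    Ng: int
    symmetrize: bool = True
    stride_all_axes: bool = False

    def __post_init__(self) -> None:
        if self.displacement < 1:
            raise ValueError("displacement must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.Ng < 2:
            raise ValueError("Ng must be >= 2")


@dataclass(frozen=True)
class CoMatrix:
    """Pair-count matrix for one (direction, displacement, stride) config."""

    counts: np.ndarray
    config: GlcmConfig
    total_pairs: int


def quantize(
    raw: np.ndarray,
    mask: np.ndarray,
    Ng: int,
    range_policy: str | tuple[float, float] = "voi-minmax",
) -> QuantizedVolume:
    """Linearly bin masked intensities into ``Ng`` equal-width gray levels.

    Parameters
    ----------
    range_policy
        ``"voi-minmax"`` bins over the min-max range of the masked voxels;
        a ``(lo, hi)`` tuple bins over that fixed range, clipping outliers
        into the end bins.  A constant masked image maps to bin 0 (a
        documented degenerate case, not an error).
    """
    raw = np.asarray(raw, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if raw.shape != mask.shape:
        raise ValueError("raw and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    if Ng < 2:
        raise ValueError("Ng must be >= 2")
    inside = raw[mask]
    if not np.isfinite(inside).all():
        raise ValueError("non-finite intensities inside the mask")
    if isinstance(range_policy, str):
        if range_policy != "voi-minmax":
            raise ValueError(f"unknown range policy {range_policy!r}")
        lo, hi = float(inside.min()), float(inside.max())
    else:
        lo, hi = map(float, range_policy)
        if hi <= lo:
            raise ValueError("fixed range must satisfy hi > lo")
    values = np.full(raw.shape, MASKED_OUT, dtype=np.int32)
    if hi == lo:  # constant VOI: single occupied bin
        values[mask] = 0
    else:
        bins = np.floor((inside - lo) / (hi - lo) * Ng).astype(np.int32)
        values[mask] = np.clip(bins, 0, Ng - 1)
    return QuantizedVolume(values=values, mask=mask, Ng=Ng)


def _stride_grid(vol: QuantizedVolume, cfg: GlcmConfig) -> np.ndarray:
    """Boolean array marking stride-grid origin positions.

    Anchored per axis at the minimum corner of the mask bounding box.
    """
    shape = vol.values.shape
    if cfg.stride == 1:
        return np.ones(shape, dtype=bool)
    bbox_min = [int(np.min(idx)) for idx in np.nonzero(vol.mask)]
    if vol.ndim == 2 or cfg.stride_all_axes:
        strided_axes = tuple(range(vol.ndim))
    else:
        strided_axes = (0, 1)  # in-plane axes; axis 2 traversed densely
    axes_idx = []
    for ax, n in enumerate(shape):
        if ax in strided_axes:
            axes_idx.append(np.arange(bbox_min[ax], n, cfg.stride))
        else:
            axes_idx.append(np.arange(n))
    grid = np.zeros(shape, dtype=bool)
    grid[np.ix_(*axes_idx)] = True
    return grid


def compute_msglcm(vol: QuantizedVolume, cfg: GlcmConfig) -> CoMatrix:
    """Count gray-level pairs at offset ``displacement * direction``.

    ``counts[i, j]`` is the number of stride-grid origins ``p`` inside the
    mask whose partner ``q = p + d * theta`` lies inside both the array and
    the mask, with ``vol(p) = i`` and ``vol(q) = j``.  If
    ``cfg.symmetrize``, the transposed counts are added (equivalent to also
    counting the antipodal direction) and ``total_pairs`` doubles.
    """
    if cfg.Ng != vol.Ng:
        raise ValueError(f"config Ng={cfg.Ng} does not match volume Ng={vol.Ng}")
    if len(cfg.direction) != vol.ndim:
        raise ValueError("direction dimensionality does not match the volume")
    if not is_canonical(cfg.direction):
        raise ValueError(
            f"direction {cfg.direction} is not canonical; use canonicalize()"
        )
    offset = np.asarray(cfg.direction, dtype=int) * cfg.displacement
    shape = vol.values.shape
    src, dst = [], []
    for ax, n in enumerate(shape):
        o = int(offset[ax])
        src.append(slice(max(0, -o), n - max(0, o)))
        dst.append(slice(max(0, -o) + o, n - max(0, o) + o))
    src, dst = tuple(src), tuple(dst)

    origin_ok = vol.mask & _stride_grid(vol, cfg)
    valid = origin_ok[src] & vol.mask[dst]
    i = vol.values[src][valid].astype(np.int64)
    j = vol.values[dst][valid].astype(np.int64)
    counts = np.bincount(i * cfg.Ng + j, minlength=cfg.Ng * cfg.Ng).reshape(
        cfg.Ng, cfg.Ng
    )
    if cfg.symmetrize:
        counts = counts + counts.T
    total = int(counts.sum())
    if total == 0:
        logger.warning("co-occurrence matrix has zero pairs for config %s", cfg)
    return CoMatrix(counts=counts, config=cfg, total_pairs=total)


def msglcm_batch(
    vol: QuantizedVolume,
    directions: DirectionSet,
    displacements: Sequence[int],
    stride: int,
    Ng: int,
    symmetrize: bool = True,
    stride_all_axes: bool = False,
) -> list[CoMatrix]:
    """One matrix per (displacement, direction) pair, displacement-major.

    E.g. 13 directions with displacements {1, 2, 3} yield three matrix
    sets of 13 matrices each, 39 in total.
    """
    if len(directions) == 0:
        raise ValueError("empty direction set")
    if len(displacements) == 0:
        raise ValueError("empty displacement list")
    out = []
    for d in displacements:
        for theta in directions:
            cfg = GlcmConfig(
                displacement=d,
                stride=stride,
                direction=theta,
                Ng=Ng,
                symmetrize=symmetrize,
                stride_all_axes=stride_all_axes,
            )
            out.append(compute_msglcm(vol, cfg))
    return out
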