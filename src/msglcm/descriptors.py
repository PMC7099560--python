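"""Per-lesion texture descriptors for the classic and multi-scale schemes.

Two descriptor families are supported:

* ``HF2D`` — the traditional 2D Haralick-feature descriptor: the 14
  classic measures over the four in-plane directions, summarized into 14
  means and 14 ranges (28 values), the rotation-tolerant form used since
  the original texture work.
* MSGLCM schemes — one retained-28 measure block per direction,
  concatenated in direction-set order, giving ``N_angles * 28`` values per
  lesion.  The scheme families vary one or two matrix parameters:

  - ``LMD``: multiple displacements (stride fixed at 1, 13 directions);
  - ``LMS``: multiple strides (displacement fixed at 1, 13 directions);
  - ``LMA``: multiple angle groups (displacement = stride = 1);
  - ``LMD_LMS``: the displacement x stride grid (e.g. 3 x 9 = 27 configs);
  - ``LMS_LMA``: the angle-group x stride grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .directions import DirectionSet, enumerate_directions
from .glcm import GlcmConfig, QuantizedVolume, compute_msglcm
from .measures import (
    RETAINED_28,
    Roster,
    classic_haralick,
    degenerate_measures,
    normalize,
    retained_28,
)

__all__ = [
    "Scheme",
    "SchemeConfig",
    "Descriptor",
    "hf2d_descriptor",
    "msglcm_descriptor",
    "build_scheme_grid",
    "descriptor_feature_names",
]

logger = logging.getLogger(__name__)


class Scheme(str, Enum):
    HF2D = "HF2D"
    LMD = "LMD"
    LMS = "LMS"
    LMA = "LMA"
    LMD_LMS = "LMD_LMS"
    LMS_LMA = "LMS_LMA"


@dataclass(frozen=True)
class SchemeConfig:
    """Grid specification for one descriptor scheme.

    ``angle_groups`` lists (max_displacement, dedup) pairs for the LMA-type
    schemes; ``displacements`` and ``strides`` feed the LMD/LMS axes.
    """

    scheme: Scheme
    displacements: tuple[int, ...] = (1, 2, 3)
    strides: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    angle_groups: tuple[tuple[int, bool], ...] = ((1, False), (2, False), (3, False))
    Ng: int = 32
    symmetrize: bool = True


@dataclass(frozen=True)
class Descriptor:
    lesion_id: str
    config_tag: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.values).all():
            raise ValueError("descriptor contains non-finite values")


def hf2d_descriptor(image: QuantizedVolume, lesion_id: str = "") -> Descriptor:
    """Classic 2D descriptor: 14 measure means + 14 ranges over the four
    in-plane directions (0, 45, 90, 135 degrees)."""
    if image.ndim != 2:
        raise ValueError("HF2D requires a 2D image")
    dirs = enumerate_directions(2, 1, dedup=False)
    per_dir = []
    for theta in dirs:
        cfg = GlcmConfig(
            displacement=1, stride=1, direction=theta, Ng=image.Ng, symmetrize=True
        )
        cm = compute_msglcm(image, cfg)
        if cm.total_pairs == 0:
            logger.warning("zero pairs for 2D direction %s; degenerate block", theta)
            per_dir.append(degenerate_measures(image.Ng, Roster.classic14).values)
        else:
            per_dir.append(classic_haralick(normalize(cm)).values)
    stack = np.vstack(per_dir)
    means = stack.mean(axis=0)
    ranges = stack.max(axis=0) - stack.min(axis=0)
    return Descriptor(
        lesion_id=lesion_id,
        config_tag="HF2D_d1_s1_Ng%d" % image.Ng,
        values=np.concatenate([means, ranges]),
    )


def msglcm_descriptor(
    vol: QuantizedVolume,
    directions: DirectionSet,
    displacement: int,
    stride: int,
    lesion_id: str = "",
    symmetrize: bool = True,
    stride_all_axes: bool = False,
) -> Descriptor:
    """Concatenate retained-28 blocks over the direction set.

    Length is ``len(directions) * 28``.  A direction whose matrix collects
    zero pairs contributes the degenerate point-mass block (with a logged
    warning) rather than failing the whole lesion.
    """
    if len(directions) == 0:
        raise ValueError("empty direction set")
    blocks = []
    for theta in directions:
        cfg = GlcmConfig(
            displacement=displacement,
            stride=stride,
            direction=theta,
            Ng=vol.Ng,
            symmetrize=symmetrize,
            stride_all_axes=stride_all_axes,
        )
        cm = compute_msglcm(vol, cfg)
        if cm.total_pairs == 0:
            logger.warning(
                "zero pairs for direction %s (d=%d, s=%d); degenerate block",
                theta,
                displacement,
                stride,
            )
            blocks.append(degenerate_measures(vol.Ng, Roster.retained28).values)
        else:
            blocks.append(retained_28(normalize(cm)).values)
    tag = "d%d_s%d_a%d_dedup%d_Ng%d" % (
        displacement,
        stride,
        len(directions),
        int(directions.dedup),
        vol.Ng,
    )
    return Descriptor(
        lesion_id=lesion_id, config_tag=tag, values=np.concatenate(blocks)
    )


def descriptor_feature_names(directions: DirectionSet) -> list[str]:
    """Column names ``{direction_index}_{measure_name}`` matching
    :func:`msglcm_descriptor` output order."""
    return [f"{k}_{m}" for k in range(len(directions)) for m in RETAINED_28]


def build_scheme_grid(cfg: SchemeConfig) -> list[tuple[str, dict]]:
    """Expand a scheme into its (config_tag, parameter-dict) list.

    Each parameter dict carries ``displacement``, ``stride`` and
    ``angle_group`` (a (max_displacement, dedup) pair) and fully determines
    one descriptor configuration.
    """

    def entry(d: int, s: int, group: tuple[int, bool]) -> tuple[str, dict]:
        tag = "%s_d%d_s%d_g%d%s_Ng%d" % (
            cfg.scheme.value,
            d,
            s,
            group[0],
            "x" if group[1] else "",
            cfg.Ng,
        )
        return tag, {
            "displacement": d,
            "stride": s,
            "angle_group": group,
            "Ng": cfg.Ng,
            "symmetrize": cfg.symmetrize,
        }

    base_group = (1, False)  # the 13-direction set
    if cfg.scheme == Scheme.HF2D:
        return [entry(1, 1, base_group)]
    if cfg.scheme == Scheme.LMD:
        if not cfg.displacements:
            raise ValueError("LMD needs a displacement list")
        return [entry(d, 1, base_group) for d in cfg.displacements]
    if cfg.scheme == Scheme.LMS:
        if not cfg.strides:
            raise ValueError("LMS needs a stride list")
        return [entry(1, s, base_group) for s in cfg.strides]
    if cfg.scheme == Scheme.LMA:
        if not cfg.angle_groups:
            raise ValueError("LMA needs an angle-group list")
        return [entry(1, 1, g) for g in cfg.angle_groups]
    if cfg.scheme == Scheme.LMD_LMS:
        if not (cfg.displacements and cfg.strides):
            raise ValueError("LMD_LMS needs displacement and stride lists")
        return [
            entry(d, s, base_group) for d in cfg.displacements for s in cfg.strides
        ]
    if cfg.scheme == Scheme.LMS_LMA:
        if not (cfg.angle_groups and cfg.strides):
            raise ValueError("LMS_LMA needs angle-group and stride lists")
        return [entry(1, s, g) for g in cfg.angle_groups for s in cfg.strides]
    raise ValueError(f"unknown scheme {cfg.scheme}")
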