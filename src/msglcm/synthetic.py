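"""Synthetic two-class 3D lesion phantoms with controllable texture gap.

Each phantom is a smoothed Gaussian random field inside an ellipsoidal
volume-of-interest mask, mimicking the stochastic, structureless texture
of soft-tissue lesions on CT.  The two classes differ in spatial
correlation length (smoothing kernel width) and contrast (field standard
deviation); a single ``separation`` scalar scales the between-class gap
on both parameters, so ``separation = 0`` makes the classes statistically
identical (a null cohort) and larger values make them progressively
easier to tell apart.

Optionally a fraction of mask voxels is replaced by connected pockets of
a very low "air" intensity, emulating gas trapped inside manually
outlined lesion regions; :func:`air_cleanse` removes such voxels by
thresholding before texture extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "Lesion", "generate_cohort", "air_cleanse"]


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort generation parameters.

    Defaults emulate a small surgical cohort: 31 benign and 32 malignant
    lesions, 24^3-voxel crops, soft-tissue-like intensities on an
    HU-like scale (mean 50, SD 15), air at -900, correlation length about
    1.5 voxels.  ``separation`` is the dimensionless between-class gap:
    class 0 uses ``corr_length * (1 - separation / 2)`` and ``contrast *
    (1 - separation / 2)``, class 1 the ``(1 + separation / 2)``
    counterparts.
    """

    n_benign: int = 31
    n_malignant: int = 32
    shape: tuple[int, int, int] = (24, 24, 24)
    corr_length: float = 1.5
    intensity_mean: float = 50.0
    intensity_sd: float = 15.0
    contrast: float = 1.0
    separation: float = 0.0
    air_fraction: float = 0.0
    air_value: float = -900.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if min(self.shape) < 8:
            raise ValueError("each axis must be >= 8 voxels")
        if self.n_benign < 2 or self.n_malignant < 2:
            raise ValueError("need at least 2 lesions per class")
        if not 0.0 <= self.air_fraction <= 0.2:
            raise ValueError("air_fraction must be in [0, 0.2]")


@dataclass(frozen=True)
class Lesion:
    volume: np.ndarray
    mask: np.ndarray
    label: int  # 0 benign, 1 malignant
    lesion_id: str


def _ellipsoid_mask(
    shape: tuple[int, int, int], rng: np.random.Generator
) -> np.ndarray:
    center = np.array(shape) / 2.0 + rng.uniform(-1.0, 1.0, size=3)
    semi = np.array([rng.uniform(0.30, 0.42) * n for n in shape])
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return r2 <= 1.0


def _correlated_field(
    shape: tuple[int, int, int],
    corr_length: float,
    sd: float,
    mean: float,
    rng: np.random.Generator,
) -> np.ndarray:
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=corr_length, mode="reflect")
    smooth /= smooth.std() or 1.0
    return mean + sd * smooth


def _air_pockets(
    mask: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Connected pockets covering ~``fraction`` of the mask volume, grown
    by dilation from a few random seed voxels inside the mask."""
    target = int(round(fraction * mask.sum()))
    if target == 0:
        return np.zeros_like(mask)
    inside = np.argwhere(mask)
    n_seeds = max(1, target // 30)
    seeds = inside[rng.choice(len(inside), size=n_seeds, replace=False)]
    pockets = np.zeros_like(mask)
    pockets[tuple(seeds.T)] = True
    struct = ndimage.generate_binary_structure(3, 1)
    while pockets.sum() < target:
        grown = ndimage.binary_dilation(pockets, structure=struct) & mask
        if grown.sum() == pockets.sum():
            break
        pockets = grown
    return pockets


def generate_cohort(spec: PhantomSpec) -> list[Lesion]:
    """Generate the phantom cohort; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    lesions: list[Lesion] = []
    half = spec.separation / 2.0
    for label, count in ((0, spec.n_benign), (1, spec.n_malignant)):
        sign = -1.0 if label == 0 else 1.0
        corr = max(spec.corr_length * (1.0 + sign * half), 0.3)
        sd = max(spec.intensity_sd * spec.contrast * (1.0 + sign * half), 1e-3)
        for k in range(count):
            mask = _ellipsoid_mask(spec.shape, rng)
            vol = _correlated_field(
                spec.shape, corr, sd, spec.intensity_mean, rng
            )
            if spec.air_fraction > 0:
                pockets = _air_pockets(mask, spec.air_fraction, rng)
                if pockets.sum() >= mask.sum():
                    raise ValueError("air pockets would consume the whole mask")
                vol = np.where(pockets, spec.air_value, vol)
            lesions.append(
                Lesion(
                    volume=vol,
                    mask=mask,
                    label=label,
                    lesion_id=f"{'benign' if label == 0 else 'malig'}_{k:03d}",
                )
            )
    return lesions


def air_cleanse(
    volume: np.ndarray, mask: np.ndarray, threshold: float
) -> tuple[np.ndarray, int]:
    """Remove predominantly-air voxels (intensity below ``threshold``)
    from the mask.  Returns (cleaned mask, number of voxels removed).

    A simple global threshold; the default pipeline cutoff is
    ``air_value + 3 * intensity SD``, far below any soft-tissue voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    cleaned = mask & (np.asarray(volume, dtype=float) >= threshold)
    if not cleaned.any():
        raise ValueError("air cleansing removed every voxel in the mask")
    return cleaned, int(mask.sum() - cleaned.sum())
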