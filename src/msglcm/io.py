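"""Volume/mask readers and writers, run configuration, and the
end-to-end pipeline: load -> air-cleanse -> quantize -> extract
descriptors over a scheme grid -> evaluate -> write summaries.

Volumes are accepted as NIfTI files (``.nii`` / ``.nii.gz``, read with
nibabel) or raw NumPy dumps (``.npy``).  Arrays are used in 0-based index
order exactly as stored; direction vectors act in this index space.
Masks are same-shape volumes thresholded at 0.5.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import EnsembleParams, EvalResult, SplitPlan, evaluate_scheme
from .descriptors import (
    Scheme,
    SchemeConfig,
    build_scheme_grid,
    descriptor_feature_names,
    msglcm_descriptor,
)
from .directions import enumerate_directions
from .glcm import quantize
from .synthetic import Lesion, PhantomSpec, air_cleanse, generate_cohort

__all__ = [
    "RunConfig",
    "load_volume",
    "load_mask",
    "write_volume",
    "write_features",
    "read_features",
    "load_cohort",
    "extract_features",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def load_volume(path: str | Path) -> np.ndarray:
    """Read a volume from NIfTI or .npy; returns a float array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        return np.asarray(np.load(path), dtype=float)
    if path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    raise ValueError(f"unsupported volume format: {path.name}")


def load_mask(path: str | Path) -> np.ndarray:
    return load_volume(path) > 0.5


def write_volume(arr: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, np.asarray(arr))
    elif path.name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.eye(4)), str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def write_features(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of one pipeline run.

    Either ``cohort_csv`` points at a table with columns
    (lesion_id, volume, mask, label) of file paths and 0/1 labels, or
    ``synthetic`` carries a :class:`PhantomSpec` and the cohort is
    simulated.  ``cleanse_threshold = None`` disables air cleansing.
    """

    scheme: str = "LMS"
    displacements: tuple[int, ...] = (1, 2, 3)
    strides: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 9)
    angle_groups: tuple[tuple[int, bool], ...] = ((1, False), (2, False), (3, False))
    Ng: int = 32
    range_policy: str | tuple[float, float] = "voi-minmax"
    cleanse_threshold: float | None = -855.0
    n_trees: int = 2000
    max_subset_size: int = 30
    n_iterations: int = 100
    n_train_benign: int = 15
    n_train_malignant: int = 16
    mode: str = "leakage-safe"
    seed: int = 0
    cohort_csv: str | None = None
    synthetic: PhantomSpec | None = None
    output_dir: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("synthetic") is not None:
            syn = dict(d["synthetic"])
            if "shape" in syn:
                syn["shape"] = tuple(syn["shape"])
            d["synthetic"] = PhantomSpec(**syn)
        for key in ("displacements", "strides"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        if d.get("angle_groups") is not None:
            d["angle_groups"] = tuple(
                (int(g[0]), bool(g[1])) for g in d["angle_groups"]
            )
        if isinstance(d.get("range_policy"), (list, tuple)):
            d["range_policy"] = tuple(d["range_policy"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_cohort(cohort_csv: str | Path) -> list[Lesion]:
    """Read a cohort table of (lesion_id, volume, mask, label) rows."""
    table = pd.read_csv(cohort_csv)
    required = {"lesion_id", "volume", "mask", "label"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort table must have columns {sorted(required)}")
    base = Path(cohort_csv).parent
    lesions = []
    for row in table.itertuples(index=False):
        vol = load_volume(base / str(row.volume))
        mask = load_mask(base / str(row.mask))
        if vol.shape != mask.shape:
            raise ValueError(f"shape mismatch for lesion {row.lesion_id}")
        lesions.append(
            Lesion(
                volume=vol,
                mask=mask,
                label=int(row.label),
                lesion_id=str(row.lesion_id),
            )
        )
    return lesions


def extract_features(
    lesions: list[Lesion],
    displacement: int,
    stride: int,
    angle_group: tuple[int, bool] = (1, False),
    Ng: int = 32,
    range_policy: str | tuple[float, float] = "voi-minmax",
    cleanse_threshold: float | None = None,
    symmetrize: bool = True,
) -> pd.DataFrame:
    """One descriptor row per lesion for a single (d, s, angle-group)
    configuration.  Columns: lesion_id, label, then
    ``{direction_index}_{measure_name}``."""
    dims = lesions[0].volume.ndim
    directions = enumerate_directions(dims, angle_group[0], angle_group[1])
    names = descriptor_feature_names(directions)
    rows = []
    for les in lesions:
        mask = les.mask
        if cleanse_threshold is not None:
            mask, removed = air_cleanse(les.volume, mask, cleanse_threshold)
            if removed:
                logger.info("lesion %s: %d air voxels removed", les.lesion_id, removed)
        qv = quantize(les.volume, mask, Ng, range_policy)
        desc = msglcm_descriptor(
            qv,
            directions,
            displacement=displacement,
            stride=stride,
            lesion_id=les.lesion_id,
            symmetrize=symmetrize,
        )
        rows.append(
            {"lesion_id": les.lesion_id, "label": les.label}
            | dict(zip(names, desc.values))
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, dict]:
    """Execute the full study for every configuration in the scheme grid.

    Returns ``{config_tag: summary_dict}``; when ``config.output_dir`` is
    set, also writes one per-iteration metrics CSV per configuration and
    an overall ``summary.json``.
    """
    if (config.cohort_csv is None) == (config.synthetic is None):
        raise ValueError("exactly one of cohort_csv or synthetic must be set")
    lesions = (
        generate_cohort(config.synthetic)
        if config.synthetic is not None
        else load_cohort(config.cohort_csv)
    )
    labels = np.array([l.label for l in lesions])
    logger.info("cohort: %d lesions (%d malignant)", len(labels), labels.sum())

    grid = build_scheme_grid(
        SchemeConfig(
            scheme=Scheme(config.scheme),
            displacements=config.displacements,
            strides=config.strides,
            angle_groups=config.angle_groups,
            Ng=config.Ng,
        )
    )
    plan = SplitPlan.generate(
        labels,
        n_iterations=config.n_iterations,
        n_train_benign=config.n_train_benign,
        n_train_malignant=config.n_train_malignant,
        seed=config.seed,
    )
    params = EnsembleParams(
        n_trees=config.n_trees,
        max_subset_size=config.max_subset_size,
        mode=config.mode,
    )
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    summaries: dict[str, dict] = {}
    for tag, pars in grid:
        logger.info("configuration %s", tag)
        table = extract_features(
            lesions,
            displacement=pars["displacement"],
            stride=pars["stride"],
            angle_group=pars["angle_group"],
            Ng=pars["Ng"],
            range_policy=config.range_policy,
            cleanse_threshold=config.cleanse_threshold,
            symmetrize=pars["symmetrize"],
        )
        feats = table.drop(columns=["lesion_id", "label"]).to_numpy()
        result = evaluate_scheme(feats, labels, plan, params)
        summaries[tag] = result.summary()
        if out_dir:
            write_features(table, out_dir / f"features_{tag}.csv")
            pd.DataFrame(
                {
                    "auc": result.auc,
                    "accuracy": result.accuracy,
                    "sensitivity": result.sensitivity,
                    "specificity": result.specificity,
                }
            ).to_csv(out_dir / f"metrics_{tag}.csv", index=False)
    if out_dir:
        with open(out_dir / "summary.json", "w") as fh:
            json.dump(summaries, fh, indent=2, sort_keys=True)
        (out_dir / "config.yaml").write_text(
            yaml.safe_dump(config.to_dict(), sort_keys=False)
        )
    return summaries
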