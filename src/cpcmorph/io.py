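"""NIfTI, manifest, and configuration plumbing for the CLI pipeline."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from cpcmorph.cpc import CpcConfig, CpcVolume, ELEMENT_NAMES
from cpcmorph.phantom import TISSUES, ProbabilityMapSet
from cpcmorph.voi import LabelVolume

TISSUE_FILENAMES = {"g": "gm", "w": "wm", "c": "csf", "b": "bg"}

MANIFEST_COLUMNS = ["subject_id", "group"] + [
    f"{TISSUE_FILENAMES[t]}_{tp}" for tp in ("t", "tt") for t in TISSUES
]


@dataclass
class PipelineConfig:
    """Numeric defaults for the whole pipeline; round-trips through YAML."""

    prob_threshold: float = 0.2
    cpc_cap: float = 5.0
    neighborhood_radius: int = 1
    min_valid_voxels: int = 14
    n_folds: int = 15
    ratio_method: str = "mean_of_ratios"

    def cpc_config(self) -> CpcConfig:
        return CpcConfig(
            prob_threshold=self.prob_threshold,
            cpc_cap=self.cpc_cap,
            neighborhood_radius=self.neighborhood_radius,
            min_valid_voxels=self.min_valid_voxels,
        )


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def _identity_nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))


def save_probability_maps(
    maps: ProbabilityMapSet, out_dir: str | Path, prefix: str
) -> dict[str, str]:
    """Write one uncompressed NIfTI per tissue channel; returns tissue -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for k, tissue in enumerate(TISSUES):
        path = out_dir / f"{prefix}_{TISSUE_FILENAMES[tissue]}.nii"
        nib.save(_identity_nifti(maps.data[k]), path)
        paths[tissue] = str(path)
    return paths


def load_probability_maps(paths: dict[str, str | Path], timepoint_tag: str = "t") -> ProbabilityMapSet:
    """Load four per-tissue volumes (g, w, c, b) into one map set."""
    data = []
    for tissue in TISSUES:
        img = nib.load(str(paths[tissue]))
        arr = np.asarray(img.dataobj, dtype=np.float64)
        if arr.ndim == 4 and arr.shape[-1] == 1:
            arr = arr[..., 0]
        data.append(arr)
    stack = np.stack(data, axis=0)
    validity = np.ones(stack.shape[1:], dtype=bool)
    return ProbabilityMapSet(stack, validity, timepoint_tag=timepoint_tag)


def save_cpc_volume(cpc: CpcVolume, out_dir: str | Path, subject_id: str) -> dict[str, str]:
    """4-D element volume + validity mask + JSON sidecar recording config."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol_path = out_dir / f"{subject_id}_cpc.nii"
    mask_path = out_dir / f"{subject_id}_cpc_mask.nii"
    sidecar_path = out_dir / f"{subject_id}_cpc.json"
    nib.save(_identity_nifti(np.moveaxis(cpc.channels, 0, -1)), vol_path)
    nib.save(_identity_nifti(cpc.validity_mask.astype(np.uint8)), mask_path)
    from cpcmorph import __version__

    sidecar = {
        "software": "cpcmorph",
        "version": __version__,
        "channel_order": list(ELEMENT_NAMES),
        "config": {
            "prob_threshold": cpc.config_used.prob_threshold,
            "cpc_cap": cpc.config_used.cpc_cap,
            "neighborhood_radius": cpc.config_used.neighborhood_radius,
            "min_valid_voxels": cpc.config_used.min_valid_voxels,
        },
        "n_valid_voxels": int(cpc.validity_mask.sum()),
    }
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return {"volume": str(vol_path), "mask": str(mask_path), "sidecar": str(sidecar_path)}


def load_cpc_volume(out_dir: str | Path, subject_id: str) -> CpcVolume:
    out_dir = Path(out_dir)
    channels = np.moveaxis(
        np.asarray(nib.load(str(out_dir / f"{subject_id}_cpc.nii")).dataobj, dtype=np.float64),
        -1,
        0,
    )
    mask = (
        np.asarray(nib.load(str(out_dir / f"{subject_id}_cpc_mask.nii")).dataobj) > 0
    )
    sidecar = json.loads((out_dir / f"{subject_id}_cpc.json").read_text())
    config = CpcConfig(**sidecar["config"])
    return CpcVolume(channels, mask, config)


def save_label_volume(labels: LabelVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.int16), affine=np.eye(4))
    nib.save(img, str(path))
    names_path = Path(str(path)).with_suffix(".labels.json")
    names_path.write_text(json.dumps({str(k): v for k, v in labels.name_map.items()}))


def load_label_volume(path: str | Path) -> LabelVolume:
    arr = np.asarray(nib.load(str(path)).dataobj).astype(np.int32)
    names_path = Path(str(path)).with_suffix(".labels.json")
    name_map = {}
    if names_path.exists():
        name_map = {int(k): v for k, v in json.loads(names_path.read_text()).items()}
    return LabelVolume(arr, name_map)


def write_manifest(rows: list[dict], path: str | Path) -> None:
    df = pd.DataFrame(rows)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("subject_ids must be unique")
    df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if df["subject_id"].duplicated().any():
        raise ValueError("subject_ids must be unique")
    return df


def manifest_tissue_paths(row: pd.Series, timepoint: str) -> dict[str, str]:
    return {t: row[f"{TISSUE_FILENAMES[t]}_{timepoint}"] for t in TISSUES}
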