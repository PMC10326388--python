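"""File formats and configuration.

Volumes travel as NIfTI-1; nuisance series as TSV (one row per
acquisition); transforms as plain-text 4x4 matrices; tables as CSV whose
first line is a ``# config_hash=...`` comment so outputs from different
configurations are detectable; graphs as GraphML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import AffineTransform, AtlasVolume, BoldScan

__all__ = [
    "AnalysisConfig",
    "StudyManifest",
    "load_config",
    "config_hash",
    "save_atlas", "load_atlas",
    "save_scan", "load_scan",
    "save_transform", "load_transform",
    "save_table", "load_table",
    "save_graphml",
]


@dataclass
class AnalysisConfig:
    """All analysis knobs in one typed record.

    Defaults follow the standard design: windows [5,45]/[300,345], q = 0.2,
    c(V) = 1, 1% magnitude gate, |Z| = 2.3, k = 5 neighbors.
    """

    baseline_window: tuple[int, int] = (5, 45)
    response_window: tuple[int, int] = (300, 345)
    fdr_q: float = 0.2
    c_v: float = 1.0
    magnitude_threshold_pct: float = 1.0
    magnitude_as_alpha: bool = False
    z_cutoff: float = 2.3
    knn_k: int = 5
    seed: int = 0
    slice_timing: bool = False
    per_roi_fdr: bool = False
    threshold_before_degree: bool = True
    smooth_fwhm_mm: float = 0.8
    bandpass_low_hz: float = 0.01
    bandpass_high_hz: float = 0.1
    motion_outlier_z: float = 5.0
    posthoc_fdr_q: float = 0.05
    schema_version: int = 1


_CONFIG_FIELDS = {f.name for f in AnalysisConfig.__dataclass_fields__.values()}  # type: ignore[attr-defined]


def load_config(path: str | Path) -> AnalysisConfig:
    """Load a flat key-value YAML config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value mapping")
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("baseline_window", "response_window"):
        if key in raw:
            raw[key] = tuple(int(v) for v in raw[key])
    return AnalysisConfig(**raw)


def save_config(cfg: AnalysisConfig, path: str | Path) -> None:
    d = asdict(cfg)
    d["baseline_window"] = list(d["baseline_window"])
    d["response_window"] = list(d["response_window"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def config_hash(cfg: AnalysisConfig) -> str:
    """Stable short hash of the canonicalized configuration."""
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyManifest:
    """Index of a study's subjects and shared resources."""

    subjects: pd.DataFrame  # subject_id, group, scan_path, transform_path, seed
    atlas_path: str
    region_names_path: str = ""
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        required = {"subject_id", "group", "scan_path"}
        missing = required - set(self.subjects.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.subjects["subject_id"].duplicated().any():
            dup = self.subjects.loc[self.subjects["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids: {dup.tolist()}")

    def save(self, path: str | Path) -> None:
        self.subjects.to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, atlas_path: str, config: AnalysisConfig | None = None) -> "StudyManifest":
        return cls(
            subjects=pd.read_csv(path),
            atlas_path=atlas_path,
            config=config or AnalysisConfig(),
        )


def _affine_from_voxel_size(voxel_size) -> np.ndarray:
    aff = np.diag(list(voxel_size) + [1.0])
    return aff


def save_atlas(atlas: AtlasVolume, path: str | Path, names_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine_from_voxel_size(atlas.voxel_size))
    nib.save(img, str(path))
    if names_path is not None:
        pd.DataFrame(
            {"region_id": list(atlas.region_names), "region_name": list(atlas.region_names.values())}
        ).to_csv(names_path, index=False)


def load_atlas(path: str | Path, names_path: str | Path | None = None) -> AtlasVolume:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    names = {}
    if names_path is not None:
        df = pd.read_csv(names_path)
        names = dict(zip(df["region_id"].astype(int), df["region_name"].astype(str)))
    return AtlasVolume(labels=labels, voxel_size=voxel_size, region_names=names)


def save_scan(scan: BoldScan, path: str | Path, nuisance_path: str | Path | None = None) -> None:
    img = nib.Nifti1Image(
        scan.data.astype(np.float32), _affine_from_voxel_size(scan.voxel_size)
    )
    img.header["pixdim"][4] = scan.tr_seconds
    nib.save(img, str(path))
    if nuisance_path is not None:
        cols = {"outlier_flag": scan.outlier_flags.astype(int)}
        if scan.motion_params is not None:
            for i in range(6):
                cols[f"motion_{i}"] = scan.motion_params[:, i]
        for name, series in scan.tissue_means.items():
            cols[name] = np.asarray(series)
        pd.DataFrame(cols).to_csv(nuisance_path, sep="\t", index=False)


def load_scan(
    path: str | Path,
    mask: np.ndarray | None = None,
    nuisance_path: str | Path | None = None,
    subject_id: str = "",
) -> BoldScan:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(float)
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    if mask is None:
        mask = data.std(axis=3) > 0
    motion = None
    flags = None
    tissue: dict[str, np.ndarray] = {}
    if nuisance_path is not None:
        df = pd.read_csv(nuisance_path, sep="\t")
        flags = df["outlier_flag"].to_numpy(bool) if "outlier_flag" in df else None
        mcols = [f"motion_{i}" for i in range(6)]
        if all(c in df for c in mcols):
            motion = df[mcols].to_numpy(float)
        for name in ("white_matter", "csf"):
            if name in df:
                tissue[name] = df[name].to_numpy(float)
    return BoldScan(
        data=data, tr_seconds=tr, mask=mask, motion_params=motion,
        outlier_flags=flags, tissue_means=tissue,
        voxel_size=tuple(float(z) for z in zooms[:3]), subject_id=subject_id,
    )


def save_transform(transform: AffineTransform, path: str | Path) -> None:
    np.savetxt(path, transform.matrix, fmt="%.12g")


def load_transform(path: str | Path) -> AffineTransform:
    return AffineTransform(np.loadtxt(path))


def save_table(df: pd.DataFrame, path: str | Path, cfg: AnalysisConfig | None = None) -> None:
    """CSV with a leading config-hash comment line for provenance."""
    tag = config_hash(cfg) if cfg is not None else "unconfigured"
    with open(path, "w") as fh:
        fh.write(f"# config_hash={tag}\n")
        df.to_csv(fh, index=False)


def load_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def save_graphml(network, path: str | Path, cfg: AnalysisConfig | None = None) -> None:
    import networkx as nx

    G = network.to_networkx()
    G.graph["threshold"] = float(network.threshold)
    if cfg is not None:
        G.graph["config_hash"] = config_hash(cfg)
    nx.write_graphml(G, str(path))
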