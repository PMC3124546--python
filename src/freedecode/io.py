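"""NIfTI / TSV / config serialization.

BOLD runs travel as 4D float32 NIfTI-1 with the TR in the fourth zoom;
event tables as plain TSV with onsets in 6-decimal fixed point; pipeline
configuration as YAML or JSON that round-trips losslessly and rejects
unknown keys.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synth import (
    EVENT_COLUMNS,
    BehaviorConfig,
    BOLDRun,
    EventTable,
    SignalConfig,
    VolumeLayout,
)

__all__ = [
    "read_bold",
    "write_bold",
    "read_mask",
    "write_mask",
    "read_events",
    "write_events",
    "PipelineConfig",
    "read_config",
    "write_config",
]


def write_bold(run: BOLDRun, path: str | Path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    zooms = img.header.get_zooms()[:3] + (run.tr,)
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def read_bold(path: str | Path, mask: np.ndarray | None = None, run_id: int = 0) -> BOLDRun:
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got {img.ndim}D")
    tr = float(img.header.get_zooms()[3])
    if tr <= 0:
        raise ValueError(f"{path}: TR missing from the time-axis header field")
    data = np.asarray(img.dataobj, dtype=np.float32)
    if mask is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    elif mask.shape != data.shape[:3]:
        raise ValueError(
            f"{path}: mask grid {mask.shape} does not match image grid {data.shape[:3]}"
        )
    return BOLDRun(run_id=run_id, data=data, tr=tr, mask=mask, affine=np.asarray(img.affine))


def write_mask(mask: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask image, got {img.ndim}D")
    return np.asarray(img.dataobj) > 0


def write_events(events: EventTable, path: str | Path) -> None:
    df = events.trials.copy()
    for col in ("onset", "probe_onset"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    df["valid"] = df["valid"].astype(int)
    df.to_csv(path, sep="\t", index=False, columns=EVENT_COLUMNS)


def read_events(path: str | Path, run_id: int = 0) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["choice"] not in ("left", "right"):
            raise ValueError(f"{path}:{line}: unknown choice token {row['choice']!r}")
        if row["probe_side"] not in ("left", "right"):
            raise ValueError(f"{path}:{line}: unknown probe_side token {row['probe_side']!r}")
        if int(row["letter_offset"]) not in (0, -1):
            raise ValueError(f"{path}:{line}: letter_offset must be 0 or -1")
    onsets = df["onset"].to_numpy(float)
    bad = np.flatnonzero(np.diff(onsets) <= 0)
    if bad.size:
        raise ValueError(f"{path}:{bad[0] + 3}: onsets not strictly increasing")
    df["valid"] = df["valid"].astype(bool)
    df["letter_offset"] = df["letter_offset"].astype(int)
    df["onset"] = df["onset"].astype(float)
    df["probe_onset"] = df["probe_onset"].astype(float)
    return EventTable(run_id=run_id, trials=df[EVENT_COLUMNS])


def write_accuracy_maps(stack_4d: np.ndarray, path: str | Path, tr: float = 1.5) -> None:
    """Per-subject accuracy maps as one 4D NIfTI (one volume per time-bin)."""
    img = nib.Nifti1Image(stack_4d.astype(np.float32), np.eye(4))
    img.header.set_zooms(img.header.get_zooms()[:3] + (tr,))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))


def write_betas(betas, out_dir: str | Path) -> None:
    """FIR estimates as one 4D NIfTI per condition (20 volumes = 20 bins)
    plus a JSON sidecar with run metadata."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_bins = betas.beta.shape[1]
    for ci, cond in enumerate(betas.conditions):
        vol = np.full(betas.mask.shape + (n_bins,), np.nan, dtype=np.float32)
        flat = vol.reshape(-1, n_bins)
        flat[betas.mask_index] = betas.beta[ci].T
        nib.save(
            nib.Nifti1Image(vol, np.eye(4)),
            str(out_dir / f"run-{betas.run_id:02d}_{cond}_beta.nii.gz"),
        )
    meta = {
        "run_id": betas.run_id,
        "conditions": list(betas.conditions),
        "n_bins": n_bins,
        "dof": betas.dof,
    }
    (out_dir / f"run-{betas.run_id:02d}_beta.json").write_text(json.dumps(meta, indent=2))


@dataclasses.dataclass(frozen=True)
class InferenceConfig:
    fwhm_mm: float = 3.0
    q: float = 0.05
    extent: int = 5


@dataclasses.dataclass(frozen=True)
class SearchlightConfig:
    radius: float = 3.0
    C: float = 1.0
    min_in_mask_fraction: float = 0.5
    bins: tuple[int, ...] | None = None


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Complete, serializable description of one pipeline execution."""

    n_subjects: int = 6
    seed: int = 0
    behavior: BehaviorConfig = BehaviorConfig()
    signal: SignalConfig = SignalConfig()
    layout: VolumeLayout = VolumeLayout()
    searchlight: SearchlightConfig = SearchlightConfig()
    inference: InferenceConfig = InferenceConfig()
    out_dir: str = "freedecode_out"
    verbosity: str = "INFO"

    def to_dict(self) -> dict:
        # via JSON so tuples become lists (YAML cannot represent tuples)
        return json.loads(json.dumps(dataclasses.asdict(self)))


_SECTION_TYPES = {
    "behavior": BehaviorConfig,
    "signal": SignalConfig,
    "layout": VolumeLayout,
    "searchlight": SearchlightConfig,
    "inference": InferenceConfig,
}


def _build_section(cls, data: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown keys in {cls.__name__}: {sorted(unknown)}")
    # YAML/JSON lists back to the tuples the dataclasses expect
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**coerced)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    sections = {}
    for name, cls in _SECTION_TYPES.items():
        if name in data:
            sections[name] = _build_section(cls, data.pop(name))
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)} - set(_SECTION_TYPES)
    unknown = set(data) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    return PipelineConfig(**data, **sections)


def read_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return config_from_dict(data or {})


def write_config(cfg: PipelineConfig, path: str | Path) -> None:
    data = cfg.to_dict()
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(data, indent=2))
    else:
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
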