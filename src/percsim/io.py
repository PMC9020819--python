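"""Readers, writers, configuration, and run manifests.

All tabular outputs are tidy CSVs (one observation per row). Voxel
patterns are stored as a portable ``.npz`` container with a JSON sidecar
index describing the trial rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import StudyConfig
from .synthetic import (
    NeuralPatternSet,
    PerfParams,
    RegionSpec,
    StructureParams,
)

RDM_COLUMNS = ["observer", "category", "exemplar_i", "exemplar_j", "raw", "percentile"]


class SchemaError(ValueError):
    """A file or config does not match its expected schema."""


# ---------------------------------------------------------------- CSV round trips


def write_arrangements_csv(arrangements: pd.DataFrame, path: Path | str) -> None:
    cols = ["observer", "category", "exemplar", "x", "y"]
    arrangements[cols].to_csv(path, index=False, float_format="%.12g")


def read_arrangements_csv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["observer", "category", "exemplar", "x", "y"], path)
    return df


def write_trials_csv(trials: dict[int, pd.DataFrame], path: Path | str) -> None:
    frames = []
    for observer, frame in sorted(trials.items()):
        f = frame.copy()
        f.insert(0, "observer", observer)
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trials_csv(path: Path | str) -> dict[int, pd.DataFrame]:
    df = pd.read_csv(path)
    _require_columns(
        df, ["observer", "run", "position", "category", "exemplar", "trial_type"], path
    )
    return {
        int(o): grp.drop(columns="observer").reset_index(drop=True)
        for o, grp in df.groupby("observer")
    }


def write_behaviour_csv(behaviour: dict[int, pd.DataFrame], path: Path | str) -> None:
    pd.concat(
        [behaviour[o] for o in sorted(behaviour)], ignore_index=True
    ).to_csv(path, index=False, float_format="%.12g")


def read_behaviour_csv(path: Path | str) -> dict[int, pd.DataFrame]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["observer", "run", "position", "category", "exemplar", "trial_type",
         "response", "rt"],
        path,
    )
    return {int(o): grp.reset_index(drop=True) for o, grp in df.groupby("observer")}


def write_rdm_csv(rdms: pd.DataFrame | list[pd.DataFrame], path: Path | str) -> None:
    """Write one or more long-form RDM frames (optionally with region/level)."""
    frame = (
        pd.concat(rdms, ignore_index=True)
        if isinstance(rdms, list)
        else rdms
    )
    cols = [c for c in ["observer", "region"] + RDM_COLUMNS[1:] + ["level"]
            if c in frame.columns]
    frame[cols].to_csv(path, index=False, float_format="%.17g")


def read_rdm_csv(path: Path | str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(
        df, ["category", "exemplar_i", "exemplar_j", "raw", "percentile"], path
    )
    return df


def split_rdms(frame: pd.DataFrame) -> dict[int, pd.DataFrame]:
    """Split a stacked RDM CSV frame into per-observer frames."""
    if "observer" not in frame.columns:
        raise SchemaError("stacked RDM frame lacks an 'observer' column")
    return {
        int(o): grp.reset_index(drop=True) for o, grp in frame.groupby("observer")
    }


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------- pattern container


def write_patterns(
    patterns: dict[tuple[int, str], NeuralPatternSet], directory: Path | str
) -> None:
    """Store pattern sets as <dir>/patterns.npz plus a JSON sidecar index."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    index = {}
    for (observer, region), pset in sorted(patterns.items()):
        key = f"obs{observer}__{region}"
        arrays[key] = pset.data
        index[key] = {
            "observer": observer,
            "region": region,
            "trials": pset.trials.to_dict(orient="list"),
        }
    np.savez_compressed(directory / "patterns.npz", **arrays)
    (directory / "patterns.json").write_text(json.dumps(index))


def read_patterns(directory: Path | str) -> dict[tuple[int, str], NeuralPatternSet]:
    directory = Path(directory)
    index = json.loads((directory / "patterns.json").read_text())
    arrays = np.load(directory / "patterns.npz")
    out = {}
    for key, meta in index.items():
        trials = pd.DataFrame(meta["trials"])
        out[(meta["observer"], meta["region"])] = NeuralPatternSet(
            observer=meta["observer"],
            region=meta["region"],
            trials=trials,
            data=arrays[key],
        )
    return out


# ---------------------------------------------------------------- configuration


@dataclass(frozen=True)
class AnalysisParams:
    """Statistical-analysis settings of a pipeline run."""

    min_gap: float = 0.1
    n_perm: int = 1000
    alpha: float = 0.05
    run_decoding: bool = True
    svm_c: float = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    study: StudyConfig = field(default_factory=StudyConfig)
    structure: StructureParams = field(default_factory=StructureParams)
    perf: PerfParams = field(default_factory=PerfParams)
    regions: tuple[RegionSpec, ...] = ()
    analysis: AnalysisParams = field(default_factory=AnalysisParams)


_SECTIONS = {
    "study": StudyConfig,
    "structure": StructureParams,
    "perf": PerfParams,
    "analysis": AnalysisParams,
}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"unknown keys in config section '{section}': {sorted(unknown)}")
    data = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**data)


def load_config(path: Path | str) -> PipelineConfig:
    """Load and validate a pipeline configuration from YAML.

    Unknown sections or keys are rejected rather than ignored.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(data) - set(_SECTIONS) - {"regions"}
    if unknown:
        raise SchemaError(f"unknown config sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        kwargs[section] = _build_section(cls, data.get(section, {}) or {}, section)
    regions = tuple(
        _build_section(RegionSpec, r, "regions") for r in data.get("regions", [])
    )
    return PipelineConfig(regions=regions, **kwargs)


def dump_config(config: PipelineConfig, path: Path | str) -> None:
    data = {
        "study": dataclasses.asdict(config.study),
        "structure": dataclasses.asdict(config.structure),
        "perf": dataclasses.asdict(config.perf),
        "analysis": dataclasses.asdict(config.analysis),
        "regions": [dataclasses.asdict(r) for r in config.regions],
    }
    data["structure"]["spacings"] = list(data["structure"]["spacings"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------- run manifest


def file_sha256(path: Path | str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    directory: Path | str,
    stage: str,
    config: PipelineConfig,
    inputs: list[Path | str] | None = None,
    version: str = "0.1.0",
) -> Path:
    """Record what produced an output directory.

    The manifest holds the stage name, a hash of the full configuration and
    of every input file, and the package version — enough to decide whether
    a rerun would reproduce the directory byte for byte. Wall-clock
    timestamps are deliberately omitted so reruns are idempotent.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg_repr = json.dumps(
        {
            "study": dataclasses.asdict(config.study),
            "structure": dataclasses.asdict(config.structure),
            "perf": dataclasses.asdict(config.perf),
            "analysis": dataclasses.asdict(config.analysis),
            "regions": [dataclasses.asdict(r) for r in config.regions],
        },
        sort_keys=True,
        default=str,
    )
    manifest = {
        "stage": stage,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "inputs": {str(p): file_sha256(p) for p in (inputs or [])},
        "package_version": version,
    }
    out = directory / f"manifest_{stage}.json"
    out.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
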