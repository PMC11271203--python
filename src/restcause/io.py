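"""Text I/O, configuration, and dataset persistence.

The canonical on-disk dialect is TSV (UTF-8, '.' decimal separator): one
T x K time-course matrix per subject with a header of component ids, one
S x T global-signal table, and K x K causality matrices carrying a
convention comment line so a transposed file can never be consumed silently.
Floats are written with ``repr`` so a read/write round trip is bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .directionality import RegionLabelMap
from .synthetic import ComponentTimeSeriesSet, GlobalSignalSet, GroundTruth

logger = logging.getLogger(__name__)

ROW_SOURCE = "row=source,col=target"
ROW_TARGET = "row=target,col=source"


def _fmt(value: float) -> str:
    return repr(float(value))


def _parse_float(token: str, path, line_no: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise ValueError(f"{path}:{line_no}: non-numeric cell {token!r}") from None


# ---------------------------------------------------------------- time series

def write_timeseries(path, data: np.ndarray, component_ids) -> None:
    """Write one subject's T x K matrix; header = component ids."""
    data = np.asarray(data, dtype=float)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(str(c) for c in component_ids) + "\n")
        for row in data:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_timeseries(path) -> tuple[np.ndarray, list[int]]:
    """Read a T x K time-course TSV; returns (matrix, component ids)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ValueError(f"{path}:1: empty time-series file")
    header = lines[0].split("\t")
    try:
        component_ids = [int(c) for c in header]
    except ValueError:
        raise ValueError(f"{path}:1: malformed header {lines[0]!r}") from None
    rows = []
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(component_ids):
            raise ValueError(
                f"{path}:{i}: ragged row ({len(cells)} cells, expected {len(component_ids)})"
            )
        rows.append([_parse_float(c, path, i) for c in cells])
    return np.array(rows, dtype=float), component_ids


# ------------------------------------------------------------------- matrices

def write_matrix(path, coeffs: np.ndarray, order: int = 1, ridge: float = 0.0,
                 convention: str = ROW_SOURCE) -> None:
    """Write a K x K causality matrix with its convention header."""
    coeffs = np.asarray(coeffs, dtype=float)
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# convention: {convention}; order={order}; ridge={_fmt(ridge)}\n")
        for row in coeffs:
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def read_matrix(path) -> tuple[np.ndarray, dict]:
    """Read a K x K matrix TSV, transposing if the header is target-major."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ValueError(f"{path}:1: missing convention header line")
    meta: dict = {"convention": ROW_SOURCE, "order": 1, "ridge": 0.0}
    for part in lines[0].lstrip("# ").split(";"):
        key, _, value = part.strip().partition(":")
        if not value:
            key, _, value = part.strip().partition("=")
        key, value = key.strip(), value.strip()
        if key == "convention":
            meta["convention"] = value
        elif key == "order":
            meta["order"] = int(value)
        elif key == "ridge":
            meta["ridge"] = float(value)
    rows = []
    width = None
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(f"{path}:{i}: ragged row ({len(cells)} cells, expected {width})")
        rows.append([_parse_float(c, path, i) for c in cells])
    coeffs = np.array(rows, dtype=float)
    if coeffs.shape[0] != coeffs.shape[1]:
        raise ValueError(f"{path}: matrix is {coeffs.shape[0]}x{coeffs.shape[1]}, not square")
    if meta["convention"] == ROW_TARGET:
        logger.info("%s stores col=source; transposing to the source-major convention", path)
        coeffs = coeffs.T
        meta["convention"] = ROW_SOURCE
    elif meta["convention"] != ROW_SOURCE:
        raise ValueError(f"{path}:1: unknown convention {meta['convention']!r}")
    return coeffs, meta


# ----------------------------------------------------------------- aggregates

def write_gs(path, gs: np.ndarray, subject_ids) -> None:
    """Write the S x T global-signal table, one row per subject."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("subject_id\t" + "\t".join(f"t{i}" for i in range(gs.shape[1])) + "\n")
        for sid, row in zip(subject_ids, gs):
            fh.write(str(sid) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_gs(path) -> GlobalSignalSet:
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject_id" not in frame.columns:
        raise ValueError(f"{path}:1: malformed header, expected a subject_id column")
    subject_ids = [str(s) for s in frame["subject_id"]]
    values = frame.drop(columns="subject_id").to_numpy(dtype=float)
    return GlobalSignalSet(gs=values, subject_ids=subject_ids)


def read_labels(path) -> RegionLabelMap:
    """Read a component label table (component_id, region, class)."""
    frame = pd.read_csv(Path(path), sep="\t")
    frame["component_id"] = frame["component_id"].astype(int)
    return RegionLabelMap(table=frame)


# ------------------------------------------------------------------- datasets

def save_dataset(
    out_dir,
    dataset: ComponentTimeSeriesSet,
    gs: GlobalSignalSet | None = None,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Persist a dataset: per-subject TSVs, global signals, truth, sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for s, sid in enumerate(dataset.subject_ids):
        write_timeseries(out_dir / f"{sid}_timeseries.tsv", dataset.data[s], dataset.component_ids)
    if gs is not None:
        write_gs(out_dir / "global_signal.tsv", gs.gs, gs.subject_ids)
    sidecar = {
        "n_subjects": dataset.n_subjects,
        "n_timepoints": dataset.n_timepoints,
        "n_components": dataset.n_components,
        "tr_seconds": dataset.tr_seconds,
        "subject_ids": list(dataset.subject_ids),
    }
    if ground_truth is not None:
        np.savetxt(out_dir / "ground_truth.tsv", ground_truth.true_matrix, delimiter="\t")
        sidecar.update(
            seed=int(ground_truth.seed),
            noise_sd=np.asarray(ground_truth.noise_sd).tolist(),
            gs_gain=np.asarray(ground_truth.gs_gain).tolist(),
            subject_jitter_sd=float(ground_truth.subject_jitter_sd),
        )
    (out_dir / "dataset.json").write_text(json.dumps(sidecar, indent=2), encoding="utf-8")
    return out_dir


def load_dataset(in_dir) -> ComponentTimeSeriesSet:
    """Load the per-subject time-course TSVs written by :func:`save_dataset`."""
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("*_timeseries.tsv"))
    if not paths:
        raise FileNotFoundError(f"no *_timeseries.tsv files in {in_dir}")
    mats, ids = [], None
    subject_ids = []
    for p in paths:
        mat, comp_ids = read_timeseries(p)
        if ids is None:
            ids = comp_ids
        elif comp_ids != ids:
            raise ValueError(f"{p}: component ids differ from the first subject's")
        mats.append(mat)
        subject_ids.append(p.name.removesuffix("_timeseries.tsv"))
    sidecar = in_dir / "dataset.json"
    tr = 2.5
    if sidecar.exists():
        tr = float(json.loads(sidecar.read_text(encoding="utf-8")).get("tr_seconds", 2.5))
    return ComponentTimeSeriesSet(
        data=np.stack(mats), tr_seconds=tr, subject_ids=subject_ids, component_ids=ids
    )


# ---------------------------------------------------------------------- NIfTI

def read_nifti_4d(path) -> np.ndarray:
    """Load a 4D NIfTI image as a voxels x time matrix (lazy nibabel import)."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got {data.ndim}D")
    return data.reshape(-1, data.shape[-1])


def read_nifti_maps(path) -> np.ndarray:
    """Load group spatial maps (4th axis = components) as voxels x K."""
    return read_nifti_4d(path)


# -------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """Validated pipeline settings; unknown keys are rejected (typo safety)."""

    ts_dir: str | None = None
    gs_path: str | None = None
    labels_path: str | None = None
    out_dir: str = "restcause_out"
    dualreg: bool = False
    gsr: bool = True
    gca: bool = True
    aggregate: bool = True
    report: bool = True
    fraction: float = 0.2
    rule: str = "value_threshold"
    approach: str = "absolute"
    ridge_lambda: float = 0.0
    seed: int = 0
    maps_path: str | None = None
    subjects_list: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.rule not in ("value_threshold", "rank_count"):
            raise ValueError(f"unknown rule {self.rule!r}")
        if self.approach not in ("split", "signed", "absolute"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
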