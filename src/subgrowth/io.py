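"""File I/O: cohort tables (TSV), ground truth and models (JSON), meshes (PLY).

All delimited output is tab-separated with a header; tables written by the
pipeline carry comment lines (``# key: value``) recording the config hash
and seed so every artifact is traceable to the run that produced it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .cohort import (
    AGE_MAX_DAYS,
    GrowthTruth,
    StructureCurve,
)
from .gamm import TrajectoryModel
from .meshes import MeshTruth
from .surface import CorrespondedMeshSeries

log = logging.getLogger(__name__)

__all__ = [
    "write_table",
    "read_cohort",
    "write_cohort",
    "write_truth",
    "read_truth",
    "write_mesh_series",
    "read_mesh_series",
    "save_model",
    "load_model",
]

REQUIRED_COLUMNS = ("subject_id", "age_days", "sex", "site", "icv")
_FLOAT_FMT = "%.10g"


def write_table(frame: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write a TSV with optional ``# key: value`` comment header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (header or {}).items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_cohort(records: pd.DataFrame, path, header=None) -> None:
    write_table(records, path, header)


def read_cohort(path, allow_extended: bool = False) -> pd.DataFrame:
    """Read and validate a cohort table (one scan per row, TSV).

    Checks the documented mandatory columns, integer ages inside the study
    span (0-810 days unless ``allow_extended``), known sex levels, positive
    volumes/ICV and uniqueness of (subject, age).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", comment="#")
    if frame.empty:
        raise ValueError(f"no records in {path}")
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s) {missing} in {path}")
    frame["age_days"] = frame["age_days"].round().astype(int)
    if not allow_extended:
        bad = frame[(frame.age_days < 0) | (frame.age_days > AGE_MAX_DAYS)]
        if len(bad):
            raise ValueError(
                f"{len(bad)} record(s) outside the 0-{AGE_MAX_DAYS}-day span "
                "(pass allow_extended to accept)"
            )
    bad_sex = set(frame["sex"].unique()) - {"male", "female"}
    if bad_sex:
        raise ValueError(f"unknown sex level(s) {sorted(bad_sex)}")
    dup = frame.duplicated(subset=["subject_id", "age_days"])
    if dup.any():
        pair = frame.loc[dup, ["subject_id", "age_days"]].iloc[0]
        raise ValueError(
            f"duplicate (subject, age): {pair.subject_id} at "
            f"{pair.age_days} days"
        )
    vol_cols = [c for c in frame.columns if c.startswith("vol_")]
    if vol_cols and (frame[vol_cols].to_numpy() <= 0).any():
        raise ValueError("nonpositive volume found in cohort table")
    if (frame["icv"].to_numpy() <= 0).any():
        raise ValueError("nonpositive icv found in cohort table")
    return frame


# --------------------------------------------------------------------------- #
# ground truth JSON
# --------------------------------------------------------------------------- #

def _truth_to_dict(truth: GrowthTruth) -> dict:
    d = {
        "curves": {
            f"{s}_{h}": {"family": c.family, "params": c.params}
            for (s, h), c in truth.curves.items()
        },
        "sex_gain": truth.sex_gain,
        "site_offsets": truth.site_offsets,
        "icv_curve": {
            "family": truth.icv_curve.family,
            "params": truth.icv_curve.params,
        },
        "icv_coefficient": truth.icv_coefficient,
        "behavior_effects": {
            f"{s}|{score}": v for (s, score), v in truth.behavior_effects.items()
        },
        "behavior_noise_sd": truth.behavior_noise_sd,
        "behavior_subject_sd": truth.behavior_subject_sd,
    }
    if truth.mesh_truth is not None:
        mt = truth.mesh_truth
        d["mesh_truth"] = {
            "structure": mt.structure,
            "hemisphere": mt.hemisphere,
            "n_vertices": mt.n_vertices,
            "high_vertices": np.asarray(mt.high_vertices).tolist(),
            "low_vertices": np.asarray(mt.low_vertices).tolist(),
            "high_mult": mt.high_mult,
            "low_mult": mt.low_mult,
            "base_radius": mt.base_radius,
            "multiplier": (
                np.asarray(mt.multiplier).tolist()
                if mt.multiplier is not None
                else None
            ),
        }
    return d


def write_truth(truth: GrowthTruth, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_truth_to_dict(truth), indent=1))


def read_truth(path) -> GrowthTruth:
    d = json.loads(Path(path).read_text())
    curves = {}
    for key, c in d["curves"].items():
        s, h = key.rsplit("_", 1)
        curves[(s, h)] = StructureCurve(c["family"], c["params"])
    truth = GrowthTruth(
        curves=curves,
        sex_gain=d["sex_gain"],
        site_offsets=d["site_offsets"],
        icv_curve=StructureCurve(
            d["icv_curve"]["family"], d["icv_curve"]["params"]
        ),
        icv_coefficient=d["icv_coefficient"],
        behavior_effects={
            tuple(k.split("|")): v for k, v in d["behavior_effects"].items()
        },
        behavior_noise_sd=d["behavior_noise_sd"],
        behavior_subject_sd=d["behavior_subject_sd"],
    )
    if d.get("mesh_truth"):
        m = d["mesh_truth"]
        truth.mesh_truth = MeshTruth(
            structure=m["structure"],
            hemisphere=m["hemisphere"],
            n_vertices=m["n_vertices"],
            high_vertices=np.asarray(m["high_vertices"], dtype=int),
            low_vertices=np.asarray(m["low_vertices"], dtype=int),
            high_mult=m["high_mult"],
            low_mult=m["low_mult"],
            base_radius=m["base_radius"],
            multiplier=(
                np.asarray(m["multiplier"])
                if m.get("multiplier") is not None
                else None
            ),
        )
    return truth


# --------------------------------------------------------------------------- #
# meshes (PLY primary, OFF accepted on read)
# --------------------------------------------------------------------------- #

def _ascii_ply(vertices: np.ndarray, faces: np.ndarray) -> str:
    """ASCII PLY text with full double precision (lossless round-trip)."""
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {len(vertices)}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {len(faces)}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in faces]
    return "\n".join(lines) + "\n"


def write_mesh_series(series: CorrespondedMeshSeries, directory) -> None:
    """One ASCII PLY per scan (scan_<i>.ply) plus a meta.tsv with metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i in range(series.n_scans):
        (directory / f"scan_{i:04d}.ply").write_text(
            _ascii_ply(series.vertices[i], series.faces)
        )
    meta = series.meta.copy()
    meta.insert(0, "mesh_file", [f"scan_{i:04d}.ply"
                                 for i in range(series.n_scans)])
    write_table(meta, directory / "meta.tsv")


def read_mesh_series(directory) -> CorrespondedMeshSeries:
    """Read a mesh series; triangulations must be byte-identical."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "meta.tsv", sep="\t", comment="#")
    faces = None
    verts = []
    for _, row in meta.iterrows():
        fp = directory / row["mesh_file"]
        if not fp.exists():
            raise FileNotFoundError(f"mesh file {fp} listed in meta.tsv missing")
        mesh = trimesh.load(str(fp), process=False)
        f = np.asarray(mesh.faces, dtype=int)
        if faces is None:
            faces = f
        elif f.shape != faces.shape or not np.array_equal(f, faces):
            raise ValueError(
                f"triangulation of {fp.name} does not match the first mesh"
            )
        verts.append(np.asarray(mesh.vertices, dtype=float))
    if faces is None:
        raise ValueError(f"no meshes listed in {directory}/meta.tsv")
    return CorrespondedMeshSeries(
        faces=faces, vertices=np.stack(verts), meta=meta.drop(columns="mesh_file")
    )


def write_vertex_field(values, path, labels=None, header=None) -> None:
    """Per-vertex scalar field (and optional labels) as a TSV."""
    frame = pd.DataFrame({"vertex": np.arange(len(values)), "value": values})
    if labels is not None:
        frame["label"] = labels
    write_table(frame, path, header)


# --------------------------------------------------------------------------- #
# model JSON
# --------------------------------------------------------------------------- #

def save_model(model: TrajectoryModel, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(model.to_dict()))


def load_model(path) -> TrajectoryModel:
    return TrajectoryModel.from_dict(json.loads(Path(path).read_text()))
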