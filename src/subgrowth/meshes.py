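"""Synthetic corresponded surface meshes with planted growth patches.

Stands in for atlas-warped, vertex-to-vertex corresponded subcortical
surfaces: every scan's mesh shares one icosphere triangulation; vertex
positions follow a mildly ellipsoidal base shape whose per-vertex radial
scale grows with age.  Contiguous high-growth and low-growth patches
(angular caps around random seed directions) expand at a multiple of the
background rate and are recorded in the ground truth for recovery tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .cohort import GrowthTruth

log = logging.getLogger(__name__)

__all__ = ["MeshTruth", "generate_meshes"]

_ELLIPSOID_AXES = np.array([1.15, 1.0, 0.9])


@dataclass
class MeshTruth:
    """Planted surface-growth structure of a synthetic mesh series.

    The planted multiplier field is 1 outside the patches, reaches
    ``high_mult`` / ``low_mult`` in the patch cores, and is tapered smoothly
    (cosine ramp over roughly two edge lengths) at the patch rims — an
    abrupt rim would create 'cliff' triangles whose tilt, not growth,
    dominates the local-area change.  ``high_vertices`` / ``low_vertices``
    are the vertices at half boost or more.
    """

    structure: str
    hemisphere: str
    n_vertices: int
    high_vertices: np.ndarray   # vertices with >= half the planted boost
    low_vertices: np.ndarray
    high_mult: float            # multiplier in the patch core
    low_mult: float
    base_radius: float          # mm
    multiplier: np.ndarray = None  # full per-vertex multiplier field

    def rate_multiplier(self) -> np.ndarray:
        if self.multiplier is not None:
            return self.multiplier
        mult = np.ones(self.n_vertices)
        mult[self.high_vertices] = self.high_mult
        mult[self.low_vertices] = self.low_mult
        return mult


def _icosphere(n_vertices: int) -> trimesh.Trimesh:
    if n_vertices < 12:
        raise ValueError(f"n_vertices must be >= 12, got {n_vertices}")
    subdiv = 0
    while 10 * 4**subdiv + 2 < n_vertices:
        subdiv += 1
    return trimesh.creation.icosphere(subdivisions=subdiv, radius=1.0)


def _cap_weights(directions, faces, seed_dir, count, taper_edges=2.0):
    """Smooth cap membership: 1 in an angular core of ``count`` vertices,
    cosine taper to 0 over ``taper_edges`` mean edge lengths."""
    theta = np.arccos(np.clip(directions @ seed_dir, -1.0, 1.0))
    theta_core = np.sort(theta, kind="stable")[count - 1]
    e = directions[faces[:, 0]] - directions[faces[:, 1]]
    edge_angle = float(np.linalg.norm(e, axis=1).mean())
    width = taper_edges * edge_angle
    w = np.clip((theta - theta_core) / width, 0.0, 1.0)
    return 0.5 * (1.0 + np.cos(np.pi * w))


def generate_meshes(
    records: pd.DataFrame,
    truth: GrowthTruth,
    n_vertices: int = 162,
    seed: int = 0,
    structure: str = "thalamus",
    hemisphere: str = "L",
    high_frac: float = 0.10,
    low_frac: float = 0.10,
    high_mult: float = 2.0,
    low_mult: float = 0.3,
    noise_rel: float = 0.01,
    subject_sd: float = 0.02,
):
    """Per-scan corresponded triangle meshes for one structure.

    One mesh per row of ``records``; all meshes share the triangulation of
    an icosphere with at least ``n_vertices`` vertices.  The per-vertex
    area-growth fraction at age t is the population area growth of the
    structure's truth curve, gA(t) = (V(t)/V(0))^(2/3) - 1, times the
    planted rate multiplier (``high_mult`` inside the high patch,
    ``low_mult`` inside the low patch, 1 elsewhere).  Set ``high_frac`` and
    ``low_frac`` to 0 for a spatially uniform growth field.

    Returns a :class:`subgrowth.surface.CorrespondedMeshSeries`; the planted
    patches are stored in ``truth.mesh_truth``.
    """
    from .surface import CorrespondedMeshSeries

    rng = np.random.default_rng(seed)
    base = _icosphere(n_vertices)
    directions = base.vertices / np.linalg.norm(base.vertices, axis=1,
                                                keepdims=True)
    V = len(directions)
    faces = np.asarray(base.faces)

    curve = truth.curves[(structure, hemisphere)]
    v0 = float(curve.value(0.0))
    r0 = (3.0 * v0 / (4.0 * math.pi)) ** (1.0 / 3.0)

    n_high = int(math.ceil(high_frac * V)) if high_frac > 0 else 0
    n_low = int(math.ceil(low_frac * V)) if low_frac > 0 else 0
    seed_dir = rng.normal(size=3)
    seed_dir /= np.linalg.norm(seed_dir)
    mult = np.ones(V)
    w_high = np.zeros(V)
    w_low = np.zeros(V)
    if n_high:
        w_high = _cap_weights(directions, faces, seed_dir, n_high)
        mult += (high_mult - 1.0) * w_high
    if n_low:
        w_low = _cap_weights(directions, faces, -seed_dir, n_low)
        mult += (low_mult - 1.0) * w_low
    mesh_truth = MeshTruth(
        structure=structure,
        hemisphere=hemisphere,
        n_vertices=V,
        high_vertices=np.flatnonzero(w_high >= 0.5),
        low_vertices=np.flatnonzero(w_low >= 0.5),
        high_mult=high_mult,
        low_mult=low_mult,
        base_radius=r0,
        multiplier=mult,
    )

    subj_factor = {
        sid: math.exp(rng.normal(0.0, subject_sd))
        for sid in pd.unique(records["subject_id"])
    }

    ages = records["age_days"].to_numpy(dtype=float)
    g_area = (curve.value(ages) / v0) ** (2.0 / 3.0) - 1.0

    base_shape = directions * _ELLIPSOID_AXES  # (V, 3)
    all_vertices = np.empty((len(records), V, 3))
    for i, (_, row) in enumerate(records.iterrows()):
        area_mult = 1.0 + g_area[i] * mult  # target per-vertex area ratio
        if np.any(area_mult <= 0):
            raise ValueError(
                "low_mult too small: planted shrinkage drives areas "
                "nonpositive at the oldest ages"
            )
        scale = r0 * np.sqrt(area_mult) * subj_factor[row["subject_id"]]
        for attempt in range(5):
            noise = (
                1.0 + rng.normal(0.0, noise_rel, V) if noise_rel > 0 else 1.0
            )
            verts = base_shape * (scale * noise)[:, None]
            if _min_triangle_area(verts, faces) > 1e-12 * r0**2:
                break
            log.warning(
                "degenerate triangle in generated mesh (scan %d); "
                "regenerating with fresh jitter (attempt %d)", i, attempt + 1
            )
        else:
            raise RuntimeError("could not generate a non-degenerate mesh")
        all_vertices[i] = verts

    meta_cols = ["subject_id", "age_days"]
    for extra in ("sex", "site", "icv"):
        if extra in records.columns:
            meta_cols.append(extra)
    meta = records[meta_cols].reset_index(drop=True)
    truth.mesh_truth = mesh_truth
    return CorrespondedMeshSeries(
        faces=faces, vertices=all_vertices, meta=meta
    )


def _min_triangle_area(vertices, faces):
    tri = vertices[faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    return float(0.5 * np.linalg.norm(cross, axis=1).min())
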