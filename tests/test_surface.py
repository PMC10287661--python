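"""Vertex areas, per-vertex trajectories, expansion maps, region labels."""

import numpy as np
import pytest
import trimesh

from subgrowth.cohort import CohortConfig, generate_cohort
from subgrowth.meshes import generate_meshes
from subgrowth.surface import (
    CorrespondedMeshSeries,
    bootstrap_rate_maps,
    detect_growth_regions,
    expansion_rate_map,
    fit_vertex_trajectories,
    vertex_local_area,
)


@pytest.fixture(scope="module")
def mesh_cohort():
    cfg = CohortConfig(n_subjects=60, seed=6)
    rec, truth = generate_cohort(cfg)
    series = generate_meshes(rec, truth, n_vertices=42, seed=17)
    return rec, truth, series


@pytest.fixture(scope="module")
def vertex_fits(mesh_cohort):
    _, _, series = mesh_cohort
    return fit_vertex_trajectories(series, k=8, span=(0, 810))


class TestLocalArea:
    def test_single_triangle_split_equally(self):
        verts = np.array([[0, 0, 0], [3, 0, 0], [0, 2, 0]], dtype=float)
        faces = np.array([[0, 1, 2]])
        va = vertex_local_area(verts, faces)
        np.testing.assert_allclose(va, 1.0)  # area 3, one third each

    def test_conservation(self, mesh_cohort):
        _, _, series = mesh_cohort
        mesh = trimesh.Trimesh(series.vertices[0], series.faces, process=False)
        va = vertex_local_area(series.vertices[0], series.faces)
        assert va.sum() == pytest.approx(mesh.area, rel=1e-12)

    def test_unit_icosphere_total_area(self):
        ico = trimesh.creation.icosphere(subdivisions=3, radius=1.0)
        total = vertex_local_area(ico).sum()
        assert abs(total - 4 * np.pi) / (4 * np.pi) < 0.01

    def test_rigid_motion_invariance(self, mesh_cohort):
        _, _, series = mesh_cohort
        v = series.vertices[0]
        rng = np.random.default_rng(0)
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        moved = v @ q.T + np.array([5.0, -3.0, 11.0])
        a = vertex_local_area(v, series.faces)
        b = vertex_local_area(moved, series.faces)
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_scaling_squares_areas(self, mesh_cohort):
        _, _, series = mesh_cohort
        v = series.vertices[0]
        a = vertex_local_area(v, series.faces)
        b = vertex_local_area(2.5 * v, series.faces)
        np.testing.assert_allclose(b, 2.5**2 * a, rtol=1e-12)

    def test_degenerate_triangle_named(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]],
                         dtype=float)
        faces = np.array([[0, 1, 2], [0, 1, 3]])
        with pytest.raises(ValueError, match="triangle index 0"):
            vertex_local_area(verts, faces)


class TestMeshSeries:
    def test_generated_series_is_closed_manifold(self, mesh_cohort):
        _, _, series = mesh_cohort
        series.validate()
        mesh = trimesh.Trimesh(series.vertices[0], series.faces, process=False)
        assert mesh.is_watertight
        assert mesh.euler_number == 2

    def test_uniform_growth_equal_area_ratios(self):
        cfg = CohortConfig(n_subjects=30, seed=3)
        rec, truth = generate_cohort(cfg)
        series = generate_meshes(rec, truth, n_vertices=42, seed=4,
                                 high_frac=0, low_frac=0, noise_rel=0.0,
                                 subject_sd=0.0)
        areas = series.vertex_areas()
        ages = series.meta.age_days.to_numpy()
        young, old = np.argmin(ages), np.argmax(ages)
        ratios = areas[old] / areas[young]
        assert np.ptp(ratios) < 1e-9 * ratios.mean()

    def test_planted_patch_outgrows_background(self):
        cfg = CohortConfig(n_subjects=30, seed=5)
        rec, truth = generate_cohort(cfg)
        series = generate_meshes(rec, truth, n_vertices=162, seed=6,
                                 noise_rel=0.0, subject_sd=0.0)
        mt = truth.mesh_truth
        areas = series.vertex_areas()
        ages = series.meta.age_days.to_numpy()
        young, old = np.argmin(ages), np.argmax(ages)
        ratios = areas[old] / areas[young]
        others = np.setdiff1d(
            np.arange(series.n_vertices),
            np.concatenate([mt.high_vertices, mt.low_vertices]),
        )
        assert ratios[mt.high_vertices].min() > np.median(ratios[others])
        assert ratios[mt.low_vertices].max() < np.median(ratios[others])


class TestVertexTrajectories:
    def test_rate_map_positive_growth(self, vertex_fits):
        rates = expansion_rate_map(vertex_fits, 6.0)
        assert np.isfinite(rates[vertex_fits.mask]).all()
        assert np.median(rates[vertex_fits.mask]) > 0

    def test_month_outside_span_raises(self, vertex_fits):
        with pytest.raises(ValueError, match="span"):
            expansion_rate_map(vertex_fits, 40.0)

    def test_masked_vertices_propagate(self, vertex_fits):
        import copy

        vt = copy.copy(vertex_fits)
        vt.mask = vertex_fits.mask.copy()
        vt.mask[3] = False
        rates = vt.rate_map(6.0)
        assert np.isnan(rates[3])
        reps = bootstrap_rate_maps(vt, [6.0], B=5, seed=0)
        assert np.isnan(reps[:, 0, 3]).all()

    def test_replicate_maps_deterministic(self, vertex_fits):
        a = bootstrap_rate_maps(vertex_fits, [6.0], B=5, seed=4)
        b = bootstrap_rate_maps(vertex_fits, [6.0], B=5, seed=4)
        np.testing.assert_array_equal(a, b)


class TestDetection:
    def test_candidate_counts_and_label_subset(self, vertex_fits):
        rates = expansion_rate_map(vertex_fits, 6.0)
        reps = bootstrap_rate_maps(vertex_fits, [6.0], B=100, seed=2)
        det = detect_growth_regions(rates, reps[:, 0, :], q=0.2)
        V = len(rates)
        n_cand = int(np.ceil(0.2 * V))
        assert (det.candidate == "high").sum() == n_cand
        assert (det.candidate == "low").sum() == n_cand
        labelled = det[det.label != "none"]
        assert (labelled.label == labelled.candidate).all()

    def test_identical_rates_yield_no_candidates(self):
        rates = np.full(40, 0.02)
        reps = np.full((30, 40), 0.02)
        det = detect_growth_regions(rates, reps)
        assert (det.label == "none").all()
        assert (det.candidate == "none").all()

    def test_planted_patch_recovered(self, mesh_cohort, vertex_fits):
        _, truth, _ = mesh_cohort
        mt = truth.mesh_truth
        rates = expansion_rate_map(vertex_fits, 6.0)
        reps = bootstrap_rate_maps(vertex_fits, [6.0], B=150, seed=8)
        det = detect_growth_regions(rates, reps[:, 0, :])
        high = set(det.loc[det.label == "high", "vertex"])
        assert len(high & set(mt.high_vertices)) >= 0.5 * len(mt.high_vertices)
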