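"""Mixed-model associations: Satterthwaite tests, BH-FDR, model comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from subgrowth.association import (
    AssociationSpec,
    _design,
    association_table,
    compare_models,
    fdr_adjust,
    fit_association_lmm,
    join_scores,
    log_volume_ratio,
    vertex_association,
)
from subgrowth.cohort import CohortConfig, generate_cohort, generate_mullen


def _cross_sectional(n=150, beta=2.0, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "age_days": rng.uniform(0, 810, n),
            "sex": rng.choice(["male", "female"], n),
            "site": rng.choice(["siteA", "siteB"], n),
            "icv": rng.normal(8e5, 5e4, n),
            "income": rng.integers(1, 6, n),
            "maternal_education": rng.integers(0, 2, n),
        }
    )
    x = rng.normal(size=n)
    df["pred"] = x
    df["mullen_RL"] = 50 + beta * x + rng.normal(0, 5, n)
    return df


class TestLogRatio:
    def test_equal_inputs_zero(self):
        assert log_volume_ratio(5.0, 5.0) == 0.0

    def test_one_over_e(self):
        assert log_volume_ratio(np.e, np.e**2) == pytest.approx(-1.0)

    def test_doubling_adds_log2(self):
        a = log_volume_ratio(2.0, 10.0)
        b = log_volume_ratio(1.0, 10.0)
        assert a - b == pytest.approx(np.log(2))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            log_volume_ratio(-1.0, 5.0)


class TestFDR:
    def test_hand_computed_example(self):
        q = fdr_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_independent_stepup(self):
        def stepup(p):
            p = np.asarray(p)
            m = p.size
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        rng = np.random.default_rng(0)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(fdr_adjust(p), stepup(p), atol=1e-12)

    def test_grouped_adjustment(self):
        p = np.array([0.01, 0.5, 0.01, 0.5])
        g = np.array(["a", "a", "b", "b"])
        q = fdr_adjust(p, g)
        np.testing.assert_allclose(q[:2], fdr_adjust(p[:2]))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestAssociationLMM:
    def test_ols_limit_no_repeats(self):
        df = _cross_sectional()
        spec = AssociationSpec(score="RL", predictor="pred")
        res = fit_association_lmm(df, spec)
        y, X, names, _ = _design(df, spec)
        ols = sm.OLS(y, X).fit()
        assert res.beta == pytest.approx(ols.params[-1], abs=1e-6)
        assert res.t == pytest.approx(ols.tvalues[-1], abs=1e-6)
        assert res.df == pytest.approx(len(y) - X.shape[1], rel=1e-3)

    def test_satterthwaite_df_bounds(self, cohort_small):
        records, _, _ = cohort_small
        res = fit_association_lmm(
            records, AssociationSpec(score="RL", predictor="thalamus")
        )
        n_obs = records.mullen_RL.notna().sum()
        assert 0 < res.df <= n_obs - 8

    def test_beta_invariant_to_predictor_units(self):
        df = _cross_sectional(seed=3)
        spec = AssociationSpec(score="RL", predictor="pred")
        a = fit_association_lmm(df, spec)
        df2 = df.assign(pred=df.pred * 1000.0 + 7.0)
        b = fit_association_lmm(df2, spec)
        assert a.beta == pytest.approx(b.beta, rel=1e-10)
        assert a.p == pytest.approx(b.p, rel=1e-8)

    def test_covariates_standardized(self, cohort_small):
        records, _, _ = cohort_small
        spec = AssociationSpec(score="RL", predictor="thalamus")
        _, X, names, _ = _design(records, spec)
        for j in range(1, X.shape[1]):
            assert abs(X[:, j].mean()) < 1e-10
            assert X[:, j].var() == pytest.approx(1.0, abs=1e-10)

    def test_planted_effect_recovered(self, cohort_small):
        records, truth, _ = cohort_small
        res = fit_association_lmm(
            records, AssociationSpec(score="RL", predictor="thalamus")
        )
        assert res.beta > 0  # planted +3.5 per SD of the log ratio


class TestCompareModels:
    def test_empty_addition_is_null(self, cohort_small):
        records, _, _ = cohort_small
        F, p = compare_models(records, "FM", [])
        assert F == 0.0 and p == 1.0

    def test_planted_joint_effect_significant(self):
        cfg = CohortConfig(n_subjects=200, seed=19)
        rec, truth = generate_cohort(cfg)
        rec = generate_mullen(rec, truth, seed=20)
        F, p = compare_models(rec, "FM", ["caudate", "putamen"])
        assert p < 0.05

    def test_noise_predictor_not_significant_on_average(self):
        pvals = []
        for seed in range(40):
            df = _cross_sectional(n=200, beta=0.0, seed=seed)
            # fresh pure-noise predictor, independent of the score
            rng = np.random.default_rng(seed + 1000)
            df["noisepred"] = rng.normal(size=len(df))
            _, p = compare_models(df, "RL", ["noisepred"],
                                  random_intercept=False)
            pvals.append(p)
        from scipy import stats

        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestVertexAssociation:
    def test_localized_planted_association_recovered(self):
        """A score coupled to the relative area of one surface patch is
        mapped back to that patch (Dice > 0.6, spillover confined to the
        one-ring halo)."""
        import trimesh

        cfg = CohortConfig(n_subjects=120, seed=23)
        rec, truth = generate_cohort(cfg)
        from subgrowth.meshes import generate_meshes

        series = generate_meshes(rec, truth, n_vertices=162, seed=24)
        areas = series.vertex_areas()
        patch = set(truth.mesh_truth.high_vertices)
        rng = np.random.default_rng(25)
        contrast = np.log(
            areas[:, sorted(patch)].mean(axis=1) / areas.mean(axis=1)
        )
        age = rec.age_days.to_numpy(float)
        A = np.column_stack([np.ones(len(rec)), age])
        resid = contrast - A @ np.linalg.lstsq(A, contrast, rcond=None)[0]
        z = (resid - resid.mean()) / resid.std()
        rec = rec.copy()
        rec["mullen_GM"] = 50 + 3.0 * z + rng.normal(0, 3.0, len(rec))
        tab = vertex_association(
            rec, areas, AssociationSpec(score="GM", predictor="area")
        )
        sig = set(tab.loc[tab.significant & (tab.beta > 0), "vertex"])
        dice = 2 * len(sig & patch) / (len(sig) + len(patch))
        assert dice > 0.6
        ico = trimesh.creation.icosphere(subdivisions=2)
        adj = {i: set() for i in range(162)}
        for f in ico.faces:
            for a in f:
                adj[a].update(f.tolist())
        halo = {v for v in range(162) if v not in patch and adj[v] & patch}
        assert len(sig - patch - halo) <= 0.05 * 162

    def test_null_geometry_controls_significance(self, cohort_small):
        records, truth, _ = cohort_small
        rng = np.random.default_rng(2)
        areas = rng.normal(10, 1, (len(records), 30))  # unrelated to scores
        tab = vertex_association(
            records, areas, AssociationSpec(score="GM", predictor="area")
        )
        assert tab.significant.mean() <= 0.05 + 2 * np.sqrt(0.05 / 30)


def test_join_scores_window():
    rec = pd.DataFrame(
        {"subject_id": ["a", "a", "b"], "age_days": [100, 400, 200]}
    )
    visits = pd.DataFrame(
        {
            "subject_id": ["a", "b"],
            "age_days": [120, 400],
            "mullen_GM": [55.0, 45.0],
        }
    )
    out = join_scores(rec, visits, window_days=45)
    assert out.mullen_GM.tolist()[0] == 55.0
    assert np.isnan(out.mullen_GM.tolist()[1])  # 280 days away
    assert np.isnan(out.mullen_GM.tolist()[2])  # 200 days away


def test_association_table_shape_and_fdr():
    cfg = CohortConfig(n_subjects=250, seed=29)
    records, truth = generate_cohort(cfg)
    records = generate_mullen(records, truth, seed=30)
    tab = association_table(records)
    assert len(tab) == 36
    assert (tab.q_value >= tab.p - 1e-12).all()
    # planted thalamus-RL effect is the strongest cell in its family
    rl = tab[tab.score == "RL"].set_index("structure")
    assert rl.loc["thalamus", "p"] == rl.p.min()
    assert rl.loc["thalamus", "beta"] > 0
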