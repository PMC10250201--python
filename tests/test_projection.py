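"""Projection-predictive machinery: design building, KL projection, forward
search and submodel selection."""

import numpy as np
import pandas as pd
import pytest

from cogstab.projection import (
    ProjectionPath,
    build_design,
    forward_search,
    performance_counts,
    project_submodel,
    select_submodel,
)


class TestDesign:
    def test_full_term_map(self, projection_data):
        X, term_map = build_design(projection_data["diary"], 1)
        assert set(term_map) == set(
            projection_data["diary"]["predictor"].unique()
        )
        assert len(term_map["group"]) == 4  # five groups, bonobo reference
        # continuous predictors standardized
        assert abs(X["age"].mean()) < 1e-9 and X["age"].std() == pytest.approx(1, rel=1e-6)

    def test_rank_deficient_design_names_aliased_columns(self, projection_data):
        diary = projection_data["diary"].copy()
        rank_rows = diary["predictor"] == "rank"
        soc_rows = diary["predictor"] == "sociality"
        diary.loc[soc_rows, "value"] = diary.loc[rank_rows, "value"].to_numpy()
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(diary, 1)


class TestProjection:
    def test_self_projection_zero_kl(self, fitted_reference):
        ref = fitted_reference
        sub = project_submodel(
            ref, list(ref.term_map_) + ["random_intercept"], n_clusters=10, seed=1
        )
        assert sub.kl < 1e-3
        assert sub.n_failed == 0

    def test_self_projection_recovers_reference(self, fitted_reference):
        ref = fitted_reference
        sub = project_submodel(
            ref, list(ref.term_map_) + ["random_intercept"], n_clusters=10, seed=1
        )
        # predictive identity: projected fitted probabilities reproduce the
        # reference fitted probabilities
        proj_prob = np.average(sub.prob, axis=0, weights=sub.weights)
        ref_prob = ref.prob_draws_.mean(axis=0)
        assert np.allclose(proj_prob, ref_prob, atol=0.02)
        # well-identified (within-subject varying) coefficients carry over;
        # between-subject columns trade off against the subject intercepts
        proj_mean = np.average(sub.coef, axis=0, weights=sub.weights)
        cols = sub.columns[1:]
        for name in ("sociality", "rank", "observer_present"):
            j = 1 + cols.index(name)
            ref_val = ref.coef_draws_.mean(axis=0)[ref.feature_names_.index(name)]
            assert proj_mean[j] == pytest.approx(ref_val, abs=0.1)

    def test_empty_terms_intercept_only(self, fitted_reference):
        sub = project_submodel(fitted_reference, [], n_clusters=5, seed=0)
        assert sub.columns == ["intercept"]
        # fitted probabilities constant across observations per cluster
        assert np.allclose(sub.prob, sub.prob[:, :1])

    def test_gaussian_projection_equals_least_squares(self, fitted_reference):
        # closed-form oracle: LS regression of reference fitted values on the
        # submodel design, trial-total weighted
        ref = fitted_reference
        sub = project_submodel(ref, ["age", "sex"], n_clusters=4, seed=2, family="gaussian")
        F = ref._obs_["F"]
        n = ref._obs_["n"]
        cols = sub.columns[1:]
        idx = [ref.feature_names_.index(c) for c in cols]
        D = np.concatenate([np.ones((F.shape[0], 1)), F[:, idx]], axis=1)
        W = np.sqrt(n)
        # oracle computed against the same cluster centers the projection used
        from cogstab.projection import _cluster_reference

        centers_ref, _, _ = _cluster_reference(ref, 4, 2)
        for c, p_ref in enumerate(centers_ref):
            beta, *_ = np.linalg.lstsq(D * W[:, None], W * p_ref, rcond=None)
            assert np.allclose(sub.coef[c], beta, atol=1e-6)


@pytest.fixture(scope="module")
def path(fitted_reference):
    return forward_search(fitted_reference, n_clusters=10, seed=7)


class TestForwardSearch:

    def test_random_intercept_forced_last(self, path):
        assert path.ranking[-1] == "random_intercept"
        assert path.table["forced"].iloc[-1]

    def test_kl_non_increasing_along_path(self, path):
        kl = path.table["kl"].to_numpy()
        assert np.all(np.diff(kl) <= 1e-6)

    def test_ranking_is_permutation(self, path, fitted_reference):
        expected = set(fitted_reference.term_map_) | {"random_intercept"}
        assert set(path.ranking) == expected
        assert len(path.ranking) == len(expected)

    def test_strong_predictors_ranked_first(self, path):
        # generative actives: observer_present, sociality, rank
        assert {"observer_present", "sociality"} <= set(path.ranking[:4])

    def test_greedy_matches_exhaustive_on_orthogonal_terms(self, fitted_reference):
        # restricted to 3 candidates, the greedy first pick must be the
        # single best of all candidates (brute force over subsets of size 1)
        ref = fitted_reference
        cands = ["age", "sex", "life_events"]
        kls = {t: project_submodel(ref, [t], n_clusters=6, seed=3).kl for t in cands}
        path = forward_search(ref, candidate_terms=cands, n_clusters=6, seed=3)
        assert path.ranking[0] == min(kls, key=kls.get)


class TestSelection:
    def _path(self, elpds, n_obs=50, noise=0.0, forced_tail=1):
        rng = np.random.default_rng(0)
        pw = []
        for e in elpds:
            base = np.full(n_obs, e / n_obs)
            pw.append(base + noise * rng.standard_normal(n_obs) / n_obs)
        sizes = len(elpds)
        forced = [False] * (sizes - forced_tail) + [True] * forced_tail
        table = pd.DataFrame(
            {
                "size": range(sizes),
                "elpd": [p.sum() for p in pw],
                "kl": np.linspace(1, 0, sizes),
                "rmse": np.linspace(1, 0, sizes),
                "forced": forced,
            }
        )
        return ProjectionPath(ranking=[f"t{i}" for i in range(1, sizes)],
                              table=table, pointwise_elpd=np.array(pw))

    def test_flat_elpd_selects_empty_set(self):
        path = self._path([-100.0] * 6, noise=0.5)
        sel = select_submodel(path)
        assert sel["size"] == 0
        assert sel["terms"] == []

    def test_jump_then_flat_selects_jump_size(self):
        path = self._path([-200, -150, -120, -100, -100.01, -99.99, -100], noise=0.1)
        sel = select_submodel(path)
        assert sel["size"] == 3

    def test_forced_sizes_excluded_from_comparison(self):
        # huge elpd gain at the forced (random intercept) size must not drag
        # the selection to the full model
        path = self._path([-200, -100, -100.01, -20], noise=0.1, forced_tail=1)
        sel = select_submodel(path)
        assert sel["size"] == 1


class TestReference:
    def test_null_effects_covered(self):
        from cogstab.projection import HierarchicalBinomialReference
        from cogstab.simulate import SimConfig, simulate_dataset

        bundle = simulate_dataset(SimConfig(seed=77, phases=1, time_points=8))
        counts = performance_counts(bundle["trials"], "quantity_discrimination", 1)
        X, tm = build_design(bundle["diary"], 1)
        ref = HierarchicalBinomialReference(seed=2, n_draws=300)
        ref.term_map_ = tm
        ref.fit(X, counts)
        s = ref.summary_.drop(index="intercept")
        cont = [t for t in ("age", "rank", "sociality", "time_outdoors") if t in s.index]
        cover = ((s.loc[cont, "ci_low"] < 0) & (s.loc[cont, "ci_high"] > 0))
        assert cover.mean() >= 0.75  # null truth: intervals typically cover 0

    def test_active_effects_detected(self, fitted_reference):
        s = fitted_reference.summary_
        assert s.loc["sociality", "ci_low"] > 0  # generative +0.5
        assert s.loc["rank", "ci_low"] > 0  # generative +0.5
        assert s.loc["observer_present", "ci_high"] < 0  # generative -0.5

    def test_refit_identical(self, projection_data):
        from cogstab.projection import HierarchicalBinomialReference

        counts = performance_counts(projection_data["trials"], "direct_causal_inference", 1)
        X, tm = build_design(projection_data["diary"], 1)
        fits = []
        for _ in range(2):
            ref = HierarchicalBinomialReference(seed=5, n_draws=100)
            ref.term_map_ = tm
            fits.append(ref.fit(X, counts))
        pd.testing.assert_frame_equal(fits[0].summary_, fits[1].summary_)

    def test_mcmc_backend_agrees_with_laplace(self, projection_data):
        from cogstab.projection import HierarchicalBinomialReference

        counts = performance_counts(projection_data["trials"], "direct_causal_inference", 1)
        X, tm = build_design(projection_data["diary"], 1)
        mc = HierarchicalBinomialReference(
            method="mcmc", seed=5, n_draws=400, draws=800, tune=300, rhat_max=None
        )
        mc.term_map_ = tm
        mc.fit(X, counts)
        la = HierarchicalBinomialReference(seed=5, n_draws=400)
        la.term_map_ = tm
        la.fit(X, counts)
        # between-subject columns (intercept, group, age...) trade off against
        # the random-effect block and are weakly identified at 43 subjects;
        # compare the well-identified within-subject-varying coefficients
        within = ["rank", "sociality", "sickness", "observer_present",
                  "study_same_day", "study_since_last"]
        diff = (mc.summary_["mean"] - la.summary_["mean"]).abs().loc[within]
        assert diff.max() < 0.15
        assert mc.diagnostics_ is not None
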