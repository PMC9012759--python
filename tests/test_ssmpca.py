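import itertools

import numpy as np
import pandas as pd
import pytest

from sertpet.ssmpca import (
    ScoreSet,
    decompose,
    derive_pattern,
    double_center,
    loocv_patterns,
    roc,
    score_subjects,
    select_components,
    stepwise_pattern,
    _logit_aic,
)
from sertpet.synth import BILATERAL_VOIS, CohortConfig, embed_pattern_maps, simulate_cohort


def _profile(values, prefix="S"):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"f{j}" for j in range(values.shape[1])],
    )


class TestDoubleCenter:
    def test_matches_four_term_formula(self, rng):
        X = rng.normal(size=(5, 4))
        res = double_center(_profile(X))
        expected = X - X.mean(1, keepdims=True) - X.mean(0, keepdims=True) + X.mean()
        assert np.allclose(res.residuals, expected, atol=1e-12)

    def test_zero_row_and_column_means(self, rng):
        res = double_center(_profile(rng.normal(size=(8, 6))))
        assert np.abs(res.residuals.mean(axis=0)).max() < 1e-10
        assert np.abs(res.residuals.mean(axis=1)).max() < 1e-10

    def test_constant_matrix_gives_zero(self):
        res = double_center(_profile(np.full((4, 5), 2.5)), mask_zero_variance=False)
        assert np.allclose(res.residuals, 0.0, atol=1e-12)

    def test_zero_variance_features_masked(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        X[:, 1] = 7.0
        res = double_center(_profile(X))
        assert res.features == ["f0", "f2"]

    def test_idempotence(self, rng):
        X = rng.normal(size=(6, 5))
        r1 = double_center(_profile(X)).residuals
        r2 = double_center(_profile(r1)).residuals
        assert np.allclose(r1, r2, atol=1e-12)

    def test_log_transform_error_names_cell(self):
        X = np.abs(np.random.default_rng(0).normal(1.0, 0.1, (4, 3)))
        X[2, 1] = -0.5
        with pytest.raises(ValueError, match="S2"):
            double_center(_profile(X), log_transform=True)

    def test_mask_floor_drops_low_features(self, rng):
        X = rng.normal(1.0, 0.1, (6, 4))
        X[:, 3] = rng.normal(0.05, 0.01, 6)
        res = double_center(_profile(X), mask_floor=0.2)
        assert res.features == ["f0", "f1", "f2"]


class TestDecompose:
    def test_rank_one_residuals(self):
        u = np.array([1.0, -1.0, 2.0, -2.0])
        v = np.array([1.0, 0.5, -1.5])
        u -= u.mean()
        v -= v.mean()
        X = np.outer(u, v)
        res = double_center(_profile(X + 1.0))
        pcs = decompose(res)
        assert pcs.n_components == 1
        assert pcs.variance_fractions[0] == pytest.approx(1.0)

    def test_eigenvalue_sum_equals_trace(self, rng):
        res = double_center(_profile(rng.normal(size=(10, 7))))
        pcs = decompose(res)
        total = np.sum(res.residuals**2) / (res.residuals.shape[0] - 1)
        assert pcs.eigenvalues.sum() == pytest.approx(total, rel=1e-9)

    def test_duality_with_feature_space_pca(self, rng):
        """Components from the subject-space decomposition agree (up to sign)
        with a direct SVD of the residuals."""
        res = double_center(_profile(rng.normal(size=(9, 6))))
        pcs = decompose(res)
        _, _, vt = np.linalg.svd(res.residuals, full_matrices=False)
        for i in range(pcs.n_components):
            dot = abs(float(pcs.components[i] @ vt[i]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_orthonormal_components(self, rng):
        pcs = decompose(double_center(_profile(rng.normal(size=(12, 8)))))
        G = pcs.components @ pcs.components.T
        assert np.allclose(G, np.eye(pcs.n_components), atol=1e-8)

    def test_rank_zero_rejected(self):
        X = np.add.outer(np.arange(4.0), np.arange(3.0))  # additive: residual 0
        res = double_center(_profile(X))
        with pytest.raises(ValueError, match="rank 0"):
            decompose(res)


class TestSelectComponents:
    def _pcs(self, fractions):
        from sertpet.ssmpca import PCSet

        fr = np.asarray(fractions, float)
        k = fr.size
        return PCSet(
            components=np.eye(k), eigenvalues=fr * 10, variance_fractions=fr,
            features=[f"f{i}" for i in range(k)],
        )

    def test_single_pc_covers_half(self):
        assert select_components(self._pcs([0.6, 0.4])).n_components == 1

    def test_two_pcs_needed(self):
        assert select_components(self._pcs([0.4, 0.2, 0.2, 0.2])).n_components == 2

    def test_full_fraction_returns_all(self):
        assert select_components(self._pcs([0.4, 0.3, 0.3]), 1.0).n_components == 3

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            select_components(self._pcs([1.0]), 0.0)


class TestStepwisePattern:
    def test_single_candidate_pattern_proportional(self, rng):
        X = rng.normal(size=(10, 5))
        X[:5] += np.array([1, 0, -1, 0.5, -0.5]) * 2  # group effect on PC1
        prof = _profile(X)
        labels = pd.Series(["DRD"] * 5 + ["control"] * 5, index=prof.index)
        res = double_center(prof)
        pcs = select_components(decompose(res), 1e-9)  # just the first PC
        from sertpet.ssmpca import PCSet

        one = PCSet(pcs.components[:1], pcs.eigenvalues[:1],
                    pcs.variance_fractions[:1], pcs.features)
        pat = stepwise_pattern(one, res, labels, "DRD")
        dot = abs(float(pat.weights.to_numpy() @ one.components[0]))
        assert dot == pytest.approx(1.0, abs=1e-9)
        assert pat.included_pcs == (0,)

    def test_noise_pc_excluded(self):
        rng = np.random.default_rng(0)
        n = 40
        signal = np.concatenate([np.full(n // 2, 2.0), np.zeros(n // 2)])
        signal += rng.normal(0, 0.3, n)
        v1 = np.array([1.0, -1, 1, -1, 1, -1]) / np.sqrt(6)
        v2 = np.array([1.0, 1, -1, -1, 1, -1]) / np.sqrt(6)
        noise_scores = rng.normal(0, 2.0, n)
        X = 1.0 + np.outer(signal, v1) + np.outer(noise_scores, v2)
        prof = _profile(X)
        labels = pd.Series(["DRD"] * (n // 2) + ["control"] * (n // 2), index=prof.index)
        pat = derive_pattern(prof, labels, "DRD", cumulative_fraction=1.0)
        # the pattern should load on the separating direction, not the noise
        assert abs(float(pat.weights.to_numpy() @ v1)) > 0.9

    def test_disease_group_has_higher_mean_score(self, rng):
        cfg = CohortConfig(group_sizes={"DRD": 8, "control": 9},
                           vois=dict(BILATERAL_VOIS)).null()
        cohort = simulate_cohort(cfg, seed=2)
        w = rng.standard_normal(13)
        emb = embed_pattern_maps(cohort, w / np.linalg.norm(w), 2.5, seed=5)
        pat = derive_pattern(emb.profile, emb.groups, "DRD")
        scores = score_subjects(pat, emb.profile, emb.groups)
        assert (
            scores.scores[emb.groups == "DRD"].mean()
            > scores.scores[emb.groups == "control"].mean()
        )

    def test_forward_close_to_exhaustive(self, rng):
        """Forward AIC search matches the exhaustive-subset optimum in most
        random instances and is never worse by more than 2 AIC (20 draws;
        the larger replication lives in the acceptance suite)."""
        hits, total = 0, 0
        for rep in range(20):
            X = rng.normal(size=(20, 8))
            prof = _profile(X, prefix=f"r{rep}_")
            labels = pd.Series(["DRD"] * 10 + ["control"] * 10, index=prof.index)
            res = double_center(prof)
            pcs = select_components(decompose(res), 0.75)
            k = min(pcs.n_components, 5)
            from sertpet.ssmpca import PCSet

            pcs = PCSet(pcs.components[:k], pcs.eigenvalues[:k],
                        pcs.variance_fractions[:k], pcs.features)
            pat = stepwise_pattern(pcs, res, labels, "DRD")
            scores = res.residuals @ pcs.components.T
            y = (labels == "DRD").to_numpy().astype(float)
            best = np.inf
            for r in range(1, k + 1):
                for combo in itertools.combinations(range(k), r):
                    _, aic, _ = _logit_aic(scores[:, list(combo)], y)
                    best = min(best, aic)
            assert pat.aic <= best + 2.0
            hits += int(pat.aic <= best + 1e-6)
            total += 1
        assert hits / total >= 0.8

    def test_single_class_rejected(self, rng):
        prof = _profile(rng.normal(size=(6, 4)))
        labels = pd.Series(["DRD"] * 6, index=prof.index)
        with pytest.raises(ValueError, match="2 classes"):
            derive_pattern(prof, labels, "DRD")


class TestLogisticAIC:
    def test_mle_matches_statsmodels_oracle(self, rng):
        """The Newton logistic solver agrees with statsmodels Logit on
        coefficients and AIC across random well-separated-but-fittable
        problems."""
        import statsmodels.api as sm
        from sertpet.ssmpca import _logit_mle

        for _ in range(20):
            n, k = 30, 3
            X = np.column_stack([np.ones(n), rng.normal(size=(n, k))])
            eta = X @ rng.normal(0, 0.8, k + 1)
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.sum() in (0, n):
                continue
            beta, ll, ok = _logit_mle(X, y)
            ref = sm.Logit(y, X).fit(disp=0)
            if not ok:
                continue  # separation: statsmodels MLE undefined too
            assert np.allclose(beta, ref.params, atol=1e-5)
            assert 2 * (k + 1) - 2 * ll == pytest.approx(ref.aic, abs=1e-6)

    def test_separation_triggers_firth_fallback(self):
        x = np.concatenate([np.full(8, -1.0), np.full(8, 1.0)])
        y = np.concatenate([np.zeros(8), np.ones(8)])
        coef, aic, fallback = _logit_aic(x[:, None], y)
        assert fallback
        assert np.isfinite(aic)


class TestScoreSubjects:
    def _pattern(self, weights, feature_means):
        from sertpet.ssmpca import DiseasePattern

        w = np.asarray(weights, float)
        return DiseasePattern(
            weights=pd.Series(w, index=[f"f{i}" for i in range(w.size)]),
            included_pcs=(0,), aic=0.0, disease_label="DRD", other_label="control",
            feature_means=np.asarray(feature_means, float),
        )

    def test_orthogonal_residual_scores_zero(self):
        w = np.array([1.0, -1.0, 0.0, 0.0])
        w /= np.linalg.norm(w)
        pat = self._pattern(w, np.zeros(4))
        resid = np.array([[1.0, 1.0, -1.0, -1.0]])  # zero-mean, orthogonal to w
        prof = _profile(resid)
        assert score_subjects(pat, prof).scores.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_residual_equal_to_pattern_scores_one(self):
        w = np.array([0.5, -0.5, 0.5, -0.5])  # unit norm, zero mean
        pat = self._pattern(w, np.full(4, 2.0))
        prof = _profile((2.0 + w)[None, :])
        assert score_subjects(pat, prof).scores.iloc[0] == pytest.approx(1.0)

    def test_matches_inner_product_oracle(self, rng):
        means = rng.normal(1.0, 0.2, 13)
        w = rng.standard_normal(13)
        w -= w.mean()  # pattern directions are feature-mean-free
        w /= np.linalg.norm(w)
        pat = self._pattern(w, means)
        X = rng.normal(1.0, 0.3, (5, 13))
        prof = _profile(X)
        got = score_subjects(pat, prof).scores.to_numpy()
        resid = X - means
        resid -= resid.mean(axis=1, keepdims=True)
        expected = np.array([float(np.sum(r * w)) for r in resid])
        assert np.allclose(got, expected, atol=1e-12)

    def test_feature_mismatch_rejected(self, rng):
        pat = self._pattern(np.ones(4) / 2, np.zeros(4))
        prof = _profile(rng.normal(size=(3, 3)))
        with pytest.raises(ValueError, match="lacks"):
            score_subjects(pat, prof)


class TestLOOCV:
    def _embedded(self, gap, seed=0):
        cfg = CohortConfig(group_sizes={"DRD": 10, "control": 12},
                           vois=dict(BILATERAL_VOIS)).null()
        cohort = simulate_cohort(cfg, seed=seed)
        rng = np.random.default_rng(seed + 100)
        w = rng.standard_normal(13)
        w /= np.linalg.norm(w)
        return embed_pattern_maps(cohort, w, gap, seed=seed + 1), w

    def test_one_score_per_subject(self):
        emb, _ = self._embedded(2.0)
        scores = loocv_patterns(emb.profile, emb.groups, "DRD")
        assert len(scores.scores) == 22
        assert scores.tag == "loocv"

    def test_fold_patterns_stable_under_strong_signal(self):
        emb, _ = self._embedded(3.0, seed=3)
        full = derive_pattern(emb.profile, emb.groups, "DRD")
        for sid in list(emb.profile.index)[:5]:
            fold = derive_pattern(
                emb.profile.drop(index=sid), emb.groups.drop(index=sid), "DRD"
            )
            r = np.corrcoef(fold.weights.to_numpy(), full.weights.to_numpy())[0, 1]
            assert abs(r) > 0.9

    def test_too_few_per_class_rejected(self, rng):
        prof = _profile(rng.normal(size=(5, 4)))
        labels = pd.Series(["DRD"] * 2 + ["control"] * 3, index=prof.index)
        with pytest.raises(ValueError, match="at least 3"):
            loocv_patterns(prof, labels, "DRD")


class TestROC:
    def _scores(self, values, labels):
        idx = [f"S{i}" for i in range(len(values))]
        return ScoreSet(
            scores=pd.Series(values, index=idx),
            labels=pd.Series(labels, index=idx),
        )

    def test_perfect_separation_auc_one(self):
        s = self._scores([3.0, 2.5, 2.0, 1.0, 0.5], ["DRD"] * 2 + ["control"] * 3)
        assert roc(s, "DRD").auc == pytest.approx(1.0)

    def test_all_tied_auc_half(self):
        s = self._scores([1.0] * 6, ["DRD"] * 3 + ["control"] * 3)
        assert roc(s, "DRD").auc == pytest.approx(0.5)

    def test_auc_equals_mannwhitney_identity(self, rng):
        from scipy.stats import mannwhitneyu

        for _ in range(10):
            n1, n2 = 7, 9
            vals = np.round(rng.normal(size=n1 + n2), 1)  # induce ties
            s = self._scores(vals, ["DRD"] * n1 + ["control"] * n2)
            auc = roc(s, "DRD").auc
            u = mannwhitneyu(vals[:n1], vals[n1:], alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n2), abs=1e-12)

    def test_curve_endpoints_and_monotonicity(self, rng):
        s = self._scores(rng.normal(size=12), ["DRD"] * 5 + ["control"] * 7)
        r = roc(s, "DRD")
        assert r.fpr[0] == 0 and r.tpr[0] == 0
        assert r.fpr[-1] == 1 and r.tpr[-1] == 1
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    def test_single_class_rejected(self):
        s = self._scores([1.0, 2.0], ["DRD", "DRD"])
        with pytest.raises(ValueError):
            roc(s, "DRD")


class TestPatternRecovery:
    def test_embedded_pattern_recovered(self):
        cfg = CohortConfig(group_sizes={"DRD": 10, "control": 12},
                           vois=dict(BILATERAL_VOIS)).null()
        cohort = simulate_cohort(cfg, seed=42)
        rng = np.random.default_rng(7)
        w = rng.standard_normal(13)
        w /= np.linalg.norm(w)
        emb = embed_pattern_maps(cohort, w, 3.0, seed=3, noise_sd=0.02)
        pat = derive_pattern(emb.profile, emb.groups, "DRD")
        r = np.corrcoef(pat.weights.to_numpy(), w)[0, 1]
        assert abs(r) > 0.95
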