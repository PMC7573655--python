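import numpy as np
import pandas as pd
import pytest

from scanharm.combat import (
    CombatModel,
    UnseenBatchError,
    age_to_category,
    combat_fit,
    combat_transform,
    merge_small_categories,
    stepwise_harmonize,
)
from scanharm.synthetic import SimConfig, simulate_cohort


class TestSingleBatch:
    def test_identity_and_null_effects(self, rng):
        X = rng.normal(2.0, 3.0, size=(50, 6))
        model = combat_fit(X, np.zeros(50, dtype=int))
        assert np.abs(model.gamma_star).max() < 1e-8
        assert np.abs(model.delta_star - 1.0).max() < 1e-8
        h, c = combat_transform(model, X, np.zeros(50, dtype=int))
        assert np.abs(c).max() < 1e-8

    def test_identity_with_covariates(self, rng):
        X = rng.normal(size=(80, 4))
        cov = rng.normal(size=(80, 2))
        X += cov @ rng.normal(size=(2, 4))
        model = combat_fit(X, np.zeros(80, dtype=int), covariates=cov)
        h, c = combat_transform(model, X, np.zeros(80, dtype=int), covariates=cov)
        assert np.abs(c).max() < 1e-8


class TestLocationScaleRecovery:
    def test_two_batch_closed_form_oracle(self, rng):
        """N(0,1) vs N(3,4): eb=off must match the explicit standardization."""
        n = 500
        x0 = rng.normal(0.0, 1.0, n)
        x1 = rng.normal(3.0, 2.0, n)
        X = np.concatenate([x0, x1])[:, None]
        batch = np.repeat([0, 1], n)
        model = combat_fit(X, batch, eb=False)

        # closed-form oracle computed independently on the same draw
        means = np.array([x0.mean(), x1.mean()])
        grand = means.mean()  # equal batch sizes
        vp = np.mean((X[:, 0] - means[batch]) ** 2)
        z = (X[:, 0] - grand) / np.sqrt(vp)
        g = np.array([z[batch == i].mean() for i in (0, 1)])
        d = np.array([z[batch == i].std(ddof=0) for i in (0, 1)])
        expected = np.sqrt(vp) * (z - g[batch]) / d[batch] + grand

        h, _ = combat_transform(model, X, batch)
        np.testing.assert_allclose(h[:, 0], expected, atol=1e-10)

        # injected shift/scale recovered within Monte-Carlo error
        gamma_data = model.gamma_star_data_units
        assert abs((gamma_data[1, 0] - gamma_data[0, 0]) - 3.0) < 3 * np.sqrt(1 / n + 4 / n)
        assert model.delta_star[1, 0] / model.delta_star[0, 0] == pytest.approx(2.0, rel=0.15)

        # harmonized batch means agree within 2 standard errors
        se = h[:, 0].std(ddof=1) * np.sqrt(2.0 / n)
        assert abs(h[batch == 0, 0].mean() - h[batch == 1, 0].mean()) <= 2 * se

    def test_transform_equalizes_batch_means(self, rng):
        n, p = 200, 10
        X = np.vstack([rng.normal(0, 1, (n, p)), rng.normal(1.0, 1.5, (n, p))])
        batch = np.repeat([0, 1], n)
        model = combat_fit(X, batch)
        h, _ = combat_transform(model, X, batch)
        se = h.std(axis=0, ddof=1) * np.sqrt(2.0 / n)
        gap = np.abs(h[batch == 0].mean(axis=0) - h[batch == 1].mean(axis=0))
        assert (gap <= 2 * se).all()


class TestEmpiricalBayes:
    def test_shrinkage_toward_prior_mean(self, rng):
        """gamma* must lie between gamma-hat and the batch prior mean for
        nearly every feature."""
        B, p, n = 5, 60, 30
        X = np.vstack([rng.normal(rng.normal(0, 0.5), 1.0, (n, p)) for _ in range(B)])
        batch = np.repeat(np.arange(B), n)
        eb_on = combat_fit(X, batch, eb=True)
        eb_off = combat_fit(X, batch, eb=False)
        frac = []
        for b in range(B):
            g_hat = eb_off.gamma_star[b]
            g_star = eb_on.gamma_star[b]
            g_bar = eb_on.gamma_prior[b, 0]
            lo = np.minimum(g_hat, g_bar) - 1e-12
            hi = np.maximum(g_hat, g_bar) + 1e-12
            frac.append(((g_star >= lo) & (g_star <= hi)).mean())
        assert np.mean(frac) >= 0.95

    def test_parameter_recovery_small(self, rng):
        B, p, n = 10, 30, 80
        sigma = rng.uniform(0.5, 2.0, p)
        gamma = rng.normal(0, 0.5, (B, p)) * sigma
        delta = np.exp(rng.normal(0, 0.2, (B, p)))
        X = np.vstack(
            [gamma[b] + delta[b] * rng.normal(size=(n, p)) * sigma for b in range(B)]
        )
        batch = np.repeat(np.arange(B), n)
        model = combat_fit(X, batch)
        cg = np.corrcoef(model.gamma_star_data_units.ravel(), gamma.ravel())[0, 1]
        cd = np.corrcoef(model.delta_star.ravel(), delta.ravel())[0, 1]
        assert cg > 0.9 and cd > 0.85

    def test_idempotence_eb_off(self, rng):
        X = np.vstack([rng.normal(0, 1, (40, 5)), rng.normal(2, 2, (40, 5))])
        batch = np.repeat([0, 1], 40)
        h, _ = combat_transform(combat_fit(X, batch, eb=False), X, batch)
        refit = combat_fit(h, batch, eb=False)
        assert np.abs(refit.gamma_star).max() < 1e-6
        assert np.abs(refit.delta_star - 1.0).max() < 1e-6


class TestErrors:
    def test_singleton_batch(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError, match="lonely"):
            combat_fit(X, ["a", "a", "a", "a", "lonely"])

    def test_zero_variance_feature(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match="f1"):
            combat_fit(X, np.repeat([0, 1], 10))

    def test_unseen_batch_mentions_learner(self, rng):
        X = rng.normal(size=(20, 3))
        model = combat_fit(X, np.repeat([0, 1], 10))
        with pytest.raises(UnseenBatchError, match="learner"):
            combat_transform(model, X[:2], ["NEW", "NEW"])


class TestNullEffectTransform:
    def test_explicit_identity_model(self, rng):
        X = rng.normal(size=(30, 4))
        model = combat_fit(X, np.repeat([0, 1], 15), eb=False)
        model.gamma_star[:] = 0.0
        model.delta_star[:] = 1.0
        h, c = combat_transform(model, X, np.repeat([0, 1], 15))
        np.testing.assert_allclose(c, 0.0, atol=1e-12)


class TestAgeCategory:
    @pytest.mark.parametrize(
        "age,expected", [(25.4, 25), (25.6, 26), (25.5, 26), (24.5, 25), (70.0, 70)]
    )
    def test_rounding_half_away_from_zero(self, age, expected):
        assert age_to_category(age) == expected

    def test_vectorized(self):
        np.testing.assert_array_equal(
            age_to_category(np.array([25.4, 25.5])), np.array([25, 26])
        )

    def test_merge_lone_category_tie_to_lower(self):
        cats = np.array([60, 60, 61, 61, 62, 62, 63, 64, 64])
        merged = merge_small_categories(cats, min_size=2)
        assert 63 not in merged
        # 63 is equidistant from 62 and 64; tie breaks to the lower value
        assert (merged == 62).sum() == 3

    def test_merge_no_change_when_populated(self):
        cats = np.array([30, 30, 31, 31])
        np.testing.assert_array_equal(merge_small_categories(cats, 2), cats)


class TestStepwise:
    def test_single_scanner_step_equals_plain_combat(self, small_cohort):
        table, _ = small_cohort
        harmonized, corr, models = stepwise_harmonize(table, steps=("scanner",))
        model = combat_fit(
            table.relative_volumes(), table.data["scanner"].to_numpy(),
            batch_variable="scanner",
        )
        h, _ = combat_transform(model, table.relative_volumes(), table.data["scanner"].to_numpy())
        np.testing.assert_allclose(harmonized.relative_volumes().to_numpy(), h, atol=1e-12)
        assert len(models) == 1

    def test_cumulative_equals_sum_of_steps(self, small_cohort):
        table, _ = small_cohort
        _, corr, _ = stepwise_harmonize(table)
        total = sum(corr.steps.values())
        np.testing.assert_allclose(
            total.to_numpy(), corr.cumulative.to_numpy(), atol=1e-10
        )

    def test_raw_plus_cumulative_is_final(self, small_cohort):
        table, _ = small_cohort
        harmonized, corr, _ = stepwise_harmonize(table)
        np.testing.assert_allclose(
            (table.relative_volumes() + corr.cumulative).to_numpy(),
            harmonized.relative_volumes().to_numpy(),
            rtol=0, atol=1e-15,
        )

    @staticmethod
    def _marginal_effects(tab):
        """Largest marginal sex difference, age slope, and scanner offset
        over ROIs, in per-ROI SD units. Marginal (not partial) effects are
        the estimand each stepwise batch removal targets."""
        rel = tab.relative_volumes().to_numpy()
        rel = rel / rel.std(axis=0)
        d = tab.data
        sex = d["sex"].to_numpy()
        sex_eff = np.abs(rel[sex == 1].mean(axis=0) - rel[sex == 0].mean(axis=0)).max()
        age = d["age"].to_numpy(float)
        X = np.column_stack([np.ones(len(age)), (age - age.mean()) / age.std()])
        age_eff = np.abs(np.linalg.lstsq(X, rel, rcond=None)[0][1]).max()
        grand = rel.mean(axis=0)
        scan_eff = max(
            np.abs(rel[(d["scanner"] == s).to_numpy()].mean(axis=0) - grand).max()
            for s in tab.scanners()
        )
        return np.array([sex_eff, age_eff, scan_eff])

    def test_effect_attenuation_balanced(self):
        """With demographically balanced scanners, every marginal effect the
        steps target is attenuated at least 10-fold."""
        cfg = SimConfig(n_scanners=5, subjects_per_scanner=400, n_rois=6, n_iqms=3,
                        seed=21, age_slope_scale=1.5, sex_offset_scale=2.0,
                        gamma_scale=1.0, log_delta_scale=0.05,
                        sex_imbalance=0.5, age_jitter=0.0)
        table, _ = simulate_cohort(cfg)
        harmonized, _, _ = stepwise_harmonize(table, eb=False)
        before = self._marginal_effects(table)
        after = self._marginal_effects(harmonized)
        assert (after <= before / 10.0).all()

    def test_effect_attenuation_imbalanced(self):
        """Under demographic imbalance the marginal removals interact
        (each step's scale division re-introduces a fraction of effects
        removed earlier), so attenuation is bounded but weaker."""
        cfg = SimConfig(n_scanners=5, subjects_per_scanner=400, n_rois=6, n_iqms=3,
                        seed=21, age_slope_scale=1.5, sex_offset_scale=2.0,
                        gamma_scale=1.0, log_delta_scale=0.05)
        table, _ = simulate_cohort(cfg)
        harmonized, _, _ = stepwise_harmonize(table)
        before = self._marginal_effects(table)
        after = self._marginal_effects(harmonized)
        assert (after <= before / 4.0).all()

    def test_covariate_preservation(self):
        """Preserving age during the scanner step keeps the simulated slope
        (within 10% plus the sampling error of a slope estimate at n=2000)."""
        cfg = SimConfig(n_scanners=4, subjects_per_scanner=500, n_rois=5, n_iqms=3,
                        seed=33, age_slope_scale=0.9, measurement_noise_sd=0.0,
                        age_jitter=0.0)
        table, truth = simulate_cohort(cfg)
        harmonized, _, _ = stepwise_harmonize(
            table, steps=("scanner",), preserve={"scanner": ("age",)}
        )
        rel = harmonized.relative_volumes()
        age = table.data.set_index("subject_id")["age"].loc[rel.index].to_numpy()
        X = np.column_stack([np.ones(len(age)), age - age.mean()])
        for roi in table.roi_cols:
            y = rel[roi].to_numpy()
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            slope = coef[1]
            se = np.sqrt(res[0] / (len(y) - 2)) / (age.std() * np.sqrt(len(y)))
            true_slope = truth.age_slope[roi]
            assert abs(slope - true_slope) <= 0.10 * abs(true_slope) + 3 * se

    def test_age_effect_removed_without_preservation(self):
        """Counterpart: the default stepwise removal flattens the age slope."""
        cfg = SimConfig(n_scanners=4, subjects_per_scanner=500, n_rois=5, n_iqms=3,
                        seed=33, age_slope_scale=0.9, measurement_noise_sd=0.0,
                        age_jitter=0.0)
        table, truth = simulate_cohort(cfg)
        harmonized, _, _ = stepwise_harmonize(table, steps=("age", "scanner"))
        rel = harmonized.relative_volumes()
        age = table.data.set_index("subject_id")["age"].loc[rel.index].to_numpy()
        X = np.column_stack([np.ones(len(age)), age - age.mean()])
        floor = 0.2 * np.abs(truth.age_slope).max()  # residual noise is absolute
        for roi in table.roi_cols:
            slope = np.linalg.lstsq(X, rel[roi].to_numpy(), rcond=None)[0][1]
            assert abs(slope) < floor

    def test_unknown_step_role(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError, match="unknown"):
            stepwise_harmonize(table, steps=("protocol",))
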