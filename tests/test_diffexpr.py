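"""Differential expression: OLS oracle agreement, moderation limits, RRHO."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circasyn import SimulationConfig, simulate_cohort
from circasyn.data import Dataset, ExpressionMatrix, SubjectRecord
from circasyn.diffexpr import (CollinearityError, DifferentialExpressionModel,
                               classify_de, fit_de, overlap_counts, rrho_map)

from conftest import ols_oracle


def _two_group_dataset(values, n_u, n_o, ages=None):
    n = n_u + n_o
    ids = [f"S{i}" for i in range(n)]
    if ages is None:
        ages = np.full(n, 40.0)
    subs = [SubjectRecord(sample_id=ids[i], subject_id=f"x{i}",
                          group="unaffected" if i < n_u else "OUD",
                          region="NAc", preparation="homogenate",
                          sex="M", age=float(ages[i]), pmi=10.0, plex="plex1",
                          tod_clock=1.0, sunrise=6.0, sunset=18.0)
            for i in range(n)]
    em = ExpressionMatrix([f"P{j}" for j in range(values.shape[0])], ids, values)
    return Dataset(em, subs)


class TestFitDE:
    def test_noise_free_group_shift_gives_exact_logfc(self):
        vals = np.tile(np.r_[np.zeros(5), np.ones(5)], (8, 1)) + np.arange(8)[:, None]
        ds = _two_group_dataset(vals, 5, 5)
        table = fit_de(ds, covariates=())
        np.testing.assert_allclose(table["logfc"], 1.0, atol=1e-12)

    def test_identical_groups_give_zero_logfc_and_no_flags(self):
        rng = np.random.default_rng(0)
        half = rng.normal(size=(10, 6))
        vals = np.hstack([half, half])
        ds = _two_group_dataset(vals, 6, 6)
        table = fit_de(ds, covariates=())
        np.testing.assert_allclose(table["logfc"], 0.0, atol=1e-12)
        assert (table["de_flag"] == "none").all()

    def test_matches_brute_force_ols_oracle_with_covariate(self):
        """Unmoderated logFC and p agree with explicit normal equations to 1e-10."""
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(20, 20))
        ages = rng.uniform(20, 70, size=20)
        ds = _two_group_dataset(vals, 10, 10, ages=ages)
        table = fit_de(ds, covariates=("age",), moderate=False)
        X = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)], ages])
        for j in range(20):
            beta, se, df = ols_oracle(vals[j], X)
            p = 2 * stats.t.sf(abs(beta[1] / se[1]), df)
            assert table["logfc"].iloc[j] == pytest.approx(beta[1], abs=1e-10)
            assert table["p"].iloc[j] == pytest.approx(p, abs=1e-10)

    def test_too_few_samples_per_group_rejected(self):
        vals = np.zeros((3, 5))
        ds = _two_group_dataset(vals, 2, 3)
        with pytest.raises(ValueError, match="fewer than 3"):
            fit_de(ds)

    def test_collinear_covariate_named(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(5, 12))
        # age perfectly tracks the group indicator
        ages = np.r_[np.full(6, 30.0), np.full(6, 60.0)]
        ds = _two_group_dataset(vals, 6, 6, ages=ages)
        with pytest.raises(CollinearityError, match="age"):
            fit_de(ds, covariates=("age",))


@pytest.fixture(scope="module")
def cohort():
    rng = np.random.default_rng(11)
    vals = rng.normal(size=(60, 16)) * rng.uniform(0.5, 2.0, size=(60, 1))
    return _two_group_dataset(vals, 8, 8)


class TestModerationLimits:
    """The moderated test interpolates between per-protein and pooled variances."""

    def test_prior_df_zero_reproduces_unmoderated(self, cohort):
        mod = fit_de(cohort, covariates=(), prior_df=0.0)
        unmod = fit_de(cohort, covariates=(), moderate=False)
        np.testing.assert_allclose(mod["p"], unmod["p"], rtol=1e-9)

    def test_large_prior_df_reproduces_pooled_variance_test(self, cohort):
        vals = cohort.expr.values
        X = np.column_stack([np.ones(16), np.r_[np.zeros(8), np.ones(8)]])
        H = np.linalg.inv(X.T @ X) @ X.T
        resid = vals - vals @ (X @ H).T
        s2 = (resid ** 2).sum(axis=1) / (16 - 2)
        pooled = float(s2.mean())
        mod = fit_de(cohort, covariates=(), prior_df=1e12, prior_var=pooled)
        t_pooled = mod["logfc"] / np.sqrt(pooled * np.linalg.inv(X.T @ X)[1, 1])
        p_pooled = 2 * stats.norm.sf(np.abs(t_pooled))
        np.testing.assert_allclose(mod["p"], p_pooled, rtol=1e-4)

    def test_null_cohort_p_value_calibration(self):
        cfg = SimulationConfig(n_per_group=10, n_proteins=2500, frac_de=0,
                               frac_rhythmic=0, n_modules=0, module_size=0, seed=13)
        ds, _ = simulate_cohort(cfg)
        table = fit_de(ds)
        frac = float((table["p"] <= 0.05).mean())
        assert 0.035 <= frac <= 0.065


class TestClassifyDE:
    @pytest.mark.parametrize("p,lfc,expected", [
        (0.04, 0.30, "up"),
        (0.04, 0.26, "up"),          # boundary included
        (0.05, 0.26, "up"),          # p boundary included
        (0.04, -0.26, "down"),
        (0.04, 0.20, "none"),
        (0.06, 0.50, "none"),
    ])
    def test_threshold_rule(self, p, lfc, expected):
        rec = pd.DataFrame(dict(protein_id=["P1"], p=[p], logfc=[lfc]))
        assert classify_de(rec)["de_flag"].iloc[0] == expected

    def test_monotone_in_p_and_lfc(self):
        rng = np.random.default_rng(5)
        rec = pd.DataFrame(dict(protein_id=[f"P{i}" for i in range(200)],
                                p=rng.uniform(0, 1, 200),
                                logfc=rng.normal(0, 0.5, 200)))
        flagged = classify_de(rec)
        better = rec.copy()
        better["p"] = better["p"] / 2
        better["logfc"] = better["logfc"] * 1.5
        flagged2 = classify_de(better)
        was_called = flagged["de_flag"] != "none"
        assert (flagged2.loc[was_called, "de_flag"] != "none").all()


class TestRRHO:
    def _records(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(dict(protein_id=[f"P{i:03d}" for i in range(n)],
                                 p=rng.uniform(1e-6, 1, n),
                                 logfc=rng.normal(0, 1, n)))

    def test_self_concordance_max_on_diagonal(self):
        rec = self._records(100, seed=2)
        m = rrho_map(rec, rec, step=10)
        i, j, _, kind = m.max_cell()
        assert kind == "concordant"
        assert i == j

    def test_negated_scores_move_maximum_off_diagonal(self):
        rec = self._records(100, seed=3)
        neg = rec.copy()
        neg["logfc"] = -neg["logfc"]
        m = rrho_map(rec, neg, step=10)
        # the top-vs-top map carries no enrichment under exact reversal
        assert m.grid.to_numpy().max() == pytest.approx(0.0, abs=1e-9)
        i, j, val, kind = m.max_cell()
        assert kind == "discordant"
        assert i != j
        assert val > 10  # reversal is an extreme anti-concordance signal

    def test_worked_hypergeometric_cell(self):
        """N=8, step=2, top-2 shared in both lists -> -log10(1/28)."""
        ids = [f"P{i}" for i in range(8)]
        rec = pd.DataFrame(dict(protein_id=ids,
                                p=np.linspace(0.001, 0.5, 8),
                                logfc=np.ones(8)))
        m = rrho_map(rec, rec, step=2)
        assert m.grid.loc[2, 2] == pytest.approx(-np.log10(1 / 28), abs=1e-12)

    def test_invariant_to_order_preserving_score_transform(self):
        rec = self._records(80, seed=4)
        # squash p-values monotonically: ranks, hence the grid, are unchanged
        squashed = rec.copy()
        squashed["p"] = rec["p"] ** 0.5
        m1 = rrho_map(rec, rec, step=8)
        m2 = rrho_map(squashed, squashed, step=8)
        np.testing.assert_allclose(m1.grid.to_numpy(), m2.grid.to_numpy())

    def test_too_few_proteins_rejected(self):
        with pytest.raises(ValueError):
            rrho_map(self._records(10), self._records(10), step=10)


class TestOverlapCounts:
    def _flags(self, up, down, universe):
        flag = ["up" if p in up else "down" if p in down else "none" for p in universe]
        return pd.DataFrame(dict(protein_id=universe, de_flag=flag))

    def test_partial_overlap(self):
        uni = ["P1", "P2", "P3", "P4"]
        a = self._flags({"P1", "P2"}, set(), uni)
        b = self._flags({"P2", "P3"}, set(), uni)
        out = overlap_counts(a, b)
        assert out["up"] == {"shared": 1, "a_only": 1, "b_only": 1}

    def test_disjoint_and_identical(self):
        uni = ["P1", "P2", "P3", "P4"]
        a = self._flags({"P1"}, {"P2"}, uni)
        b = self._flags({"P3"}, {"P4"}, uni)
        assert overlap_counts(a, b)["up"]["shared"] == 0
        same = overlap_counts(a, a)
        assert same["up"] == {"shared": 1, "a_only": 0, "b_only": 0}
        assert same["down"] == {"shared": 1, "a_only": 0, "b_only": 0}
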