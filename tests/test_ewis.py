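"""Per-CpG logistic interaction models, BH control, hs-CRP check."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.stats import chi2, norm

from ewistk import ModelSpec, bh_adjust, crp_association, fit_interaction_model, run_ewis
from ewistk.ewis import build_design
from ewistk.simulate import CELL_TYPES


def _covariates(n=200, seed=0):
    rng = np.random.default_rng(seed)
    cells = rng.dirichlet([5, 15, 10, 6, 8, 3, 53], size=n)
    cov = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(n)],
            "asthma": (rng.random(n) < 0.3).astype(int),
            "bmi_s2": rng.normal(24.5, 3.5, n),
            "bmi_change": rng.normal(0.5, 1.5, n),
            "age": rng.normal(58, 10, n),
            "sex": rng.choice(["F", "M"], n),
            "education": rng.choice(["low", "middle", "high"], n, p=[0.1, 0.6, 0.3]),
            "area": rng.choice(["area1", "area2", "area3"], n),
            "packyears": rng.gamma(1, 5, n),
            "benchtime": rng.normal(80, 20, n),
            "phys_act": rng.choice(["insufficient", "sufficient", "NA"], n, p=[0.2, 0.75, 0.05]),
            "hs_crp": rng.lognormal(0, 0.5, n),
        }
    )
    cov["bmi_s3"] = cov["bmi_s2"] + cov["bmi_change"]
    for j, ct in enumerate(CELL_TYPES):
        cov[ct] = cells[:, j]
    return cov


class TestBuildDesign:
    def test_bmi_change_forces_earlier_bmi_adjustment(self):
        X, _, _ = build_design(_covariates(), ModelSpec(exposure="bmi_change"))
        assert "bmi_s2" in X.columns and "bmi_change" in X.columns

    def test_neutrophil_sensitivity_adds_neu_and_basic_never_has_it(self):
        cov = _covariates()
        X0, _, ledger0 = build_design(cov, ModelSpec())
        X1, _, _ = build_design(cov, ModelSpec(extra_adjust=("neutrophils",)))
        assert "Neu" not in X0.columns and "Neu" not in ledger0
        assert "Neu" in X1.columns

    def test_phys_act_missing_rows_dropped_only_in_sensitivity_model(self):
        cov = _covariates()
        n_na = int((cov["phys_act"] == "NA").sum())
        X0, _, led0 = build_design(cov, ModelSpec())
        X1, _, led1 = build_design(cov, ModelSpec(extra_adjust=("phys_act",)))
        assert led0["_n_dropped_missing"] == "0"
        assert int(led1["_n_dropped_missing"]) == n_na
        assert len(X0) - len(X1) == n_na
        assert "phys_act_insufficient" in X1.columns

    def test_constant_categorical_contributes_no_column(self):
        cov = _covariates()
        cov["education"] = "middle"
        X, _, ledger = build_design(cov, ModelSpec())
        assert not any(c.startswith("education_") for c in X.columns)
        assert "dropped (constant)" in ledger["education_middle"]
        # the declared-but-absent level is recorded as such
        assert "absent" in ledger["education_high"]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(exposure="weight")
        with pytest.raises(ValueError):
            ModelSpec(extra_adjust=("smoking",))


def _scratch_mle(y, X):
    """From-scratch penalized-free logistic MLE (independent oracle)."""

    def nll(b):
        eta = X @ b
        return -(y * eta - np.logaddexp(0.0, eta)).sum()

    def grad(b):
        mu = 1 / (1 + np.exp(-np.clip(X @ b, -35, 35)))
        return -X.T @ (y - mu)

    b0 = np.zeros(X.shape[1])
    out = minimize(nll, b0, jac=grad, method="BFGS",
                   options={"maxiter": 5000, "gtol": 1e-10})
    return out.x, nll(out.x)


class TestInteractionFit:
    def test_constant_residual_is_degenerate(self):
        cov = _covariates()
        X, e, _ = build_design(cov, ModelSpec())
        y = cov["asthma"].to_numpy(float)
        res = fit_interaction_model(y, e, np.zeros(len(y)), X.to_numpy())
        assert not res.converged and res.reason == "degenerate methylation"

    def test_single_class_rejected(self):
        cov = _covariates()
        X, e, _ = build_design(cov, ModelSpec())
        r = np.random.default_rng(0).normal(size=len(X))
        res = fit_interaction_model(np.zeros(len(X)), e, r, X.to_numpy())
        assert not res.converged

    def test_estimate_matches_independent_scratch_mle(self):
        rng = np.random.default_rng(3)
        n = 600
        bmi = rng.normal(25, 4, n)
        r = rng.normal(0, 0.2, n)
        eta = -0.8 + 0.05 * (bmi - 25) + 0.6 * r * (bmi - 25) * 0.2
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        X = np.column_stack([np.ones(n), bmi])
        res = fit_interaction_model(y, bmi, r, X)
        Xf = np.column_stack([X, r, (r - r.mean()) * (bmi - bmi.mean())])
        b_hat, _ = _scratch_mle(y, Xf)
        assert res.converged
        assert res.beta_int == pytest.approx(b_hat[-1], abs=1e-5)

    def test_batched_engine_agrees_with_per_probe_reference(self, bundle_planted, residuals_planted):
        sub = residuals_planted.values.iloc[40:80]
        t1 = run_ewis(sub, bundle_planted["covariates"], ModelSpec(), engine="batched")
        t2 = run_ewis(sub, bundle_planted["covariates"], ModelSpec(), engine="per_probe")
        both = (t1["converged"] & t2["converged"]).to_numpy()
        assert both.sum() >= 35
        np.testing.assert_allclose(
            t1.loc[both, "beta_int"], t2.loc[both, "beta_int"], rtol=1e-4, atol=1e-6
        )
        np.testing.assert_allclose(t1.loc[both, "se"], t2.loc[both, "se"], rtol=1e-4)

    def test_wald_agrees_with_signed_root_lrt(self):
        """Large-sample equivalence: |z| and sqrt(LR) within 10% for |z| < 3."""
        from ewistk.simulate import SimDesign, generate_manifest, simulate_cohort

        mani = generate_manifest(60, n_chroms=2, cluster_size=6, seed=60,
                                 sex_chrom_frac=0.0, masked_frac=0.0)
        design = SimDesign(n_cases=700, n_controls=700, seed=61, batch_sd=0.0,
                           cell_profile_shift={}, missing_rate=0.0,
                           target_prevalence=0.5, oversample=6,
                           gamma={p: 0.6 for p in mani["probe_id"][::4]})
        beta, detp, controls, cov, _ = simulate_cohort(design, mani)
        X, e, _ = build_design(cov, ModelSpec())
        y = cov.loc[X.index, "asthma"].to_numpy(float)
        R = beta.sub(beta.mean(axis=1), axis=0).to_numpy()[:, X.index.to_numpy()]
        checked = 0
        for i in range(40):
            r = R[i]
            obs = np.isfinite(r)
            ro, eo, yo, Xo = r[obs], e[obs], y[obs], X.to_numpy()[obs]
            res = fit_interaction_model(yo, eo, ro, Xo)
            if not res.converged or abs(res.z) > 3 or abs(res.z) < 0.3:
                continue
            pc = (ro - ro.mean()) * (eo - eo.mean())
            Xf = np.column_stack([Xo, ro / ro.std(), pc / pc.std()])
            sd = Xf.std(0); sc = sd > 0; sc[0] = False
            Xf[:, sc] = (Xf[:, sc] - Xf.mean(0)[sc]) / sd[sc]
            _, nll1 = _scratch_mle(yo, Xf)
            _, nll0 = _scratch_mle(yo, Xf[:, :-1])
            lr = max(2 * (nll0 - nll1), 0.0)
            assert np.sqrt(lr) == pytest.approx(abs(res.z), rel=0.10, abs=0.05)
            checked += 1
        assert checked >= 5


def _bh_direct(p):
    """Direct step-up evaluation: q_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        prev = min(prev, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = prev
    return q


class TestBHAdjust:
    def test_matches_direct_step_up_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            np.testing.assert_allclose(bh_adjust(p), _bh_direct(p), atol=1e-12)

    @pytest.mark.parametrize("p,expected", [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2, 0.2, 0.2], [0.2, 0.2, 0.2]),
    ])
    def test_reference_cases(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(6)
        p = rng.random(100)
        perm = rng.permutation(100)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)

    def test_nan_excluded_and_bad_values_rejected(self):
        out = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and np.isfinite(out[0])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRunEwis:
    def test_flags_honor_fdr_and_metadata_recorded(self, ewis_planted):
        t = ewis_planted
        assert (t.loc[t["significant"], "bh_q"] < 0.1).all()
        assert t.attrs["n_converged"] + t.attrs["n_failed"] == len(t)
        assert t.attrs["exposure"] == "bmi_s3"
        assert "Neu" not in t.attrs["column_ledger"]
        ok = t["converged"]
        assert (t.loc[ok, "bh_q"] >= t.loc[ok, "p"] - 1e-12).all()
        np.testing.assert_allclose(
            t.loc[ok, "z"], t.loc[ok, "beta_int"] / t.loc[ok, "se"]
        )

    def test_effect_per_sd_scaling(self, ewis_planted, residuals_planted):
        sd = np.nanstd(residuals_planted.values.to_numpy(), axis=1, ddof=1)
        ok = ewis_planted["converged"].to_numpy()
        np.testing.assert_allclose(
            ewis_planted.loc[ok, "effect_per_sd"],
            ewis_planted.loc[ok, "beta_int"] * sd[ok],
        )

    def test_no_converged_probe_is_an_error(self):
        cov = _covariates(80, seed=9)
        R = pd.DataFrame(
            np.zeros((4, 80)), index=[f"cg{i}" for i in range(4)],
            columns=cov["sample_id"],
        )
        with pytest.raises(RuntimeError, match="no probe converged"):
            run_ewis(R, cov, ModelSpec())


class TestCrpAssociation:
    def test_recovers_planted_slope_without_noise(self):
        cov = _covariates(300, seed=10)
        cov["hs_crp"] = np.exp(0.1 * cov["bmi_s2"] - 2.0)
        fit = crp_association(cov)
        assert fit["coef"] == pytest.approx(0.1, abs=1e-10)
        assert fit["n_excluded"] == 0

    def test_nonpositive_and_missing_excluded_with_count(self):
        cov = _covariates(100, seed=11)
        cov.loc[0, "hs_crp"] = np.nan
        cov.loc[1, "hs_crp"] = 0.0
        fit = crp_association(cov)
        assert fit["n_excluded"] == 2 and fit["n_used"] == 98

    def test_permuted_bmi_ci_covers_zero_mostly(self):
        rng = np.random.default_rng(12)
        cover = 0
        for rep in range(20):
            cov = _covariates(150, seed=100 + rep)
            cov["bmi_s2"] = rng.permutation(cov["bmi_s2"].to_numpy())
            fit = crp_association(cov)
            cover += fit["ci_low"] <= 0 <= fit["ci_high"]
        assert cover >= 17

    def test_too_few_samples_rejected(self):
        cov = _covariates(30, seed=13)
        cov.loc[cov.index[5:], "hs_crp"] = np.nan
        with pytest.raises(ValueError):
            crp_association(cov)
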