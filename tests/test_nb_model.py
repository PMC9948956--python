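"""NB offset model: closed-form likelihood values, equal-offset MLE
identities, brute-force and statsmodels oracles, per-animal estimates."""

import numpy as np
import pandas as pd
import pytest
import scipy.optimize
import scipy.stats

from kdquant import counts_io, nb_model
from kdquant.nb_model import (
    DesignSpec,
    build_design,
    fit_nb_offset_model,
    nb_loglik,
    per_animal_estimates,
    residual_fractions,
)
from kdquant.synthetic import CellTypeSpec, CohortSpec, generate_cohort


def _table(rows):
    return pd.DataFrame(
        rows, columns=["animal", "cell_type", "treatment", "target_umi", "total_umi", "n_cells"]
    )


def _control_table(counts, totals):
    return _table(
        [(f"C{i+1}", "ct", "control", y, t, 1) for i, (y, t) in enumerate(zip(counts, totals))]
    )


def _two_arm_table(ctrl, trt, total=10000):
    rows = [(f"C{i+1}", "ct", "control", y, total, 1) for i, y in enumerate(ctrl)]
    rows += [(f"T{i+1}", "ct", "ASO", y, total, 1) for i, y in enumerate(trt)]
    return _table(rows)


def brute_force_fit(table, design, x0):
    """Independent oracle: direct Nelder-Mead maximization of nb_loglik
    over (beta, log theta)."""

    def neg(params):
        beta, lt = params[:-1], params[-1]
        if not np.all(np.isfinite(beta)) or abs(lt) > 20:
            return 1e12
        return -nb_loglik(table, beta, float(np.exp(lt)), design)

    res = scipy.optimize.minimize(
        neg, x0, method="Nelder-Mead",
        options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12},
    )
    return -res.fun, res.x


class TestLoglik:
    def test_closed_form_zero_count(self):
        """y=0, mu=1, theta=1: P = (theta/(theta+mu))^theta = 1/2."""
        table = _control_table([0], [1])
        design = DesignSpec.from_table(table, "control")
        assert nb_loglik(table, np.array([0.0]), 1.0, design) == pytest.approx(
            np.log(0.5), abs=1e-12
        )

    def test_poisson_limit(self):
        table = _control_table([3, 7, 5], [100, 100, 100])
        design = DesignSpec.from_table(table, "control")
        beta = np.array([np.log(0.05)])
        mu = 0.05 * 100
        expected = scipy.stats.poisson.logpmf([3, 7, 5], mu).sum()
        assert nb_loglik(table, beta, 1e8, design) == pytest.approx(expected, abs=1e-4)

    def test_matches_term_by_term_pmf_oracle(self):
        rng = np.random.default_rng(4)
        totals = rng.integers(5000, 20000, 8)
        counts = rng.integers(0, 200, 8)
        table = _two_arm_table(counts[:4], counts[4:], total=None)
        table["total_umi"] = totals
        design = DesignSpec.from_table(table, "control")
        beta = np.array([np.log(0.008), np.log(0.6)])
        theta = 3.7
        X, y, off, _ = build_design(table, design)
        mu = np.exp(X @ beta + off)
        oracle = sum(
            scipy.stats.nbinom.logpmf(yi, theta, theta / (theta + mi))
            for yi, mi in zip(y, mu)
        )
        assert nb_loglik(table, beta, theta, design) == pytest.approx(oracle, abs=1e-9)

    def test_nonfinite_beta_rejected(self):
        table = _control_table([1], [10])
        design = DesignSpec.from_table(table, "control")
        with pytest.raises(ValueError):
            nb_loglik(table, np.array([np.nan]), 1.0, design)


class TestFit:
    def test_equal_offset_intercept_is_ratio_of_sums(self):
        """With equal offsets the score equation forces sum(y) = sum(mu), so
        exp(beta0) is exactly the mean ratio."""
        table = _control_table([80, 120, 100, 100], [10000] * 4)
        design = DesignSpec.from_table(table, "control")
        fit = fit_nb_offset_model(table, design)
        assert np.exp(fit.coef("ct[ct]")) == pytest.approx(0.01, abs=1e-10)

    def test_equal_offset_interaction_is_ratio_of_arm_means(self):
        table = _two_arm_table([80, 120, 100, 100], [40, 60, 50, 50])
        design = DesignSpec.from_table(table, "control")
        fit = fit_nb_offset_model(table, design)
        assert np.exp(fit.coef("ct[ct]:trt[ASO]")) == pytest.approx(0.5, abs=1e-10)
        assert np.exp(fit.coef("ct[ct]")) == pytest.approx(0.01, abs=1e-10)

    def test_beta_matches_brute_force_likelihood_oracle(self):
        """3 cell types x 2 arms x 4 animals, unequal offsets: the
        alternating fit attains the brute-force optimum."""
        spec = CohortSpec(
            cell_types=[
                CellTypeSpec("a", 0.4, 0.002, 2.0, 0.4),
                CellTypeSpec("b", 0.3, 0.008, 2.0, 0.6),
                CellTypeSpec("c", 0.3, 0.0005, 2.0, 0.9),
            ],
            n_animals_per_arm=4,
            cells_per_animal=200,
            seed=11,
        )
        cohort = generate_cohort(spec)
        table = counts_io.aggregate_pseudobulk(cohort.counts, cohort.annotations, "Target")
        design = DesignSpec.from_table(table, "control")
        fit = fit_nb_offset_model(table, design)
        assert fit.converged
        x0 = np.concatenate([fit.beta + 0.05, [np.log(fit.theta) + 0.3]])
        ll_bf, params_bf = brute_force_fit(table, design, x0)
        assert fit.loglik >= ll_bf - 1e-6
        assert np.max(np.abs(fit.beta - params_bf[:-1])) < 1e-3

    def test_matches_statsmodels_negative_binomial(self, small_pseudobulk):
        sm = pytest.importorskip("statsmodels.api")
        table = small_pseudobulk
        design = DesignSpec.from_table(table, "control")
        fit = fit_nb_offset_model(table, design)
        X, y, off, _ = build_design(table, design)
        res = sm.NegativeBinomial(y, X, offset=off, loglike_method="nb2").fit(
            disp=0, maxiter=500
        )
        assert np.max(np.abs(res.params[:-1] - fit.beta)) < 1e-5
        assert fit.loglik == pytest.approx(res.llf, abs=1e-6)
        assert fit.theta == pytest.approx(1.0 / res.params[-1], rel=1e-3)

    def test_permuting_cell_type_order_permutes_estimates(self, small_pseudobulk):
        d1 = DesignSpec("control", ["astrocyte", "neuron"], ["ASO", "control"])
        d2 = DesignSpec("control", ["neuron", "astrocyte"], ["ASO", "control"])
        e1 = {e.cell_type: e.residual for e in
              residual_fractions(fit_nb_offset_model(small_pseudobulk, d1), d1)}
        e2 = {e.cell_type: e.residual for e in
              residual_fractions(fit_nb_offset_model(small_pseudobulk, d2), d2)}
        for ct in e1:
            assert e1[ct] == pytest.approx(e2[ct], rel=1e-9)

    def test_all_zero_treated_arm_flagged_as_separation(self):
        table = _two_arm_table([80, 120, 100, 100], [0, 0, 0, 0])
        design = DesignSpec.from_table(table, "control")
        fit = fit_nb_offset_model(table, design)
        est = residual_fractions(fit, design, table)[0]
        assert "separation" in est.flags
        assert np.isinf(est.ci_high)
        assert 0 < est.residual < 0.05  # continuity-corrected point estimate

    def test_missing_control_rows_rejected(self):
        table = _table([("T1", "ct", "ASO", 10, 1000, 1)])
        design = DesignSpec("control", ["ct"], ["ASO", "control"])
        with pytest.raises(ValueError, match="control"):
            fit_nb_offset_model(table, design)


class TestResidualFractions:
    def test_ci_closed_form(self):
        fit = nb_model.NBFit(
            beta=np.array([np.log(0.01), np.log(0.5)]),
            se=np.array([0.05, 0.1]),
            coef_names=["ct[ct]", "ct[ct]:trt[ASO]"],
            theta=10.0, loglik=0.0, converged=True, n_iter=1,
        )
        design = DesignSpec("control", ["ct"], ["ASO", "control"])
        est = residual_fractions(fit, design)[0]
        assert est.residual == pytest.approx(0.5)
        assert est.ci_low == pytest.approx(0.5 * np.exp(-0.196), rel=1e-9)
        assert est.ci_high == pytest.approx(0.5 * np.exp(0.196), rel=1e-9)
        assert est.ci_low == pytest.approx(0.411, abs=5e-4)
        assert est.ci_high == pytest.approx(0.608, abs=5e-4)

    def test_null_interaction_gives_100_percent_symmetric_ci(self):
        fit = nb_model.NBFit(
            beta=np.array([np.log(0.01), 0.0]),
            se=np.array([0.05, 0.2]),
            coef_names=["ct[ct]", "ct[ct]:trt[ASO]"],
            theta=10.0, loglik=0.0, converged=True, n_iter=1,
        )
        design = DesignSpec("control", ["ct"], ["ASO", "control"])
        est = residual_fractions(fit, design)[0]
        assert est.residual == pytest.approx(1.0)
        assert est.ci_low * est.ci_high == pytest.approx(1.0, rel=1e-12)

    def test_missing_interaction_term_rejected(self):
        fit = nb_model.NBFit(
            beta=np.array([0.0]), se=np.array([0.1]), coef_names=["ct[ct]"],
            theta=1.0, loglik=0.0, converged=True, n_iter=1,
        )
        design = DesignSpec("control", ["ct"], ["ASO", "control"])
        with pytest.raises(KeyError):
            residual_fractions(fit, design)


class TestPerAnimal:
    def test_log_ratio_residual_identities(self):
        table = _two_arm_table([100, 100, 100, 100], [40, 60, 50, 50])
        design = DesignSpec.from_table(table, "control")
        fit = fit_nb_offset_model(table, design)
        pa = per_animal_estimates(fit, table, design)
        r_hat = np.exp(fit.coef("ct[ct]:trt[ASO]"))
        # a row matching its fitted mean returns exp(beta_int) exactly;
        # y = 2*mu returns 2*exp(beta_int) (log-ratio residual definition)
        X, y, off, _ = build_design(table, design)
        mu = np.exp(X @ fit.beta + off)
        treated = table["treatment"] == "ASO"
        expected = y[treated] / mu[treated] * r_hat
        assert np.allclose(np.sort(pa["residual"]), np.sort(expected), rtol=1e-10)
        # equal offsets: total-weighted mean reproduces the pooled ratio
        pooled = (y[treated].sum() / table.loc[treated, "total_umi"].sum()) / np.exp(
            fit.coef("ct[ct]")
        )
        assert np.average(
            pa["residual"], weights=table.loc[treated, "total_umi"]
        ) == pytest.approx(pooled, rel=1e-8)

    def test_zero_count_rows_flagged(self):
        table = _two_arm_table([100, 100, 100, 100], [0, 60, 50, 50])
        design = DesignSpec.from_table(table, "control")
        fit = fit_nb_offset_model(table, design)
        pa = per_animal_estimates(fit, table, design)
        flagged = pa[pa["flag"] == "zero_count_corrected"]
        assert len(flagged) == 1
        assert (flagged["residual"] > 0).all()


def test_overall_residual_pools_cell_types(small_pseudobulk):
    est = nb_model.overall_residual(small_pseudobulk, "control")
    assert est.cell_type == "all"
    assert 0.2 < est.residual < 0.6  # between the two per-type truths
    ctrl_only = small_pseudobulk[small_pseudobulk.treatment == "control"]
    with pytest.raises(ValueError):
        nb_model.overall_residual(ctrl_only, "control")
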