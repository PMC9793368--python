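import numpy as np
import pytest
from scipy.stats import nbinom, poisson

from cdikit.io import LabelSet
from cdikit.nb_model import (
    compute_size_factors,
    fit_family,
    fit_nb_cell,
    nb_log_pmf,
    predict_zero_proportions,
    zinb_log_pmf,
)

from .conftest import make_counts, nb_rvs


class TestSizeFactors:
    def test_identical_libraries_all_one(self):
        counts = make_counts(np.full((4, 6), 3))
        np.testing.assert_allclose(compute_size_factors(counts).s, 1.0)

    def test_ratio_to_median(self):
        X = np.array([[100, 200, 400]])
        np.testing.assert_allclose(
            compute_size_factors(make_counts(X)).s, [0.5, 1.0, 2.0]
        )

    def test_even_n_median_is_midpoint(self):
        X = np.array([[100, 200, 300, 400]])
        np.testing.assert_allclose(
            compute_size_factors(make_counts(X)).s, [0.4, 0.8, 1.2, 1.6]
        )

    def test_mean_definition(self):
        X = np.array([[100, 300]])
        np.testing.assert_allclose(
            compute_size_factors(make_counts(X), method="mean").s, [0.5, 1.5]
        )

    def test_zero_count_cell_named(self):
        X = np.array([[1, 0], [2, 0]])
        with pytest.raises(ValueError, match="c2"):
            compute_size_factors(make_counts(X))


class TestNbLogPmf:
    def test_matches_scipy_nbinom(self):
        for m, phi in [(1.7, 0.8), (0.3, 2.0), (5.0, 0.1)]:
            r = 1.0 / phi
            xs = np.arange(30)
            np.testing.assert_allclose(
                nb_log_pmf(xs, m, phi), nbinom.logpmf(xs, r, r / (r + m)), atol=1e-10
            )

    def test_zero_count_closed_form(self):
        for m, phi in [(2.0, 0.5), (0.4, 3.0)]:
            assert nb_log_pmf(0, m, phi) == pytest.approx(-np.log1p(phi * m) / phi)

    def test_poisson_limit(self):
        assert nb_log_pmf(3, 2.0, 1e-10) == pytest.approx(
            poisson.logpmf(3, 2.0), abs=1e-6
        )
        np.testing.assert_allclose(nb_log_pmf([0, 4], 2.0, 0.0), poisson.logpmf([0, 4], 2.0))

    def test_zero_mean_point_mass(self):
        assert nb_log_pmf(0, 0.0, 0.5) == 0.0
        assert nb_log_pmf(2, 0.0, 0.5) == -np.inf

    @pytest.mark.parametrize("m,phi", [
        (1.7, 0.8), (0.1, 0.01), (0.5, 5.0), (3.0, 0.0), (10.0, 1.0),
        (0.05, 2.0), (2.0, 0.5), (20.0, 0.2), (7.3, 3.3), (0.9, 0.9),
        (4.4, 0.05), (15.0, 0.6), (0.2, 10.0), (1.0, 1.0), (6.0, 2.5),
        (30.0, 0.1), (0.7, 0.3), (2.5, 1.8), (12.0, 0.9), (0.33, 0.77),
    ])
    def test_normalizes_to_one(self, m, phi):
        xs = np.arange(10_001)
        total = np.exp(nb_log_pmf(xs, m, phi)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nb_log_pmf(-1, 1.0, 0.5)
        with pytest.raises(ValueError):
            nb_log_pmf(1, -1.0, 0.5)
        with pytest.raises(ValueError):
            nb_log_pmf(1, 1.0, -0.5)


class TestZinbLogPmf:
    def test_pi_zero_equals_nb(self):
        xs = np.arange(20)
        np.testing.assert_allclose(
            zinb_log_pmf(xs, 1.7, 0.8, 0.0), nb_log_pmf(xs, 1.7, 0.8)
        )

    def test_positive_count_mixture_algebra(self):
        for x in (1, 3, 9):
            assert zinb_log_pmf(x, 2.0, 0.7, 0.3) == pytest.approx(
                np.log(0.7) + nb_log_pmf(x, 2.0, 0.7)
            )

    def test_normalizes_to_one(self):
        xs = np.arange(10_001)
        for pi0 in (0.1, 0.5, 0.9):
            total = np.exp(zinb_log_pmf(xs, 1.7, 0.8, pi0)).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            zinb_log_pmf(0, 1.0, 0.5, 1.0)


class TestFitNbCell:
    def test_all_zero_boundary(self):
        mu, phi, ll, conv = fit_nb_cell(np.zeros(10, dtype=int))
        assert (mu, phi, ll) == (0.0, 0.0, 0.0) and conv

    def test_equal_size_factors_mean_is_sample_mean(self, rng):
        x = nb_rvs(rng, 3.0, 0.6, 500)
        s = np.full(500, 2.0)
        mu, phi, ll, conv = fit_nb_cell(x, s)
        assert mu == pytest.approx(x.mean() / 2.0, rel=1e-6)

    def test_recovery_with_size_factors(self, rng):
        # NB(3 * s_c, 0.6) with s_c in {0.5, 1, 2}; at n = 20000 the MLE
        # standard errors are well below the +/-0.1 tolerance
        s = np.tile([0.5, 1.0, 2.0], 6667)[:20_000]
        x = nb_rvs(rng, 3.0 * s, 0.6)
        mu, phi, ll, conv = fit_nb_cell(x, s)
        assert mu == pytest.approx(3.0, abs=0.1)
        assert phi == pytest.approx(0.6, abs=0.1)

    def test_grid_dominance_with_size_factors(self, rng):
        # fitted loglik dominates every point of a 50x50 oracle grid
        s = np.tile([0.5, 1.0, 2.0], 667)[:2000]
        x = nb_rvs(rng, 3.0 * s, 0.6)
        mu, phi, ll, conv = fit_nb_cell(x, s)
        best_grid = -np.inf
        for mu_g in np.linspace(1.0, 5.0, 50):
            for phi_g in np.linspace(0.1, 1.5, 50):
                r = 1.0 / phi_g
                llg = nbinom.logpmf(x, r, r / (r + mu_g * s)).sum()
                best_grid = max(best_grid, llg)
        assert ll >= best_grid - 1e-6

    def test_bias_shrinks_with_n(self, rng):
        errs = []
        for n in (200, 2000, 20_000):
            x = nb_rvs(rng, 3.0, 0.6, n)
            mu, phi, _, _ = fit_nb_cell(x)
            errs.append(abs(mu - 3.0) + abs(phi - 0.6))
        assert errs[2] < 0.05 and errs[2] < errs[0]


class TestFitFamily:
    def test_gene_common_recovers_shared_dispersion(self, rng):
        G, n, phi_true = 200, 2000, 0.4
        mus = rng.uniform(0.5, 4.0, G)
        X = nb_rvs(rng, mus[:, None], phi_true, (G, n))
        fit = fit_family(make_counts(X), None, "gene-common-nb")
        phis = fit.params["phi"].unique()
        assert phis.size == 1
        assert phis[0] == pytest.approx(phi_true, rel=0.10)

    def test_cell_type_specific_on_k1_equals_gene_specific(self, rng):
        X = nb_rvs(rng, 2.0, 0.5, (10, 300))
        counts = make_counts(X)
        labels = LabelSet(np.ones(300, dtype=int))
        specific = fit_family(counts, labels, "cell-type-specific-nb")
        gene = fit_family(counts, None, "gene-specific-nb")
        np.testing.assert_allclose(
            specific.params["loglik"], gene.params["loglik"], rtol=1e-10
        )
        np.testing.assert_allclose(specific.params["mu"], gene.params["mu"], rtol=1e-8)

    def test_nested_families_loglik_monotone(self, rng):
        # common <= specific (cell-type); gene-common <= gene-specific;
        # NB <= ZINB at matched dispersion structure
        mus = np.array([[0.5, 2.0], [1.0, 4.0], [2.0, 0.3]])
        phis = np.array([[0.3, 1.5], [0.8, 0.2], [1.0, 1.0]])
        blocks = [nb_rvs(rng, mus[:, [k]], phis[:, [k]], (3, 150)) for k in (0, 1)]
        X = np.concatenate(blocks, axis=1)
        counts = make_counts(X)
        labels = LabelSet(np.repeat([1, 2], 150))
        ll = {
            fam: fit_family(counts, labels if "cell-type" in fam else None, fam).total_loglik
            for fam in ("cell-type-common-nb", "cell-type-specific-nb",
                        "gene-common-nb", "gene-specific-nb", "gene-specific-zinb",
                        "gene-common-zinb")
        }
        tol = 1e-6
        assert ll["cell-type-common-nb"] <= ll["cell-type-specific-nb"] + tol
        assert ll["gene-common-nb"] <= ll["gene-specific-nb"] + tol
        assert ll["gene-specific-nb"] <= ll["gene-specific-zinb"] + tol
        assert ll["gene-common-nb"] <= ll["gene-common-zinb"] + tol
        # cell-type-common pools across clusters: same as gene-specific fit
        assert ll["cell-type-common-nb"] == pytest.approx(ll["gene-specific-nb"], abs=1e-8)

    def test_empty_cluster_is_error(self, rng):
        X = nb_rvs(rng, 2.0, 0.5, (3, 10))
        labels = LabelSet(np.ones(10, dtype=int))
        labels.K = 2  # fabricate an empty cluster
        with pytest.raises(Exception):
            fit_family(make_counts(X), labels, "cell-type-specific-nb")


class TestZeroProportionPrediction:
    def test_poisson_closed_form(self, rng):
        x = rng.poisson(1.0, 400)
        counts = make_counts(x[None, :])
        fit = fit_family(counts, None, "gene-specific-nb")
        mu, phi = fit.params.loc[0, ["mu", "phi"]]
        table = predict_zero_proportions(fit, counts)
        if phi == 0.0:
            assert table.loc[0, "expected_zero"] == pytest.approx(np.exp(-mu))
        assert table.loc[0, "observed_zero"] == pytest.approx(np.mean(x == 0))

    def test_in_sample_calibration(self, rng):
        # train = test: differences centered at 0 (in-sample MLE calibration)
        X = nb_rvs(rng, rng.uniform(0.3, 3.0, 60)[:, None], 0.6, (60, 500))
        counts = make_counts(X)
        fit = fit_family(counts, None, "gene-specific-nb")
        table = predict_zero_proportions(fit, counts)
        assert abs(table["difference"].mean()) < 0.005

    def test_unknown_gene_skipped_with_warning(self, rng):
        X = nb_rvs(rng, 2.0, 0.5, (2, 100))
        counts = make_counts(X)
        fit = fit_family(counts, None, "gene-specific-nb")
        test = make_counts(X[:1])  # only g1 present
        with pytest.warns(UserWarning, match="absent"):
            table = predict_zero_proportions(fit, test)
        assert list(table["gene"]) == ["g1"]
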