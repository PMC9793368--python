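import numpy as np
import pytest

from cdikit.cdi import batch_effect_lrt, compute_cdi, rank_label_sets
from cdikit.io import LabelSet, StructuralError
from cdikit.nb_model import fit_family

from .conftest import make_clustered_counts, make_counts, nb_rvs


def _random_two_type_counts(rng, G=12, nk=80):
    mus = np.column_stack([rng.uniform(0.3, 2.0, G), rng.uniform(0.3, 2.0, G) * 3.0])
    phis = np.column_stack([rng.uniform(0.2, 1.0, G)] * 2)
    return make_clustered_counts(rng, mus, phis, [nk, nk])


class TestComputeCdi:
    def test_k1_matches_gene_specific_fit(self, rng):
        X = nb_rvs(rng, 1.5, 0.7, (8, 200))
        counts = make_counts(X)
        labels = LabelSet(np.ones(200, dtype=int))
        score = compute_cdi(counts, labels)
        fit = fit_family(counts, None, "gene-specific-nb")
        assert score.loglik == pytest.approx(fit.total_loglik, rel=1e-10)
        assert score.d == 2 * 8
        assert score.aic == pytest.approx(-2 * fit.total_loglik + 2 * (2 * 8))

    def test_relabeling_invariance(self, rng):
        counts, labels = _random_two_type_counts(rng)
        flipped = LabelSet(3 - labels.labels)  # swap cluster ids 1 <-> 2
        a, b = compute_cdi(counts, labels), compute_cdi(counts, flipped)
        assert a.loglik == pytest.approx(b.loglik, rel=1e-12)
        assert a.d == b.d and a.bic == pytest.approx(b.bic, rel=1e-12)

    def test_bic_aic_identity(self, rng):
        counts, labels = _random_two_type_counts(rng)
        score = compute_cdi(counts, labels)
        assert score.bic - score.aic == pytest.approx(
            (np.log(counts.n_cells) - 2.0) * score.d, rel=1e-12
        )
        assert score.d == 2 * counts.n_genes * labels.K

    def test_loglik_monotone_under_refinement(self, rng):
        counts, labels = _random_two_type_counts(rng)
        coarse = compute_cdi(counts, labels)
        # split cluster 1 at random into clusters 1 and 3
        refined = labels.labels.copy()
        ones = np.flatnonzero(refined == 1)
        refined[rng.choice(ones, size=ones.size // 2, replace=False)] = 3
        fine = compute_cdi(counts, LabelSet(refined))
        assert fine.loglik >= coarse.loglik - 1e-8

    def test_gene_additivity(self, rng):
        counts, labels = _random_two_type_counts(rng, G=10)
        a = compute_cdi(counts.subset_genes(counts.gene_ids[:4]), labels)
        b = compute_cdi(counts.subset_genes(counts.gene_ids[4:]), labels)
        full = compute_cdi(counts, labels)
        assert full.loglik == pytest.approx(a.loglik + b.loglik, rel=1e-12)
        assert full.d == a.d + b.d

    def test_empty_cluster_is_error(self, rng):
        counts, labels = _random_two_type_counts(rng)
        labels.K = 3  # cluster 3 has no cells
        with pytest.raises(StructuralError):
            compute_cdi(counts, labels)

    @pytest.mark.parametrize("seed", range(20))
    def test_truth_beats_random_labels(self, seed):
        # 20 genes x 300 cells from 3 NB cell types: the true label set has
        # lower CDI than a uniformly random 3-cluster label set, AIC and BIC
        rng = np.random.default_rng(seed)
        G = 20
        base = rng.uniform(0.3, 1.5, G)
        mus = np.column_stack([base, base * 4.0, base * 0.25])
        phis = np.tile(rng.uniform(0.3, 0.8, G)[:, None], (1, 3))
        counts, truth = make_clustered_counts(rng, mus, phis, [100, 100, 100])
        random_labels = LabelSet.from_raw(rng.integers(0, 3, 300).astype(str))
        t, r = compute_cdi(counts, truth), compute_cdi(counts, random_labels)
        assert t.aic < r.aic and t.bic < r.bic


class TestBatchEffectLrt:
    def test_identical_batches_statistic_zero(self, rng):
        x = nb_rvs(rng, 2.0, 0.5, 200)
        xx = np.concatenate([x, x])
        batches = np.array(["a"] * 200 + ["b"] * 200)
        res = batch_effect_lrt(xx, batches)
        assert res.statistic == pytest.approx(0.0, abs=1e-6)
        assert not res.rejected
        assert res.df == 2

    def test_nonnegative_on_any_input(self, rng):
        for _ in range(5):
            x = nb_rvs(rng, rng.uniform(0.2, 3.0), rng.uniform(0.1, 2.0), 120)
            batches = rng.choice(["a", "b", "c"], 120)
            res = batch_effect_lrt(x, batches)
            assert res.statistic >= 0.0
            assert res.df == 2 * (len(np.unique(batches)) - 1)

    def test_detects_strong_batch_shift(self, rng):
        x = np.concatenate([nb_rvs(rng, 1.0, 0.3, 400), nb_rvs(rng, 6.0, 0.3, 400)])
        batches = np.array(["a"] * 400 + ["b"] * 400)
        assert batch_effect_lrt(x, batches).rejected

    def test_single_batch_is_error(self, rng):
        x = nb_rvs(rng, 2.0, 0.5, 50)
        with pytest.raises(StructuralError):
            batch_effect_lrt(x, np.array(["a"] * 50))


class TestMultiBatchCdi:
    def test_degrees_of_freedom_bookkeeping(self, rng):
        # strong batch effect in every gene: every H0_gk rejected -> d = 2B*G*K;
        # no batch effect: d = 2*G*K
        G, nk = 6, 300
        mus = rng.uniform(0.5, 2.0, G)
        shifted = np.concatenate(
            [nb_rvs(rng, mus[:, None], 0.4, (G, nk)),
             nb_rvs(rng, 8.0 * mus[:, None], 0.4, (G, nk))], axis=1
        )
        batch = np.array(["b1"] * nk + ["b2"] * nk)
        counts = make_counts(shifted, batch=batch)
        labels = LabelSet(np.ones(2 * nk, dtype=int))
        score = compute_cdi(counts, labels)
        assert score.d == 2 * 2 * G  # 2B with B = 2
        assert score.batch_tests["rejected"].all()

        same = make_counts(nb_rvs(rng, mus[:, None], 0.4, (G, 2 * nk)), batch=batch)
        score0 = compute_cdi(same, labels, batch_alpha=1e-6)
        assert score0.d == 2 * G

    def test_multibatch_bic_aic_identity(self, rng):
        G, nk = 4, 150
        X = nb_rvs(rng, 1.0, 0.5, (G, 2 * nk))
        batch = np.array(["b1", "b2"] * nk)
        counts = make_counts(X, batch=batch)
        labels = LabelSet(np.repeat([1, 2], nk))
        score = compute_cdi(counts, labels)
        assert score.bic - score.aic == pytest.approx(
            (np.log(counts.n_cells) - 2.0) * score.d, rel=1e-12
        )


class TestRankLabelSets:
    def test_single_candidate_is_both_optima(self, rng):
        counts, labels = _random_two_type_counts(rng)
        with pytest.warns(UserWarning, match="at least ten"):
            report, best_aic, best_bic = rank_label_sets(counts, [labels])
        assert best_aic == best_bic == labels.name
        assert len(report) == 1

    def test_duplicate_names_disambiguated_scores_equal(self, rng):
        counts, labels = _random_two_type_counts(rng)
        twin = LabelSet(labels.labels.copy(), name=labels.name)
        with pytest.warns(UserWarning):
            report, _, _ = rank_label_sets(counts, [labels, twin])
        assert report["CDI_BIC"].nunique() == 1
        assert report["label_set"].nunique() == 2

    def test_bic_picks_truth_over_merge_and_random(self, rng):
        # well separated 3-type data: candidates are the truth, the truth
        # with two clusters merged, and uniform random labels
        G = 30
        base = rng.uniform(0.5, 2.0, G)
        mus = np.column_stack([base, base * 5.0, base * 0.2])
        phis = np.tile(rng.uniform(0.3, 0.8, G)[:, None], (1, 3))
        counts, truth = make_clustered_counts(rng, mus, phis, [120, 120, 120])
        truth.name = "truth"
        merged = truth.labels.copy()
        merged[merged == 3] = 2
        cands = [
            truth,
            LabelSet.from_raw(merged, name="merged"),
            LabelSet.from_raw(rng.integers(0, 3, 360).astype(str), name="random"),
        ]
        with pytest.warns(UserWarning, match="at least ten"):
            report, best_aic, best_bic = rank_label_sets(counts, cands)
        assert best_bic == "truth"
        assert report.iloc[0]["label_set"] == "truth"
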