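"""PALHI histograms, BoW TF-IDF, component classifiers, ensemble, MV baseline."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epla.aggregation import (
    BowVocabulary,
    EplaModel,
    build_histogram,
    build_tfidf,
    feature_names,
    fit_bow,
    fit_bow_vocabulary,
    fit_ensemble_weight,
    fit_palhi,
    likelihood_word,
    majority_vote_baseline,
    predict_wsi,
    signature_vector,
)
from epla.evaluation import roc_auc

bags_strategy = st.lists(
    st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=60
)


class TestHistogram:
    def test_forced_binning(self):
        h = build_histogram([0.005, 0.005, 0.995])
        assert h[0] == pytest.approx(2 / 3)
        assert h[99] == pytest.approx(1 / 3)
        assert h[1:99].sum() == 0

    def test_boundary_one_in_last_bin(self):
        h = build_histogram([1.0])
        assert h[99] == 1.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(bags_strategy)
    def test_sums_to_one(self, bag):
        assert build_histogram(bag).sum() == pytest.approx(1.0)

    def test_counting_oracle(self, rng):
        bag = rng.uniform(0, 1, 1000)
        h = build_histogram(bag)
        # brute-force per-bin counting
        for i in range(100):
            lo, hi = i / 100, (i + 1) / 100
            if i == 99:
                want = np.sum((bag >= lo) & (bag <= hi))
            else:
                want = np.sum((bag >= lo) & (bag < hi))
            assert h[i] == pytest.approx(want / 1000)

    def test_empty_and_out_of_range_error(self):
        with pytest.raises(ValueError):
            build_histogram([])
        with pytest.raises(ValueError):
            build_histogram([0.2, 1.4])


class TestBowVocabulary:
    def test_idf_word_in_all_slides(self):
        vocab = fit_bow_vocabulary([[0.065], [0.0649], [0.0601]])  # all word 7
        assert likelihood_word(0.065) == 7
        assert vocab.idf[6] == pytest.approx(np.log(4 / 4) + 1)

    def test_idf_absent_word(self):
        vocab = fit_bow_vocabulary([[0.5], [0.5], [0.5]])
        assert vocab.idf[0] == pytest.approx(np.log(4 / 1) + 1)  # ~2.3863

    def test_idf_monotone_in_df(self):
        vocab = fit_bow_vocabulary([[0.005, 0.995], [0.995], [0.5]])
        # df: word1=1, word50=1, word100=2
        assert vocab.idf[99] < vocab.idf[0]

    def test_word_mapping_edges(self):
        assert likelihood_word(0.0) == 1
        assert likelihood_word(1.0) == 100
        assert likelihood_word(0.011) == 2


class TestTfidf:
    def test_single_word_unit_vector(self):
        vocab = fit_bow_vocabulary([[0.005]])
        v = build_tfidf([0.002, 0.009, 0.004], vocab)
        assert v[0] == pytest.approx(1.0)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_hand_computed_three_slide_corpus(self):
        """tf-idf on slides A={.05,.05}, B={.05,.95}, C={.95,.95} (words 5, 95)."""
        bags = {"A": [0.05, 0.05], "B": [0.05, 0.95], "C": [0.95, 0.95]}
        vocab = fit_bow_vocabulary(bags.values())
        n = 3
        idf5 = np.log((1 + n) / (1 + 2)) + 1  # word 5 in A, B
        idf95 = np.log((1 + n) / (1 + 2)) + 1  # word 95 in B, C
        assert vocab.idf[4] == pytest.approx(idf5)
        assert vocab.idf[94] == pytest.approx(idf95)
        va = build_tfidf(bags["A"], vocab)
        assert va[4] == pytest.approx(1.0)  # single-word slide
        vb = build_tfidf(bags["B"], vocab)
        raw = np.array([0.5 * idf5, 0.5 * idf95])
        want = raw / np.linalg.norm(raw)
        assert vb[4] == pytest.approx(want[0])
        assert vb[94] == pytest.approx(want[1])
        vc = build_tfidf(bags["C"], vocab)
        assert vc[94] == pytest.approx(1.0)

    def test_duplication_invariance(self, rng):
        bag = rng.uniform(0, 1, 30)
        vocab = fit_bow_vocabulary([bag])
        np.testing.assert_allclose(
            build_tfidf(bag, vocab), build_tfidf(np.repeat(bag, 2), vocab)
        )


class TestComponentClassifiers:
    def test_palhi_separable_training_auc(self):
        x = np.zeros((20, 100))
        x[:10, 0] = 1.0
        x[10:, 99] = 1.0
        y = np.r_[np.zeros(10), np.ones(10)]
        model = fit_palhi(x, y, cv_folds=2, seed=0)
        assert roc_auc(model.predict_proba(x)[:, 1], y) == 1.0

    def test_palhi_deterministic_choice(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(40, 100))
        y = (x[:, 0] + rng.normal(0, 0.3, 40) > 0.5).astype(int)
        a = fit_palhi(x, y, cv_folds=3, seed=11)
        b = fit_palhi(x, y, cv_folds=3, seed=11)
        assert a.best_params_ == b.best_params_

    def test_palhi_single_class_error(self):
        with pytest.raises(ValueError):
            fit_palhi(np.ones((5, 100)), np.ones(5))

    def test_bow_uninformative_posterior_is_prior(self):
        # same multiset of feature vectors in both classes -> no information
        a, b = np.full(100, 0.2), np.full(100, 0.7)
        x = np.stack([a, b, a, b, a, b, a, b, a, b, a, b])
        y = np.r_[np.zeros(4), np.ones(8)]
        model = fit_bow(x, y)
        post = model.predict_proba(x[:1])[0, 1]
        assert post == pytest.approx(8 / 12, abs=1e-6)

    def test_bow_separable(self):
        x = np.zeros((10, 100))
        x[:5, 0] = 1.0
        x[5:, 99] = 1.0
        y = np.r_[np.zeros(5), np.ones(5)]
        model = fit_bow(x, y)
        assert roc_auc(model.predict_proba(x)[:, 1], y) == 1.0

    def test_bow_matches_closed_form_gaussian_nb(self):
        """4 slides, 2 informative features: posterior from hand-rolled Gaussian NB."""
        x = np.zeros((4, 100))
        x[:, 0] = [0.1, 0.2, 0.8, 0.9]
        x[:, 1] = [0.9, 0.8, 0.2, 0.1]
        y = np.array([0, 0, 1, 1])
        model = fit_bow(x, y)
        query = x[2:3]
        log_post = []
        for cls in (0, 1):
            lp = np.log(0.5)
            for col in range(100):
                mu = x[y == cls, col].mean()
                var = x[y == cls, col].var() + 1e-9 * x.var(axis=0).max()
                lp += -0.5 * np.log(2 * np.pi * var) - (query[0, col] - mu) ** 2 / (
                    2 * var
                )
            log_post.append(lp)
        log_post = np.array(log_post)
        want = np.exp(log_post - log_post.max())
        want = want / want.sum()
        got = model.predict_proba(query)[0]
        np.testing.assert_allclose(got, want, atol=1e-9)


class TestEnsembleWeight:
    def test_identical_scores_pick_half(self):
        s = np.array([0.1, 0.9, 0.2, 0.8])
        y = np.array([0, 1, 0, 1])
        assert fit_ensemble_weight(s, s, y) == 0.5

    def test_perfect_palhi_random_bow(self, rng):
        y = np.r_[np.zeros(20), np.ones(20)]
        palhi = np.r_[rng.uniform(0, 0.4, 20), rng.uniform(0.6, 1, 20)]
        bow = rng.uniform(size=40)
        alpha = fit_ensemble_weight(palhi, bow, y)
        # grid-scan oracle: alpha must achieve the global max AUC
        best = max(
            roc_auc(a * palhi + (1 - a) * bow, y) for a in np.arange(0, 1.01, 0.01)
        )
        assert roc_auc(alpha * palhi + (1 - alpha) * bow, y) == pytest.approx(best)
        assert alpha >= 0.5  # palhi carries the signal

    def test_never_below_components(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            p = rng.uniform(size=30)
            b = rng.uniform(size=30)
            alpha = fit_ensemble_weight(p, b, y)
            ens = roc_auc(alpha * p + (1 - alpha) * b, y)
            assert ens >= max(roc_auc(p, y), roc_auc(b, y)) - 1e-12

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            fit_ensemble_weight([0.1], [0.1, 0.2], [0, 1])


class TestPredictWsi:
    def test_ensemble_arithmetic_and_boundary(self, fitted_epla):
        # direct arithmetic identity on the dataclass contract
        from epla.aggregation import WSIPrediction

        p = WSIPrediction("s", 0.2, 0.6, 0.4, 0.5, "MSI", 0.4)
        assert p.ensemble_score == pytest.approx(
            p.alpha * p.palhi_score + (1 - p.alpha) * p.bow_score
        )

    def test_predict_wsi_matches_components(self, fitted_epla, rng):
        bag = rng.uniform(0, 1, 40)
        m = fitted_epla
        pred = predict_wsi(bag, m.vocab, m.palhi, m.bow, 0.5, 0.4, slide_id="s")
        assert pred.ensemble_score == pytest.approx(
            0.5 * pred.palhi_score + 0.5 * pred.bow_score
        )
        label = "MSI" if pred.ensemble_score >= 0.4 else "MSS"
        assert pred.predicted_label == label

    def test_boundary_cutoff_calls_msi(self, fitted_epla):
        m = fitted_epla
        bag = [0.5] * 10
        pred = predict_wsi(bag, m.vocab, m.palhi, m.bow, 0.5, 0.0)
        assert pred.predicted_label == "MSI"  # any score >= 0

    def test_empty_bag_errors(self, fitted_epla):
        m = fitted_epla
        with pytest.raises(ValueError):
            predict_wsi([], m.vocab, m.palhi, m.bow, 0.5, 0.5)


class TestMajorityVote:
    @pytest.mark.parametrize(
        "bag,frac,label",
        [
            ([0.9, 0.8, 0.1], 2 / 3, "MSI"),
            ([0.4, 0.4], 0.0, "MSS"),
            ([0.6, 0.4], 0.5, "MSS"),  # strict majority required
        ],
    )
    def test_examples(self, bag, frac, label):
        f, lab = majority_vote_baseline(bag)
        assert f == pytest.approx(frac)
        assert lab == label

    def test_empty_bag(self):
        with pytest.raises(ValueError):
            majority_vote_baseline([])


def test_feature_names_layout():
    names = feature_names()
    assert len(names) == 200
    assert names[0] == "FEA#001" and names[99] == "FEA#100"
    assert names[100] == "FEA#101" and names[-1] == "FEA#200"


def test_signature_vector_blocks(rng):
    bag = rng.uniform(0, 1, 50)
    vocab = fit_bow_vocabulary([bag])
    sig = signature_vector(bag, vocab)
    assert sig.shape == (200,)
    assert sig[:100].sum() == pytest.approx(1.0)
    assert np.linalg.norm(sig[100:]) == pytest.approx(1.0)
    assert (sig >= 0).all()
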