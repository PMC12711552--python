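import itertools
import math

import numpy as np
import pytest

from wsisubtyper.aggregation import (ClassWeights, FeatureVector, PredictionBag,
                                     TfidfBagVectorizer, compute_class_weights,
                                     fit_slide_classifier, histogram_features,
                                     majority_vote, predict_slide,
                                     tfidf_features)
from wsisubtyper.evaluation import auroc
from wsisubtyper.synthetic import make_prediction_bags


def bag_of(tokens, slide_id="s", case_id=None):
    probs = [0.9 if t == "AC" else 0.1 for t in tokens]
    return PredictionBag(slide_id=slide_id, case_id=case_id,
                         tokens=list(tokens), probs=np.array(probs))


def brute_force_tfidf(docs, ngram_range=(1, 3), dim=10):
    """Independent smoothed tf-idf: explicit loops, no shared code paths."""
    lo, hi = ngram_range

    def grams(doc):
        out = []
        for n in range(lo, hi + 1):
            for i in range(len(doc) - n + 1):
                out.append(" ".join(doc[i:i + n]))
        return out

    df = {}
    for doc in docs:
        for g in set(grams(doc)):
            df[g] = df.get(g, 0) + 1
    vocab = sorted(df, key=lambda g: (-df[g], g))[:dim]
    n_docs = len(docs)
    rows = []
    for doc in docs:
        gs = grams(doc)
        row = []
        for g in vocab:
            tf = sum(1 for x in gs if x == g)
            idf = math.log((1 + n_docs) / (1 + df[g])) + 1.0
            row.append(tf * idf)
        norm = math.sqrt(sum(v * v for v in row))
        rows.append([v / norm if norm > 0 else 0.0 for v in row])
    return np.array(rows), vocab


class TestMajorityVote:
    @pytest.mark.parametrize("tokens,expected", [
        (["SCC", "SCC", "SCC", "AC"], "SCC"),
        (["AC", "AC", "SCC"], "AC"),
        (["SCC", "AC"], "AC"),  # exact tie goes to the minority class
    ])
    def test_examples(self, tokens, expected):
        assert majority_vote(bag_of(tokens)) == expected

    def test_exhaustive_up_to_length_12(self):
        for n in (1, 2, 3, 5, 12):
            for combo in itertools.product("SA", repeat=n):
                tokens = ["SCC" if c == "S" else "AC" for c in combo]
                n_ac = tokens.count("AC")
                expected = "AC" if n_ac >= n - n_ac else "SCC"
                assert majority_vote(bag_of(tokens)) == expected

    def test_empty_bag_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            PredictionBag(slide_id="s", tokens=[], probs=np.array([]))


class TestHistogramFeatures:
    def test_examples(self):
        bag = PredictionBag("s", ["AC"] * 4, np.ones(4))
        fv = histogram_features(bag, 10)
        assert fv.scheme == "histogram" and fv.dim == 10
        np.testing.assert_allclose(fv.values, [0] * 9 + [1.0])

        bag2 = PredictionBag("s", ["SCC", "AC"], np.array([0.05, 0.95]))
        np.testing.assert_allclose(histogram_features(bag2, 10).values,
                                   [0.5] + [0] * 8 + [0.5])

    def test_sums_to_one_and_jitter_invariance(self, rng):
        probs = rng.uniform(0, 1, 50)
        probs = np.where(np.abs(probs - 0.5) < 0.02, 0.6, probs)  # keep off boundary
        tokens = ["AC" if p >= 0.5 else "SCC" for p in probs]
        bag = PredictionBag("a", tokens, probs)
        fv = histogram_features(bag)
        assert fv.values.sum() == pytest.approx(1.0)
        assert np.all(fv.values >= 0)
        # tiny jitter that crosses no bin boundary leaves the vector unchanged
        eps = np.minimum(probs % 0.1, 0.1 - probs % 0.1) / 3
        jit = PredictionBag("b", tokens, probs + np.where(probs % 0.1 < 0.05, eps, -eps))
        np.testing.assert_allclose(histogram_features(jit).values, fv.values)


class TestTfidf:
    def test_hand_computed_two_doc_corpus(self):
        # doc1 = "SCC SCC", doc2 = "AC"; unigrams only
        bags = [bag_of(["SCC", "SCC"], "d1"), bag_of(["AC"], "d2")]
        X, vec = tfidf_features(bags, ngram_range=(1, 1), dim=10)
        i_scc = vec.vocabulary_.index("SCC")
        i_ac = vec.vocabulary_.index("AC")
        # tf-idf(d1, SCC) pre-norm = 2*(ln(3/2)+1); sole nonzero -> 1.0 after L2
        assert X[0, i_scc] == pytest.approx(1.0)
        assert X[0, i_ac] == 0.0
        raw = 2 * (math.log(3 / 2) + 1)
        idf = vec.idf_[i_scc]
        assert 2 * idf == pytest.approx(raw)

    def test_oracle_equivalence_random_corpora(self, rng):
        for _ in range(100):
            n_docs = rng.integers(2, 6)
            docs = [[("AC" if rng.random() < 0.5 else "SCC")
                     for _ in range(rng.integers(1, 7))] for _ in range(n_docs)]
            bags = [bag_of(d, f"d{i}") for i, d in enumerate(docs)]
            X, vec = tfidf_features(bags)
            expected, vocab = brute_force_tfidf(docs)
            assert vec.vocabulary_ == vocab
            np.testing.assert_allclose(X, expected, atol=1e-12)

    def test_identical_docs_and_unit_norm(self, rng):
        bags = [bag_of(["AC", "SCC", "AC"], f"d{i}") for i in range(3)]
        bags.append(bag_of(["SCC"] * 5, "d3"))
        X, _ = tfidf_features(bags)
        np.testing.assert_allclose(X[0], X[1])
        np.testing.assert_allclose(np.linalg.norm(X, axis=1), 1.0)

    def test_transform_unseen_and_errors(self):
        bags = [bag_of(["SCC", "AC"], "a"), bag_of(["AC"], "b")]
        _, vec = tfidf_features(bags)
        unseen = vec.transform([bag_of(["AC", "AC"], "c")])
        assert unseen.shape == (1, len(vec.vocabulary_))
        with pytest.raises(ValueError, match="empty"):
            tfidf_features([])
        with pytest.raises(ValueError, match="2 bags"):
            TfidfBagVectorizer().fit([bag_of(["AC"])])


class TestClassWeights:
    def test_training_corpus_ratio(self):
        # the imbalanced slide corpus: 245 SCC vs 36 AC
        labels = ["SCC"] * 245 + ["AC"] * 36
        w = compute_class_weights(labels)
        assert w.w_ac / w.w_scc == pytest.approx(245 / 36)
        assert w.w_scc * 245 + w.w_ac * 36 == pytest.approx(281)

    def test_balanced_and_invariant(self, rng):
        w = compute_class_weights(["SCC", "AC"] * 10)
        assert w.w_scc == w.w_ac == 1.0
        n_scc, n_ac = rng.integers(1, 50, 2)
        w = compute_class_weights(["SCC"] * n_scc + ["AC"] * n_ac)
        assert w.w_scc * n_scc + w.w_ac * n_ac == pytest.approx(n_scc + n_ac)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            compute_class_weights(["SCC"] * 5)


@pytest.fixture(scope="module")
def separable():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-2, 0.3, (20, 2)), rng.normal(2, 0.3, (20, 2))])
    y = ["SCC"] * 20 + ["AC"] * 20
    return X, y


class TestSlideClassifier:

    def test_separable_lr_perfect_cv(self, separable):
        X, y = separable
        model = fit_slide_classifier(X, y, algo="lr")
        assert model.cv_table["mean_cv_auroc"].max() == pytest.approx(1.0)

    def test_permuted_labels_null(self, separable):
        X, y = separable
        rng = np.random.default_rng(1)
        yp = list(rng.permutation(y))
        model = fit_slide_classifier(X, yp, algo="lr")
        assert 0.35 <= model.cv_table["mean_cv_auroc"].max() <= 0.65

    def test_weight_scale_invariance(self, separable):
        X, y = separable
        # with negligible regularization the weighted-loss argmin is scale
        # invariant: doubling every class weight leaves the boundary alone
        m1 = fit_slide_classifier(X, y, algo="lr", weights=ClassWeights(1.0, 2.0),
                                  cv_grid={"C": [1e6]})
        m2 = fit_slide_classifier(X, y, algo="lr", weights=ClassWeights(2.0, 4.0),
                                  cv_grid={"C": [1e6]})
        np.testing.assert_allclose(m1.estimator.coef_, m2.estimator.coef_, rtol=1e-2)

    def test_insufficient_class_count_names_class(self, separable):
        X, y = separable
        with pytest.raises(ValueError, match="AC"):
            fit_slide_classifier(X[:24], y[:20] + ["AC"] * 4, algo="lr")

    @pytest.mark.parametrize("algo", ["rf", "svm", "adaboost", "xgb"])
    def test_all_algorithms_fit_and_predict(self, separable, algo):
        X, y = separable
        grid = {"rf": {"n_estimators": [50]}, "svm": {"C": [1.0]},
                "adaboost": {"n_estimators": [20]},
                "xgb": {"n_estimators": [30], "max_depth": [2]}}[algo]
        model = fit_slide_classifier(X, y, algo=algo, cv_grid=grid,
                                     weights=compute_class_weights(y))
        p_ac, label = predict_slide(model, X[-1])
        assert 0.0 <= p_ac <= 1.0 and label in ("SCC", "AC")
        assert model.cv_table["mean_cv_auroc"].max() > 0.9


class TestPredictSlide:
    def test_scheme_mismatch_and_routing(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(-1, 0.5, (10, 10)), rng.normal(1, 0.5, (10, 10))])
        y = ["SCC"] * 10 + ["AC"] * 10
        model = fit_slide_classifier(X, y, algo="lr", cv_grid={"C": [1.0]},
                                     scheme="histogram")
        with pytest.raises(ValueError, match="scheme"):
            predict_slide(model, FeatureVector(np.zeros(10), scheme="tfidf"))
        # majority vote ignores any fitted classifier
        assert majority_vote(bag_of(["AC", "AC", "SCC"])) == "AC"

    def test_all_ac_bags_predicted_ac(self):
        bags, truth = make_prediction_bags(60, prevalence=0.5, q=1.0, seed=4)
        X, vec = tfidf_features(bags)
        model = fit_slide_classifier(X, truth, algo="lr", cv_grid={"C": [1.0]},
                                     weights=compute_class_weights(truth))
        model.vectorizer = vec
        all_ac = bag_of(["AC"] * 20, "pure")
        p_ac, label = predict_slide(model, all_ac)
        assert label == "AC" and p_ac > 0.5


class TestEndToEndSignal:
    def test_auroc_increases_with_token_fidelity(self):
        results = {}
        for q in (0.5, 0.7, 0.9):
            bags, truth = make_prediction_bags(200, 0.5, q, seed=11)
            X, vec = tfidf_features(bags)
            model = fit_slide_classifier(X, truth, algo="lr",
                                         weights=compute_class_weights(truth))
            test_bags, test_truth = make_prediction_bags(200, 0.5, q, seed=211)
            Xt = vec.transform(test_bags)
            scores = model.estimator.predict_proba(Xt)[:, 1]
            results[q] = auroc(scores, np.array(test_truth))
        assert abs(results[0.5] - 0.5) <= 0.1
        assert results[0.7] > 0.8
        assert results[0.9] > 0.98
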