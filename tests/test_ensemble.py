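"""Ensemble construction: bagging, subspaces, interactions, screening,
per-bag fitting, aggregation and OOB estimation."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from rglm import (
    EnsembleConfig,
    Family,
    RGLMModel,
    draw_bag,
    expand_interactions,
    fit_bag,
    oob_predict,
    predict,
    sample_subspace,
    screen_candidates,
    term_covariates,
    train_rglm,
)
from rglm.ensemble import bag_response
from rglm.simulate import make_benchmark


# -- sampling primitives -----------------------------------------------------

def test_draw_bag_partition_identity():
    rng = np.random.default_rng(0)
    for n in (1, 2, 17, 100):
        bag, oob = draw_bag(n, rng)
        assert len(bag) == n
        assert set(bag) | set(oob) == set(range(n))
        assert set(bag) & set(oob) == set()
    bag, oob = draw_bag(1, rng)
    assert list(bag) == [0] and len(oob) == 0


def test_bootstrap_unique_fraction_632():
    rng = np.random.default_rng(1)
    n = 1000
    fracs = [len(np.unique(draw_bag(n, rng)[0])) / n for _ in range(2000)]
    expected = 1 - (1 - 1 / n) ** n
    assert np.mean(fracs) == pytest.approx(expected, abs=0.002)


def test_sample_subspace_contract():
    rng = np.random.default_rng(2)
    assert list(sample_subspace(5, 5, rng)) == [0, 1, 2, 3, 4]
    sub = sample_subspace(100, 20, rng)
    assert len(sub) == 20 and len(set(sub)) == 20
    assert sub.min() >= 0 and sub.max() < 100
    with pytest.raises(ValueError):
        sample_subspace(10, 11, rng)


def test_sample_subspace_uniform():
    rng = np.random.default_rng(3)
    counts = np.zeros(10)
    reps = 5000
    for _ in range(reps):
        counts[sample_subspace(10, 3, rng)] += 1
    freq = counts / reps
    assert freq == pytest.approx(np.full(10, 0.3), abs=0.03)


def test_expand_interactions_distinct_pairs():
    terms = expand_interactions([1, 2, 3], 2, include_self=False)
    assert terms == [(1,), (2,), (3,), (1, 2), (1, 3), (2, 3)]
    assert expand_interactions([7], 3, include_self=False) == [(7,)]


def test_expand_interactions_with_self_products():
    terms = expand_interactions([1, 2], 2, include_self=True)
    assert terms == [(1,), (2,), (1, 1), (1, 2), (2, 2)]


@pytest.mark.parametrize("m,order", [(4, 3), (5, 2), (6, 1)])
def test_expand_count_matches_enumeration(m, order):
    from math import comb

    terms = expand_interactions(range(m), order, include_self=False)
    assert len(terms) == sum(comb(m, j) for j in range(1, order + 1))
    assert len(set(terms)) == len(terms)


def test_term_covariates_are_products():
    X = np.array([[1.0, 2, 3], [4, 5, 6]])
    covs = term_covariates(X, [(0,), (1, 2), (2, 2)])
    assert covs[:, 0] == pytest.approx(X[:, 0])
    assert covs[:, 1] == pytest.approx(X[:, 1] * X[:, 2])
    assert covs[:, 2] == pytest.approx(X[:, 2] ** 2)


# -- screening ---------------------------------------------------------------

def test_screen_perfect_covariate_first():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 5))
    y = X[:, 3].copy()
    terms = [(j,) for j in range(5)]
    kept = screen_candidates(terms, X, y, 3, "gaussian")
    assert kept[0] == (3,)
    assert len(kept) == 3
    # fewer terms than the cap: all pass through
    assert len(screen_candidates(terms, X, y, 50, "gaussian")) == 5


def test_screen_order_matches_independent_rank_oracle():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(25, 20))
    y = rng.normal(size=25)
    terms = [(j,) for j in range(20)]
    kept = screen_candidates(terms, X, y, 20, "gaussian")
    scores = [abs(pearsonr(X[:, j], y)[0]) for j in range(20)]
    oracle = [terms[i] for i in sorted(range(20), key=lambda i: (-scores[i], terms[i]))]
    assert kept == oracle


# -- bag fitting and training ------------------------------------------------

def test_fit_bag_containment_chain():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(40, 8))
    y = X[:, 2] + 0.1 * rng.normal(size=40)
    cfg = EnsembleConfig(family="gaussian", max_interaction_order=2,
                         n_features_in_bag=4, n_candidate_covariates=6, seed=0)
    bag = fit_bag(X, y, cfg, np.random.default_rng(1))
    expanded = set(expand_interactions(bag.subspace, 2, True))
    assert set(bag.candidate_terms) <= expanded
    assert set(bag.model.selected_terms) <= set(bag.candidate_terms)
    assert len(bag.candidate_terms) <= 6


def test_fit_bag_finds_perfect_feature():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(30, 5))
    y = X[:, 1].copy()
    cfg = EnsembleConfig(family="gaussian", n_features_in_bag=5, seed=0)
    bag = fit_bag(X, y, cfg, np.random.default_rng(2))
    assert (1,) in bag.model.selected_terms


def test_fit_bag_deterministic():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(30, 6))
    y = (X[:, 0] > 0).astype(float)
    cfg = EnsembleConfig(n_features_in_bag=4, seed=0)
    b1 = fit_bag(X, y, cfg, np.random.default_rng(3))
    b2 = fit_bag(X, y, cfg, np.random.default_rng(3))
    assert np.array_equal(b1.bag_indices, b2.bag_indices)
    assert np.array_equal(b1.subspace, b2.subspace)
    assert b1.model.selected_terms == b2.model.selected_terms
    assert b1.model.fit.coefficients == b2.model.fit.coefficients


def test_train_validates_inputs():
    X = np.random.default_rng(0).normal(size=(20, 3))
    with pytest.raises(ValueError):
        train_rglm(X, np.ones(20), EnsembleConfig(n_bags=2))  # constant y
    with pytest.raises(ValueError):
        train_rglm(np.empty((20, 0)), np.arange(20.0),
                   EnsembleConfig(n_bags=2, family="gaussian"))
    with pytest.raises(ValueError):
        train_rglm(X, np.arange(20.0), EnsembleConfig(n_bags=2))  # not 0/1


def test_train_deterministic_given_seed():
    X, y = make_benchmark("twonorm", 80, rng=0)
    cfg = EnsembleConfig(n_bags=8, seed=42)
    m1 = train_rglm(X, y, cfg)
    m2 = train_rglm(X, y, cfg)
    X_new, _ = make_benchmark("twonorm", 30, rng=1)
    assert np.array_equal(predict(m1, X_new), predict(m2, X_new))


def test_single_bag_ensemble_equals_its_model():
    X, y = make_benchmark("twonorm", 60, rng=2)
    cfg = EnsembleConfig(n_bags=1, seed=0)
    m = train_rglm(X, y, cfg)
    direct = bag_response(m.bags[0], X, Family.BINOMIAL)
    assert predict(m, X, output="prob") == pytest.approx(direct, abs=1e-14)


# -- aggregation and OOB -----------------------------------------------------

def test_predict_is_mean_of_bag_responses(small_binary_model):
    model, X, y = small_binary_model
    per_bag = np.stack([bag_response(b, X, Family.BINOMIAL) for b in model.bags])
    external = per_bag.mean(axis=0)
    assert predict(model, X, output="prob") == pytest.approx(external, abs=1e-12)
    probs = predict(model, X, output="prob")
    assert np.all((probs >= 0) & (probs <= 1))
    cls = predict(model, X, output="class")
    assert set(np.unique(cls)) <= {0, 1}
    assert np.array_equal(cls, (probs >= 0.5).astype(int))


def test_predict_rejects_wrong_width(small_binary_model):
    model, X, _ = small_binary_model
    with pytest.raises(ValueError):
        predict(model, X[:, :-1])


def test_class_threshold_boundary():
    # averaged probability exactly at the threshold goes to class 1
    assert (np.array([0.4]) >= 0.5).astype(int)[0] == 0
    X, y = make_benchmark("twonorm", 60, rng=3)
    m = train_rglm(X, y, EnsembleConfig(n_bags=4, seed=1, classify_threshold=0.5))
    probs = predict(m, X, output="prob")
    cls = predict(m, X, output="class")
    assert np.array_equal(cls, (probs >= 0.5).astype(int))


def test_oob_single_bag_leaves_in_bag_samples_missing():
    X, y = make_benchmark("twonorm", 40, rng=4)
    m = train_rglm(X, y, EnsembleConfig(n_bags=1, seed=0))
    pred, _acc = oob_predict(m, X, y)
    in_bag = np.unique(m.bags[0].bag_indices)
    assert np.all(np.isnan(pred[in_bag]))
    oob = m.bags[0].oob_indices
    assert np.all(np.isfinite(pred[oob]))


def test_oob_covers_all_samples_with_enough_bags(small_binary_model):
    model, X, y = small_binary_model
    pred, acc = oob_predict(model, X, y)
    assert np.all(np.isfinite(pred))
    assert 0.0 <= acc <= 1.0


def test_oob_accuracy_high_on_separable_problem():
    rng = np.random.default_rng(9)
    X = rng.normal(size=(100, 10))
    y = (X[:, 0] > 0).astype(float)  # one feature dichotomizes the outcome
    m = train_rglm(X, y, EnsembleConfig(n_bags=30, seed=2))
    _, acc = oob_predict(m, X, y)
    assert acc > 0.95


# -- serialization -----------------------------------------------------------

def test_model_json_roundtrip_bit_exact(small_binary_model):
    model, X, _ = small_binary_model
    restored = RGLMModel.from_json(model.to_json())
    assert np.array_equal(
        predict(restored, X, output="prob"), predict(model, X, output="prob")
    )
    assert restored.config == model.config
    for b1, b2 in zip(model.bags, restored.bags):
        assert np.array_equal(b1.oob_indices, b2.oob_indices)
        assert b1.model.selected_terms == b2.model.selected_terms
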