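import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import auc_pairs_oracle
from petrad.classify import (
    AucResult,
    auc_rank,
    fit_multinomial,
    make_folds,
    multiclass_auc,
    pairwise_auc,
    run_cv,
    sham_experiment,
)
from petrad.dimred import DimredConfig
from petrad.models import BIOCHEM_COLS, ModelSpec, model_menu


# ------------------------------------------------------------------ folds

def test_folds_40_lesions_train_32():
    labels = np.array(["cluster1"] * 13 + ["cluster2"] * 18 + ["sporadic"] * 9)
    folds = make_folds(labels, k=5, seed=0)
    sizes = np.bincount(folds, minlength=5)
    assert (sizes == 8).all()
    for f in range(5):
        assert (folds != f).sum() == 32
        for cls in ("cluster1", "cluster2", "sporadic"):
            per_fold = [np.sum((folds == g) & (labels == cls)) for g in range(5)]
            assert max(per_fold) - min(per_fold) <= 1


def test_folds_leave_one_out_layout():
    labels = np.array(["a", "a", "b", "b", "c"])
    folds = make_folds(labels, k=5, seed=1)
    assert sorted(np.bincount(folds, minlength=5)) == [1, 1, 1, 1, 1]


def test_folds_deterministic():
    labels = np.array(["a"] * 10 + ["b"] * 10)
    np.testing.assert_array_equal(make_folds(labels, 5, seed=3), make_folds(labels, 5, seed=3))
    assert not np.array_equal(make_folds(labels, 5, seed=3), make_folds(labels, 5, seed=4))


def test_folds_k_exceeds_n():
    with pytest.raises(ValueError):
        make_folds(np.array(["a", "b"]), k=5, seed=0)


# ------------------------------------------------------------------ model

def test_intercept_only_predicts_frequencies():
    y = np.array(["a"] * 6 + ["b"] * 3 + ["c"] * 1)
    model = fit_multinomial(np.empty((10, 0)), y)
    proba = model.predict_proba(np.empty((4, 0)))
    np.testing.assert_allclose(proba, np.tile([0.6, 0.3, 0.1], (4, 1)))


def test_separable_predictor_training_auc_one():
    x = np.array([0, 0.1, 0.2, 5, 5.1, 5.2, 10, 10.1, 10.2])[:, None]
    y = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    model = fit_multinomial(x, y)
    proba = model.predict_proba(x)
    res = AucResult.from_proba(proba, y, classes=("a", "b", "c"))
    assert res.multiclass == pytest.approx(1.0)


def test_multinomial_parameter_recovery():
    rng = np.random.default_rng(0)
    n = 10000
    X = rng.normal(size=(n, 2))
    beta = np.array([[1.5, -0.5], [0.0, 1.0]])  # class b, c vs baseline a
    logits = np.column_stack([np.zeros(n), X @ beta[0], X @ beta[1]])
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    y = np.array([["a", "b", "c"][rng.choice(3, p=pi)] for pi in p])
    model = fit_multinomial(X, y, ridge_lambda=1e-8)
    coef = model.coef_  # 3 x 2, reference-coded internally by sklearn (softmax)
    order = list(model.classes_)
    rec_b = coef[order.index("b")] - coef[order.index("a")]
    rec_c = coef[order.index("c")] - coef[order.index("a")]
    se = 3 * 2.5 / np.sqrt(n)  # coarse 3-se bound
    np.testing.assert_allclose(rec_b, beta[0], atol=se)
    np.testing.assert_allclose(rec_c, beta[1], atol=se)


def test_single_class_training_rejected():
    with pytest.raises(ValueError):
        fit_multinomial(np.zeros((4, 1)), np.array(["a"] * 4))


# -------------------------------------------------------------------- AUC

def test_auc_perfect_and_ties():
    assert auc_rank([1, 2, 3, 10, 11], [False, False, False, True, True]) == 1.0
    assert auc_rank([5, 5, 5, 5], [True, False, True, False]) == 0.5


def test_pairwise_auc_six_lesion_toy_vs_oracle():
    proba = np.array(
        [
            [0.7, 0.2, 0.1],
            [0.5, 0.3, 0.2],
            [0.4, 0.4, 0.2],
            [0.3, 0.5, 0.2],
            [0.4, 0.5, 0.1],
            [0.2, 0.6, 0.2],
        ]
    )
    y = np.array(["a", "a", "a", "b", "b", "b"])
    sel = slice(None)
    a_ij = auc_pairs_oracle(proba[sel, 0], y == "a")
    a_ji = auc_pairs_oracle(proba[sel, 1], y == "b")
    expected = 0.5 * (a_ij + a_ji)
    assert pairwise_auc(proba, y, "a", "b", ("a", "b", "c")) == pytest.approx(expected)


@settings(max_examples=60, deadline=None)
@given(st.lists(st.integers(0, 6), min_size=4, max_size=20))
def test_auc_rank_matches_pair_counting(scores):
    labels = [i % 2 == 0 for i in range(len(scores))]
    if not (any(labels) and not all(labels)):
        return
    ours = auc_rank(np.array(scores, dtype=float), np.array(labels))
    assert ours == pytest.approx(auc_pairs_oracle(scores, labels), abs=1e-12)


def test_pairwise_auc_symmetric_in_roles():
    rng = np.random.default_rng(1)
    proba = rng.dirichlet([1, 1, 1], size=12)
    y = np.array(["a", "b", "c"] * 4)
    ab = pairwise_auc(proba, y, "a", "b", ("a", "b", "c"))
    ba = pairwise_auc(proba, y, "b", "a", ("a", "b", "c"))
    assert ab == pytest.approx(ba)


def test_multiclass_auc_arithmetic():
    assert multiclass_auc({(1, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0}) == 1.0
    assert multiclass_auc({(1, 2): 1.0, (1, 3): 0.9, (2, 3): 0.7}) == pytest.approx(0.8667, abs=1e-4)


def test_multiclass_random_scores_near_half():
    rng = np.random.default_rng(2)
    n = 3000
    proba = rng.dirichlet([1, 1, 1], size=n)
    y = rng.choice(["a", "b", "c"], size=n)
    res = AucResult.from_proba(proba, y, classes=("a", "b", "c"))
    assert res.multiclass == pytest.approx(0.5, abs=0.02)


def test_absent_class_gives_nan():
    proba = np.array([[0.5, 0.3, 0.2]] * 4)
    y = np.array(["a"] * 4)
    assert np.isnan(pairwise_auc(proba, y, "a", "b", ("a", "b", "c")))


# --------------------------------------------------------------- pipeline

def test_run_cv_planted_signal(synthetic_features):
    labels = synthetic_features["cluster"].to_numpy()
    block = synthetic_features.drop(columns=["cluster"])
    res = run_cv(block, labels, ModelSpec("suvmax"), k=5, seed=0)
    assert res.mean_test.pairwise[("cluster1", "cluster2")] >= 0.95


def test_run_cv_null_labels_near_half(synthetic_features):
    rng = np.random.default_rng(7)
    block = synthetic_features.drop(columns=["cluster"])
    aucs = []
    for it in range(20):
        y = rng.permutation(synthetic_features["cluster"].to_numpy())
        res = run_cv(block, y, ModelSpec("suvmax"), k=5, seed=it)
        aucs.append(res.mean_test.multiclass)
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.06)


def test_run_cv_combined_models_overfit_pattern(synthetic_features):
    """Adding biochemistry inflates training AUC relative to its own base."""
    labels = synthetic_features["cluster"].to_numpy()
    block = synthetic_features.drop(columns=["cluster"])
    base = run_cv(block, labels, ModelSpec("pet3factor"), DimredConfig(subjects_per_factor=10), seed=2)
    combo = run_cv(
        block, labels, ModelSpec("pet3factor", add_biochem=True),
        DimredConfig(subjects_per_factor=10), seed=2,
    )
    assert combo.mean_train.multiclass >= base.mean_train.multiclass - 1e-9


def test_run_cv_deterministic(synthetic_features):
    labels = synthetic_features["cluster"].to_numpy()
    block = synthetic_features.drop(columns=["cluster"])
    a = run_cv(block, labels, ModelSpec("pet3feature"), seed=5)
    b = run_cv(block, labels, ModelSpec("pet3feature"), seed=5)
    assert a.mean_test.multiclass == b.mean_test.multiclass
    assert a.mean_train.pairwise == b.mean_train.pairwise


def test_no_leakage_training_artifacts(synthetic_features):
    """Mutating test-fold lesions leaves all training-fold artefacts identical."""
    labels = synthetic_features["cluster"].to_numpy()
    block = synthetic_features.drop(columns=["cluster"])
    folds = make_folds(labels, k=5, seed=0)
    res = run_cv(block, labels, ModelSpec("pet3factor"), folds=folds)

    mutated = block.copy()
    test_rows = np.flatnonzero(folds == 0)
    num_cols = [c for c in mutated.columns if c not in BIOCHEM_COLS]
    mutated.iloc[test_rows, [mutated.columns.get_loc(c) for c in num_cols]] += 137.0
    res2 = run_cv(mutated, labels, ModelSpec("pet3factor"), folds=folds)

    fm1 = res.folds[0].artifacts["factor_model"]
    fm2 = res2.folds[0].artifacts["factor_model"]
    assert fm1.retained == fm2.retained
    np.testing.assert_array_equal(fm1.loadings, fm2.loadings)
    np.testing.assert_array_equal(fm1.scaler.mean, fm2.scaler.mean)
    np.testing.assert_array_equal(fm1.scaler.sd, fm2.scaler.sd)
    c1 = res.folds[0].artifacts["classifier"].coef_
    c2 = res2.folds[0].artifacts["classifier"].coef_
    np.testing.assert_array_equal(c1, c2)
    # train metrics identical, test metrics (of the mutated fold) generally not
    assert res.folds[0].train.multiclass == res2.folds[0].train.multiclass


def test_model_menu_structure():
    menu = model_menu()
    assert len(menu) == 9
    names = [m.name for m in menu]
    assert names[0] == "biochem"
    assert "pet3factor" in names and "pet3factor+biochem" in names
    with pytest.raises(ValueError):
        ModelSpec("biochem", add_biochem=True)
    with pytest.raises(ValueError):
        ModelSpec("nonsense")


# ------------------------------------------------------------------- sham

def test_sham_identity_permutation_reproduces_cv(synthetic_features):
    labels = synthetic_features["cluster"].to_numpy()
    block = synthetic_features.drop(columns=["cluster"])
    idperm = [np.arange(len(labels))]
    sham = sham_experiment(
        block, labels, ModelSpec("suvmax"), iterations=1, seed=4, permutations=idperm
    )
    direct = run_cv(block, labels, ModelSpec("suvmax"), k=5, seed=4)
    assert sham.per_iteration[0] == pytest.approx(direct.mean_test.multiclass)


def test_sham_deterministic(synthetic_features):
    labels = synthetic_features["cluster"].to_numpy()
    block = synthetic_features.drop(columns=["cluster"])
    a = sham_experiment(block, labels, ModelSpec("suvmax"), iterations=3, seed=11)
    b = sham_experiment(block, labels, ModelSpec("suvmax"), iterations=3, seed=11)
    assert a.per_iteration == b.per_iteration


def test_sham_mean_near_half(synthetic_features):
    labels = synthetic_features["cluster"].to_numpy()
    block = synthetic_features.drop(columns=["cluster"])
    res = sham_experiment(block, labels, ModelSpec("suvmax"), iterations=40, seed=0)
    assert 0.44 <= res.mean <= 0.56
    assert len(res.per_iteration) == 40
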