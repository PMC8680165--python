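import numpy as np
import pytest

from pharmspace import (
    ExpressionMatrix,
    KernelMatrix,
    ResponsePanel,
    TrainConfig,
    ValidationError,
    classify_sensitive,
    compute_kernel,
    cross_validate,
    evaluate,
    filter_drugs_by_response_rate,
    kfold_split,
    load_model,
    logistic_weight,
    objective,
    predict_scores,
    save_model,
    train,
)
from pharmspace.model import _gradients, _loss_terms


def _random_instance(rng, n_drugs=5, n_samples=8, d=6, f=3, missing=0.2):
    X = rng.uniform(-1, 1, size=(n_samples, d))
    W_P = rng.normal(size=(d, f))
    Q = rng.normal(size=(n_drugs, f))
    b_Q = rng.normal(size=n_drugs)
    s = rng.normal(size=(n_drugs, n_samples))
    observed = rng.random((n_drugs, n_samples)) >= missing
    observed[0, 0] = True
    o = rng.normal(size=n_drugs)
    panel = ResponsePanel([f"d{i}" for i in range(n_drugs)],
                          [f"u{j}" for j in range(n_samples)], s, observed, o)
    kernel = KernelMatrix(panel.sample_ids, [f"r{k}" for k in range(d)], X)
    return X, W_P, Q, b_Q, panel, kernel


# ---------------------------------------------------------------------------
# prediction


def test_predict_zero_latent_returns_bias(toy_model_factory):
    model = toy_model_factory(f=1, b_Q=np.array([3.5, -1.0]))
    k = KernelMatrix(["q"], ["R1", "R2"], np.array([[0.2, -0.2]]))
    pred = predict_scores(model, k)
    np.testing.assert_allclose(pred[:, 0], [3.5, -1.0])


def test_predict_scalar_example(toy_model_factory):
    # f=1, q=2, W_P maps x=(3, 0) to p=3 -> s_hat = b + 6
    model = toy_model_factory(f=1, Q=np.array([[2.0], [0.0]]), b_Q=np.array([1.0, 0.0]))
    k = KernelMatrix(["q"], ["R1", "R2"], np.array([[1.0, 0.0]]))
    model.W_P = np.array([[3.0], [0.0]])
    assert predict_scores(model, k)[0, 0] == pytest.approx(7.0)


def test_predict_matches_triple_loop_oracle(rng, toy_model_factory):
    model = toy_model_factory(f=3, n_drugs=4,
                              W_P=rng.normal(size=(2, 3)),
                              Q=rng.normal(size=(4, 3)),
                              b_Q=rng.normal(size=4))
    X = rng.uniform(-1, 1, size=(5, 2))
    k = KernelMatrix([f"q{j}" for j in range(5)], ["R1", "R2"], X)
    pred = predict_scores(model, k)
    for i in range(4):
        for u in range(5):
            p_u = [sum(X[u, a] * model.W_P[a, c] for a in range(2)) for c in range(3)]
            expected = model.b_Q[i] + sum(model.Q[i, c] * p_u[c] for c in range(3))
            assert pred[i, u] == pytest.approx(expected, abs=1e-12)


def test_predict_axis_mismatch(toy_model_factory):
    model = toy_model_factory()
    k = KernelMatrix(["q"], ["other"], np.array([[0.1]]))
    with pytest.raises(ValidationError):
        predict_scores(model, k)


def test_predict_permutation_equivariance(rng, toy_model_factory):
    model = toy_model_factory(f=2, W_P=rng.normal(size=(2, 2)),
                              Q=rng.normal(size=(2, 2)), b_Q=rng.normal(size=2))
    X = rng.uniform(-1, 1, size=(4, 2))
    ids = [f"q{j}" for j in range(4)]
    perm = [2, 0, 3, 1]
    p1 = predict_scores(model, KernelMatrix(ids, ["R1", "R2"], X))
    p2 = predict_scores(model, KernelMatrix([ids[j] for j in perm],
                                            ["R1", "R2"], X[perm]))
    np.testing.assert_allclose(p2, p1[:, perm])


# ---------------------------------------------------------------------------
# calibration weight


def test_logistic_weight_midpoint_and_min_branch():
    assert logistic_weight(0.0, 0.0, 0.0, 1.0) == pytest.approx(0.5)
    # observed deeply insensitive dominates via the min
    w = logistic_weight(-30.0, 30.0, 0.0, 1.0)
    assert w == pytest.approx(1.0 / (1.0 + np.exp(30.0)), rel=1e-9)
    # closed form: s_obs = o + 10/l, s_pred = o + 20/l
    l = 2.5
    w2 = logistic_weight(10 / l, 20 / l, 0.0, l)
    assert w2 == pytest.approx(1.0 / (1.0 + np.exp(-10.0)), rel=1e-12)


def test_logistic_weight_monotone_in_both_arguments():
    base = logistic_weight(0.3, -0.2, 0.0, 1.0)
    assert logistic_weight(0.5, -0.2, 0.0, 1.0) >= base
    assert logistic_weight(0.3, 0.0, 0.0, 1.0) >= base
    with pytest.raises(ValidationError):
        logistic_weight(0.0, 0.0, 0.0, -1.0)


def test_deeply_insensitive_pair_downweighted_below_one_percent(toy_model_factory):
    """The extrapolation calibration: a pair observed AND predicted far
    beyond the max dosage contributes <1% of its unweighted loss."""
    s_obs, s_pred, o = -8.0, -7.0, -2.0   # both ~5-6 log2 units past the dosage
    c = logistic_weight(s_obs, s_pred, o, 1.0)
    weighted = c * (s_obs - s_pred) ** 2
    unweighted = (s_obs - s_pred) ** 2
    assert weighted < 0.01 * unweighted


# ---------------------------------------------------------------------------
# objective and gradients


def test_objective_perfect_predictions(toy_model_factory, rng):
    model = toy_model_factory(f=2, n_drugs=3, W_P=rng.normal(size=(2, 2)),
                              Q=rng.normal(size=(3, 2)), b_Q=rng.normal(size=3),
                              o=rng.normal(size=3))
    X = rng.uniform(-1, 1, size=(4, 2))
    kernel = KernelMatrix([f"u{j}" for j in range(4)], ["R1", "R2"], X)
    s = predict_scores(model, kernel)
    panel = ResponsePanel(model.drug_ids, kernel.query_sample_ids, s,
                          np.ones_like(s, bool), model.max_dose_log2)
    cfg = TrainConfig(f=2, l2_lambda=0.0)
    loss, diag = objective(model, panel, kernel, cfg)
    assert loss == pytest.approx(0.0, abs=1e-15)
    assert diag["K"] == s.size


def test_objective_single_pair_arithmetic(toy_model_factory):
    # one observed pair, residual 2, c forced to 1, d=1, lambda=0 -> 0.5*4/1 = 2
    model = toy_model_factory(f=1, n_drugs=1, Q=np.array([[0.0]]), b_Q=np.array([0.0]))
    kernel = KernelMatrix(["u0"], ["R1", "R2"], np.array([[0.0, 0.0]]))
    panel = ResponsePanel(["D0"], ["u0"], np.array([[2.0]]),
                          np.array([[True]]), np.array([0.0]))
    cfg = TrainConfig(f=1, l2_lambda=0.0)
    loss, _ = objective(model, panel, kernel, cfg, c=np.ones((1, 1)))
    assert loss == pytest.approx(2.0)


def test_objective_matches_loop_oracle(rng):
    X, W_P, Q, b_Q, panel, kernel = _random_instance(rng)
    cfg = TrainConfig(f=3, l2_lambda=0.37, logistic_slope=1.4,
                      sample_weights={"u0": 3.0})
    d_u = cfg.weights_for(panel.sample_ids)
    s_hat = b_Q[:, None] + Q @ (X @ W_P).T
    c = logistic_weight(np.where(panel.observed, panel.s, 0.0), s_hat,
                        panel.max_dose_log2[:, None], cfg.logistic_slope)
    loss, *_ = _loss_terms(W_P, Q, b_Q, X, panel, d_u, c, cfg.l2_lambda)
    total = 0.0
    for i in range(len(panel.drug_ids)):
        for u in range(len(panel.sample_ids)):
            if panel.observed[i, u]:
                total += d_u[u] * c[i, u] * (panel.s[i, u] - s_hat[i, u]) ** 2
    total += cfg.l2_lambda * ((Q ** 2).sum() + (W_P ** 2).sum())
    expected = 0.5 * total / panel.n_observed
    assert loss == pytest.approx(expected, abs=1e-12)


def _finite_diff_check(rng, seed_shift=0):
    rng = np.random.default_rng(rng.integers(2**31) + seed_shift)
    X, W_P, Q, b_Q, panel, kernel = _random_instance(rng)
    cfg = TrainConfig(f=3, l2_lambda=0.1, sample_weights={"u1": 2.0})
    d_u = cfg.weights_for(panel.sample_ids)
    s_hat = b_Q[:, None] + Q @ (X @ W_P).T
    c = logistic_weight(np.where(panel.observed, panel.s, 0.0), s_hat,
                        panel.max_dose_log2[:, None], cfg.logistic_slope)
    _, g_WP, g_Q, g_bQ = _gradients(W_P, Q, b_Q, X, panel, d_u, c, cfg.l2_lambda)

    def loss_at(Wp, Qp, bp):
        return _loss_terms(Wp, Qp, bp, X, panel, d_u, c, cfg.l2_lambda)[0]

    eps = 1e-6
    worst = 0.0
    for grad, arr, setter in [
        (g_WP, W_P, lambda A: loss_at(A, Q, b_Q)),
        (g_Q, Q, lambda A: loss_at(W_P, A, b_Q)),
        (g_bQ, b_Q, lambda A: loss_at(W_P, Q, A)),
    ]:
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            up, dn = arr.copy(), arr.copy()
            up[idx] += eps
            dn[idx] -= eps
            fd = (setter(up) - setter(dn)) / (2 * eps)
            denom = max(abs(fd), abs(grad[idx]), 1e-8)
            worst = max(worst, abs(fd - grad[idx]) / denom)
    return worst


def test_gradients_match_finite_differences(rng):
    """Analytic gradients (c, d frozen) vs central differences, rel 1e-5."""
    assert _finite_diff_check(rng) < 1e-5


# ---------------------------------------------------------------------------
# classification and evaluation


@pytest.mark.parametrize("ic50,max_dose,expected",
                         [(2.0, 8.0, True), (8.0, 8.0, False), (16.0, 8.0, False)])
def test_classify_sensitive_strict_boundary(ic50, max_dose, expected):
    s, o = -np.log2(ic50), -np.log2(max_dose)
    assert bool(classify_sensitive(s, o)) is expected


def test_evaluate_perfect_and_degenerate():
    s = np.array([[1.0, -1.0, 2.0], [0.5, 0.1, -0.3]])
    panel = ResponsePanel(["d0", "d1"], ["u0", "u1", "u2"], s,
                          np.ones_like(s, bool), np.zeros(2))
    out = evaluate(s, panel)
    assert out["pooled_accuracy"] == 1.0
    assert out["pooled_mae_sensitive"] == 0.0
    # a drug with zero observed pairs reports missing metrics
    panel2 = ResponsePanel(["d0", "d1"], ["u0", "u1", "u2"], s,
                           np.array([[True, True, True], [False] * 3]), np.zeros(2))
    out2 = evaluate(s, panel2)
    assert np.isnan(out2["per_drug"]["d1"]["accuracy"])


def test_evaluate_accuracy_and_median_mae():
    # all predicted insensitive while half the observed pairs are sensitive
    s = np.array([[1.0, 2.0, -1.0, -2.0]])
    pred = np.full_like(s, -5.0)
    panel = ResponsePanel(["d0"], ["a", "b", "c", "d"], s,
                          np.ones_like(s, bool), np.zeros(1))
    out = evaluate(pred, panel)
    assert out["pooled_accuracy"] == 0.5
    # sensitive-pair errors {1, 2, 9} -> median 2
    s2 = np.array([[1.0, 1.0, 1.0]])
    pred2 = np.array([[0.0, 3.0, 10.0]])
    panel2 = ResponsePanel(["d0"], ["a", "b", "c"], s2,
                           np.ones_like(s2, bool), np.zeros(1))
    assert evaluate(pred2, panel2)["pooled_mae_sensitive"] == pytest.approx(2.0)


def test_kfold_partition_properties():
    ids = [f"u{j}" for j in range(5)]
    folds = kfold_split(ids, 5, seed=3)
    assert sorted(sum(folds, [])) == sorted(ids)
    assert all(len(f) == 1 for f in folds)
    assert kfold_split(ids, 5, seed=3) == folds   # reproducible
    assert kfold_split(ids, 5, seed=4) != folds
    with pytest.raises(ValidationError):
        kfold_split(ids, 6, seed=0)


# ---------------------------------------------------------------------------
# training


def test_train_interpolates_single_pair():
    expr = ExpressionMatrix(["g0", "g1", "g2"], ["u0", "u1"],
                            [[1.0, 2.0], [3.0, 1.0], [0.0, 4.0]], "log_normalized")
    s = np.array([[1.5, -0.5]])
    panel = ResponsePanel(["d0"], ["u0", "u1"], s, np.ones_like(s, bool),
                          np.array([0.0]))
    cfg = TrainConfig(f=1, max_epochs=30_000, learning_rate=0.05, l2_lambda=0.0,
                      seed=0, tol=0.0)
    model = train(panel, expr, expr.gene_ids, cfg)
    assert model.loss_trace[-1] < 1e-6


def test_train_large_lambda_collapses_to_bias(tiny_panel):
    """With overwhelming regularization the latent part vanishes and each
    drug's prediction settles at its calibration-weighted mean score."""
    expr, panel, _ = tiny_panel
    cfg = TrainConfig(f=2, max_epochs=4000, learning_rate=0.01,
                      l2_lambda=1e3, seed=0)
    model = train(panel, expr, expr.gene_ids, cfg)
    assert np.abs(model.Q).max() < 1e-3 and np.abs(model.W_P).max() < 1e-3
    k = compute_kernel(expr, model.basis)
    pred = predict_scores(model, k)
    np.testing.assert_allclose(pred, model.b_Q[:, None] * np.ones(pred.shape[1]),
                               atol=1e-3)
    # fixed point of the weighted bias update: sum_u c_iu (s_iu - b_i) = 0
    c = logistic_weight(panel.s, pred, panel.max_dose_log2[:, None], 1.0)
    for i in range(len(panel.drug_ids)):
        obs = panel.observed[i]
        resid = float((c[i, obs] * (panel.s[i, obs] - model.b_Q[i])).sum())
        assert abs(resid) / obs.sum() < 0.01


def test_train_recovers_in_class_noiseless_panel(tiny_panel):
    """A panel generated from a known (W_P, Q, b_Q) applied to the realized
    kernel features is recovered: held-out correlation >= 0.95."""
    expr, _, _ = tiny_panel
    rng = np.random.default_rng(1)
    held = expr.sample_ids[-5:]
    kept = expr.sample_ids[:-5]
    from pharmspace import fit_reference_basis
    basis = fit_reference_basis(expr.select_samples(kept), expr.gene_ids)
    X_all = compute_kernel(expr, basis).values
    f, n_drugs = 2, 4
    W_true = rng.normal(size=(len(kept), f))
    Q_true = rng.normal(size=(n_drugs, f))
    b_true = rng.normal(size=n_drugs)
    s_all = b_true[:, None] + Q_true @ (X_all @ W_true).T
    panel = ResponsePanel([f"d{i}" for i in range(n_drugs)], expr.sample_ids,
                          s_all, np.ones_like(s_all, bool),
                          np.median(s_all, axis=1))
    cfg = TrainConfig(f=2, max_epochs=20_000, learning_rate=0.05, seed=0, tol=1e-9)
    model = train(panel.select_samples(kept), expr.select_samples(kept),
                  expr.gene_ids, cfg)
    k = compute_kernel(expr.select_samples(held), model.basis)
    pred = predict_scores(model, k)
    idx = [panel.sample_ids.index(u) for u in held]
    r = np.corrcoef(pred.ravel(), s_all[:, idx].ravel())[0, 1]
    assert r >= 0.95


def test_train_divergence_raises(tiny_panel):
    expr, panel, _ = tiny_panel
    cfg = TrainConfig(f=2, max_epochs=2000, learning_rate=1e4, seed=0)
    with pytest.raises(ValidationError, match="learning rate"):
        train(panel, expr, expr.gene_ids, cfg)


def test_train_seeded_determinism_and_serialization(tiny_panel, tmp_path):
    expr, panel, _ = tiny_panel
    cfg = TrainConfig(f=2, max_epochs=500, seed=11)
    m1 = train(panel, expr, expr.gene_ids, cfg)
    m2 = train(panel, expr, expr.gene_ids, cfg)
    assert np.array_equal(m1.W_P, m2.W_P)
    assert np.array_equal(m1.Q, m2.Q)
    assert np.array_equal(m1.b_Q, m2.b_Q)
    p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
    save_model(m1, p1)
    save_model(m2, p2)
    assert p1.read_bytes() == p2.read_bytes()   # bit-identical archives
    back = load_model(p1)
    assert np.array_equal(back.W_P, m1.W_P) and np.array_equal(back.b_Q, m1.b_Q)
    assert back.drug_ids == m1.drug_ids
    k = compute_kernel(expr, m1.basis)
    np.testing.assert_array_equal(predict_scores(back, k), predict_scores(m1, k))


def test_train_loss_trace_non_increasing(tiny_panel):
    expr, panel, _ = tiny_panel
    cfg = TrainConfig(f=2, max_epochs=2000, learning_rate=0.01, seed=0)
    model = train(panel, expr, expr.gene_ids, cfg)
    diffs = np.diff(model.loss_trace)
    if not np.all(diffs <= 1e-10):
        cfg_small = TrainConfig(f=2, max_epochs=2000, learning_rate=0.001, seed=0)
        model = train(panel, expr, expr.gene_ids, cfg_small)
        assert np.all(np.diff(model.loss_trace) <= 1e-10)


def test_cross_validate_pooled_accuracy_noiseless(tiny_panel):
    expr, panel, _ = tiny_panel
    cfg = TrainConfig(f=2, max_epochs=20_000, learning_rate=0.05, seed=0, tol=1e-9)
    cv = cross_validate(panel, expr, expr.gene_ids, cfg, k_folds=5, seed=0)
    assert cv["pooled"]["pooled_accuracy"] >= 0.9
    assert np.all(np.isfinite(cv["predictions"]))


def test_filter_drugs_by_response_rate():
    s = np.array([[1.0, 1.0, 1.0, -1.0],    # 75% sensitive
                  [-1.0, -1.0, -1.0, 1.0]]) # 25% sensitive
    panel = ResponsePanel(["hit", "miss"], list("abcd"), s,
                          np.ones_like(s, bool), np.zeros(2))
    out = filter_drugs_by_response_rate(panel, list("abcd"), min_fraction=0.3)
    assert out.drug_ids == ["hit"]
    with pytest.raises(ValidationError):
        filter_drugs_by_response_rate(panel, ["zz"])
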