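"""The calibrated matrix-factorization recommender for drug response.

A sample's kernel features x_u (correlations to the d training cell lines)
are projected into an f-dimensional latent "pharmacogenomic space" by a
learned matrix W_P; each drug i lives in the same space as a vector q_i
with a bias b_i^Q, and the predicted sensitivity is

    s_hat(i, u) = b_i^Q + q_i . (x_u W_P).

Training minimises a weighted squared error over the observed drug-sample
pairs.  Each pair carries a calibration weight

    c_iu = min(sigmoid(l (s_iu - o_i)), sigmoid(l (s_hat_iu - o_i)))

where o_i is the drug's maximum tested dosage on the -log2-uM scale: when
both the observed and the predicted IC50 lie beyond the maximum tested
dosage, both sigmoids are small and the pair is down-weighted, because an
IC50 extrapolated past the dosage range is unreliable by construction.
A per-sample weight d_u > 1 focuses the model on a cancer type of interest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .data_model import ExpressionMatrix, ResponsePanel, ValidationError
from .kernel import KernelMatrix, ReferenceBasis, compute_kernel, fit_reference_basis


@dataclass
class TrainConfig:
    """Hyper-parameters of the pharmacogenomic-space fit.

    Defaults follow the reference protocol: a 10-dimensional space trained
    full-batch at learning rate 0.01 for at most 100,000 epochs.  ``tol``
    stops training early when the relative loss change over a 100-epoch
    window falls below it.  ``sample_weights`` maps sample id -> d_u
    (unlisted samples get 1); ``logistic_slope`` is l in the calibration
    weight, in -log2-uM units.
    """

    f: int = 10
    learning_rate: float = 0.01
    max_epochs: int = 100_000
    l2_lambda: float = 0.01
    logistic_slope: float = 1.0
    sample_weights: dict | None = None
    seed: int = 0
    tol: float = 1e-7
    optimizer: str = "gd"  # "gd" (plain full-batch) or "adam"

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValidationError("learning_rate must be positive")
        if self.logistic_slope <= 0:
            raise ValidationError("logistic_slope must be positive")
        if self.f < 1:
            raise ValidationError("latent dimension f must be >= 1")
        if self.sample_weights is not None:
            if any(w <= 0 for w in self.sample_weights.values()):
                raise ValidationError("sample weights d_u must be positive")
        if self.optimizer not in ("gd", "adam"):
            raise ValidationError("optimizer must be 'gd' or 'adam'")

    def weights_for(self, sample_ids) -> np.ndarray:
        w = np.ones(len(sample_ids))
        if self.sample_weights:
            sw = {str(k): float(v) for k, v in self.sample_weights.items()}
            for j, u in enumerate(sample_ids):
                w[j] = sw.get(str(u), 1.0)
        return w


@dataclass
class PharmacogenomicModel:
    """Learned parameters plus the frozen featurization state."""

    f: int
    W_P: np.ndarray            # d reference lines x f
    Q: np.ndarray              # n_drugs x f
    b_Q: np.ndarray            # n_drugs
    drug_ids: list
    basis: ReferenceBasis
    max_dose_log2: np.ndarray  # o_i per drug
    config: TrainConfig = field(default_factory=TrainConfig)
    loss_trace: np.ndarray | None = None

    def __post_init__(self):
        self.W_P = np.asarray(self.W_P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.b_Q = np.asarray(self.b_Q, dtype=float)
        self.max_dose_log2 = np.asarray(self.max_dose_log2, dtype=float)
        n_drugs = len(self.drug_ids)
        if self.W_P.shape != (self.basis.n_reference, self.f):
            raise ValidationError("W_P must be (n_reference_lines x f)")
        if self.Q.shape != (n_drugs, self.f):
            raise ValidationError("Q must be (n_drugs x f)")
        if self.b_Q.shape != (n_drugs,) or self.max_dose_log2.shape != (n_drugs,):
            raise ValidationError("b_Q / max_dose_log2 must have one entry per drug")


def predict_scores(model: PharmacogenomicModel, kernel: KernelMatrix) -> np.ndarray:
    """Predicted sensitivity scores, drugs x query samples."""
    if list(kernel.reference_sample_ids) != list(model.basis.reference_sample_ids):
        raise ValidationError("kernel reference axis does not match the model basis")
    P = kernel.values @ model.W_P            # queries x f
    return model.b_Q[:, None] + model.Q @ P.T


def predict_scores_from_expression(
    model: PharmacogenomicModel, expr: ExpressionMatrix
) -> np.ndarray:
    """Convenience: featurize a log-scale expression matrix, then predict."""
    return predict_scores(model, compute_kernel(expr, model.basis))


def logistic_weight(s_obs, s_pred, o, l: float = 1.0):
    """Calibration weight c = min(sigmoid(l(s_obs-o)), sigmoid(l(s_pred-o)))."""
    if l <= 0:
        raise ValidationError("logistic slope must be positive")
    def f(s):
        return expit(l * (np.asarray(s, dtype=float) - np.asarray(o, dtype=float)))
    return np.minimum(f(s_obs), f(s_pred))


def classify_sensitive(score, threshold):
    """Sensitive iff IC50 < max tested dose, i.e. s > o on the -log2 scale."""
    return np.asarray(score, dtype=float) > np.asarray(threshold, dtype=float)


def _loss_terms(W_P, Q, b_Q, X, panel, d_u, c, l2_lambda):
    """Weighted loss and its pieces for fixed calibration weights ``c``."""
    P = X @ W_P
    s_hat = b_Q[:, None] + Q @ P.T
    resid = np.where(panel.observed, panel.s - s_hat, 0.0)
    K = panel.n_observed
    wsq = d_u[None, :] * c * resid ** 2 * panel.observed
    data_term = wsq.sum()
    reg = l2_lambda * (np.sum(Q ** 2) + np.sum(W_P ** 2))
    loss = 0.5 * (data_term + reg) / K
    return loss, s_hat, resid, P


def objective(model: PharmacogenomicModel, panel: ResponsePanel, kernel: KernelMatrix,
              config: TrainConfig | None = None, c: np.ndarray | None = None):
    """Loss of ``model`` on ``panel``; c_iu computed from current predictions
    unless supplied.  Returns (loss, diagnostics dict)."""
    config = config or model.config
    if panel.n_observed == 0:
        raise ValidationError("response panel has no observed entries")
    X = kernel.values
    d_u = config.weights_for(panel.sample_ids)
    if c is None:
        P = X @ model.W_P
        s_hat = model.b_Q[:, None] + model.Q @ P.T
        c = logistic_weight(np.where(panel.observed, panel.s, 0.0), s_hat,
                            panel.max_dose_log2[:, None], config.logistic_slope)
    loss, s_hat, resid, _ = _loss_terms(
        model.W_P, model.Q, model.b_Q, X, panel, d_u, c, config.l2_lambda
    )
    K = panel.n_observed
    diagnostics = {
        "data_term": float((d_u[None, :] * c * resid ** 2 * panel.observed).sum() / (2 * K)),
        "reg_term": float(config.l2_lambda
                          * (np.sum(model.Q ** 2) + np.sum(model.W_P ** 2)) / (2 * K)),
        "K": K,
        "c": c,
        "s_hat": s_hat,
    }
    return float(loss), diagnostics


def _gradients(W_P, Q, b_Q, X, panel, d_u, c, l2_lambda):
    """Analytic gradients with the calibration weights c (and d_u) frozen."""
    loss, s_hat, resid, P = _loss_terms(W_P, Q, b_Q, X, panel, d_u, c, l2_lambda)
    K = panel.n_observed
    G = (d_u[None, :] * c * -resid * panel.observed) / K   # dL/d s_hat
    g_bQ = G.sum(axis=1)
    g_Q = G @ P + (l2_lambda / K) * Q
    g_WP = X.T @ (G.T @ Q) + (l2_lambda / K) * W_P
    return loss, g_WP, g_Q, g_bQ


def train(panel: ResponsePanel, train_expr: ExpressionMatrix, essential_genes,
          config: TrainConfig | None = None) -> PharmacogenomicModel:
    """Fit the pharmacogenomic space by full-batch gradient descent.

    The calibration weights c_iu are recomputed from the current
    predictions at the start of every epoch and treated as constants
    inside the epoch's gradient; letting the gradient flow through c
    would reward pushing all predictions insensitive to zero the loss.
    Deterministic for a fixed config and inputs.
    """
    config = config or TrainConfig()
    missing = [u for u in panel.sample_ids if u not in set(train_expr.sample_ids)]
    if missing:
        raise ValidationError(f"panel samples absent from expression: {missing[:5]}")
    basis = fit_reference_basis(train_expr.select_samples(panel.sample_ids), essential_genes)
    kernel = compute_kernel(train_expr.select_samples(panel.sample_ids), basis)
    X = kernel.values
    d = X.shape[1]
    n_drugs = len(panel.drug_ids)
    d_u = config.weights_for(panel.sample_ids)
    K = panel.n_observed
    if K == 0:
        raise ValidationError("response panel has no observed entries")

    rng = np.random.default_rng(config.seed)
    W_P = rng.normal(0.0, 0.01, size=(d, config.f))
    Q = rng.normal(0.0, 0.01, size=(n_drugs, config.f))
    # bias starts at its closed-form optimum for the zero-latent model
    w_obs = d_u[None, :] * panel.observed
    b_Q = (w_obs * np.where(panel.observed, panel.s, 0.0)).sum(axis=1) / \
        np.maximum(w_obs.sum(axis=1), 1e-300)

    o = panel.max_dose_log2[:, None]
    s_obs = np.where(panel.observed, panel.s, 0.0)
    lr = config.learning_rate
    trace = []
    if config.optimizer == "adam":
        m = [np.zeros_like(W_P), np.zeros_like(Q), np.zeros_like(b_Q)]
        v = [np.zeros_like(W_P), np.zeros_like(Q), np.zeros_like(b_Q)]
        beta1, beta2, eps = 0.9, 0.999, 1e-8

    for epoch in range(config.max_epochs):
        P = X @ W_P
        s_hat = b_Q[:, None] + Q @ P.T
        c = logistic_weight(s_obs, s_hat, o, config.logistic_slope)
        loss, g_WP, g_Q, g_bQ = _gradients(W_P, Q, b_Q, X, panel, d_u, c, config.l2_lambda)
        if not np.isfinite(loss):
            raise ValidationError(
                f"training diverged at epoch {epoch} (non-finite loss); "
                "reduce the learning rate"
            )
        trace.append(loss)
        if config.optimizer == "adam":
            t = epoch + 1
            grads = [g_WP, g_Q, g_bQ]
            params = [W_P, Q, b_Q]
            for k in range(3):
                m[k] = beta1 * m[k] + (1 - beta1) * grads[k]
                v[k] = beta2 * v[k] + (1 - beta2) * grads[k] ** 2
                mhat = m[k] / (1 - beta1 ** t)
                vhat = v[k] / (1 - beta2 ** t)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
            W_P, Q, b_Q = params
        else:
            W_P = W_P - lr * g_WP
            Q = Q - lr * g_Q
            b_Q = b_Q - lr * g_bQ
        if epoch >= 100 and epoch % 100 == 0:
            prev = trace[epoch - 100]
            if abs(prev - loss) <= config.tol * max(abs(prev), 1e-12):
                break

    return PharmacogenomicModel(
        f=config.f, W_P=W_P, Q=Q, b_Q=b_Q, drug_ids=list(panel.drug_ids),
        basis=basis, max_dose_log2=panel.max_dose_log2.copy(), config=config,
        loss_trace=np.array(trace),
    )


# ---------------------------------------------------------------------------
# Evaluation


def evaluate(pred: np.ndarray, panel: ResponsePanel) -> dict:
    """Per-drug accuracy and median absolute error over sensitive pairs.

    Accuracy is the fraction of observed pairs whose predicted class
    (IC50 below the drug's max dose) matches the observed class.  The
    error metric conditions on pairs whose *observed* class is sensitive,
    so it does not depend on the classifier under evaluation, and uses
    the median of |s - s_hat|.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.shape != panel.s.shape:
        raise ValidationError("prediction matrix shape does not match the panel")
    o = panel.max_dose_log2[:, None]
    obs_cls = classify_sensitive(panel.s, o)
    pred_cls = classify_sensitive(pred, o)
    per_drug = {}
    accs, maes = [], []
    for i, drug in enumerate(panel.drug_ids):
        mask = panel.observed[i]
        if not mask.any():
            per_drug[drug] = {"accuracy": np.nan, "mae_sensitive": np.nan, "n": 0}
            continue
        acc = float((obs_cls[i, mask] == pred_cls[i, mask]).mean())
        sens = mask & obs_cls[i]
        mae = float(np.median(np.abs(panel.s[i, sens] - pred[i, sens]))) if sens.any() else np.nan
        per_drug[drug] = {"accuracy": acc, "mae_sensitive": mae, "n": int(mask.sum())}
        accs.append(acc)
        if np.isfinite(mae):
            maes.append(mae)
    mask = panel.observed
    pooled_acc = float((obs_cls[mask] == pred_cls[mask]).mean())
    sens = mask & obs_cls
    pooled_mae = float(np.median(np.abs(panel.s[sens] - pred[sens]))) if sens.any() else np.nan
    return {
        "per_drug": per_drug,
        "pooled_accuracy": pooled_acc,
        "pooled_mae_sensitive": pooled_mae,
    }


def kfold_split(sample_ids, k_folds: int, seed: int) -> list:
    """Seeded partition of samples into k folds (sizes differ by <= 1)."""
    n = len(sample_ids)
    if n < k_folds:
        raise ValidationError(f"cannot make {k_folds} folds from {n} samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [[sample_ids[i] for i in order[j::k_folds]] for j in range(k_folds)]


def cross_validate(panel: ResponsePanel, expr: ExpressionMatrix, essential_genes,
                   config: TrainConfig | None = None, k_folds: int = 5,
                   seed: int = 0) -> dict:
    """Held-out evaluation: each fold's samples are hidden entirely
    (expression and response) while the rest train the model.

    Returns per-fold metrics, pooled metrics over all held-out
    predictions, and the full held-out prediction matrix aligned to the
    panel axes.
    """
    config = config or TrainConfig()
    folds = kfold_split(list(panel.sample_ids), k_folds, seed)
    pred = np.full_like(panel.s, np.nan, dtype=float)
    col = {u: j for j, u in enumerate(panel.sample_ids)}
    fold_metrics = []
    for test_ids in folds:
        train_ids = [u for u in panel.sample_ids if u not in set(test_ids)]
        model = train(panel.select_samples(train_ids), expr.select_samples(train_ids),
                      essential_genes, config)
        test_kernel = compute_kernel(expr.select_samples(test_ids), model.basis)
        p = predict_scores(model, test_kernel)
        for jj, u in enumerate(test_ids):
            pred[:, col[u]] = p[:, jj]
        fold_metrics.append(evaluate(p, panel.select_samples(test_ids)))
    pooled = evaluate(pred, panel)
    return {"per_fold": fold_metrics, "pooled": pooled, "predictions": pred,
            "folds": folds}


def filter_drugs_by_response_rate(panel: ResponsePanel, focus_samples,
                                  min_fraction: float = 0.3) -> ResponsePanel:
    """Keep drugs effective in at least ``min_fraction`` of the focus samples.

    Used to restrict an indication-specific model to drugs with enough
    sensitive cell lines of the focus cancer type to learn from.
    """
    focus = [u for u in panel.sample_ids if str(u) in {str(x) for x in focus_samples}]
    if not focus:
        raise ValidationError("no focus samples present in the panel")
    sub = panel.select_samples(focus)
    o = sub.max_dose_log2[:, None]
    sens = classify_sensitive(sub.s, o) & sub.observed
    keep = []
    for i, drug in enumerate(sub.drug_ids):
        n_obs = sub.observed[i].sum()
        if n_obs and sens[i].sum() / n_obs >= min_fraction:
            keep.append(drug)
    if not keep:
        raise ValidationError("no drugs pass the response-rate filter")
    return panel.select_drugs(keep)


# ---------------------------------------------------------------------------
# Serialization — a single JSON archive; floats round-trip exactly via repr.


def save_model(model: PharmacogenomicModel, path) -> None:
    cfg = asdict(model.config)
    payload = {
        "format": "pharmspace-model-v1",
        "f": model.f,
        "drug_ids": model.drug_ids,
        "W_P": model.W_P.tolist(),
        "Q": model.Q.tolist(),
        "b_Q": model.b_Q.tolist(),
        "max_dose_log2": model.max_dose_log2.tolist(),
        "config": cfg,
        "basis": {
            "gene_ids": model.basis.gene_ids,
            "reference_mean": model.basis.reference_mean.tolist(),
            "essential_gene_ids": model.basis.essential_gene_ids,
            "reference_sample_ids": model.basis.reference_sample_ids,
            "reference_fold_change": model.basis.reference_fold_change.tolist(),
        },
        "loss_trace": None if model.loss_trace is None else model.loss_trace.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> PharmacogenomicModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "pharmspace-model-v1":
        raise ValidationError(f"{path}: not a pharmspace model archive")
    b = payload["basis"]
    basis = ReferenceBasis(
        b["gene_ids"], np.array(b["reference_mean"], dtype=float),
        b["essential_gene_ids"], b["reference_sample_ids"],
        np.array(b["reference_fold_change"], dtype=float),
    )
    cfg = payload["config"]
    config = TrainConfig(**cfg)
    trace = payload.get("loss_trace")
    return PharmacogenomicModel(
        f=payload["f"], W_P=np.array(payload["W_P"], dtype=float),
        Q=np.array(payload["Q"], dtype=float),
        b_Q=np.array(payload["b_Q"], dtype=float),
        drug_ids=payload["drug_ids"], basis=basis,
        max_dose_log2=np.array(payload["max_dose_log2"], dtype=float),
        config=config,
        loss_trace=None if trace is None else np.array(trace, dtype=float),
    )
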