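"""Small feed-forward MLP (default 8:5:1) with batch back-propagation.

The network uses the bipolar sigmoid f(x) = 2/(1+exp(-x)) - 1 (= tanh(x/2))
on the hidden and output layers, mean-squared-error loss with targets
DIL = +1 / NT = -1, full-batch gradient accumulation and a momentum term.
Validation follows two strategies: subject-level leave-one-out
cross-validation (a subject's DIL and NT rows leave together, the same
initial weights are reused in every fold) and repeated stratified 67/33
train/validation splits. ROC analytics report the trapezoidal AUROC, the
optimal cut-point (closest point to the (0,1) corner of the ROC plane) and
PPV/NPV there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ANNModel", "TrainConfig", "ROCAnalysis", "CVResult",
           "init_model", "forward", "train", "loocv", "architecture_search",
           "stopping_epoch", "split_strategy", "roc_analysis",
           "cross_cohort_eval", "bipolar_sigmoid"]


def bipolar_sigmoid(x: np.ndarray) -> np.ndarray:
    """f(x) = 2/(1+e^-x) - 1, the bipolar logistic (== tanh(x/2))."""
    return np.tanh(np.asarray(x, dtype=float) / 2.0)


def _dsigmoid(fx: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation value: (1 - f^2)/2
    return (1.0 - fx * fx) / 2.0


@dataclass
class ANNModel:
    """Weights of an input:hidden:1 perceptron with bias terms."""

    W1: np.ndarray                  # (hidden, n_in)
    b1: np.ndarray                  # (hidden,)
    W2: np.ndarray                  # (1, hidden)
    b2: np.ndarray                  # (1,)
    init_seed: int = 0

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    def copy(self) -> "ANNModel":
        return ANNModel(self.W1.copy(), self.b1.copy(), self.W2.copy(),
                        self.b2.copy(), self.init_seed)


@dataclass
class TrainConfig:
    """Batch back-propagation hyperparameters."""

    learning_rate: float = 0.01
    momentum: float = 0.01
    max_epochs: int = 300
    record_ccf: bool = False

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class ROCAnalysis:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auroc: float
    optimal_cutpoint: float
    sensitivity: float              # TPR at the optimal cut-point
    specificity: float
    ppv: float
    npv: float
    ccf: float                      # correct classification fraction there


@dataclass
class CVResult:
    predictions: np.ndarray
    labels: np.ndarray
    roc: ROCAnalysis | None = None
    auroc_samples: np.ndarray | None = None
    ppv_samples: np.ndarray | None = None
    npv_samples: np.ndarray | None = None
    auroc_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    npv_ci: tuple[float, float] | None = None
    ccf_curve: np.ndarray | None = None
    auccf: float | None = None
    chosen_hidden: int | None = None
    stop_epoch: int | None = None


def init_model(n_inputs: int = 8, n_hidden: int = 5, seed: int = 0) -> ANNModel:
    """Uniform [-0.5, 0.5] weight initialization from ``seed``."""
    rng = np.random.default_rng(seed)
    return ANNModel(
        W1=rng.uniform(-0.5, 0.5, (n_hidden, n_inputs)),
        b1=rng.uniform(-0.5, 0.5, n_hidden),
        W2=rng.uniform(-0.5, 0.5, (1, n_hidden)),
        b2=rng.uniform(-0.5, 0.5, 1),
        init_seed=seed)


def forward(model: ANNModel, x: np.ndarray) -> np.ndarray:
    """Network output in (-1, 1) for one sample or a batch of rows."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} inputs, got {X.shape[1]}")
    h = bipolar_sigmoid(X @ model.W1.T + model.b1)
    out = bipolar_sigmoid(h @ model.W2.T + model.b2)[:, 0]
    return float(out[0]) if single else out


def _forward_full(model: ANNModel, X: np.ndarray):
    h = bipolar_sigmoid(X @ model.W1.T + model.b1)
    out = bipolar_sigmoid(h @ model.W2.T + model.b2)[:, 0]
    return h, out


def gradients(model: ANNModel, X: np.ndarray, t: np.ndarray):
    """Analytic gradient of the batch MSE loss w.r.t. all weights."""
    n = X.shape[0]
    h, out = _forward_full(model, X)
    err = out - t                                     # (n,)
    delta_out = err * _dsigmoid(out) * (2.0 / n)      # d(MSE)/d(pre-act)
    gW2 = delta_out[None, :] @ h                      # (1, hidden)
    gb2 = np.array([delta_out.sum()])
    delta_h = np.outer(delta_out, model.W2[0]) * _dsigmoid(h)
    gW1 = delta_h.T @ X
    gb1 = delta_h.sum(axis=0)
    return gW1, gb1, gW2, gb2


def mse(model: ANNModel, X: np.ndarray, t: np.ndarray) -> float:
    _, out = _forward_full(model, X)
    return float(np.mean((out - t) ** 2))


def train(model: ANNModel, X: np.ndarray, targets: np.ndarray,
          config: TrainConfig | None = None) -> tuple[ANNModel, np.ndarray, np.ndarray | None]:
    """Full-batch gradient descent with momentum.

    Weight changes are accumulated over the whole training set and applied
    once per epoch. Returns (trained model, MSE trace, optional CCF trace:
    the fraction of correct sign-rule decisions per epoch).

    Raises on a non-finite loss (diverged training).
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    t = np.asarray(targets, dtype=float)
    if np.unique(t[t > 0]).size == 0 or np.unique(t[t < 0]).size == 0:
        raise ValueError("need samples of both classes (+1 / -1 targets)")
    m = model.copy()
    vel = [np.zeros_like(w) for w in (m.W1, m.b1, m.W2, m.b2)]
    trace = np.empty(config.max_epochs)
    ccf = np.empty(config.max_epochs) if config.record_ccf else None
    for epoch in range(config.max_epochs):
        loss = mse(m, X, t)
        if not np.isfinite(loss):
            raise FloatingPointError(f"non-finite MSE at epoch {epoch}")
        trace[epoch] = loss
        if ccf is not None:
            _, out = _forward_full(m, X)
            ccf[epoch] = float(np.mean((out >= 0) == (t > 0)))
        grads = gradients(m, X, t)
        for w, v, g in zip((m.W1, m.b1, m.W2, m.b2), vel, grads):
            v *= config.momentum
            v -= config.learning_rate * g
            w += v
    return m, trace, ccf


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCAnalysis:
    """Threshold sweep over the observed scores; trapezoidal AUROC.

    ``labels`` are boolean/{0,1} with 1 = DIL (positive). The optimal
    cut-point minimizes the Euclidean distance of (FPR, TPR) to (0, 1).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # sweep thresholds from above max to below min; predict positive if score >= thr
    thr = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tp = np.array([(scores[y] >= th).sum() for th in thr], dtype=float)
    fp = np.array([(scores[~y] >= th).sum() for th in thr], dtype=float)
    tpr, fpr = tp / n_pos, fp / n_neg
    auroc = float(np.trapezoid(tpr, fpr))
    dist = np.hypot(fpr, 1.0 - tpr)
    i = int(np.argmin(dist))
    cut = float(thr[i]) if np.isfinite(thr[i]) else float(scores.max())
    pred = scores >= cut
    tp_c, fp_c = float((pred & y).sum()), float((pred & ~y).sum())
    fn_c, tn_c = float((~pred & y).sum()), float((~pred & ~y).sum())
    ppv = tp_c / (tp_c + fp_c) if tp_c + fp_c else 0.0
    npv = tn_c / (tn_c + fn_c) if tn_c + fn_c else 0.0
    return ROCAnalysis(thresholds=thr, tpr=tpr, fpr=fpr, auroc=auroc,
                       optimal_cutpoint=cut,
                       sensitivity=tp_c / n_pos, specificity=tn_c / n_neg,
                       ppv=ppv, npv=npv,
                       ccf=(tp_c + tn_c) / (n_pos + n_neg))


def _subject_folds(subject_ids: np.ndarray) -> list[np.ndarray]:
    order = []
    seen = set()
    for s in subject_ids:
        if s not in seen:
            seen.add(s)
            order.append(s)
    return [np.nonzero(subject_ids == s)[0] for s in order]


def loocv(features: np.ndarray, labels: np.ndarray, subject_ids: np.ndarray,
          n_hidden: int = 5, config: TrainConfig | None = None,
          init_seed: int = 0) -> CVResult:
    """Subject-level leave-one-out cross-validation.

    Each fold holds out one subject (its DIL and NT rows together); the
    same initial weights are reused in every fold. Held-out predictions
    are pooled into a single ROC and CCF-vs-epoch curve.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    sids = np.asarray(subject_ids)
    folds = _subject_folds(sids)
    if len(folds) < 3:
        raise ValueError("LOOCV needs at least 3 subjects")
    config = config or TrainConfig()
    cfg = TrainConfig(config.learning_rate, config.momentum,
                      config.max_epochs, record_ccf=True)
    init = init_model(X.shape[1], n_hidden, seed=init_seed)
    preds = np.empty(X.shape[0])
    ccf_curves = []
    for test_idx in folds:
        train_mask = np.ones(X.shape[0], bool)
        train_mask[test_idx] = False
        t = np.where(y[train_mask], 1.0, -1.0)
        m, _, ccf = train(init, X[train_mask], t, cfg)
        preds[test_idx] = forward(m, X[test_idx])
        ccf_curves.append(ccf)
    ccf_curve = np.mean(ccf_curves, axis=0)
    roc = roc_analysis(preds, y)
    return CVResult(predictions=preds, labels=y, roc=roc,
                    ccf_curve=ccf_curve,
                    auccf=float(np.trapezoid(ccf_curve) / max(len(ccf_curve) - 1, 1)),
                    stop_epoch=stopping_epoch(ccf_curve))


def architecture_search(features: np.ndarray, labels: np.ndarray,
                        subject_ids: np.ndarray, hidden_range=range(1, 11),
                        config: TrainConfig | None = None,
                        init_seed: int = 0) -> tuple[int, dict[int, CVResult]]:
    """LOOCV per hidden-layer size; returns (best H, per-H results).

    Ties in AUROC go to the smaller hidden layer.
    """
    hidden_range = list(hidden_range)
    if not hidden_range:
        raise ValueError("hidden_range must be non-empty")
    results = {h: loocv(features, labels, subject_ids, n_hidden=h,
                        config=config, init_seed=init_seed)
               for h in hidden_range}
    best = max(sorted(results), key=lambda h: results[h].roc.auroc)
    return best, results


def stopping_epoch(ccf_curve: np.ndarray, plateau_fraction: float = 0.10,
                   mode: str = "of_plateau") -> int:
    """First epoch where the CCF curve is within 10% of its plateau.

    The plateau is the mean CCF over the final 10% of epochs. With
    ``mode="of_plateau"`` the criterion is ccf >= (1 - fraction) * plateau;
    with ``mode="of_rise"`` it is ccf >= plateau - fraction * (plateau -
    min(ccf)). Returns a 1-based epoch index.
    """
    c = np.asarray(ccf_curve, dtype=float)
    if c.size < 2:
        raise ValueError("CCF curve needs at least 2 epochs")
    tail = c[-max(1, int(round(0.1 * c.size))):]
    plateau = float(tail.mean())
    if mode == "of_plateau":
        target = (1.0 - plateau_fraction) * plateau
    elif mode == "of_rise":
        target = plateau - plateau_fraction * (plateau - float(c.min()))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    hits = np.nonzero(c >= target)[0]
    if hits.size == 0:
        import warnings
        warnings.warn("CCF curve never reaches its plateau; using last epoch")
        return int(c.size)
    return int(hits[0]) + 1


def split_strategy(features: np.ndarray, labels: np.ndarray,
                   subject_ids: np.ndarray, n_iter: int = 100,
                   train_frac: float = 2 / 3,
                   config: TrainConfig | None = None, seed: int = 0,
                   n_hidden: int = 5) -> CVResult:
    """Repeated stratified random 67/33 train/validation splits.

    Splits are drawn at the subject level; each iteration trains from the
    shared initial weights and records AUROC/PPV/NPV on the validation
    part. Confidence intervals are 2.5/97.5 percentiles over iterations.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    sids = np.asarray(subject_ids)
    uniq = list(dict.fromkeys(sids))
    n_train = int(round(train_frac * len(uniq)))
    if n_train < 1 or n_train >= len(uniq):
        raise ValueError("dataset too small for the requested split")
    rng = np.random.default_rng(seed)
    config = config or TrainConfig()
    init = init_model(X.shape[1], n_hidden, seed=seed)
    au, ppv, npv = np.empty(n_iter), np.empty(n_iter), np.empty(n_iter)
    preds_last = labels_last = None
    for it in range(n_iter):
        while True:
            chosen = rng.choice(len(uniq), size=n_train, replace=False)
            train_mask = np.isin(sids, [uniq[i] for i in chosen])
            if y[train_mask].any() and (~y[train_mask]).any() \
                    and y[~train_mask].any() and (~y[~train_mask]).any():
                break
        t = np.where(y[train_mask], 1.0, -1.0)
        m, _, _ = train(init, X[train_mask], t, config)
        preds = forward(m, X[~train_mask])
        roc = roc_analysis(preds, y[~train_mask])
        au[it], ppv[it], npv[it] = roc.auroc, roc.ppv, roc.npv
        preds_last, labels_last = preds, y[~train_mask]

    def ci(v):
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return CVResult(predictions=preds_last, labels=labels_last,
                    roc=roc_analysis(preds_last, labels_last),
                    auroc_samples=au, ppv_samples=ppv, npv_samples=npv,
                    auroc_ci=ci(au), ppv_ci=ci(ppv), npv_ci=ci(npv),
                    chosen_hidden=n_hidden)


def cross_cohort_eval(train_features: np.ndarray, train_labels: np.ndarray,
                      train_subjects: np.ndarray,
                      test_features: np.ndarray, test_labels: np.ndarray,
                      test_subjects: np.ndarray,
                      n_hidden: int = 5, config: TrainConfig | None = None,
                      init_seed: int = 0) -> tuple[ROCAnalysis, ANNModel]:
    """Train on cohort A, evaluate frozen on disjoint cohort B."""
    if set(np.asarray(train_subjects)) & set(np.asarray(test_subjects)):
        raise ValueError("train and test cohorts overlap")
    y_tr = np.asarray(train_labels).astype(bool)
    t = np.where(y_tr, 1.0, -1.0)
    init = init_model(np.asarray(train_features).shape[1], n_hidden, seed=init_seed)
    model, _, _ = train(init, train_features, t, config or TrainConfig())
    preds = forward(model, np.asarray(test_features, dtype=float))
    return roc_analysis(preds, test_labels), model
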