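"""Consistency validation of the rule-based risk classes.

The rule-based general risk class is, by construction, a deterministic
function of 24 per-participant inputs (6 tasks x {pupil dilation, blink
rate, normalized GSR, task performance}).  To check that the rule encodes
a structure conventional classifiers can also express, three families are
trained on the *full* cohort — training equals evaluation on purpose,
because the question is label consistency, not generalization:

* binary logistic regression, all 24 predictors entered as one block,
  classification tables at cut-offs 0.50 and 0.70, with the likelihood
  -ratio (omnibus) chi-square and Nagelkerke pseudo-R²;
* a CART decision tree (greedy binary splits minimizing Gini impurity);
* a feedforward network with one tanh hidden layer and softmax output,
  trained by batch, online or mini-batch gradient descent.

Supporting arithmetic reproduced here in closed form: paired t statistics
from summary moments (mean difference, sd, n) as used for subjective
workload scores, and per-class / overall percent-correct tables from 2x2
confusion counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .tasks import FEATURE_NAMES

__all__ = [
    "PairedTTestResult",
    "ConfusionMatrix2",
    "LogisticModel",
    "CartTree",
    "MlpModel",
    "paired_t_from_summary",
    "confusion_metrics",
    "logistic_fit",
    "logistic_classify",
    "nagelkerke_r2",
    "omnibus_test",
    "cart_fit",
    "cart_predict",
    "mlp_fit",
    "mlp_proba",
    "mlp_predict",
    "design_matrix",
    "consistency_report",
]


# ----------------------------------------------------------------------
# paired t from summary statistics

@dataclass(frozen=True)
class PairedTTestResult:
    mean_diff: float
    sd_diff: float
    n: int
    se: float
    ci_low: float
    ci_high: float
    t: float
    df: int
    p: float


def paired_t_from_summary(mean_diff: float, sd_diff: float,
                          n: int) -> PairedTTestResult:
    """Two-sided paired t-test from the mean and sd of the differences.

    Reproduces the full summary row: standard error ``sd/sqrt(n)``, the
    95% confidence interval, ``t = mean/se`` with ``n - 1`` degrees of
    freedom, and the two-sided p-value.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive (zero-variance differences)")
    se = sd_diff / math.sqrt(n)
    df = n - 1
    t = mean_diff / se
    tcrit = stats.t.ppf(0.975, df)
    p = 2 * stats.t.sf(abs(t), df)
    return PairedTTestResult(mean_diff=mean_diff, sd_diff=sd_diff, n=n,
                             se=se, ci_low=mean_diff - tcrit * se,
                             ci_high=mean_diff + tcrit * se,
                             t=t, df=df, p=p)


# ----------------------------------------------------------------------
# confusion-matrix arithmetic

@dataclass(frozen=True)
class ConfusionMatrix2:
    """2x2 table, observed {high, low} x predicted {high, low}."""

    n_hh: int
    n_hl: int
    n_lh: int
    n_ll: int

    def __post_init__(self) -> None:
        if min(self.n_hh, self.n_hl, self.n_lh, self.n_ll) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty confusion matrix")

    @property
    def total(self) -> int:
        return self.n_hh + self.n_hl + self.n_lh + self.n_ll


def confusion_metrics(cm: ConfusionMatrix2) -> Dict[str, float]:
    """Percent-correct summary of a 2x2 classification table.

    Returns per-class recalls, the predicted-class marginals and the
    overall percent correct, all as percentages.  A recall over an empty
    observed class is NaN; the overall percent is still defined.
    """
    def pct(num: float, den: float) -> float:
        return float("nan") if den == 0 else 100.0 * num / den

    return {
        "recall_high_pct": pct(cm.n_hh, cm.n_hh + cm.n_hl),
        "recall_low_pct": pct(cm.n_ll, cm.n_lh + cm.n_ll),
        "predicted_high_pct": pct(cm.n_hh + cm.n_lh, cm.total),
        "predicted_low_pct": pct(cm.n_hl + cm.n_ll, cm.total),
        "overall_pct": pct(cm.n_hh + cm.n_ll, cm.total),
    }


# ----------------------------------------------------------------------
# binary logistic regression (IRLS)

@dataclass
class LogisticModel:
    """Binary logit fitted by IRLS; class 1 is the positive (low-risk) class."""

    coef: np.ndarray          # intercept first
    ll: float
    ll_null: float
    converged: bool
    separation: bool
    n_obs: int
    n_predictors: int


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically safe sum of y*log(mu) + (1-y)*log(1-mu)
    return float(-np.sum(np.logaddexp(0.0, -eta) * y
                         + np.logaddexp(0.0, eta) * (1 - y)))


def logistic_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                 ridge_eps: float = 1e-8, tol: float = 1e-10) -> LogisticModel:
    """Fit a binary logistic regression with all predictors entered at once.

    Iteratively reweighted least squares with a tiny ridge term on the
    normal equations for numerical safety.  Under complete separation the
    likelihood has no maximum; iteration then stops at ``max_iter`` with
    the ``separation`` flag set, leaving a model that classifies the
    training data perfectly (the behaviour classical packages report as a
    perfect classification table with pseudo-R² 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.maximum(mu * (1 - mu), 1e-12)
        A = (Xd * w[:, None]).T @ Xd + ridge_eps * np.eye(p + 1)
        g = Xd.T @ (y - mu)
        try:
            step = np.linalg.solve(A, g)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "singular IRLS system beyond ridge rescue") from exc
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = Xd @ beta
    ll = _log_likelihood(eta, y)
    n1 = y.sum()
    if n1 in (0, n):
        raise ValueError("y must contain both classes")
    p1 = n1 / n
    ll_null = float(n1 * math.log(p1) + (n - n1) * math.log(1 - p1))
    perfect = np.all((eta > 0) == (y == 1))
    separation = bool(not converged and perfect and ll > -1e-2 * n)
    return LogisticModel(coef=beta, ll=ll, ll_null=ll_null,
                         converged=converged, separation=separation,
                         n_obs=n, n_predictors=p)


def logistic_predict_proba(model: LogisticModel, X: np.ndarray) -> np.ndarray:
    Xd = np.hstack([np.ones((len(X), 1)), np.asarray(X, dtype=float)])
    eta = np.clip(Xd @ model.coef, -35, 35)
    return 1.0 / (1.0 + np.exp(-eta))


def logistic_classify(model: LogisticModel, X: np.ndarray, y: np.ndarray,
                      cutoff: float = 0.50) -> ConfusionMatrix2:
    """Classification table at a probability cut-off.

    The positive class (coded 1) is *low risk*; a case is predicted low
    iff P(low) >= cutoff.
    """
    prob_low = logistic_predict_proba(model, X)
    pred_low = prob_low >= cutoff
    y = np.asarray(y).astype(bool)
    return ConfusionMatrix2(
        n_hh=int(np.sum(~y & ~pred_low)), n_hl=int(np.sum(~y & pred_low)),
        n_lh=int(np.sum(y & ~pred_low)), n_ll=int(np.sum(y & pred_low)))


def nagelkerke_r2(ll_null: float, ll_model: float, n: int) -> float:
    """Nagelkerke's rescaled pseudo-R²: the Cox-Snell ratio divided by its
    maximum attainable value, so a perfectly fitting model scores 1."""
    if ll_model < ll_null - 1e-9:
        raise ValueError("model log-likelihood below null log-likelihood")
    denom = 1.0 - math.exp(2.0 * ll_null / n)
    if denom == 0:
        raise ValueError("degenerate one-class outcome")
    num = 1.0 - math.exp(2.0 * (ll_null - ll_model) / n)
    return num / denom


def omnibus_test(ll_null: float, ll_model: float,
                 n_predictors: int) -> Tuple[float, int, float]:
    """Likelihood-ratio chi-square of the fitted model against the
    intercept-only model.  Returns (chi_square, df, p)."""
    chi2 = -2.0 * (ll_null - ll_model)
    p = float(stats.chi2.sf(chi2, n_predictors))
    return chi2, n_predictors, p


# ----------------------------------------------------------------------
# CART (Gini)

@dataclass
class CartNode:
    feature: Optional[int] = None
    threshold: Optional[float] = None
    left: Optional["CartNode"] = None
    right: Optional["CartNode"] = None
    prediction: Optional[int] = None  # leaf majority class

    @property
    def is_leaf(self) -> bool:
        return self.prediction is not None


@dataclass
class CartTree:
    root: CartNode
    n_nodes: int
    depth: int


def _gini(y: np.ndarray) -> float:
    if len(y) == 0:
        return 0.0
    p = y.mean()
    return 2.0 * p * (1.0 - p)


def _best_split(X: np.ndarray, y: np.ndarray,
                min_leaf: int) -> Optional[Tuple[int, float, float]]:
    """Best (feature, threshold, decrease); ties resolved toward the lowest
    feature index then the lowest threshold by strict-improvement search."""
    n = len(y)
    parent = _gini(y)
    best = None
    for j in range(X.shape[1]):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        # candidate thresholds: midpoints between distinct consecutive values
        for i in range(min_leaf, n - min_leaf + 1):
            if i == 0 or i == n or xs[i - 1] == xs[i]:
                continue
            thr = 0.5 * (xs[i - 1] + xs[i])
            gl, gr = _gini(ys[:i]), _gini(ys[i:])
            dec = parent - (i * gl + (n - i) * gr) / n
            if best is None or dec > best[2] + 1e-15:
                best = (j, thr, dec)
    return best


def _grow(X: np.ndarray, y: np.ndarray, depth: int, min_leaf: int,
          max_depth: Optional[int], min_decrease: float) -> CartNode:
    maj = int(round(y.mean())) if len(y) else 0
    if (len(np.unique(y)) == 1 or len(y) < 2 * min_leaf
            or (max_depth is not None and depth >= max_depth)):
        return CartNode(prediction=maj)
    split = _best_split(X, y, min_leaf)
    if split is None or split[2] < min_decrease - 1e-15:
        return CartNode(prediction=maj)
    j, thr, _ = split
    mask = X[:, j] <= thr
    return CartNode(feature=j, threshold=thr,
                    left=_grow(X[mask], y[mask], depth + 1, min_leaf,
                               max_depth, min_decrease),
                    right=_grow(X[~mask], y[~mask], depth + 1, min_leaf,
                                max_depth, min_decrease))


def cart_fit(X: np.ndarray, y: np.ndarray, min_leaf: int = 1,
             max_depth: Optional[int] = None,
             min_decrease: float = 0.0) -> CartTree:
    """Greedy binary CART minimizing weighted Gini impurity.

    Deterministic given the data; with ``min_leaf=1`` and unlimited depth
    the tree memorizes any consistent labelling of distinct rows.  Splits
    with zero immediate impurity decrease are allowed by default (an
    impure node is still divided, which is what lets parity-like patterns
    be resolved one level deeper); raise ``min_decrease`` to prune them.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(float)
    if len(y) == 0:
        raise ValueError("empty training data")
    root = _grow(X, y, 0, min_leaf, max_depth, min_decrease)

    def count(node):
        if node.is_leaf:
            return 1, 1
        nl, dl = count(node.left)
        nr, dr = count(node.right)
        return nl + nr + 1, 1 + max(dl, dr)

    n_nodes, depth = count(root)
    return CartTree(root=root, n_nodes=n_nodes, depth=depth - 1)


def cart_predict(tree: CartTree, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    out = np.empty(len(X), dtype=int)
    for i, x in enumerate(X):
        node = tree.root
        while not node.is_leaf:
            node = node.left if x[node.feature] <= node.threshold else node.right
        out[i] = node.prediction
    return out


# ----------------------------------------------------------------------
# feedforward network: tanh hidden layer, softmax output

@dataclass
class MlpModel:
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    mode: str
    seed: int
    loss_trace: List[float] = field(default_factory=list)


def mlp_proba(model: MlpModel, X: np.ndarray) -> np.ndarray:
    """Class probabilities (columns: high=0, low=1); rows sum to 1."""
    h = np.tanh(np.asarray(X, dtype=float) @ model.w1 + model.b1)
    z = h @ model.w2 + model.b2
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def mlp_predict(model: MlpModel, X: np.ndarray) -> np.ndarray:
    return mlp_proba(model, X).argmax(axis=1)


def _mlp_grads(model: MlpModel, X: np.ndarray, Y: np.ndarray):
    h = np.tanh(X @ model.w1 + model.b1)
    z = h @ model.w2 + model.b2
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(X)
    dz = (p - Y) / n
    dw2 = h.T @ dz
    db2 = dz.sum(axis=0)
    dh = dz @ model.w2.T * (1 - h ** 2)
    dw1 = X.T @ dh
    db1 = dh.sum(axis=0)
    loss = float(-np.sum(Y * np.log(np.maximum(p, 1e-12))) / n)
    return loss, dw1, db1, dw2, db2


def mlp_fit(X: np.ndarray, y: np.ndarray, hidden_units: Optional[int] = None,
            mode: str = "batch", seed: int = 0, epochs: int = 2000,
            lr: float = 0.5, batch_size: int = 8,
            init_scale: float = 0.5) -> MlpModel:
    """Train the one-hidden-layer tanh/softmax network by cross-entropy
    gradient descent.

    ``mode`` sets the update granularity: ``batch`` (one update per epoch
    over the full cohort), ``online`` (one update per case, reshuffled
    each epoch) or ``minibatch`` (updates on shuffled blocks of
    ``batch_size``).  Deterministic given ``seed``.  ``hidden_units``
    defaults to half the input width, rounded up.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be binary 0/1")
    if mode not in ("batch", "online", "minibatch"):
        raise ValueError(f"unknown training mode {mode!r}")
    n, d = X.shape
    if hidden_units is None:
        hidden_units = max(1, (d + 1) // 2)
    if hidden_units < 1:
        raise ValueError("hidden_units must be >= 1")
    rng = np.random.default_rng(seed)
    model = MlpModel(
        w1=rng.normal(0, init_scale / math.sqrt(d), (d, hidden_units)),
        b1=np.zeros(hidden_units),
        w2=rng.normal(0, init_scale / math.sqrt(hidden_units), (hidden_units, 2)),
        b2=np.zeros(2),
        mode=mode, seed=seed)
    Y = np.eye(2)[y]
    # per-update step size: online/minibatch gradients are per-block means
    step = lr if mode == "batch" else lr * 0.2
    for _ in range(epochs):
        if mode == "batch":
            blocks = [np.arange(n)]
        else:
            perm = rng.permutation(n)
            size = 1 if mode == "online" else batch_size
            blocks = [perm[i:i + size] for i in range(0, n, size)]
        epoch_loss = 0.0
        for idx in blocks:
            loss, dw1, db1, dw2, db2 = _mlp_grads(model, X[idx], Y[idx])
            if not math.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (non-finite loss); reduce lr")
            model.w1 -= step * dw1
            model.b1 -= step * db1
            model.w2 -= step * dw2
            model.b2 -= step * db2
            epoch_loss += loss * len(idx)
        model.loss_trace.append(epoch_loss / n)
    return model


# ----------------------------------------------------------------------
# cohort-level consistency report

def design_matrix(feature_table: pd.DataFrame,
                  task_ids: Optional[Sequence[str]] = None
                  ) -> Tuple[np.ndarray, List[str], List[str]]:
    """Build the 24-column design: per task, the three physiological
    features plus the task performance, one row per participant.

    Returns (matrix, participant ids, column names).
    """
    if task_ids is None:
        task_ids = list(dict.fromkeys(feature_table["task"]))
    wide = feature_table.pivot(index="participant", columns="task",
                               values=[*FEATURE_NAMES, "performance_pct"])
    cols, names = [], []
    for tid in task_ids:
        for var in (*FEATURE_NAMES, "performance_pct"):
            cols.append(wide[(var, tid)])
            names.append(f"{tid}:{var}")
    M = np.column_stack([c.to_numpy(dtype=float) for c in cols])
    if np.isnan(M).any():
        raise ValueError("design matrix has missing cells")
    return M, list(wide.index), names


def _table_block(cm: ConfusionMatrix2) -> Dict:
    return {"counts": {"n_hh": cm.n_hh, "n_hl": cm.n_hl,
                       "n_lh": cm.n_lh, "n_ll": cm.n_ll},
            **confusion_metrics(cm)}


def consistency_report(feature_table: pd.DataFrame,
                       general_risk_labels: pd.DataFrame,
                       seed: int = 0,
                       mlp_modes: Sequence[str] = ("batch", "online", "minibatch"),
                       mlp_epochs: int = 2000) -> Dict:
    """Train all benchmark classifiers on the full cohort and report their
    agreement with the rule-based general risk classes.

    ``general_risk_labels`` needs columns ``participant`` and
    ``general_risk`` ("high"/"low").  Predictors are standardized
    column-wise (an affine change that leaves logistic and tree fits
    equivalent but conditions the network training).  Training set =
    evaluation set by design: the report measures whether the rule-based
    labels are a learnable function of the 24 inputs, not generalization.
    """
    X_raw, pids, names = design_matrix(feature_table)
    labels = (general_risk_labels.set_index("participant")
              .loc[pids, "general_risk"])
    y = (labels == "low").to_numpy().astype(int)  # positive class = low risk
    mu, sdev = X_raw.mean(axis=0), X_raw.std(axis=0)
    sdev = np.where(sdev == 0, 1.0, sdev)
    X = (X_raw - mu) / sdev
    report: Dict = {"n": len(y),
                    "class_counts": {"high": int((y == 0).sum()),
                                     "low": int((y == 1).sum())}}

    model = logistic_fit(X, y)
    logit_block: Dict = {
        "separation": model.separation,
        "nagelkerke_r2": nagelkerke_r2(model.ll_null, model.ll, len(y)),
    }
    chi2, dfree, p = omnibus_test(model.ll_null, model.ll, model.n_predictors)
    logit_block["omnibus"] = {"chi_square": chi2, "df": dfree, "p": p}
    for cutoff in (0.50, 0.70):
        cm = logistic_classify(model, X, y, cutoff)
        logit_block[f"cutoff_{cutoff:.2f}"] = _table_block(cm)
    report["logistic"] = logit_block

    tree = cart_fit(X, y, min_leaf=1, max_depth=None)
    pred = cart_predict(tree, X)
    report["cart"] = {**_table_block(_cm_from_pred(y, pred)),
                      "depth": tree.depth, "n_nodes": tree.n_nodes}

    mlp_block = {}
    for mode in mlp_modes:
        m = mlp_fit(X, y, mode=mode, seed=seed, epochs=mlp_epochs)
        mlp_block[mode] = _table_block(_cm_from_pred(y, mlp_predict(m, X)))
    report["mlp"] = mlp_block
    return report


def _cm_from_pred(y: np.ndarray, pred: np.ndarray) -> ConfusionMatrix2:
    y = np.asarray(y).astype(bool)
    pred = np.asarray(pred).astype(bool)
    return ConfusionMatrix2(
        n_hh=int(np.sum(~y & ~pred)), n_hl=int(np.sum(~y & pred)),
        n_lh=int(np.sum(y & ~pred)), n_ll=int(np.sum(y & pred)))
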