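"""Partial least squares discriminant analysis (PLS-DA) on shape coordinates.

The predictor block X holds flattened Procrustes shape coordinates (one
row per specimen, 87 columns for 29 landmarks); the response is the binary
tear status (control ``y = 0``, FTT ``y = 1``). PLS1 with X-block deflation
extracts modes that explain successively smaller amounts of covariation
between shape and tear status. Columns are centred but not autoscaled:
Procrustes coordinates share units, so autoscaling would only inflate
low-variance landmarks.

Model selection follows the cross-validation protocol of the analysis this
package reproduces: an upper mode count M is chosen so the PLS modes
explain a target fraction (default 70%) of total shape variance, models
with 1..M modes are scored by leave-one-out cross-validation, and the mode
count with the highest balanced accuracy wins (ties go to the smaller
model). Significance is assessed against PLS-DA models refit on
label-permuted cohorts with preserved group proportions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PLSModel",
    "PerformanceReport",
    "NullComparison",
    "fit_pls",
    "predict_response",
    "classify",
    "loocv_mode_selection",
    "n_modes_for_variance",
    "performance_metrics",
    "null_model_comparison",
    "group_shape",
]

_WEIGHT_EPS = 1e-12


@dataclass
class PLSModel:
    """Fitted PLS1 model for a binary response.

    Attributes follow the usual NIPALS naming: weights ``W`` (p x m),
    scores ``T`` (N x m, mutually orthogonal), X-loadings ``P`` (p x m) and
    y-loadings ``q`` (m,). ``x_variance_explained[k]`` is the fraction of
    total centred-X variance captured by mode k.
    """

    x_mean: np.ndarray
    y_mean: float
    W: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    n_modes: int
    x_variance_explained: np.ndarray
    y: np.ndarray = field(repr=False)

    def coefficients(self, m: int | None = None) -> np.ndarray:
        """Regression coefficients using the first ``m`` modes."""
        m = self.n_modes if m is None else m
        if not 1 <= m <= self.n_modes:
            raise ValueError(f"m must be in 1..{self.n_modes}, got {m}")
        W, P, q = self.W[:, :m], self.P[:, :m], self.q[:m]
        return W @ np.linalg.solve(P.T @ W, q)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "W": self.W.tolist(),
            "T": self.T.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "n_modes": self.n_modes,
            "x_variance_explained": self.x_variance_explained.tolist(),
            "y": self.y.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        d = json.loads(Path(path).read_text())
        return cls(
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            W=np.array(d["W"]),
            T=np.array(d["T"]),
            P=np.array(d["P"]),
            q=np.array(d["q"]),
            n_modes=int(d["n_modes"]),
            x_variance_explained=np.array(d["x_variance_explained"]),
            y=np.array(d["y"]),
        )


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2D with one row per element of y")
    if len(X) < 3:
        raise ValueError("need at least 3 specimens")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("y must be binary (0/1)")
    if len(classes) < 2:
        raise ValueError("both classes must be present in y")
    return X, y


def fit_pls(X: np.ndarray, y: np.ndarray, m: int) -> PLSModel:
    """Fit a PLS1 model with ``m`` modes by iterative X-block deflation.

    Each weight vector is proportional to the covariance of the deflated X
    with the centred response; in particular the first mode is parallel to
    the group-mean difference direction.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if not 1 <= m <= min(n - 1, p):
        raise ValueError(f"m must be in 1..min(N-1, p) = {min(n - 1, p)}, got {m}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xk = X - x_mean
    yc = y - y_mean
    total_var = float(np.sum(Xk * Xk))

    W = np.zeros((p, m))
    T = np.zeros((n, m))
    P = np.zeros((p, m))
    q = np.zeros(m)
    xvar = np.zeros(m)
    fitted = 0
    for k in range(m):
        w = Xk.T @ yc
        nw = np.linalg.norm(w)
        if nw < _WEIGHT_EPS * max(1.0, total_var):
            break  # residual X no longer covaries with y
        w /= nw
        t = Xk @ w
        tt = float(t @ t)
        if tt < _WEIGHT_EPS:
            break
        pk = Xk.T @ t / tt
        W[:, k], T[:, k], P[:, k] = w, t, pk
        q[k] = float(yc @ t / tt)
        xvar[k] = tt * float(pk @ pk) / total_var if total_var > 0 else 0.0
        Xk = Xk - np.outer(t, pk)
        fitted = k + 1
    if fitted == 0:
        raise ValueError("X does not covary with y; no PLS mode can be extracted")
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean,
        W=W[:, :fitted], T=T[:, :fitted], P=P[:, :fitted], q=q[:fitted],
        n_modes=fitted, x_variance_explained=xvar[:fitted], y=y.copy(),
    )


def predict_response(model: PLSModel, x: np.ndarray, m: int | None = None) -> np.ndarray | float:
    """Predicted response score(s) using the first ``m`` modes.

    With ``m = 0`` the prediction is the constant ``y_mean`` (null model).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != len(model.x_mean):
        raise ValueError(f"expected {len(model.x_mean)} features, got {X.shape[1]}")
    if m == 0:
        out = np.full(len(X), model.y_mean)
    else:
        b = model.coefficients(m)
        out = model.y_mean + (X - model.x_mean) @ b
    return float(out[0]) if single else out


def classify(scores: np.ndarray | float) -> np.ndarray | int:
    """Threshold predicted response scores: y > 0.5 is FTT, else control."""
    arr = np.asarray(scores)
    labels = (arr > 0.5).astype(int)
    return int(labels) if arr.ndim == 0 else labels


@dataclass
class PerformanceReport:
    """Confusion counts and the derived classification metrics.

    ``balanced_accuracy`` is the arithmetic mean of sensitivity and
    specificity; ``f1`` and ``g_mean`` are the harmonic and geometric means
    of precision and recall. With no predicted positives, precision is
    reported as 0 and flagged.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    precision: float
    recall: float
    balanced_accuracy: float
    f1: float
    g_mean: float
    precision_undefined: bool = False
    n_failed_folds: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "recall": self.recall,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
            "g_mean": self.g_mean,
        }


def performance_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> PerformanceReport:
    """Binary classification metrics from true and predicted labels."""
    y_true = np.asarray(y_true).astype(int).ravel()
    y_pred = np.asarray(y_pred).astype(int).ravel()
    if len(y_true) == 0:
        raise ValueError("empty label arrays")
    if len(y_true) != len(y_pred):
        raise ValueError("label arrays must have equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec_undef = (tp + fp) == 0
    prec = 0.0 if prec_undef else tp / (tp + fp)
    recall = sens
    f1 = 0.0 if prec + recall == 0 else 2 * prec * recall / (prec + recall)
    return PerformanceReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, precision=prec, recall=recall,
        balanced_accuracy=(sens + spec) / 2.0,
        f1=f1, g_mean=math.sqrt(prec * recall),
        precision_undefined=prec_undef,
    )


def n_modes_for_variance(X: np.ndarray, y: np.ndarray, fraction: float = 0.70) -> int:
    """Smallest PLS mode count whose cumulative X-variance reaches ``fraction``.

    Fits as many modes as the data support and returns the first count at
    which the cumulative explained X-block variance meets the target. If the
    covariance with y is exhausted first, the number of extractable modes
    is returned.
    """
    if not 0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    X, y = _validate_xy(X, y)
    max_m = min(len(X) - 1, X.shape[1])
    model = fit_pls(X, y, max_m)
    cum = np.cumsum(model.x_variance_explained)
    hit = np.nonzero(cum >= fraction - 1e-12)[0]
    return int(hit[0]) + 1 if len(hit) else model.n_modes


def loocv_mode_selection(
    X: np.ndarray, y: np.ndarray, m_max: int
) -> tuple[pd.DataFrame, int, dict[int, PerformanceReport]]:
    """Leave-one-out cross-validation over mode counts 1..``m_max``.

    Each specimen is held out once; the model is refit on the remainder and
    the held-out specimen classified for every mode count. Folds whose
    training set loses a class (or cannot support a mode) are excluded from
    the metrics and counted in ``n_failed_folds``. Returns the per-m metric
    table, the optimal m (highest balanced accuracy, ties to the smallest
    m), and the per-m reports.
    """
    X, y = _validate_xy(X, y)
    n = len(X)
    if n < 4:
        raise ValueError("LOOCV mode selection needs at least 4 specimens")
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    preds = np.full((n, m_max), np.nan)
    failed = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        y_tr = y[mask]
        if len(np.unique(y_tr)) < 2:
            failed[i] = True
            continue
        m_fit = min(m_max, n - 2, X.shape[1])
        try:
            model = fit_pls(X[mask], y_tr, m_fit)
        except ValueError:
            failed[i] = True
            continue
        for m in range(1, m_max + 1):
            mm = min(m, model.n_modes)
            preds[i, m - 1] = predict_response(model, X[i], mm)

    reports: dict[int, PerformanceReport] = {}
    rows = []
    for m in range(1, m_max + 1):
        ok = ~failed & ~np.isnan(preds[:, m - 1])
        rep = performance_metrics(y[ok], classify(preds[ok, m - 1]))
        rep.n_failed_folds = int(np.sum(~ok))
        reports[m] = rep
        rows.append({"m": m, **rep.as_dict(), "n_failed_folds": rep.n_failed_folds})
    table = pd.DataFrame(rows)
    best = int(table.loc[table["balanced_accuracy"].idxmax(), "m"])  # idxmax: first max
    return table, best, reports


@dataclass
class NullComparison:
    """True-model metrics against random-label (permutation) null models."""

    n_null: int
    seed: int
    true_report: PerformanceReport
    true_m: int
    null_table: pd.DataFrame          # one row per replicate
    z_scores: dict[str, float]
    p_values: dict[str, float]
    zero_sd_metrics: list[str]


def _full_pipeline_metrics(
    X: np.ndarray, y: np.ndarray, fraction: float, m_cap: int | None
) -> tuple[PerformanceReport, int]:
    m_max = n_modes_for_variance(X, y, fraction)
    if m_cap is not None:
        m_max = min(m_max, m_cap)
    _, best, reports = loocv_mode_selection(X, y, m_max)
    return reports[best], best


def null_model_comparison(
    X: np.ndarray,
    y: np.ndarray,
    n_null: int = 20,
    seed: int = 0,
    fraction: float = 0.70,
    m_cap: int | None = None,
) -> NullComparison:
    """Compare the true PLS-DA model against random-label null models.

    Each null replicate permutes the labels (group proportions exactly
    preserved) and reruns the full pipeline, including its own mode-count
    selection. Z-scores are (true - null mean) / null SD per metric and
    p-values come from the standard normal upper tail (one-sided,
    true-better-than-null). A zero null SD yields +/- infinite z and is
    flagged.
    """
    X, y = _validate_xy(X, y)
    rng = np.random.default_rng(seed)
    true_report, true_m = _full_pipeline_metrics(X, y, fraction, m_cap)

    rows = []
    for rep in range(n_null):
        y_null = rng.permutation(y)
        while len(np.unique(y_null)) < 2:  # pragma: no cover - permutation keeps counts
            y_null = rng.permutation(y)
        null_rep, null_m = _full_pipeline_metrics(X, y_null, fraction, m_cap)
        rows.append({"replicate": rep, "m": null_m, **null_rep.as_dict()})
    null_table = pd.DataFrame(rows)

    metrics = ("balanced_accuracy", "f1", "g_mean")
    z_scores: dict[str, float] = {}
    p_values: dict[str, float] = {}
    zero_sd = []
    true_vals = true_report.as_dict()
    for met in metrics:
        mu = float(null_table[met].mean())
        sd = float(null_table[met].std(ddof=1))
        if sd == 0.0:
            zero_sd.append(met)
            z = math.inf if true_vals[met] > mu else (-math.inf if true_vals[met] < mu else 0.0)
        else:
            z = (true_vals[met] - mu) / sd
        z_scores[met] = z
        p_values[met] = float(norm.sf(z))
    return NullComparison(
        n_null=n_null, seed=seed, true_report=true_report, true_m=true_m,
        null_table=null_table, z_scores=z_scores, p_values=p_values,
        zero_sd_metrics=zero_sd,
    )


def group_shape(model: PLSModel, target: int) -> np.ndarray:
    """Landmark shape associated with a response score of 0 or 1.

    The point on the discriminant axis at the requested group's end,
    mapped back to landmark space through the retained modes: equivalently
    the group's mean shape projected onto the retained PLS modes. Returned
    as a (k, 3) landmark array.
    """
    if target not in (0, 1):
        raise ValueError("target must be 0 (control) or 1 (FTT)")
    t_group = model.T[model.y == target].mean(axis=0)
    flat = model.x_mean + model.P @ t_group
    return flat.reshape(-1, 3)
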