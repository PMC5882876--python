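"""Elastic-net logistic regression: penalized fit, tuning, export.

The fitted objective, on internally standardized features with an
unpenalized intercept, is

    (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
        + lam * ( alpha * ||beta||_1 + (1 - alpha)/2 * ||beta||_2^2 ),

minimized by cyclic coordinate descent. Coordinate updates use the exact
local curvature; if a sweep ever fails to decrease the objective the solver
falls back to the conservative 1/4 curvature bound, whose updates minimize a
true majorizer, so the objective is non-increasing across sweeps by
construction. Convergence is declared when the objective changes by less
than ``tol`` between sweeps.

Reported coefficients are de-standardized to the original feature scale
(odds ratio per raw unit); the per-standard-deviation coefficients are kept
alongside, since both scalings are in common use.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .evaluation import roc_auc
from .exceptions import ModelSchemaError

logger = logging.getLogger(__name__)

MODEL_SCHEMA = "rxremit-model/1"


@dataclasses.dataclass
class EnetHyperparams:
    """Selected mixing weight / penalty strength and the grid searched."""

    alpha: float
    lam: float
    metric: str = "auc"
    cv_results: pd.DataFrame | None = None  # one row per grid point


@dataclasses.dataclass
class FittedModel:
    """Elastic-net logistic model on the original feature scale.

    ``coefficients`` (per raw unit) and ``coefficients_std`` (per training
    standard deviation) hold only the model's features — unselected features
    are absent, not zero-filled. ``standardization`` maps each feature to its
    training (mean, sd).
    """

    intercept: float
    coefficients: dict[str, float]
    coefficients_std: dict[str, float]
    feature_names: list[str]
    feature_kinds: dict[str, str]
    alpha: float
    lam: float
    train_drug: str | None
    standardization: dict[str, tuple[float, float]]
    provenance: dict
    threshold: float | None = None
    training_predictions: np.ndarray | None = None

    def odds_ratios(self) -> dict[str, float]:
        return {k: float(np.exp(b)) for k, b in self.coefficients.items()}


def _objective(eta, y, beta, lam, alpha):
    loss = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
    pen = lam * (alpha * np.abs(beta).sum() + (1 - alpha) / 2 * (beta**2).sum())
    return loss + pen


def _soft(z: float, g: float) -> float:
    return np.sign(z) * max(abs(z) - g, 0.0)


def _cd_sweep(Xs, y, eta, beta, b, lam, alpha, colsq, conservative):
    """One cyclic coordinate-descent sweep in place; returns (beta, b, eta)."""
    n = len(y)
    p_vec = expit(eta)
    # intercept step: exact curvature, or the 1/4 majorizer bound
    if conservative:
        h0 = 0.25
    else:
        h0 = max(float(np.mean(p_vec * (1 - p_vec))), 1e-10)
    step = float(np.mean(p_vec - y)) / h0
    b -= step
    eta = eta - step
    for j in range(len(beta)):
        p_vec = expit(eta)
        gj = float(Xs[:, j] @ (p_vec - y)) / n
        if conservative:
            hj = 0.25 * colsq[j]
        else:
            hj = max(float((p_vec * (1 - p_vec)) @ (Xs[:, j] ** 2)) / n, 1e-10)
        num = _soft(hj * beta[j] - gj, lam * alpha)
        new = num / (hj + lam * (1 - alpha))
        if new != beta[j]:
            eta = eta + Xs[:, j] * (new - beta[j])
            beta[j] = new
    return beta, b, eta


def _fit_standardized(
    Xs: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    beta_init: np.ndarray | None = None,
    b_init: float | None = None,
    tol: float = 1e-10,
    max_sweeps: int = 5000,
) -> tuple[float, np.ndarray, list[float]]:
    """Coordinate descent on standardized features. Returns (b, beta, path of
    per-sweep objective values, non-increasing)."""
    n, p = Xs.shape
    beta = np.zeros(p) if beta_init is None else beta_init.copy()
    ybar = float(np.mean(y))
    b = float(np.log(ybar / (1 - ybar))) if b_init is None else float(b_init)
    eta = b + Xs @ beta
    colsq = (Xs**2).mean(axis=0)
    obj = _objective(eta, y, beta, lam, alpha)
    history = [obj]
    conservative = False
    for _ in range(max_sweeps):
        beta_try, b_try, eta_try = _cd_sweep(
            Xs, y, eta.copy(), beta.copy(), b, lam, alpha, colsq, conservative
        )
        new_obj = _objective(eta_try, y, beta_try, lam, alpha)
        if new_obj > obj + 1e-15:
            if not conservative:
                conservative = True  # redo with guaranteed-monotone updates
                continue
            break
        beta, b, eta = beta_try, b_try, eta_try
        history.append(new_obj)
        if obj - new_obj < tol:
            obj = new_obj
            break
        obj = new_obj
    else:
        logger.warning("elastic net: max sweeps reached without convergence")
    return b, beta, history


def lambda_max(Xs: np.ndarray, y: np.ndarray, alpha: float) -> float:
    """Smallest penalty zeroing every coefficient at the given alpha."""
    n = len(y)
    ybar = np.mean(y)
    g = np.abs(Xs.T @ (y - ybar)) / n
    return float(g.max() / max(alpha, 1e-3))


def lambda_path(
    Xs: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int = 10, decades: float = 4.0
) -> np.ndarray:
    """Log-spaced penalty path from lambda_max down ``decades`` decades."""
    lmax = lambda_max(Xs, y, alpha)
    return np.geomspace(lmax, lmax * 10.0**-decades, n_lambda)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd, mean, sd


def fit_enet_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    alpha: float,
    lam: float,
    feature_names: Sequence[str] | None = None,
    feature_kinds: Mapping[str, str] | None = None,
    train_drug: str | None = None,
    tol: float = 1e-10,
    provenance: dict | None = None,
) -> FittedModel:
    """Fit the penalized logistic model and return it on the original scale."""
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
        if feature_names is None:
            feature_names = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite entries in X or y")
    classes = np.unique(y)
    if not (len(classes) == 2 and set(classes) <= {0.0, 1.0}):
        raise ValueError("y must be binary with both classes present")

    Xs, mean, sd = _standardize(X)
    b_std, beta_std, _ = _fit_standardized(Xs, y, alpha, lam, tol=tol)

    beta_raw = beta_std / sd
    b_raw = float(b_std - np.sum(beta_std * mean / sd))
    preds = expit(b_raw + X @ beta_raw)
    kinds = dict(feature_kinds or {})
    model = FittedModel(
        intercept=b_raw,
        coefficients={n: float(v) for n, v in zip(feature_names, beta_raw)},
        coefficients_std={n: float(v) for n, v in zip(feature_names, beta_std)},
        feature_names=list(feature_names),
        feature_kinds={n: kinds.get(n, "unknown") for n in feature_names},
        alpha=float(alpha),
        lam=float(lam),
        train_drug=train_drug,
        standardization={
            n: (float(mu), float(s)) for n, mu, s in zip(feature_names, mean, sd)
        },
        provenance=provenance or {},
        training_predictions=preds,
    )
    return model


def fit_intercept_only(
    y: np.ndarray, train_drug: str | None = None, provenance: dict | None = None
) -> FittedModel:
    """Fallback constant model (used when selection retains no feature)."""
    y = np.asarray(y, dtype=float)
    ybar = float(np.clip(np.mean(y), 1e-12, 1 - 1e-12))
    b = float(np.log(ybar / (1 - ybar)))
    return FittedModel(
        intercept=b,
        coefficients={},
        coefficients_std={},
        feature_names=[],
        feature_kinds={},
        alpha=1.0,
        lam=float("inf"),
        train_drug=train_drug,
        standardization={},
        provenance=provenance or {},
        training_predictions=np.full(len(y), expit(b)),
    )


def kkt_residuals(model: FittedModel, X: pd.DataFrame | np.ndarray, y: np.ndarray):
    """Max violation of the subgradient conditions on the standardized scale.

    Returns (zero-coefficient violation, active-coefficient violation): for
    zero coefficients |(1/n) x_j^T (y - p)| must not exceed lam * alpha; for
    active ones the full subgradient must vanish.
    """
    if isinstance(X, pd.DataFrame):
        X = X[model.feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mean = np.array([model.standardization[n][0] for n in model.feature_names])
    sd = np.array([model.standardization[n][1] for n in model.feature_names])
    Xs = (X - mean) / sd
    beta = np.array([model.coefficients_std[n] for n in model.feature_names])
    p = expit(model.intercept + X @ np.array(
        [model.coefficients[n] for n in model.feature_names]
    ))
    g = Xs.T @ (y - p) / len(y)
    zero = beta == 0
    viol_zero = float(np.max(np.abs(g[zero]) - model.lam * model.alpha, initial=0.0))
    active = ~zero
    sub = -g[active] + model.lam * (
        (1 - model.alpha) * beta[active] + model.alpha * np.sign(beta[active])
    )
    viol_active = float(np.max(np.abs(sub), initial=0.0))
    return viol_zero, viol_active


def predict_probability(model: FittedModel, X: pd.DataFrame | Mapping | np.ndarray):
    """Per-participant remission probability under a fitted model.

    DataFrame/mapping inputs are matched by feature name (extra columns are
    ignored); a missing model feature is a hard error. Array inputs must
    follow ``model.feature_names`` order.
    """
    if isinstance(X, pd.DataFrame):
        for name in model.feature_names:
            if name not in X.columns:
                raise KeyError(f"model feature {name!r} missing from input")
        if model.feature_names:
            V = X[model.feature_names].to_numpy(dtype=float)
        else:
            V = np.zeros((len(X), 0))
    elif isinstance(X, Mapping):
        for name in model.feature_names:
            if name not in X:
                raise KeyError(f"model feature {name!r} missing from input")
        if model.feature_names:
            V = np.column_stack(
                [np.asarray(X[n], dtype=float) for n in model.feature_names]
            )
        else:
            V = np.zeros((1, 0))
    else:
        V = np.asarray(X, dtype=float)
        if V.ndim == 1:
            V = V.reshape(1, -1)
        if V.shape[1] != len(model.feature_names):
            raise KeyError(
                f"expected {len(model.feature_names)} features, got {V.shape[1]}"
            )
    beta = np.array([model.coefficients[n] for n in model.feature_names])
    eta = model.intercept + V @ beta
    return expit(eta)


def tune_hyperparameters(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    alphas: Sequence[float] = (0.1, 0.55, 1.0),
    n_lambda: int = 10,
    folds: int = 5,
    repetitions: int = 100,
    seed: int = 0,
    tol: float = 1e-8,
) -> EnetHyperparams:
    """Choose (alpha, lambda) by mean out-of-fold AUC over repeated CV.

    The lambda path is log-spaced per alpha from lambda_max down 4 decades
    (computed on the full supplied data) and fitted warm-started from strong
    to weak penalty. Ties in mean AUC are broken toward larger lambda, then
    larger alpha. Deterministic given ``seed``.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(alphas) < 2:
        raise ValueError("grid must cover at least 2 alpha values")
    Xs_full, _, _ = _standardize(X)
    paths = {a: lambda_path(Xs_full, y, a, n_lambda=n_lambda) for a in alphas}

    sums = {(a, l): 0.0 for a in alphas for l in paths[a]}
    counts = {(a, l): 0 for a in alphas for l in paths[a]}
    children = np.random.SeedSequence(seed).spawn(repetitions)
    for child in children:
        rep_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        for tr, te in skf.split(X, y):
            if len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
                continue
            Xtr_s, mean, sd = _standardize(X[tr])
            Xte_s = (X[te] - mean) / sd
            for a in alphas:
                beta = np.zeros(X.shape[1])
                b = None
                for l in paths[a]:
                    b, beta, _ = _fit_standardized(
                        Xtr_s, y[tr], a, l, beta_init=beta, b_init=b, tol=tol
                    )
                    scores = Xte_s @ beta + b
                    sums[(a, l)] += roc_auc(scores, y[te])
                    counts[(a, l)] += 1

    rows = [
        {
            "alpha": a,
            "lam": l,
            "mean_auc": sums[(a, l)] / counts[(a, l)] if counts[(a, l)] else np.nan,
            "n_rounds": counts[(a, l)],
        }
        for a in alphas
        for l in paths[a]
    ]
    table = pd.DataFrame(rows)
    best = max(
        (r for r in rows if r["n_rounds"] > 0),
        key=lambda r: (round(r["mean_auc"], 12), r["lam"], r["alpha"]),
    )
    return EnetHyperparams(
        alpha=float(best["alpha"]), lam=float(best["lam"]), cv_results=table
    )


def export_model(model: FittedModel) -> dict:
    """JSON-serializable document for a fitted model (schema-versioned)."""
    return {
        "schema": MODEL_SCHEMA,
        "intercept": model.intercept,
        "features": [
            {
                "name": n,
                "kind": model.feature_kinds.get(n, "unknown"),
                "coefficient": model.coefficients[n],
                "coefficient_per_sd": model.coefficients_std[n],
                "odds_ratio": float(np.exp(model.coefficients[n])),
                "odds_ratio_per_sd": float(np.exp(model.coefficients_std[n])),
                "mean": model.standardization[n][0],
                "sd": model.standardization[n][1],
            }
            for n in model.feature_names
        ],
        "hyperparameters": {"alpha": model.alpha, "lambda": model.lam},
        "train_drug": model.train_drug,
        "threshold": model.threshold,
        "provenance": model.provenance,
    }


def export_model_json(model: FittedModel) -> str:
    return json.dumps(export_model(model), indent=2, sort_keys=True)


def import_model(doc: dict | str) -> FittedModel:
    """Rebuild a fitted model from an exported document."""
    if isinstance(doc, str):
        doc = json.loads(doc)
    if doc.get("schema") != MODEL_SCHEMA:
        raise ModelSchemaError(
            f"expected schema {MODEL_SCHEMA!r}, got {doc.get('schema')!r}"
        )
    feats = doc.get("features", [])
    hyper = doc.get("hyperparameters", {})
    return FittedModel(
        intercept=float(doc["intercept"]),
        coefficients={f["name"]: float(f["coefficient"]) for f in feats},
        coefficients_std={
            f["name"]: float(f.get("coefficient_per_sd", 0.0)) for f in feats
        },
        feature_names=[f["name"] for f in feats],
        feature_kinds={f["name"]: f.get("kind", "unknown") for f in feats},
        alpha=float(hyper.get("alpha", 1.0)),
        lam=float(hyper.get("lambda", 0.0)),
        train_drug=doc.get("train_drug"),
        standardization={
            f["name"]: (float(f.get("mean", 0.0)), float(f.get("sd", 1.0)))
            for f in feats
        },
        provenance=doc.get("provenance", {}),
        threshold=doc.get("threshold"),
    )
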