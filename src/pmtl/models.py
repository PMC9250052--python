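"""Logistic risk models: global, subgroup, and per-patient personalized
fits, each optionally warm-started from (and softly anchored to) a
large-sample global model.

The transfer mechanism is a quadratic anchor: the personalized objective is

    sum_i logloss_i(beta)  +  lambda_a * ||beta - beta_init||^2
                           +  lambda_r * ||beta||^2

minimized from beta_init. The anchor competes with the local likelihood on
the total-log-likelihood scale, so a small neighborhood stays close to the
transferred global knowledge while a large one is free to adapt — the
behavior that lets personalization help under subgroup heterogeneity
without hurting under homogeneity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

DEFAULT_RIDGE = 1.0
MIN_NEIGHBORS = 50


@dataclass
class TransferConfig:
    """Penalties (total-log-likelihood scale) and optimizer controls."""

    lambda_anchor: float = 20.0
    lambda_ridge: float = DEFAULT_RIDGE
    max_iter: int = 500
    tol: float = 1e-10

    def __post_init__(self):
        if self.lambda_anchor < 0 or self.lambda_ridge < 0:
            raise ValueError("penalty strengths must be nonnegative")


@dataclass
class GlobalFit:
    """Intercept + coefficients (log-odds scale) of a logistic risk model."""

    intercept: float
    coef: np.ndarray
    feature_names: Optional[list[str]] = None
    se_intercept: Optional[float] = None
    se_coef: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coef = np.asarray(self.coef, dtype=float)
        if not np.all(np.isfinite(self.coef)) or not np.isfinite(self.intercept):
            raise ValueError("model coefficients must be finite")

    @property
    def d(self) -> int:
        return self.coef.size


@dataclass
class PersonalizedFit(GlobalFit):
    """A logistic fit trained on one target patient's nearest neighbors."""

    target_id: Optional[str] = None
    neighbor_ids: list = field(default_factory=list)
    k: int = 0
    init: Optional[GlobalFit] = None

    def __post_init__(self):
        super().__post_init__()
        if self.k != len(self.neighbor_ids):
            raise ValueError("k must equal the number of neighbors")
        if self.target_id is not None and self.target_id in set(self.neighbor_ids):
            raise ValueError("target must not be among its own neighbors")


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _feature_names(X, d: int) -> Optional[list[str]]:
    if isinstance(X, pd.DataFrame):
        return [str(c) for c in X.columns]
    return None


def _penalized_logistic(
    X: np.ndarray,
    y: np.ndarray,
    theta0: Optional[np.ndarray],
    lambda_anchor: float,
    lambda_ridge: float,
    start: Optional[np.ndarray],
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Minimize the anchored/ridged logistic loss; return (theta, se).

    theta = [intercept, coef]; the anchor acts on the whole vector, the
    ridge on coefficients only (intercept unpenalized, as usual). Standard
    errors come from the observed information of the penalized objective.
    """
    n, d = X.shape
    Z = np.column_stack([np.ones(n), X])
    yy = 2.0 * y - 1.0
    ridge_mask = np.ones(d + 1)
    ridge_mask[0] = 0.0

    def fun(theta):
        m = yy * (Z @ theta)
        # log(1 + exp(-m)) evaluated stably
        loss = np.logaddexp(0.0, -m).sum()
        grad = Z.T @ (-yy * expit(-m))
        if lambda_anchor > 0:
            dv = theta - theta0
            loss += lambda_anchor * dv @ dv
            grad = grad + 2.0 * lambda_anchor * dv
        if lambda_ridge > 0:
            loss += lambda_ridge * (ridge_mask * theta) @ theta
            grad = grad + 2.0 * lambda_ridge * ridge_mask * theta
        return loss / n, grad / n

    x0 = np.zeros(d + 1) if start is None else np.asarray(start, dtype=float)
    res = minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
    )
    theta = res.x
    p = expit(Z @ theta)
    w = p * (1.0 - p)
    H = (Z * w[:, None]).T @ Z
    H[np.diag_indices_from(H)] += 2.0 * lambda_anchor + 2.0 * lambda_ridge * ridge_mask
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return theta, se


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("degenerate outcome: a single class was supplied")


def fit_logistic(
    X, y, penalty: float = DEFAULT_RIDGE, seed: Optional[int] = None, **meta
) -> GlobalFit:
    """Ridge-penalized maximum-likelihood logistic regression (cold start).

    ``penalty`` is the ridge strength on the total-log-likelihood scale;
    the fit is deterministic given its inputs (``seed`` is recorded in the
    metadata only).
    """
    Xm = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    _check_two_classes(y)
    theta, se = _penalized_logistic(
        Xm, y, None, 0.0, penalty, None, max_iter=500, tol=1e-10
    )
    return GlobalFit(
        intercept=float(theta[0]),
        coef=theta[1:],
        feature_names=_feature_names(X, Xm.shape[1]),
        se_intercept=float(se[0]),
        se_coef=se[1:],
        meta={"n": int(len(y)), "penalty": penalty, "seed": seed, **meta},
    )


def fit_transfer(X, y, init: GlobalFit, cfg: Optional[TransferConfig] = None) -> GlobalFit:
    """Warm-started, anchor-penalized logistic fit initialized at ``init``.

    With ``cfg.max_iter == 0`` the initializing coefficients are returned
    unchanged (pure transfer, no local learning).
    """
    cfg = cfg or TransferConfig()
    Xm = _as_matrix(X)
    if Xm.shape[1] != init.d:
        raise ValueError(
            f"dimension mismatch: data has {Xm.shape[1]} features, init has {init.d}"
        )
    y = np.asarray(y, dtype=float)
    theta0 = np.concatenate([[init.intercept], init.coef])
    if cfg.max_iter == 0:
        return GlobalFit(
            intercept=init.intercept,
            coef=init.coef.copy(),
            feature_names=init.feature_names,
            se_intercept=init.se_intercept,
            se_coef=None if init.se_coef is None else init.se_coef.copy(),
            meta={"n": int(len(y)), "transfer": True, "max_iter": 0},
        )
    _check_two_classes(y)
    theta, se = _penalized_logistic(
        Xm,
        y,
        theta0,
        cfg.lambda_anchor,
        cfg.lambda_ridge,
        start=theta0,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
    )
    return GlobalFit(
        intercept=float(theta[0]),
        coef=theta[1:],
        feature_names=_feature_names(X, Xm.shape[1]) or init.feature_names,
        se_intercept=float(se[0]),
        se_coef=se[1:],
        meta={
            "n": int(len(y)),
            "transfer": True,
            "lambda_anchor": cfg.lambda_anchor,
            "lambda_ridge": cfg.lambda_ridge,
        },
    )


def fit_subgroup(
    X,
    y,
    subgroup_ids: Sequence,
    group,
    transfer: Optional[GlobalFit] = None,
    cfg: Optional[TransferConfig] = None,
    min_n: int = MIN_NEIGHBORS,
) -> GlobalFit:
    """Fit on the rows of one subgroup only, optionally transfer-initialized."""
    cfg = cfg or TransferConfig()
    mask = np.asarray([g == group for g in subgroup_ids])
    n_sel = int(mask.sum())
    if n_sel < min_n:
        raise ValueError(f"subgroup {group!r} has only {n_sel} members (minimum {min_n})")
    Xg = X[mask] if isinstance(X, pd.DataFrame) else _as_matrix(X)[mask]
    yg = np.asarray(y, dtype=float)[mask]
    if np.unique(yg).size < 2:
        raise ValueError(f"subgroup {group!r} contains a single outcome class")
    if transfer is None:
        fit = fit_logistic(Xg, yg, penalty=cfg.lambda_ridge)
    else:
        fit = fit_transfer(Xg, yg, transfer, cfg)
    fit.meta["subgroup"] = group
    return fit


def personalize(
    target_x,
    pool_X,
    pool_y,
    pool_ids: Sequence,
    weights=None,
    k_fraction: float = 0.10,
    global_fit: Optional[GlobalFit] = None,
    cfg: Optional[TransferConfig] = None,
    target_id: Optional[str] = None,
    min_k: int = MIN_NEIGHBORS,
) -> PersonalizedFit:
    """Build an on-demand model for one target patient.

    Retrieves ``round(k_fraction * |pool|)`` nearest neighbors under the
    weighted patient distance, then fits a logistic model on the neighbors
    only — warm-started from ``global_fit`` when given, cold otherwise. If
    the neighborhood contains a single outcome class the global model is
    returned as a flagged fallback.
    """
    from .similarity import find_similar_indices

    cfg = cfg or TransferConfig()
    pool_Xm = _as_matrix(pool_X)
    pool_y = np.asarray(pool_y, dtype=float)
    pool_ids = list(pool_ids)
    n_pool = pool_Xm.shape[0]
    k = int(round(k_fraction * n_pool))
    if k < min_k:
        raise ValueError(
            f"neighborhood of {k} is below the minimum of {min_k}; "
            "increase k_fraction or the pool size"
        )
    tx = np.asarray(target_x, dtype=float).ravel()
    if weights is None:
        weights = np.ones(pool_Xm.shape[1])
    idx = find_similar_indices(tx, pool_Xm, pool_ids, weights, k)
    neigh_ids = [pool_ids[i] for i in idx]
    Xn, yn = pool_Xm[idx], pool_y[idx]

    names = _feature_names(pool_X, pool_Xm.shape[1])
    if np.unique(yn).size < 2:
        if global_fit is None:
            raise ValueError(
                "neighborhood contains a single outcome class and no global "
                "fallback model was provided"
            )
        return PersonalizedFit(
            intercept=global_fit.intercept,
            coef=global_fit.coef.copy(),
            feature_names=names or global_fit.feature_names,
            target_id=target_id,
            neighbor_ids=neigh_ids,
            k=k,
            init=global_fit,
            meta={"fallback": True},
        )
    if global_fit is None:
        base = fit_logistic(Xn, yn, penalty=cfg.lambda_ridge)
    else:
        base = fit_transfer(Xn, yn, global_fit, cfg)
    return PersonalizedFit(
        intercept=base.intercept,
        coef=base.coef,
        feature_names=names,
        se_intercept=base.se_intercept,
        se_coef=base.se_coef,
        target_id=target_id,
        neighbor_ids=neigh_ids,
        k=k,
        init=global_fit,
        meta={"fallback": False, **base.meta},
    )


def predict_risk(fit: GlobalFit, X) -> np.ndarray | float:
    """Event probability logistic(intercept + coef . x)."""
    Xm = _as_matrix(X)
    squeeze = Xm.ndim == 1
    if squeeze:
        Xm = Xm[None, :]
    if Xm.shape[1] != fit.d:
        raise ValueError("feature dimension does not match the fit")
    p = expit(fit.intercept + Xm @ fit.coef)
    return float(p[0]) if squeeze else p


def fit_to_json(fit: GlobalFit) -> str:
    names = fit.feature_names or [f"x{j}" for j in range(fit.d)]
    payload = {
        "intercept": fit.intercept,
        "coef": {n: float(c) for n, c in zip(names, fit.coef)},
        "meta": {k: v for k, v in fit.meta.items() if _json_safe(v)},
    }
    if fit.se_coef is not None:
        payload["se"] = {
            "intercept": fit.se_intercept,
            "coef": {n: float(s) for n, s in zip(names, fit.se_coef)},
        }
    return json.dumps(payload, indent=1)


def fit_from_json(text: str) -> GlobalFit:
    obj = json.loads(text)
    names = list(obj["coef"])
    fit = GlobalFit(
        intercept=float(obj["intercept"]),
        coef=np.array([obj["coef"][n] for n in names], dtype=float),
        feature_names=names,
        meta=obj.get("meta", {}),
    )
    if "se" in obj:
        fit.se_intercept = obj["se"]["intercept"]
        fit.se_coef = np.array([obj["se"]["coef"][n] for n in names], dtype=float)
    return fit


def _json_safe(v) -> bool:
    return isinstance(v, (int, float, str, bool, type(None)))
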