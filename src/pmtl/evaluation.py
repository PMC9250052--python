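"""Model evaluation and comparison.

Metrics (AUROC as the Mann-Whitney statistic, AUPRC by the
average-precision convention, binned mean-squared calibration error),
paired statistical comparisons (DeLong test, z test, paired bootstrap),
the stratified 5-fold cross-validation harness over the six benchmark
model families, the training-fraction learning-curve sweep, and the
alert-matched AKI-retrieval comparison.

All test-fold scores are pooled across folds before any metric is
computed, which keeps a single paired score vector per model and makes
the DeLong and bootstrap comparisons straightforward.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import average_precision_score
from sklearn.model_selection import StratifiedKFold, train_test_split

from .models import (
    GlobalFit,
    TransferConfig,
    fit_logistic,
    fit_subgroup,
    fit_transfer,
    personalize,
    predict_risk,
    MIN_NEIGHBORS,
)
from .preprocess import Preprocessor

log = logging.getLogger(__name__)

SIX_MODELS = (
    "global",
    "global_tl",
    "subgroup",
    "subgroup_tl",
    "personalized",
    "personalized_tl",
)


@dataclass
class EvaluationReport:
    model: str
    auroc: float
    auprc: float
    calibration_error: float
    n: int
    prevalence: float
    ci: dict = field(default_factory=dict)  # metric -> (lo, hi), bootstrap percentile


@dataclass
class ComparisonResult:
    metric: str
    delta: float
    p_value: float
    wins: int = 0
    losses: int = 0
    ties: int = 0
    B: int = 0
    redraws: int = 0


def _validate_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    return y


def auroc(y, scores) -> float:
    """P(random case outscores random control), ties counted 1/2."""
    y = _validate_binary(y)
    s = np.asarray(scores, dtype=float)
    r = rankdata(s)
    n1 = int(y.sum())
    n0 = y.size - n1
    return float((r[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auprc(y, scores) -> float:
    """Area under precision-recall, average-precision (step) convention."""
    y = np.asarray(y, dtype=float)
    if y.sum() == 0:
        raise ValueError("AUPRC requires at least one case")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def calibration_error(y, scores, n_bins: int = 10) -> float:
    """Mean over equal-frequency bins of (mean predicted - observed rate)^2."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.size < n_bins:
        raise ValueError(
            f"n={y.size} is smaller than n_bins={n_bins}; use fewer bins"
        )
    order = np.argsort(s, kind="stable")
    err = 0.0
    for chunk in np.array_split(order, n_bins):
        err += (s[chunk].mean() - y[chunk].mean()) ** 2
    return float(err / n_bins)


def _delong_components(y: np.ndarray, s: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUROC plus its case/control structural components (midrank form)."""
    pos, neg = s[y == 1], s[y == 0]
    m, n = pos.size, neg.size
    all_r = rankdata(np.concatenate([pos, neg]))
    pos_r, neg_r = rankdata(pos), rankdata(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    a = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return a, v10, v01


def delong_test(y, s1, s2) -> tuple[float, float]:
    """DeLong test for two correlated AUROCs on paired scores.

    Returns (auroc1 - auroc2, two-sided p). Identical score vectors give
    delta 0 and p 1.
    """
    y = _validate_binary(y)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    a1, v10_1, v01_1 = _delong_components(y, s1)
    a2, v10_2, v01_2 = _delong_components(y, s2)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    delta = a1 - a2
    if var <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var)
    return float(delta), float(2.0 * norm.sf(abs(z)))


def z_test_metric_diff(est1: float, se1: float, est2: float, se2: float) -> float:
    """Two-sided normal p for a difference of independent estimates."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (est1 - est2) / np.sqrt(se1**2 + se2**2)
    return float(2.0 * norm.sf(abs(z)))


def _auroc_rows(yb: np.ndarray, sb: np.ndarray) -> np.ndarray:
    """Row-wise AUROC for matrices of bootstrap resamples."""
    r = rankdata(sb, axis=1)
    n1 = yb.sum(axis=1)
    n0 = yb.shape[1] - n1
    case_ranks = (r * yb).sum(axis=1)
    return (case_ranks - n1 * (n1 + 1) / 2.0) / (n1 * n0)


_METRICS: dict[str, Callable] = {}


def _register_metrics():
    _METRICS.update({"auroc": auroc, "auprc": auprc, "calibration": calibration_error})


_register_metrics()


def bootstrap_compare(
    y,
    s1,
    s2,
    metric: str = "auroc",
    B: int = 20000,
    seed: int = 0,
    chunk: int = 2000,
) -> ComparisonResult:
    """Paired bootstrap over test indices: in how many of B resamples does
    model 1 strictly beat model 2 on the metric?

    Higher-is-better metrics count wins as metric1 > metric2; for
    calibration error lower is better and the comparison is flipped.
    Single-class resamples are redrawn (count reported). The two-sided
    sign-test p is 2*min(wins, losses)/B.
    """
    y = _validate_binary(y)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    higher_better = metric != "calibration"
    rng = np.random.default_rng(seed)
    n = y.size
    wins = losses = ties = redraws = 0

    def resample_rows(size):
        nonlocal redraws
        idx = rng.integers(0, n, size=(size, n))
        bad = np.flatnonzero(~((y[idx] == 1).any(axis=1) & (y[idx] == 0).any(axis=1)))
        while bad.size:
            redraws += int(bad.size)
            idx[bad] = rng.integers(0, n, size=(bad.size, n))
            bad = bad[~(((y[idx[bad]] == 1).any(axis=1)) & ((y[idx[bad]] == 0).any(axis=1)))]
        return idx

    done = 0
    while done < B:
        size = min(chunk, B - done)
        idx = resample_rows(size)
        yb = y[idx]
        if metric == "auroc":
            m1 = _auroc_rows(yb, s1[idx])
            m2 = _auroc_rows(yb, s2[idx])
        else:
            f = _METRICS[metric]
            m1 = np.array([f(yb[i], s1[idx[i]]) for i in range(size)])
            m2 = np.array([f(yb[i], s2[idx[i]]) for i in range(size)])
        d = m1 - m2
        if not higher_better:
            d = -d
        wins += int((d > 0).sum())
        losses += int((d < 0).sum())
        ties += int((d == 0).sum())
        done += size

    f = _METRICS[metric]
    delta = f(y, s1) - f(y, s2)
    p = 2.0 * min(wins, losses) / B
    return ComparisonResult(
        metric=metric,
        delta=float(delta),
        p_value=float(min(1.0, p)),
        wins=wins,
        losses=losses,
        ties=ties,
        B=B,
        redraws=redraws,
    )


def evaluate_scores(
    y, scores, model: str = "model", n_boot: int = 1000, seed: int = 0,
    n_bins: int = 10,
) -> EvaluationReport:
    """Point metrics with bootstrap-percentile CIs for one score vector."""
    y = _validate_binary(y)
    s = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = y.size
    ci = {}
    if n_boot > 0:
        idx = rng.integers(0, n, size=(n_boot, n))
        ok = (y[idx] == 1).any(axis=1) & (y[idx] == 0).any(axis=1)
        idx = idx[ok]
        a = _auroc_rows(y[idx], s[idx])
        pr = np.array([auprc(y[i], s[i]) for i in idx])
        ce = np.array([calibration_error(y[i], s[i], n_bins) for i in idx])
        for name, vals in [("auroc", a), ("auprc", pr), ("calibration_error", ce)]:
            ci[name] = (float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5)))
    return EvaluationReport(
        model=model,
        auroc=auroc(y, s),
        auprc=auprc(y, s),
        calibration_error=calibration_error(y, s, n_bins),
        n=n,
        prevalence=float(y.mean()),
        ci=ci,
    )


@dataclass
class CVResult:
    reports: dict[str, EvaluationReport]
    scores: pd.DataFrame        # pooled out-of-fold scores, one column per model
    y: np.ndarray
    delong: dict[tuple[str, str], tuple[float, float]]
    bootstrap: dict[tuple[str, str], ComparisonResult]
    fold: np.ndarray


def _fit_fold_models(
    Z_tr, y_tr, ids_tr, subgroup_tr, Z_te, subgroup_te, ids_te,
    models, k_fraction, cfg, weights, min_k,
):
    """Fit the requested model families on one training fold and score the
    test fold; returns {model: scores}."""
    out = {}
    need_global = bool(
        {"global", "global_tl", "subgroup_tl", "personalized_tl"} & set(models)
    ) or weights is not None
    gfit = fit_logistic(Z_tr, y_tr, penalty=cfg.lambda_ridge) if need_global else None

    if "global" in models:
        out["global"] = predict_risk(gfit, Z_te)
    if "global_tl" in models:
        f = fit_transfer(Z_tr, y_tr, gfit, cfg)
        out["global_tl"] = predict_risk(f, Z_te)

    for tag, transfer in (("subgroup", None), ("subgroup_tl", gfit)):
        if tag not in models:
            continue
        scores = np.empty(len(Z_te))
        for g in np.unique(subgroup_te):
            te_mask = subgroup_te == g
            try:
                f = fit_subgroup(Z_tr, y_tr, subgroup_tr, g, transfer=transfer, cfg=cfg)
            except ValueError as e:
                log.warning("subgroup fallback to global: %s", e)
                f = gfit if gfit is not None else fit_logistic(Z_tr, y_tr, penalty=cfg.lambda_ridge)
            scores[te_mask] = predict_risk(f, Z_te.loc[te_mask] if isinstance(Z_te, pd.DataFrame) else Z_te[te_mask])
        out[tag] = scores

    Z_te_m = Z_te.to_numpy(dtype=float) if isinstance(Z_te, pd.DataFrame) else np.asarray(Z_te, float)
    for tag, gf in (("personalized", None), ("personalized_tl", gfit)):
        if tag not in models:
            continue
        scores = np.empty(len(Z_te_m))
        for i in range(len(Z_te_m)):
            pf = personalize(
                Z_te_m[i], Z_tr, y_tr, ids_tr,
                weights=weights, k_fraction=k_fraction, global_fit=gf,
                cfg=cfg, target_id=ids_te[i], min_k=min_k,
            )
            scores[i] = predict_risk(pf, Z_te_m[i])
        out[tag] = scores
    return out


def crossvalidate(
    X: pd.DataFrame,
    y,
    subgroups: Optional[Sequence] = None,
    models: Sequence[str] = SIX_MODELS,
    folds: int = 5,
    k_fraction: float = 0.10,
    cfg: Optional[TransferConfig] = None,
    weights=None,
    optimize_weights_hyper: Optional[dict] = None,
    seed: int = 0,
    min_k: int = MIN_NEIGHBORS,
    n_boot: int = 500,
    compare_B: int = 2000,
    n_bins: int = 10,
) -> CVResult:
    """Stratified k-fold benchmark of the requested model families.

    Standardization, imputation, the global fit, and (optionally)
    similarity-weight optimization are all learned inside each training
    fold; out-of-fold scores are pooled before metrics and comparisons.
    Pass ``weights="optimize"`` to tune retrieval weights per fold on an
    internal pool/probe split of the training data.
    """
    from .similarity import optimize_weights as _optimize_weights

    cfg = cfg or TransferConfig()
    y = np.asarray(y, dtype=float)
    _validate_binary(y)
    n = y.size
    ids = np.asarray(X.index.astype(str)) if isinstance(X, pd.DataFrame) else np.array([str(i) for i in range(n)])
    subgroups = np.asarray(subgroups) if subgroups is not None else np.zeros(n, dtype=int)
    unknown = set(models) - set(SIX_MODELS)
    if unknown:
        raise ValueError(f"unknown models {sorted(unknown)}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.empty(n, dtype=int)
    pooled = {m: np.empty(n) for m in models}
    for f_idx, (tr, te) in enumerate(skf.split(np.zeros(n), y)):
        fold_of[te] = f_idx
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError(
                "a fold is missing an outcome class; try another seed or fewer folds"
            )
        prep = Preprocessor()
        Z_tr = prep.fit_transform(X.iloc[tr])
        Z_te = prep.transform(X.iloc[te])
        w = weights
        if isinstance(weights, str) and weights == "optimize":
            hyper = dict(optimize_weights_hyper or {})
            p_tr, p_pr = train_test_split(
                np.arange(len(tr)), test_size=hyper.pop("probe_fraction", 0.25),
                random_state=seed + f_idx, stratify=y[tr],
            )
            gfit_w = fit_logistic(Z_tr.iloc[p_tr], y[tr][p_tr], penalty=cfg.lambda_ridge)
            sw = _optimize_weights(
                Z_tr.iloc[p_tr], y[tr][p_tr], ids[tr][p_tr],
                Z_tr.iloc[p_pr], y[tr][p_pr],
                k_fraction=k_fraction, global_fit=gfit_w, cfg=cfg,
                seed=seed + f_idx, min_k=min(min_k, max(1, int(round(k_fraction * len(p_tr))))),
                **hyper,
            )
            w = sw.w
        fold_scores = _fit_fold_models(
            Z_tr, y[tr], list(ids[tr]), subgroups[tr],
            Z_te, subgroups[te], list(ids[te]),
            models, k_fraction, cfg, w, min_k,
        )
        for m, s in fold_scores.items():
            pooled[m][te] = s

    reports = {
        m: evaluate_scores(y, pooled[m], model=m, n_boot=n_boot, seed=seed, n_bins=n_bins)
        for m in models
    }
    delong = {}
    boot = {}
    mlist = list(models)
    for i in range(len(mlist)):
        for j in range(i + 1, len(mlist)):
            a, b = mlist[i], mlist[j]
            delong[(a, b)] = delong_test(y, pooled[a], pooled[b])
            if compare_B > 0:
                boot[(a, b)] = bootstrap_compare(
                    y, pooled[a], pooled[b], metric="auroc", B=compare_B, seed=seed
                )
    return CVResult(
        reports=reports,
        scores=pd.DataFrame(pooled, index=ids),
        y=y,
        delong=delong,
        bootstrap=boot,
        fold=fold_of,
    )


def training_fraction_sweep(
    X: pd.DataFrame,
    y,
    fractions: Sequence[float] = (0.05, 0.25, 1.0),
    repeats: int = 10,
    seed: int = 0,
    cfg: Optional[TransferConfig] = None,
    test_size: float = 0.25,
) -> pd.DataFrame:
    """Learning-curve sweep: global model refit on random training
    subsamples, with and without transfer initialization from the
    full-training-data global fit, evaluated on an untouched test split.

    Returns one row per (fraction, repeat, model) with its test AUROC;
    single-class subsamples are skipped with a log entry.
    """
    cfg = cfg or TransferConfig()
    y = np.asarray(y, dtype=float)
    _validate_binary(y)
    if any(f <= 0 or f > 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    rows = []
    for rep in range(repeats):
        tr_idx, te_idx = train_test_split(
            np.arange(y.size), test_size=test_size, random_state=seed + rep, stratify=y
        )
        prep = Preprocessor()
        Z_tr = prep.fit_transform(X.iloc[tr_idx])
        Z_te = prep.transform(X.iloc[te_idx])
        y_tr, y_te = y[tr_idx], y[te_idx]
        full_fit = fit_logistic(Z_tr, y_tr, penalty=cfg.lambda_ridge)
        rng = np.random.default_rng(seed * 1000 + rep)
        for frac in fractions:
            if frac >= 1.0:
                sub = np.arange(y_tr.size)
            else:
                sub = rng.choice(y_tr.size, size=max(2, int(round(frac * y_tr.size))), replace=False)
            if np.unique(y_tr[sub]).size < 2:
                log.warning("fraction %.3f repeat %d: single-class subsample, skipped", frac, rep)
                continue
            Zs, ys = Z_tr.iloc[sub], y_tr[sub]
            cold = fit_logistic(Zs, ys, penalty=cfg.lambda_ridge)
            warm = fit_transfer(Zs, ys, full_fit, cfg)
            rows.append((frac, rep, "global", auroc(y_te, predict_risk(cold, Z_te))))
            rows.append((frac, rep, "global_tl", auroc(y_te, predict_risk(warm, Z_te))))
    return pd.DataFrame(rows, columns=["fraction", "repeat", "model", "auroc"])


def recall_at_matched_alerts(
    y, s1, s2, budgets: Optional[Sequence[int]] = None
) -> tuple[float, pd.DataFrame]:
    """Percent more true cases captured by s1 than s2 at equal alert budgets.

    The headline number uses a budget equal to the number of true cases;
    a per-budget table is returned alongside. Swapping the arguments flips
    the comparison's direction but not symmetrically (the denominator is
    always the second model's capture count).
    """
    y = _validate_binary(y)
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    n_cases = int(y.sum())
    if budgets is None:
        budgets = [n_cases]

    def captured(s, m):
        top = np.argsort(-s, kind="stable")[:m]
        return int(y[top].sum())

    rows = []
    headline = None
    for m in budgets:
        c1, c2 = captured(s1, m), captured(s2, m)
        if c2 == 0:
            raise ValueError("comparator captures no cases; percent change undefined")
        pct = 100.0 * (c1 - c2) / c2
        rows.append((m, c1, c2, pct))
        if m == n_cases:
            headline = pct
    table = pd.DataFrame(rows, columns=["budget", "captured_1", "captured_2", "pct_more"])
    if headline is None:
        headline = float(table["pct_more"].iloc[0])
    return float(headline), table
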