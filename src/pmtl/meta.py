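"""Metaregression over per-patient personalized coefficients.

Each personalized model is treated as an independent "study" whose effect
size is the coefficient of a target variable and whose variance is that
coefficient's squared standard error; the patient's remaining covariates
become study-level moderators. A random-effects metaregression
(DerSimonian-Laird method-of-moments residual heterogeneity, weighted
least squares point estimates) screens for moderators, and a stratified
refit with a z test verifies candidate interactions on the raw data —
the personalized fits share neighbors, so the metaregression is treated
as hypothesis-generating only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .evaluation import z_test_metric_diff
from .models import GlobalFit, PersonalizedFit, TransferConfig, fit_logistic
from scipy.stats import norm


@dataclass
class EffectStudy:
    study_id: str
    effect: float      # log-odds coefficient of the target variable
    variance: float    # squared SE of that coefficient
    covariates: pd.Series = field(default_factory=pd.Series)

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("study variance must be positive")


@dataclass
class MetaRegressionResult:
    moderators: list[str]
    gamma: np.ndarray      # includes intercept first
    se: np.ndarray
    p: np.ndarray
    tau2: float
    n_studies: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gamma": self.gamma, "se": self.se, "p": self.p},
            index=["intercept"] + self.moderators,
        )


def collect_effect_studies(
    fits: Sequence[PersonalizedFit],
    target: str,
    moderators: Sequence[str],
    covariates: Optional[pd.DataFrame] = None,
    observed: Optional[pd.DataFrame] = None,
) -> list[EffectStudy]:
    """One study per personalized fit whose patient recorded the target.

    ``covariates`` holds each patient's moderator values (indexed by
    target id); ``observed`` is an optional boolean mask (same indexing)
    saying which variables were actually recorded for each patient — fits
    of patients missing the target are skipped, mirroring "patients who
    had the variable recorded".
    """
    studies = []
    for fit in fits:
        if fit.se_coef is None or fit.meta.get("fallback"):
            continue
        if fit.feature_names is None or target not in fit.feature_names:
            continue
        if observed is not None and not bool(observed.loc[fit.target_id, target]):
            continue
        j = fit.feature_names.index(target)
        se = float(fit.se_coef[j])
        cov = (
            covariates.loc[fit.target_id, list(moderators)]
            if covariates is not None
            else pd.Series(dtype=float)
        )
        studies.append(
            EffectStudy(
                study_id=str(fit.target_id),
                effect=float(fit.coef[j]),
                variance=se**2,
                covariates=cov,
            )
        )
    if not studies:
        raise ValueError(f"no eligible personalized fits for target {target!r}")
    return studies


def fit_metaregression(
    studies: Sequence[EffectStudy], moderators: Optional[Sequence[str]] = None
) -> MetaRegressionResult:
    """Random-effects metaregression (method-of-moments tau^2).

    Point estimates by WLS with weights 1/(variance + tau^2); tau^2 from
    the DerSimonian-Laird generalization: tau^2 = max(0, (Q - df) / tr(P))
    with Q the fixed-effects weighted residual sum of squares and
    P = W - W X (X'WX)^-1 X'W. Two-sided normal p per moderator.
    """
    eff = np.array([s.effect for s in studies])
    v = np.array([s.variance for s in studies])
    k = eff.size
    if moderators is None:
        moderators = list(studies[0].covariates.index)
    Xm = np.column_stack(
        [np.ones(k)]
        + [np.array([float(s.covariates[m]) for s in studies]) for m in moderators]
    )
    p = Xm.shape[1]
    if k <= p:
        raise ValueError("need more studies than moderators + 1")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        # identify offending columns by greedy rank check
        bad = []
        cols = [0]
        for j in range(1, p):
            if np.linalg.matrix_rank(Xm[:, cols + [j]]) == len(cols):
                bad.append(moderators[j - 1])
            else:
                cols.append(j)
        raise ValueError(f"collinear moderators: {bad}")

    w = 1.0 / v
    fe = sm.WLS(eff, Xm, weights=w).fit()
    resid = eff - Xm @ fe.params
    Q = float(w @ resid**2)
    W = np.diag(w)
    XtWX_inv = np.linalg.inv(Xm.T @ W @ Xm)
    trP = float(w.sum() - np.trace(XtWX_inv @ (Xm.T @ (W @ W) @ Xm)))
    tau2 = max(0.0, (Q - (k - p)) / trP)

    w_re = 1.0 / (v + tau2)
    re = sm.WLS(eff, Xm, weights=w_re).fit()
    # classical meta-analytic (inverse-variance) SEs, not WLS scale-adjusted
    cov = np.linalg.inv(Xm.T @ np.diag(w_re) @ Xm)
    se = np.sqrt(np.diag(cov))
    z = re.params / se
    pvals = 2.0 * norm.sf(np.abs(z))
    return MetaRegressionResult(
        moderators=list(moderators),
        gamma=np.asarray(re.params),
        se=se,
        p=pvals,
        tau2=tau2,
        n_studies=k,
    )


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Odds ratio (a*d)/(b*c) with Haldane-Anscombe +0.5 correction when
    any cell is zero; returns (OR, SE of log OR on corrected cells)."""
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0) or np.any(cells != np.round(cells)):
        raise ValueError("cells must be nonnegative integers")
    a, b, c, d = cells
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("a row or column of the 2x2 table is entirely zero")
    if np.any(cells == 0):
        a, b, c, d = cells + 0.5
    or_ = (a * d) / (b * c)
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    return float(or_), se


def subgroup_interaction_check(
    X: pd.DataFrame,
    y,
    target: str,
    moderator: str,
    cfg: Optional[TransferConfig] = None,
    binary_target: Optional[bool] = None,
) -> dict:
    """Verify a metaregression finding by stratification.

    Splits the cohort into moderator-exposed (>= its median for continuous
    moderators, == 1 for binary) and unexposed strata, estimates the
    target variable's effect in each (adjusted logistic coefficient, plus
    a raw 2x2 odds ratio when the target is binary), and z-tests the
    difference of the stratum log effects.
    """
    cfg = cfg or TransferConfig()
    y = np.asarray(y, dtype=float)
    mod = X[moderator].to_numpy(dtype=float)
    uniq = np.unique(mod[~np.isnan(mod)])
    exposed = mod == 1 if set(uniq) <= {0.0, 1.0} else mod >= np.median(mod)

    results = {}
    effects, ses = [], []
    for name, mask in (("exposed", exposed), ("unexposed", ~exposed)):
        ys = y[mask]
        if mask.sum() == 0:
            raise ValueError(f"empty {name} stratum")
        if np.unique(ys).size < 2:
            raise ValueError(f"{name} stratum contains a single outcome class")
        Xs = X.loc[mask, [c for c in X.columns if c != moderator]]
        fit = fit_logistic(Xs, ys, penalty=cfg.lambda_ridge)
        j = fit.feature_names.index(target)
        eff, se = float(fit.coef[j]), float(fit.se_coef[j])
        entry = {"n": int(mask.sum()), "coef": eff, "se": se}
        tvals = X.loc[mask, target].dropna().unique()
        is_bin = binary_target if binary_target is not None else set(np.asarray(tvals, float)) <= {0.0, 1.0}
        if is_bin:
            tcol = X.loc[mask, target].to_numpy(dtype=float)
            a = int(((tcol == 1) & (ys == 1)).sum())
            b = int(((tcol == 1) & (ys == 0)).sum())
            c = int(((tcol == 0) & (ys == 1)).sum())
            d = int(((tcol == 0) & (ys == 0)).sum())
            try:
                entry["odds_ratio"], entry["log_or_se"] = odds_ratio_2x2(a, b, c, d)
            except ValueError:
                entry["odds_ratio"] = np.nan
        results[name] = entry
        effects.append(eff)
        ses.append(se)
    results["p_difference"] = z_test_metric_diff(effects[0], ses[0], effects[1], ses[1])
    return results


def pooled_random_effect(studies: Sequence[EffectStudy]) -> tuple[float, float, float]:
    """DerSimonian-Laird pooled mean with no moderators: (mean, SE, tau^2)."""
    eff = np.array([s.effect for s in studies])
    v = np.array([s.variance for s in studies])
    w = 1.0 / v
    mu_fe = float(w @ eff / w.sum())
    Q = float(w @ (eff - mu_fe) ** 2)
    c = float(w.sum() - (w @ w) / w.sum())
    tau2 = max(0.0, (Q - (eff.size - 1)) / c)
    w_re = 1.0 / (v + tau2)
    mu = float(w_re @ eff / w_re.sum())
    se = float(np.sqrt(1.0 / w_re.sum()))
    return mu, se, tau2


def studies_to_frame(studies: Sequence[EffectStudy]) -> pd.DataFrame:
    rows = []
    for s in studies:
        row = {"study_id": s.study_id, "effect": s.effect, "variance": s.variance}
        row.update({f"mod_{k}": v for k, v in s.covariates.items()})
        rows.append(row)
    return pd.DataFrame(rows)
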