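"""Predictor importance and heterogeneity analyses.

Three importance measures per predictor (standardized coefficient,
permutation AUROC gain, interclass score difference), subgroup
heterogeneity summarized as the mean absolute pairwise Pearson correlation
among top predictors, relative-effect matrices comparing predictor payoff
across subgroups and model families, and the coefficient of variation of
personalized-model coefficients across patients.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import auroc
from .models import GlobalFit, predict_risk


def _resolve_feature(fit: GlobalFit, feature) -> int:
    if isinstance(feature, (int, np.integer)):
        return int(feature)
    if fit.feature_names is None:
        raise ValueError("fit has no feature names; pass an index")
    return fit.feature_names.index(feature)


def importance_auroc_gain(
    fit: GlobalFit, X, y, feature, R: int = 20, seed: int = 0
) -> float:
    """Permutation importance on AUROC: base AUROC minus the mean AUROC
    after permuting the feature's column (R permutations, seeded)."""
    j = _resolve_feature(fit, feature)
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    base = auroc(y, predict_risk(fit, Xm))
    rng = np.random.default_rng(seed)
    perm_auc = np.empty(R)
    Xp = Xm.copy()
    for r in range(R):
        Xp[:, j] = Xm[rng.permutation(Xm.shape[0]), j]
        perm_auc[r] = auroc(y, predict_risk(fit, Xp))
    return float(base - perm_auc.mean())


def importance_interclass_diff(fit: GlobalFit, X, y, feature) -> float:
    """|mean(case) - mean(control)| of the risk obtained by varying only
    the chosen feature, all other features held at their population mean
    (single-feature contribution passed through the logistic link)."""
    j = _resolve_feature(fit, feature)
    Xm = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    base = Xm.mean(axis=0)
    Z = np.tile(base, (Xm.shape[0], 1))
    Z[:, j] = Xm[:, j]
    s = predict_risk(fit, Z)
    return float(abs(s[y == 1].mean() - s[y == 0].mean()))


def importance_table(
    fit: GlobalFit, X, y, R: int = 20, seed: int = 0
) -> pd.DataFrame:
    """All three importance measures side by side, with per-measure ranks
    (1 = most important)."""
    names = fit.feature_names or [f"x{j}" for j in range(fit.d)]
    rows = []
    for j, name in enumerate(names):
        rows.append(
            (
                name,
                float(fit.coef[j]),
                importance_auroc_gain(fit, X, y, j, R=R, seed=seed),
                importance_interclass_diff(fit, X, y, j),
            )
        )
    df = pd.DataFrame(rows, columns=["feature", "coefficient", "auroc_gain", "interclass_diff"])
    df["rank_coefficient"] = df["coefficient"].abs().rank(ascending=False, method="first").astype(int)
    df["rank_auroc_gain"] = df["auroc_gain"].rank(ascending=False, method="first").astype(int)
    df["rank_interclass_diff"] = df["interclass_diff"].rank(ascending=False, method="first").astype(int)
    return df


def subgroup_heterogeneity(
    X_sub: pd.DataFrame, top_features: Sequence[str], top_k: int = 50
) -> float:
    """Mean absolute pairwise Pearson correlation among the top predictors
    within a subgroup; high values mean the subgroup's important predictors
    co-occur, i.e. its patients present homogeneously. Constant columns are
    dropped (logged)."""
    import logging

    feats = list(top_features)[:top_k]
    if len(X_sub) <= len(feats):
        raise ValueError("subgroup must contain more rows than top_k features")
    M = X_sub[feats].to_numpy(dtype=float)
    keep = M.std(axis=0) > 0
    dropped = [f for f, k in zip(feats, keep) if not k]
    if dropped:
        logging.getLogger(__name__).info("dropping constant columns: %s", dropped)
    M = M[:, keep]
    if M.shape[1] < 2:
        raise ValueError("fewer than 2 usable (non-constant) features")
    C = np.corrcoef(M, rowvar=False)
    iu = np.triu_indices_from(C, k=1)
    return float(np.abs(C[iu]).mean())


def relative_effect_global_in_subgroup(gain_sub: float, gain_pop: float) -> Optional[float]:
    """(gain in subgroup - gain in population) / gain in population, for a
    predictor under the global model; None when the population gain is 0
    (reported as a missing heatmap cell)."""
    if gain_pop == 0:
        return None
    return (gain_sub - gain_pop) / gain_pop


def relative_effect_pmtl_vs_global(
    gain_pmtl_sub: float, gain_glob_sub: float, gain_glob_pop: float
) -> Optional[float]:
    """(personalized-in-subgroup gain - global-in-subgroup gain) / global
    gain in the general population; None on a zero denominator."""
    if gain_glob_pop == 0:
        return None
    return (gain_pmtl_sub - gain_glob_sub) / gain_glob_pop


def relative_effect_heatmap(
    global_fit: GlobalFit,
    X: pd.DataFrame,
    y,
    subgroups: Sequence,
    top_features: Sequence[str],
    R: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Subgroup x predictor matrix of relative effects of the global
    model's top predictors when applied within each subgroup."""
    y = np.asarray(y, dtype=float)
    subgroups = np.asarray(subgroups)
    pop_gain = {
        f: importance_auroc_gain(global_fit, X, y, f, R=R, seed=seed) for f in top_features
    }
    rows = {}
    for g in np.unique(subgroups):
        mask = subgroups == g
        if np.unique(y[mask]).size < 2:
            continue
        rows[g] = {
            f: relative_effect_global_in_subgroup(
                importance_auroc_gain(global_fit, X[mask], y[mask], f, R=R, seed=seed),
                pop_gain[f],
            )
            for f in top_features
        }
    return pd.DataFrame(rows).T


def coefficient_variation_across_models(
    fits: Sequence[GlobalFit], feature
) -> float:
    """Coefficient of variation, percent: 100 * sample SD / |mean| of one
    feature's coefficient across personalized fits."""
    coefs = []
    for fit in fits:
        j = _resolve_feature(fit, feature)
        coefs.append(float(fit.coef[j]))
    if len(coefs) < 2:
        raise ValueError("need at least 2 fits")
    coefs = np.asarray(coefs)
    mean = coefs.mean()
    if mean == 0:
        raise ValueError("mean coefficient is zero; CV undefined")
    return float(100.0 * coefs.std(ddof=1) / abs(mean))
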