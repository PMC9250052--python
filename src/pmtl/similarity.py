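"""Patient similarity: weighted distances, exact k-NN retrieval, and the
performance-driven similarity-weight optimization loop.

The distance between two (preprocessed) patients is a weighted Euclidean
metric, sqrt(sum_j w_j (x1_j - x2_j)^2), with one nonnegative weight per
feature normalized to mean 1. Weights are tuned by a gradient-free
multiplicative coordinate search: each candidate weight vector is scored
by the AUROC that personalized models built under it achieve on a probe
set held out from the retrieval pool, and only score-improving updates
are accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import GlobalFit, TransferConfig, personalize, predict_risk, MIN_NEIGHBORS


@dataclass
class SimilarityWeights:
    """Per-feature retrieval weights (nonnegative, mean 1)."""

    w: np.ndarray
    feature_names: Optional[list[str]] = None
    trace: list = field(default_factory=list)  # (iteration, probe AUROC) accepted steps
    n_iter: int = 0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("similarity weights must be nonnegative")

    def to_json(self) -> str:
        names = self.feature_names or [f"x{j}" for j in range(self.w.size)]
        return json.dumps({n: float(v) for n, v in zip(names, self.w)}, indent=1)


def _normalize(w: np.ndarray) -> np.ndarray:
    w = np.clip(w, 0.0, None)
    m = w.mean()
    if m <= 0:
        raise ValueError("weights collapsed to zero")
    return w / m


def weighted_distance(x1, x2, w) -> float:
    """sqrt(sum_j w_j (x1_j - x2_j)^2); symmetric, zero iff the weighted
    coordinates coincide."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x1.shape == x2.shape == w.shape):
        raise ValueError("x1, x2 and w must have equal dimensions")
    if np.any(w < 0):
        raise ValueError("similarity weights must be nonnegative")
    d = x1 - x2
    return float(np.sqrt(np.sum(w * d * d)))


def find_similar_indices(
    target_x: np.ndarray, pool_X: np.ndarray, pool_ids: Sequence, w, k: int
) -> np.ndarray:
    """Positions of the k nearest pool rows, ascending distance; exact
    distance ties broken by ascending encounter id (stable under pool
    reordering)."""
    if k > len(pool_ids):
        raise ValueError(f"k={k} exceeds pool size {len(pool_ids)}")
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("similarity weights must be nonnegative")
    diff = pool_X - target_x[None, :]
    d2 = (diff * diff) @ w
    ids = np.asarray(pool_ids)
    order = np.lexsort((ids, d2))
    return order[:k]


def find_similar(target_x, pool_X, pool_ids: Sequence, w, k: int) -> list:
    """The k pool member ids most similar to the target, closest first."""
    pool_Xm = pool_X.to_numpy(dtype=float) if isinstance(pool_X, pd.DataFrame) else np.asarray(pool_X, dtype=float)
    idx = find_similar_indices(np.asarray(target_x, dtype=float).ravel(), pool_Xm, pool_ids, w, k)
    return [pool_ids[i] for i in idx]


def _probe_auroc(
    w: np.ndarray,
    probe_idx: np.ndarray,
    pool_X: np.ndarray,
    pool_y: np.ndarray,
    pool_ids: Sequence,
    probe_X: np.ndarray,
    probe_y: np.ndarray,
    k_fraction: float,
    global_fit: Optional[GlobalFit],
    cfg: TransferConfig,
    min_k: int,
) -> float:
    from .evaluation import auroc

    preds = np.empty(probe_idx.size)
    for j, i in enumerate(probe_idx):
        fit = personalize(
            probe_X[i],
            pool_X,
            pool_y,
            pool_ids,
            weights=w,
            k_fraction=k_fraction,
            global_fit=global_fit,
            cfg=cfg,
            min_k=min_k,
        )
        preds[j] = predict_risk(fit, probe_X[i])
    return auroc(probe_y[probe_idx], preds)


def _stratified_subset(y: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """A class-balanced-ish random subset that always contains both classes."""
    idx = np.arange(y.size)
    if size >= y.size:
        return idx
    cases, controls = idx[y == 1], idx[y == 0]
    n_cases = max(1, int(round(size * cases.size / y.size)))
    n_cases = min(n_cases, cases.size, size - 1)
    chosen = np.concatenate(
        [
            rng.choice(cases, size=n_cases, replace=False),
            rng.choice(controls, size=size - n_cases, replace=False),
        ]
    )
    return np.sort(chosen)


def optimize_weights(
    pool_X,
    pool_y,
    pool_ids: Sequence,
    probe_X,
    probe_y,
    k_fraction: float = 0.10,
    global_fit: Optional[GlobalFit] = None,
    cfg: Optional[TransferConfig] = None,
    step: float = 0.5,
    gain: float = 1.0,
    max_iter: int = 5,
    tol: float = 1e-4,
    probes_per_iter: int = 100,
    seed: int = 0,
    min_k: int = MIN_NEIGHBORS,
) -> SimilarityWeights:
    """Tune retrieval weights by the probe-set AUROC of personalized models.

    Starting from uniform weights, each iteration perturbs every coordinate
    multiplicatively (factor 1+step), measures the change in mean probe
    AUROC on a random probe subsample, proposes a multiplicative update
    proportional to those changes, renormalizes to mean 1, and accepts the
    proposal only if it improves the AUROC on the full probe set by more
    than ``tol``; a rejected proposal leaves the weights unchanged and the
    next iteration draws a fresh probe subsample. Returns the best-scoring
    weights with the trace of accepted steps.
    """
    cfg = cfg or TransferConfig()
    pool_Xm = pool_X.to_numpy(dtype=float) if isinstance(pool_X, pd.DataFrame) else np.asarray(pool_X, dtype=float)
    probe_Xm = probe_X.to_numpy(dtype=float) if isinstance(probe_X, pd.DataFrame) else np.asarray(probe_X, dtype=float)
    pool_y = np.asarray(pool_y, dtype=float)
    probe_y = np.asarray(probe_y, dtype=float)
    if np.unique(probe_y).size < 2:
        raise ValueError("probe set contains a single outcome class")
    names = list(pool_X.columns) if isinstance(pool_X, pd.DataFrame) else None
    rng = np.random.default_rng(seed)
    d = pool_Xm.shape[1]
    all_probes = np.arange(probe_y.size)

    def score(w, idx):
        return _probe_auroc(
            w, idx, pool_Xm, pool_y, list(pool_ids), probe_Xm, probe_y,
            k_fraction, global_fit, cfg, min_k,
        )

    w = np.ones(d)
    if max_iter == 0:
        return SimilarityWeights(w, feature_names=names, trace=[], n_iter=0)

    best = score(w, all_probes)
    trace = [(0, best)]
    it = 0
    for it in range(1, max_iter + 1):
        sub = _stratified_subset(probe_y, probes_per_iter, rng)
        base = score(w, sub)
        deltas = np.empty(d)
        for j in range(d):
            wj = w.copy()
            wj[j] *= 1.0 + step
            deltas[j] = score(_normalize(wj), sub) - base
        scale = np.max(np.abs(deltas))
        if scale == 0:
            continue
        proposal = _normalize(w * np.exp(gain * deltas / scale))
        cand = score(proposal, all_probes)
        if cand > best + tol:
            w, best = proposal, cand
            trace.append((it, best))
    return SimilarityWeights(w, feature_names=names, trace=trace, n_iter=it)
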