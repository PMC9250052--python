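"""Synthetic heterogeneous EHR cohorts.

Emulates the statistical structure that personalized modeling exploits: a
population composed of latent subgroups (think admission-diagnosis strata)
whose logistic risk coefficients share a global component plus
subgroup-specific deviations, with mixed binary/continuous covariates,
optional completely-at-random missingness, realistic demographics, ~9.4%
event prevalence, and serum-creatinine trajectories constructed to cross —
or provably never cross — the KDIGO stage-1 criteria at the intended onset
times, so the labeling pipeline can be verified by round trip.

Subgroup membership is reflected in the covariates through mean shifts on
a small set of informative continuous features; this is what gives the
patient-distance metric something to retrieve on, mirroring how admission
diagnoses co-vary with the rest of a real chart.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import cohort as _cohort

# Demographics matched to a large US tertiary-care inpatient population
AGE_MEAN, AGE_SD, AGE_MIN, AGE_MAX = 55.5, 17.4, 18.0, 85.0
P_MALE = 0.548
RACES = ("White", "African American", "Asian", "Other")
P_RACE = (0.70, 0.15, 0.05, 0.10)


@dataclass
class SyntheticConfig:
    """Knobs of the cohort generator; defaults are the study conditions."""

    n: int = 20000
    d: int = 50
    n_subgroups: int = 5
    mix: Optional[np.ndarray] = None          # subgroup proportions, sum 1
    beta_global: Optional[np.ndarray] = None  # shared log-odds component
    tau: float = 0.5            # SD of subgroup coefficient deviations
    sparsity: float = 0.5       # fraction of features carrying deviations
    target_prevalence: float = 0.094
    frac_binary: float = 0.5
    missing_rate: float = 0.0
    n_informative: int = 10     # continuous features carrying subgroup mean shifts
    separation: float = 1.0     # SD of subgroup centers on informative features
    beta_scale: float = 0.35    # SD of nonzero global coefficients
    beta_density: float = 0.3   # fraction of features with nonzero global effect
    seed: int = 0

    def __post_init__(self):
        if self.mix is not None:
            self.mix = np.asarray(self.mix, dtype=float)
            if abs(self.mix.sum() - 1.0) > 1e-8:
                raise ValueError("subgroup proportions must sum to 1")
        if not 0.0 <= self.target_prevalence <= 1.0:
            raise ValueError("target prevalence must lie in [0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated cohort."""

    beta_global: np.ndarray
    delta: np.ndarray        # (G, d) subgroup deviations, zero off-support
    beta_g: np.ndarray       # (G, d) = beta_global + delta
    intercepts: np.ndarray   # (G,) shared prevalence-calibrated intercept
    subgroup: np.ndarray     # (n,) assignment per encounter
    support: np.ndarray      # feature indices carrying deviations
    informative: np.ndarray  # continuous features carrying subgroup mean shifts
    centers: np.ndarray      # (G, n_informative) subgroup means
    feature_names: list
    binary_idx: np.ndarray

    def to_json_dict(self) -> dict:
        return {
            "beta_global": self.beta_global.tolist(),
            "beta_g": self.beta_g.tolist(),
            "intercepts": self.intercepts.tolist(),
            "subgroup": self.subgroup.tolist(),
            "support": self.support.tolist(),
            "informative": self.informative.tolist(),
            "feature_names": list(self.feature_names),
        }


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("f")and c[1:].isdigit()]


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a cohort and its generating truth, deterministic under seed.

    A shared intercept is solved numerically so that the mean event
    probability over the realized design equals the target prevalence.
    """
    cfg = config
    if cfg.target_prevalence > 0.999 or cfg.target_prevalence < 0.001:
        raise ValueError("infeasible target prevalence")
    rng = np.random.default_rng(cfg.seed)
    G, n, d = cfg.n_subgroups, cfg.n, cfg.d
    mix = cfg.mix if cfg.mix is not None else np.full(G, 1.0 / G)

    n_bin = int(round(cfg.frac_binary * d))
    n_cont = d - n_bin
    cont_idx = np.arange(n_cont)
    binary_idx = np.arange(n_cont, d)
    n_inf = min(cfg.n_informative, n_cont)
    informative = rng.choice(cont_idx, size=n_inf, replace=False)
    informative.sort()

    subgroup = rng.choice(G, size=n, p=mix)
    X = np.empty((n, d))
    X[:, cont_idx] = rng.standard_normal((n, n_cont))
    centers = rng.normal(0.0, cfg.separation, size=(G, n_inf))
    X[:, informative] += centers[subgroup]
    p_bin = rng.uniform(0.1, 0.5, size=n_bin)
    X[:, binary_idx] = (rng.random((n, n_bin)) < p_bin).astype(float)

    if cfg.beta_global is None:
        beta_global = np.zeros(d)
        nz = rng.choice(d, size=max(1, int(round(cfg.beta_density * d))), replace=False)
        beta_global[nz] = rng.normal(0.0, cfg.beta_scale, size=nz.size)
    else:
        beta_global = np.asarray(cfg.beta_global, dtype=float)
        if beta_global.size != d:
            raise ValueError("beta_global must have length d")

    support = rng.choice(d, size=int(round(cfg.sparsity * d)), replace=False)
    support.sort()
    delta = np.zeros((G, d))
    if cfg.tau > 0 and support.size:
        delta[:, support] = rng.normal(0.0, cfg.tau, size=(G, support.size))
    beta_g = beta_global[None, :] + delta

    lp = np.einsum("ij,ij->i", X, beta_g[subgroup])

    def excess(alpha):
        return expit(alpha + lp).mean() - cfg.target_prevalence

    alpha = brentq(excess, -30.0, 30.0)
    y = (rng.random(n) < expit(alpha + lp)).astype(int)

    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, size=n), AGE_MIN, AGE_MAX)
    sex = np.where(rng.random(n) < P_MALE, "male", "female")
    race = rng.choice(RACES, size=n, p=P_RACE)

    names = [f"f{j:02d}" for j in range(d)]
    df = pd.DataFrame(X, columns=names)
    df.insert(0, "encounter_id", [f"E{i:06d}" for i in range(n)])
    df.insert(1, "age", np.round(age, 1))
    df.insert(2, "sex", sex)
    df.insert(3, "race", race)
    df.insert(4, "subgroup_id", [f"G{g}" for g in subgroup])
    df.insert(5, "y", y)

    truth = SyntheticTruth(
        beta_global=beta_global,
        delta=delta,
        beta_g=beta_g,
        intercepts=np.full(G, alpha),
        subgroup=subgroup,
        support=support,
        informative=informative,
        centers=centers,
        feature_names=names,
        binary_idx=binary_idx,
    )
    return df, truth


def generate_scr_trajectories(
    cohort: pd.DataFrame, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Creatinine tables consistent with the cohort's outcome labels.

    AKI encounters (y=1) receive a flat trajectory that first crosses the
    KDIGO stage-1 criteria exactly at a sampled onset in [48, 120] h;
    non-AKI encounters receive trajectories whose within-48 h rises stay
    below 0.3 mg/dL and whose values stay below 1.5x baseline, so the
    labeler provably recovers the intended labels and onsets.

    Returns (scr table, intended-truth table).
    """
    rng = np.random.default_rng(seed)
    rows, intended = [], []
    for eid, y in zip(cohort["encounter_id"], cohort["y"]):
        b = rng.uniform(0.5, 0.8)
        if y == 1:
            onset = float(np.round(rng.uniform(48.0, 120.0), 1))
            pts = [(0.0, b), (onset - 24.0, b), (onset, b + 0.35), (onset + 24.0, b + 0.40)]
            intended.append((eid, "AKI", onset, b))
        else:
            t_last = float(np.round(rng.uniform(72.0, 168.0), 1))
            times = np.linspace(0.0, t_last, max(3, int(t_last // 24) + 1))
            vals = b * (1.0 + rng.uniform(0.0, 0.15, size=times.size))
            vals[0] = b
            pts = list(zip(times, vals))
            intended.append((eid, "no-AKI", np.nan, b))
        for t, v in pts:
            rows.append((eid, round(float(t), 2), round(float(v), 4)))
    scr = pd.DataFrame(rows, columns=["encounter_id", "t_hours", "scr_mgdl"])
    truth = pd.DataFrame(intended, columns=["encounter_id", "label", "onset_t", "baseline_scr"])
    return scr, truth


def inject_missingness(
    features: pd.DataFrame, missing_rate: float, seed: int = 0,
    columns: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Mask feature cells missing completely at random at the given rate.

    Only feature columns are eligible; identifiers, demographics and
    outcome labels are never masked. Deterministic under seed.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must lie in [0, 1)")
    out = features.copy()
    if missing_rate == 0.0:
        return out
    cols = columns if columns is not None else feature_columns(out)
    rng = np.random.default_rng(seed)
    mask = rng.random((len(out), len(cols))) < missing_rate
    block = out[cols].to_numpy(dtype=float)
    block[mask] = np.nan
    out[cols] = block
    return out


def encounters_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """The encounters.csv view of a generated cohort (admission at t=0)."""
    return pd.DataFrame(
        {
            "encounter_id": cohort["encounter_id"],
            "age": cohort["age"],
            "sex": cohort["sex"],
            "race": cohort["race"],
            "admission_ts": "2015-01-01T00:00:00",
        }
    )


def simulate_study(config: SyntheticConfig) -> dict:
    """One-call generation of every artifact the pipeline consumes."""
    cohort, truth = generate_cohort(config)
    scr, intended = generate_scr_trajectories(cohort, seed=config.seed + 1)
    features = cohort.drop(columns=["y", "subgroup_id"])
    if config.missing_rate > 0:
        features = inject_missingness(features, config.missing_rate, seed=config.seed + 2)
    return {
        "cohort": cohort,
        "truth": truth,
        "scr": scr,
        "intended_labels": intended,
        "encounters": encounters_table(cohort),
        "features": features,
    }
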