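"""Feature standardization and missing-data handling.

All statistics (medians, means, SDs, missingness schema) are learned on
training data only and applied unchanged to held-out data, so evaluation
folds never leak into fitted models.

Continuous features are median-imputed and z-scored; binary features are
median-imputed and kept on the 0/1 scale. Every feature that had any
missing value during fitting additionally contributes a 0/1
missing-indicator column, which downstream models and the patient-distance
metric treat as an ordinary binary feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MISSING_SUFFIX = "__missing"


def _is_binary(col: pd.Series) -> bool:
    vals = col.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


class Preprocessor:
    """Train-fold feature transformer (impute + indicator + scale)."""

    def __init__(self):
        self.columns_: list[str] | None = None

    def fit(self, X: pd.DataFrame) -> "Preprocessor":
        X = X.astype(float)
        self.columns_ = list(X.columns)
        self.binary_ = {c: _is_binary(X[c]) for c in X.columns}
        self.median_ = X.median(skipna=True).fillna(0.0)
        self.indicator_cols_ = [c for c in X.columns if X[c].isna().any()]
        self.mean_ = {}
        self.sd_ = {}
        for c in X.columns:
            if self.binary_[c]:
                continue
            col = X[c].fillna(self.median_[c])
            sd = float(col.std(ddof=0))
            self.mean_[c] = float(col.mean())
            self.sd_[c] = sd if sd > 0 else 1.0  # constant-column guard
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.columns_ is None:
            raise RuntimeError("Preprocessor must be fit before transform")
        X = X.reindex(columns=self.columns_).astype(float)
        out = {}
        for c in self.columns_:
            col = X[c]
            filled = col.fillna(self.median_[c])
            if not self.binary_[c]:
                filled = (filled - self.mean_[c]) / self.sd_[c]
            out[c] = filled
        for c in self.indicator_cols_:
            out[c + MISSING_SUFFIX] = X[c].isna().astype(float)
        return pd.DataFrame(out, index=X.index)

    def fit_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return self.fit(X).transform(X)

    @property
    def feature_names_out(self) -> list[str]:
        return self.columns_ + [c + MISSING_SUFFIX for c in self.indicator_cols_]
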