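"""Shared design-matrix construction for the regression modules.

Conventions: sex enters as a 0/1 code, smoking as unordered categories expanded
to indicator columns (reference level dropped), everything else as-is. An
intercept column named ``const`` is always prepended.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

CATEGORICAL_TERMS = {"smoking"}


def build_design(df: pd.DataFrame, terms: Sequence[str]) -> pd.DataFrame:
    """Build a numeric design matrix (with intercept) from named columns."""
    cols = [pd.Series(1.0, index=df.index, name="const")]
    for term in terms:
        if term not in df.columns:
            raise KeyError(f"design column {term!r} not found in table")
        s = df[term]
        if term in CATEGORICAL_TERMS:
            dummies = pd.get_dummies(s.astype("category"), prefix=term, drop_first=True)
            cols.extend(dummies[c].astype(float) for c in dummies.columns)
        else:
            cols.append(s.astype(float))
    X = pd.concat(cols, axis=1)
    return X


def check_full_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise np.linalg.LinAlgError(
            f"singular design matrix (rank-deficient over columns {list(X.columns)})"
        )


def residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of ``y`` (vector or matrix of columns) on covariate block ``C``."""
    Q, _ = np.linalg.qr(C)
    return y - Q @ (Q.T @ y)
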