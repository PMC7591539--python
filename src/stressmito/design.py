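"""Minimal design-matrix builder for formulas like ``~ group + age``.

Supports an intercept plus additive main effects.  String/categorical
metadata columns are treatment-coded against their first level (sorted,
except ``group`` and ``susceptibility`` which use CTR as reference when
present); numeric columns enter as-is.  No interactions or
transformations — design specs in this package are additive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["build_design", "parse_formula"]

_REFERENCE_FIRST = {"CTR"}


def parse_formula(formula: str) -> list[str]:
    """Return the term names of an additive formula ``~ a + b + c``."""
    f = formula.strip()
    if not f.startswith("~"):
        raise ValueError(f"formula must start with '~': {formula!r}")
    body = f[1:].strip()
    if body in ("", "1"):
        return []
    terms = [t.strip() for t in body.split("+")]
    terms = [t for t in terms if t not in ("", "1")]
    if any(not t.replace("_", "").isalnum() for t in terms):
        raise ValueError(f"unsupported term in formula: {formula!r}")
    return terms


def build_design(metadata: pd.DataFrame, formula: str) -> pd.DataFrame:
    """Build the design matrix (rows = samples in metadata order)."""
    terms = parse_formula(formula)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(metadata))}
    for term in terms:
        if term not in metadata.columns:
            raise ValueError(f"design term {term!r} not in metadata columns")
        col = metadata[term]
        if pd.api.types.is_numeric_dtype(col):
            cols[term] = col.to_numpy(dtype=float)
        else:
            levels = sorted(col.astype(str).unique())
            ref = next((l for l in levels if l in _REFERENCE_FIRST), levels[0])
            for level in levels:
                if level == ref:
                    continue
                cols[f"{term}[{level}]"] = (col.astype(str) == level).to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=metadata.index)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(f"design from {formula!r} is rank deficient")
    return X
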