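"""Design-matrix construction and rank-aware multi-response OLS.

All probe-sweep models share one design matrix per cohort, so every fit is
a multi-right-hand-side least-squares problem.  Linearly dependent columns
are swept out in entry order (the convention of classical GLM software for
singular designs, e.g. when Hb genotype and clinical status are partially
aliased in an HbSS-only cohort), so downstream drop-term F tests carry the
df the data actually support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

FACTOR_TERMS = ("hb_genotype", "clin_status", "sex", "phase", "family_id")


@dataclass
class Design:
    """A full-column-rank design matrix with term bookkeeping."""

    X: np.ndarray
    columns: List[str]
    term_cols: Dict[str, List[int]]           # term -> column indices in X
    dropped: Dict[str, List[str]] = field(default_factory=dict)
    factor_levels: Dict[str, List[str]] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def rank(self) -> int:
        return self.X.shape[1]

    def without_term(self, term: str) -> np.ndarray:
        keep = [j for j in range(self.X.shape[1]) if j not in set(self.term_cols[term])]
        return self.X[:, keep]


def _term_columns(meta: pd.DataFrame, term: str) -> Tuple[np.ndarray, List[str], List[str]]:
    """Columns for one model term (treatment coding, first level baseline)."""
    if term in FACTOR_TERMS or meta[term].dtype == object:
        vals = meta[term].astype(str).to_numpy()
        levels = sorted(pd.unique(vals))
        cols = [(vals == lv).astype(float) for lv in levels[1:]]
        names = [f"{term}[{lv}]" for lv in levels[1:]]
        mat = np.column_stack(cols) if cols else np.empty((len(meta), 0))
        return mat, names, levels
    x = meta[term].to_numpy(dtype=float)
    return x[:, None], [term], []


def build_design(meta: pd.DataFrame, terms: Sequence[str]) -> Design:
    """Intercept + terms, sweeping out columns aliased with earlier ones."""
    n = len(meta)
    X_cols: List[np.ndarray] = [np.ones(n)]
    names: List[str] = ["Intercept"]
    term_cols: Dict[str, List[int]] = {}
    dropped: Dict[str, List[str]] = {}
    factor_levels: Dict[str, List[str]] = {}
    basis = np.ones((n, 1)) / np.sqrt(n)  # orthonormal basis of kept columns
    for term in terms:
        mat, col_names, levels = _term_columns(meta, term)
        if levels:
            factor_levels[term] = levels
        term_cols[term] = []
        dropped[term] = []
        for k in range(mat.shape[1]):
            col = mat[:, k]
            resid = col - basis @ (basis.T @ col)
            nrm = np.linalg.norm(resid)
            if nrm < 1e-8 * max(1.0, np.linalg.norm(col)):
                dropped[term].append(col_names[k])
                continue
            basis = np.column_stack([basis, resid / nrm])
            term_cols[term].append(len(X_cols))
            X_cols.append(col)
            names.append(col_names[k])
    return Design(
        X=np.column_stack(X_cols),
        columns=names,
        term_cols=term_cols,
        dropped=dropped,
        factor_levels=factor_levels,
    )


def ols_multi(X: np.ndarray, Y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """OLS of many responses on one design.

    Y is responses-as-columns (n x P).  Returns (coef (k x P), rss (P,)).
    X must be full column rank (as produced by build_design).
    """
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return coef, np.einsum("ij,ij->j", resid, resid)


def drop_term_f(
    X_full: np.ndarray,
    X_reduced: np.ndarray,
    Y: np.ndarray,
    rank_full: Optional[int] = None,
) -> Tuple[np.ndarray, int, int, np.ndarray]:
    """Marginal F test of the columns X_full has beyond X_reduced.

    Returns (F, df1, df2, p) with F broadcast over response columns.
    A zero-variance response takes the F = 0, p = 1 convention.
    """
    n = X_full.shape[0]
    rf = rank_full if rank_full is not None else X_full.shape[1]
    rr = X_reduced.shape[1]
    df1, df2 = rf - rr, n - rf
    _, rss_full = ols_multi(X_full, Y)
    _, rss_red = ols_multi(X_reduced, Y)
    if df1 <= 0 or df2 <= 0:
        p = Y.shape[1] if Y.ndim > 1 else 1
        return np.full(p, np.nan), df1, df2, np.full(p, np.nan)
    num = np.maximum(rss_red - rss_full, 0.0) / df1
    den = rss_full / df2
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / den
    scale = np.einsum("ij,ij->j", Y, Y) / n + 1.0
    degenerate = den <= 1e-14 * scale
    F = np.where(degenerate & (num <= 1e-14 * scale), 0.0, F)
    F = np.where(degenerate & (num > 1e-14 * scale), np.inf, F)
    pvals = np.where(np.isinf(F), 0.0, stats.f.sf(np.where(np.isfinite(F), F, 0.0), df1, df2))
    pvals = np.where(F == 0.0, 1.0, pvals)
    return F, df1, df2, pvals


def t_test_coefficient(
    X: np.ndarray, Y: np.ndarray, col: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int]:
    """t test of one coefficient across many responses.

    Returns (beta, se, t, p, df).  X full column rank.
    """
    n, k = X.shape
    coef, rss = ols_multi(X, Y)
    df = n - k
    xtx_inv = np.linalg.inv(X.T @ X)
    sigma2 = rss / df
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sigma2 * xtx_inv[col, col])
        t = coef[col] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isnan(t), 1.0, np.where(np.isinf(t), 0.0, p))
    return coef[col], se, t, p, df
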