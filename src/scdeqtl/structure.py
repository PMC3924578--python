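"""Cohort structure: PCA, variance components of expression PCs,
hierarchical clustering, and Weir–Cockerham Fst.

The expression PCA feeds a variance-component analysis (VCA): each leading
expression PC is modeled by REML with every design factor (Hb genotype,
clinical status, sex, and optionally their pairwise combinations) as a
random effect, and the estimated components are reported as proportions of
the PC's variance.  Genotype PCA uses the Eigenstrat normalization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import GenotypeMatrix

logger = logging.getLogger("scdeqtl")


@dataclass
class PcaResult:
    scores: np.ndarray            # samples x components
    loadings: np.ndarray          # features x components
    variance_explained: np.ndarray  # fraction per component

    def scores_frame(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=list(sample_ids),
            columns=[f"PC{i + 1}" for i in range(self.scores.shape[1])],
        )


def pca(
    matrix: np.ndarray,
    n_components: int = 3,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA of a samples x features matrix via SVD.

    Deterministic sign convention: each component's largest-magnitude
    loading is positive.  Components are capped at the matrix rank.
    """
    X = np.asarray(matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    if not np.all(np.isfinite(X)):
        raise ValueError("PCA input must be finite")
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1, keepdims=True)
        X = X / np.where(sd > 0, sd, 1.0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    k = min(n_components, rank) if rank else 0
    total_var = (s**2).sum()
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T
    for j in range(k):
        i_max = np.argmax(np.abs(loadings[:, j]))
        if loadings[i_max, j] < 0:
            loadings[:, j] = -loadings[:, j]
            scores[:, j] = -scores[:, j]
    ve = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    return PcaResult(scores=scores, loadings=loadings, variance_explained=ve)


def genotype_pca(g: GenotypeMatrix, n_components: int = 10) -> PcaResult:
    """Genotype PCA with Eigenstrat normalization.

    Dosages are centered by 2*p_hat and scaled by sqrt(p_hat*(1-p_hat));
    missing dosages are mean-imputed for the PCA only.
    """
    d = g.dosage.copy()
    p_hat = np.nanmean(d, axis=0) / 2.0
    nan_r, nan_c = np.where(np.isnan(d))
    d[nan_r, nan_c] = 2.0 * p_hat[nan_c]
    denom = np.sqrt(p_hat * (1.0 - p_hat))
    keep = denom > 0
    Z = (d[:, keep] - 2.0 * p_hat[keep]) / denom[keep]
    return pca(Z, n_components=n_components, center=True, scale=False)


# ---------------------------------------------------------------------------
# variance components


def _combine_factors(meta: pd.DataFrame, factors: Sequence[str]) -> pd.DataFrame:
    """Factor columns incl. 'a:b' pairwise combination labels."""
    out = pd.DataFrame(index=meta.index)
    for f in factors:
        if ":" in f:
            a, b = f.split(":", 1)
            out[f] = meta[a].astype(str) + "/" + meta[b].astype(str)
        else:
            out[f] = meta[f].astype(str)
    return out


def variance_components(
    epc_scores: pd.DataFrame,
    meta: pd.DataFrame,
    factors: Sequence[str] = ("hb_genotype", "clin_status", "sex"),
    weights: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """REML variance-component analysis of leading expression PCs.

    Every factor enters as a random effect (variance components model), so
    estimated proportions are non-negative and comparable across PCs.
    Returns per-factor (plus residual) proportions per PC and a pooled
    column: the variance-explained-weighted mean over PCs (``weights``).
    Aliased factor pairs (one factor's levels nested in another's) are
    reported but marked non-identifiable via a NaN.
    """
    import statsmodels.api as sm

    if len(epc_scores) != len(meta):
        raise ValueError("scores and factors must align sample-wise")
    fac = _combine_factors(meta, factors)
    aliased = [
        f for f in factors
        if fac[f].nunique() <= 1
    ]
    usable = [f for f in factors if f not in aliased]
    for f in aliased:
        logger.warning("variance_components: factor %s has a single level; skipped", f)

    rows: Dict[str, List[float]] = {f: [] for f in list(factors) + ["residual"]}
    data = fac.copy()
    data["_group"] = 1
    vc_formula = {f: f"0 + C({f})" for f in usable}
    for pc in epc_scores.columns:
        y = epc_scores[pc].to_numpy(dtype=float)
        sd = y.std()
        data["_y"] = (y - y.mean()) / (sd if sd > 0 else 1.0)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.MixedLM.from_formula(
                    "_y ~ 1", groups="_group", vc_formula=vc_formula, data=data
                )
                # Powell is markedly more reliable than gradient methods on
                # these small crossed variance-component problems
                res = model.fit(reml=True, method="powell", maxiter=1000)
            vc_names = list(model.exog_vc.names)
            comps = {
                f: max(float(res.vcomp[vc_names.index(f)]), 0.0) for f in usable
            }
            resid = float(res.scale)
        except Exception as exc:  # non-convergence on degenerate input
            logger.warning("variance_components: REML failed for %s (%s)", pc, exc)
            comps = {f: np.nan for f in usable}
            resid = np.nan
        total = sum(comps.values()) + resid
        for f in factors:
            if f in aliased:
                rows[f].append(np.nan)
            else:
                rows[f].append(comps[f] / total if total and np.isfinite(total) else np.nan)
        rows["residual"].append(resid / total if total and np.isfinite(total) else np.nan)

    table = pd.DataFrame(rows, index=epc_scores.columns).T
    if weights is None:
        weights = np.ones(len(epc_scores.columns))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    table["pooled"] = table[epc_scores.columns].to_numpy() @ w
    return table


# ---------------------------------------------------------------------------
# clustering


def hierarchical_cluster(
    correlation: np.ndarray, linkage: str = "average"
) -> np.ndarray:
    """Leaf order of hierarchical clustering at distance 1 - correlation.

    Exact distance ties break toward the lower original indices: an
    index-ordered jitter, far below meaningful correlation differences,
    makes the merge order deterministic.
    """
    C = np.asarray(correlation, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    n = C.shape[0]
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = np.maximum((D + D.T) / 2.0, 0.0)
    i_idx, j_idx = np.triu_indices(n, k=1)
    condensed = D[i_idx, j_idx]
    eps = 1e-10 * max(1.0, condensed.max() if condensed.size else 1.0) / max(n * n, 1)
    condensed = condensed + eps * (i_idx * n + j_idx)
    Z = hierarchy.linkage(condensed, method=linkage)
    # traverse with the child containing the smallest original index first,
    # so identical inputs keep their input order
    order: List[int] = []
    min_leaf: Dict[int, int] = {}
    children: Dict[int, Tuple[int, int]] = {}
    for m, (a, b, _, _) in enumerate(Z):
        node = n + m
        children[node] = (int(a), int(b))
    def _min_leaf(node: int) -> int:
        if node < n:
            return node
        if node not in min_leaf:
            a, b = children[node]
            min_leaf[node] = min(_min_leaf(a), _min_leaf(b))
        return min_leaf[node]
    stack = [n + len(Z) - 1] if len(Z) else list(range(n))
    while stack:
        node = stack.pop()
        if node < n:
            order.append(node)
            continue
        a, b = children[node]
        first, second = (a, b) if _min_leaf(a) <= _min_leaf(b) else (b, a)
        stack.append(second)
        stack.append(first)
    return np.asarray(order, dtype=int)


# ---------------------------------------------------------------------------
# Fst


def fst_weir_cockerham(
    g: GenotypeMatrix,
    groups: Sequence,
    snp_subset: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Weir–Cockerham theta per SNP plus the ratio-of-sums set estimate.

    Returns a per-SNP table with the a/b/c variance components and theta;
    the attribute ``.attrs['fst_overall']`` carries sum(a)/sum(a+b+c) over
    SNPs with defined components (monomorphic SNPs are excluded).  Raw
    theta is retained; a clipped-to-[0,1] column is provided for reporting.
    """
    labels = np.asarray(groups)
    if len(labels) != g.n_samples:
        raise ValueError("groups must align with samples")
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if snp_subset is not None:
        idx = [g.snps.index.get_loc(s) for s in snp_subset]
        sub = g.take_snps(np.asarray(idx))
    else:
        sub = g
    for grp in uniq:
        if (labels == grp).sum() < 2:
            raise ValueError(f"group {grp!r} has fewer than 2 samples")

    r = len(uniq)
    n_i = np.zeros((r, sub.n_snps))
    p_i = np.zeros((r, sub.n_snps))
    h_i = np.zeros((r, sub.n_snps))
    for gi, grp in enumerate(uniq):
        d = sub.dosage[labels == grp]
        called = ~np.isnan(d)
        n_i[gi] = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p_i[gi] = np.nansum(d, axis=0) / (2.0 * n_i[gi])
            h_i[gi] = np.nansum(d == 1, axis=0) / n_i[gi]

    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
        theta = a / (a + b + c)

    monomorphic = (pbar <= 0) | (pbar >= 1)
    theta = np.where(monomorphic, np.nan, theta)
    table = pd.DataFrame(
        {"a": a, "b": b, "c": c, "theta": theta,
         "theta_clipped": np.clip(theta, 0.0, 1.0)},
        index=sub.snps.index,
    )
    ok = ~monomorphic & np.isfinite(a + b + c)
    denom = (a + b + c)[ok].sum()
    table.attrs["fst_overall"] = float(a[ok].sum() / denom) if denom > 0 else float("nan")
    table.attrs["groups"] = list(map(str, uniq))
    return table
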