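"""Probe-by-probe ANCOVA differential expression.

Fits, for every probe, the linear model

    Expression = mu + Hb genotype + ClinStatus + Sex + WBC + RBC + eps

by ordinary least squares (eps ~ N(0, sigma^2)), reports per-term marginal
(drop-term, "Type III") F tests — or sequential Type I tests on request —
controls the false discovery rate per term by Benjamini–Hochberg, and
evaluates the pairwise clinical-status contrasts E−FU, E−Ctls, FU−Ctls.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import Design, build_design, drop_term_f, ols_multi
from .containers import ExpressionMatrix

logger = logging.getLogger("scdeqtl")

DEFAULT_TERMS = ("hb_genotype", "clin_status", "sex", "wbc", "rbc")


def bh_fdr(pvalues: Sequence[float], q: float = 0.01) -> Tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: returns (q-values, reject flags at q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return qvals, qvals <= q


class AncovaScan:
    """Differential-expression model over all probes of a cohort.

    Parameters
    ----------
    expression : ExpressionMatrix (probes x samples, normalized log2 scale)
    metadata : sample table aligned to ``expression.sample_ids``
    terms : model terms in entry order; factors get treatment coding and
        continuous covariates enter untransformed.  Samples with a missing
        covariate are dropped globally so all probes share one design.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        metadata: pd.DataFrame,
        terms: Sequence[str] = DEFAULT_TERMS,
    ) -> None:
        if list(metadata["sample_id"]) != list(expression.sample_ids):
            raise ValueError("metadata must be aligned to expression sample order")
        self.terms = list(terms)
        complete = ~metadata[self.terms].isna().any(axis=1).to_numpy()
        if not complete.all():
            logger.info(
                "AncovaScan: dropped %d samples with incomplete covariates",
                int((~complete).sum()),
            )
        self.meta = metadata.loc[complete].reset_index(drop=True)
        self.expression = expression.take_samples(np.flatnonzero(complete))
        self.design: Design = build_design(self.meta, self.terms)

    def fit(self, fdr_q: float = 0.01, ss_type: str = "III") -> "AncovaResults":
        Y = self.expression.values.T  # samples x probes
        X = self.design.X
        probe_ids = self.expression.probe_ids
        rows = []
        if ss_type == "III":
            for term in self.terms:
                cols = self.design.term_cols[term]
                if not cols:
                    rows.append((term, np.full(Y.shape[1], np.nan), 0, 0,
                                 np.full(Y.shape[1], np.nan), False))
                    continue
                F, df1, df2, p = drop_term_f(X, self.design.without_term(term), Y)
                rows.append((term, F, df1, df2, p, True))
        elif ss_type == "I":
            included: List[int] = [0]
            for term in self.terms:
                cols = self.design.term_cols[term]
                if not cols:
                    rows.append((term, np.full(Y.shape[1], np.nan), 0, 0,
                                 np.full(Y.shape[1], np.nan), False))
                    continue
                X_red = X[:, included]
                X_seq = X[:, included + cols]
                F, df1, df2, p = drop_term_f(X_seq, X_red, Y)
                # denominator refit against the full model's residual
                _, rss_full = ols_multi(X, Y)
                _, rss_red = ols_multi(X_red, Y)
                _, rss_seq = ols_multi(X_seq, Y)
                df2 = X.shape[0] - X.shape[1]
                with np.errstate(divide="ignore", invalid="ignore"):
                    F = ((rss_red - rss_seq) / df1) / (rss_full / df2)
                p = stats.f.sf(F, df1, df2)
                rows.append((term, F, df1, df2, p, True))
                included = included + cols
        else:
            raise ValueError("ss_type must be 'III' or 'I'")

        frames = []
        for term, F, df1, df2, p, estimable in rows:
            qvals, flags = (
                bh_fdr(np.nan_to_num(p, nan=1.0), fdr_q)
                if estimable
                else (np.full(len(probe_ids), np.nan), np.zeros(len(probe_ids), bool))
            )
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probe_ids,
                        "term": term,
                        "F": F,
                        "df1": df1,
                        "df2": df2,
                        "p": p,
                        "q": qvals,
                        "significant": flags,
                        "estimable": estimable,
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)
        return AncovaResults(self, table, fdr_q)


@dataclass
class AncovaResults:
    """Per-probe per-term F tests with per-term FDR control."""

    model: AncovaScan
    terms_table: pd.DataFrame
    fdr_q: float

    def term(self, term: str) -> pd.DataFrame:
        return (
            self.terms_table[self.terms_table["term"] == term]
            .set_index("probe_id")
            .copy()
        )

    def significant_probes(self, term: str) -> List[str]:
        t = self.term(term)
        return list(t.index[t["significant"]])

    def pairwise_contrasts(
        self, term: str = "clin_status", fdr_q: Optional[float] = None
    ) -> pd.DataFrame:
        """t tests of all pairwise level contrasts of a factor term.

        Contrast estimates come from the swept (full-rank) design; a level
        whose dummy was aliased away yields a skipped contrast with warning.
        """
        fdr_q = fdr_q if fdr_q is not None else self.fdr_q
        design = self.model.design
        levels = design.factor_levels.get(term)
        if levels is None:
            raise ValueError(f"{term} is not a factor term")
        X = design.X
        Y = self.model.expression.values.T
        coef, rss = ols_multi(X, Y)
        df = X.shape[0] - X.shape[1]
        xtx_inv = np.linalg.inv(X.T @ X)
        sigma2 = rss / df

        # map each level to its coefficient vector (baseline = 0)
        level_vec: Dict[str, Optional[np.ndarray]] = {levels[0]: np.zeros(X.shape[1])}
        names = design.columns
        for lv in levels[1:]:
            name = f"{term}[{lv}]"
            if name in names:
                v = np.zeros(X.shape[1])
                v[names.index(name)] = 1.0
                level_vec[lv] = v
            else:
                level_vec[lv] = None  # aliased away

        out = []
        present = [lv for lv in levels if (self.model.meta[term] == lv).any()]
        for a, b in itertools.combinations(present, 2):
            va, vb = level_vec.get(a), level_vec.get(b)
            if va is None or vb is None:
                logger.warning(
                    "contrast %s-%s skipped: level aliased in the design", a, b
                )
                continue
            L = va - vb
            est = L @ coef
            se = np.sqrt(sigma2 * (L @ xtx_inv @ L))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = est / se
            p = 2.0 * stats.t.sf(np.abs(t), df)
            p = np.where(np.isfinite(t), p, 1.0)
            qv, flag = bh_fdr(p, fdr_q)
            out.append(
                pd.DataFrame(
                    {
                        "probe_id": self.model.expression.probe_ids,
                        "contrast": f"{a}-{b}",
                        "estimate": est,
                        "se": se,
                        "t": t,
                        "p": p,
                        "q": qv,
                        "significant": flag,
                    }
                )
            )
        if not out:
            return pd.DataFrame(
                columns=["probe_id", "contrast", "estimate", "se", "t", "p", "q",
                         "significant"]
            )
        return pd.concat(out, ignore_index=True)

    def summary(self) -> str:
        lines = [
            "ANCOVA differential expression",
            f"  probes: {self.model.expression.n_probes}"
            f"   samples: {self.model.design.n}"
            f"   FDR q: {self.fdr_q}",
            f"  model: Expression ~ {' + '.join(self.model.terms)}",
            "  term              df1   df2   #significant",
        ]
        for term in self.model.terms:
            t = self.term(term)
            if not t["estimable"].any():
                lines.append(f"  {term:<16} (non-estimable)")
                continue
            lines.append(
                f"  {term:<16} {int(t['df1'].iloc[0]):>4} "
                f"{int(t['df2'].iloc[0]):>5}   {int(t['significant'].sum())}"
            )
        dropped = {k: v for k, v in self.model.design.dropped.items() if v}
        if dropped:
            lines.append(f"  aliased columns swept: {dropped}")
        return "\n".join(lines)


def unique_de_sets(flags: pd.DataFrame) -> pd.Series:
    """Venn-style exclusive/shared counts from per-contrast significance flags.

    ``flags`` is probes x contrasts boolean.  Returns counts keyed by the
    sorted tuple of contrast names joined with '&' ('none' for no flags).
    """
    counts: Dict[str, int] = {}
    names = list(flags.columns)
    for combo_size in range(0, len(names) + 1):
        for combo in itertools.combinations(names, combo_size):
            key = "&".join(combo) if combo else "none"
            in_combo = np.ones(len(flags), dtype=bool)
            for c in names:
                col = flags[c].to_numpy(dtype=bool)
                in_combo &= col if c in combo else ~col
            counts[key] = int(in_combo.sum())
    return pd.Series(counts)
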