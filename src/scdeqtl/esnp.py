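"""Genome-wide eSNP mapping (Model 1) and the conditioning comparison.

Model 1 per probe-SNP pair:

    Expression = mu + SNP + ClinStatus + WBC + RBC + Sex + eps

with the SNP coded additively as the minor-allele dosage.  Associations are
classed local (probe and SNP on the same chromosome) or distal (different
chromosomes), each class judged against its own Bonferroni threshold:
local alpha/(n_probes * avg_local_snps), distal alpha/(n_probes * n_snps).

The scan residualizes expression and dosage on the covariates once per
missingness pattern (Frisch–Waugh–Lovell), so the full probe x SNP grid
reduces to matrix products while remaining exact OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._linalg import build_design
from .containers import ExpressionMatrix, GenotypeMatrix, normalize_chrom

logger = logging.getLogger("scdeqtl")

MODEL1_COVARIATES = ("clin_status", "wbc", "rbc", "sex")


@dataclass
class ThresholdScheme:
    """Two-tier Bonferroni thresholds for local and distal associations."""

    alpha: float
    n_probes: int
    n_snps_total: int
    avg_local_snps: int
    local_threshold: float
    distal_threshold: float

    @property
    def local_nlp(self) -> float:
        return float(-np.log10(self.local_threshold))

    @property
    def distal_nlp(self) -> float:
        return float(-np.log10(self.distal_threshold))

    def threshold_for(self, assoc_class: str) -> float:
        return self.local_threshold if assoc_class == "local" else self.distal_threshold


def compute_bonferroni_thresholds(
    n_probes: int,
    n_snps_total: int,
    avg_local_snps: int = 200,
    alpha: float = 0.05,
) -> ThresholdScheme:
    """Bonferroni thresholds accounting for both probes and SNPs tested."""
    if min(n_probes, n_snps_total, avg_local_snps) <= 0:
        raise ValueError("counts must be positive")
    return ThresholdScheme(
        alpha=alpha,
        n_probes=n_probes,
        n_snps_total=n_snps_total,
        avg_local_snps=avg_local_snps,
        local_threshold=alpha / (n_probes * avg_local_snps),
        distal_threshold=alpha / (n_probes * n_snps_total),
    )


def classify_association(probe_chrom, snp_chrom) -> Optional[str]:
    """'local' if probe and SNP share a chromosome, else 'distal'.

    Returns None (pair excluded) when the probe location is missing.
    """
    pc = normalize_chrom(probe_chrom) if probe_chrom not in (None, "") else ""
    if pc in ("", "nan", "NA"):
        return None
    return "local" if pc == normalize_chrom(snp_chrom) else "distal"


def fit_model1(
    y: np.ndarray,
    dosage: np.ndarray,
    covariates: Optional[pd.DataFrame] = None,
    covariate_terms: Sequence[str] = MODEL1_COVARIATES,
) -> Dict[str, float]:
    """Single probe-SNP OLS fit with a t test on the SNP coefficient.

    Samples with missing dosage are dropped pairwise.  Partial R² is
    (RSS_reduced - RSS_full) / RSS_reduced with the reduced model omitting
    the SNP term.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(dosage, dtype=float)
    used = ~np.isnan(g) & ~np.isnan(y)
    y, g = y[used], g[used]
    if len(np.unique(g)) < 2:
        raise ValueError("SNP is monomorphic among usable samples")
    if covariates is not None:
        C = build_design(covariates.loc[used].reset_index(drop=True),
                         list(covariate_terms)).X
    else:
        C = np.ones((used.sum(), 1))
    X = np.column_stack([C, g])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss_full = float(resid @ resid)
    coef_r, _, _, _ = np.linalg.lstsq(C, y, rcond=None)
    resid_r = y - C @ coef_r
    rss_red = float(resid_r @ resid_r)
    df = len(y) - X.shape[1]
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = float(coef[-1])
    sigma2 = rss_full / df if df > 0 else np.nan
    se = float(np.sqrt(sigma2 * xtx_inv[-1, -1])) if df > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se if se else np.inf
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    partial_r2 = (rss_red - rss_full) / rss_red if rss_red > 0 else 1.0
    return {
        "beta": beta, "se": se, "t": float(t), "p": p,
        "partial_r2": float(partial_r2), "n_used": int(len(y)), "df": int(df),
    }


class EsnpScan:
    """Model-1 association scan over every probe x SNP pair.

    ``expression`` and ``genotypes`` must be sample-aligned with ``metadata``.
    Probes without a chromosome annotation are excluded (association class
    undefined); SNPs monomorphic among usable samples are skipped.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        metadata: pd.DataFrame,
        covariate_terms: Sequence[str] = MODEL1_COVARIATES,
        thresholds: Optional[ThresholdScheme] = None,
        avg_local_snps: int = 200,
        alpha: float = 0.05,
    ) -> None:
        ids = list(metadata["sample_id"])
        if ids != list(expression.sample_ids) or ids != list(genotypes.sample_ids):
            raise ValueError("inputs must be sample-aligned (use io.align_cohort)")
        annotated = expression.probes["chrom"].to_numpy() != ""
        self.n_probes_excluded = int((~annotated).sum())
        if self.n_probes_excluded:
            logger.info(
                "EsnpScan: %d probes without chromosome annotation excluded",
                self.n_probes_excluded,
            )
        self.expression = expression.take_probes(annotated)
        self.genotypes = genotypes
        self.metadata = metadata
        self.covariate_terms = list(covariate_terms)
        self.thresholds = thresholds or compute_bonferroni_thresholds(
            self.expression.n_probes, genotypes.n_snps, avg_local_snps, alpha
        )

    def fit(self, emit_all: bool = False, snp_block: int = 2048) -> "EsnpScanResults":
        e, g = self.expression, self.genotypes
        Y = e.values.T  # samples x probes
        probe_chrom = e.probes["chrom"].to_numpy()
        snp_chrom = g.snps["chrom"].to_numpy()
        local_mask_cache: Dict[str, np.ndarray] = {}

        C_full = build_design(self.metadata, self.covariate_terms).X
        n, k = C_full.shape
        records: List[pd.DataFrame] = []
        n_skipped = 0
        n_tested = 0

        miss = np.isnan(g.dosage)
        pattern_keys = [miss[:, j].tobytes() for j in range(g.n_snps)]
        patterns: Dict[bytes, List[int]] = {}
        for j, key in enumerate(pattern_keys):
            patterns.setdefault(key, []).append(j)

        for key, snp_idx in patterns.items():
            used = ~np.frombuffer(key, dtype=bool)
            n_used = int(used.sum())
            C = C_full[used]
            Q, _ = np.linalg.qr(C)
            Yu = Y[used]
            Yr = Yu - Q @ (Q.T @ Yu)
            rss0 = np.einsum("ij,ij->j", Yr, Yr)
            df = n_used - k - 1
            if df <= 0:
                n_skipped += len(snp_idx)
                continue
            for start in range(0, len(snp_idx), snp_block):
                block = np.asarray(snp_idx[start:start + snp_block])
                G = g.dosage[used][:, block]
                poly = np.array([len(np.unique(G[:, c])) > 1 for c in range(G.shape[1])])
                if not poly.any():
                    n_skipped += len(block)
                    continue
                n_skipped += int((~poly).sum())
                block = block[poly]
                G = G[:, poly]
                Gr = G - Q @ (Q.T @ G)
                s2g = np.einsum("ij,ij->j", Gr, Gr)
                ok = s2g > 1e-12
                if not ok.all():
                    n_skipped += int((~ok).sum())
                    block, Gr, s2g = block[ok], Gr[:, ok], s2g[ok]
                if block.size == 0:
                    continue
                B = (Gr.T @ Yr) / s2g[:, None]          # snps x probes
                rss_full = np.maximum(rss0[None, :] - B**2 * s2g[:, None], 0.0)
                with np.errstate(divide="ignore", invalid="ignore"):
                    se = np.sqrt(rss_full / (df * s2g[:, None]))
                    tstat = B / se
                p = 2.0 * stats.t.sf(np.abs(tstat), df)
                p = np.where(np.isfinite(tstat), p, 0.0)
                with np.errstate(invalid="ignore"):
                    pr2 = np.where(rss0[None, :] > 0,
                                   1.0 - rss_full / rss0[None, :], 1.0)
                n_tested += block.size * e.n_probes

                # class-appropriate significance per pair
                is_local = np.zeros((len(block), e.n_probes), dtype=bool)
                for bi, j in enumerate(block):
                    ch = snp_chrom[j]
                    if ch not in local_mask_cache:
                        local_mask_cache[ch] = probe_chrom == ch
                    is_local[bi] = local_mask_cache[ch]
                thr = np.where(is_local, self.thresholds.local_threshold,
                               self.thresholds.distal_threshold)
                keep = np.ones_like(p, dtype=bool) if emit_all else (p < thr)
                if not keep.any():
                    continue
                si, pi = np.where(keep)
                records.append(pd.DataFrame({
                    "probe_id": np.asarray(e.probe_ids, dtype=object)[pi],
                    "snp_id": np.asarray(g.snp_ids, dtype=object)[block[si]],
                    "beta": B[si, pi],
                    "se": se[si, pi],
                    "t": tstat[si, pi],
                    "p": p[si, pi],
                    "class": np.where(is_local[si, pi], "local", "distal"),
                    "partial_r2": pr2[si, pi],
                    "n_used": n_used,
                    "significant": (p < thr)[si, pi],
                }))

        if records:
            table = pd.concat(records, ignore_index=True)
        else:
            table = pd.DataFrame(
                columns=["probe_id", "snp_id", "beta", "se", "t", "p", "class",
                         "partial_r2", "n_used", "significant"]
            )
        table["significant"] = table["significant"].astype(bool)
        sig = table[table["significant"]]
        counts = {
            "n_pairs_tested": n_tested,
            "n_snps_skipped": n_skipped,
            "n_probes_excluded": self.n_probes_excluded,
            "n_significant": int(len(sig)),
            "n_local_significant": int((sig["class"] == "local").sum()),
            "n_distal_significant": int((sig["class"] == "distal").sum()),
        }
        return EsnpScanResults(self, table, counts)


@dataclass
class EsnpScanResults:
    model: EsnpScan
    records: pd.DataFrame
    counts: Dict[str, int]

    @property
    def significant(self) -> pd.DataFrame:
        return self.records[self.records["significant"]].reset_index(drop=True)

    def peaks(self) -> pd.DataFrame:
        return select_peak_associations(self.significant)

    def summary(self) -> str:
        t = self.model.thresholds
        pk = self.peaks()
        return "\n".join([
            "Model 1 eSNP scan",
            f"  pairs tested: {self.counts['n_pairs_tested']}"
            f"   SNPs skipped: {self.counts['n_snps_skipped']}",
            f"  local threshold:  {t.local_threshold:.3g} (NLP {t.local_nlp:.2f})",
            f"  distal threshold: {t.distal_threshold:.3g} (NLP {t.distal_nlp:.2f})",
            f"  significant pairs: {self.counts['n_significant']}"
            f" ({self.counts['n_local_significant']} local /"
            f" {self.counts['n_distal_significant']} distal)",
            f"  peak associations: {len(pk)}"
            f" ({int((pk['class'] == 'local').sum())} local /"
            f" {int((pk['class'] == 'distal').sum())} distal)",
        ])


def select_peak_associations(records: pd.DataFrame) -> pd.DataFrame:
    """Per probe and class, the strongest association.

    Minimum p wins; exact ties break toward larger |beta|, then the
    lexicographically smallest snp_id.
    """
    if records.empty:
        return records.copy()
    df = records.copy()
    df["_absbeta"] = -df["beta"].abs()
    df = df.sort_values(["probe_id", "class", "p", "_absbeta", "snp_id"],
                        kind="stable")
    peaks = df.groupby(["probe_id", "class"], as_index=False).head(1)
    return peaks.drop(columns="_absbeta").reset_index(drop=True)


def condition_on_esnp(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    peaks: pd.DataFrame,
    covariate_terms: Sequence[str] = ("sex", "wbc", "rbc"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Clinical-status significance with and without each probe's peak eSNP.

    For every probe with a peak association, fits the full ANCOVA with and
    without the SNP term and extracts the ClinStatus omnibus F p-value from
    both.  The returned table carries both p-values and NLPs plus a
    sign-consistency flag of the status effect between models; summary
    statistics (rank correlation, Bonferroni-significant counts) are in
    ``.attrs``.
    """
    ids = list(metadata["sample_id"])
    if ids != list(expression.sample_ids) or ids != list(genotypes.sample_ids):
        raise ValueError("inputs must be sample-aligned")
    if peaks.empty:
        out = pd.DataFrame(columns=["probe_id", "snp_id", "p_status_without",
                                    "p_status_with", "nlp_without", "nlp_with",
                                    "sign_consistent"])
        out.attrs.update({"rank_correlation": float("nan"),
                          "n_significant_either": 0, "frac_sign_consistent": float("nan")})
        return out

    best = peaks.sort_values("p", kind="stable").groupby("probe_id",
                                                         as_index=False).head(1)
    probe_pos = {pid: i for i, pid in enumerate(expression.probe_ids)}
    snp_pos = {sid: i for i, sid in enumerate(genotypes.snp_ids)}

    terms = ["clin_status"] + list(covariate_terms)
    design = build_design(metadata, terms)
    status_cols = design.term_cols["clin_status"]
    X_with_status = design.X
    X_wo_status = design.without_term("clin_status")

    rows = []
    for rec in best.itertuples(index=False):
        y = expression.values[probe_pos[rec.probe_id]]
        gdos = genotypes.dosage[:, snp_pos[rec.snp_id]]
        used = ~np.isnan(gdos) & ~np.isnan(y)
        yu, gu = y[used], gdos[used]
        Xf0, Xr0 = X_with_status[used], X_wo_status[used]
        # without the SNP
        F0, df10, df20, p0 = _status_f(Xf0, Xr0, yu)
        b0 = _status_coefs(Xf0, yu, status_cols)
        # with the SNP
        Xf1 = np.column_stack([Xf0, gu])
        Xr1 = np.column_stack([Xr0, gu])
        F1, df11, df21, p1 = _status_f(Xf1, Xr1, yu)
        b1 = _status_coefs(Xf1, yu, status_cols)
        consistent = bool(np.all(np.sign(b0) == np.sign(b1))) if len(b0) else True
        rows.append((rec.probe_id, rec.snp_id, p0, p1,
                     -np.log10(max(p0, 1e-300)), -np.log10(max(p1, 1e-300)),
                     consistent))
    out = pd.DataFrame(rows, columns=["probe_id", "snp_id", "p_status_without",
                                      "p_status_with", "nlp_without", "nlp_with",
                                      "sign_consistent"])
    bonf = alpha / max(len(out), 1)
    rho = (
        stats.spearmanr(out["nlp_without"], out["nlp_with"]).statistic
        if len(out) > 2 else float("nan")
    )
    out.attrs.update({
        "rank_correlation": float(rho),
        "bonferroni_level": bonf,
        "n_significant_either": int(
            ((out["p_status_without"] < bonf) | (out["p_status_with"] < bonf)).sum()
        ),
        "n_significant_without": int((out["p_status_without"] < bonf).sum()),
        "n_significant_with": int((out["p_status_with"] < bonf).sum()),
        "frac_sign_consistent": float(out["sign_consistent"].mean()),
    })
    return out


def _status_f(X_full: np.ndarray, X_red: np.ndarray, y: np.ndarray):
    from ._linalg import drop_term_f

    F, df1, df2, p = drop_term_f(X_full, X_red, y[:, None])
    return float(F[0]), df1, df2, float(p[0])


def _status_coefs(X: np.ndarray, y: np.ndarray, status_cols: Sequence[int]) -> np.ndarray:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return coef[list(status_cols)]
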