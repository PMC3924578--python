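"""SNP-by-clinical-status interaction mapping and relatedness correction.

Model 2 adds a SNP x ClinStatus term to the eSNP model:

    Expression = mu + SNP + ClinStatus + WBC + RBC + Sex + SNP*ClinStatus + eps

and the interaction is judged by the partial F test of Model 2 against
Model 1.  Pairs passing the two-tier Bonferroni screen are refit in a Q-K
mixed model: a polygenic random effect with covariance sigma_g^2 * 2K built
from pairwise IBD estimates (pi-hat) on an LD-pruned SNP set, optionally
with ancestry PCs (Q) as fixed covariates; REML via the spectral
decomposition of 2K, Wald F on the interaction terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats

from ._linalg import build_design
from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    KinshipMatrix,
)
from .esnp import ThresholdScheme, compute_bonferroni_thresholds

logger = logging.getLogger("scdeqtl")

MODEL2_COVARIATES = ("clin_status", "wbc", "rbc", "sex")


# ---------------------------------------------------------------------------
# LD pruning and kinship


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.3,
    maf_min: float = 0.10,
    window: int = 50,
    step: int = 5,
) -> List[str]:
    """Greedy windowed LD pruning; returns surviving snp_ids.

    Pre-filters to SNPs with MAF >= maf_min and zero missingness, then
    slides a ``window``-SNP window along each chromosome in position order,
    dropping the later-position SNP of any pair with squared dosage
    correlation >= r2_max.
    """
    from .qc import minor_allele_frequency

    d = g.dosage
    eligible = []
    for j in range(g.n_snps):
        col = d[:, j]
        if np.isnan(col).any():
            continue
        if minor_allele_frequency(col) >= maf_min and np.var(col) > 0:
            eligible.append(j)
    snps = g.snps.iloc[eligible]
    order = np.lexsort((snps["pos"].to_numpy(),
                        snps["chrom"].to_numpy().astype(object)))
    ordered = [eligible[i] for i in order]
    chroms = g.snps["chrom"].to_numpy()

    removed = set()
    by_chrom: Dict[str, List[int]] = {}
    for j in ordered:
        by_chrom.setdefault(chroms[j], []).append(j)
    for chrom_snps in by_chrom.values():
        for start in range(0, len(chrom_snps), step):
            idx = [j for j in chrom_snps[start:start + window] if j not in removed]
            if len(idx) < 2:
                continue
            G = d[:, idx]
            corr = np.corrcoef(G.T)
            r2 = corr**2
            for a in range(len(idx)):
                if idx[a] in removed:
                    continue
                for b in range(a + 1, len(idx)):
                    if idx[b] in removed:
                        continue
                    if r2[a, b] >= r2_max:
                        removed.add(idx[b])  # keep the earlier-position SNP
    kept = [j for j in ordered if j not in removed]
    logger.info("ld_prune: %d of %d eligible SNPs retained (%d input)",
                len(kept), len(ordered), g.n_snps)
    return [g.snp_ids[j] for j in kept]


def estimate_kinship(
    g: GenotypeMatrix,
    snp_ids: Optional[Sequence[str]] = None,
    min_snps: int = 50,
) -> KinshipMatrix:
    """Method-of-moments IBD pi-hat for every sample pair.

    For each pair, observed identity-by-state (IBS) counts are combined
    with their expectations given allele frequencies to solve for
    P(IBD=0/1/2); pi-hat = P(IBD=1)/2 + P(IBD=2), truncated to [0, 1].
    Pairs with fewer than ``min_snps`` comparable SNPs get pi-hat = NaN.
    """
    if snp_ids is not None:
        idx = [g.snps.index.get_loc(s) for s in snp_ids]
        sub = g.take_snps(np.asarray(idx))
    else:
        sub = g
    d = sub.dosage
    n, m = d.shape
    if m == 0:
        raise ValueError("empty SNP set for kinship estimation")
    p = np.nanmean(d, axis=0) / 2.0  # minor-allele frequency per SNP
    informative = (p > 0) & (p < 1)
    d = d[:, informative]
    p = p[informative]
    q = 1.0 - p
    m = d.shape[1]

    # per-SNP IBS-state expectations under IBD 0 / 1 / 2
    e0_ibs0 = 2 * p**2 * q**2
    e0_ibs1 = 4 * p**3 * q + 4 * p * q**3
    e1_ibs1 = 2 * p**2 * q + 2 * p * q**2
    e1_ibs2 = p**3 + q**3 + p**2 * q + p * q**2

    valid = ~np.isnan(d)
    pihat = np.full((n, n), np.nan)
    np.fill_diagonal(pihat, 1.0)
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            L = int(both.sum())
            if L < min_snps:
                continue
            diff = np.abs(d[i, both] - d[j, both])
            n_ibs0 = int((diff == 2).sum())
            n_ibs1 = int((diff == 1).sum())
            n_ibs2 = L - n_ibs0 - n_ibs1
            E00 = e0_ibs0[both].sum()
            E10 = e0_ibs1[both].sum()
            E11 = e1_ibs1[both].sum()
            E21 = e1_ibs2[both].sum()
            E20_full = L - E00 - E10  # P(IBS=2|IBD=0) summed
            z0 = n_ibs0 / E00 if E00 > 0 else 0.0
            z1 = (n_ibs1 - z0 * E10) / E11 if E11 > 0 else 0.0
            z2 = (n_ibs2 - z0 * E20_full - z1 * E21) / L
            # truncate only the final estimate: clipping the components
            # individually biases near-zero relatedness upward
            pihat[i, j] = pihat[j, i] = float(np.clip(z1 / 2.0 + z2, 0.0, 1.0))
    return KinshipMatrix(sample_ids=list(g.sample_ids), pihat=pihat)


# ---------------------------------------------------------------------------
# Model 2 screen


class InteractionScan:
    """Partial-F interaction screen of Model 2 against Model 1.

    ``expression`` should be restricted to differentially expressed probes
    and ``genotypes`` to per-group QC-passed SNPs before construction.
    """

    def __init__(
        self,
        expression: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        metadata: pd.DataFrame,
        covariate_terms: Sequence[str] = MODEL2_COVARIATES,
        thresholds: Optional[ThresholdScheme] = None,
        avg_local_snps: int = 200,
        alpha: float = 0.05,
    ) -> None:
        ids = list(metadata["sample_id"])
        if ids != list(expression.sample_ids) or ids != list(genotypes.sample_ids):
            raise ValueError("inputs must be sample-aligned (use io.align_cohort)")
        annotated = expression.probes["chrom"].to_numpy() != ""
        self.expression = expression.take_probes(annotated)
        self.genotypes = genotypes
        self.metadata = metadata
        self.covariate_terms = list(covariate_terms)
        self.thresholds = thresholds or compute_bonferroni_thresholds(
            self.expression.n_probes, genotypes.n_snps, avg_local_snps, alpha
        )
        status = metadata["clin_status"].astype(str).to_numpy()
        self.status_levels = sorted(pd.unique(status))
        self.status = status

    def fit(self, emit_all: bool = False) -> "InteractionScanResults":
        e, g = self.expression, self.genotypes
        design = build_design(self.metadata, self.covariate_terms)
        C = design.X
        n, k = C.shape
        Q, _ = np.linalg.qr(C)
        Y = e.values.T
        Yr = Y - Q @ (Q.T @ Y)
        rss0 = np.einsum("ij,ij->j", Yr, Yr)
        probe_chrom = e.probes["chrom"].to_numpy()
        snp_chrom = g.snps["chrom"].to_numpy()

        nonbase = self.status_levels[1:]
        dummies = np.column_stack(
            [(self.status == lv).astype(float) for lv in nonbase]
        ) if nonbase else np.empty((n, 0))

        rows = []
        n_skipped = 0
        for j in range(g.n_snps):
            gdos = g.dosage[:, j]
            if np.isnan(gdos).any():
                n_skipped += 1  # per-group filter requires complete data
                continue
            mono_in_group = any(
                len(np.unique(gdos[self.status == lv])) < 2
                for lv in self.status_levels
            )
            if mono_in_group:
                n_skipped += 1
                continue
            B = np.column_stack([gdos, dummies * gdos[:, None]])
            Br = B - Q @ (Q.T @ B)
            Qb, Rb = np.linalg.qr(Br)
            diag = np.abs(np.diag(Rb))
            rank_cols = diag > 1e-8 * max(diag.max(), 1.0)
            Qb = Qb[:, rank_cols]
            r_full = int(rank_cols.sum())
            r_snp = 1  # first column is the main SNP effect
            if r_full <= r_snp:
                n_skipped += 1
                continue
            proj = Qb.T @ Yr                     # r_full x probes
            rss2 = np.maximum(rss0 - np.einsum("ij,ij->j", proj, proj), 0.0)
            rss1 = np.maximum(rss0 - proj[0] ** 2, 0.0)
            df1 = r_full - r_snp
            df2 = n - k - r_full
            with np.errstate(divide="ignore", invalid="ignore"):
                F = ((rss1 - rss2) / df1) / (rss2 / df2)
            p = stats.f.sf(F, df1, df2)
            p = np.where(np.isfinite(F), p, 0.0)

            coefs, _, _, _ = np.linalg.lstsq(Br, Yr, rcond=None)
            base_slope = coefs[0]
            slopes = {self.status_levels[0]: base_slope}
            for gi, lv in enumerate(nonbase):
                slopes[lv] = base_slope + coefs[1 + gi]

            is_local = probe_chrom == snp_chrom[j]
            thr = np.where(is_local, self.thresholds.local_threshold,
                           self.thresholds.distal_threshold)
            keep = np.ones_like(p, dtype=bool) if emit_all else (p < thr)
            if not keep.any():
                continue
            for pi in np.flatnonzero(keep):
                rows.append({
                    "probe_id": e.probe_ids[pi],
                    "snp_id": g.snp_ids[j],
                    "F": float(F[pi]),
                    "df1": df1,
                    "df2": df2,
                    "p": float(p[pi]),
                    "class": "local" if is_local[pi] else "distal",
                    **{f"slope_{lv}": float(slopes[lv][pi]) for lv in self.status_levels},
                    "significant": bool(p[pi] < thr[pi]),
                })
        cols = ["probe_id", "snp_id", "F", "df1", "df2", "p", "class"] + [
            f"slope_{lv}" for lv in self.status_levels
        ] + ["significant"]
        table = pd.DataFrame(rows, columns=cols)
        table["significant"] = table["significant"].astype(bool)
        return InteractionScanResults(self, table, n_skipped)


@dataclass
class InteractionScanResults:
    model: InteractionScan
    records: pd.DataFrame
    n_snps_skipped: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.records[self.records["significant"]].reset_index(drop=True)

    def refit_mixed(
        self,
        kinship: KinshipMatrix,
        q_scores: Optional[np.ndarray] = None,
    ) -> pd.DataFrame:
        """Q-K mixed-model refit of the OLS-significant pairs.

        Applied only to pairs that passed the screen (the refit is the
        expensive step); returns the screen records with ``mixedmodel_p``
        and a convergence flag appended.
        """
        recs = self.significant.copy()
        if recs.empty:
            recs["mixedmodel_p"] = []
            recs["refit_converged"] = []
            return recs
        if list(kinship.sample_ids) != list(self.model.metadata["sample_id"]):
            raise ValueError("kinship matrix must be sample-aligned")
        e, g = self.model.expression, self.model.genotypes
        probe_pos = {pid: i for i, pid in enumerate(e.probe_ids)}
        snp_pos = {sid: i for i, sid in enumerate(g.snp_ids)}
        C = build_design(self.model.metadata, self.model.covariate_terms).X
        nonbase = self.model.status_levels[1:]
        dummies = np.column_stack(
            [(self.model.status == lv).astype(float) for lv in nonbase]
        ) if nonbase else np.empty((len(C), 0))
        K2 = 2.0 * np.nan_to_num(kinship.pihat, nan=0.0)

        ps, flags = [], []
        for rec in recs.itertuples(index=False):
            y = e.values[probe_pos[rec.probe_id]]
            gdos = g.dosage[:, snp_pos[rec.snp_id]]
            B = np.column_stack([gdos, dummies * gdos[:, None]])
            X = np.column_stack([C, B])
            if q_scores is not None:
                X = np.column_stack([X, q_scores])
            test_cols = list(range(C.shape[1] + 1, C.shape[1] + B.shape[1]))
            mm = QKMixedModel(y, X, K2, test_cols=test_cols)
            res = mm.fit()
            ps.append(res.test_p)
            flags.append(res.converged)
        recs["mixedmodel_p"] = ps
        recs["refit_converged"] = flags
        return recs

    def summary(self) -> str:
        t = self.model.thresholds
        return "\n".join([
            "Model 2 SNP-by-ClinStatus interaction screen",
            f"  probes: {self.model.expression.n_probes}"
            f"   SNPs: {self.model.genotypes.n_snps}"
            f"   skipped SNPs: {self.n_snps_skipped}",
            f"  local threshold:  {t.local_threshold:.3g} (NLP {t.local_nlp:.2f})",
            f"  distal threshold: {t.distal_threshold:.3g} (NLP {t.distal_nlp:.2f})",
            f"  OLS-significant pairs: {int(self.records['significant'].sum())}",
        ])


def finalize_interactions(
    records: pd.DataFrame, thresholds: ThresholdScheme
) -> pd.DataFrame:
    """Interactions still significant after the mixed-model refit.

    Non-converged refits are excluded with a reason column; the report is
    ordered by mixed-model p.
    """
    if records.empty or "mixedmodel_p" not in records.columns:
        return records.head(0)
    out = records.copy()
    thr = out["class"].map(thresholds.threshold_for)
    converged = out["refit_converged"].astype(bool)
    out["final"] = converged & (out["mixedmodel_p"] < thr)
    out["reason"] = np.where(
        ~converged, "refit_not_converged",
        np.where(out["final"], "", "above_threshold"),
    )
    return out[out["final"]].sort_values("mixedmodel_p").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Q-K mixed model


@dataclass
class QKMixedResults:
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    cov_beta: np.ndarray
    test_F: float
    test_df: Tuple[int, int]
    test_p: float
    converged: bool
    reml_loglik: float

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else float("nan")

    def summary(self) -> str:
        return (
            "Q-K mixed model (REML)\n"
            f"  sigma_g^2 = {self.sigma_g2:.4g}   sigma_e^2 = {self.sigma_e2:.4g}"
            f"   h^2 = {self.heritability:.3f}\n"
            f"  Wald F({self.test_df[0]}, {self.test_df[1]}) = {self.test_F:.3f}"
            f"   p = {self.test_p:.3g}   converged = {self.converged}"
        )


class QKMixedModel:
    """Linear mixed model y = X beta + u + eps with cov(u) = sigma_g^2 * G.

    ``G`` is the numerator relationship matrix (2K from pi-hat estimates);
    non-PSD G receives minimal eigenvalue bending.  The single variance
    ratio is profiled out by REML on the spectral decomposition of G, and
    the coefficients in ``test_cols`` get a Wald F test with residual df.
    With G proportional to the identity the GLS fit reduces exactly to OLS.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        G: np.ndarray,
        test_cols: Sequence[int],
    ) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        G = np.asarray(G, dtype=float)
        G = (G + G.T) / 2.0
        evals, evecs = np.linalg.eigh(G)
        if evals.min() < 1e-8:
            bend = 1e-8 - evals.min()
            evals = evals + bend
            logger.debug("QKMixedModel: bent G eigenvalues by %.3g", bend)
        self.evals, self.evecs = evals, evecs
        self.test_cols = list(test_cols)

    def _neg2_reml(self, log_delta: float) -> float:
        delta = np.exp(log_delta)  # sigma_g^2 / sigma_e^2
        w = 1.0 / (delta * self.evals + 1.0)
        ys = self.evecs.T @ self.y
        Xs = self.evecs.T @ self.X
        XtWX = Xs.T @ (w[:, None] * Xs)
        XtWy = Xs.T @ (w * ys)
        beta = np.linalg.solve(XtWX, XtWy)
        r = ys - Xs @ beta
        n, p = self.X.shape
        rss = float(r @ (w * r))
        sigma_e2 = rss / (n - p)
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        return (
            (n - p) * np.log(sigma_e2)
            + float(np.sum(np.log(delta * self.evals + 1.0)))
            + logdet_XtWX
        )

    def fit(self) -> QKMixedResults:
        res = optimize.minimize_scalar(
            self._neg2_reml, bounds=(-12.0, 12.0), method="bounded",
            options={"xatol": 1e-8},
        )
        log_delta = float(res.x)
        converged = bool(res.success)
        at_bound = log_delta <= -11.9 or log_delta >= 11.9
        delta = np.exp(log_delta)
        w = 1.0 / (delta * self.evals + 1.0)
        ys = self.evecs.T @ self.y
        Xs = self.evecs.T @ self.X
        XtWX = Xs.T @ (w[:, None] * Xs)
        beta = np.linalg.solve(XtWX, Xs.T @ (w * ys))
        r = ys - Xs @ beta
        n, p = self.X.shape
        sigma_e2 = float(r @ (w * r)) / (n - p)
        sigma_g2 = delta * sigma_e2
        cov_beta = sigma_e2 * np.linalg.inv(XtWX)
        q = len(self.test_cols)
        L_beta = beta[self.test_cols]
        L_cov = cov_beta[np.ix_(self.test_cols, self.test_cols)]
        df2 = n - p
        if q:
            F = float(L_beta @ np.linalg.solve(L_cov, L_beta)) / q
            pval = float(stats.f.sf(F, q, df2))
        else:
            F, pval = float("nan"), float("nan")
        return QKMixedResults(
            sigma_g2=sigma_g2, sigma_e2=sigma_e2, beta=beta, cov_beta=cov_beta,
            test_F=F, test_df=(q, df2), test_p=pval,
            converged=converged and not at_bound or delta < 1e-4,
            reml_loglik=-0.5 * float(res.fun),
        )


def fit_qk_mixed(
    y: np.ndarray,
    X: np.ndarray,
    kinship: KinshipMatrix,
    test_cols: Sequence[int],
    q_scores: Optional[np.ndarray] = None,
) -> QKMixedResults:
    """Convenience wrapper: builds 2K, appends Q columns, fits, tests."""
    if q_scores is not None:
        X = np.column_stack([X, q_scores])
    K2 = 2.0 * np.nan_to_num(kinship.pihat, nan=0.0)
    return QKMixedModel(y, X, K2, test_cols).fit()
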