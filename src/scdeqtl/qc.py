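"""Genotype- and expression-side quality control.

Genotype side: per-SNP minor-allele frequency, call rate, and the exact
Hardy-Weinberg-equilibrium test; joint filtering optionally applied within
each clinical group separately (the interaction-stage rule).

Expression side: log2 transform + quantile normalization, background probe
filtering at the knee of the rank-ordered mean-intensity curve, technical
replicate averaging, and per-probe winsorization of outlying intensities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger("scdeqtl")


# ---------------------------------------------------------------------------
# genotype QC


def minor_allele_frequency(dosages: np.ndarray) -> float:
    """Frequency of the less-common allele among non-missing calls.

    Dosages are minor-allele counts in {0,1,2}; NaN = missing.  Returns NaN
    when every call is missing (such a SNP fails QC downstream).
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    f = d.sum() / (2.0 * d.size)
    return float(min(f, 1.0 - f))


def call_rate(dosages: np.ndarray) -> float:
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        return 0.0
    return float(1.0 - np.isnan(d).mean())


def hwe_exact_pvalue(n_hom_major: int, n_het: int, n_hom_minor: int) -> float:
    """Exact two-sided HWE test p-value.

    Sums, over the conditional distribution of the heterozygote count given
    the allele counts, the probabilities of all outcomes no more probable
    than the observed one (the standard exact formulation, not mid-p).
    Monomorphic samples return 1.0.
    """
    if min(n_hom_major, n_het, n_hom_minor) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_major + n_het + n_hom_minor
    if n < 1:
        raise ValueError("need at least one genotype")
    rare = 2 * min(n_hom_major, n_hom_minor) + n_het
    if rare == 0 or rare == 2 * n:
        return 1.0

    h_max = min(rare, 2 * n - rare)
    h_min = rare % 2
    # unnormalized probabilities over het counts h = h_min, h_min+2, ..., h_max
    hs = np.arange(h_min, h_max + 1, 2)
    probs = np.zeros(len(hs))
    mid = len(hs) // 2
    probs[mid] = 1.0
    # recurrence downward: P(h-2)/P(h) = h(h-1) / (4 (r_h + 1)(c_h + 1))
    for k in range(mid, 0, -1):
        h = hs[k]
        rare_hom = (rare - h) // 2
        common_hom = n - h - rare_hom
        probs[k - 1] = probs[k] * h * (h - 1) / (4.0 * (rare_hom + 1) * (common_hom + 1))
    # recurrence upward: P(h+2)/P(h) = 4 r_h c_h / ((h+2)(h+1))
    for k in range(mid, len(hs) - 1):
        h = hs[k]
        rare_hom = (rare - h) // 2
        common_hom = n - h - rare_hom
        probs[k + 1] = probs[k] * 4.0 * rare_hom * common_hom / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    obs = probs[(n_het - h_min) // 2]
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


def _genotype_counts(dosage_col: np.ndarray) -> Tuple[int, int, int]:
    d = dosage_col[~np.isnan(dosage_col)]
    return int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())


def snp_qc_table(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.99,
    hwe_p_min: float = 0.001,
    hwe_samples: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-SNP QC metrics and pass flags with reason codes.

    ``hwe_samples`` optionally restricts the HWE test to a boolean mask of
    samples (e.g. founders only — relatedness distorts HWE in sibship data).
    """
    n_snps = g.n_snps
    maf = np.empty(n_snps)
    cr = np.empty(n_snps)
    hwe = np.empty(n_snps)
    hwe_dosage = g.dosage if hwe_samples is None else g.dosage[np.asarray(hwe_samples)]
    for j in range(n_snps):
        col = g.dosage[:, j]
        maf[j] = minor_allele_frequency(col)
        cr[j] = call_rate(col)
        c0, c1, c2 = _genotype_counts(hwe_dosage[:, j])
        hwe[j] = hwe_exact_pvalue(c0, c1, c2) if (c0 + c1 + c2) else float("nan")
    report = pd.DataFrame(
        {"maf": maf, "call_rate": cr, "hwe_p": hwe}, index=g.snps.index
    )
    reasons = []
    for j in range(n_snps):
        r = []
        if not (maf[j] >= maf_min):
            r.append("low_maf")
        if not (cr[j] >= callrate_min):
            r.append("low_callrate")
        if not (hwe[j] >= hwe_p_min):
            r.append("hwe_fail")
        reasons.append(";".join(r))
    report["reasons"] = reasons
    report["pass"] = report["reasons"] == ""
    return report


def filter_snps(
    g: GenotypeMatrix,
    maf_min: float = 0.05,
    callrate_min: float = 0.99,
    hwe_p_min: float = 0.001,
    per_group: Optional[Sequence] = None,
    hwe_samples: Optional[np.ndarray] = None,
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Retain SNPs passing MAF / call-rate / HWE thresholds.

    With ``per_group`` (a per-sample label sequence) every criterion must
    pass within every group separately — the interaction-stage rule, where
    missingness <= 1% per group corresponds to ``callrate_min = 0.99``.
    """
    if per_group is None:
        report = snp_qc_table(g, maf_min, callrate_min, hwe_p_min, hwe_samples)
    else:
        labels = np.asarray(per_group)
        if len(labels) != g.n_samples:
            raise ValueError("per_group labels must align with samples")
        passes = np.ones(g.n_snps, dtype=bool)
        frames = {}
        for grp in pd.unique(labels):
            mask = labels == grp
            sub = GenotypeMatrix(
                sample_ids=[s for s, m in zip(g.sample_ids, mask) if m],
                snps=g.snps,
                dosage=g.dosage[mask],
            )
            rep = snp_qc_table(sub, maf_min, callrate_min, hwe_p_min)
            passes &= rep["pass"].to_numpy()
            frames[grp] = rep
        report = pd.concat(frames, axis=1)
        report["pass"] = passes
    kept = report["pass"].to_numpy(dtype=bool)
    if not kept.any():
        logger.warning("filter_snps: no SNPs passed QC")
    logger.info("filter_snps: %d of %d SNPs retained", int(kept.sum()), g.n_snps)
    return g.take_snps(kept), report


# ---------------------------------------------------------------------------
# expression QC


def winsorize_outliers(e: ExpressionMatrix, n_sd: float = 4.0) -> ExpressionMatrix:
    """Clip per-probe values beyond ``n_sd`` SDs of the probe mean."""
    v = e.values.copy()
    mu = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)
    lo, hi = mu - n_sd * sd, mu + n_sd * sd
    return ExpressionMatrix(
        probes=e.probes, sample_ids=list(e.sample_ids), values=np.clip(v, lo, hi)
    )


def log2_quantile_normalize(
    e: ExpressionMatrix, log_transform: bool = True
) -> ExpressionMatrix:
    """Log2 transform then quantile-normalize samples against each other.

    After normalization every sample's sorted value vector equals the
    cross-sample mean of order statistics; tied values receive the mean of
    the quantile values their ranks span.
    """
    v = e.values
    if log_transform:
        bad = np.argwhere(v <= 0)
        if len(bad):
            i, j = bad[0]
            raise ValueError(
                f"non-positive intensity at probe {e.probes.index[i]}, "
                f"sample {e.sample_ids[j]}: {v[i, j]}"
            )
        v = np.log2(v)
    if e.n_samples == 1:
        return ExpressionMatrix(
            probes=e.probes, sample_ids=list(e.sample_ids), values=v.copy()
        )
    ref = np.sort(v, axis=0).mean(axis=1)  # mean order statistics
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        x = v[:, j]
        order = np.argsort(x, kind="stable")
        col = np.empty_like(x)
        col[order] = ref
        # average quantile values across runs of exactly tied input values
        xs = x[order]
        run_start = 0
        for k in range(1, len(xs) + 1):
            if k == len(xs) or xs[k] != xs[run_start]:
                if k - run_start > 1:
                    col[order[run_start:k]] = ref[run_start:k].mean()
                run_start = k
        out[:, j] = col
    return ExpressionMatrix(probes=e.probes, sample_ids=list(e.sample_ids), values=out)


def find_background_cutoff(
    mean_intensity: np.ndarray, smooth_window: Optional[int] = None
) -> float:
    """Knee of the rank-ordered mean-intensity curve.

    The cutoff is the smoothed intensity at the rank minimizing the discrete
    second difference of the smoothed curve (where the rise toward expressed
    probes decelerates).  A curve with no knee (essentially linear) raises.
    """
    s = np.sort(np.asarray(mean_intensity, dtype=float))
    p = len(s)
    if p < 5:
        raise ValueError("too few probes to locate a background knee")
    w = smooth_window or max(5, p // 50)
    kernel = np.ones(w) / w
    sm = np.convolve(s, kernel, mode="valid")
    d2 = sm[2:] - 2.0 * sm[1:-1] + sm[:-2]
    spread = s[-1] - s[0]
    if spread <= 0 or np.max(np.abs(d2)) < 1e-8 * spread:
        raise ValueError("rank-ordered intensity curve has no knee")
    knee = int(np.argmin(d2)) + 1
    return float(sm[knee])


def background_filter(
    e: ExpressionMatrix,
    explicit_cutoff: Optional[float] = None,
    smooth_window: Optional[int] = None,
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop probes whose mean intensity lies below background.

    The cutoff is located automatically at the knee of the rank-ordered
    mean-intensity curve unless ``explicit_cutoff`` overrides it; a curve
    with no knee falls back to the explicit cutoff and errors without one.
    """
    mean_int = e.values.mean(axis=1)
    if explicit_cutoff is not None:
        cutoff = float(explicit_cutoff)
    else:
        cutoff = find_background_cutoff(mean_int, smooth_window)
    above = mean_int >= cutoff
    report = pd.DataFrame(
        {"mean_intensity": mean_int, "above_background": above, "retained": above},
        index=e.probes.index,
    )
    if not above.any():
        logger.warning("background_filter: cutoff %.3f removed every probe", cutoff)
    logger.info(
        "background_filter: cutoff %.4f, %d of %d probes retained",
        cutoff, int(above.sum()), e.n_probes,
    )
    return e.take_probes(above), report


def remove_snp_overlapping_probes(
    e: ExpressionMatrix, overlapping_probe_ids: Sequence[str]
) -> Tuple[ExpressionMatrix, pd.DataFrame]:
    """Drop probes whose target sequence overlays a genotyped SNP."""
    overlap = e.probes.index.isin(set(overlapping_probe_ids))
    report = pd.DataFrame(
        {"overlaps_snp": overlap, "retained": ~overlap}, index=e.probes.index
    )
    logger.info(
        "remove_snp_overlapping_probes: %d probes removed", int(overlap.sum())
    )
    return e.take_probes(~overlap), report


def average_technical_replicates(
    e: ExpressionMatrix, replicate_map: Dict[str, str]
) -> ExpressionMatrix:
    """Average replicate columns into one column per sample.

    ``replicate_map`` maps a column id to its canonical sample id; columns
    not named map to themselves.  Naming an absent column is an error.
    """
    absent = [c for c in replicate_map if c not in set(e.sample_ids)]
    if absent:
        raise ValueError(f"replicate map names absent columns: {absent}")
    canonical = [replicate_map.get(c, c) for c in e.sample_ids]
    seen: Dict[str, list] = {}
    order = []
    for idx, name in enumerate(canonical):
        if name not in seen:
            seen[name] = []
            order.append(name)
        seen[name].append(idx)
    values = np.column_stack(
        [e.values[:, seen[name]].mean(axis=1) for name in order]
    )
    return ExpressionMatrix(probes=e.probes, sample_ids=order, values=values)
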