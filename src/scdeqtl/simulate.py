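"""Synthetic SCD cohort generator with known ground truth.

Emulates the statistical structure the analysis models assume:

* genotypes — biallelic autosomal SNPs, founders drawn binomially at a MAF
  sampled per SNP (so HWE holds in founders), full-sib pairs generated by
  gene-dropping from two simulated parents, optional AR(1) copula LD on the
  latent gametes, per-call missingness;
* metadata — clinical statuses E / FU / Ctls, HbSS patients and HbAS/HbAA
  sibling controls (3:1 AS:AA), sex ~ Bernoulli(0.5), log-normal WBC/RBC
  counts with patient leukocytosis and anemia;
* expression — per-probe linear model
  ``intercept + Hb + ClinStatus + Sex + WBC·b + RBC·b + eSNP + interaction + noise``
  with the eSNP slope calibrated so its expected partial R² equals the
  configured target, and optional per-clinical-group allelic slopes.

Every random draw flows from ``config.seed``; regenerating with the same
config reproduces all outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    KinshipMatrix,
    METADATA_COLUMNS,
)

# sub-stream offsets so the three generators are independent yet reproducible
_GENO_STREAM = 0
_META_STREAM = 1
_EXPR_STREAM = 2
_CHROM_LENGTH_BP = 200_000_000


@dataclass
class GroundTruth:
    """What was planted, for recovery oracles.

    esnp_assignments rows: (probe_id, snp_id, class, true_slope, true_partial_r2).
    interaction_assignments rows: (probe_id, snp_id, {group: slope}).
    """

    esnp_assignments: List[Tuple[str, str, str, float, float]] = field(default_factory=list)
    interaction_assignments: List[Tuple[str, str, Dict[str, float]]] = field(default_factory=list)
    de_probes: set = field(default_factory=set)
    kinship_true: Optional[KinshipMatrix] = None

    def merged_with(self, other: "GroundTruth") -> "GroundTruth":
        return GroundTruth(
            esnp_assignments=self.esnp_assignments + other.esnp_assignments,
            interaction_assignments=(
                self.interaction_assignments + other.interaction_assignments
            ),
            de_probes=self.de_probes | other.de_probes,
            kinship_true=self.kinship_true or other.kinship_true,
        )


def _sample_ids(config: SimulationConfig) -> List[str]:
    return [f"S{i + 1:04d}" for i in range(config.n_samples)]


def _statuses(config: SimulationConfig) -> List[str]:
    return (
        ["E"] * config.n_patients_E
        + ["FU"] * config.n_patients_FU
        + ["Ctl"] * config.n_controls
    )


def family_structure(config: SimulationConfig) -> Tuple[List[str], List[Tuple[int, int]]]:
    """Deterministic sib-pair assignment shared by all generators.

    Pairs patients with controls first (the cohort's controls are healthy
    siblings of patients), then remaining patients with each other, then
    remaining controls.  Returns per-sample family ids and the index pairs.
    """
    n = config.n_samples
    n_pairs = int(np.floor(config.sibling_fraction * n / 2.0))
    n_pat = config.n_patients_E + config.n_patients_FU
    patients = list(range(n_pat))
    controls = list(range(n_pat, n))
    pairs: List[Tuple[int, int]] = []
    while len(pairs) < n_pairs and patients and controls:
        pairs.append((patients.pop(0), controls.pop(0)))
    while len(pairs) < n_pairs and len(patients) >= 2:
        pairs.append((patients.pop(0), patients.pop(0)))
    while len(pairs) < n_pairs and len(controls) >= 2:
        pairs.append((controls.pop(0), controls.pop(0)))
    family = [""] * n
    for k, (i, j) in enumerate(pairs):
        family[i] = family[j] = f"F{k + 1:04d}"
    singleton = len(pairs)
    for i in range(n):
        if not family[i]:
            singleton += 1
            family[i] = f"F{singleton:04d}"
    return family, pairs


def _haplotypes(rng, n_hap: int, mafs: np.ndarray, chroms: np.ndarray,
                ld_rho: float) -> np.ndarray:
    """n_hap x n_snps binary gametes; optional AR(1) Gaussian copula within
    each chromosome so adjacent SNPs are in LD."""
    s = len(mafs)
    if ld_rho == 0.0:
        return (rng.random((n_hap, s)) < mafs).astype(np.int8)
    z = np.empty((n_hap, s))
    innov = rng.standard_normal((n_hap, s))
    start = 0
    sqrt_term = np.sqrt(1.0 - ld_rho**2)
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        z[:, idx[0]] = innov[:, idx[0]]
        for a, b in zip(idx[:-1], idx[1:]):
            z[:, b] = ld_rho * z[:, a] + sqrt_term * innov[:, b]
        start += len(idx)
    thresh = stats.norm.ppf(mafs)
    return (z < thresh).astype(np.int8)


def simulate_genotypes(config: SimulationConfig) -> Tuple[GenotypeMatrix, GroundTruth]:
    """Simulate the genotype matrix and the true kinship ground truth.

    Founders' genotypes are binomial draws at a per-SNP MAF uniform on
    ``config.maf_range`` (HWE holds among founders); each sib pair is
    gene-dropped from two simulated parents; missing calls are masked at
    ``config.missing_rate``.
    """
    rng = np.random.default_rng(config.seed * 8 + _GENO_STREAM)
    n, s = config.n_samples, config.n_snps

    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=s)
    chroms = rng.integers(1, config.n_chromosomes + 1, size=s)
    positions = rng.integers(1, _CHROM_LENGTH_BP, size=s)
    order = np.lexsort((positions, chroms))
    mafs, chroms, positions = mafs[order], chroms[order], positions[order]
    snps = pd.DataFrame(
        {
            "chrom": [str(c) for c in chroms],
            "pos": positions.astype(int),
            "allele_minor": "B",
            "allele_major": "A",
        },
        index=pd.Index([f"snp{i + 1:05d}" for i in range(s)], name="snp_id"),
    )

    family, pairs = family_structure(config)
    in_pair = np.zeros(n, dtype=bool)
    for i, j in pairs:
        in_pair[i] = in_pair[j] = True

    dosage = np.zeros((n, s), dtype=float)
    founder_idx = np.flatnonzero(~in_pair)
    if len(founder_idx):
        haps = _haplotypes(rng, 2 * len(founder_idx), mafs, chroms, config.ld_rho)
        dosage[founder_idx] = haps[0::2] + haps[1::2]
    for i, j in pairs:
        parent_haps = _haplotypes(rng, 4, mafs, chroms, config.ld_rho)
        for child in (i, j):
            if config.ld_rho == 0.0:
                pat = np.where(rng.random(s) < 0.5, parent_haps[0], parent_haps[1])
                mat = np.where(rng.random(s) < 0.5, parent_haps[2], parent_haps[3])
            else:
                # no-recombination transmission: whole chromosomes, keeps LD
                pat = np.empty(s, dtype=np.int8)
                mat = np.empty(s, dtype=np.int8)
                for chrom in pd.unique(chroms):
                    idx = chroms == chrom
                    pat[idx] = parent_haps[rng.integers(0, 2), idx]
                    mat[idx] = parent_haps[2 + rng.integers(0, 2), idx]
            dosage[child] = pat + mat

    if config.missing_rate > 0:
        mask = rng.random((n, s)) < config.missing_rate
        dosage[mask] = np.nan

    kin = np.eye(n)
    for i, j in pairs:
        kin[i, j] = kin[j, i] = 0.5
    truth = GroundTruth(
        kinship_true=KinshipMatrix(sample_ids=_sample_ids(config), pihat=kin)
    )
    return GenotypeMatrix(sample_ids=_sample_ids(config), snps=snps, dosage=dosage), truth


# log-normal blood-count parameters (units 1e9/L WBC, 1e12/L RBC); patients
# show leukocytosis and anemia relative to sibling controls
_WBC_LOG_MEDIAN = {"patient": np.log(15.0), "control": np.log(7.5)}
_WBC_LOG_SD = 0.30
_RBC_LOG_MEDIAN = {"patient": np.log(2.8), "control": np.log(4.4)}
_RBC_LOG_SD = 0.15


def simulate_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the sample-metadata table (one row per child)."""
    rng = np.random.default_rng(config.seed * 8 + _META_STREAM)
    statuses = _statuses(config)
    family, _ = family_structure(config)
    n = config.n_samples
    is_patient = np.array([st != "Ctl" for st in statuses])

    sex = np.where(rng.random(n) < 0.5, "M", "F")
    # patients HbSS (optionally a compound-heterozygote HbSC fraction,
    # emulating the full cohort rather than the HbSS-only slice); controls
    # are three quarters HbAS carriers, one quarter HbAA
    patient_hb = np.where(rng.random(n) < config.hbsc_fraction, "HbSC", "HbSS")
    hb = np.where(
        is_patient,
        patient_hb,
        np.where(rng.random(n) < 0.75, "HbAS", "HbAA"),
    )
    wbc = np.exp(
        np.where(is_patient, _WBC_LOG_MEDIAN["patient"], _WBC_LOG_MEDIAN["control"])
        + _WBC_LOG_SD * rng.standard_normal(n)
    )
    rbc = np.exp(
        np.where(is_patient, _RBC_LOG_MEDIAN["patient"], _RBC_LOG_MEDIAN["control"])
        + _RBC_LOG_SD * rng.standard_normal(n)
    )
    phase = np.where(rng.random(n) < 0.5, "discovery", "replication")
    return pd.DataFrame(
        {
            "sample_id": _sample_ids(config),
            "family_id": family,
            "hb_genotype": hb,
            "clin_status": statuses,
            "sex": sex,
            "wbc": np.round(wbc, 3),
            "rbc": np.round(rbc, 3),
            "phase": phase,
        },
        columns=METADATA_COLUMNS,
    )


def esnp_slope(target_r2: float, noise_sd: float, dosage_sd: float) -> float:
    """Allelic slope giving expected partial R² = target against noise_sd.

    beta = sqrt(r2 / (1 - r2)) * sigma_noise / sigma_genotype.
    """
    if target_r2 <= 0 or dosage_sd <= 0:
        return 0.0
    return float(np.sqrt(target_r2 / (1.0 - target_r2)) * noise_sd / dosage_sd)


def simulate_expression(
    genotypes: GenotypeMatrix,
    metadata: pd.DataFrame,
    config: SimulationConfig,
) -> Tuple[ExpressionMatrix, GroundTruth]:
    """Simulate the probe x sample log2 expression matrix.

    Each probe follows the generative counterpart of the full ANCOVA model
    plus (for planted probes) an additive eSNP term and/or per-clinical-group
    allelic slopes; Gaussian noise has SD ``config.noise_sd``.
    """
    if list(metadata["sample_id"]) != list(genotypes.sample_ids):
        raise ValueError(
            "sample-id mismatch between genotype matrix and metadata; align first"
        )
    rng = np.random.default_rng(config.seed * 8 + _EXPR_STREAM)
    n, p = config.n_samples, config.n_probes
    if genotypes.n_snps == 0 and (config.n_local_esnps or config.n_distal_esnps
                                  or config.n_interaction_effects):
        raise ValueError("cannot plant eSNPs without SNPs")

    probe_ids = [f"probe{i + 1:05d}" for i in range(p)]
    probe_chrom = rng.integers(1, config.n_chromosomes + 1, size=p)
    probe_pos = rng.integers(1, _CHROM_LENGTH_BP, size=p)

    status = metadata["clin_status"].to_numpy()
    hb = metadata["hb_genotype"].to_numpy()
    sex = metadata["sex"].to_numpy()
    wbc = metadata["wbc"].to_numpy(dtype=float)
    rbc = metadata["rbc"].to_numpy(dtype=float)
    wbc_c = wbc - wbc.mean()
    rbc_c = rbc - rbc.mean()

    values = 8.0 + config.noise_sd * rng.standard_normal((p, n))
    truth = GroundTruth()

    # clinical-status effects on a de_fraction subset of probes
    n_de = int(round(config.de_fraction * p))
    de_idx = rng.choice(p, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    status_levels = ["E", "FU", "Ctl", "A"]
    status_onehot = {lv: (status == lv).astype(float) for lv in status_levels}
    for i in de_idx:
        offsets = {lv: config.clinstatus_effect_sd * rng.standard_normal()
                   for lv in status_levels}
        if config.clinstatus_effect_sd > 0:
            values[i] += sum(offsets[lv] * status_onehot[lv] for lv in status_levels)
            truth.de_probes.add(probe_ids[i])

    if config.hb_effect_sd > 0:
        hb_levels = pd.unique(hb)
        for i in range(p):
            for lv in hb_levels:
                values[i] += (config.hb_effect_sd * rng.standard_normal()) * (hb == lv)

    if config.sex_effect_sd > 0:
        male = (sex == "M").astype(float)
        values += np.outer(config.sex_effect_sd * rng.standard_normal(p), male)
    if config.wbc_slope_sd > 0:
        values += np.outer(config.wbc_slope_sd * rng.standard_normal(p), wbc_c)
    if config.rbc_slope_sd > 0:
        values += np.outer(config.rbc_slope_sd * rng.standard_normal(p), rbc_c)

    # planted eSNPs: first local (probe moved onto the SNP's chromosome),
    # then distal (probe moved off it)
    snp_chrom = genotypes.snps["chrom"].to_numpy()
    snp_pos = genotypes.snps["pos"].to_numpy()
    dosage_filled = genotypes.dosage.copy()
    if np.isnan(dosage_filled).any():
        col_mean = np.nanmean(dosage_filled, axis=0)
        nan_r, nan_c = np.where(np.isnan(dosage_filled))
        dosage_filled[nan_r, nan_c] = col_mean[nan_c]

    n_planted = config.n_local_esnps + config.n_distal_esnps
    planted_probes = (
        rng.choice(p, size=n_planted, replace=False) if n_planted else np.array([], dtype=int)
    )
    planted_snps = (
        rng.choice(genotypes.n_snps, size=n_planted, replace=(genotypes.n_snps < n_planted) if genotypes.n_snps else False)
        if n_planted else np.array([], dtype=int)
    )
    for k in range(n_planted):
        i, j = planted_probes[k], planted_snps[k]
        local = k < config.n_local_esnps
        if local:
            probe_chrom[i] = int(snp_chrom[j])
            probe_pos[i] = max(1, int(snp_pos[j]) + int(rng.integers(-500_000, 500_000)))
        else:
            others = [c for c in range(1, config.n_chromosomes + 1)
                      if str(c) != str(snp_chrom[j])]
            if not others:
                continue  # single-chromosome genome cannot host a distal pair
            probe_chrom[i] = int(rng.choice(others))
        g = dosage_filled[:, j]
        beta = esnp_slope(config.esnp_r2, config.noise_sd, g.std())
        values[i] += beta * (g - g.mean())
        truth.esnp_assignments.append(
            (probe_ids[i], genotypes.snp_ids[j], "local" if local else "distal",
             beta, config.esnp_r2)
        )

    # planted SNP-by-status interactions (extra allelic slope in FU), placed
    # on status-affected probes where possible so the DE screen retains them
    if config.n_interaction_effects:
        pool = [i for i in de_idx if i not in set(planted_probes)]
        if len(pool) < config.n_interaction_effects:
            pool += [i for i in range(p)
                     if i not in set(planted_probes) and i not in set(pool)]
        chosen = np.array(pool[: config.n_interaction_effects], dtype=int)
        snp_choice = rng.choice(genotypes.n_snps, size=len(chosen),
                                replace=genotypes.n_snps < len(chosen))
        groups_present = [lv for lv in ("E", "FU", "Ctl", "A") if (status == lv).any()]
        boosted = "FU" if "FU" in groups_present else groups_present[0]
        for i, j in zip(chosen, snp_choice):
            probe_chrom[i] = int(snp_chrom[j])  # local interaction eSNP
            g = dosage_filled[:, j]
            slopes = {lv: 0.0 for lv in groups_present}
            slopes[boosted] = config.interaction_delta
            for lv in groups_present:
                values[i] += slopes[lv] * (g - g.mean()) * status_onehot[lv]
            truth.interaction_assignments.append(
                (probe_ids[i], genotypes.snp_ids[j], slopes)
            )
            if config.clinstatus_effect_sd > 0 and probe_ids[i] in truth.de_probes:
                pass  # already DE; otherwise the screen may drop it by design

    probes = pd.DataFrame(
        {
            "gene_symbol": [f"GENE{i + 1}" for i in range(p)],
            "chrom": [str(c) for c in probe_chrom],
            "pos": probe_pos.astype(int),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    expr = ExpressionMatrix(
        probes=probes, sample_ids=list(genotypes.sample_ids), values=values
    )
    return expr, truth


def simulate_cohort(
    config: SimulationConfig,
) -> Tuple[GenotypeMatrix, ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Generate the aligned genotype / expression / metadata triple."""
    geno, truth_g = simulate_genotypes(config)
    meta = simulate_metadata(config)
    expr, truth_e = simulate_expression(geno, meta, config)
    return geno, expr, meta, truth_g.merged_with(truth_e)
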