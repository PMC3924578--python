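"""In-memory containers for the three data matrices and derived objects.

Conventions
-----------
* Genotype dosages are minor-allele counts in {0, 1, 2}; missing calls are
  ``NaN`` in a float array (a distinct sentinel — never silently imputed).
* Coordinates are 1-based inclusive; chromosome labels are strings and are
  normalized so that ``"chr1"`` compares equal to ``"1"``.
* Expression values are log2 intensities, probes x samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

HB_GENOTYPES = ("HbSS", "HbSC", "HbAS", "HbAA")
CLIN_STATUSES = ("E", "FU", "A", "Ctl")
METADATA_COLUMNS = [
    "sample_id", "family_id", "hb_genotype", "clin_status",
    "sex", "wbc", "rbc", "phase",
]


def normalize_chrom(label) -> str:
    """Normalize a chromosome label: 'chr1', ' 1 ', 1 -> '1'."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


@dataclass
class SampleRecord:
    """One child's phenotypic and clinical covariates."""

    sample_id: str
    family_id: str
    hb_genotype: str
    clin_status: str
    sex: str
    wbc: float
    rbc: float
    phase: str = "NA"

    def __post_init__(self) -> None:
        if self.hb_genotype not in HB_GENOTYPES:
            raise ValueError(f"{self.sample_id}: unknown hb_genotype {self.hb_genotype!r}")
        if self.clin_status not in CLIN_STATUSES:
            raise ValueError(f"{self.sample_id}: unknown clin_status {self.clin_status!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.sample_id}: sex must be 'M' or 'F'")
        if not (self.wbc > 0 and self.rbc > 0):
            raise ValueError(f"{self.sample_id}: wbc and rbc must be strictly positive")
        # Controls carry at least one normal beta-globin allele; patients are HbSS/HbSC.
        is_carrier = self.hb_genotype in ("HbAS", "HbAA")
        if is_carrier != (self.clin_status == "Ctl"):
            raise ValueError(
                f"{self.sample_id}: hb_genotype {self.hb_genotype} inconsistent "
                f"with clin_status {self.clin_status}"
            )


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [[r.sample_id, r.family_id, r.hb_genotype, r.clin_status,
          r.sex, r.wbc, r.rbc, r.phase] for r in records],
        columns=METADATA_COLUMNS,
    )


def frame_to_records(meta: pd.DataFrame) -> List[SampleRecord]:
    return [
        SampleRecord(
            sample_id=str(row.sample_id), family_id=str(row.family_id),
            hb_genotype=str(row.hb_genotype), clin_status=str(row.clin_status),
            sex=str(row.sex), wbc=float(row.wbc), rbc=float(row.rbc),
            phase=str(row.phase),
        )
        for row in meta.itertuples(index=False)
    ]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosages plus a SNP map.

    ``snps`` is indexed by snp_id with columns ``chrom`` (normalized string),
    ``pos`` (1-based int), ``allele_minor``, ``allele_major``.
    """

    sample_ids: List[str]
    snps: pd.DataFrame
    dosage: np.ndarray  # float, NaN = missing

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, s = self.dosage.shape
        if n != len(self.sample_ids):
            raise ValueError("dosage rows must match sample_ids")
        if s != len(self.snps):
            raise ValueError("dosage columns must match snp map")
        if self.snps.index.has_duplicates:
            raise ValueError("duplicate snp_ids")
        self.snps = self.snps.copy()
        self.snps["chrom"] = [normalize_chrom(c) for c in self.snps["chrom"]]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> List[str]:
        return list(self.snps.index)

    def take_samples(self, order: Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(order)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            snps=self.snps,
            dosage=self.dosage[idx],
        )

    def take_snps(self, mask_or_idx) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_idx)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snps=self.snps.iloc[arr],
            dosage=self.dosage[:, arr],
        )


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities plus probe annotation.

    ``probes`` is indexed by probe_id with columns ``gene_symbol``,
    ``chrom`` (normalized string; empty string = unannotated), ``pos``.
    """

    probes: pd.DataFrame
    sample_ids: List[str]
    values: np.ndarray  # probes x samples

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p, n = self.values.shape
        if p != len(self.probes):
            raise ValueError("values rows must match probe annotation")
        if n != len(self.sample_ids):
            raise ValueError("values columns must match sample_ids")
        if self.probes.index.has_duplicates:
            raise ValueError("duplicate probe_ids")
        self.probes = self.probes.copy()
        self.probes["chrom"] = [
            normalize_chrom(c) if str(c) not in ("", "nan", "None", "NA") else ""
            for c in self.probes["chrom"]
        ]

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def probe_ids(self) -> List[str]:
        return list(self.probes.index)

    def take_samples(self, order: Sequence[int]) -> "ExpressionMatrix":
        idx = np.asarray(order)
        return ExpressionMatrix(
            probes=self.probes,
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
        )

    def take_probes(self, mask_or_idx) -> "ExpressionMatrix":
        arr = np.asarray(mask_or_idx)
        if arr.dtype == bool:
            arr = np.flatnonzero(arr)
        return ExpressionMatrix(
            probes=self.probes.iloc[arr],
            sample_ids=list(self.sample_ids),
            values=self.values[arr],
        )


@dataclass
class KinshipMatrix:
    """Symmetric pairwise relatedness (pi-hat) with unit diagonal."""

    sample_ids: List[str]
    pihat: np.ndarray

    def __post_init__(self) -> None:
        self.pihat = np.asarray(self.pihat, dtype=float)
        n = len(self.sample_ids)
        if self.pihat.shape != (n, n):
            raise ValueError("pihat must be square over sample_ids")
        finite = np.isfinite(self.pihat)
        if not np.allclose(
            np.where(finite, self.pihat, 0.0),
            np.where(finite.T, self.pihat.T, 0.0),
            atol=1e-10,
        ):
            raise ValueError("pihat must be symmetric")
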