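"""Readers/writers for the on-disk formats and cohort alignment.

Formats
-------
* PLINK .ped/.map (space-delimited, 6 leading ped columns, missing "0 0");
* genotype TSV: rows = SNPs (snp_id, chrom, pos, allele_minor, allele_major),
  columns = samples, dosages 0/1/2 with NA for missing;
* expression TSV: rows = probes (probe_id, gene_symbol, chrom, pos),
  columns = samples, log2 intensities;
* metadata TSV with the fixed column set
  sample_id, family_id, hb_genotype, clin_status, sex, wbc, rbc, phase;
* ground-truth sidecar as JSON.

Every filter and alignment step logs before/after counts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    KinshipMatrix,
    METADATA_COLUMNS,
)
from .simulate import GroundTruth

logger = logging.getLogger("scdeqtl")


class ParseError(ValueError):
    """A file failed to parse; the message carries the line number."""


# ---------------------------------------------------------------------------
# genotypes


def write_pedmap(g: GenotypeMatrix, prefix: str,
                 family_ids: Optional[Sequence[str]] = None) -> None:
    """Write PLINK .ped/.map; dosage 2 -> two minor alleles, NaN -> '0 0'."""
    prefix = str(prefix)
    with open(prefix + ".map", "w") as fh:
        for snp_id, row in g.snps.iterrows():
            fh.write(f"{row['chrom']} {snp_id} 0 {int(row['pos'])}\n")
    minor = g.snps["allele_minor"].to_numpy()
    major = g.snps["allele_major"].to_numpy()
    fams = list(family_ids) if family_ids is not None else list(g.sample_ids)
    with open(prefix + ".ped", "w") as fh:
        for i, sid in enumerate(g.sample_ids):
            fields = [fams[i], sid, "0", "0", "0", "-9"]
            for j in range(g.n_snps):
                d = g.dosage[i, j]
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [major[j], major[j]]
                elif d == 1:
                    fields += [major[j], minor[j]]
                else:
                    fields += [minor[j], minor[j]]
            fh.write(" ".join(fields) + "\n")


def read_pedmap(prefix: str) -> GenotypeMatrix:
    """Read PLINK .ped/.map, orienting dosage to the data's minor allele.

    On an exact 50/50 allele-frequency tie the lexicographically larger
    allele code is called minor (so A/B data keep B as minor).
    """
    prefix = str(prefix)
    map_rows = []
    with open(prefix + ".map") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ParseError(f"{prefix}.map line {ln}: expected 4 fields")
            map_rows.append((parts[0], parts[1], int(parts[3])))
    if not map_rows:
        raise ParseError(f"{prefix}.map: no SNPs defined")
    n_snps = len(map_rows)

    sample_ids: List[str] = []
    family_ids: List[str] = []
    allele_rows: List[np.ndarray] = []
    with open(prefix + ".ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ParseError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * n_snps} fields, "
                    f"got {len(parts)}"
                )
            family_ids.append(parts[0])
            sample_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype=object).reshape(n_snps, 2))
    alleles = np.array(allele_rows, dtype=object)  # samples x snps x 2

    dosage = np.full((len(sample_ids), n_snps), np.nan)
    minor_alleles, major_alleles = [], []
    for j in range(n_snps):
        col = alleles[:, j, :]
        called = col[col != "0"]
        codes, counts = np.unique(called, return_counts=True)
        if len(codes) > 2:
            raise ParseError(
                f"{prefix}.ped: SNP {map_rows[j][1]} has >2 allele codes: {list(codes)}"
            )
        if len(codes) == 0:
            minor_alleles.append("B")
            major_alleles.append("A")
            continue
        if len(codes) == 1:
            major, minor = codes[0], "B" if codes[0] != "B" else "A"
        else:
            order = np.lexsort((codes, counts))  # by count, tie -> code order
            minor, major = codes[order[0]], codes[order[1]]
        minor_alleles.append(str(minor))
        major_alleles.append(str(major))
        missing = (col == "0").any(axis=1)
        dosage[:, j] = np.where(missing, np.nan, (col == minor).sum(axis=1))

    snps = pd.DataFrame(
        {
            "chrom": [r[0] for r in map_rows],
            "pos": [r[2] for r in map_rows],
            "allele_minor": minor_alleles,
            "allele_major": major_alleles,
        },
        index=pd.Index([r[1] for r in map_rows], name="snp_id"),
    )
    return GenotypeMatrix(sample_ids=sample_ids, snps=snps, dosage=dosage)


def write_genotypes_tsv(g: GenotypeMatrix, path: str) -> None:
    df = g.snps.copy()
    dos = g.dosage.T  # snps x samples
    body = pd.DataFrame(dos, index=df.index, columns=g.sample_ids)
    out = pd.concat([df, body], axis=1)
    out.to_csv(path, sep="\t", na_rep="NA", index_label="snp_id")


def read_genotypes_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="snp_id", dtype={"chrom": str})
    anno_cols = ["chrom", "pos", "allele_minor", "allele_major"]
    missing_cols = [c for c in anno_cols if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing annotation columns {missing_cols}")
    sample_cols = [c for c in df.columns if c not in anno_cols]
    dosage = df[sample_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(
        sample_ids=sample_cols, snps=df[anno_cols], dosage=dosage
    )


def read_genotypes(path: str, dialect: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix (``dialect`` = 'pedmap' prefix or 'tsv')."""
    if dialect == "pedmap":
        return read_pedmap(path)
    if dialect == "tsv":
        return read_genotypes_tsv(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


# ---------------------------------------------------------------------------
# expression / metadata


def write_expression_tsv(e: ExpressionMatrix, path: str) -> None:
    body = pd.DataFrame(e.values, index=e.probes.index, columns=e.sample_ids)
    out = pd.concat([e.probes, body], axis=1)
    out.to_csv(path, sep="\t", na_rep="NA", index_label="probe_id")


def read_expression_tsv(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="probe_id", dtype={"chrom": str})
    anno_cols = [c for c in ("gene_symbol", "chrom", "pos") if c in df.columns]
    sample_cols = [c for c in df.columns if c not in anno_cols]
    probes = df[anno_cols].copy()
    for c in ("gene_symbol", "chrom", "pos"):
        if c not in probes.columns:
            probes[c] = "" if c != "pos" else 0
    probes["chrom"] = probes["chrom"].fillna("")
    return ExpressionMatrix(
        probes=probes[["gene_symbol", "chrom", "pos"]],
        sample_ids=sample_cols,
        values=df[sample_cols].to_numpy(dtype=float),
    )


def write_metadata_tsv(meta: pd.DataFrame, path: str) -> None:
    meta[METADATA_COLUMNS].to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str})
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise ParseError(f"{path}: missing metadata columns {missing}")
    return meta[METADATA_COLUMNS]


# ---------------------------------------------------------------------------
# ground truth sidecar


def write_ground_truth(truth: GroundTruth, path: str) -> None:
    payload = {
        "esnp_assignments": [list(t) for t in truth.esnp_assignments],
        "interaction_assignments": [
            [pid, sid, slopes] for pid, sid, slopes in truth.interaction_assignments
        ],
        "de_probes": sorted(truth.de_probes),
    }
    if truth.kinship_true is not None:
        kin = truth.kinship_true
        iu = np.triu_indices(len(kin.sample_ids), k=1)
        nz = kin.pihat[iu] != 0
        payload["kinship"] = {
            "sample_ids": kin.sample_ids,
            "related_pairs": [
                [int(i), int(j), float(kin.pihat[i, j])]
                for i, j in zip(iu[0][nz], iu[1][nz])
            ],
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_ground_truth(path: str) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    truth = GroundTruth(
        esnp_assignments=[tuple(t) for t in payload["esnp_assignments"]],
        interaction_assignments=[
            (pid, sid, slopes)
            for pid, sid, slopes in payload["interaction_assignments"]
        ],
        de_probes=set(payload["de_probes"]),
    )
    if "kinship" in payload:
        ids = payload["kinship"]["sample_ids"]
        mat = np.eye(len(ids))
        for i, j, v in payload["kinship"]["related_pairs"]:
            mat[i, j] = mat[j, i] = v
        truth.kinship_true = KinshipMatrix(sample_ids=ids, pihat=mat)
    return truth


# ---------------------------------------------------------------------------
# alignment and cohort slicing


def align_cohort(
    g: GenotypeMatrix, e: ExpressionMatrix, meta: pd.DataFrame
) -> Tuple[GenotypeMatrix, ExpressionMatrix, pd.DataFrame]:
    """Restrict all three inputs to their common samples, in metadata order."""
    common = [
        sid for sid in meta["sample_id"]
        if sid in set(g.sample_ids) and sid in set(e.sample_ids)
    ]
    if not common:
        raise ValueError("no samples shared by genotypes, expression and metadata")
    for name, total in (("genotypes", g.n_samples), ("expression", e.n_samples),
                        ("metadata", len(meta))):
        dropped = total - len(common)
        if dropped:
            logger.info("align_cohort: dropped %d of %d %s samples", dropped, total, name)
    g_pos = {sid: i for i, sid in enumerate(g.sample_ids)}
    e_pos = {sid: i for i, sid in enumerate(e.sample_ids)}
    g2 = g.take_samples([g_pos[s] for s in common])
    e2 = e.take_samples([e_pos[s] for s in common])
    m2 = meta.set_index("sample_id").loc[common].reset_index()[METADATA_COLUMNS]
    return g2, e2, m2


SUBSET_RULES = ("discovery", "replication", "combined_I", "combined_II")


def subset_dataset(meta: pd.DataFrame, rule: str) -> List[str]:
    """Sample ids for a named cohort slice.

    combined_II keeps HbSS patients at steady state (status E or FU,
    excluding acute crises) plus all controls; combined_I keeps everyone;
    discovery / replication select on the sampling phase.
    """
    if rule not in SUBSET_RULES:
        raise ValueError(f"unknown subset rule {rule!r}; expected one of {SUBSET_RULES}")
    if rule == "combined_I":
        keep = pd.Series(True, index=meta.index)
    elif rule == "combined_II":
        patient = (meta["hb_genotype"] == "HbSS") & meta["clin_status"].isin(["E", "FU"])
        if not patient.any():
            logger.warning("subset combined_II: no steady-state HbSS patients present")
        keep = patient | (meta["clin_status"] == "Ctl")
    else:
        keep = meta["phase"] == rule
    logger.info("subset %s: %d of %d samples kept", rule, int(keep.sum()), len(meta))
    return list(meta.loc[keep, "sample_id"])


def write_cohort(out_dir: str, g: GenotypeMatrix, e: ExpressionMatrix,
                 meta: pd.DataFrame, truth: Optional[GroundTruth] = None) -> None:
    """Write the full simulated cohort in all supported dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fam = meta.set_index("sample_id")["family_id"].reindex(g.sample_ids).fillna("0")
    write_pedmap(g, str(out / "genotypes"), family_ids=list(fam))
    write_genotypes_tsv(g, str(out / "genotypes.tsv"))
    write_expression_tsv(e, str(out / "expression.tsv"))
    write_metadata_tsv(meta, str(out / "metadata.tsv"))
    if truth is not None:
        write_ground_truth(truth, str(out / "ground_truth.json"))
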