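"""Readers and writers for the standard interchange formats.

Coordinates are converted to the package's 1-based inclusive convention at
this boundary: BED input (0-based half-open) has 1 added to its start; GTF
and VCF are already 1-based.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypePanel, GWASSummary, ModelDB, SNPMap, TranscriptomeAnnotation, WeightModel

__all__ = [
    "read_vcf",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "read_bed_blocks",
    "read_gwas_tsv",
    "write_gwas_tsv",
    "read_gtf_annotation",
    "write_model_db_tsv",
    "read_model_db_tsv",
    "write_model_db_cache",
    "read_model_db_cache",
]

GWAS_COLUMNS = ["snp_id", "chrom", "pos", "a_ref", "a_alt", "beta", "se", "z", "n"]


def read_vcf(path: str | Path) -> GenotypePanel:
    """Load a biallelic-SNP VCF into a dosage panel (GT preferred, DS fallback)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, dosage_cols = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        if np.all(gts == 2):  # no GT calls: fall back to DS
            ds = var.format("DS")
            if ds is None:
                continue
            dos = np.asarray(ds, dtype=float).reshape(-1)
        else:
            dos = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts))
            if np.isnan(dos).any():  # mean-impute missing calls
                dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
        rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "allele_ref": var.REF,
                "allele_alt": var.ALT[0],
            }
        )
        dosage_cols.append(dos)
    if not rows:
        raise ValueError(f"no biallelic SNPs in {path}")
    snp_map = SNPMap(pd.DataFrame(rows))
    return GenotypePanel(np.column_stack(dosage_cols), snp_map, samples)


def write_genotype_tsv(panel: GenotypePanel, matrix_path: str | Path, map_path: str | Path) -> None:
    """Plain-TSV dialect: matrix rows=individuals, cols=snp_ids; map alongside."""
    df = pd.DataFrame(panel.dosages, index=panel.sample_ids, columns=panel.snp_map.snp_ids)
    df.to_csv(matrix_path, sep="\t", index_label="sample_id")
    panel.snp_map.table.to_csv(map_path, sep="\t", index=False)


def read_genotype_tsv(matrix_path: str | Path, map_path: str | Path) -> GenotypePanel:
    df = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    snp_map = SNPMap(pd.read_csv(map_path, sep="\t", dtype={"chrom": str}))
    if list(df.columns) != list(snp_map.snp_ids):
        df = df[list(snp_map.snp_ids)]
    return GenotypePanel(df.to_numpy(dtype=float), snp_map, list(df.index.astype(str)))


def read_bed_blocks(path: str | Path) -> pd.DataFrame:
    """Read BED intervals (0-based half-open) as 1-based inclusive blocks."""
    bed = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
    )
    out = pd.DataFrame(
        {"chrom": bed["chrom"].astype(str), "start": bed["start"] + 1, "end": bed["end"]}
    )
    if (out["end"] < out["start"]).any():
        raise ValueError("malformed BED interval (end < start)")
    return out


def write_gwas_tsv(gwas: GWASSummary, path: str | Path) -> None:
    t = gwas.table.rename(columns={"allele_ref": "a_ref", "allele_alt": "a_alt"})
    for col in GWAS_COLUMNS:
        if col not in t.columns:
            t[col] = np.nan
    t[GWAS_COLUMNS].to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str | Path) -> GWASSummary:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    t = t.rename(columns={"a_ref": "allele_ref", "a_alt": "allele_alt"})
    return GWASSummary(t)


def _gtf_attributes(attr: str) -> dict[str, str]:
    out = {}
    for field in attr.strip().split(";"):
        field = field.strip()
        if not field:
            continue
        key, _, val = field.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gtf_annotation(path: str | Path) -> TranscriptomeAnnotation:
    """Read gene/transcript feature lines of a GTF into an annotation.

    The TSS is the strand-aware 5' end of each feature (start on '+',
    end on '-'); gene TSS is taken from the gene line.
    """
    genes, transcripts = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _, feature, start, end, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "transcript"):
                continue
            a = _gtf_attributes(attrs)
            start_i, end_i = int(start), int(end)
            tss = start_i if strand == "+" else end_i
            if feature == "gene":
                genes.append(
                    {
                        "gene_id": a["gene_id"],
                        "chrom": str(chrom),
                        "strand": strand,
                        "gene_start": start_i,
                        "gene_end": end_i,
                        "tss": tss,
                    }
                )
            else:
                transcripts.append(
                    {"transcript_id": a["transcript_id"], "gene_id": a["gene_id"], "tss": tss}
                )
    if not genes:
        raise ValueError(f"no gene lines in {path}")
    return TranscriptomeAnnotation(pd.DataFrame(genes), pd.DataFrame(transcripts))


def write_model_db_tsv(db: ModelDB, path: str | Path) -> None:
    """Long-format TSV: one row per (feature, SNP) nonzero weight."""
    rows = []
    for (fid, level), m in sorted(db.models.items()):
        nz = np.flatnonzero(m.weights)
        if len(nz) == 0:
            rows.append(
                {
                    "feature_id": fid, "level": level, "gene_id": m.gene_id or "",
                    "snp_id": "", "weight": 0.0, "cv_r2": m.cv_r2,
                    "family": m.family, "n_train": m.n_train,
                    "retained": db.retained.get((fid, level), False),
                }
            )
        for j in nz:
            rows.append(
                {
                    "feature_id": fid, "level": level, "gene_id": m.gene_id or "",
                    "snp_id": m.snp_ids[j], "weight": m.weights[j], "cv_r2": m.cv_r2,
                    "family": m.family, "n_train": m.n_train,
                    "retained": db.retained.get((fid, level), False),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_model_db_tsv(path: str | Path) -> ModelDB:
    t = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    db = ModelDB()
    for (fid, level), grp in t.groupby(["feature_id", "level"], sort=False):
        nz = grp[grp["snp_id"] != ""]
        model = WeightModel(
            feature_id=fid,
            level=level,
            snp_ids=nz["snp_id"].to_numpy(),
            weights=nz["weight"].to_numpy(dtype=float),
            cv_r2=float(grp["cv_r2"].iloc[0]),
            family=str(grp["family"].iloc[0]),
            n_train=int(grp["n_train"].iloc[0]),
            gene_id=str(grp["gene_id"].iloc[0]) or None,
        )
        db.add(model)
        db.retained[(fid, level)] = bool(grp["retained"].iloc[0] in (True, "True", "true", 1))
    return db


def write_model_db_cache(db: ModelDB, path: str | Path) -> None:
    """Binary cache (npz) for fast reload of large model collections."""
    payload = {}
    meta = []
    for i, ((fid, level), m) in enumerate(sorted(db.models.items())):
        payload[f"snp_ids_{i}"] = np.asarray(m.snp_ids, dtype=str)
        payload[f"weights_{i}"] = m.weights
        meta.append(
            (fid, level, m.gene_id or "", repr(m.cv_r2), m.family, str(m.n_train),
             str(db.retained.get((fid, level), False)))
        )
    payload["meta"] = np.asarray(meta, dtype=str)
    np.savez_compressed(path, **payload)


def read_model_db_cache(path: str | Path) -> ModelDB:
    with np.load(path, allow_pickle=False) as z:
        meta = z["meta"]
        db = ModelDB()
        for i, (fid, level, gene_id, cv_r2, family, n_train, retained) in enumerate(meta):
            m = WeightModel(
                feature_id=str(fid),
                level=str(level),
                snp_ids=z[f"snp_ids_{i}"],
                weights=z[f"weights_{i}"],
                cv_r2=float(cv_r2),
                family=str(family),
                n_train=int(n_train),
                gene_id=str(gene_id) or None,
            )
            db.add(m)
            db.retained[(str(fid), str(level))] = retained == "True"
    return db
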