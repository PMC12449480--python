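"""Shared loading helpers for the numbered analysis drivers."""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from twaskit import io as tio
from twaskit.types import ExpressionSet, TranscriptomeAnnotation

RESULTS = Path(__file__).resolve().parent.parent / "results" / "study"


def parse_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--dir", type=str, default=str(RESULTS))
    return ap.parse_args()


def study_dir(args) -> Path:
    d = Path(args.dir)
    d.mkdir(parents=True, exist_ok=True)
    return d


def write_expression(expr: ExpressionSet, path: Path) -> None:
    pd.DataFrame(expr.values, columns=expr.feature_ids).to_csv(path, sep="\t", index=False)


def read_expression(path: Path, level: str, covariates=None) -> ExpressionSet:
    df = pd.read_csv(path, sep="\t")
    return ExpressionSet(df.to_numpy(float), list(df.columns), level, covariates)


def write_annotation(anno: TranscriptomeAnnotation, d: Path) -> None:
    anno.genes.to_csv(d / "genes.tsv", sep="\t", index=False)
    anno.transcripts.to_csv(d / "transcripts.tsv", sep="\t", index=False)


def read_annotation(d: Path) -> TranscriptomeAnnotation:
    return TranscriptomeAnnotation(
        pd.read_csv(d / "genes.tsv", sep="\t", dtype={"chrom": str}),
        pd.read_csv(d / "transcripts.tsv", sep="\t"),
    )


def load_cohort(d: Path):
    panel = tio.read_genotype_tsv(d / "genotypes.tsv", d / "snp_map.tsv")
    anno = read_annotation(d)
    cov = pd.read_csv(d / "covariates.tsv", sep="\t").to_numpy(float)
    iso = read_expression(d / "expression_isoform.tsv", "isoform", cov)
    gene = read_expression(d / "expression_gene.tsv", "gene", cov)
    gwas = tio.read_gwas_tsv(d / "gwas.tsv")
    meta = json.loads((d / "cohort_meta.json").read_text())
    return panel, anno, iso, gene, gwas, meta
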