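#!/usr/bin/env python
"""Weighted burden association of predicted expression with the GWAS trait,
two-stage multiple testing for isoforms, BH-FDR for genes, and the
10,000-draw permutation filter for significant features."""

import pandas as pd

from _common import load_cohort, parse_args, study_dir
from twaskit import io as tio
from twaskit.assoc import (
    DegenerateModelError,
    burden_test,
    fdr_adjust,
    harmonize_gwas,
    is_significant,
    permutation_test,
    two_stage_adjust,
)
from twaskit.syndata import estimate_ld


def records_frame(records):
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in records],
            "gene_id": [r.gene_id for r in records],
            "level": [r.level for r in records],
            "z": [r.z_assoc for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_screen": [r.p_gene_screen for r in records],
            "p_fwer": [r.p_fwer_within for r in records],
            "p_fdr": [r.p_fdr for r in records],
            "p_perm": [r.p_perm for r in records],
            "chisq": [r.chisq for r in records],
            "significant": [is_significant(r) for r in records],
        }
    )


def main() -> None:
    args = parse_args(__doc__)
    out = study_dir(args)
    panel, anno, iso, gene, gwas, meta = load_cohort(out)
    gwas = harmonize_gwas(gwas, panel.snp_map, drop_ambiguous=False)
    ld = estimate_ld(panel)
    db = tio.read_model_db_tsv(out / "models.tsv")
    recs = {"gene": [], "isoform": []}
    for level in recs:
        for m in db.by_level(level, retained_only=True):
            try:
                recs[level].append(burden_test(m, gwas, ld))
            except DegenerateModelError:
                continue
    fdr_adjust(recs["gene"])
    two_stage_adjust(recs["isoform"])
    n_perm = 0
    for level, rr in recs.items():
        for r in rr:
            if is_significant(r):
                r.p_perm = permutation_test(
                    db.get(r.feature_id, level), gwas, ld, B=10_000, seed=meta["stage_seeds"][5]
                )
                n_perm += 1
    for level, rr in recs.items():
        frame = records_frame(rr)
        frame.to_csv(out / f"assoc_{level}.tsv", sep="\t", index=False)
        print(f"{level}: {int(frame['significant'].sum())}/{len(frame)} significant")
    print(f"permutation filter applied to {n_perm} features")


if __name__ == "__main__":
    main()
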