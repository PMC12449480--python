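#!/usr/bin/env python
"""Residualize expression on covariates and train the cross-validated cis
weight models at both gene and isoform level; report retention at the
CV R2 > 0.01 rule."""

from pathlib import Path

from _common import load_cohort, parse_args, study_dir
from twaskit import io as tio
from twaskit.expr_models import residualize_expression, train_models


def main() -> None:
    args = parse_args(__doc__)
    out = study_dir(args)
    panel, anno, iso, gene, _, meta = load_cohort(out)
    iso_res = residualize_expression(iso)
    gene_res = residualize_expression(gene)
    db = train_models(panel, iso_res, gene_res, anno, k_folds=10, seed=meta["stage_seeds"][4])
    for level in ("gene", "isoform"):
        total = len(db.by_level(level))
        kept = len(db.by_level(level, retained_only=True))
        print(f"{level}: {kept}/{total} models retained (CV R2 > 0.01)")
    tio.write_model_db_tsv(db, out / "models.tsv")
    print(f"models written to {out / 'models.tsv'}")


if __name__ == "__main__":
    main()
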