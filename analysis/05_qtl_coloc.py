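#!/usr/bin/env python
"""Map cis-QTLs by OLS (TSS +/- 1 Mb) for genes and isoforms, then
colocalize each significant feature's QTL signal with the GWAS (CLPP and
the three-condition rule)."""

import numpy as np
import pandas as pd
from scipy import stats

from _common import load_cohort, parse_args, study_dir
from twaskit.assoc import harmonize_gwas
from twaskit.expr_models import residualize_expression
from twaskit.qtl_coloc import colocalize_feature, map_cis_qtl
from twaskit.syndata import estimate_ld


def main() -> None:
    args = parse_args(__doc__)
    out = study_dir(args)
    panel, anno, iso, gene, gwas, _ = load_cohort(out)
    gwas = harmonize_gwas(gwas, panel.snp_map, drop_ambiguous=False)
    ld = estimate_ld(panel)
    qtl = {
        "isoform": map_cis_qtl(panel, residualize_expression(iso), anno),
        "gene": map_cis_qtl(panel, residualize_expression(gene), anno),
    }
    pd.concat(
        [qtl["gene"].assign(level="gene"), qtl["isoform"].assign(level="isoform")],
        ignore_index=True,
    ).to_csv(out / "qtl.tsv", sep="\t", index=False)

    gwas_t = gwas.table.set_index("snp_id")
    gwas_p = pd.Series(2.0 * stats.norm.sf(np.abs(gwas_t["z"])), index=gwas_t.index)
    ld_index = {s: i for i, s in enumerate(ld.snp_ids)}
    rows = []
    for level in ("gene", "isoform"):
        assoc = pd.read_csv(out / f"assoc_{level}.tsv", sep="\t")
        for _, arow in assoc[assoc["significant"]].iterrows():
            sub = qtl[level][qtl[level]["feature_id"] == arow["feature_id"]]
            snps = [s for s in sub["snp_id"] if s in ld_index]
            if len(snps) < 2:
                continue
            sub = sub.set_index("snp_id").loc[snps]
            idx = [ld_index[s] for s in snps]
            res = colocalize_feature(
                arow["feature_id"], str(arow["gene_id"]),
                gwas_t.loc[snps, "z"].to_numpy(), gwas_p.loc[snps].to_numpy(),
                (sub["beta"] / sub["se"]).to_numpy(), sub["p"].to_numpy(),
                ld.r[np.ix_(idx, idx)],
            )
            rows.append(
                {"locus_id": res.locus_id, "feature_id": res.feature_id, "level": level,
                 "clpp": res.clpp, "gwas_min_p": res.gwas_min_p, "qtl_min_p": res.qtl_min_p,
                 "colocalized": res.colocalized}
            )
    coloc = pd.DataFrame(
        rows, columns=["locus_id", "feature_id", "level", "clpp", "gwas_min_p", "qtl_min_p", "colocalized"]
    )
    coloc.to_csv(out / "coloc.tsv", sep="\t", index=False)
    for level in ("gene", "isoform"):
        sub = coloc[coloc["level"] == level]
        if len(sub):
            print(
                f"{level}: {int(sub['colocalized'].sum())}/{len(sub)} features colocalized, "
                f"median CLPP = {sub['clpp'].median():.3g}"
            )


if __name__ == "__main__":
    main()
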