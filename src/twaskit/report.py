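"""Locus definitions, discovery tallies, and the comparison statistics that
summarize an isoform-level vs gene-level association study: independent
GWAS loci, locus tagging by each method, percent-increase arithmetic, and
2x2 enrichment tests (e.g., of strongly constrained genes, s_het > 0.1,
among each method's significant genes).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .types import AssociationRecord, GWASLocus, GWASSummary, TranscriptomeAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "define_gwas_loci",
    "tag_loci",
    "percent_increase",
    "proportion_enrichment_test",
    "SHET_THRESHOLD",
]

SHET_THRESHOLD = 0.1  # published cutoff for strongly constrained genes


def _pvals(gwas: GWASSummary) -> np.ndarray:
    return 2.0 * stats.norm.sf(np.abs(gwas.z))


def define_gwas_loci(
    gwas: GWASSummary,
    blocks: pd.DataFrame | None = None,
    clump_distance: int = 1_000_000,
    p_max: float = 5e-8,
) -> list[GWASLocus]:
    """Independent risk loci: one per LD block containing a SNP with
    P strictly below ``p_max`` (lead = smallest P).

    ``blocks`` is a 1-based inclusive chrom/start/end table (e.g. converted
    from a BED of approximately independent LD blocks). Without blocks,
    significant SNPs within ``clump_distance`` of each other are merged into
    distance clumps.
    """
    t = gwas.table.copy()
    if "pos" not in t.columns or "chrom" not in t.columns:
        raise ValueError("GWAS table needs chrom/pos for locus definition")
    t["p"] = _pvals(gwas)
    sig = t[t["p"] < p_max].sort_values(["chrom", "pos"]).reset_index(drop=True)
    loci: list[GWASLocus] = []
    if sig.empty:
        return loci
    if blocks is not None:
        for bi, blk in blocks.iterrows():
            inside = sig[
                (sig["chrom"] == blk["chrom"])
                & (sig["pos"] >= blk["start"])
                & (sig["pos"] <= blk["end"])
            ]
            if inside.empty:
                continue
            lead = inside.loc[inside["p"].idxmin()]
            loci.append(
                GWASLocus(
                    locus_id=f"locus_{len(loci):04d}",
                    chrom=str(blk["chrom"]),
                    start=int(blk["start"]),
                    end=int(blk["end"]),
                    lead_snp=str(lead["snp_id"]),
                    lead_p=float(lead["p"]),
                )
            )
        return loci
    # distance-clumping fallback
    cur: list[pd.Series] = []
    for _, row in sig.iterrows():
        if cur and row["chrom"] == cur[-1]["chrom"] and row["pos"] - cur[-1]["pos"] <= clump_distance:
            cur.append(row)
        else:
            if cur:
                loci.append(_clump_to_locus(cur, len(loci)))
            cur = [row]
    if cur:
        loci.append(_clump_to_locus(cur, len(loci)))
    return loci


def _clump_to_locus(rows: list[pd.Series], index: int) -> GWASLocus:
    lead = min(rows, key=lambda r: r["p"])
    return GWASLocus(
        locus_id=f"locus_{index:04d}",
        chrom=str(rows[0]["chrom"]),
        start=int(rows[0]["pos"]),
        end=int(rows[-1]["pos"]),
        lead_snp=str(lead["snp_id"]),
        lead_p=float(lead["p"]),
    )


def tag_loci(
    loci: list[GWASLocus],
    significant: dict[str, list[AssociationRecord]],
    annotation: TranscriptomeAnnotation,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Flag each locus by which methods tag it.

    ``significant`` maps a method name (e.g. 'twas', 'isotwas') to its
    significant association records; a locus is tagged by a method iff at
    least one of that method's features has a gene body within ``window``
    of the locus bounds. Returns one row per locus with per-method boolean
    columns, plus attrs['outside'] counting significant features (by gene)
    outside all loci per method.
    """
    methods = list(significant)
    spans: dict[str, list[tuple[str, int, int, str]]] = {}
    for meth, recs in significant.items():
        out = []
        for r in recs:
            gid = r.gene_id if r.level == "isoform" else r.feature_id
            g = annotation.gene_row(gid)
            out.append((str(g["chrom"]), int(g["gene_start"]), int(g["gene_end"]), gid))
        spans[meth] = out
    rows = []
    tagged_genes: dict[str, set[str]] = {m: set() for m in methods}
    for loc in loci:
        row = {"locus_id": loc.locus_id, "chrom": loc.chrom, "start": loc.start, "end": loc.end}
        for meth in methods:
            hit = False
            for chrom, gs, ge, gid in spans[meth]:
                if chrom == loc.chrom and gs <= loc.end + window and ge >= loc.start - window:
                    hit = True
                    tagged_genes[meth].add(gid)
            row[meth] = hit
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["outside"] = {
        m: len({gid for _, _, _, gid in spans[m]} - tagged_genes[m]) for m in methods
    }
    return table


def percent_increase(count_new: float, count_ref: float) -> float:
    """Percent increase of count_new over count_ref: 100*(new/ref - 1)."""
    if count_ref == 0:
        raise ValueError("reference count must be nonzero")
    return 100.0 * (count_new / count_ref - 1.0)


def proportion_enrichment_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> dict[str, float]:
    """2x2 chi-square test comparing proportions k1/n1 vs k2/n2.

    Returns chi2_stat, p_two_sided, and the enrichment ratio
    (k1/n1)/(k2/n2). Continuity correction on by default; when any expected
    cell is below 5 the two-sided Fisher exact test is used instead (logged)
    and chi2_stat reported as NaN.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2 and n1 > 0 and n2 > 0):
        raise ValueError("invalid counts")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    expected = stats.contingency.expected_freq(table)
    ratio = (k1 / n1) / (k2 / n2) if k2 > 0 else float("inf")
    if (expected < 5).any():
        logger.info("expected cell < 5; using Fisher exact test")
        _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        return {"chi2_stat": float("nan"), "p_two_sided": float(p), "ratio": ratio}
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return {"chi2_stat": float(chi2), "p_two_sided": float(p), "ratio": ratio}
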