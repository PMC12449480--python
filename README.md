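# twaskit

Isoform- and gene-level transcriptome-wide association analysis of GWAS
summary statistics, with feature fine-mapping, QTL colocalization, and
expression-mediated heritability estimation — plus a synthetic-data
generator that exercises the whole pipeline end to end.

## The problem

A transcriptome-wide association study (TWAS) asks whether the
*genetically predicted* component of a gene's expression associates with a
trait: cis-SNP weights **w** are trained on a reference expression panel,
and the burden statistic

```
z_assoc = wᵀz / √(wᵀVw)
```

combines the GWAS z-scores **z** with reference LD **V**. Modeling
expression at transcript-isoform resolution (isoTWAS) can recover signals
that vanish at the gene level: when two isoforms carry cis effects of
opposite sign, the aggregated gene expression has no predictable genetic
component even though one isoform mediates the trait. This package
implements that comparison as a tested pipeline:

- **Weight training** — 10-fold cross-validated elastic net per feature,
  plus a multi-response elastic net that shares support across a gene's
  isoforms; features kept at CV R² > 0.01.
- **Association** — weighted burden test; isoforms pass a two-stage
  multiple-testing rule (ACAT gene screen with Benjamini–Hochberg FDR
  across genes, then within-gene Bonferroni), followed by a
  10,000-draw permutation filter that reassigns weights to SNP positions.
- **Fine-mapping** — feature correlations induced by LD and shared
  weights (ω_ab = w_aᵀVw_b / √(w_aᵀVw_a·w_bᵀVw_b)), spike-and-slab
  configuration posteriors, PIPs, and 90% credible sets.
- **Colocalization** — per-SNP causal posteriors for GWAS and cis-QTL
  signals; CLPP = Σⱼ P(causal_GWAS = j)·P(causal_QTL = j); a feature
  colocalizes iff GWAS P < 5×10⁻⁸, QTL P < 10⁻⁶, and CLPP > 0.01.
- **Mediated heritability** — regression of GWAS χ² on LD scores and
  LD-smeared squared cis effects (expression scores), yielding h²_med/h²
  with block-jackknife SEs and a Wald test.
- **Comparison statistics** — independent GWAS loci, per-method locus
  tagging, percent-increase arithmetic, the mean-χ² effective-sample-size
  proxy, and 2×2 enrichment tests.

## Worked example

```python
import twaskit as tk

res = tk.run_pipeline(tk.PipelineConfig(), seed=1)
t = res.tallies
print(t["n_sig_genes_twas"], t["n_sig_genes_isotwas"], round(t["pct_increase_genes"], 1))
# 17 20 17.6
print(t["n_loci"], t["n_tagged_twas"], t["n_tagged_isotwas"])
# 2 2 2
```

With the default configuration (400-individual reference panel, 300 SNPs in
blocks of 15 with adjacent-allele correlation 0.8, 20 genes × 2 isoforms,
cis-h² 0.25, 6 trait-mediated genes — 3 through an opposing-isoform pair —
and a 100,000-sample GWAS), the gene-level scan finds 17 significant genes
while the isoform-level scan recovers 20 (a 17.6% increase); both tag the 2
independent genome-wide-significant loci. `res.truth` carries the planted
architecture (here h²_med = 0.144), so every downstream estimate can be
checked against ground truth.

The same study can be run step by step with the numbered drivers:

```bash
cd analysis
python 01_simulate_cohort.py --seed 1   # cohort TSVs -> results/study/
python 02_train_models.py    --seed 1   # cis weight models
python 03_associate.py       --seed 1   # burden tests + two-stage + permutation
python 04_finemap.py         --seed 1   # PIPs and 90% credible sets
python 05_qtl_coloc.py       --seed 1   # cis-QTLs and CLPP
python 06_mediation.py       --seed 1   # h2_med / h2 per level
python 07_compare_methods.py --seed 1   # loci, tagging, percent increases
```

Printed-count comparisons work directly on published tallies:

```python
from twaskit.report import percent_increase, proportion_enrichment_test
percent_increase(6163, 2336)                     # 163.8  (% more significant genes)
proportion_enrichment_test(1226, 6163, 293, 2336)["p_two_sided"]  # 3.7e-15
```

## Layout

```
src/twaskit/       library: syndata, expr_models, assoc, finemap,
                   qtl_coloc, mediation, report, pipeline, studies, io
analysis/          numbered study drivers (thin wrappers over the library)
scripts/           acceptance.py
tests/             pytest suite (unit, property, and acceptance tests)
docs/methods.md    model and design notes
```
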