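# mescore

Residue-level population constraint in protein domain families.

Human population sequencing (gnomAD-scale) shows which protein residues
tolerate missense variation in people alive today — a signal complementary
to evolutionary conservation across species. At any single protein the
variants are too sparse to resolve individual residues, but the columns of a
protein-family multiple sequence alignment pool homologous positions across
all of a family's human paralogs. `mescore` implements that comparative
analysis for anyone studying protein families, variant interpretation or
functional site prediction:

- **Missense Enrichment Score (MES).** For alignment column *x*, build the
  2×2 table *a* = variants in *x*, *b* = variants in all other columns,
  *c* = human residues in *x*, *d* = human residues elsewhere. The MES is
  the Fisher's-exact odds ratio of this table (conditional MLE, as R's
  `fisher.test` reports; the sample estimator (a·d)/(b·c) is available),
  with a two-sided exact p-value. Columns with p < 0.1 are *missense
  depleted* (OR < 1, under relatively strong constraint) or *missense
  enriched* (OR > 1); the rest are *neutral*. The score is intrinsically
  normalised for family depth and gene-level effects, and the column tests
  of one family are interdependent (in a two-column domain the two ORs are
  exact reciprocals with identical p), so no multiple-testing correction is
  applied within a family.
- **Shenkin conservation.** Per-column diversity V = 6·2^H (H = Shannon
  entropy in bits of the residue composition; 6 = invariant, 120 = maximally
  diverse), percent-ranked within the family; the 50% most diverse columns
  are *unconserved*.
- **Conservation plane.** Crossing the two classifications gives six site
  categories — CMD, CME, CMN, UMD, UME, UMN — where the discordant UMD
  class (evolutionarily diverse yet population-constrained) flags candidate
  specificity-determining positions.
- **Domain regression.** Per family, the no-intercept model
  ΣX_missense = β₁·n_human + β₁₂·n_human·V_Shenkin, with β₁ the missense
  rate per human residue and β₁₂ its sensitivity to divergence;
  Benjamini–Hochberg FDR across families.
- **Structural features.** RSA from DSSP ASA via Tien et al. max-ASA
  normalisation; exposure classes core (<5%), partially exposed (5–25%),
  surface (≥25%); two-stage aggregation (chains → residue → column) that is
  unbiased by PDB coverage; stratified feature-enrichment odds ratios with
  exact confidence intervals.
- **Synthetic families.** Generators for alignments, variant tables and
  structural tables with known per-column ground truth.

## Worked example

Simulate a 40-sequence family (20 human paralogs, 30 columns, strongly
depleted truth columns at 5% of the baseline missense rate), then score and
classify it:

```bash
mescore simulate scenario.yaml -o fam
mescore score fam/family.sto fam/variants.tsv -o mes.tsv
mescore conservation fam/family.sto -o cons.tsv
mescore classify mes.tsv cons.tsv -o classified.tsv
```

`mes.tsv` holds one row per scorable column:

```
column  a   b    c   d    mes           p_value        call      estimator
1       9   246  20  580  1.060901355   0.8393852628   neutral   conditional_mle
3       2   253  20  580  0.2295231654  0.03264219416  depleted  conditional_mle
```

Column 3 carries 2 of the domain's 255 missense variants on 20 of its 600
human residues — less than a quarter of the domain-average rate
(MES = 0.23, p = 0.033), so it is called depleted. Crossing with the
Shenkin classes gives the conservation-plane categories:

```
UMN 13   CMN 8   CMD 6   UME 2   CME 1

 column   shenkin  percent_rank      mes  p_value   category
      3 11.901515     26.666667 0.229523 0.032642   CMD
     28 11.865251     20.000000 0.000000 0.000967   CMD
```

The depleted, low-diversity columns land in CMD (conserved-missense
depleted), exactly where the generator planted the constraint. A column
with MES = 0 had no missense variants at all.

The same workflow runs on real data: a Pfam Stockholm alignment, a
VEP-annotated VCF (`SwissProt` + `Protein_position` CSQ fields) or a
pre-mapped variant TSV, and a per-residue structural TSV (optionally built
from DSSP output plus a SIFTS-style residue mapping with
`mescore.struct_features`).

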