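# Methods

## The missense enrichment score

For each alignment column *x* of a domain family, variants mapped to the
family's human sequences are split into the column and the rest of the
domain, and likewise the human residues (column occupancy restricted to
human sequences):

|                | column *x* | other columns |
|----------------|-----------|----------------|
| variants       | a         | b              |
| human residues | c         | d              |

The MES is the odds ratio of this table and its p-value is the two-sided
Fisher's exact test. The p-value uses the minimum-likelihood summation
convention: with all margins fixed, sum the hypergeometric point
probabilities of every table whose probability is at most that of the
observed table times 1 + 1e-7. The relative tolerance guarantees that
opposite-tail tables with mathematically equal probability are included
despite floating-point rounding; it matches the convention of the widely
used R implementation, so results are reproducible against it. Degenerate
tables (an empty row or column) have p = 1. Internally every table is first
mapped to a canonical representative of its row-swap/column-swap/transpose
orbit, all of which share the same p; this makes invariances such as the
two-site reciprocity (OR₁ = 1/OR₂, p₁ = p₂) hold bit-for-bit rather than
approximately.

Two odds-ratio estimators are provided.

- `conditional_mle` (default): the value maximising the Fisher noncentral
  hypergeometric likelihood of cell *a* conditioned on the margins, found by
  solving E[A | ψ] = a with Brent's method on log ψ (xtol 1e-12). This is
  the estimate R's `fisher.test` prints. At the boundary of the support the
  MLE is 0 or +∞.
- `sample`: (a·d)/(b·c), with a = 0 ⇒ 0 and b·c = 0 (a > 0) ⇒ +∞.

A column with no variants has MES = 0 under either estimator. Columns with
no human residues cannot form a valid table; they are excluded and reported
rather than silently dropped. Calls use a configurable threshold, default
p < 0.1: depleted if OR < 1, enriched if OR > 1, neutral otherwise. In a
two-sided exact test this threshold carves out the same critical regions as
one-sided tests at p < 0.05. No correction is applied across the columns of
one family: the tests share margins and are strongly interdependent, which
breaks the independence premises of standard corrections.

Exact 95% confidence intervals for enrichment odds ratios invert the
conditional tail probabilities (P(A ≥ a | ψ) = 0.025 for the lower bound,
P(A ≤ a | ψ) = 0.025 for the upper), again matching the R convention; a
Woolf log-OR interval with Haldane–Anscombe correction is available where
speed matters.

## Conservation

Shenkin diversity is V = 6·2^H with H the Shannon entropy (bits) of the
column's residue composition over all sequences, human and not. V = 6 for a
monomorphic column and 120 for a uniform spread over the 20 amino acids.
Gaps are excluded from the composition by default so the score reflects the
diversity of residues actually present; a mode counting the gap as a 21st
symbol is provided because both conventions exist in conservation software.
All-gap columns are unranked and excluded downstream.

Because V's range depends on alignment depth, classification is relative:
the percent rank of V within the family, computed as
100·(#{scores ≤ s} − 1)/n with ties sharing the rank of the highest tied
member. Ranks at or above the threshold (default 50%) are unconserved. The
ties-high rule is deterministic and places a fully tied family on the
unconserved side, the conservative choice for a relative "most diverse
half" definition. `top_n_conserved` supplies the complementary matched-count
conserved set (the n lowest-V columns, ties to the lower index), sized for
comparison against a family's number of depleted columns.

The normalised diversity (V − 6)/114 × 100 is exposed for plotting only;
classification always uses the percent rank.

## Regression

Per family, ordinary least squares without intercept:

    ΣX_missense = β₁·n_human + β₁₂·n_human·V_Shenkin

β₁ is the family's average missense count per human residue; β₁₂ is the
sensitivity of that rate to divergence. The response is a count but the fit
is deliberately Gaussian OLS — the simple linear model with per-coefficient
t tests (n − 2 residual degrees of freedom) — keeping the estimates directly
comparable to the standard `lm`-style analysis this procedure descends
from; no quasi-Poisson variant is offered in this version. Columns with
n_human = 0 carry no information about a per-human-residue rate and are
dropped before fitting (at least three columns must remain). A constant
V_Shenkin makes the two regressors collinear and raises a singular-fit
error rather than returning arbitrary coefficients. β₁₂ p-values are
Benjamini–Hochberg adjusted across families.

## Structural features

RSA = 100 × ASA / maxASA(residue type), with the Tien et al. (2013)
maximum-ASA tables embedded (theoretical values by default, empirical
selectable). Values above 100% are possible for extended conformations and
are not clipped. Exposure classes: core (RSA < 5%), partially exposed
(5% ≤ RSA < 25%), surface (RSA ≥ 25%). ASA values are expected to come from
per-chain calculations with non-protein atoms stripped, so burial measures
the single biopolymer; the package consumes DSSP output (classic text
format) joined to UniProt numbering through a SIFTS-style mapping table and
does not recompute ASA from coordinates.

Aggregation is two-stage so families with well-studied members are not
biased by their PDB coverage: first each (accession, position) is
summarised over all covering chains — modal exposure class, any-contact
flags, chain count — then columns are summarised over those per-residue
summaries. A residue contacting a ligand in 5 of 20 structures counts once.
Modal ties break toward the more buried class (core over partially exposed
over surface), a deterministic rule that makes the conservative structural
call. Column-level outputs: consensus exposure, numbers of sequences with
ligand/domain contacts, sequence coverage (residues with ≥ 1 chain) and
total coverage (sum of residue chain counts). Duplicating structures
changes only the total-coverage tally, which by construction counts chains;
every other column summary is invariant.

## Synthetic data

The generators produce the study conditions used throughout the tests:

- Alignments: conserved truth columns draw from 1–2 residue types,
  unconserved from 6–12; human sequences are gap-free (uniform human
  occupancy), other sequences carry 5% gaps. Depleted truth columns are
  drawn preferentially from the conserved set, biased toward buried
  exposure, with elevated contact probabilities — the structural correlates
  of constraint.
- Variants: per human residue, missense counts are Poisson with the
  column's true rate. The default baseline is 0.46 missense variants per
  human residue, the density observed when population missense variants are
  mapped across domain families at proteome scale; depleted columns default
  to 5% of baseline. Synonymous counts use a flat rate (default 0.5)
  independent of divergence, preserving their role as a negative control.
  Pathogenic labels can be planted at chosen columns.
- Structures: several pseudo-chains per residue; contact flags drawn once
  per residue and replicated across chains, exposure optionally perturbed
  per chain.

Everything is a pure function of (parameters, seed). What passing tests on
these fixtures do *not* show: behaviour under phylogenetic correlation
between sequences, residue-type-dependent mutability, allele-frequency
structure, or misalignment — none of which the generator emulates.

Problem sizes in the test suite and acceptance script are desk-scale by
design: exhaustive Fisher enumeration over ~10⁴ small tables, 500-table
estimator comparisons, 500 null regressions, and 50-replicate power runs
with 120-sequence families — enough for the stochastic checks' tolerances
while keeping the whole suite in the tens of seconds.

## Numerical choices

- Hypergeometric log-pmfs via log-gamma, renormalised by log-sum-exp over
  the support before exponentiation.
- Conditional-MLE root finding brackets log ψ by doubling until the mean
  equation changes sign; a bracket beyond e±700 is treated as a boundary
  case (0 or ∞).
- Percent ranks, modal classes and top-n sets all have explicit,
  deterministic tie rules (documented above) so outputs are byte-stable.
- Protein positions given as ranges ("12-13") take the first position and
  are logged; variants are de-duplicated on (accession, position, allele).

## Known limitations

- The Fisher machinery enumerates the full support of each table; for
  margins in the tens of thousands a column scores in milliseconds, but
  very deep proteome-scale scans would benefit from saddlepoint shortcuts
  that are not implemented.
- ClinVar "Likely pathogenic" is treated as pathogenic by default
  (configurable); no review-status filtering is applied.
- The regression offers no overdispersion handling; families with strongly
  clumped variants will show anticonservative β₁₂ p-values.
- Exposure consensus assumes the three-class scheme; no per-chain B-factor
  or occupancy weighting is applied.
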