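# Methods

## Scope and model

`codonforge` quantifies synonymous codon usage bias (CUB) in sets of
in-frame protein-coding sequences and diagnoses whether that bias is driven
by directional mutation pressure or by selection. The statistics are the
classical ones of the CUB literature; the package computes them over the
synonymous-family partition of an NCBI translation table.

All family-based statistics default to the standard code (table 1), under
which the 61 sense codons contain 59 analyzable codons (the single-codon
families Met and Trp are excluded everywhere). For mitochondrial data this
is a deliberate convention, not an oversight: the 59-codon convention is
what the standard CUB tool chain applies to fungal mitochondrial genes, and
it keeps indices comparable with published values. `transl_table=4` (mold
mitochondrial) is available and changes translation and the family
partition consistently; under table 4, TGA is Trp, the code has 60
analyzable sense codons, and indices shift slightly. In-frame TGA codons
met under the standard code are tallied as stops and excluded from family
statistics, with a count kept.

Terminal stop codons are always excluded from codon counts. The
100-amino-acid length filter counts translated residues excluding the
terminal stop.

## Statistics

* **RSCU**: `RSCU_ij = k_i n_ij / Σ_j n_ij` within each family of size
  `k ≥ 2`; family sums equal `k` whenever the family is observed. Unobserved
  families carry RSCU 0 with a flag.
* **ENC** (Wright): per-family homozygosity `F = (n Σ p_i² − 1)/(n − 1)` for
  families with `n ≥ 2`; class means `F̄_k` over the degeneracy classes;
  `ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆` under the standard code. Families
  with `n < 2` or `F = 0` are excluded from class means. A missing k = 3
  class is imputed as `(F̄₂ + F̄₄)/2`; any other missing class is dropped and
  the sum rescaled to the 20–61 range, with the affected classes recorded on
  the result. Values are capped to [20, 61]. Because `F` carries a
  small-sample correction, ENC at fixed usage proportions still depends
  weakly on gene length; the dependence vanishes for long genes (the suite
  checks the doubling shift falls below 0.2 by 20 000 codons).
* **GC3s and X3s**: GC3s is the G+C fraction at third positions of
  synonymous-family codons. The base-specific A3s/T3s/G3s/C3s use
  base-specific denominators — only codons whose family offers base X at
  position 3 enter the denominator of X3s — so the four values may sum above
  100%. This is the convention under which published values like
  A3s + T3s > 100% are coherent. A base never offered yields an explicit
  undefined flag, not NaN.
* **CAI**: relative adaptiveness `w = RSCU/RSCU_max` per family on a pooled
  reference; CAI is the geometric mean of `w` over counted codons (Met, Trp,
  stops excluded). Codons absent from the reference are smoothed to
  `w = 0.01` (configurable). No curated highly-expressed reference exists
  for fungal mitochondria, so the default reference is the species' own
  pooled gene set; absolute CAI values are therefore convention-dependent
  and it is the CAI *ranking* that downstream steps consume.
* **CBI** (Bennetzen–Hall): `(N_opt − N_ran)/(N_tot − N_ran)` over families
  containing at least one optimal codon, `N_ran` the expectation under
  uniform synonymous usage; 1 means only optimal codons, negative means
  avoidance.
* **FOP**: optimal-codon count over all synonymous-family codons.
* **GRAVY / AROMO**: mean Kyte–Doolittle hydropathy, and the F+Y+W residue
  fraction, of the translation.

## Selection diagnostics

* **Neutrality plot**: OLS of GC12 on GC3 across the genes of a species
  (axis order fixed; no errors-in-variables correction), with Pearson r and
  its t-test p-value. GC3 (all third positions) is the default abscissa,
  with a switch to GC3s.
* **Expected-ENC curve**: `ENC_exp(s) = 2 + s + 29/(s² + (1−s)²)` at
  `s = GC3s`, the ENC a gene would show if third-position composition were
  the only force. The signed deficit `(ENC_exp − ENC_obs)/ENC_exp` is
  reported as a percentage; the denominator is `ENC_exp`, consistent with a
  positive deficit when genes sit below the curve. A flag switches the
  denominator to `ENC_obs` for comparison with sources that normalize the
  other way.
* **PR2 bias**: per-gene point `(G3/(G3+C3), A3/(A3+T3))` at third positions
  of four-fold degenerate families (Sueoka's convention; an all-synonymous
  scope is available). (0.5, 0.5) is the no-asymmetry point; zero counts on
  an axis flag the record rather than producing NaN.
* **Correlations**: pairwise Pearson r/p between indices across genes, with
  significance stars at p < 0.05 / p < 0.01 and a Holm-adjusted column
  emitted alongside the raw p-values (the stars deliberately reflect the
  unadjusted values, matching how such heatmaps are usually drawn).

## Correspondence analysis and optimal codons

CA is the chi-square-residual SVD of the genes × 59-codon RSCU matrix:
`S = D_r^{-1/2}(P − rcᵀ)D_c^{-1/2}`, principal inertias `λ_k = σ_k²`, axis
contributions `100 λ_k/Σλ`. Zero-sum rows/columns are dropped with a
warning; rank-deficient inputs return fewer axes. CA axis signs are
arbitrary, so each axis is oriented to make its largest-|loading| codon
positive, making coordinates reproducible run to run.

Optimal codons follow the ΔRSCU procedure: genes ranked by CAI
(ties broken lexicographically by gene label), the top and bottom
`max(1, ceil(0.10 n))` genes pooled into high- and low-expression subsets
(2 per end for a 12-gene set — a 1-gene "subset" would make pooled RSCU
degenerate too often), ΔRSCU = RSCU_high − RSCU_low, and

    optimal = { c : ΔRSCU(c) > 0.08  and  RSCU_full(c) > 1 }

with RSCU_full evaluated on the full pooled species set. Every optimal
codon is by construction also high-expression (ΔRSCU > 0.08) and
high-frequency (RSCU > 1); the report keeps all three sets and the
subset relation is asserted in the test suite.

Species clustering is agglomerative with average linkage (UPGMA) on
Euclidean distances over the species × 59-codon pooled-RSCU matrix —
defaults chosen because they are the common dendrogram convention for
RSCU profiles; both are configurable. The dendrogram is serialized as
Newick with ultrametric branch lengths.

## Synthetic data

The generator draws amino acids i.i.d. from a frequency vector and codons
from per-family weights, so every statistic has closed-form ground truth
(`expected_rscu`, `expected_composition`). Two knobs act strictly within
families: `gc3_pressure` reweights third-position bases (silent-site
mutation pressure — provably leaves GRAVY/AROMO untouched), and
`selection_strength` multiplies each family's preferred codon by
`exp(strength)` (translational selection). Stop codons are fixed to TAA,
the AT-rich choice, for determinism. Genes are i.i.d. per codon — no
positional autocorrelation, no phylogenetic correlation between species,
no indels; the generator reproduces the marginal composition structure the
statistics consume, not the linkage structure of real genomes, so passing
tests certify the estimators, not organism-level conclusions.

Scenario presets encode the two causal regimes the diagnostics are meant
to separate: the mutation scenario applies one per-gene GC pressure
(U(0.15, 0.75)) to all three positions, giving a neutrality slope near 1
and genes on the expected-ENC curve; the selection scenario fixes the
amino-acid composition (flat GC12), varies per-gene silent-site GC
(U(0.1, 0.7)) and sharpens weights (strength 3), giving a slope near 0 and
genes well below the curve.

The `amanita_like` preset emulates the composition regime of fungal
mitochondrial core genes: 12 genes per species, body lengths uniform over
the 376–2004 bp range, pooled T ≈ 41% and A ≈ 32%, GC3s ≈ 0.11. Its
third-position base weights are T/A/G/C = 0.42/0.47/0.065/0.045 and its
amino-acid frequencies were calibrated once by constrained least squares
(simplex-bounded SLSQP against the closed-form pooled composition,
regularized toward a hydrophobic, AT-rich membrane-protein-like profile)
and then frozen in code; they are defaults of the package, not fitting
knobs. The preset applies no selection sharpening, so its ENC (~38) sits
essentially on the expected curve; study-level analyses over several
"species" jitter the third-base weights per species so that cross-species
clustering has structure to find.

Default problem sizes were chosen so the full suite and the acceptance
script each complete in seconds on one core: scenario checks use 50 genes
of 300 codons; limiting-case ENC checks use 10 000 codons; parameter
recovery uses a single 50 000-codon gene.

## Numerical choices and edge cases

* Family homozygosity needs `n ≥ 2`; a gene with no such family yields an
  explicit undefined ENC with a message.
* RSCU of unobserved families, X3s with empty denominators and PR2 axes
  with zero counts are flagged rather than propagated as NaN.
* CA rank detection uses an absolute singular-value floor (1e-14) so an
  identical-rows matrix reports zero axes rather than numerical dust.
* Tables are written at 2 decimals with a parallel full-precision file;
  all computation is double precision throughout.
* Species-level summaries are unweighted means across genes
  (length-weighting available via flag); on write the bundle re-verifies
  that species means equal the mean of the per-gene rows.

## Known limitations

* Absolute CAI/CBI/FOP magnitudes depend on the reference and optimal-codon
  conventions; only their ordering and signs are convention-free.
* The generator's i.i.d. structure cannot produce autocorrelated codon
  runs, context-dependent mutation, or shared phylogenetic history.
* ENC's small-sample correction makes short-gene values length-dependent;
  comparisons across genes of very different length should lean on the
  ENC-ratio against the expected curve rather than raw ENC.
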