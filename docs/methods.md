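# Methods

## Taste scoring

**TAV.** `TAV = C/T` with the concentration *C* in mg/100 g tissue and the
sensory threshold *T* tabulated in mg/100 mL. The unit mismatch is resolved
by treating the two as directly comparable (tissue density ≈ 1 g/mL), which
is the convention the field's printed TAV tables follow; the packaged
reference reproduces the published thresholds (e.g. Ala 60, Glu 30, IMP 25).
TAVs are computed on group-mean concentrations by default — the way
composition tables report them — with a per-replicate mode available.
Compounds without a tabulated threshold (Tyr, Gln, Asn, Cys) have no TAV;
requesting one raises an explicit error rather than scoring zero.
Nothing is rounded internally; display rounding happens only in report
CSVs (2 decimals, the precision of published tables).

**Category aggregates** are sums of per-compound group means (not means of
per-animal sums), again matching published table layout;
`replicate_category_sums` provides per-animal totals when SDs of aggregates
are wanted. UAA/SAA/BAA membership follows the packaged reference; TAA is
all free amino acids including the tasteless pool (Gln, Asn, Cys); EAA
defaults to the standard nine-member set (Val, Leu, Ile, Phe, Trp, His,
Met, Thr, Lys). Note that published EAA rows for this panel are *not* the
sum of those nine compounds from the same table (e.g. the control column
sums to 647.32 vs a printed 553.00); the operational set behind the printed
EAA rows is not recoverable, so EAA membership is exposed as configuration
(`is_essential` in the reference CSV) and EAA totals are not treated as
reproducible quantities. Summing 20 independently rounded means also
accumulates rounding error of up to a few hundredths of a mg/100 g in TAA,
slightly above the per-category agreement seen for UAA/SAA/BAA.

**EUC.** `EUC = Σaᵢbᵢ + 1218(Σaᵢbᵢ)(Σaⱼbⱼ)` with concentrations converted
from mg/100 g to g/100 g before the coefficients (Glu 1, Asp 0.077; IMP 1,
GMP 2.3, AMP 0.18) are applied. Only those five compounds enter; a missing
compound contributes zero with a warning so partial panels remain scorable,
while a negative concentration is an error. Group EUC from replicate-level
data defaults to per-animal EUC then mean ± SD (the natural way to put error
bars on a nonlinear score); from a means-only table it is the EUC of the
means. Both conventions agree to well within reporting precision at the
packaged effect sizes because the synergy term is locally near-linear.

## Group comparisons

Two pipelines reflect the two conventions used for compound panels:

* **Kruskal–Wallis + BH** (`kruskal_groups`): tie-corrected KW omnibus as a
  gate at α, then all pairwise two-sided Mann–Whitney tests — exact null
  distribution when the pooled sample is ≤ 30 and tie-free (always true at
  n = 6 per group with continuous data), tie-corrected normal approximation
  otherwise. The BH family is the set of pairwise comparisons within one
  variable, mirroring per-row table annotation; correcting across compounds
  as well is possible by calling `benjamini_hochberg` over the pooled
  p-values. With all observations identical the omnibus is reported as
  p = 1 and a single letter.
* **ANOVA + Duncan** (`anova_duncan`): one-way ANOVA F, then Duncan's
  multiple range test. For a span of p ordered means the least significant
  range is `R_p = q(1 − α_p; p, df_err)·√(MSE/n_h)` with the Duncan
  protection level `α_p = 1 − (1 − α)^(p−1)`, studentized-range quantiles
  from `scipy.stats.studentized_range`, and the harmonic mean n for unequal
  groups. The standard containment rule applies: a pair inside a span
  already declared non-significant is non-significant. Zero within-group
  variance with distinct means yields letters by mean equality plus a
  warning. The procedure reproduces the classic five-treatment textbook
  worked example exactly (see the test suite).

**Compact letter display** uses the insert-and-absorb algorithm: start with
one column holding all groups; for each significant pair, split every column
containing both and absorb redundant subsets. Groups are ordered by
descending mean so letters read 'a' for the largest mean. Sharing a letter
is equivalent to non-significance (verified exhaustively for k ≤ 4); the
letter set is kept small but global minimality is not guaranteed.

`benjamini_hochberg` is the statsmodels step-up implementation behind a
validated interface; tests check it element-wise against an independently
coded step-up.

## DEG screening

`filter_degs` keeps genes with |log₂FC| ≥ 1 **and** FDR ≤ 0.05, both
boundaries inclusive, matching the ≥/≤ convention of threshold DEG calling;
if only p-values are present BH is applied first. Count normalization,
dispersion estimation and the DE model fit itself are out of scope — the
module consumes any table with the required columns. log₂FC = 0 survivors
are excluded from direction counts with a warning. Upset counts
(all-intersection, per-set exclusives, pairwise intersections) are exact set
operations; sign-consistency between two contrasts counts a zero fold change
as opposing, with a warning.

## Co-expression network

`build_network` computes all-pairs Pearson correlation (Spearman optional;
`log2_transform` for raw normalized counts — correlation on a log scale is
the default recommendation), p-values from the exact t-transform of r with
n − 2 df, and BH over all pairs tested in one build. An edge survives iff
|r| > r_min and q < q_max, both strict. Both correlation signs are kept by
default. At least 4 samples are required (correlation p-values are unstable
below that); zero-variance genes are dropped with a warning, and genes left
with no surviving edge are reported as isolates rather than kept as
degree-0 nodes — which is why such networks have fewer nodes than input
genes.

**Modules** come from greedy modularity maximisation (the module-detection
algorithm for such networks is a free choice; greedy modularity is
deterministic given the node order, which is fixed by sorting). The `seed`
parameter is accepted for interface stability. Module ids are stable:
ordered by size, then smallest member.

**Node cartography** follows Guimerà–Amaral, the source of the 2.5/0.62
thresholds: Zᵢ standardizes the within-module degree against the node's own
module (population SD; SD = 0 ⇒ Z = 0), Pᵢ = 1 − Σₛ(kᵢₛ/kᵢ)². Roles:
module hub (Z > 2.5, P ≤ 0.62), connector (P > 0.62, Z ≤ 2.5), network hub
(both), peripheral (neither); thresholds are strict, so a node exactly on a
boundary does not acquire the role. Key nodes are the non-peripheral ones.
Note P > 0.62 requires edges into ≥ 3 modules (max P with 2 modules is 0.5).

**Module quality** (`filter_modules`) counts over a user-supplied gene →
functions map: pass ⇔ ≥ 10 annotated genes ∧ ≥ 50 % annotation rate ∧ ≥ 3
distinct functions ∧ ≥ 3 genes for the top function (ties broken
lexicographically). Enrichment p-values are out of scope (annotation-database
dependent).

## Synthetic data

`gen_panel` draws truncated-normal replicates (resampling below zero) around
a mean/SD grid; the default grid is the packaged panel (3 groups × 23
compounds, n = 6), so simulations run at the study's own effect sizes. The
distributional family behind reported mean ± SD values is unknowable from
the summaries; truncated normal is chosen for transparency, with a
moment-matched lognormal alternative. Truncation bias is < 1 % of the mean
whenever mean > 3·SD, which nearly all grid cells satisfy. Each
(compound, group) cell consumes an independent SHA-256-keyed substream of
the global seed, so editing the panel never shifts other cells' draws.

`gen_expression` builds genes × samples matrices (log2 scale) as
`x = loading·f_module + noise_sd·ε` with a shared latent factor per module
and sample, background genes as pure noise, and optional per-module log₂
fold changes added to the non-reference groups; the planted truth (module
labels, true log₂FC, sample groups) is returned for recovery testing.
Defaults (5 × 40-gene modules, loading 0.9, noise SD 0.3, 6 samples/group)
give within-module correlations ≈ 0.9 and near-perfect module recovery.
`gen_deg_table` plants a known DEG set above the filter thresholds among
null genes with uniform p-values.

What the generators do **not** emulate: chromatographic/batch noise,
compound-compound correlations within an animal, count-level sequencing
noise and mean-variance coupling, or partially overlapping modules. Passing
tests therefore certify the algorithms and their contracts at realistic
effect sizes, not instrument-level behavior on raw data.

## Problem sizes and verification

The suite's stochastic checks run at sizes chosen to keep the whole run
under a minute of CPU while leaving Monte-Carlo error well inside the
asserted margins: 200 reseeded panels for the separation-power check, 2000
null panels (4 groups × 6) for the empirical type-I error of the letter
procedure, 100 random graphs ≤ 50 nodes for Zi/Pi oracle equality, and
200-gene matrices for module recovery (ARI ≥ 0.9). Deterministic headline
values (EUC per group, TAV spot checks, category rows) are recomputed from
the packaged means and compared at ±0.05 g/100 g, ±0.01 and ±0.02 mg/100 g
respectively — the resolution the printed values support. The two TAA cells
whose printed totals disagree with the sum of printed means by 0.03–0.04
mg/100 g (accumulated rounding over 20 addends) are asserted at the same
±0.02 and fail honestly; see the category-aggregates discussion above.

## Known limitations

* Letter displays are not guaranteed minimal in letter count (NP-hard in
  general); the iff-sharing property is what is guaranteed.
* Duncan's test assumes homoscedasticity and is anti-conservative relative
  to Tukey by design; it is provided because it is the field's convention
  for amino-acid panels, not as a recommendation.
* `build_network` materialises the full correlation matrix: fine for the
  ~10³-gene DEG subsets it targets, not for whole transcriptomes.
* The greedy-modularity partition is one defensible choice among many; the
  number of modules on real data is algorithm-dependent, and Zi/Pi roles
  should be read relative to the chosen partition.
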