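# Methods

## Study design and data model

The package models a two-site clonal common-garden trial: each *variety* is
a clonally propagated genotype represented by a few trees per site (the
canonical design has 17 varieties common to both sites, 33 distinct per
site, and 2–3 trees per variety), and ten phenotypic traits measured per
tree. Because varieties are clones, a common variety is genetically
identical at the two sites, which is what licenses reading cross-site trait
differences as phenotypic plasticity rather than genetic turnover.

Tables are tidy CSV, one row per tree, keyed by `(site, variety, tree)`
with trait columns `LA, LW, LL_LW, LMA, LDMC, LT, SSL, AS_AL, BWD, RBT`.
Variety names are matched exactly after Unicode NFC normalization and
whitespace trimming — no fuzzy matching, since a silent merge of two
varieties is worse than a missed match. Missing values are empty cells or
`NA` on disk and NaN in memory, never zero. The common/distinct design is
always re-derived from site × variety occupancy, never stored.

## Trait derivation

Ratio traits are computed per organ sample and then averaged to tree level,
not as ratios of tree-level means; the two conventions differ whenever
replicates vary and the per-sample one matches how replicated organ
measurements are taken. Unit conversions are centralized: LMA in g m⁻²
(from g and cm²), LDMC in mg g⁻¹, A_S in cm² from mm diameters. The twig
sapwood cross-section uses the ellipse formula A_S = (π/4)·d₁·d₂ from the
two perpendicular bark-removed diameters (a mean-diameter circle is the
main alternative; the ellipse is chosen because both diameters are measured
and it is symmetric and exact for elliptic sections). Leaf thickness is the
unweighted mean of the four lamina readings; RBT = 2·(mean bark
thickness)/(mean branch diameter); branch wood density is measured upstream
by densitometry and passed through.

## Variance partitioning

Three quantities are computed per trait from tree-level values, each from
its own one-way ANOVA and reported with its own denominator:

- genetic % = SS(variety)/SS_total, variety as factor, all varieties across
  both sites;
- plasticity % = SS(site)/SS_total, site as factor, common varieties only;
- residual % = within-variety SS of the variety ANOVA.

The three shares are deliberately **not** forced to sum to 100: they come
from different models over different subsets. A consequence worth knowing:
for common varieties the within-variety spread spans the two sites, so the
residual share converges to the sum of the site, interaction and tree-level
variance fractions, not to the tree-level fraction alone. The site ×
variety interaction is tested separately with a two-way fixed-effects ANOVA
on the common varieties using Type II sums of squares (tree counts of 2–3
make the design mildly unbalanced; Type II tests each term adjusted for the
others and reduces to the sequential decomposition when balanced).

Engines are written in the package: one-way SS from group means, two-way SS
from least-squares full-vs-reduced model comparisons, Tukey HSD with the
Tukey–Kramer standard error and p-values from the studentized-range
distribution, an insert-and-absorb compact letter display, and the Pearson
t-transform test. scipy supplies only the reference distributions; the test
suite cross-checks every engine against an independent oracle (projection
matrices, statsmodels, Monte-Carlo simulation of the studentized range,
brute-force letter-consistency enumeration). Sample (n−1) SDs are used
throughout — the variety groups are small — and p-values are floored at
1e-300.

## Plasticity indices

Traits are first z-scored over all trees of the common varieties, both
sites pooled; the mean/SD pairs are returned as provenance so the transform
is reproducible.

**PhD.** The per-variety, per-trait index is
`PhD = max(0, (B̄ − W̄)/B̄)`, with B̄ the mean |z-difference| over all
cross-site tree pairs of the variety and W̄ the mean within-site pairwise
difference pooled over both sites (0 when no within-site pair exists), and
PhD = 0 when B̄ = 0. This concrete form was chosen because it is an average
pairwise cross-site dissimilarity, discounts within-site variability, and
respects the 0 (no plasticity) to 1 (maximum plasticity) range; the
formula is isolated in one function and two named alternatives ship with
it: `overlap` (one minus the equal-variance normal overlap coefficient,
2·Φ(−|Δ|/2σ)) and `rdpi` (mean relative distance |xᵢ−xⱼ|/(xᵢ+xⱼ) over
cross-site pairs, meant for raw positive values). Trait-level plasticity is
the mean PhD over varieties, compared across traits with a trait-factor
one-way ANOVA, Tukey HSD and compact letters.

**MVPi.** A single PCA is fitted on the pooled standardized tree × trait
matrix of both sites (a cross-site distance needs one common space; the
per-site ordinations below are kept separate from this). Trees are
projected on the first three components as raw principal scores without
eigenvalue scaling, and MVPi(v) is the mean Euclidean distance over all
cross-site tree pairs of variety v. With as many components as traits the
projection is a full orthonormal basis and MVPi equals the mean cross-site
distance in the standardized trait space itself — the rotation-invariance
property the tests verify to 1e-10. Trees missing any trait are dropped for
MVPi only (complete-case per analysis, never globally).

## Ordination and the fast–slow axis

Per-site PCAs use the correlation matrix (per-site standardization) of
individual trees, not variety means; variety scores are averaged
afterwards. Loadings are correlation-scaled (eigenvector × √eigenvalue), so
communalities (row sums of squares) are invariant under orthogonal
rotation; scores are unit-variance standardized scores. Signs are fixed
deterministically (largest-|loading| trait positive per component).

Varimax uses the classic iterative pairwise planar rotations with Kaiser
normalization, closed-form optimal angle per pair
(φ = ¼·atan2 of the standard fourth-order moments), convergence when a full
sweep improves the criterion by less than 1e-8, and a hard failure after
1000 sweeps. The first three components are rotated by default (the
interpreted subspace); rotated axes are re-ordered by explained variance.

The fast–slow axis is the rotated component maximizing
|loading(LMA)| + |loading(LDMC)| among the first three, oriented so LMA
loads positive — positive scores mean denser, more conservative ("slow")
phenotypes. Ties keep the first index and warn. Per-site variety scores on
this axis are correlated (Pearson, Fisher-z 95% CIs) with each trait's PhD
and with MVPi — 11 tests per site, uncorrected by default to keep single-
test interpretability (a Holm option exists but is off).

## Synthetic data generator

Each trait value is drawn from
`x = μ_t + G_v + E_s + I_vs + ε`, additive on the natural scale, with the
component variances scaled so that the total is (μ_t·CV_t)² split by the
configured fractions (f_G, f_E, f_I, f_res). The site effect is a fixed
two-level contrast ±σ_E with a per-trait direction (mirroring a fixed-site,
sampled-variety design); genetic and interaction effects are Gaussian
draws, and common varieties receive one genetic draw reused at both sites
(clonal identity). Negative draws are truncated at 1e-6·μ with a warning —
essentially never triggered at the default CVs. A log-normal option applies
the same decomposition on the log scale. One integer seed drives a single
generator stream; replicate seeds are derived by unit offsets.

Defaults encode the canonical study conditions: 17 common + 33 distinct
varieties per site, 2–3 trees per variety, trait means centered in reported
varietal ranges (LMA 277 g m⁻², BWD 0.75 g cm⁻³, …), CVs averaging ~14%
with A_S:A_L and LA most variable and LDMC and BWD least, and site
(plastic) fractions concentrated in the structural/density traits (LDMC
0.35, A_S:A_L 0.30, LMA 0.25, …) with near-zero site effects for leaf
dimensions and thickness. Semi-arid shifts are positive for LMA, LDMC, BWD
and RBT and negative for A_S:A_L and SSL.

What the generator does *not* emulate: trait–trait correlation structure
(components are drawn independently per trait, so simulated fast–slow axes
are weaker and less interpretable than in real data, where LMA and LDMC
covary), spatial/plot structure, measurement-year effects, and non-Gaussian
tails. Passing tests therefore demonstrate the estimators' correctness and
calibration under the additive model, not the ecological structure of any
real garden; printed index values from field studies are qualitative
anchors only, not targets.

## Calibration and recovery checks (problem sizes used)

The suite verifies, at sizes chosen to keep the full run under a minute or
two: uniformity of the two-way site p-value under f_E = f_I = 0 over 500
replicates (KS at α = 0.01; the two-way test is used because the variety
factor absorbs the shared genetic draws — a one-way site test on common
varieties is not an exact null even without site effects); a ~5%
false-positive rate of the fast–slow correlation screen over 1000
replicates of independent n = 17 scores; recovery of a configured 30%
plasticity share within ±5 points averaged over 200 replicates at 17
varieties × 3 trees; and convergence of realized components at 200
varieties × 20 trees.

## Numerical conventions and limitations

- Type II SS for the unbalanced two-way ANOVA; tiny negative SS from
  round-off are clipped at zero.
- Studentized-range p-values come from scipy's numerically integrated CDF,
  validated against 1e6-draw Monte-Carlo to < 0.003.
- PCA requires more complete-case trees than traits and fails loudly on
  constant traits; whole-pipeline outputs are byte-identical for identical
  config + seed (manifest checksums).
- The climate classifier uses the standard 10/20/30 De Martonne thresholds,
  lower-inclusive, with "humid" strictly above 30.
- Mixed-model (REML) variance components, PCA significance testing and
  multiplicity control beyond Tukey HSD are out of scope.
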