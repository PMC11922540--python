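# Methods

## Quantification model

Metabarcoding observes a composition: the read count of ASV *i* in sample
*j* estimates a share, not an amount. The package converts shares to
amounts with a microscopy anchor measured on the same water sample.

Let a_ij and m_ij be the microscopy abundance (cells L⁻¹) and biomass
(mg L⁻¹) of species *i* in sample *j*, and

    A_j  = Σ_i a_ij        M_j  = Σ_i m_ij          (sample totals)
    A_jc = Σ_{i∈c} a_ijc   M_jc = Σ_{i∈c} m_ijc     (per class c)

With R_ij the ASV's share of the sample's phytoplankton reads and R_ijc
its share of its class's reads, the two anchoring schemes are

    total:  ā_ij  = R_ij  · A_j      m̄_ij  = R_ij  · M_j
    class:  ā_ijc = R_ijc · A_jc     m̄_ijc = R_ijc · M_jc

Both are exact redistributions: Σ_i ā_ij = A_j per sample, and
Σ_{i∈c} ā_ijc = A_jc per sample and class, to machine precision. The
modelling assumption behind the total scheme is that read shares track
community shares; behind the class scheme, that they track shares *within
a class*. The second is weaker and more defensible, because the dominant
amplification biases — 18S rRNA gene copy number, which grows with cell
biovolume, and primer affinity — are structured largely at the class
level: a class-wide multiplicative bias cancels in R_ijc but not in R_ij.

The class scheme's cost is missing values: where a class has reads in a
sample but microscopy counted no cells of it, A_jc = 0 and no absolute
value exists. Such cells are masked (NaN), not set to zero — zeros would
be fabricated measurements and would bias rank correlations downward —
and every downstream correlation is computed pairwise-complete. Classes
observed only by metabarcoding (no microscopy analogue at all) can be
anchored by a configured proxy class chosen for morphological similarity;
the proxy map is validated against the anchor table at fit time.

Biomass anchoring uses the same read shares as abundance anchoring; no
per-ASV biovolume correction is applied by default. A per-taxon
multiplicative correction-factor hook exists on the total-anchoring
estimator (rows are re-closed after correction, so conservation still
holds) but is off unless configured.

Both quantifiers follow the sklearn estimator protocol: `fit(anchors)`
captures the anchor totals, `transform(R)` maps a relative-abundance
matrix to a `QuantifiedAsvTable`, and `get_params`/`set_params`/`clone`
work as usual, so the quantifiers compose with sklearn tooling.

## Microscopy side

Species biovolume comes from an assigned geometric shape (sphere,
cylinder, prolate spheroid, box, cone, double cone, ellipsoid — a
registry extensible at run time) and measured linear dimensions; biomass
is abundance × mean cell volume × density, with density 1 g cm⁻³. The
unit scale is configurable with default 10⁻⁹, which converts
µm³ · cells L⁻¹ to mg L⁻¹ (1 µm³ of unit-density tissue weighs 10⁻⁹ mg).
Source datasets are not always consistent about per-litre versus
per-cubic-metre biomass, which is why the scale is a parameter rather
than a constant.

Morphologically similar species pairs that light microscopy cannot
separate are split by SEM relative counts: each species receives the pair
total times its share of the SEM count, conserving the pair total
exactly; a warning (not an error) is raised when fewer than 100 cells
were counted, the customary minimum for a stable split. Cyanobacteria are
dropped before any totals — they carry no 18S rRNA gene, so leaving them
in the anchors would inflate every ASV's estimate.

## ASV filtering

Raw ASV tables pass through, in order: (1) removal of ASVs with ≤ 2 reads
in total and of lineages matching Metazoa, Streptophyta, nucleomorph
(":nucl"), Bacteria, Archaea, or unclassified at the domain rank;
(2) trophic selection keeping autotrophs and mixotrophs (chrysophytes,
cryptophytes and dinoflagellates count as phytoplankton), driven by a
configurable class → trophic lookup; (3) optionally, the top-n ASVs by
total reads (ties broken lexicographically by ASV id so runs are
deterministic). Features entering a correlation grid must additionally be
present in at least 8 samples (configurable): a rank correlation over 27
samples supported by fewer points is noise. Every filter appends an
in/out record to a provenance trail serialized with each run.

The denominator of R_ij is the sample's *phytoplankton* reads (after
heterotroph removal), not all microeukaryote reads — the anchoring
premise "read share ≈ community share" is only coherent for the community
the anchor measures.

## Consistency statistics

**Spearman grids.** Every (microscopy feature, ASV feature) pair gets an
average-rank Spearman r computed on pairwise-complete samples; cells with
fewer than 4 complete pairs, or zero rank variance, stay undefined.
Two-sided p-values use the t approximation t = r√((n−2)/(1−r²)) with
n − 2 df; an exact permutation p is available for n ≤ 12.
Benjamini–Hochberg adjustment is applied jointly over all defined cells
of a grid — one family per grid, matching how per-figure corrections are
normally reported. The critical value r* = t_crit/√(n−2+t_crit²) is
0.381 for n = 27 at α = 0.05.

**Co-inertia / RV.** The RV coefficient between two column-centered
sample × feature tables, tr(XᵀY·YᵀX)/√(tr((XᵀX)²)·tr((YᵀY)²)), measures
global co-structure in [0, 1]; the co-inertia decomposition comes from
the SVD of the cross-covariance XᵀY/n, whose squared singular values are
per-axis co-inertia. Co-inertia is computed directly on the centered
quantitative tables: a classical-MDS (Euclidean PCoA) embedding of each
table is rotation-equivalent to the centered table itself and yields the
identical RV, so the embedding step is omitted (and the equivalence is
what the rotation-invariance unit test asserts).

**Transforms.** The clr transform ln(x_i/g(x)) maps closed compositions
to an unconstrained space; rows are closed first, so clr is scale
invariant per row. Zeros are replaced multiplicatively per row with
δ = half the smallest nonzero proportion of that row (nonzero entries
rescaled so the row still sums to 1); the per-sample δ values are
recorded in the output metadata because zero handling is a modelling
choice that must be reproducible. The rank-[0,1] transform replaces each
feature's values by (rank − 1)/(n − 1) with average ranks for ties and
0.5 for constant features.

**Diversity.** Shannon in nats, Simpson as 1 − Σp² (Gini–Simpson), Chao1
in the bias-corrected form S + F1(F1−1)/(2(F2+1)) requiring integer
counts, and analytic rarefaction E[S_d] = Σ_i [1 − C(N−N_i,d)/C(N,d)]
computed with log-gamma for stability.

**Heatmap ordering.** Complete-linkage agglomerative clustering on
Euclidean distances, rows and columns independently; undefined
correlations are imputed as 0 for the distance computation only, and
labels are pre-sorted so equal profiles tie-break deterministically.

## Synthetic community generator

The generator emulates the data-generating process of a multi-year lake
monitoring survey, defaulting to 9 stations × 3 years = 27 samples.

*Community.* Eight classes (three diatom classes, chrysophytes,
cryptophytes, dinoflagellates, two green-algal classes) with lognormal
species abundances and cell volumes. The log abundance of species *s*
(class *c*) in sample (station, year) is

    mu_c + delta_s + kappa_y + eta_{c,y} + zeta_{s,y} + eps

with delta_s the species baseline (which species dominate their class),
kappa_y a community-wide year effect (bloom intensity; sd 1.0), eta_{c,y}
a class-level year effect shared by the class's species (year-dominant
class turnover; sd 1.5), zeta_{s,y} species-level year individuality
(species of one class peaking in different years; sd 1.0), and eps
station-level noise (sd 0.6). The class means are hierarchical — diatoms
and chrysophytes one to two orders of magnitude above the minor classes —
because spring lake communities are strongly dominance-structured: single
species reach well over half the community in their bloom year. kappa_y
deserves emphasis: it cancels exactly in every relative quantity (read
shares and microscopy shares alike) but drives the anchors A_j and M_j,
so it is precisely the signal that only absolute anchoring can recover.
These magnitudes were fixed once, from the qualitative features of spring
lake phytoplankton dynamics (order-of-magnitude interannual swings,
year-dominant turnover, strong within-class dominance).

*Observation models.* Microscopy Poisson-counts the cells in an
effective volume of 0.005 L (tens of cells for a mid-abundance species,
i.e. realistic counting error) and reports count/volume as cells L⁻¹;
zero-count species are absent from the table, so sparsity arises
naturally. Reads are multinomial at depth 50 000 with per-species weight
abundance × copy number × primer efficiency, where copy number ∝
biovolume^0.6 and primer efficiency is a class-level multiplier
(dinoflagellates 2.0, others 0.8–1.3). Species↔ASV mapping is imperfect:
70% one-to-one, 20% merged pairwise into a shared genus-level ASV, 10%
visible only to metabarcoding; 22 heterotroph ASVs (ciliates, cercozoans,
bicosoecids, fungi) take 40% of the expected library and must be filtered
out downstream. The within-class read shares remain unbiased under
class-level bias up to the residual within-class copy-number variation —
the premise that makes class anchoring the more accurate scheme.

All randomness flows from one seed through per-stage seed sequences, so
each stage and the composed dataset are individually reproducible.

*What the generator does not emulate:* sequence-level error (no FASTQ,
chimeras or per-base error model — denoising is upstream of this
package), tag jumping / cross-talk, DNA extraction efficiency differences
within a class, spatial structure beyond station-level noise, and
seasonal (within-year) dynamics. Passing tests therefore demonstrate that
the workflow's logic and statistics behave correctly under a controlled
bias structure, not that any particular field dataset satisfies the
anchoring assumptions.

## Numerical and design choices

- Non-empty relative-abundance rows must sum to 1 within 1e−9; clr rows
  sum to 0 within 1e−9; conservation assertions use 1e−9 relative
  tolerance. Anchoring itself is a single multiply, so errors stay at
  machine precision.
- Zero-read samples in a scope are flagged empty (NaN rows) rather than
  raising, since a class being absent from a sample is data, not error.
- Undefined correlation cells are excluded from the BH family; they can
  neither gain nor cost significance.
- Ordering ties (top-n selection, clustering leaves) break by feature
  label so that repeated runs are byte-identical.
- The exact-permutation Spearman p is limited to n ≤ 12 (factorial
  enumeration); above that the t approximation is the only option
  offered, which at n = 27 is accurate far beyond the precision of any
  decision made at α = 0.05.
- The problem sizes run by the test-suite and the acceptance script — 27
  samples, ~38 species, 36 phytoplankton ASVs, read depth 5×10⁴ (10⁵ in
  the recovery study), 100 random conservation fixtures, 10⁴ Monte-Carlo
  rarefaction replicates — were chosen to match the emulated survey
  design; the statistics of interest stabilize well below these sizes.

## Known limitations

- The anchoring transfers microscopy's counting error into every ASV
  estimate; the package propagates no uncertainty intervals.
- Class anchoring needs reliable class assignment on both sides;
  ASVs with unresolvable class are silently restricted to the total
  scheme (with a warning).
- The RV comparison uses complete-case matrices (masked cells filled
  with 0 after the pairwise statistics are done); a masked-aware RV is
  not implemented.
- Chao1 on microscopy abundances is meaningless (non-integer) and is
  reported as NaN in the diversity table rather than computed on rounded
  values.
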