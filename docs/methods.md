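# Methods

This note documents the statistical models implemented in `aerosource`, the
conventions fixed where the field leaves a choice open, and what the
synthetic studies used for validation do and do not establish.

## The synthetic study model

The generator (`aerosource.synth`) emulates the *post-clustering* stage of a
paired source→sink aerobiology campaign. Its defaults describe one study:
8 usable sites, 300 OTUs, 20,000 reads per environmental library.

For a study with `n_otus` OTUs, the OTU axis is partitioned into a
designated epiphyte block (`n_plant_otus`, default 60), a plant-tail block,
a background block, and a reagent-contaminant block (`n_contam_otus`,
default 30) at the end. Profiles:

* **Plant (per site).** A `plant_dominance` fraction (default 0.5) of the
  mass sits on the epiphyte block with log-normal relative abundances
  (σ = 1.5), because real epiphyte communities are dominated by a handful
  of taxa — on the order of twenty OTUs carrying about half the reads. The
  remaining mass is a symmetric Dirichlet over the plant-tail block.
* **Background (shared).** One regional community, symmetric Dirichlet over
  the background block plus an `overlap` fraction (default 0.1) of the
  plant support. `overlap = 0` makes plant and background supports
  disjoint; 0.1 keeps them mostly, but not perfectly, separable — the
  realistic regime in which both the source tracker and the enrichment
  regression have to work.
* **Contaminant (shared).** Symmetric Dirichlet over the contaminant block.

Sampling is *mixture-at-composition-level*: a sample with plant-origin
fraction `m` and contamination rate `c` (default 0.02) is one multinomial
draw from `(1−m−c)·background + m·plant + c·contaminant`. Summing
independent per-source draws would have the same expectation but a more
awkward likelihood; the single draw keeps every expected downwind
proportion an exact convex combination, which the recovery tests exploit.
Controls (2 NTCs + 3 extraction controls by default) are drawn from the
contaminant profile alone at `library_size // 50` reads — the 10–100×
smaller low-biomass regime the decontamination stage is designed for.

Seeding: one master seed; every sample gets its own generator derived from
`SeedSequence([seed, site_index, habitat_code])`, so adding a site never
changes another site's draws.

**What the generator does not emulate:** overdispersion beyond the
multinomial (no Dirichlet-multinomial read noise per sample),
taxon-specific release efficiency from the leaf surface, wind-direction
failures, spatial autocorrelation between nearby sites, and sequencing-era
artifacts (chimeras, singleton inflation). Passing recovery tests therefore
show the *estimators* are correct under the stated mixture model, not that
real field data will be as well-behaved.

## Decontamination

Two-stage correction, NTCs first: environmental samples and extraction
controls are amplified under the same conditions, so NTC signal must be
removed from both before the extraction controls can be interpreted.

For each OTU with nonzero control reads, per environmental sample the ratio
of its environmental relative abundance to its control relative abundance
is formed (equivalently, environmental count over the control count scaled
by the library-size ratio), and the **median** ratio over environmental
samples decides:

* median < `similarity_threshold` (default 5): the OTU is present at
  similar scaled read numbers → the whole row is removed;
* median ≥ `subtract_threshold` (default 5): the control reads are treated
  as a spill-over floor → per-sample relative subtraction
  `count_s − (lib_s/lib_control)·count_control`, clamped at zero.

Choices fixed here, with rationale:

* The two thresholds coincide by default, giving a single boundary; the
  prose "five-times" rule is grammatically ambiguous about direction, so
  `invert_rule=True` swaps the two sets for sensitivity analysis.
* Multiple controls of one habitat are aggregated by summing counts and
  libraries (per-control sequential application behind
  `per_control_sequential=True`).
* Stage-2 classification uses the *corrected* extraction controls and the
  *current* (post-stage-1) library sizes — the quantities that exist at
  that point in the procedure.
* Corrected values are real-valued; they are rounded half-to-even before
  rarefaction because subsampling is defined on integers. Negative
  corrected counts clamp to zero (counts cannot be negative).

Rarefaction subsamples each library to the common depth without replacement
(`numpy`'s multivariate hypergeometric), drops and reports samples below
depth, and is bit-reproducible for a fixed seed. The orchestration defaults
follow the original survey design: 4,714 reads (bacteria), 1,200 (fungi),
3,801 after correction.

## Diversity, distance, ordination

Shannon entropy is reported in nats (base unstated in common usage; natural
log chosen and documented). Chao1 uses the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))`, finite even with no doubletons. Canberra is
normalised by the number of nonzero pairs so values are in [0, 1] and
comparable across pairs (raw sum behind a flag). nMDS is nonmetric MDS with
isotonic regression minimising Kruskal stress-1; defaults 20 random
restarts, 300 iterations, convergence at stress change < 1e-6 (none of
these is dictated by the design; they are conventional). Hierarchical
clustering is fixed to average linkage (UPGMA), whose merge heights are
non-decreasing on a dissimilarity; dendrograms serialise to Newick with
branch lengths of half the height difference (ultrametric convention).

## Permutation inference

ANOSIM: R = (r̄_between − r̄_within) / (n(n−1)/4) on the ranks of all
pairwise dissimilarities; R is invariant to monotone transforms of the
distances. PERMANOVA: total sum of squares `Σ_{i<j} d²_ij / n`, within-group
analogues per group, pseudo-F with (a−1, n−a) degrees of freedom; on
Euclidean distances of 1-D data this reduces exactly to the classical
one-way ANOVA F, which the tests assert to 1e-9. Both tests permute sample
labels with a seeded generator and use the +1 convention (observed
statistic included in the reference set), so p ≥ 1/(B+1) and the test is
exact-level on the discrete p-grid — the type-I error calibration check
relies on this. One-factor only: the paired design gives marginal
habitat/site questions; interactions and strata are out of scope.

Mann-Whitney pairwise comparisons use exact enumeration for tie-free groups
of ≤ 8, the tie-corrected normal approximation otherwise; Bonferroni
multiplies by the number of pairs and caps at 1.

## Enrichment regression

For every site with all three habitats, every OTU recovered on the plant at
relative abundance ≥ `min_plant_prop` (default 0.001 = 0.1%) contributes
one point: response `d_air = p_downwind − p_upwind` (fractional scale, so
d_air ∈ [−1, 1]); predictor `log(1 + plant abundance in percent)` —
the percent scale matches how such axes are conventionally drawn, and a
flag switches to fractions. The filter is applied per site, so an OTU can
enter from one site and not another; points are pooled and fitted by OLS
with a two-sided t-test on the slope. Sites missing a habitat are excluded
and reported. A degenerate all-zero response (downwind ≡ upwind) returns
slope 0 with p = 1 rather than an undefined t-statistic.

## Source tracking

Collapsed Gibbs sampler over per-read source labels; conditional for read i
carrying OTU o:

    P(z_i = v) ∝ (S_vo + A_vo + α_v) / (S_v· + m_v + α_v·K) · (m_v + β_v)

with training counts S, current assigned counts A (the unknown source has
S ≡ 0 and lives entirely off A), α_source = 0.001 and α_unknown = 0.1 per
OTU, and β total mass 10 spread uniformly over sources. Burn-in 25 sweeps,
25 retained draws, 10 independent restarts averaged — the published
defaults of this family of samplers; all configurable. Posterior means,
2.5/97.5 percentile intervals. Sinks are rarefied to a common depth
(default 1000 reads) before attribution because the m_v prior term scales
with depth. The inner sweep is JIT-compiled with numba; a fixed seed gives
bit-identical posteriors for a fixed restart count.

One caveat discovered during validation: sending α_unknown → ∞ does *not*
drive all mass to the unknown source — the unknown per-OTU probability
tends to 1/K, which a well-matched known source still beats. The defensible
monotonic property (larger α_unknown ⇒ larger unknown share on a mixed
sink) is what the tests assert.

## qPCR

Efficiency `E = −1 + 10^(−1/slope)`; −3.3219 cycles per decade is perfect
doubling. Unknowns are interpolated through the curve inverse
`copies = 10^((Cq − intercept)/slope)`; duplicate reactions are averaged on
the copy scale (geometric mean behind a flag). Copies per m³ undo the
protocol bookkeeping: `copies/rxn × (elution/template volume) / filter
fraction / air volume`.

## Problem sizes used in validation

Recovery tests run the default study design (8 sites, 300 OTUs, 20,000-read
libraries) across 20 seeds per condition for decontamination recovery,
source-attribution recovery at mixing fractions {0, 0.25, 0.5, 0.75}, and
the enrichment power check at mixing 0.4; the permutation type-I
calibration uses 1,000 null datasets of 10 samples at 199 permutations
each. These sizes give Monte-Carlo standard errors comfortably below the
asserted tolerances. `scripts/acceptance.py` reports the same quantities at
10 seeds per condition, which leaves its estimates within a percentage
point or two of the 20-seed values.

## Known limitations

* Decontamination classifies on the aggregated controls; very uneven
  control libraries can let one deep control dominate the median ratio.
* The enrichment regression inherits OLS assumptions; d_air is bounded and
  heteroscedastic, so the slope's p-value is anti-conservative in the
  extreme tails.
* The source tracker's unknown source absorbs background *and* any plant
  signal the smoothing cannot explain; attribution at mixing fractions
  above ~0.75 biases slightly low.
* nMDS stress depends on restarts; with few restarts a local optimum is
  possible (the default 20 restarts makes this rare for n ≤ 50).
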