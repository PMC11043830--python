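# Methods

## Data model

The unit of observation is a 4 cm² cell with an integer shoot count per
moss species. Units nest as cells ⊂ quadrats ⊂ exclosure-scale plots,
with a paired structure: each pair holds one `absence` plot (inside the
goose exclosure) and one `presence` plot (open control). Aggregation to
a coarser scale always **sums** raw counts — the bias-corrected inverse
Simpson estimator needs integer totals, and sums make conservation an
exact integer invariant, checked in tests. Zero-count rows are accepted
on input and treated as explicit absences; presence always means
count > 0. Cell labels are 1-based, row-major on the 5 × 5 grid and
carry no spatial meaning — no analysis uses coordinates.

Shoot density is the mean over cells of (total shoots / 4 cm²). Cells
whose total is zero are included in the mean: excluding them would bias
density upward in sparse communities, and the data model keeps empty
cells enumerable precisely so they can enter here.

## Alpha diversity

* **Richness** counts species with positive abundance.
* **Evenness** is Smith & Wilson's E_var,
  `E = 1 − (2/π)·arctan(V)` with `V` the *population* (divide-by-S)
  variance of log abundances over the S species present. Species with
  zero abundance are excluded (ln 0 is undefined) and S is the observed
  richness of the unit. A single-species unit necessarily gets E = 1
  (arctan 0); the per-unit table flags these rows `degenerate_evenness`
  so they are not over-interpreted. E is invariant to rescaling all
  abundances by a common factor (the log shift cancels), which the suite
  asserts to 1e-12.
* **Inverse Simpson** uses the without-replacement estimator
  `λ = Σ n_i(n_i−1)/(T(T−1))`. It is undefined (NaN) for T < 2 and when
  every species is a singleton (λ = 0). Undefined values are excluded
  from treatment means and the exclusion count is reported; coding them
  as 0 would bias the means downward.

## Beta diversity

Pairwise dissimilarity uses the abundance-based Bray–Curtis form and
Baselga's decomposition into balanced variation (`β_bal`, turnover:
shoots of some species substituted by equal numbers of shoots of other
species) and abundance gradients (`β_gra`, nestedness: shoots lost from
one unit without substitution). `β_bal + β_gra = β_BC` holds exactly
and is enforced to 1e-12 on random pairs; `β_BC` is cross-checked
against an independent classical Bray–Curtis implementation (scipy).
Degenerate pairs: if both units are empty all three values are
undefined (NaN, excluded from means with a logged count); if exactly
one unit is empty the pair is a pure gradient (`β_BC = β_gra = 1`,
`β_bal = 0`).

Per-unit summaries average each unit's pairwise partitions against its
*comparison group*: cells against the other 24 cells of their quadrat,
quadrats against the other 4 of their plot, exclosure-scale plots
against the other 9 of their treatment. This convention yields the
design's per-treatment unit counts of 1250 / 50 / 10 and never forms
cross-treatment pairs; groups of size one are skipped with a warning.

**SCBD** is computed from raw abundances, `SCBD_i = SS_i / Σ SS` with
`SS_i` the among-unit sum of squares of species i. No Hellinger or
other transformation is applied — common library defaults transform
first, but the raw-abundance form is the definition used here, and the
vector sums to 1 by construction.

## Interspecific association

The variance-ratio test operates on presence/absence. With occurrence
frequencies `p_i = n_i/N`, observed variance of per-plot richness
`S_T² = (1/N)Σ(T_j − t̄)²` and its independence expectation
`δ_T² = Σ p_i(1−p_i)`: `VR = S_T²/δ_T²` and `W = VR·N`. VR > 1 flags
positive overall association, VR < 1 negative; significance uses the
two-sided chi-square criterion with N degrees of freedom, where the
"upper" critical value is the 0.95 quantile of χ²_N and the "lower" the
0.05 quantile — the only convention under which the two-sided rule is
coherent. A verdict of `positive` requires both VR > 1 and W above the
upper bound, `negative` both VR < 1 and W below the lower bound. The
statistic is validated by calibration: for species occurring
independently across 10,000 plots, |VR − 1| < 0.05. The default input
is the quadrat-scale matrix of one treatment (N = 50); the scale is an
ordinary argument.

Pairwise associations are Spearman rank correlations of abundances
across units (quadrat scale by default), average ranks on ties.
Species present in fewer than 3 units are skipped (degenerate ranks;
the count is recorded), a constant species yields an undefined rho and
a `neutral` label. Classification as positive/negative requires the
multiplicity-adjusted p below α; Holm is the default adjustment
(conservative, no dependence assumptions) and both raw and adjusted
p-values are reported so either convention can be read off.

## Permutation inference

Model-based mixed-effects fits are deliberately out of scope; the
package's inferential tools are two permutation tests chosen to respect
the design.

* **PERMANOVA**: pseudo-F from the partition of summed squared
  Bray–Curtis distances, null distribution from Monte-Carlo label
  permutations (default 999), optionally restricted within strata
  (e.g. pairs); unrestricted by default. p-values use the add-one rule
  and cannot be 0. The pseudo-F is cross-checked against scikit-bio's
  PERMANOVA in the suite. Note a small-sample floor: with two groups of
  5 a uniform permutation re-creates the observed split with
  probability 2/252, so the attainable minimum p at 999 permutations is
  ≈ 0.009, not 1/1000 — any label-permutation implementation shares
  this property.
* **Paired sign-flip contrast**: per-unit statistics are averaged to
  one value per (pair, treatment) arm; the observed effect is the mean
  of within-pair presence-minus-absence differences, and the null flips
  each difference's sign independently. Exact enumeration of all 2^B
  sign patterns is available for B ≤ 20 blocks; otherwise Monte-Carlo
  with the add-one rule. Type-I error at nominal 0.05 is verified to
  lie in [0.02, 0.09] for both tests on null data (250 replicates of
  i.i.d. 20-unit communities for PERMANOVA; 200 replicates of a
  reduced-size exchangeable-arms synthetic design for the contrast —
  calibration is a property of the test, so modest problem sizes
  suffice and keep the suite fast).

## Synthetic generator

The generator draws from an explicit hierarchical model, fully
deterministic given its seed (per-unit substreams are spawned with
fixed keys, so enlarging the design leaves earlier units unchanged —
asserted in the suite).

1. Global species relative abundances from a lognormal SAD,
   `sigma = sad_sigma` (default 1.5, a typical skew: a few dominants,
   a long rare tail). Species below the median weight are
   "subordinate".
2. Plot- and quadrat-level lognormal random effects
   (`patchiness_sigma`, default 0.7) multiply species weights —
   compositional patchiness of the carpet.
3. Treatment effects in presence plots:
   * `evenness_effect` (default 0.25) flattens global weights,
     `w → w^(1−effect)`;
   * `richness_effect` (default 0.3) adds to subordinate species'
     per-quadrat occupancy probability (baseline
     `subordinate_occupancy` = 0.5; dominants always occupy) —
     emulating the opening of regeneration niches;
   * `homogenization` (default 0.5) mixes quadrat weights toward their
     plot pool and plot weights toward the shared pool, shrinking
     patchiness at both levels.
4. Expected cell total = `base_density` (36 shoots ≙ 9.0 shoots/cm²)
   × `density_multiplier` (1.7) in presence; quadrat weights are
   renormalized so this expectation is exact. Totals therefore carry
   pure Poisson noise while patchiness acts on composition only — a
   direct consequence of fixing the expected cell total.
5. Cell counts are independent Poisson draws, mean = total × weight.
   Cell-level overdispersion relative to a marginal Poisson arises from
   the hierarchical log-normal effects on composition.
6. Growth forms are assigned from the configured pool counts
   (34 acrocarps / 16 pleurocarps / 2 *Sphagnum* of 52 species).

Defaults are the study conditions: 10 pairs × 5 quadrats × 25 cells ×
2 treatments = 2500 cells, and the 9.0 vs 15.3 shoots/cm² density
contrast. Effect-size defaults were fixed once, during generator
design, so that each knob demonstrably drives its matched statistic at
the default design size; they are documented here and not tuned per
analysis.

**Matched statistics and what recovery shows.** Each knob moves one
pipeline statistic in a documented direction, verified over 100
replicate seeds with ≥ 95% concordance: richness_effect → quadrat-scale
mean richness up in presence (the occupancy mechanism operates per
quadrat; at the cell scale rare subordinates are heavily diluted by
detection noise); evenness_effect → quadrat E_var up; homogenization →
quadrat- and exclosure-scale β_BC and β_bal down (cells within one
quadrat share a single weight vector, so pool mixing cannot move
within-quadrat cell-scale beta — the cell-scale beta decline seen under
the full default configuration comes from the density and evenness
effects); density_multiplier → presence/absence density ratio within 5%
of 1.7. With all effects zero the two arms are exchangeable and the
paired contrast rejects at ≈ the nominal rate.

What the generator does **not** emulate: spatially explicit grubbing
patches, temporal dynamics, species-specific responses, and the unknown
dispersion structure of real field data. Passing recovery tests
therefore demonstrates that the pipeline detects effects of the assumed
generative form at the study's design size — not that real moss data
meet those assumptions.

## Numerical conventions

* Tolerances: exact integer equality for count conservation; 1e-12 for
  partition additivity, SCBD normalization, relative-frequency
  normalization and E_var scale invariance.
* Undefined markers are NaN throughout (never 0), with exclusion
  counts reported wherever means are taken.
* All randomness flows from a single seed; permutation tests take the
  seed explicitly; the CLI requires `--seed`.
* Pipeline outputs are plain CSV plus a JSON manifest (package and
  library versions, configuration, seed, file list); reruns with the
  same configuration and seed are byte-identical.

## Limitations

* GLMM/SEM machinery, NMDS ordination, dispersion tests and post-hoc
  HSD are intentionally absent; the permutation contrast is a
  methodological substitute for model-based treatment inference, not a
  re-implementation of it.
* The comparison-group convention for per-unit beta means and the
  quadrat-scale default for associations are design choices; both are
  configurable at the call sites.
* SCBD on raw abundances makes dominant species carry most of the
  signal, by construction; transform upstream if that is not wanted.
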