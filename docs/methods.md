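# Methods

`pleioscan` implements the statistical core of a systems-genetics workflow
that connects gut-microbial abundances and metabolite (bile-acid) levels to
host genetic variation in a multiparent mouse population, and then asks
whether co-mapping microbe–metabolite pairs are driven by one shared locus
and in which causal direction. Everything below is exercised on synthetic
data with known truth; the package ships no study data.

## Mapping model

Phenotypes are regressed on founder-haplotype dosages. At marker *m*,
individual *i* carries an expected count `d_imf ∈ [0, 2]` of each of the
eight founder alleles (A–H; the slices sum to 2). The scan model is

    y = X β + d_m γ + u + ε,     u ~ N(0, σg² K),  ε ~ N(0, σe² I)

with additive covariates X (intercept, sex, wave dummies, centered days on
diet), founder contrasts γ constrained to sum to zero (all eight strains are
treated symmetrically; only seven contrasts are identifiable because the
dosages sum to 2), and a polygenic term whose covariance is the
leave-one-chromosome-out (LOCO) kinship

    K_ij = (1/M') Σ_{m ∉ c} Σ_f (d_imf/2)(d_jmf/2)

for markers on all chromosomes except the scanned one. The mapping statistic
is `LOD = (n/2)·log10(RSS0/RSS1)` from generalized-least-squares fits in the
eigenbasis of K.

Numerical choices:

- The variance ratio h² = σg²/(σg²+σe²) is estimated once per (trait,
  chromosome) under the no-QTL null by REML (bounded 1-D optimization on
  [0, 0.999]) and held fixed across markers — the standard speed/accuracy
  trade-off in multiparent mapping. When the restricted likelihood is flat
  (e.g. K = I) the boundary convention h² = 0 applies.
- Kinship eigenvalues are rescaled to mean 1 inside the REML fit (equivalent
  to dividing K by its average diagonal, which is ~0.55 for an 8-founder
  mosaic), so h² reads as a fraction of trait variance.
- Missing trait values are dropped trait-wise (complete cases); the kinship
  sub-matrix is re-eigendecomposed for incomplete traits.
- A trait with zero residual variance after covariates yields a flat zero
  LOD curve rather than an error in the scan (the null REML fit, called
  directly, rejects it).

**Permutation thresholds.** Each permutation shuffles the rows of
(phenotype + covariates) jointly against the genotypes, preserving the
trait–covariate association, and records the genome-wide maximum LOD.
Max-LOD values are pooled across traits and the threshold at level α is the
(1−α) quantile of the pooled distribution — one common threshold for all
phenotypes. One shared permutation order per iteration is applied to every
trait (each iteration contributes one max-LOD per trait); for independent
traits this leaves the pooled quantile unbiased and lets the null scans be
batched. Default 1000 permutations (configurable; the calibration checks use
fewer, stated below).

**Peaks and support intervals.** Peaks are per-chromosome local maxima above
a threshold, merged within a 10-cM window (higher LOD wins). The support
interval treats `10^LOD`, normalized over the chromosome's marker grid, as a
posterior and grows the interval symmetrically outward from the peak until
it holds 95% of the mass. This is an approximation; its empirical coverage
is checked by simulation rather than assumed.

## Pleiotropy versus two linked loci

For two traits mapping to the same region, every ordered position pair
(λ₁, λ₂) in the interval is fit with the bivariate model: trait 1 on the
dosage at λ₁, trait 2 on the dosage at λ₂, shared covariates, and an
unstructured 2×2 residual covariance (seemingly-unrelated regressions,
iterated feasible GLS; on the diagonal λ₁ = λ₂ the fit is the exact
multivariate-regression MLE). The statistic is the log10 likelihood ratio

    lrt = [max over all (λ₁, λ₂) − max over λ₁ = λ₂] / ln 10.

Significance comes from a parametric bootstrap: data are resimulated from
the fitted single-locus null (bivariate normal residuals around the fitted
means at the diagonal argmax), the statistic is recomputed B times (default
1000), and `p = (1 + #{lrt_b ≥ lrt_obs}) / (B + 1)`. Replicates whose
profile fit fails are counted as exceeding the observed statistic
(conservative) and reported, never dropped.

Implementation notes:

- All design-side cross-product tensors are precomputed once per interval,
  so a bootstrap replicate costs only the trait-side products; the FGLS
  iteration runs batched over all grid cells. The GLS normal equations are
  scaled by det(S), which leaves the solution unchanged and keeps perfectly
  correlated trait pairs finite; a 1e-10 relative ridge guards the stacked
  system.
- Kinship is omitted from the bivariate model by default (the intended
  intervals are short and covariates absorb most structure); an optional
  shared-rotation whitening with the average of the two traits' null h² is
  available.
- The statistic has a point mass at zero: whenever the surface maximum falls
  on the diagonal, lrt = 0 and p = 1 by construction. On a coarse marker
  grid with a strong shared QTL this atom approaches 1 and the test cannot
  reject at any level — the grid must be dense enough that neighboring
  positions genuinely compete (the motivating studies scan interpolated
  pseudomarker grids at 0.02-cM spacing). The calibration checks therefore
  run on a 0.5-cM grid; with it, the lower tail of p is close to uniform
  and the size at 0.05 lands in the expected band.

## Mediation and causal model selection

A candidate mediator M of target T at locus Q is screened by rescanning T
with M appended as an additive covariate, over the individuals measured for
both traits; a LOD drop > 2 at Q passes the screen. Negative drops
(conditioned LOD higher) are flagged, not clipped. A mediator collinear with
the existing covariates is rejected.

Directionality is classified by BIC over four generative models, each a
product of Gaussian regressions given the locus dosage (entering as the
8-column allele dosage through the sum-to-zero contrast) and covariates:
M1 causal `f(M|Q)·f(T|M)`, M2 reactive `f(T|Q)·f(M|T)`, M3 independent
`f(M|Q)·f(T|Q)`, M4 full `f(M|Q)·f(T|Q,M)`. The verdict is the best model's
label, or *undecided* when the top-two BIC gap is under 2 or when M4 wins
(no direction resolved). This is a penalized-likelihood simplification of
the published causal-model-selection test, which uses pairwise penalized
z-tests; the BIC variant keeps the same model set and decision semantics.

A caveat the synthetic experiments make visible: measurement noise on the
mediator (e.g. a microbial trait observed through sparse over-dispersed
counts) attenuates `f(T|M)` and biases the verdict toward *reactive*. The
classifier is accurate when both traits are observed on comparable noise
scales; verdicts across very different observation processes should be read
with that asymmetry in mind.

## Trait preparation

- **CMM filter**: keep features with a nonzero count in ≥ 20% of individuals
  (inclusive; presence means count > 0, not an abundance floor).
- **CSS**: per-sample scaling factor `s_j` = sum of counts ≤ the sample's
  median (quantile l = 0.5, configurable) of *positive* counts; output
  `count/s_j × 1000`. The downstream rank transform makes the scale constant
  irrelevant to mapping. The quantile heuristic of the reference CSS
  implementation is data-adaptive; a fixed quantile keeps runs deterministic.
- **RINT**: `Φ⁻¹((r − 3/8)/(n + 1/4))` (Blom offset), average ranks for
  ties, missing values preserved.
- **Internal-standard normalization**: `(area/IS_j)·mean(IS_j)` per sample,
  removing injection/extraction factors while keeping the area scale;
  metabolites are then log2-transformed (pseudo-count 0; areas are strictly
  positive after IS normalization).
- **Agglomeration**: features sharing a Greengenes lineage prefix through
  the requested rank are summed; features unassigned at that rank go to an
  explicit `unclassified-<parent>` bucket. Column totals are conserved.
- The correlation screen (Spearman, pairwise-complete, BH adjustment,
  defaults q < 0.01 and |ρ| > 0.35) runs on the CSS/RINT microbial scale and
  log2 metabolite scale; Spearman is rank-based, so the CSS step matters
  only through ties.

## Synthetic data generator

The generator emulates the statistical structure the mapping model assumes,
with these choices (defaults in parentheses):

- **Genomes**: two independent founder mosaics per chromosome per
  individual; founder switches form a homogeneous Poisson process on the cM
  scale (0.2 switches/cM per chromosome pair, i.e. 0.1 per gamete,
  approximating the block structure after ~20 outbreeding generations —
  a knob, not a claim); after a switch the new founder is uniform over the
  other seven. Pedigree-accurate DO breeding and the X chromosome are out of
  scope; the scan needs realistic block structure, not genealogy.
  Optional Dirichlet mixing (weight 0.05 when enabled) emulates
  haplotype-reconstruction uncertainty; slices still sum to 2.
- **Traits**: latent value = QTL term (empirically standardized so the
  requested variance fraction is realized in-sample) + polygenic draw with
  covariance ∝ genome-wide K + covariate effects + Gaussian noise.
- **Microbial counts**: negative binomial (Gamma–Poisson, size 5) with log
  link, slope 0.7 per latent SD, baseline mean 50; one log-normal
  library-size factor per *sample*, shared by all features (this is exactly
  what CSS removes). Requested prevalence π is enforced by zeroing samples
  below the (1−π) latent quantile, so sparsity correlates with true
  abundance.
- **Metabolites**: log-normal peak areas (scale 0.5 per latent SD) times a
  per-sample injection factor shared with the internal-standard channel, so
  internal-standard normalization can undo it.
- **Covariates**: sex Bernoulli(½), wave uniform 1–5, days on diet uniform
  147–175 (21–25 weeks).
- **Pair architectures**: *pleiotropic* (one locus, shared effect vector,
  independent noise), *linked* (two distinct loci), *causal*/*reactive*
  (locus → source trait → downstream trait with no direct edge, path
  coefficient 1 by default), *independent*. Architecture tags and all
  effect vectors are recorded as ground truth.
- One global seed fans out to per-component child seeds, so stages can be
  regenerated independently and byte-identically.

What the generator does **not** emulate: compositionality constraints and
taxon–taxon interactions, phylogenetic correlation between features, batch
effects beyond a scalar library factor, real LC-MS peak-picking artifacts,
linkage disequilibrium with ungenotyped variants, and DO pedigree structure.
Passing tests therefore show the statistical machinery is correct and
calibrated under its assumed model, not that the assumptions hold in any
particular real data set.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run everything at desk scale, the
package's own choice of simulation size: oracle equivalence on 50 (tests) /
20 (script) random data sets of n = 100 with 200 markers; threshold
calibration with 100 null traits and 200 permutations pooled; QTL recovery
with 200 (tests) / 100 (script) replicates of a 20%-variance QTL at n = 400
on a 10×30-marker genome; pleiotropy size over 100 (tests) / 60 (script)
pleiotropic pairs and power over 30 two-locus pairs at B = 200; mediation
over 30 full-mediation and 100/50 independent-mediator replicates; CMST over
100/60 replicates per generating model; and an end-to-end demo at n = 200
with 5 chromosomes, 100 permutations and B = 200, run twice to confirm
byte-identical outputs.

## Known limitations

- The Bayes support interval is a grid approximation; coverage is checked
  empirically (target band 0.80–0.995 for strong QTL), not guaranteed.
- The pleiotropy bootstrap is conservative on coarse grids (see above) and
  slightly anti-conservative when a strong shared polygenic signal is left
  unmodeled; the kinship-whitening option addresses the latter.
- BIC-based CMST does not reproduce the published test's penalized z-tests
  and inherits the mediator-measurement-noise asymmetry described above.
- Permutations re-estimate h² per chromosome per trait, which is exact but
  makes LMM permutations ~10× the cost of the OLS fast path used when no
  kinship is supplied.
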