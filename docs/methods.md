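# Methods

## The experimental design being modeled

A spawning event (block) contributes one or two factorial sets of three
sires crossed with three dams, giving 9–18 full-sib families of which a
random subset is reared: each reared family gets one tank of 50 larvae
per seawater treatment (ambient ~pH 8.0 vs acidified ~pH 7.6), and a
fraction of families get duplicate tanks. Tanks are followed for 14
days with daily survivor counts; 10 larvae per tank are measured for
standard length at day 0 and day 14. The default design has 16 blocks,
two sets per block, at most 12 family slots per block and a duplicate
fraction of 0.25, which reproduces the scale of the motivating
experiment (~150 family-by-treatment replicates, 76 paternal half-sib
and 67 maternal half-sib contrasts).

## Traits

*Daily mortality rate*: the negated OLS slope of ln(survivors) on day,
using only days with a positive count. Day 0 is included (the stocking
count is known exactly); days after a tank empties carry no information
and ln(0) is undefined, so the series is truncated at the last positive
count rather than offset-corrected — this keeps the estimator exact on
noiseless exponential decay. *Growth*: change in mean standard length
(mm) over the experiment, not a daily rate.

Treatment contrasts use spawning blocks as replicates: a paired t test
on block means with df = blocks − 1. An added daily mortality Δm
sustained for D days multiplies survivorship by exp(−Δm·D); the
percentage decrease 100(1 − exp(−Δm·D)) is the headline survival
number. Note that with the published per-pH-unit sensitivity of 0.109
this arithmetic gives 19.6% for a 0.1-unit drop over 20 days (19.5% is
obtained from a less-rounded coefficient).

## The animal model

Records are tanks. Each tank is entered in the pedigree as an offspring
of its family's sire and dam ("tank-level pseudo-individual"), which is
the only encoding consistent with group phenotypes whose full-sib
similarity is 0.5·V_A and half-sib similarity 0.25·V_A. The model is

    y_tank = mu + a_tank + m_dam + b_block + e_tank,

with a ~ N(0, A ⊗ G) over the pedigree (A the additive relationship
matrix), m ~ N(0, I ⊗ M), b ~ N(0, I ⊗ B), e ~ N(0, I ⊗ R), all four
components unstructured 4×4. Each tank observes exactly the two traits
of its treatment; cross-environment (co)variances are identified
through relatives split across treatments.

Priors are inverse-Wishart per component, density ∝
|Σ|^−(ν+p+1)/2 exp(−½ tr(νV₀ Σ⁻¹)), with V₀ diagonal at ¼ of the
observed per-trait phenotypic variance, modal covariances zero, and
ν = 0.001 — essentially flat. With four traits a component needs at
least four levels for its full conditional to be proper
(df = ν + levels > p − 1); the sampler refuses degenerate designs with
a clear error. One practical consequence of this prior worth knowing:
for weakly informed covariances its implied marginal on a correlation
is U-shaped (mass near ±1), so posterior correlations from small
designs lean toward the extremes.

### Sampler

A systematic-scan Gibbs sampler, partially collapsed over the
unobserved traits:

1. trait means from their normal conditional under the observed-data
   likelihood (per-record precision is the inverse of the observed
   2×2 sub-block of R, embedded in 4×4);
2. additive values, jointly per independence class of the A⁻¹
   adjacency (graph colouring: all tank pseudo-individuals form one
   class, sires and dams two more), each class vectorized by grouping
   levels with identical conditional precision;
3. maternal and block effect vectors, vectorized the same way;
4. G, M and B from their inverse-Wishart full conditionals (additive
   cross-product weighted by A⁻¹, df = ν + number of levels);
5. imputation of the unobserved two traits of each record from their
   conditional normal, immediately followed by the conjugate
   inverse-Wishart draw of R (df = ν + records) — the completed data
   are used nowhere else.

Collapsing the missing traits out of steps 1–3 matters: with full data
augmentation the ~2 imputed values per record feed the current
cross-environment covariances back into the next sweep, and the
covariance parameters mix so slowly that chains of the length used here
are visibly unconverged. The collapsed scheme is an ordinary Gibbs
sampler on the observed-data posterior, with R updated through a single
augmentation step (an invariant sub-kernel for R's marginal
conditional).

Three families of extra posterior-invariant moves accelerate mixing,
all validated by a prior-reproduction (Geweke-style) check:

- *translation moves* (generalized Gibbs on the translation group):
  the flat ridge between the fixed means and each effect vector's mean
  is resampled exactly, eliminating the intercept/effect random walk;
- *per-trait scale moves* (parameter expansion): (u·c, c²X) for trait
  k, sampled by one slice-sampling update of the exact group-move
  density (likelihood Gaussian part × c^−(ν+1) × exp(−κ/2c²), the
  Haar measure of the multiplicative group included);
- *shear moves*: u[:,l] += γ·u[:,k] with the matching congruence on X;
  the unipotent transformation has unit Jacobians and an exactly
  Gaussian move density, so covariance directions jump in one draw.

The scale and shear moves are numba-compiled with randomness pre-drawn
from the single chain generator, so runs are deterministic per seed.
Chain bookkeeping stores every thin-th post-burn-in state
(floor((n_iter − burn-in)/thin) samples; the reference configuration
150,000/1,000/80 stores 1,862).

Numerical safeguards: Cholesky factorizations retry once with a
1e-10·I jitter; Bartlett chi-square draws are floored at 1e-12, which
only binds for near-degenerate dfs.

### Validation

The sampler is checked four independent ways: (i) Henderson's sparse
A⁻¹ against the dense inverse of the tabular A, and both against
gene-drop Monte Carlo; (ii) a degenerate single-component model against
the closed-form inverse-Wishart posterior; (iii) prior reproduction —
run with no observed data, the sweep must return the proper test prior,
which it does for every component; (iv) spot comparison against an
independent random-walk Metropolis sampler on the marginal likelihood
(effects integrated out analytically) on small designs.

## Derived quantities

Per-sample: h² and the four variance proportions (which sum to one by
construction), r_G and r_M from the sampled matrices (PSD by
construction, so |r| ≤ 1 per sample), and Δz = Gβ. Intervals are
highest-posterior-density (shortest interval at 95%, leftmost on ties);
central quantile intervals are available as an option. Selection
projections are single-generation only — iterating them would assume G
constant across generations.

## Convergence diagnostics

Per scalar parameter: lag-1 autocorrelation of the thinned chain and
the Heidelberger–Welch tests. Stationarity uses the Cramér–von Mises
statistic of the partial-sum bridge normalized by n·S(0), with S(0)
estimated from the second half of the chain by an AIC-selected
Yule–Walker AR fit (Levinson–Durbin recursion), iterated over initial
10% discards up to 50%; the halfwidth test requires
1.96√(S(0)/n) ≤ 0.1·|mean|. The single-window test at α = 0.05 passes
~93–95% of iid chains (near-nominal); the iterated procedure, by
design, converts most marginal failures into passes after discarding a
burn-in prefix, so its pass rate on iid chains is higher. Both are
exposed.

## Synthetic data: what it does and does not emulate

The generator draws tank-level traits directly from the generative
model (pedigree-recursive breeding values; dam, block and tank effects
from the specified matrices), then layers observation processes on
top: survivor counts by daily binomial thinning with survival
exp(−m) (so the log-survivor regression is estimating the right rate),
and length samples with Gaussian noise around the latent growth.
Latent mortality rates can be negative under the Gaussian trait model;
count generation truncates them at zero. Default generating parameters
(`default_truth`) emulate the published variance proportions and
correlations, with total SDs of 0.045 per day (mortality) and 0.5 mm
(growth); block-effect correlations, which were not reported, are set
to moderate positive values (0.8 within a trait across environments,
0.3 across traits). Not emulated: egg/embryo mortality, size-selective
mortality within tanks, tank-position effects beyond the residual,
parental-condition (transgenerational) effects, and any seawater
chemistry dynamics. Passing recovery tests therefore demonstrates that
the estimation machinery is correct under the stated generative model,
not that real data meet its assumptions.

## Parameter-recovery study

Twenty synthetic experiments at four times the default scale (64
blocks, ~1,500 tank records each) are generated from a truth with
mortality h² = 0.2, growth h² = 0.1, cross-environment r_G = 0.45
(mortality) and 0.15 (growth), maternal share 0.3, block share 0.4
(residual the remainder), r_M = 0.8 and block-effect correlation 0.5.
Each is fit with a reduced chain (15,000 iterations, burn-in 2,500,
thin 10 — sizes chosen to keep the whole study in the tens of minutes
on one CPU); the truth should fall inside the 95% HPD in at least 17
of 20 runs per parameter. The recovery harness fits the latent tank
traits directly, isolating the animal model from trait-estimation
noise.

## Meta-analysis conventions

"Added mortality" subtracts each experiment's mean ambient daily
mortality from all of its replicates, removing between-species baseline
differences. The sensitivity slopes are pooled OLS of added mortality
on pCO₂ and, separately, on pH (reported per unit pH *decrease*, i.e.
negated); a per-species-slope average is available since the published
averaging convention is ambiguous. Long-horizon projections expose the
driver, its annual rate and the exposure window as parameters rather
than hard-coding any single end-of-century figure.
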