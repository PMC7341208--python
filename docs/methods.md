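# Methods

## Model

`ranktraits` estimates variance components and breeding values for *ranking
traits* — finishing positions of horses (or any competitors) within
competition events — jointly with continuous and threshold traits, under a
Thurstonian liability model fitted by Gibbs sampling.

Each start (one competitor in one event) contributes a record row. The
liability `l` of a start and any correlated observed trait `y` on the same
row follow

    (l, y) ~ MVN( (x_l' b_l + z_l' a_l,  x_y' b_y + z_y' a_y),  R )

where `b` collects systematic effects (including an optional per-event
effect on the liability), optional permanent environmental effects have
prior `MVN(0, P ⊗ I)`, and the additive genetic effects are
`(a_l, a_y) ~ MVN(0, G ⊗ A)` with `A` the numerator relationship matrix of
the pedigree. Rows are conditionally independent given the effects
(`R ⊗ I`); a residual correlation therefore acts *within* one row, which is
why the simulator emits one continuous record per start with the residual
pair drawn jointly.

The observed rank vector of an event is the descending order of its
liabilities. The scale and location of a latent liability are not
identifiable from ranks, so (i) the liability residual variance is fixed
(default 1.0, configurable via `RANKING_RESIDUAL_VAR`; threshold-trait
liabilities are likewise fixed at 1.0) and (ii) within each event the
winner's liability is pinned at exactly 0 while an event effect is
estimated. Under this identification the event effect is not a property of
the race itself: it indexes (negatively) the average level of the
competitors, because a stronger field forces the winner's — and hence
everyone's — liabilities to sit further above the event mean.

## Gibbs sampler

One iteration updates, in order:

1. **Missing-record augmentation.** Missing continuous/threshold cells and
   liabilities without a rank are redrawn from their row-wise Gaussian
   conditionals given the observed residuals, so full-row multivariate
   algebra applies everywhere downstream.
2. **Event liabilities.** For each ranking trait, the conditional mean and
   variance of a liability given the row's other traits use the precision
   form of the multivariate-normal conditional:
   `sigma² = 1/(R⁻¹)_ll` and `mu = x'b_l + z'a_l − sigma² Σ_q (R⁻¹)_lq e_q`.
   Within each event, ranks are swept best-to-worst: the winner is set to 0
   and each later rank is drawn from a truncated normal bounded above by the
   just-updated liability of the preceding competitor and below by the
   current liability of the next one (−∞ for the last). Because events are
   mutually independent, the sweep is vectorised across events by rank
   position.
3. **Threshold liabilities** are drawn between the thresholds of the
   observed category (binary traits use the single fixed threshold 0; with
   more categories the interior thresholds are resampled uniformly between
   the extreme liabilities of adjacent categories).
4. **Location effects.** Systematic and environmental effects are updated
   single-site with residual-precision weighting across traits; levels of
   one effect never share records, so all levels are drawn in one
   vectorised step. Additive effects are blocked per individual across
   traits — an exact scheme with better mixing — in a sequential sweep
   (numba-compiled) that couples relatives through the sparse `A⁻¹` and the
   current `G⁻¹`. Genetic-group columns participate with zero record count.
5. **Covariance matrices.** `G | a ~ IW(a'A⁻¹a + S₀, N + df₀)` (with
   groups, the Quaas–Westell augmented quadratic form, which equals the
   Mendelian-sampling form `(a−Qg)'A⁻¹(a−Qg)`; degrees of freedom count
   real individuals only). `P` analogously from the environmental
   solutions. `R` is drawn from the residual crossproducts; when one trait
   has a fixed residual variance `v`, `R` is decomposed into `v`, the
   regression `b` of the remaining traits on the liability residual
   (Gaussian conditional), and their conditional covariance `S` (inverted
   Wishart), then reassembled so `R_ll = v` holds bit-exactly. Models with
   more than one fixed-variance trait in a multivariate residual matrix are
   rejected as unsupported.

Default priors on `G`, `P`, `R` are the flat limiting inverted-Wishart form
(df = −(t+1), S = 0); proper priors can be supplied (`*_PRIOR_DF`,
`*_PRIOR_SCALE` keys, or `IWPrior` objects). A proper residual prior is
only supported when no trait has a fixed residual variance.

**Initialisation.** Location effects start at 0; liabilities on a
deterministic rank ladder (winner 0, each next rank 0.5 lower); covariance
matrices are diagonal, splitting the raw variance of the initialised
response equally among the variance components of each trait.

**Numerical choices.** Truncated normals are drawn by the inverse-CDF
method with a symmetry flip that keeps evaluation in the lower tail;
intervals whose probability mass falls below 1e-10 switch to exact
rejection samplers (Robert's exponential proposal for one-sided tails, a
clipped uniform proposal with the mode-side envelope otherwise).
Inverted-Wishart draws use the Bartlett decomposition driven by the chain's
single `numpy` Generator, so a seed reproduces a chain bit-exactly.
Cholesky factorisations guard positive definiteness every time a covariance
matrix is used; a failure aborts with a `NumericalError`. Systematic-effect
levels never observed have zero precision under the flat prior and are left
at 0 and flagged (`GibbsChain.skipped_levels`).

The precision-ratio regression in the liability conditional is
`(R⁻¹)_lq/(R⁻¹)_ll`, the unique form consistent with
`sigma² = 1/(R⁻¹)_ll`; tests verify it against the covariance-form
conditional `E[l|y] = mu_l + (sigma_ly/sigma_yy)(y − mu_y)`.

## Inference outputs

Posterior summaries use the retained (post-burn-in, thinned) variance
component samples: means, SDs and 95% HPD intervals (shortest contiguous
interval on the sorted samples). Heritabilities
`h² = sigma²_a/(sigma²_a + sigma²_pe + sigma²_e)`, variance ratios (total
phenotypic variance in the denominator) and additive/environmental/residual
correlations are computed **per sample** and then summarised — a mean of
ratios, not a ratio of means. Breeding values and effect solutions are
accumulated as running means/SDs over every post-burn-in iteration. Four
tab-separated files are written: `Results.txt` (components and derived
quantities), `Breeding.txt` (per-individual EBVs), `Solutions.txt`
(systematic and environmental solutions, event effects included),
`Iterations.txt` (one row per retained sample).

## Synthetic data

The simulator reproduces a one-generation validation design: unrelated
sires and dams draw true breeding values from `MVN(0, G)`; each offspring
takes a uniformly random sire and dam and adds a Mendelian-sampling
deviation `MVN(0, G/2)`; events draw `event_size` distinct horses without
replacement (with replacement across events); ranks are the descending
order of `l = a_l + e_l` within the event, and every start carries a
continuous record `y = a_y + e_y` with `(e_l, e_y)` drawn jointly.

Defaults are the validation-study conditions: 100 sires × 500 dams → 2000
horses, 2000 events of 10 (10 starts per horse on average), liability
variances 0.25/1 (h² = 0.2), continuous-trait variances 1/2 (h² = 1/3),
genetic correlation 0.3, residual correlation −0.2. `scaled_config()` is a
40% replicate (40×200→800 horses, 800 events of 10) that keeps the
per-horse information — the driver of EBV accuracy — unchanged; the
acceptance script and the heavier tests use it with chains of 20,000
iterations (4,000 burn-in) over three seeds, which one CPU core completes
in a few minutes.

What the generator does *not* emulate: structured (non-random) event
participation — prestige classes that attract the best horses, where
event-effect estimates are known to bias rank-based evaluations — multiple
generations, selection, inbreeding loops, and alphanumeric pedigrees.
Passing tests therefore demonstrate correct inference under random event
assignment, not robustness to structured participation (a mixture over
competitor classes would be the natural extension). Inbreeding and genetic
groups *are* fully supported in `A⁻¹` and are exercised by dedicated
pedigree unit tests rather than by the simulation.

## Design choices that were genuinely open

- **Ties in ranks** are rejected rather than silently broken: tie semantics
  would corrupt the rank-order constraint set.
- **Gaps in finishing positions** are allowed; truncation adjacency follows
  the sort order of observed positions, not the raw integers.
- **Genetic groups** are encoded as negative parent codes; Quaas–Westell
  phantom-parent rows are appended to `A⁻¹`, with group parents treated as
  unknown when computing Mendelian-sampling variances.
- **Winner-zeroing vs. fixed event effects**: the equivalent alternative
  (event effect fixed at 0, winner sampled truncated) is not implemented.
- **One random environmental effect** with a full covariance matrix `P`
  across its traits; multiple environmental effects are rejected.
- **Parameter-file dialect** is line-oriented `KEY = value` (documented in
  `ranktraits.io`), chosen for reproducible parsing with clear errors.

## Known limitations

- A horse's single continuous measurement cannot be linked residually to
  several of its ranking rows; residual covariance acts within a row only.
- At most one fixed-residual-variance trait per multivariate model.
- EBV/solution posteriors are summarised by running mean/SD only; full
  per-effect chains are not stored (variance components are, in
  `Iterations.txt`).
- A general mean on a liability that also carries an event effect is
  confounded with the average event effect: only their sum is identified,
  the split performs a slow random walk, and the event effects lose their
  "forced negative" interpretation. The simulator's analysis model
  therefore applies the general mean to the continuous trait only; a user
  model that includes both is tolerated but its intercept-like solutions
  should not be interpreted individually.
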