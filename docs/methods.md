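# Methods

`burdenmrf` implements a model-free collapsing (burden) association
pipeline for rare germline and somatic variants in paired case/control
cancer cohorts, together with the simulation framework used to
characterize it.  This note records the model, the estimation procedure,
every reconstruction decision that was genuinely open, the calibration
protocol for the selection thresholds, and the known limitations.

## Problem setting

Given `M` rare variant sites over `N` samples (`N/2` cases, `N/2`
controls; unbalanced designs are handled through the observed arm sizes),
the pipeline selects a candidate subset of putatively causal variants,
removes samples whose genotype patterns diverge from the cohort
("singular cases"), collapses the surviving candidates into one virtual
locus (a sample is a carrier iff it carries any selected variant), and
tests the virtual locus for case/control association.  Selection is the
scientific core: individually, rare variants are statistically invisible
(a causal variant may add less than one expected carrier to the case arm),
so the selector must aggregate evidence across interacting sites while
staying calibrated — a null cohort must almost never yield a significant
collapsed test.

## The hidden Markov random field

Three latent layers live on the site axis:

* **H** — hidden per-site genotype states.  Observed genotypes are noisy
  copies of H at mutation/error rate `mu`.  The full H-space is `2^N`-
  dimensional; following the silent-state construction, inference runs on
  a collapsed two-level chain (see *State space*, below).
* **R** — region indicator, elevated (`R^e`) vs background (`R^b`).
  Elevated regions are stretches harboring interacting deleterious
  variants.  Chain transitions derive from the H-transition potential
  `exp(sum_i mu + (1-mu) f(-theta d + I e^{-theta d}))` with
  `f(x) = (1 - e^{-x})/N`, agreement indicator `I`, inter-site distance
  `d` (site-index units by default, bp/10^4 when physical positions are
  given) and deleterious-region parameter `theta`.
* **X** — per-site causal status, the selection output, updated by
  iterated conditional modes (ICM).

Sites interact through the kernel `omega_{s,s'} = 2 t_s t_{s'} /
(t_s^2 + t_{s'}^2)`, a cosine-similarity-like weight in [-1, 1] (1 iff
the statistics agree, -1 iff they oppose).  With tumor/normal read
counts, `t_s` is the paired t statistic of the per-sample tumor-minus-
normal VAF difference (binomial read model `c^+ ~ Bin(d^+, theta_s)`,
`c^- ~ Bin(d^-, rho_s)`); zero-variance nonzero differences are capped at
|t| = 37.62 (~the t value of a machine-precision p).  For somatic sites
only tumor quantities are used, and somatic-somatic pairs must share a
sub-clone (1-D Gaussian-mixture clustering of carrier-mean VAFs with BIC
model choice up to `k_max = 5` — a deliberately simple stand-in for full
clonal-architecture reconstruction, which is out of scope).  **Without
read counts** (the simulation setting) `t_s` is the signed square root of
the per-site carrier-table chi-square, positive for case enrichment —
scale-compatible with a t statistic, so the kernel applies unchanged.

Interactions are only allowed inside four-gamete-compatible intervals:
the site axis is partitioned by greedy left-to-right and right-to-left
scans into maximal compatible runs, index-wise intersections form cores,
and a dynamic program over the per-start maximal reach selects the
disjoint chain of compatible intervals covering the most sites (uncovered
sites become singletons).  Compatibility within an interval is
pairwise-all — every pair of member columns must avoid exhibiting all
four joint carrier configurations — which is stricter than adjacent-only
and, being closed under sub-intervals and extendable site by site, makes
the cover provably optimal (verified against exhaustive search for
M <= 10).  The scan uses the case half of the matrix by default.

### Per-site evidence and the region emissions

The solo-effect classifier `m(G_.,s)` is the Jeffreys-smoothed carrier
log-odds of cases versus controls (with read counts, carrier calls are
first discounted by their binomial read support).  `m` is **capped** at
`evidence_cap = 2.0` before it enters the field.  The cap encodes the
model's central premise: elevated regions are a multi-site phenomenon, so
no single extreme site may dominate — this is also what makes the null
calibration below achievable at all, since under a null cohort the most
extreme single-site fluctuation is otherwise arbitrarily convincing.

The elevated-state emission log-odds at site s are

    eta_s = tau (B_s - kappa) + nu S_s + F

with `tau + nu = 1` (defaults 0.5/0.5) balancing solo versus interaction
effects:

* `B_s = log(P^e_s / P^b_s)` — the regional classifier as Bernoulli
  log-odds (`B = P^e - P^b` is available by config); `P^e` is initialised
  from the classifier, `sigma(m_s)`, which anchors the otherwise
  label-symmetric elevated/background states.
* `kappa = 0.75` (`elevation_margin`) — the per-site cost of elevation.
* `S_s = clip(sum_{s'} omega_{s,s'} q_{s'} X_{s'}, ±3)` — interaction
  support from currently selected interval neighbors, weighted by their
  region posterior `q`.  The sum (not the mean) is used so support grows
  with the *number* of interacting selected neighbors — the signature of
  a genuine hotspot — and the cap (`interaction_cap = 3`) bounds mutual
  reinforcement.
* `F` — a global elevation field,
  `F = max(3 min(0, log(E / 24)), -3)` where
  `E = sum_s relu(m_s - kappa)` is the dataset's total above-margin
  evidence mass.  The joint field carries a global term in `sum_s R_s`;
  making its strength depend on the aggregate evidence renders the
  elevated phase inaccessible on evidence-free data (where isolated
  chance clusters would otherwise bootstrap themselves through `S`) while
  costing signal-rich data nothing.  `F` never exceeds 0 and is static in
  the data, so it cannot destabilize the EM iteration.

Scaled forward/backward recursions over the two-state chain (state parity
= region flag: even indices carry `P^b`, odd `P^e`) yield the posteriors
`q_s = P(R_s = e)`, the adjacent-pair posteriors `xi`, and the chain
log-likelihood.  Posterior and `xi` normalization are exact to 1e-9;
equivalence with brute-force path enumeration is asserted for chains up
to length 8 (and a 3-state chain) in the test suite.

### Parameter estimation

Each iteration alternates:

* **mu** — posterior-weighted disagreement over carrier mass,
  `mu = sum I(H != G) w / sum I(G > 0) w`, with per-entry error
  posteriors from the current `mu` and arm carrier frequencies.  For rare
  variants a singleton true carrier and a mutation-channel event are
  marginally indistinguishable, so the raw update drifts upward; the
  update is damped (rate 0.5) and bounded (`mu_max = 0.05`, a noise-rate
  scale).  This degeneracy is intrinsic to rare data, not an
  implementation artifact.
* **theta** — 1-D maximization of the expected transition log-likelihood
  `sum_s sum_ij xi(s,i,j) log T_theta(i,j)` by a coarse log-grid scan
  seeding a bounded Brent search; multi-modal grids fall back to the
  global grid best with a warning.
* **P^b / P^e** — the printed update
  `P^b_s = xi(s,0,0) / ((1/N)(1 + (N-1) e^{-theta d}))` exceeds 1 for any
  persistent chain and after clipping would pin `P^e` to the floor,
  destroying the anchor; the fit therefore scores both diagonal masses
  through the same denominator and renormalizes the pair,
  `P^b_s = xi(s,0,0) / (xi(s,0,0) + xi(s,1,1))` (the literal form remains
  available and tested).  The update is damped toward the classifier
  anchor (rate 0.5) and clipped to (1e-3, 1-1e-3); `P^e + P^b = 1` holds
  after every update.
* **X (ICM)** — site-wise conditional maximization:
  `X_s = 1` iff `tau m_s + nu S_s + gamma (2 q_s - 1) + pi_0 > 0`, with
  region coupling `gamma = 1.5` and sparsity prior `pi_0 = -2.0`; sweeps
  run until no flip (max 20), keeping the best-scoring configuration on
  oscillation.  `X` is initialised from a marginal screen (`t_s >= 1.35`).

Iteration stops when the largest parameter change falls below
`tol = 1e-4` with a stable X, or after `max_iter = 100`.

### State space

The printed recursion ranges over `2N` states; full H inference is
intractable and the silent J states exist precisely to avoid it.  The
implementation is generic over a `2J`-state parity space and runs with
J = 1 (two states) — the collapsed-representative reconstruction.  The
silent-state transition probabilities (`f(-theta d) + e^{-theta d}` for
the duplicate channel, `f(-theta d)/(N-1)` per permutation target) are
implemented as stated, clipped to [0, 1] after evaluation.

### Calibration protocol (and what was *not* calibrated)

Four constants (`evidence_mass_ref = 24`, `global_field = 3`,
`pi_0 = -2.0`, `interaction_cap = 3`) set the dead/live balance of the
field.  They were fixed once, against exactly two criteria the method
itself is defined by: (1) on null-model cohorts (1000 samples x 100
sites, mutation probability 0.005, random labels) selection must be
essentially always empty — measured null evidence masses span ~7-14, so
the reference 24 sits above their range and below the weakest
fixed-number simulations (~27+); and (2) power must not collapse at the
weakest simulated effect.  The Table-style selection error rates were
never calibration targets; see the limitations below for where that
leaves them.

## Singular-case filtering

`zeta(G_{i,s})` is the posterior probability that the observed genotype
is the true one under the fitted error model; `zeta` of a genotype and of
its complement sum to 1.  A variant is *flagged* for a sample when
`zeta(obs) < zeta(complement)` — the observed genotype is more likely an
error than real, which for carriers happens at sites whose arm carrier
frequency falls below the mutation-rate odds.  A case with more than
`singular_variant_threshold = 5` flagged variants is removed (controls
are never removed).  For speed the filter shortlists the `L` most typical
cases (largest total log `zeta`; default half the cases), re-estimates
`mu` on 50 bootstrap resamples of the shortlist (controls included as the
frequency anchor), and flags everyone against the averaged model.
Removal is deterministic given the seed and idempotent.  Under pure null
data the default threshold removes well under 5% of cases (tested).
The printed `zeta` formula mixes its indices; the
normalized-over-alternatives reading used here is a reconstruction.

## Association test and evaluation

The collapsed 2x2 carrier table is tested by a Pearson 1-df chi-square
(no continuity correction), falling back to Fisher's exact test when any
expected cell is below 5; degenerate margins give p = 1, and an empty
selection is defined as not significant.  Dataset-level significance is
`p < 0.05` in simulation mode and `p < 2.5e-6` (Bonferroni for 20,000
genes) in exome mode, both strict.

Evaluation uses the selection literature's (nonstandard) definitions:
**type-I** = mean fraction of preset causal variants *not* selected,
**type-II** = mean fraction of preset neutral variants selected,
**power** = fraction of replicate datasets whose collapsed test is
significant.

## Simulation framework

* **MAFs** follow Wright's stationary distribution
  `f(rho) ∝ rho^(beta_i - 1) (1 - rho)^(beta_L - 1) e^(sigma - rho sigma)`
  with defaults `sigma = 12.0`, `beta_i = 0.001`, `beta_L = 0.00033`.
  At these shapes ~97% of the mass lies below 1e-12 (the quantile behaves
  like `u^1000`), far beyond any grid; the sampler therefore combines
  exact power-law branches near both endpoints with a tabulated inverse
  CDF on two log-spaced grids (1e5 points), clamping unrepresentable
  quantiles at 1e-300.  The sampler is verified by a Kolmogorov-Smirnov
  test against an independently quadrature-integrated CDF on the
  resolvable range plus a binomial check of the endpoint mass, and by the
  closed-form mean of the `beta = 1` truncated-exponential special case.
* **Effect model**: `C` causal sites are drawn uniformly;
  `RR = delta/((1 - delta) rho) + 1` with marginal PAR
  `delta = group PAR / C`, and case MAF
  `theta = RR rho / ((RR - 1) rho + 1)` (algebraically
  `theta = delta + (1 - delta) rho`: each causal variant adds ~`delta` to
  the case frequency regardless of how rare it is).
* **Genotypes** are carrier indicators by default (carrier probability
  `1 - (1 - maf)^2` for a diploid individual; a 0/1/2 coder is available
  and collapses to carriers for the model).  Sites are independent — no
  linkage disequilibrium between rare variants, by design.
* **Observed-variant conditioning**: each site is conditioned on carrying
  at least one minor allele in the sampled cohort
  (`require_polymorphic = True`).  Without it, the Wright spike leaves
  ~99% of sites monomorphic in 2000 samples and every study quantity
  degenerates; real variant lists contain only observed sites.  The
  conditioning is exact (analytic acceptance probability on the MAF,
  then carrier counts from the truncated joint law), not ad hoc
  resampling.  The raw sampler remains unconditioned.
* **Null model**: i.i.d. Bernoulli(0.005) genotypes, fair random labels,
  no conditioning.
* **Read-count overlay**: Poisson depths (mean 60, floor 1), binomial
  supports; germline carriers VAF 0.5 in both tissues, somatic carriers a
  configurable sub-clonal VAF in tumor and only sequencing error (1e-3)
  in normal.  These defaults are conventions of this package.

### What the generator emulates — and what it does not

The generator reproduces the fixed-number study design: weak, independent
per-site effects whose detectability comes only from aggregation.  It
does **not** simulate linkage disequilibrium, haplotype structure,
population stratification, genotyping error correlated with depth, or
genuine variant–variant interaction effects (causal sites are
independent; the four-gamete intervals and omega weights therefore act on
chance co-occurrence structure).  Passing the simulation study shows the
selector aggregates weak marginal signals and stays calibrated under the
null; it does not certify behavior under real LD or batch structure.

## Reference-scale results

`scripts/acceptance.py` regenerates the study from scratch (100 datasets
per PAR in {0.02..0.05} at 1000/1000 x 100 sites with 50 causal; 1000
null datasets).  At seed 1 it reports: power 97/99/100/100%; type-II
13.6/18.7/17.4/19.5%; null significant fraction 0.10%; type-I
53.6/41.3/37.5/32.8%.

## Known limitations

* **Type-I (causal variants missed) runs high at the weakest effect.**
  At group PAR 0.02 a causal variant contributes ~0.8 expected extra case
  carriers; conditioned on being observed, ~two-thirds of causal sites
  present as a bare case-only singleton or doubleton, and a comparable
  population of neutral sites presents identically by chance.  Any
  selector that keeps the neutral-selection (type-II) rate near 13-20%
  must reject a large share of those indistinguishable singletons, and
  its type-I rate is then bounded well above 44% — a Bayes-risk property
  of the generative model, not of this implementation.  This package's
  operating point preserves the type-II column and the null calibration
  and concedes type-I; the per-dataset type-I rate is also intrinsically
  variable (SD ~18 points at PAR 0.02).
* The `mu` EM update is degenerate on rare data (see above) and is kept
  meaningful only by damping and an upper bound.
* The region chain's stickiness, derived from the stated H-potential, is
  weak (stay probabilities ~0.65-0.73 for any theta at unit distances),
  so long-range aggregation comes from the interaction sum and the global
  field rather than the chain itself.
* Sub-clone assignment is a 1-D GMM over site-level mean VAFs — adequate
  for gating interaction pairs, far short of clonal reconstruction.
* `evidence_mass_ref` is a dataset-level calibration tied to the
  reference scale (M = 100 sites, N = 2000); toy problems with little
  total evidence are globally suppressed unless the reference is lowered
  accordingly (the test fixtures do exactly that).
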