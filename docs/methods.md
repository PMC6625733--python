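# Methods

## The problem

Shotgun proteomics identifies peptides by matching MS2 fragmentation spectra
to sequences. Each peptide-spectrum match (PSM) carries a posterior error
probability (PEP) estimated from the spectrum alone; low-abundance samples —
single-cell multiplexed sets in particular — produce many spectra too weak
for confident identification, so much of the acquired data is discarded. A
peptide's liquid-chromatography retention time (RT) is a reproducible
function of its sequence under a consistent LC setup, which makes RT an
independent source of identity evidence. `rtalign` aligns RTs globally
across many runs, infers a latent reference RT per peptide, and folds the
aligned-RT evidence back into each PSM's error probability through Bayes'
theorem.

## Global alignment model

Let rho_ik be the observed RT of peptide i in run k and lambda_ik its
spectral PEP. Each peptide has one latent reference RT mu_i; each run has a
monotone two-segment linear map from the reference scale to its own RT axis

    g_k(mu) = beta0_k + beta1_k * min(mu, s_k) + beta2_k * max(mu - s_k, 0),

with beta1_k, beta2_k > 0, g_k(0) >= 0 and split point s_k in (0, max RT).
A two-segment map captures the dominant distortion of gradient LC runs (a
different effective slope before and after a change in gradient regime)
while staying trivially invertible; spline or LOESS monotone maps would be a
drop-in generalization but are not implemented.

A correctly matched PSM scatters around g_k(mu_i) with Laplace-distributed
residuals; the Laplace's heavier tails make the fit robust to stray
observations. Residual spread grows along the gradient and differs between
runs, modeled as sigma_ik = a_k + b_k * mu_i with a_k, b_k > 0. An
incorrectly matched PSM carries no RT information about its assigned
peptide; its RT follows a broad run-level null, Normal(nullmean_k,
nullsd_k), fixed at the run's empirical RT mean and SD and never optimized.
Each PSM contributes the mixture

    P(rho_ik | ...) ∝ 1{rho_ik > 0} [ (1 - lambda_ik) Laplace(rho_ik; g_k(mu_i), sigma_ik)
                                      + lambda_ik Normal(rho_ik; nullmean_k, nullsd_k) ],

so even low-confidence PSMs inform the alignment, discounted by their own
error probability. The support indicator is honored by rejecting
non-positive RTs rather than renormalizing the truncated densities: the
truncated mass is negligible on real gradients and dropping the constant
keeps the likelihood simple.

### Priors

mu_i ~ Normal(RT_mean, RT_sd) with RT_mean/RT_sd the moments of all observed
RTs; beta0 ~ Normal(0, 10) truncated to keep g_k(0) >= 0; beta1, beta2 ~
Lognormal(0, 0.5); a ~ Lognormal(0, 2); b_k ~ Lognormal(log b_global, 1)
with the shared hyperparameter b_global ~ Lognormal(0.1, 0.5); s_k ~
Uniform(0, max RT). Lognormal parameters are (location, scale) of the log.
These defaults suit groups of ~60-min runs and scale through the
data-derived hyperpriors for other gradients.

### Inference

All parameters (one mu per peptide, six free parameters per run, b_global)
are estimated jointly by maximum a posteriori optimization: L-BFGS with
analytic gradients on an unconstrained reparameterization (log for positive
parameters, scaled logit for s_k), maximizing the constrained-space
posterior without a Jacobian adjustment. Full posterior sampling would make
the uncertainty treatment automatic but is far too slow at tens of
thousands of PSMs; the bootstrap below recovers the part of the uncertainty
that matters most.

Two numerical choices matter in practice:

* **Initialization.** Alternating rounds (3 by default) of (i) per-run
  two-segment least squares with the split on a quantile grid and one
  5x-median-absolute-residual trimming pass, and (ii) re-estimation of each
  reference RT as the median of its inverse-transformed observations.
  Round zero is a plain linear fit to per-peptide median RTs. A purely
  linear initialization leaves the joint optimizer in local optima whenever
  the true distortion has a pronounced kink.
* **Split refinement.** After the joint fit, each run's six parameters are
  conditionally re-optimized from a coarse grid of split positions
  (experiments are conditionally independent given the references, so this
  is a valid block ascent; only improvements are accepted), followed by a
  joint polish. Repeated up to three times or until no improvement.

Convergence is declared at relative objective change < 1e-7 (configurable),
capped at 2*10^4 iterations. Runs with fewer than two distinct alignable
peptides are dropped with a warning and their PSMs routed to pass-through.

### Identifiability of the latent scale

The likelihood is exactly invariant under affine reparameterization of the
reference axis: mu -> c*mu + d can be absorbed by every g_k (slopes scaled
by 1/c, intercepts and splits shifted). Only the priors pin the gauge, and
the maximum sits a few percent away from any particular generator's frame.
Consequently the *identified* quantities are the reference RTs up to an
affine map and the transforms composed with that map; recovery should be
(and in the test suite is) assessed after aligning frames by least squares.
Within-frame agreement of slopes is ~1-2% and split points ~1-2 min at the
default synthetic conditions.

### Finite-sample residual-scale correction

An L1-type fit with p location parameters (N references + 4 per run)
interpolates roughly p of its n observations, deflating both the observed
median absolute residual and the maximum-likelihood scale estimates by a
predictable amount (~15% at the default synthetic conditions). The fitted
model therefore carries a scale-inflation factor n/(n - p) (capped at 1.5)
that multiplies sigma_ik wherever the density is evaluated downstream —
the analogue of using n-1 in a variance estimate. Without it the updated
PEPs of far-outlying correct PSMs are measurably conservative.

## Confidence update

With MAP estimates mu_hat_i and sigma_hat_ik in hand, Bayes' theorem gives
the posterior probability that PSM ik is correct given its RT; the prior is
1 - lambda_ik. Reference-RT uncertainty — the dominant uncertainty, since a
peptide is observed in at most a handful of runs while each run's transform
rests on thousands of PSMs — is propagated by a parametric bootstrap: for
each replicate b, every observation of peptide i is resampled from its
fitted mixture (Laplace with probability 1 - lambda, null otherwise),
mapped back through g_k^-1, and the median across runs taken as mu_i^(b)
(the median is the Laplace maximum-likelihood location). The update then
averages the correct-match density over B replicates (B = 100 by default;
the average is stable well below that at desk scale):

    P(correct | rho) = (1-lam) * (1/B) sum_b f(rho | g_k(mu^(b)), sigma_hat)
                       / [ same + lam * f0(rho) ].

The updated PEP is 1 minus this, floored at 1e-16 (so downstream q-value
arithmetic and log-scale displays stay finite) and capped at 1. sigma_hat
uses the MAP reference, held fixed across the bootstrap sum. Alignment
parameter uncertainty is deliberately not propagated.

Pass-through PSMs (removed by the eligibility filters, or from dropped
runs) keep their spectral PEP unless their peptide gained a reference RT
from other runs, in which case they are updated like any other PSM.

q-values are recomputed set-wide as the running mean of ascending-sorted
PEPs — the expected false fraction among all PSMs accepted at that rank.
Ties share the q of the last tied rank (conservative, order-invariant). By
default q-values are computed over target PSMs only; decoys can be pooled
in by configuration.

## Eligibility filters

Alignment uses PSMs that pass, in order: parseable required fields; not in
a manually excluded run; not decoy (unless decoy inclusion is on); not
contaminant (contaminant retention is often chromatographically ill-defined);
spectral PEP < 0.5; retention length (elution-peak width) at most 1/60 of
the gradient length (or an absolute cutoff); and peptide observed in at
least 3 distinct runs, counted after the per-PSM filters. Everything
removed becomes pass-through, never silently dropped. Peptide identity is
the modified sequence with charge state excluded — charge does not affect
retention, modifications do.

## Reporter-ion normalization and the protein-CV benchmark

Isobaric (TMT) reporter intensities form a PSM x channel matrix.
Configured empty channels are dropped, rows with missing values removed,
then columns are divided by their medians (channel loading) and rows by
their medians (relative enrichment), iterated until both median sets are 1
— a single pass leaves the column medians slightly perturbed by the row
step, and the converged matrix makes the operation idempotent. Peptide and
protein tables are channel-wise medians of their constituent PSMs and
peptides.

The internal-consistency benchmark partitions PSMs into disjoint subsets —
`spectra` (spectral PEP < 0.01) and `upgraded` (spectral PEP > 0.01 and
updated PEP < 0.01) — and compares per-protein coefficients of variation
(sample SD over mean of normalized intensities across a protein's PSMs,
computed per channel and averaged; proteins need >= 3 PSMs in a subset).
A negative control permutes the protein assignments with a fixed seed. If
upgraded PSMs are correctly identified, their protein CVs match the
spectra subset and both sit well below the permuted control.

## Synthetic data generator

The generator inverts the model's generative story on a 60-minute gradient:
reference RTs uniform over the gradient interior; per-run transforms with
slopes in (0.85, 1.15), intercepts in (0, 2) min, splits in the middle
third (20-40 min), and at least 0.1 separation between the two slopes (the
distortions are genuinely two-segment; a near-zero kink would leave the
split unidentifiable for any method); residual scales a in (0.05, 0.15)
min and b in (0.002, 0.008); each peptide observed in each run with
probability 0.8; 5% incorrect matches drawing their RT from the run-wide
null. Spectral PEPs come from Beta(1, 19) for correct and Beta(4, 4) for
incorrect PSMs — overlapping but separable, reproducing the gray zone that
RT evidence resolves.

Two PEP modes: `conditional` (default) draws the correctness label first
and the PEP from the label-conditioned Beta — the incorrect fraction equals
the configured rate, but the PEPs are *not* calibrated probabilities.
`calibrated` draws the PEP from the Beta mixture marginal and the label as
Bernoulli(1 - PEP), making P(incorrect | PEP) = PEP exactly; FDR and
calibration checks use this mode, since no posterior built on miscalibrated
priors can be calibrated. Optional decoy flagging and protein-structured
reporter intensities (lognormal noise around per-protein channel profiles)
round out the outputs.

What the generator does **not** emulate: spectra and search-engine score
distributions, correlated residuals within a run (column aging within one
gradient), retention drift over acquisition order, co-eluting isobaric
interference, or missingness that depends on abundance. Passing tests show
the method is correct and calibrated *under its own assumptions*, with
sample sizes and noise scales typical of the motivating experiments; they
do not certify performance on any particular real dataset.

## Default problem sizes

The test suite and the acceptance script run the full method at 10 runs x
300 peptides (~2,400 PSMs, the standard study conditions) for recovery and
residual checks, and pool ten 6-run x 150-peptide replicates for FDR
calibration. These sizes put every estimate well inside its asymptotic
regime while keeping a full suite run within a few minutes on one CPU.

## Known limitations

* Updated PEPs near 1 are conservative (the realized error fraction among
  PSMs called >= 30% likely-wrong is lower than stated): reference-RT
  resampling is the only uncertainty the update propagates, so residual
  mis-estimation lands in the far tail. Downstream acceptance decisions
  (small q-value thresholds) are unaffected.
* The latent reference scale is identified only up to an affine map (see
  above); reference RTs are comparable within one fitted model, not across
  independently fitted models.
* One split point per run; gradients with more than one regime change need
  the (unimplemented) spline/LOESS generalization.
* The null RT density is a single Normal per run; strongly non-linear
  gradients that flatten the RT distribution would motivate a uniform or
  empirical null instead.
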