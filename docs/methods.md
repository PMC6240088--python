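# Methods

This package re-creates, end to end, a meta-Bayesian analysis of neural
cultures learning to separate hidden sources of stimulation: a simulated
stimulation protocol, an ideal-observer encoder that minimises variational
free energy, a synthetic multi-electrode recording emulating the culture, a
GLM/CVA analysis that detects emerging functional specialisation, and a
mapping from the detected specialisation back onto free energy and its
accuracy/complexity decomposition.

## Generative process

Two hidden binary sources s1, s2 are drawn i.i.d. Bernoulli(0.5) per
one-second epoch, organised into sessions of 256 epochs (the full protocol
is 100 sessions, 25,600 epochs; rest periods between sessions carry no
epochs and appear only as session boundaries).  32 stimulation sites,
chosen once uniformly without replacement from the 8x8 electrode grid
(0-based, row-major), receive independent Bernoulli stimulation with
probabilities given by a fixed likelihood: with only source 1 active,
pool-1 sites (the first 16 by site index) fire with probability 3/4 and
pool-2 sites with 1/4; with only source 2 the probabilities are mirrored;
with both sources absent no site fires, with both present every site fires.
Pools are defined by site index, not geometry; placement on the grid is
uniform random.  One global seed expands into independent per-purpose
substreams (sources, stimuli, sites, agent, recording, surrogate) so
changing how much randomness one stage consumes never shifts another.

## The encoder

The observer entertains four joint hidden states — the product of the two
binary sources, ordered (0,0), (0,1), (1,0), (1,1) — with a uniform
categorical prior D (the product of per-source (0.5, 0.5) priors) and a
Dirichlet-parameterised likelihood over each site's binary outcome, with
prior concentration counts of one everywhere (a single virtual
observation).  State transitions are the identity; epochs are exchangeable.

Per epoch:

- **Inference.**  The posterior over joint states is
  `softmax(ln D + sum_i E[ln A_i](o_i))`, where `E[ln A] = psi(a) -
  psi(sum_j a)` (digamma expectation under the Dirichlet).  Outcomes are
  one-hot over {0, 1} per site, so silence at a site is as informative as
  stimulation.  A neuronally interpretable relaxation computes the same
  posterior: a log-expectation ("voltage") variable integrates prediction
  errors, `v <- v + step * eps`, `eps = (ln D + lnA . o) - v`, with the
  posterior the softmax of v.  Solver defaults: step 0.25, at most 16
  iterations, tolerance 1e-8 on the gauge-invariant part of eps — chosen
  for stable convergence and a plausible within-epoch trace; they are not
  derived from any reported value.  Closed-form and relaxed posteriors
  agree to 1e-6 at these tolerances (tested).
- **Learning.**  The Dirichlet counts accumulate the outcome/posterior
  co-occurrence, `a[i, o_i, k, l] += s_kl` — an associative Hebbian rule
  adding exactly one unit of count mass per site per epoch.
- **Free energy.**  Scored exactly, in nats: inaccuracy `-s . lnA . o`;
  state complexity `s . ln s - s . ln D` (the KL from prior, equal to the
  negentropy plus ln 4 under the uniform prior); parameter complexity as
  the exact Dirichlet KL from the prior, with the truncated bookkeeping
  form (which omits the `+ ln Beta(a0)` constant) also exposed because
  reference implementations differ in which they report.  With flat unit
  priors the two coincide.

**Symmetry breaking.**  With exactly uniform initial counts the four state
columns are indistinguishable: every posterior is uniform, every update
increments all columns equally, and blind learning sits on an unstable
fixed point forever.  We add a seeded Uniform(0, 0.01) jitter to the
initial *learning* counts only (the KL prior stays exactly one).  The
magnitude matters: 0.01 lets state identities crystallise gradually over
the first ~50 epochs — reproducing the gradual emergence of selective
responses that is the phenomenon of interest — whereas large jitter commits
instantly and erases the learning curve.  The cost of gradual commitment is
that roughly a quarter of seeds show partial label mixing after 512 epochs
(pool-level recovery error 0.1–0.45 instead of ~0.02); this is genuine
stochasticity of blind categorical learning at this data size, and runs
longer than 512 epochs largely resolve it.

**Identifiability.**  The model is exactly invariant under all 24
relabellings of its four states (source swap and per-source level flips are
special cases, but learned runs also land outside that subgroup).  Recovery
of the generative likelihood is therefore always reported up to the best
state relabelling, and measured on pool-averaged probabilities — the scale
on which the generative matrix is defined (constant within each 16-site
pool); site-level maxima are dominated by binomial noise
(`sqrt(p(1-p)/n_visits)` ≈ 0.04 per cell at 512 epochs).  Analyses that
compare the agent with true source labels (the closed loop below) first
align the agent's labelling to the known generative likelihood, the same
post-hoc interpretation step as calling a simulated unit "the source-1
unit".

**Free-energy trend.**  The cumulative parameter KL grows ~logarithmically
with accumulated evidence, so the per-epoch *total* including it rises with
training by construction.  The learning signature — free energy falling as
the likelihood is learned — lives in the state terms (inaccuracy + state
complexity), the same decomposition used on the empirical side, and that is
the quantity our learning-trend tests and trajectories use.

## Synthetic recordings

Spike counts per electrode per 1-s epoch follow a log-linear Poisson model:

    ln rate_e,t = ln baseline + stim_gain * own_stim_e,t
                  + sum_src gain_e,src * g(t) * 2 (m_src,t - 0.5) + drift_e(t)

Defaults: baseline 20 counts/epoch (a plausible evoked-response count for a
dense culture); stim_gain 0.7 (the obligatory response roughly doubles the
rate at a stimulated site); specialisation gain 0.5 at full posterior
confidence for 8 electrodes per source (disjoint, chosen at random;
remaining electrodes carry no source signal — specialisation distributed
but dominated by a few electrodes); drift a per-electrode random 4-term
low-order cosine series with coefficient sd 0.2 (the smooth-confound family
the GLM's drift basis removes); Poisson noise (a "gaussian" log-intensity
noise and a deterministic "none" mode exist for calibration studies).
`m_src,t` is the true source (parametric mode) or the aligned encoder's
marginal posterior of source presence (agent mode, the closed loop).  The
gain envelope g(t) is a logistic ramp (midpoint at 40% of the recording,
rate 10 in fractional time) in *both* modes: it models the culture's slow
synaptic-plasticity timescale, deliberately much slower than the encoder's
in-silico learning; the epoch mapping below reconciles the two timescales.
The generator stores full ground truth (who specialises, for which source,
with what gain and envelope) with every recording.

Surrogate controls permute each source train independently over epochs:
marginals preserved exactly, all alignment with the stimuli destroyed.

What the generator does *not* model: spike waveforms and sorting, bursting
dynamics, inter-epoch spontaneous activity, electrode cross-talk, and any
feedback from culture activity to the stimulation.  Passing tests on these
data show the analysis chain is correct and calibrated for this response
family; they cannot certify biological claims about real cultures.

## Specialisation GLM

Per electrode and per source, ordinary least squares with an
effects-of-interest partition of 8 columns — an orthonormal DCT-II time
basis (components 0–7) multiplied by the centred source-presence indicator,
so selectivity may emerge at an arbitrary rate and a constant selectivity
loads on the DC component — against confounds: the electrode's own-site
stimulation indicator (only for stimulated sites), the per-epoch total
stimulation count, 32 non-constant DCT drift components, the other source's
centred main effect, and an intercept (44 columns at a stimulated site).
Specialisation is the extra-sum-of-squares partial F for the interest
partition (central-F p-values; no correction across electrodes — maps are
descriptive).  The fitted interest component evaluated at the two indicator
levels gives the present/absent response traces; their difference is the
learning curve.  F values placed at the grid positions give the 8x8 map.

Because the total-stimulation confound is itself driven by the sources, a
*constant* source effect is largely absorbed by the confounds — by design:
a response that is merely stimulation-evoked (larger on average under one
source) must not count as specialisation.  Only time-modulated (emerging)
selectivity survives the partialling, which is what the interest partition
is built to capture.

The per-epoch stimulation regressors are a modelling choice (own-site
indicator + total count); 32 separate site columns would be collinear with
the source indicators by construction of the generative likelihood.  Both
the count and the basis sizes are configurable.

Calibration: on electrodes whose generative model the linear GLM nests
(non-stimulated: baseline, drift, Poisson noise), the partial-F type-I
error is 0.05 as it should be, and the F statistic matches a reference OLS
restriction test to 1e-10.  At *stimulated* sites the generator's
multiplicative stimulation effect interacts with drift, which a linear
stimulation regressor cannot fully absorb; the residual inflates F there.
This mirrors the real identifiability problem the confound set addresses
and is why the calibration null is the non-stimulated population.  The
amplitude-recovery study (epoch-mean present-minus-absent contrast, with
its OLS standard error) uses the Gaussian log-intensity noise mode, where
the 95% interval is exact.

Selection reduces the 64 electrodes to one specialisation series: the
max-F electrode, the mean over electrodes with F > 80 (threshold
configurable; its calibration depends on the degrees of freedom), or the
principal canonical variate.  CVA residualises responses and interest
columns against the confounds and solves the generalised eigenproblem of
hypothesis vs error sums of squares; ill-conditioned error matrices get a
logged ridge; significance uses Bartlett's chi-square approximation to
Wilks' lambda.  The variate's sign is fixed by requiring positive
late-epoch specialisation, making the series invariant under orthogonal
rotations of the electrode space.

## Free-energy mapping

The fitted present/absent traces are read as posterior expectations: the
95th percentile of the late-quarter fitted "present" response anchors
posterior 1, zero fitted specialisation anchors the 0.5 prior, and values
are clipped to [1e-3, 1 - 1e-3].  (How sub-asymptotic specialisation maps
to probabilities is not derivable from first principles; the anchor rule is
declared, robust to outliers by using a quantile, and configurable.)  The
joint over the four states is the product of the two source marginals — a
mean-field choice, since the GLM estimates each source's encoding
separately.  An all-zero curve maps to the flat prior throughout; a curve
whose late "present" response is not positive is degenerate and rejected.

Learning progress is the monotone non-decreasing envelope of the absolute
specialisation curve.  The empirical curve (from the selected electrode) is
affinely regressed onto the encoder's curve — itself obtained by fitting
the *same* GLM to the encoder's source-presence unit — and each of 512
equally spaced empirical epochs is assigned the simulation epoch of nearest
matched progress (ties toward the earlier epoch; monotone by construction;
out-of-range progress is clamped with a warning).

Empirical free energy per selected epoch uses the actual stimulation
pattern, the empirical posterior, and the encoder's `E[ln A]` at the
matched epoch: `F = -accuracy + complexity` with accuracy `s . lnA . o` and
complexity `s . ln s - s . ln D`; parameter complexity is reported as zero
on this scale (beliefs about the likelihood come from the matched
simulation, not the recording).  Trajectories are smoothed by a simple
32-epoch moving average (valid region only) and plotted as accuracy against
complexity — the variational information plane.  All quantities are in
nats; a drop of 3 nats is an evidence odds factor of exp(3) ≈ 20:1.

## Problem sizes and defaults used in tests and drivers

The full protocol (100 x 256 epochs) is simulated where it is cheap (source
and stimulus statistics).  Encoder learning runs use 512 epochs, the scale
at which the blind-recovery behaviour is characterised.  The closed-loop
study — encoder, agent-driven recording, both-source GLM with true and
surrogate trains, free-energy mapping — uses 8 sessions x 256 epochs per
seed and ten seeds for trend statements (free-energy drop in >= 9/10 seeds,
accuracy rise, initial complexity rise, surrogate nullity); these sizes
give each stage comfortable statistical margin while keeping a ten-seed
study quick to re-run.  GLM calibration uses 500 null electrode fits and
100 amplitude recoveries at 16 x 256 epochs.

## Known limitations

- Blind learning occasionally (roughly 1 seed in 4 at 512 epochs) mixes
  state labels; recovery error is then reported honestly rather than
  suppressed.
- The linear GLM is miscalibrated at stimulated sites under the
  multiplicative generator (documented above); inference about
  specialisation at stimulated sites rides on the time-modulated interest
  partition, which the planted-signal and closed-loop tests exercise.
- The epoch mapping is only as good as the learning curves: flat or
  saturated curves make progress values tie, and the mapping then
  concentrates on plateau boundaries (ties break earlier).
- The empirical posterior anchor (late-quarter 95th percentile) is a
  convention; different anchors rescale the complexity trajectory without
  changing its shape.
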