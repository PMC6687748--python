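# Methods

## The model

`pibsampler` treats the reaction coordinate (RC) of a rare-event system as a
*predictive information bottleneck*: the simplest variable chi that, given
the present state, is most informative about the state a delay Delta-t into
the future.  The state is summarized by d pre-selected order parameters
s_1..s_d (distances, dihedral trig functions, ...), and the bottleneck is
restricted to a physically interpretable linear form

    chi = sum_i c_i * zscore(s_i),        ||c||_2 = 1.

The encoder is deterministic and linear; interpretability comes from reading
the weights c_i directly.  Model capacity is controlled on the decoder side:
Gaussian noise of fixed variance sigma^2 is added to chi before a
two-hidden-layer ELU network f(chi) predicts the (standardized) order
parameters a lag of k frames ahead under a spherical Gaussian observation
model Q(X_{t+dt} | chi) = N(f(chi), sigma^2 I).  Training maximizes the
variational lower bound on the predictive information,

    L' = { sum_n w^n }^{-1} sum_n w^n log Q(X^{n+k} | chi^n),

which under the Gaussian decoder is exactly

    L' = -wMSE / (2 sigma^2) - (d/2) log(2 pi sigma^2),

so the fit is weighted mean-square-error minimization.  The importance
weights w^n = exp(beta V^n) undo an applied bias potential V; they are exact
in the limit of small delay, which is why the working delay is chosen as the
*smallest* lag at which the learned weights plateau (`delay_scan`, angular
criterion: 1 - |cos angle| < 1 - cos 5 degrees against the next two lags).

No complexity penalty on the encoder is used; with a linear, unit-norm
encoder the noise variance alone sets the effective capacity.

### Optimization

RMSprop (decay 0.9, epsilon 1e-8) with learning rate 0.003, minibatches of
512, uniform initialization in [-0.005, 0.005], bottleneck noise resampled
per minibatch, and the encoder re-projected to unit L2 norm after every
step.  Training is restarted `n_restarts` times from independent random
initializations and the restart with the lowest final noise-free loss is
kept (ties break to the lowest restart index; the final loss is evaluated
at the decoder mean so selection is deterministic).  A restart whose loss
becomes non-finite is discarded.  The sign gauge fixes the
largest-magnitude weight positive; the matched decoder input column is
negated so predictions are unchanged.  The network is implemented directly
in numpy (forward and backward passes are a few dense layers); the whole
model is a few thousand parameters and trains in seconds on one CPU.

Defaults worth knowing: noise_variance 0.005 (the variance of the bottleneck
Gaussian; too large washes out features), hidden width 128, 2 hidden
layers, epochs 200, n_restarts 3.  Inputs are z-scored with
importance-weighted moments so the init scale and noise are meaningful
across systems; a zero-variance order parameter is rejected by name.  The
decoder predicts standardized coordinates; the stored transform lets
exported biases act on raw coordinates.

## Iterative biasing

Each round: sample several replicas under the current bias, train the RC on
the replica with the highest pooled-z-scored variance (the most ergodic
one), estimate the unbiased density along the new RC from all replicas by
the weighted histogram

    P_u(chi) ~ <w delta(chi - chi_t)>_biased / <w>_biased,  w = e^{beta V},

and build the next bias V(chi) = (1/beta) log P_u(chi), shaped by three
rules:

* minimum 0 over the grid;
* maximum capped at (max bias of the previous round + delta_V), delta_V a
  confidence constant guarding poorly sampled regions — caps grow
  arithmetically while they bind and stall once the bias is bounded by the
  transition-state rule;
* free-energy barriers ("transition states": local maxima of F separating
  minima by at least `min_barrier` on both sides) carry exactly zero bias
  over a margin `ts_margin` below the top, and the bias is anchored to
  vanish *continuously* into each barrier region (the shift is set at the
  barrier-region edge).  A discontinuous zeroing was tried and rejected: a
  jump of order ts_margin in V at the region boundary makes the applied
  force inconsistent with the recorded energy exactly where rates are
  measured, and produced a visible systematic error in reweighted free
  energies.

Replicas continue from their previous round's end points (warm restart).
This matters: the reweighting assumes each round samples approximately its
own biased ensemble, and cold restarts from a fixed configuration were
observed to lock the second-stage bias into a self-reinforcing lopsided
state (one basin's density overestimated by several e-folds).

Saturation of the bias — the trigger for the two-coordinate stage — is
declared when the bias maximum no longer tracks the growing cap (the added
delta_V headroom stays more than 75% unused) and sampling visits no new
bins.  Convergence of a stage is declared when consecutive RCs agree within
5 degrees and free-energy profiles within 0.5/beta sup-norm on common
support.

### Second coordinate (washing out)

After saturation, a second bottleneck chi_2 is learned conditioned on the
first: chi_1 and V_1(chi_1) stay frozen, chi_1 is fed to the decoder as a
fixed extra input, the importance weights account for V_2 only, and the
applied bias is the separable sum V_1(chi_1) + V_2(chi_2).  As an added
stabilizer (not part of the original construction), chi_2 is
re-orthogonalized against chi_1 in weight space after every fit; this
prevents re-learning chi_1 and is flagged as an extension.

## Kinetics

With barriers bias-free, the biased run preserves the unbiased
state-to-state sequence, and physical time is recovered frame by frame:
t_u(n) = sum_{i<=n} dt * exp(beta V(chi_i)).  First-passage events are the
first entries into an absorbing chi-interval sustained for a commit time
(default 10 frames; suppresses recrossing artifacts); runs without an event
are censored.  The escape rate is the censoring-aware exponential MLE
k = n_events / total observed rescaled time with a bootstrap standard error
(1000 resamples, seeded); a least-squares fit of the empirical CDF to
1 - e^{-kt} is provided as a cross-check.  Self-consistency across biasing
protocols passes when every pair of k +- 2 stderr intervals overlaps — a
deliberate interval-overlap reading, under which two estimates like
5.2 +- 0.8 and 5.8 +- 0.9 agree; note that any such fixed-multiple test
still rejects a few percent of genuinely consistent triples.

Two numerical points, both verified against exact mean-first-passage-time
quadrature on the 1D double well:

* the bias-free margin around a barrier must be wide — several 1/beta —
  because the rescaled-time estimator picks up occupation weighted by
  exp(beta U + beta V) near the top, and a plateau sitting `margin` below
  the top contributes ~e^{-margin} of the barrier flux integral.  The
  kinetics benchmarks use ts_margin = 4/beta (intrinsic error ~3%).
* biased runs need a finer timestep and bias grid than equilibrium sampling:
  the engine applies the force interpolated from the exported derivative
  column (the same contract an external engine honors), which is not
  exactly the gradient of the interpolated energy at clip kinks; at
  dt = 2.5e-4, 480 bins the residual systematic is ~6%.

## The toy engine

Overdamped Langevin (Euler–Maruyama):
x' = x - D beta grad[U + V(chi(x))] dt + sqrt(2 D dt) xi.  It emulates the
one thing the method needs from real MD — metastable wells separated by
hard barriers with separable slow/fast directions, order-parameter time
series, and per-frame bias energies.  It does not emulate inertia,
thermostats, force-field detail, or high-dimensional degeneracy of order
parameters, so passing tests demonstrate correctness of the learning,
reweighting and rescaling machinery, not force-field realism.  Built-ins:
1D symmetric/asymmetric double wells (barrier in 1/beta units), a 2D double
well rotated to plant a known slow axis, a separable 2D two-barrier
landscape (four wells; the two-coordinate testbed), and a periodic
two-torsion toy emitting (cos phi, sin phi, cos psi, sin psi).  Same seed
gives bit-identical paths; chi values leaving the bias grid feel zero force
and are counted.

## Density and MI estimators

Free-energy profiles are weighted histograms (default 100 bins), optionally
Gaussian-smoothed *for bias construction* (1 bin default) — smoothing
inflates F where the profile is steep, so final reported profiles should
use smoothing 0.  A probability floor 0.1/(M binwidth) keeps logs finite in
unvisited bins; the Kish effective sample size (sum w)^2 / sum w^2 is
reported and warned below 50.

Mutual information uses a 30x30 weighted 2D histogram — quantile edges on
the bottleneck axis, fixed-width periodic edges for angles — with the
Miller–Madow occupancy correction evaluated at the Kish size and clipped at
zero.  Reweighting to the unbiased ensemble is on by default and
switchable.  Feature ranking reports, per labeled (phi, psi) pair, the
maximum MI against either angle and over bottleneck components.

## Benchmark problem sizes

The shipped validation (tests and `scripts/acceptance.py`) uses desk-scale
problems chosen to keep every run seeded and reproducible on one CPU:
reweighting under a fully flattening bias with 40 replicas x 800k steps;
slow-axis recovery over 5 seeds with 20k-frame trajectories; kinetics with
160 unbiased and 3x96 biased replicas (>= 50 first-passage events per arm);
the full two-stage protocol with 4 replicas of 50k steps per round and an
8-replica frozen-bias production ensemble.  Free-energy agreement is judged
on bins with at least 10 effective samples.

## Known limitations

* Linear encoders stand or fall with the order-parameter basis; a bad basis
  shows up as non-improving ergodicity across rounds, not as an error.
* The importance-sampled objective is a small-delay approximation; no
  runtime diagnostic exists for its validity beyond the weight-plateau
  choice of delay.
* The separable V1+V2 ansatz cannot represent coupled two-coordinate
  barriers.
* Histogram MI needs ~10^4 samples per feature for the Miller–Madow
  correction to hold the independence baseline near zero.
* The encoder retains an O(1/sqrt(M)) admixture of fast directions; in
  reweighted profiles this couples to large weight spreads, which is why
  production ensembles should be long enough to equilibrate the slow
  coordinate under the final bias.
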