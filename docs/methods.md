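# Methods

## Statistical model of motion sensitivity

Spike trains are reduced to Bernoulli data: each 2 ms bin of a phase
either contains a spike or not. 2 ms is the approximate refractory
period, so bin occupancy is close to a spike count while keeping the
observation model binary. Counts are pooled over the trials of one
neuron × motion direction: `(k_m, n_m)` spike-bins/bins for the motion
phases and `(k_s, n_s)` for the stationary phases. Phases of 6 s are
truncated to their first 5 s so every trial contributes the same
`n = 2500` bins per phase; adaptation phases are discarded, and
repeated series of one direction are pooled as a single series.

Three hypotheses about the per-bin rates are compared under a uniform
hypothesis prior:

* `H(==)`: one shared rate `r ~ Beta(α, β)`. Marginal likelihood
  `B(α + k_m + k_s, β + n_m + n_s − k_m − k_s) / B(α, β)` (Bernoulli-
  sequence likelihood; binomial coefficients cancel across hypotheses).
* `H(<)`, `H(>)`: independent rates under the joint prior
  `Beta(α, β) × Beta(α, β)` truncated to the ordered region and
  renormalized by the region's prior mass. Because both rates share one
  prior, exchangeability makes that mass exactly 1/2 for any `(α, β)`.
  The marginal likelihood factorizes into the two independent-rate
  evidence terms times `P(X < Y)` for the Beta posteriors
  `X ~ Beta(α + k_m, β + n_m − k_m)`, `Y ~ Beta(α + k_s, β + n_s − k_s)`.

The equality hypothesis is the spike-and-slab treatment of the
measure-zero diagonal: a shared single rate with the same prior.
Everything is computed in log space; posteriors are normalized marginal
likelihoods.

`P(X < Y)` is computed three ways, selectable per call:

* `quadrature` (default): `P(X < Y) = ∫ F_X(y) f_Y(y) dy` evaluated by
  adaptive quadrature after substituting `t = logit(y)`, with
  breakpoints at quantiles of both posteriors. On the logit scale both
  Beta kernels have O(1) width however concentrated they are, so the
  adaptive rule resolves the overlap region even when it is a far tail;
  both ordered probabilities are computed directly (never as `1 − p`),
  preserving relative accuracy down to ~1e-12.
* `closed_form_mix`: the cumulative-distribution decomposition
  `E_u[F_X(Q_Y(u))]` on fixed Gauss–Legendre nodes in quantile space.
  It broadcasts over arrays (the power analysis scores thousands of
  simulated datasets at once) and is accurate to ~1e-5 relative or
  better away from extreme tails (ordered probabilities ≳ 1e-6).
* `monte_carlo`: paired Beta draws; used as an independent cross-check
  at three standard errors in the tests.

The test suite additionally verifies both implementations against a
brute-force oracle — nested Gauss–Legendre product integration of the
joint model on a 2000×2000 node grid in log space, exact for the
polynomial Beta kernels — to 1e-6 relative marginal-likelihood error
over 22 fixtures, with measured oracle self-convergence ~1e-13.

**Prior.** The default is the uniform `Beta(1, 1)`; informative
hyperparameters are exposed in every API and in the run config, since
nothing in the package depends on the uniform choice (the region mass
is computed generally). **Bayes factor.** `BF_ne = (P(<|D) + P(>|D)) /
P(==|D)`; an exactly zero `P(==|D)` maps to `+inf`, which sorts above
any finite value; the strong-evidence flag uses the conventional ≥ 10
cutoff. Because the two ordered evidences sum to twice the
independent-rates evidence, `BF_ne` also has the closed form
`2·L_indep / L_shared`, which the vectorized power analysis uses.

**Scores.** MSS, DSS are posterior expectations of ±1/0 case scores and
live in [−1, 1]; AMSS, ADSS live in [0, 1]; `|DSS| ≤ AMSS` follows from
the case structure and is property-tested. Class aggregates sum the
scores over tested neurons, so a cell's maximum attainable |value|
equals the number tested; untested cells stay empty rather than zero.

**Power analysis.** For given `(r_m, r_s)`, bins per trial and trial
count, pooled binomial datasets are simulated and the fraction reaching
`BF_ne ≥ 10` reported with a 95% Clopper–Pearson interval, alongside
the same fraction under `r_m = r_s` (the false-positive rate). With the
defaults (2500 bins × 3 trials, `r_s = 0.02`), detection crosses ~60%
at `r_m = 0.03` and saturates by `r_m = 0.04`, while the null rate is
at or near zero — the criterion is conservative.

## Spike detection and trial processing

Detection subtracts a centered running median (default 500 ms window,
edge-replicated at the trace boundaries) and takes upward threshold
crossings of the residual, timing each suprathreshold run at its peak;
events closer than the 2 ms refractory period merge. The threshold is
applied to the baseline-subtracted signal rather than the raw voltage —
the filter is named by the procedure but its reference point is not, and
subtraction makes a single manual threshold workable under drift; the
choice is exposed for sensitivity testing. Bins are half-open
`[t, t + 2 ms)`, 0-based from phase onset, so boundary spikes are never
double-counted.

## Compass network model

States are deviations from baseline firing, 16 CL1a + 16 CL2 components
ordered by PB column L8…L1, R1…R8, updated linearly (`x_{t+1} = M x_t`;
the circuit is linearized around its operating point). Targets are
`x̂_c(j) = cos(2π(j − c)/16)` duplicated across the two populations —
one full period across the bridge, i.e. a single 360° heading
representation, with the maximum in column `c`.

**Mask geometry.** The five-column CL2→CL1a footprint is realized as
half-width-2 bands around both the same-column diagonal and the
hemisphere-mirror anti-diagonal, abstracting the intercalated
contralateral projection scheme; the half-width is a parameter, and an
arbitrary mask can be supplied for alternative projection schemes. The
bridge is open: same-type adjacency does not connect positions L8 and
R8. The noduli variant adds all same-hemisphere CL2→CL2 pairs.

**Optimization.** The maintenance objective is the mean squared
deviation of all 16 targets from their one- and two-step images (mean
over targets, steps and components, so the regularization weight is
size-independent) plus `λ · mean(w²)` over the free weights. Weights
start from the fixed sign template (+0.5 for CL1a output and same-type
synapses, −0.5 for CL2→CL1a) and are fitted in two deterministic
L-BFGS phases: a *structure* phase with the regularizer (default
`λ = 0.15`, the midpoint of the range over which results are stable;
this phase drives non-essential connectivity toward zero and selects
the solution branch) and a *fit-only polish* from that solution, which
removes the regularization bias without leaving the branch (the fit
gradient vanishes along the directions the regularizer had shrunk, so
the polish does not repopulate them). The polished fixed-point error is
~1e-9 per component, far inside the 1e-3 acceptance tolerance, and the
final fit is insensitive to `λ` anywhere in [0.1, 0.2] — the
regularizer chooses structure, not the answer. Sign constraints are
never imposed; the emergent layout (all CL1a→CL2 synapses excitatory,
same-column CL2→CL1a band excitatory) is recorded in the model
metadata. In our solutions the mirror-band CL2→CL1a synapses come out
mixed-sign rather than uniformly inhibitory; sign structure is
reported, not asserted, since multiple sign layouts fit the targets
equally well.

**Turn modulations.** Additive, mask-respecting `ΔM` optimized the same
two-phase way against targets shifted one column per step — toward
higher index for left turns (the bump moves opposite to the turn) and
lower for right turns, with cyclic wrap even though the mask has no
L8–R8 adjacency: the network realizes the wrap internally, and the
simulation confirms clean L8↔R8 transitions. The left and right
modulations come out as quadrant-wise 180° rotations of each other to
~1e-6, as the mirror symmetry of mask and targets implies. Additive
modulation is the minimal reading of a "modulatory input acting on the
connectivity"; re-optimizing the full matrix per direction would
subsume it.

**Feed-forward control.** A constant input `u` under
`x_{t+1} = M x_t + u`, optimized against the same shifted targets. Its
optimum is `u ≈ 0` with fit loss equal to the do-nothing baseline
(≈ 0.1845): summed over all 16 cyclic initial states, any fixed input
helps some bump positions only by hurting others, so a feed-forward
drive cannot shift the bump at all while the modulatory mechanism
reaches ~1e-18. The acceptance suite asserts the strict inequality and
a ratio > 1e3 for both variants and directions.

**Simulation.** Commands select `M` or `M + ΔM_dir` per step. Because
the fixed points are numerically approximate, the state is rescaled to
unit peak after each step by default; bump positions are
scale-invariant, and the suite checks that traces with and without
renormalization are identical over ≥ 30 steps. The demo trajectory —
forward, an 8-step right-turn block, forward, an equal left-turn block,
forward, started at L4 — is chosen so the bump crosses both bridge ends
and closes the loop; block lengths and start column are configurable,
and the preset is representative rather than a replica of any
particular recording session's trajectory.

## Synthetic data: what it does and does not emulate

Generated trial counts are independent Bernoulli draws per bin, exactly
the observation model the statistics assume; an optional refractory
correlation (suppressing the bin after a spike bin) is provided for
robustness testing but off by default. Default baseline rates are drawn
from 0.02–0.06 per 2 ms bin (10–30 Hz equivalent) — configurable,
since recorded firing-rate magnitudes vary — and the synthetic
population contains a mirrored CL2 pair (one neuron excited by
simulated right yaw and inhibited by left, the other the reverse,
2.5×/0.4× baseline) emulating opposite-polarity yaw selectivity.
Voltage traces superimpose a stereotyped 1.5 ms biphasic waveform
(shape invented; only detectability matters), Gaussian noise and slow
sinusoidal drift. Passing tests therefore show that the pipeline
recovers what its own model family generates; they do not certify
behavior under real-data violations such as bursting, strong rate
nonstationarity within phases, or electrode artifacts beyond drift.

## Numerical choices and problem sizes

Bump readout is the argmax of a population subvector, ties broken
toward the lower index with a degeneracy flag, and an all-equal state
is an error. Non-convergent optimizer runs warn with their loss trace
rather than fail. Test and acceptance runs use desk-scale sizes chosen
to keep the whole suite in the low minutes: 1000-replicate power
curves, 10^6-draw Monte-Carlo cross-checks, 22 oracle fixtures, and the
16-column network (the anatomical size). All randomness flows from
explicit integer seeds; model fitting is deterministic and seed-free.

## Known limitations

No spiking or conductance dynamics, no velocity-dependent shift
magnitude (turns advance exactly one column per step), no CL1b-d, TB1/
TB2, TN or TB7 neurons; the same-type lateral connectivity stands in
for pathways likely mediated by such cell types. The statistics assume
within-phase stationarity of the Bernoulli rate; and `closed_form_mix`
is not tail-accurate (use `quadrature`, the default, when ordered
probabilities may be below ~1e-6).
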