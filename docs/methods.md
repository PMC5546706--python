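# Methods

## The problem

When yeast cells respond to mating pheromone, the abundance of almost every
tagged protein changes — but much of that change has nothing to do with
gene-specific regulation. Growth slows (diluting protein more slowly) and
the cell's global translation capacity shifts, so a protein can rise
1.5-fold while its own synthesis is being *repressed*. `psdanet` separates
these two signals and then reverse-engineers the dose-dependent regulatory
circuit from the gene-specific part.

## Protein life-cycle model

The core balance for one protein's concentration `P(t)` (arbitrary
fluorescence units) is

    dP/dt = alpha(t) - (d + gamma(t)) * P(t)

with `alpha(t)` the synthesis rate (a.u./min), `d` the first-order
degradation rate (1/min, `ln 2 / half-life`), and `gamma(t)` the dilution
rate set by exponential cell-mass accumulation (1/min). The model is solved
and inverted *discretely on the measurement grid* (forward Euler / forward
difference):

    P(t_{k+1}) = P(t_k) + dt_k [alpha(t_k) - (d + gamma(t_k)) P(t_k)]
    alpha(t_k) = (P(t_{k+1}) - P(t_k)) / dt_k + (d + gamma(t_k)) P(t_k)

No interpolation or smoothing is applied, so simulation and inversion are
*exact* mutual inverses (verified to <= 1e-9 relative error); that identity
anchors every downstream stage. Euler requires `dt*(d+gamma) < 1`
everywhere, which a 5-min grid satisfies for any realistic yeast turnover;
coarser grids raise a hard error.

## The physiology-only null

The global synthesis rate `s_norm(t)` (dimensionless, baseline = 1) is the
per-gene-normalized average of inverted synthesis traces across a gene panel
— a reference panel of unregulated genes, all genes, or (pipeline default)
the cross-gene median. Because the forward difference amplifies measurement
noise roughly as `CV * P * sqrt(2) / dt`, each gene's trace is normalized by
the mean of its first few (>= 4) alpha samples rather than a single
baseline point; a one-point baseline makes the normalized traces
heavy-tailed and wrecks the mean estimator. The median combiner is the
default because, in a cohort where most genes are regulated, the mean
absorbs the regulation itself.

The null model for gene g rescales this shared profile so that the
pre-stimulus level is a steady state:

    S_g(t) = p0_g * (d_g + gamma_0) * s_norm(t)

Simulating every gene under `S_g` with its measured `gamma(t)` and `d_g`
yields the "global null" trajectories. The fold-change summary per gene is
the *signed peak* |log2 P(t)/P(baseline)| (endpoint is available as an
alternative); Pearson r across genes between null-predicted and observed
fold changes, and r^2 as variance explained, quantify how much physiology
alone accounts for. In synthetic cohorts this r falls monotonically as the
fraction of pulse-regulated genes rises — the null explains less when more
genes carry gene-specific events.

## Pulse decoupling (PSDA)

Gene-specific regulation enters as a multiplier on synthesis:

    dP/dt = R(t) * S_g(t) - (d + gamma(t)) P(t)

`R(t)` is a single pulse: value `F` (fold) inside `[t_on, t_off)`, 1
outside, with logistic ramps whose 10–90% rise spans `edge_width` (default
10 min) at both edges. `F > 1` is activation, `F < 1` inhibition; three free
parameters (t_on, t_off, log2 F). A single rectangle is the minimal shape
that captures one event per gene; down-then-recover dynamics are
represented by a finite `t_off`. Multi-pulse and time-varying degradation
are out of scope.

The fit minimizes the sum of squared errors between the simulated and
observed trajectory (simulation starts at the observed baseline, which is
not a free parameter). The optimizer is seeded simulated annealing with

- chain length 100 evaluations per temperature stage,
- geometric cooling (x0.95 per chain), initial temperature set by the
  starting error,
- Gaussian proposals scaled to the parameter ranges and annealed with
  temperature (so late chains refine locally),
- bounds: t_on/t_off within the grid +/- one step, F in [1/16, 16] searched
  in log space, window width >= max(step, 2*edge_width),
- 3 restarts sharing a hard cap of 2000 objective evaluations per gene,
  best-of retained; bit-identical results per seed.

The width floor is an identifiability constraint: a window narrower than
its two ramps never attains its nominal fold, so amplitude and width trade
off freely and the fit happily explains single noisy samples with extreme
folds. With the floor in place an unregulated gene at 5% noise stays below
the event threshold in ~19/20 seeded fits.

A gene is called *activated* when `log2 F >= 0.3` (~1.23-fold), *inhibited*
when `<= -0.3`, else *none*; the threshold is configurable. On the default
synthetic cohort (below) the fit recovers the true fold with ~7% median
error, event boundaries within ~6–8 min, and the regulation sign for 100%
of regulated genes, and its optimum matches a coarse 3-parameter grid
search within 5% on noise-free genes.

## Meta-genes and discretization

log2 R(t) traces of genes *with a detected event* are normalized to unit
peak magnitude and clustered by k-means (Euclidean, default k = 6, best of
50 restarts). Flat traces are excluded on purpose: unit-peak normalization
would blow pure noise up to amplitude 1 and swamp the distance. Clusters
are relabeled by ascending 50% activation/inhibition time (first
interpolated crossing of half the peak on the way to the peak) so labels
are stable; each cluster's sign is the sign of its centroid at its peak.
Cluster activities are member means renormalized to +/-1.

The threshold model turns activities into a Boolean trajectory: a node is
ON while |activity| >= threshold (default 50% of peak; events are pulses,
the alternative latch convention keeps nodes ON once triggered). States are
sampled at every switching time, consecutive duplicates collapsed, and an
always-ON input node (the pheromone-activated transcription factors)
prepended. Event *order* — scored as Kendall concordance of
first-activation ranks — is conserved across 30/50/70% thresholds on the
default synthetic meta-genes.

## Boolean network inference

A network is a ternary signed adjacency `a[j,i] in {-1, 0, +1}` with
synchronous threshold dynamics: node i turns ON when the signed input sum
is positive, OFF when negative, and *holds its state* at exactly zero; the
input node is clamped at 1 and has no incoming edges. Unit weights suffice
because only the sign of the input sum matters for 0/1 states.

Because each node's update depends only on its own incoming signs,
consistency with a trajectory factorizes per target: the consistent set is
the Cartesian product of per-target sign vectors (at most 3^7 = 2187
candidates each for 6 clusters + input), so exact counting is a product of
six small enumerations. This factorized count is verified against a brute
force that simulates every complete network, on random small trajectories.

*Minimal* networks keep, per target, the consistent vectors whose nonzero
support is inclusion-minimal **and** single-deletion-critical (zeroing any
one edge breaks that target's consistency — the operational reading of
"no redundant edges"); assembled networks are re-verified. Edges are
*rigid* (same nonzero sign in every consistent vector), *forbidden* (always
zero), or *interchangeable*. Prior-knowledge filters (required signed
edges, forbidden edges) act on materialized network lists, capped at 1e6.

The attractor landscape enumerates all 2^N free-node states (64 for six
meta-genes), follows the deterministic successor map to its terminal cycle
and reports attractors with basin sizes, which always sum to 2^N.

## Synthetic cohorts

The generator forward-simulates the same balance the analysis inverts, so
ground truth is exact by construction (noise-free datasets reproduce their
own pulses with zero objective). Defaults mirror the study scale: 195
genes, 5-min grid over 360 min, six staggered cluster templates (two
inhibitory, four activating; onsets 5–210 min, windows 60–200 min,
|log2 F| in [1, 2], 8-min window jitter), ~28% of genes unregulated.

- **shmoo** (high dose): gamma drops smoothly to half its pre-stimulus
  value (default gamma0 = 0.006/min) by 60 min; `s_norm` rises to ~1.2x
  near 50 min then declines to ~0.6x baseline after two hours (the curve's
  floor/peak are solved by fixed-point iteration so the *normalized*
  profile hits those values).
- **elongation** (intermediate dose): hyperbolic gamma decay
  `gamma0 * t0/(t0+t)` (linear mass accumulation) and a global profile
  fluctuating around 1 with a mild prolonged rise.

Per-gene parameters: half-lives log-normal around 43 min (log-sd 0.5),
baselines log-normal around 100 a.u.; measurement noise is multiplicative
log-normal on P(t) with CV 5% (mean-one on the natural scale); growth noise
off by default. Same seed => bit-identical dataset.

What the generator does *not* emulate: single-cell variability,
background/segmentation artifacts, gap/missing-value patterns, multi-pulse
regulation, or regulated degradation. Passing tests therefore demonstrate
correctness of the inference machinery under the model's own assumptions,
not robustness to every failure mode of real microscopy data.

## Numerical and design choices

- Baseline index = last time <= 0, else the first sample.
- Negative inverted alpha values are retained for averaging (truncation
  would bias the global profile) but floored at 1e-6 x baseline when used
  as a simulation rate; simulated trajectories clamp at 0 with a warning.
- z-scores use the population (n) standard deviation; constant traces map
  to zeros with a warning instead of NaN.
- Degradation fallback for genes missing from the half-life table:
  ln 2 / 43 min (configurable, logged).
- k-means ties in the half-time ordering break by descending cluster size;
  empty or duplicate clusters flag the assignment degenerate.
- The 4-convention sweep (pulse/latch x self-edges) can make a trajectory
  infeasible for some target; counts then report 0 with a log entry naming
  the violated transitions.
- Problem sizes in the test-suite and acceptance script (20 replicate
  cohorts for recovery statistics, 50 random trajectories for the counting
  oracle, 100 traces for the round-trip bound) keep a full run in minutes
  on one CPU while leaving every statistic estimable.

## Known limitations

- One pulse per gene: genuinely biphasic regulation is summarized by the
  dominant event.
- The global profile estimated from a mostly-regulated cohort retains a
  few percent structural bias even with the median combiner; a curated
  unregulated reference panel is preferable when one exists.
- Synchronous Boolean semantics only; no asynchronous or probabilistic
  updates, and edge identity (which protein mediates an interaction) is
  config/prior data, not an inference target.
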