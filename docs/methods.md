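# Methods

## Model and state space

The package models an N-region circuit as a pairwise maximum-entropy
(Ising-type) distribution over binary microstates. Everything is
computed by exact enumeration of the 2^N states: energies, the
Boltzmann distribution (normalized after subtracting the maximum of −E,
so arbitrarily large parameters stay finite), model moments ⟨σᵢ⟩ and
⟨σᵢσⱼ⟩, local minima, and basin assignments. There is deliberately no
Monte-Carlo fallback; the enumeration cap (default N = 20) is a hard
precondition, and state tables are memoized because the iterative
dynamics revisit the same parameter sets constantly.

State labels are 1-based: label = 1 + Σᵢ σᵢ 2^i, so the all-inactive
pattern is state 1 and the all-active pattern is state 2^N. This is a
convention of this package (chosen so attractor names are stable,
readable integers); nothing in the mathematics depends on it. Region
indices in the API are 0-based, as usual in Python.

## Landscape analysis

A local minimum is a state with strictly lower energy than all N of its
single-flip neighbors. Basins are assigned by discrete steepest
descent: move to the lowest-energy neighbor while that energy is
strictly below the current one. "Descending the energy gradient" on a
hypercube does not uniquely fix a rule; steepest descent with a
deterministic tie-break (lowest flipped-region index) was chosen
because it is order-free and reproducible. Ties and plateaus have
measure zero for generic real parameters; a guarded equal-energy walk
handles them anyway. The occupation-time ratio (OCR) of a minimum is
its basin's total probability; OCRs sum to 1 by construction. "Major
attractors" default to the top 5 by OCR.

## Distances

The functional distance between systems is the partial KL divergence
over a support set R, by default the basin states of the *reference*
(first-argument) system's top-5 attractors. Two open choices are made
explicit and configurable:

* whose basins define R — the reference system's, recomputed whenever
  the reference changes (the reference's probabilities are the weights
  in the sum, so its landscape is the natural domain);
* probabilities are **not** renormalized over R. The sum over a strict
  subset of states is then not a true divergence and can be negative;
  only the full-support case is guaranteed non-negative. Supports from
  top-5 basins typically cover ≳95% of the mass, so values are
  near-KL in practice.

The parameter distance is a true root-mean-square deviation over the
selected coordinate subset ("J" = upper-triangle interactions, "H", or
"all"), so curves are comparable across subsets of different sizes; a
`norm="euclidean"` flag gives the plain vector norm instead.
Recovery capacity is ΔD = D(pre, treated) − D(pre, recovered).

## Self-restoration dynamic

A treatment adds α to one coordinate (node H or edge J; dissection sets
an edge to exactly 0 and freezes it). The recovering coordinates are
the treated element's strong neighbors: for a node m, the edges with
|J_mk| ≥ 0.1; for an edge (i, j), both endpoint sensitivities plus the
strong edges of both endpoints. The treated coordinate itself is frozen
by default (`fix_treated`). The threshold 0.1 is the working definition
of "strongly connected" and is a config field.

Each iteration updates every neighbor coordinate by
α_g·(ln m_pre − ln m_current) with learning rate α_g = 0.2, where m is
the corresponding exact model moment (floored at 1e−12 before the log).
Three constraints shape the trajectory:

* **Step cap.** Each coordinate's applied change at iteration t is
  capped at 20% of its own applied change at t−1 (first iteration
  uncapped), plus a floor of 1e−6 so updates never freeze outright.
  This reading of "changes < 20% of the previous step" produces the
  smooth, quickly saturating recovery curves the dynamic is meant to
  have; an alternative reading — cap at 20% of the coordinate's current
  magnitude — is available as `cap_mode="fraction_of_value"` and gives
  slower, deeper recoveries.
* **Flexibility box.** Every recovering parameter stays within
  ±bound_fraction·max(|pre value|, 0.1) of its pre-treatment value
  (default ±100%; the 0.1 floor keeps near-zero parameters from being
  pinned in a zero-width box).
* **Noise (optional).** Gaussian noise of standard deviation
  `noise_sd` added to each applied change turns the deterministic
  dynamic into a Monte-Carlo one, seeded and reproducible.

Saturation ends a run when the relative change of the distance to the
pre-treatment system stays below 1e−4 for 5 consecutive iterations, or
when every applied change has sat at the cap floor (≤ 5e−6) for 5
consecutive iterations — the latter because floor-level crawling can
keep relative changes just above tolerance for hundreds of iterations
without altering the outcome. Runs whose distance exceeds 10× its
initial value for 5 consecutive iterations abort with the partial trace
attached. Only a saturated system may be promoted (`stabilize`) to the
new pre-treatment reference; treating a transient system leaves the
reference at the last stabilized state.

## Treatment optimization

All searches are exhaustive grids, scored by the partial KL divergence
D⁺ from the goal system evaluated on the goal's top-5 attractor basins
(the goal's functionality is the clinical criterion; the support is
computed once per goal). The default strength grid is ±{0.05 … 0.50 in
steps of 0.05}; ties break to smaller |α|, then lower target index.

* `optimize_single` simulates full recovery for every (target, α).
* `optimize_naive` scores the immediate post-treatment system — the
  restoration-blind baseline — then realizes its chosen plan under
  restoration so results are directly comparable.
* `optimize_repetitive` fixes one target and greedily re-searches the
  strength grid each round, applying doses at saturation, stopping at
  `max_treatments` or when no dose improves D⁺.
* `optimize_timed` additionally grids the application time T of each
  subsequent dose as a fraction of the previous recovery's saturation
  time. The pure wait-for-saturation plan is always evaluated alongside
  the timed plans, so enlarging the timing grid can never worsen the
  reported best. Greedy (per-round) optimization is used throughout
  rather than joint optimization over whole sequences, for tractability.
* `optimize_dissection` cuts every unordered k-set of left×right
  interhemispheric edges, freezes them at zero, and simulates the
  neighbors' restoration. The candidate enumerator reports both the
  unordered counts (each physical cut once — what is evaluated) and the
  ordered counts (k-permutations: 49, 2 352, 110 544 for 7×7
  hemispheres and k = 1, 2, 3).

## Fitting

`fit_mem` estimates {H, J} from binarized recordings by iterating the
same log-moment-matching updates against the exact model moments, which
is maximum likelihood for this exponential family. Initialization is
H = J = 0, learning rate 0.2, convergence when the largest log-moment
gap drops below `tol` (default 1e−6); the log-likelihood is tracked and
the learning rate halves (up to 6 times) if it ever decreases. A
`update="raw"` option uses plain moment differences (the literal
likelihood gradient). Empirical moments at exactly 0 or 1 are floored
into (0, 1) at 1/(2T). Binarization of continuous signals (per-region
median by default) is a preprocessing helper with the threshold always
explicit — the model itself starts from binary data.

## Synthetic test systems

`make_bilateral_system` generates the study's stand-in for a
subcortical-limbic network: 7 homologous regions per hemisphere (a
3-region limbic-like and a 4-region striatal-thalamic-like module) plus
a midline brainstem-like node. Couplings are positive within modules
(~0.3) and across homologous pairs (~0.4), sparsely negative between
modules (~−0.15), midline positive (~0.2); sensitivities ~−0.3; all
with mirrored jitter (sd 0.05) so the hemisphere swap is an exact
symmetry. These scales are a calibration chosen so the emitted
landscape has a handful of dominant, hemisphere-symmetric attractors
(every emitted system is checked to have ≥ 2 minima with top-5
cumulative OCR > 0.5, redrawing up to 20 times); they are conventions
of this package, not measured values. Diseased variants add N(0, 0.1)
to every parameter; hyperconnected variants add |N(0, 0.1)| to each
nonzero interhemispheric coupling in the direction of its sign.
`sample_states` draws exact i.i.d. microstates from the enumerated
distribution.

What the generator does *not* emulate: hemodynamics, temporal
autocorrelation of real recordings, measurement noise, or any
particular anatomical parameter values. Passing tests therefore show
that the algorithms behave as specified on networks with realistic
modular/bilateral structure — not that any specific clinical parameter
set has these properties.

## Problem sizes and scenario defaults

The scenario runners and the acceptance script use the 15-region
system (32 768 states), a reduced strength grid ±{0.1, 0.25, 0.5},
10 diseased variants for the planning comparison, a 10-edge sample for
the edge-capacity sweep, 200 random N ≤ 8 systems for the brute-force
cross-checks, and 10^5 samples for the fitting check. These sizes were
chosen so a full reproduction runs in minutes on one CPU while every
qualitative comparison remains decisively resolved; all of them are
ordinary function arguments and can be scaled up.

## Known limitations

* Exact enumeration limits N to ~20; there is no pseudo-likelihood or
  MCMC path for larger systems.
* The step-cap and flexibility-bound interpretations, the saturation
  criterion, and the support-set conventions are explicit modelling
  choices (flagged above) where the underlying recovery principle does
  not prescribe a unique rule.
* Greedy multi-round planning can be suboptimal relative to joint
  optimization over treatment sequences.
* Restricted-support KL values can be negative and should be compared,
  not read as absolute divergences.
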