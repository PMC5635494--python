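# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `oscperturb`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
acceptance script, not asserted from elsewhere.

## The question the package operationalizes

Biochemical oscillators differ in how their frequency and amplitude can be
regulated. Interaction perturbation probes this directly at the network
level: every interaction of an oscillating ODE model corresponds to one
element `a_ij = ∂f_i/∂x_j` of the Jacobian, so multiplying that single
element by a weakening factor w < 1 during exactly one oscillation period
weakens one network link — and only that link — regardless of how many
rate constants implement it. The lasting change in frequency and amplitude,
expressed as ratios to the unperturbed cycle, is the link's regulatory
fingerprint. Aggregated over a random parameter ensemble, all links, a
grid of starting phases and (optionally) several weakening factors, the
fingerprints classify a network structure as robust (pattern R),
frequency-tunable (pattern F) or amplitude-tunable (pattern A).

## 3-node oscillator models

All built-in 3-node models share the node roles X (activator), Y
(inhibitor), Z (mediator) and the link convention `Lpq` = "node p is
influenced by node q" = Jacobian row p, column q. Nodes map to matrix
indices in the order (X, Y, Z); `Lyx` is row 2, column 1. Diagonal
elements (`Lxx`, `Lyy`, `Lzz`) are structurally nonzero for every node —
each node degrades — and are perturbable interactions like any other.

Six conceptual topologies are built in:

| id | off-diagonal links | class |
|---|---|---|
| `simple_nfo` | Lyx+, Lzy+, Lxz− | I (delayed negative feedback) |
| `activator_amplified_nfo` | Lyx+, Lxy−, Lzx−, Lxz− | II (amplified) |
| `inhibitor_amplified_nfo` | Lyx+, Lxy−, Lzy−, Lyz− | II (amplified) |
| `incoherent_nfo_type1` | Lyx+, Lzy+, Lxz−, Lxy+ | III (incoherent) |
| `incoherent_nfo_type2` | Lyx+, Lzy−, Lxz+, Lxy+ | III (incoherent) |
| `incoherent_nfo_type3` | Lyx+, Lzy+, Lxz−, Lyz− | III (incoherent) |

Amplification in the class II designs is realized as a double-negative
(mutual antagonism) positive loop between Z and the amplified node; the
incoherent link of type 1/2 is the inhibitor directly activating X, and of
type 3 the mediator suppressing the inhibitor. Where a published diagram
admits more than one sign assignment these choices are this package's own
reconstruction; they are fixed in `models.py` and tested structurally
(cycle enumeration per class).

### Kinetic templates

The reference publications for this family of designs describe their ODEs
only as combinations of mass-action and saturating (Michaelis–Menten/Hill)
kinetics, so the right-hand sides here are explicit, documented templates:

**Hill-product template** (`hill_product`; simple NFO and the three
incoherent types, plus the controlled-comparison variants):

* each activating input contributes an independent synthesis channel
  `v · H+(A) = v·Aⁿ/(Kⁿ+Aⁿ)`; channels add;
* a basal (constitutive) rate joins the sum for nodes with no activating
  input and for inhibited nodes lying on a positive feedback cycle.
  Without the leak such nodes have an absorbing off-state: once their
  positive loop collapses nothing can re-ignite it, and no limit cycle can
  exist. With the leak the off-state relaxes back and relaxation cycling
  becomes possible;
* the summed synthesis is gated multiplicatively by `H−(I) = Kⁿ/(Kⁿ+Iⁿ)`
  per inhibiting input;
* degradation is first order, `−kd·x`.

A pure product-of-Hill-factors template with linear degradation was
implemented first and rejected on feasibility grounds: at Hill n = 2 the
three-stage loop's logarithmic gain is bounded by n³ = 8, exactly the
secant-condition threshold, so the simple NFO essentially never oscillates;
and multiplicative AND-gating of activators gives the amplified designs
absorbing off-states (zero oscillatory yield in 8 000 random draws).

**Antagonist-switch template** (`antagonist_switch`; the two amplified
topologies): the mediator Z is a zero-order covalent-modification switch
(Goldbeter–Koshland kinetics, total pool normalized to 1) locked in mutual
antagonism with the node it amplifies — Z promotes that node's degradation
by mass action (`−k·Z·x`), the node drives Z's inactivation
(`−V·x·Z/(J+Z)`). The switch threshold is a *ratio* of rate constants, so
it stays sharp across the six-decade sampling range; plain Hill
realizations of the amplifying loop have oscillatory yields indistinguishable
from zero under random sampling. This is the canonical construction for
relaxation oscillators built from a bistable antagonism plus a slower
negative feedback.

Hill coefficients are structural constants, never sampled; the default is
n = 4 for every saturating term (n = 2 is infeasible for the simple NFO
under this template, see above; n = 4 gives workable oscillatory yields
without implausibly steep cooperativity).

Both templates expose analytic Jacobians; agreement with central finite
differences to 1e−5 is asserted in the tests at random positive states.
Declarative YAML round-trips are supported for the Hill-product family.

## Parameter ensembles

All rate and Michaelis constants are sampled log-uniformly on
[0.001, 1000] — uniform on the exponent, the standard reading of an
"exponential" parameter range spanning decades — by Latin hypercube
sampling: for n sets, each dimension is cut into n equal-probability
strata with exactly one draw per stratum (verified as a property test).
A truncated-exponential distribution object is provided as a swappable
alternative.

Screening retains parameter sets that sustain a limit cycle. A cheap
two-window probe (loose tolerances, three initial conditions, an
extended-horizon retry for slow relaxation oscillators, and a hard budget
on right-hand-side evaluations) rejects the bulk of non-oscillatory
draws; survivors are confirmed by the full multi-start cycle search. The
screen is a pure filter — retained sets are bitwise identical to the
drawn candidates — and it reports its acceptance rate and a
`budget_exhausted` status when the attempt cap is hit before the target
count.

Oscillatory abundance differs enormously between designs: roughly 2–3% of
draws for the simple NFO, 0.2–2% for the incoherent types, but only
~2×10⁻⁴–10⁻³ for the two amplified designs (whose relaxation mechanism
requires several rate orderings to hold simultaneously). Class II
ensembles are therefore gathered under explicit attempt budgets and are
smaller than the others; every output records the realized ensemble size.

## Limit-cycle detection and measurement

`find_limit_cycle` integrates (LSODA, rtol = atol = 1e−8 by default) from
up to three log-perturbed initial conditions: a transient of 50× a crude
timescale estimate (the slowest degradation time), a coarse peak-finding
window with doubling for slow cycles, then convergence rounds on ~8-period
dense windows until the last five inter-peak intervals and per-cycle
amplitudes agree to 0.1% relative. Extrema are refined by locally
re-evaluating the solver's continuous (dense) output — grid-parabolic
refinement alone leaves ~0.1% amplitude jitter on spiky relaxation
waveforms, which defeats the convergence test. A found orbit must pass an
attraction check: a trajectory restarted 0.5% off the anchor state has to
relax back to the same period and amplitude. Non-oscillatory outcomes are
classified fixed-point / damped / divergent (state beyond 1e9).

The cycle object stores the period, per-variable amplitude (max − min
over one period), and states at `phase_count` evenly spaced times, with
phase 0 anchored at the reporter's maximum. The reporter is node X for
3-node models (the activator is the natural reference node of all six
diagrams) and a declared variable for catalog models; frequency is defined
as 1/period, so frequency × period = 1 holds identically.

## The perturbation engine

Differentiating dx/dt = f(x) in time gives the second-order form
d²x/dt² = J(x)·dx/dt. One perturbation run:

1. take the baseline cycle state at one of `phase_count` (default 40)
   evenly spaced phases;
2. integrate the second-order system for exactly one baseline period with
   the addressed Jacobian element multiplied by the weakening factor
   (default factors 0.99, 0.98, 0.96, 0.92). The factor multiplies the
   *state-dependent* element along the trajectory, not a frozen matrix —
   freezing would change the system class; this is the single most
   consequential interpretation choice in the package. This window runs
   at 100× tightened solver tolerance: the velocity offset it accumulates
   *is* the perturbation's lasting effect, and at ordinary tolerances
   solver error in that offset masquerades as signal (it alone shifts the
   null perturbation's amplitude ratio by ~0.1% on spiky cycles);
3. continue with the unmodified second-order system until stabilization,
   then measure frequency and amplitude on the tail and divide by the
   baseline values.

Step 3 uses an exact reduction: along the unmodified second-order flow,
w = dx/dt − f(x) is conserved (dw/dt = J·ẋ − J·ẋ = 0), so the relaxation
is the first-order flow of the displaced field f + w₀ with w₀ fixed at
the end of the perturbation window. The perturbation therefore acts by
displacing the vector field, and the measured cycle is the limit cycle of
the displaced field — which is why a 1% weakening leaves a lasting, finite
frequency/amplitude change rather than relaxing back to the original
cycle. Stabilization is declared when five successive peak amplitudes
agree to 0.1% within a 50-period budget; trajectories that decay, diverge,
or fail the solver are flagged `damped` / `diverged` /
`integration_failed` and excluded from pattern statistics (counts are
retained in run metadata). An oscillation that persists but is still
drifting when the budget ends is measured from its final window.

A campaign emits exactly one row per (parameter set × structurally
nonzero element × factor × phase); results are keyed and
order-independent, so sharded execution concatenates to the serial table.

## Patterns

With Δf = |frequency ratio − 1| and Δa = |amplitude ratio − 1| and a 1%
threshold: R if both Δf and Δa are below the threshold (strictly — a
change of exactly 1% is not R); else F if Δf > Δa, else A (ties go to A
and are counted; they have essentially zero measure). Classification is
per perturbation result, matching the way the pattern table pools
results; a per-parameter-set aggregation (max deviation over phases) is
available as an option. Summaries default to the 1% weakening factor only,
with a pooling flag, since stronger weakenings give qualitatively the same
patterns. Density grids cut the (frequency ratio, amplitude ratio) plane
into 100 × 100 equal cells holding percentages of sustained results
(default bounds [0.9, 1.1]², widened to the 0.5–99.5 percentile range when
results spill over; out-of-range mass is reported so totals conserve), and
render with a white → yellow → red → black density ramp.

For single-parameter-set comparisons (the catalog models), sensitivity is
summarized by the *median* |ratio − 1| over all sustained (element,
phase) perturbations rather than the maximum: the max is an outlier
statistic dominated by a handful of extreme phase alignments and is
unstable at n = 1 parameter set, while medians separate the oscillator
classes by orders of magnitude.

## Mathematically controlled comparisons

The three variants (self-activated X, self-activated Y, added Lxy⁺) share
every unaltered-process parameter bitwise with the simple-NFO base; the
altered process is the synthesis of the added link's target node, and all
of that node's synthesis parameters (rates and Hill constants) are free.
Free values are found by seeded log-uniform random search under two
constraints: the variant must oscillate, and its frequency and amplitude
must match the base within a similarity tolerance (default 5% relative —
"similar" is otherwise unquantified). The search warm-starts from the
base values with a deliberately weak added link (rate 0.01, threshold at
the base amplitude scale), which is almost always feasible because a
sufficiently weak extra link perturbs the base cycle only slightly; the
random search then looks for closer points. Derived sets are re-verified
through the ordinary limit-cycle path, never trusted from the search
loop. The published "representative" base parameterization is not
reproducible from available sources; the bundled base set is a synthetic
stand-in found by this package's own screen (seed 2017, candidate 65) and
frozen with that provenance. "Representative" is operationalized as every
link dynamically engaged: each Hill threshold lies inside its input's
swing on the cycle and every node oscillates visibly. The criterion
matters — a set whose inhibition threshold sits far below its input's
swing is a hair-trigger, and single-link 1% weakenings can then move
frequency or amplitude by tens of percent, which contradicts the premise
of a controlled comparison built on a representative design.

## Catalog models

Four canonical published oscillators ship with their textbook parameters:
the repressilator (6 variables, class I), the Hodgkin–Huxley squid-axon
model under 10 µA/cm² sustained current (class II), the Sel'kov glycolytic
oscillator (class III), and the Goldbeter 5-variable circadian PER model
(class I; the 1995 single-loop parameterization, period ≈ 23.7 h).
Jacobians are analytic where compact and central finite differences
otherwise; the same structural-consistency tests apply.

## Problem sizes

Scaled-down study conditions are used throughout so everything runs on a
single CPU: the test suite screens ensembles of up to 8 sets per topology
(class II capped by attempt budget) and asserts the class signatures as
orderings on a 1%-weakening, 6-phase campaign; the acceptance script uses
20-set ensembles (8 for class II), a 10-phase grid (8 for class II), and
a 400-candidate MCC budget. Full-protocol runs (1000 sets, 4 factors, 40
phases) use the same code path via `RunConfig.preset("full")`.

## What the generator does and does not emulate

The synthetic ensembles reproduce the stated sampling protocol (LHS,
log-range, fixed Hill exponents) over reconstructed kinetic templates.
They do not reproduce the unavailable original equations, so quantities
that depend on *how often* a sampled link is dynamically potent are not
transferable:

* A sampled Hill constant lands outside its input's dynamic swing for
  most draws, making that channel's Jacobian element numerically tiny.
  Perturbing an inert element changes nothing, so each extra (mostly
  inert) link dilutes a model's statistics toward pattern R. This raises
  the incoherent designs' robust fraction to ≈ (6·R_simple + 100)/7 and
  can push it marginally *above* the simple NFO's — inverting the
  robustness ranking that holds when incoherent links are potent — and it
  caps the amplitude-tunable fractions of incoherent types 2/3 far below
  values reported for ensembles whose incoherent links matter
  dynamically.
* Class II ensembles of fewer than ~10 sets have large per-set
  heterogeneity; the frequency-over-amplitude ordering of the
  inhibitor-amplified design is reproducible in direction but not
  significant at that size (adjacent seeds give F − A of −4 and +4
  percentage points).
* Pattern fractions for the simple NFO, by contrast, are insensitive to
  all of this (its links are all backbone links) and land within ~1
  percentage point of the published distribution already at 12 sets.

## Other limitations

No Floquet/monodromy analysis (out of scope by design); no strengthening
(factor > 1) campaigns by default — weakening beyond 8% frequently
destabilizes the cycle; stiff parameter draws are abandoned when an
integration exceeds its evaluation budget (~4×10⁵ right-hand-side calls)
and counted as failures rather than silently skipped.
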