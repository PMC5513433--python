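# Methods

This note records the model as implemented, the choices made where the
design was genuinely open, and what the synthetic fixtures do and do not
establish.

## Model overview and assumptions

The model treats transcription of a locus as the outcome of four coupled
layers, evaluated independently at each axis position (percent embryo
length). The key assumptions are: binding is at thermodynamic equilibrium;
TF concentration profiles are inputs, not state; context rules
(coactivation, quenching) act on occupancies through fixed distance
cutoffs; and only a finite window of α bp of DNA can influence the
promoter at one time, with windows competing for promoter access in
proportion to their bound activation.

### Occupancy

A binding configuration is any subset of called sites whose footprints are
pairwise disjoint (steric exclusion). Its weight is `∏ q_i · ω^(#pairs)`,
where `q_i = A_a · [a](x) · exp((s_i − s_max,a)/λ_a)` and the ω factor
applies once for each pair of *consecutively bound sites of the
cooperative TF* with edge-to-edge gap ≤ `d_omega`. "Consecutive" is read
as adjacent within the bound sites of that TF: a bound site of a different
TF sitting between two cooperative sites does not break the pair. The
alternative reading (any intervening bound molecule breaks the contact) is
defensible on steric grounds; the adjacent-within-TF rule was chosen
because the cooperative contact in this model family is a protein–protein
interaction between like molecules and because it gives a strictly larger
state space for the dynamic program, making it the harder contract to
implement and test. Both the enumeration oracle and the DP implement the
same rule, so the equivalence tests would catch any divergence.

The fractional occupancy of site *i* is the weight share of configurations
containing *i*; the empty configuration has weight 1.

### The dynamic program

Sites are sorted by start. For disjoint intervals, sorting by start also
sorts ends, so a left-to-right scan needs only the identity of the most
recently bound site to enforce sterics — maintained implicitly as a
running prefix sum over "closed" sites (those whose footprint ends before
the scan frontier). Cooperativity adds a second state component: the most
recently bound cooperative site. Because a cooperative site whose end lies
more than `d_omega` bp behind the frontier can never again contribute an ω
factor, such states are folded into a single "distant" state; the state
space per step is therefore bounded by the local density of cooperative
sites, and the whole pass is linear in site count for bounded overlap.

Occupancies come from a forward and a backward pass (the backward pass is
the forward algorithm run on the mirror image of the locus) combined per
site, with an explicit cross term for the case where the nearest
cooperative sites on either side of a bound non-cooperative site pair with
each other across it.

All accumulation is in the log domain (`numpy.logaddexp`), so weights as
extreme as `ω^n · ∏ q_i` with ω = 1000 never overflow; agreement with the
linear-domain enumeration oracle is required to 1e-10 relative in every
occupancy and in log Z and is measured on 200 random cooperative instances
in the acceptance suite (observed: ~1e-13). Everything is vectorised over
axis positions, since configuration geometry is position-independent.

`occupancy_bruteforce` enumerates all 2^n subsets (bitmask arithmetic,
refused above n = 20) and is the reference oracle throughout.

### Context rules

Coactivation first, then quenching, without feedback: quenching reduces
only the activating occupancy and does not weaken a coactivator's ability
to coactivate. The converse design (feedback from quenching into
coactivation) is not described by the model family this implements and
would make the layers mutually recursive; the sequential order matches the
enumerated mechanism ordering of the underlying model.

Multiple nearby coactivators combine by the complement product
`1 − ∏(1 − f_j)` ("at least one bound"), which is bounded in [0, 1] and
reduces to the single-coactivator case. Distances are centre-to-centre of
footprints with inclusive cutoffs; defaults `d_coact` = 150 bp and
`d_quench` = 100 bp, the short-range scale over which quenching operates
in this model family. Repressors do not quench repressors, and no site
quenches itself. A coactivated repressor contributes its repressing
remainder `f_rep = f − f_act` to quenching.

### Competition

Window starts run from −α to l−1 (half-open windows, `l + α` windows), so
every site — a site belongs to a window when its footprint midpoint falls
inside — appears in exactly α windows, and sliding prefix sums give all
window sums in O(l + n) per position. Edge windows that extend past the
locus ends are retained. `N`, `R`, `T`, and `R_total` follow the equations
in the README; the identity `Σ_m T[m] = S/(1+S)` with `S = β ΣN` holds to
1e-12 and is asserted. In `no_competition` mode a single whole-locus
window feeds the rate law directly and no T weighting is applied.
Predicted mRNA equals `R_total`, with the data scale carried entirely by
`Rmax` (the proportionality between synthesis rate and steady-state mRNA
is absorbed into the fit).

## Parameters

| parameter | meaning | bounds | scale |
|---|---|---|---|
| `A_a` | fluorescence×affinity → weight conversion | 1e-6 … 4 | log |
| `λ_a` | PWM score-to-affinity softening | 0.5 … 5 | linear |
| `ω` | cooperative pair weight boost | 1 … 1000 | log |
| `E_A` | adaptors recruited per activating site | 0 … 25 | linear |
| `E_Q` | quenching efficiency | 0 … 1 | linear |
| `E_C` | coactivation efficiency | 0 … 1 | linear |
| `θ` | energy barrier (basal leak `1/(1+e^θ)`) | 5 … 25 | linear |
| `β` | promoter-interaction gain per adaptor | 1e-6 … 1e2 | log |
| `Rmax` | saturating rate (data units) | 1e-2 … 1e4 | log |
| `α` | window size, bp | fixed (default 1000) | — |
| `d_omega` | cooperativity gap cutoff, bp | fixed (default 60) | — |

The β and Rmax bounds are this package's defaults (the source model family
does not publish them); both are configurable. `d_omega` is likewise not
published; 60 bp is within the short-range protein–protein contact scale
of this model family and the occupancy contract does not depend on it.

## Fitting

The annealer proposes single-coordinate Gaussian moves in a unit-cube
transform of the bounded search space (logarithmic for the multi-decade
parameters), reflects at the bounds, adapts step sizes toward a moderate
acceptance rate, and cools geometrically over a move budget that scales as
1/κ (κ is the accuracy knob: smaller κ, more moves). The best state then
receives a deterministic two-stage polish — L-BFGS-B with finite-difference
gradients, then a bounded Nelder–Mead pass that is insensitive to the
gradient noise floor. Every run is driven by an integer seed and is
exactly reproducible; traces record (move, SSE).

Two controls mirror standard optimisation practice for this model class:

* **fit-known-optimum** — replace the data with the model's own output for
  a known parameter set, so the global minimum is exactly zero; report the
  recovered SSE and the Spearman ρ between true and recovered parameter
  vectors. On the 6 kb benchmark with the 10-parameter free set, restarts
  reach SSE ratios below 1e-6 of a random-parameter score with ρ > 0.9.
* **permuted-sequence** — shuffle the (non-protected) bases and refit;
  permuted fits score worse than the real-sequence fit because the planted
  site architecture is destroyed while base composition is preserved.

## Attribution

Per-position derivatives `∂R_i/∂[A]_i` use the symmetric difference
quotient where `[A]_i > 0` (with the backward step shrunk so concentrations
stay non-negative) and Newton's forward quotient at zero; default
h = 1e-3 concentration units, with a convergence sweep over h = 1e-1 …
1e-11 available as a diagnostic. Because the model is columnwise in the
axis, a whole derivative profile costs two predictions.

The concentration change entering the border decomposition is the central
difference `([A]_{i+1} − [A]_{i−1})/2`; the literal adjacent-position
average `([A]_{i-1} + [A]_{i+1})/2` is implemented behind
`delta_mode="literal_average"` for auditability, since the defining text of
this quantity in the source model family is typographically ambiguous —
"the amount the factor is changing" fixes the central-difference reading.
First-order consistency (per-TF contributions summing to the output's
spatial derivative within 10% where the output is changing) holds on the
smooth benchmark profiles.

Activation shares weight the per-TF window adaptors by the promoter time
fractions, `N_a = Σ_m N[m; a]·T[m]`; the summation index runs over
windows, matching T's indexing. The decomposition `Σ_a N_a = Σ_m N[m]·T[m]`
is exact by linearity and asserted to 1e-10.

Fragment assays run the full pipeline on a subsequence alone and
standardise the output to a maximum of 1, emulating an enhancer-reporter
experiment outside native chromatin context (no accessibility mask by
default); raw outputs are retained.

## Chromatin accessibility

Accessible regions are the union of any number of BED inputs intersected
with the locus. Masking keeps exactly the sites whose full footprint lies
inside an accessible interval — "within accessible chromatin" read
strictly; an any-overlap variant exists for sensitivity analysis
(`apply_mask_overlap`). Masking is applied after site calling, which is
equivalent to masking the scan itself under the containment rule. BED
inputs must already be on the locus assembly; no coordinate lifting is
performed.

## Synthetic data

The generator emulates the structure of the real inputs: count-matrix PWMs
with controlled information content, i.i.d. background sequence at a
stated GC fraction (default 0.41) with planted consensus or
controlled-mismatch sites, and smooth profiles on a 58-point grid from
35.5% to 92.5% embryo length at 1% spacing with a 0–255 fluorescence-like
amplitude — the unit convention the `A_a` range was designed around.
Profile shapes cover anterior/posterior exponential gradients, Gaussian
bumps, uniform levels, and an anterior-plateau-plus-posterior-band shape
(the Hb-like case). All outputs are byte-identical under a fixed seed.

The standing benchmark is a 6 kb locus with two planted enhancers 3 kb
apart and six TFs — a cooperative anterior-gradient activator, a uniform
activator, two bump repressors, a posterior-gradient repressor, and a
coactivated repressor — sized to exercise every mechanism while keeping a
full prediction around 30 ms (310 called sites, 58 positions), so the
fitting controls finish in minutes on one CPU. Its hand-chosen parameters
drive two separated expression domains with a deep interstripe.

What the fixtures do *not* emulate: real binding-site clustering
statistics, PWM redundancy between paralogous factors, measurement noise
in expression profiles, and the 13 kb/8-TF scale of a real locus (the DP
is exercised at 3000 sites in the tests, but the fitted problems are
smaller). Passing tests therefore establish the correctness of the
machinery and the qualitative phenomenology (competition sub-additivity,
dual regulation, border attribution), not biological parameter values.

## Numerical choices and degenerate inputs

* Occupancy accumulates in the log domain throughout; occupancies are
  clipped to [0, 1] against last-bit round-off.
* Zero concentrations give q = 0 (log-weight −inf) and propagate exactly:
  occupancy, F, N and competition-mode output are exactly zero.
* N bases score −inf, so no called site spans an N.
* Sites on opposite strands at the same position are distinct sites; their
  mutual exclusion is handled by the occupancy layer.
* Quench/coactivation range products run over log factors floored at
  1e-300, exact until a factor underflows (where the product is 0 to
  machine precision anyway).
* The empty site list, the empty mask, single-row profile tables and
  fragments shorter than α are all legal inputs with the obvious limits.

## Known limitations

* One cooperative TF per model (the motivating system needs only Bcd).
* Cooperativity chains: occupancy of a site is *not* invariant to adding
  remote cooperative sites (chains propagate); the invariance test uses
  non-cooperative additions.
* No kinetic/non-equilibrium binding, no DNA looping energetics, no
  direct long-range repression of the basal complex.
* The annealer is an adaptive geometric-schedule design, not a
  Lam–Delosme implementation; it satisfies the same recovery contracts on
  the problems shipped here.
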