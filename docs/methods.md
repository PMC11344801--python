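# Methods

## Model and assumptions

fluxcap operates on genome-scale metabolic models under the standard FBA
assumptions: steady-state mass balance (`S v = 0`), flux bounds in
mmol/gDW/h (the biomass pseudo-reaction in g/gDW/h), and a single linear
objective maximising biomass flux.  Because biomass flux is the growth
rate, its inverse is the doubling time; experimental doubling times
therefore translate directly into minimum admissible predicted growth
rates ("growth floors").

The integration algorithm assumes transcript abundance is a usable but
imperfect proxy for enzyme capacity.  Expression values on the log2(TPM+1)
scale are used *numerically* as flux bounds (mmol/gDW/h); no unit
conversion is attempted, since only the relative capacity ordering of
reactions is meaningful.  The growth floor is precisely the mechanism that
absorbs the cases where this proxy fails: any single constraint that would
force predicted growth below the measured floor is rejected (the reaction
is "reopened" to its prior bounds) rather than kept.

## The sequential loop and its semantics

Reactions are visited in model document order (option: lexicographic by
id).  The loop is order-sensitive — an early kept constraint changes which
later constraints are tolerable — so the order is fixed for determinism
and recorded in the report.  Per reaction, checks run in this order:

1. **media_locked** — the reaction's bounds were set by the medium; never
   touched.
2. **essential_locked** — closing the reaction (bounds (0,0)) drops the FBA
   optimum of the *current, partially constrained* model below
   `essential_fraction` × the current optimum.  Default
   `essential_fraction = 0.01`: a reaction is essential when its loss
   removes ≥99% of achievable growth.  Evaluating against the current
   model (rather than the media-only model) was a genuinely open choice;
   it makes the lock consistent with the state the constraint would
   actually perturb.
3. **andor_skipped** — mixed isoenzyme/subunit rules are excluded from
   integration (no principled single formula combines sum and min without
   resolving the parse tree's semantics against enzyme abundances).
4. **genes_missing** — any rule gene absent from the profile leaves the
   reaction at its prior bounds.  Requiring *all* genes is the
   conservative reading; a flag (`allow_partial_or`) permits partial
   isoenzyme sums.  Reactions with no GPR at all also land here (they have
   no usable genes); the disposition vocabulary is kept to the six states
   above so every reaction receives exactly one.
5. **constrained / reopened** — provisional bounds, one FBA solve, keep or
   restore.

Relaxation scope: only the currently provisional reaction is ever
reverted, never previously kept constraints.  Reopened reactions end with
their pre-integration bounds bit-identically.  If the requested floor
exceeds what the media-constrained model can reach at all, a warning is
recorded and the achievable optimum becomes the effective floor — the loop
then never makes things worse than the media baseline.

Numerical choices: objective comparisons use an absolute tolerance of
1e-9; fluxes below 1e-6 mmol/gDW/h count as zero in the differential
criteria; no cap is applied to isoenzyme sums (they are far below the
default ±1000 mmol/gDW/h bound magnitude on the log2 scale).

## Media and serum estimation

Applying a medium sets the listed exchange bounds exactly and closes
uptake on every other exchange while leaving secretion open.  The closing
rule is not optional: without it a media dictionary would not constrain
anything.  Serum (FBS) components, which no medium file can enumerate, are
estimated by a greedy loop: while the optimum is below the growth floor,
every closed candidate exchange is temporarily restored to default bounds
(±1000), and the single best improver is permanently reopened, ties broken
by document order.  This is a deterministic reconstruction of what is, in
practice, a manual curation step; the estimate is flagged unsatisfied when
no candidate chain of reopenings reaches the floor.

## Knockouts and flux solutions

A gene knockout evaluates every affected reaction's GPR boolean expression
with that gene false and all others true; reactions evaluating false are
closed, and the growth ratio is KO optimum / baseline optimum (baseline
computed once per screen).  Plain FBA optima are unique but flux vectors
are not; wherever a flux *vector* is exported for group comparison the
parsimonious solution (minimal total absolute flux at the fixed optimum)
is used by default, and the plain-FBA choice remains available.  The
integration loop itself only needs optima and uses plain FBA.

## Differential criteria

The between-group filter is `(rel_change >= 0.10 AND magnitude_ok) OR
sign_change`, with `rel_change = |mean_low − mean_high| / max(|mean_low|,
|mean_high|)` (0 when both means vanish), `magnitude_ok` true when any
sample-level flux in either group reaches |0.5| mmol/gDW/h, and
`sign_change` true for opposite-signed means beyond the zero tolerance.
The three clauses are reported separately in the output so alternative
combinations can be audited.  The denominator of the relative change
(larger absolute mean) and the sample-level reading of the magnitude
condition were open choices; both are symmetric under group relabelling,
which the tests assert.

## Validation statistics

Over-representation uses the hypergeometric upper tail: for a list of N
genes drawn from a reference universe of M, a set with K reference members
and overlap k has `p = P[X >= k]`, `X ~ Hypergeom(M, K, N)`;
Benjamini–Hochberg FDR is applied across sets and the enrichment ratio is
`k / (N·K/M)`.  The reference defaults to all genes in the dependency
dataset.  Gene-id namespace mapping is out of scope: inputs must share a
namespace and unmapped genes are reported, not silently dropped.  The
knockout-versus-dependency agreement is the Pearson correlation (p-value
via the t-transform with n−2 degrees of freedom) over genes with a
predicted growth effect (ratio < 1 by default); model-data agreement
appears as a negative coefficient, since high dependency means strong
growth impairment on knockout.

## What the synthetic fixtures do and do not show

The generator emits parallel linear chains (exchange → conversions → a
shared biomass precursor), so the FBA optimum is the sum over chains of
the minimum capacity along each chain — an exact analytic oracle.  Planted
bottlenecks, essential genes (on shared mandatory steps) and differential
effects are recoverable by construction, and all randomness flows through
one seeded generator.  Defaults (2–3 chains of length 3, uptake capacity
5, base expression 8 on the log2 scale with jitter 0.05, dependency scores
at 0.9/0.1 ± 0.05 clipped to [0,1]) are chosen so that one low-expressed
gene can bind a chain without being essential.

Passing on these fixtures demonstrates the *logic*: bound formulas, loop
semantics, threshold safety, boolean knockouts, criteria flags and the
statistics.  It does not demonstrate performance on a real reconstruction
— toy chains have no alternate optima to speak of, no compartments, no
futile cycles, and far denser gene annotation than a genuine GEM — so
biological conclusions still require a curated model and real expression,
growth and dependency data.  At genome scale the loop costs roughly two LP
solves per reaction (one essentiality check, one provisional solve), which
is the dominant runtime.

## Known limitations

* `andor` rules are skipped, not approximated.
* The serum estimator is greedy; it finds *a* sufficient reopening set,
  not a minimum-cardinality one (the last reopening is always necessary,
  earlier ones may be superseded).
* Flux-vector-based comparisons inherit pFBA's arbitration among alternate
  optima; differential flags on near-degenerate reactions should be read
  with that in mind.
* Doubling-time conversion ignores death rates and lag phases: it is the
  exponential-growth inverse rule only.
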