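# Methods

This note documents the model as implemented: its assumptions, the numerical
choices behind the dynamics, the points where the design was genuinely open
and what was decided, and what the simulations at the sizes used here do and
do not show.

## Model structure

A host genotype is an architecture tag plus a protein roster and a signed
edge list.  Proteins have a stable integer id, a role (detector, signalling,
effector) and a network (immune, developmental, or — for the pleiotropic
effector — shared).  Independent hosts start with 10 proteins (two complete
detector/3-signal/effector networks); shared hosts start with 9 (one effector
serving both networks).  At initialization every legal ordered same-network
pair carries an edge with probability 0.5 and a coefficient drawn uniformly
from [−1, 1]; both architectures have exactly 42 legal founder pairs, so
founder wiring density is comparable.

Edge legality, everywhere (initialization, mutation, loading from disk):
detectors and effectors never connect directly in either direction;
self-loops are allowed on signalling proteins only; cross-network edges are
illegal at initialization but may evolve through mutation (upstream
pleiotropy).  The shared effector belongs to both networks, so its edges are
within-network by construction.

A parasite genotype is a target index, a signed target coefficient, and two
fixed constants: self-upregulation 0.8 (replication) and +1 onto the host's
immune detector.  The target index addresses the host's immune signalling
proteins sorted by id, modulo their count, so any parasite resolves a target
on any host regardless of network size.

## Dynamics

Active fractions evolve by forward Euler with dt = 1, one step per model
timestep, clamped to [0, 1] after every step.  The per-step change of
protein *i* is `(1−Pi*)·Σk_ij·Pj* − Pi*·ΣI_ij·Pj* − use_coef·N_out(i)`,
where positive coefficients route to the upregulatory sum and magnitudes of
negative coefficients to the downregulatory sum.  `N_out(i)` counts outgoing
edges of *i* ("protein use"); during infection the effector's −1 link onto
the parasite counts toward the effector's use, and the parasite pays for its
own two or three outgoing links.  The resource cap is applied to the net
per-node deltas: if the sum of positive deltas exceeds the budget, all
positive deltas are scaled by a common factor so the sum equals the budget;
negative deltas are never rescaled.  The parasite node sits under the same
cap — replication competes for the same activation budget as host
signalling.

Two integrators implement these semantics: a readable per-edge reference
(`lifecycle.simulate_life`) and a padded, vectorized population engine
(`lifecycle.simulate_population`) used by the evolutionary loop.  The
test-suite holds them to each other at 1e−10 over short horizons.  Over a
full 150-step life the clamp and cap introduce branch points at which the
(expansive) dynamics amplify float-rounding differences between summation
orders exponentially, so full-life agreement is asserted at a loose bound
(2e−3) that still catches semantic divergence; all scientific quantities are
computed consistently within one engine, and every run is bit-reproducible
for a fixed seed and engine.

## Life cycle

Equilibrium: all proteins start at P* = 0.5 and free-run for 5 steps with no
input.  Life: 150 steps.  The developmental signal sin(x/2) + 0.5, with x on
the 50-point inclusive grid [0, 8π], enters as an external node with a fixed
+1 link to the developmental detector during the 50-step window.  Two open
readings of the signal formula exist because the source rendering is
ambiguous; the implementation defaults to sin(x/2) + 0.5 (the half-angle
reading, four full pulses) and exposes sin(x)/2 + 0.5 as the config switch
`signal_variant="half-amplitude"`.  The signal may leave [0, 1]; it is an
input and a cost reference, never a clamped state variable.

Infection windows (development-first order): synchronous = steps 0–49,
asynchronous = steps 50–99.  In the reversed (development-last) order the
windows flip: development occupies steps 100–149, synchronous infection with
it, and asynchronous infection falls in steps 0–49 — the first 50 of the
signal-free steps, mirroring the development-first case.  The infecting
parasite enters with abundance 0.5, the same value as protein
initialization, since it is treated as one more network node; its inoculum
is not otherwise constrained by the model description.

Fitness components: immune effector area is the mean effector activity over
all 150 life steps; parasite area is the mean parasite abundance from the
infection step to the end of life (zero when uninfected); developmental cost
is (1 − Pearson correlation) + mean absolute difference between signal and
developmental effector output over the 50-step window, with the correlation
defined as 0 when either series is constant (a flat output carries no
tracking information).  Host fitness is exp(−(sum of the three)).

## Selection and reproduction

Per generation, each parasite infects one distinct host chosen uniformly, so
prevalence is parasites/hosts (50% in isolated evolution, 25% once merged
populations compete at the doubled host target).  Deaths are capped at
floor(0.30·N) per population.  Hosts whose parasite area exceeds 0.9 die
first; if they exceed the cap, a uniform subset of exactly the cap dies.
Otherwise remaining deaths come from one randomized pass over the other
hosts, each dying with probability 1 − W/W_max.  The inverse-fitness rule is
stated only qualitatively in the model description; this form was chosen
because it needs no normalizing constant and guarantees the fittest host
survives its visit.  Parasite deaths are strictly rank-based: the least-fit
30% die, ties broken by stable input order.

Host reproduction draws parents from survivors with replacement,
probability ∝ W, until the population is restored (500 isolated, 1000
competitive).  Parasites reproduce in descending fitness order, each
contributing 1, 2 or 3 offspring as its final within-host abundance falls in
[0, 1/3], (1/3, 2/3] or (2/3, 1] — the printed bins (0–0.33 / 0.34–0.66 /
>0.66) leave gaps for continuous abundances, so they are read as a partition
at the thirds — cycling until replenished, with the final batch truncated.

Mutation applies exactly one event per mutated offspring.  Host events and
weights: add edge 0.25 (any legal ordered pair, cross-network allowed),
delete edge 0.25, redraw one coefficient 0.30, delete a signalling protein
0.10, duplicate a signalling protein with all incoming and outgoing edges
0.10.  Infeasible events (deleting an edge from an edgeless genotype,
deleting a network's last signalling protein) are no-ops rather than
resampled, keeping the per-event probabilities as specified without
rejection loops.  Duplication copies the full edge neighbourhood, giving
immediate functional redundancy.  Parasite events: retarget (uniform over a
fixed index domain of 8, resolved per-host by the modulo rule) or redraw the
coefficient, each 0.5.

Under the alternating resource condition the budget switches per generation
— scarce on even generation indices, plentiful on odd, starting scarce —
one of several schedules compatible with the model description; per-life or
per-timestep alternation would be alternative readings.

## Randomness and reproducibility

Each run spawns four named substreams (initialization, infection, death,
mutation) from a single seed via `numpy.random.SeedSequence`, so identical
seeds give bit-identical histories and analyses can hold individual sources
fixed.  Campaign tables record a per-row seed sufficient to replay any
single competition in isolation.

## Analyses

**Knockout robustness.**  For each signalling protein, the knockout genotype
removes the protein and its edges; intact and knockout hosts live through
identical lives infected by a non-disrupting parasite (detector, self and
effector links intact; no target link) at a fixed timestep — the midpoint of
the scenario's infection window — so score differences reflect structure,
not timing noise.  The score is the mean absolute difference of the immune
effector trajectories over the 150 life steps; the summary is the mean over
all single knockouts, with the per-knockout distribution also reported.

**Network features.**  Connectivity is realized within-network edges over
the legal within-network ordered pairs of the current roster (the same
legality rules as above, self-loops on signalling proteins included in the
denominator); it is invariant under protein relabelling.  Size is the
protein count, reported minus one for independent hosts to offset their
extra founder protein.  Upstream pleiotropy is the existence of any edge
bridging the immune and developmental networks, excluding edges incident to
a shared effector (which is downstream pleiotropy by definition).  Features
are computed for the modal genotype of a population under structural
equality.

**Quasi-binomial regression.**  The final shared-effector fraction of each
competition is regressed on synchrony, resource condition (two dummies,
scarce reference) and burn-in length (numeric, per 250 generations) with a
logit-link binomial GLM (statsmodels); the dispersion is estimated as
Pearson chi-square over residual df and standard errors are scaled by its
square root.  With dispersion 1 the fit reduces to ordinary logistic
regression; the test-suite cross-checks the scaling against statsmodels'
own Pearson-scaled refit.  Draws keep their fractional composition in the
regression response; for win percentages, draws are excluded from
numerators and kept in denominators.

**Geometric mean fitness** is exp(mean(log W)) over a per-generation fitness
series, defined only for positive series (W > 0 always holds here).

## Problem sizes used in tests and the acceptance script

The full study conditions (500/250 populations, 1000-generation horizons,
hundreds of replicates) are ensemble-scale computations.  The packaged
checks use the same generator defaults at reduced scale: a 20-generation run
at full default sizes for generation mechanics; 1000 founder initializations
for connection density; and, for the competitive headline, an ensemble of 30
scaled-down competitions (50 + 50 hosts, 25 + 25 parasites, 200-generation
burn-in, competition capped at 300 generations) under synchronous signalling
with scarce resources.  Thirty replicates were sized from a pilot estimate
of the shared-effector win probability (~2/3 under these conditions) so that
a strict majority is detected with ~95% probability; at these population
sizes drift is strong and individual competitions resolve quickly (median
~30 generations), so any single replicate is uninformative — only the
ensemble percentage is.

## Limitations

The synthetic populations are the model; no empirical data enters.  What
passing tests show is internal consistency and qualitative reproduction of
the model's behaviour at reduced scale — not quantitative win percentages at
the full study scale, which would need the full ensemble.  The model itself
abstracts heavily: haploid clonal hosts, one parasite per host per life, no
spatial structure, equal fitness weighting of the two traits, and a
parasite that manipulates exactly one signalling protein.
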