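# Methods

`pararep` simulates finite populations of RNA-like template replicators
whose growth is *parabolic*: template-directed, non-enzymatic copying turns
a single-stranded template into a template–copy duplex, and because strand
association (rate constant `c_a = 1`) is fast relative to dissociation
(`c_d <= 0.63`), most strands sit in duplexes that cannot act as templates.
The per-capita replication rate then falls with abundance, the population
grows like `dN/dt ∝ sqrt(N)`, and competition between sequence variants is
strongly damped. The package quantifies how much heritable sequence
information such a regime can maintain under mutation, drift and resource
limitation.

## State space and reactions

A replicator is a fixed-length string over `{A, U, G, C}` (default
`L = 10`; no insertions or deletions). The population state is a multiset
of simplex strands, a multiset of duplexes (unordered strand pairs), and —
in the chemostat — four monomer pools.

Constant-population (Moran) regime:

    S_i  ->  S_i S_j        (replication, c_r)
    S_i + S_j  ->  S_i S_j  (association, c_a)
    S_i S_j  ->  S_i + S_j  (dissociation, c_d)

Every newborn strand replaces a strand drawn uniformly from the rest of
the population, keeping the total strand count at `N`; when the victim
sits inside a duplex the whole duplex is removed and the count reads
`N - 1` until the next replication, which then skips the removal. The
template and the newborn strand are excluded from the victim draw (a
newborn that instantly deleted itself or its template would make the
bookkeeping of the replacement ill-defined; the exclusion is our
interpretation of "a randomly chosen sequence").

Chemostat regime: the same three reactions plus monomer inflow at `c_in`
per base type, simplex decay at `c_dss = 1e-4`, duplex decay at
`c_dds = f * c_dss * 0.8^Eb` (`0 < f <= 1`), and outflow of every
molecular species — simplex, duplex (as one unit; a duplex is one molecule
in the outflow reaction) and free monomer — at the per-molecule rate
`c_out`. Each replication consumes one monomer per base of the realized
product. Replication channels are gated on every pool holding at least
`L` monomers, which makes any realized product affordable and keeps the
simulation exact; resource limitation binds through depletion below the
gate. (The alternative — mass-action dependence of the replication
propensity on pool sizes — is not stated by the model definition we
follow; the gate keeps the rate law clean and was chosen as the default.)

## Kinetic laws

**Replicability.** Master type `i` (of `T = 10`) replicates at
`phi_i = phi_min + (i - 1) * delta` with `phi_min = 0.005`; `delta` (the
"replicability distance") is the fitness-spacing control parameter. An
arbitrary sequence is scored against every master type by Hamming
distance, taking for each type the minimum over the master and its
complement (both strands of a type replicate at the type's rate — without
this, the plus/minus replication cycle could not sustain a master's
abundance; a plus-strand-only mode is available as
`KineticParams(include_complements=False)`). Distance 0, 1, 2 map to
factors 1, 0.2, 0.05 of the type's rate; the best value over types is
used, and sequences more than two errors from every master replicate at
`0.05 * phi_min`.

**Duplex energetics.** Strands pair antiparallel in a fixed register
(no frameshift): position `k` of one strand against position `L-1-k` of
the other. The binding energy is `Eb = nAU + 2 nGC` (G-C pairs count
double), with maximum `2L = 20`; association requires at least two
Watson-Crick pairs. Complementarity is reverse-complementarity throughout
(`complement(s, reverse=False)` gives the positionwise variant for
sensitivity checks, paired with the matching register flag).

**Dissociation.** Two conventions are implemented because they correspond
to two readings of the same calibration ("the maximum-energy duplex
dissociates with probability 0.01"):

* `calibrated` (default): `p_diss(Eb) = 0.01^(Eb/2L)`, i.e.
  `exp(-kappa' Eb)` with `kappa' = ln(100)/2L ≈ 0.2303`. This pins
  `p_diss(2L) = 0.01` exactly and spans `[0.01, 0.6309]` over
  `Eb ∈ [2, 20]`.
* `normalized`: the Boltzmann distribution over admissible energy levels,
  `exp(-kappa Eb) / Σ_{E=2}^{2L} exp(-kappa E)`; with `kappa = 0.15` the
  maximum-energy duplex gets 0.009935.

Both are strictly decreasing in `Eb`; `calibrate_kappa` solves either
convention for a target maximum-energy probability (closed form or
bracketed root finding). The dissociation rate constant equals the
probability (`c_d = p_diss`), and likewise `c_r = phi`.

**Mutation.** Each base of the newly synthesized complementary strand is
substituted independently with probability `p_mut`, uniformly over the
three alternative bases (the substitution kernel is not otherwise
constrained by the model; uniformity is the least-informative choice). If
a mutated product shares fewer than two Watson-Crick pairs with its
template, no duplex can form and the product is released as a free
simplex — a corner the reaction scheme does not itself cover.

## Stochastic simulation

Two implementations realize the same process:

* **Reference engine** (`pararep.ssa`): a transparent direct-method SSA
  over explicit `ReactionChannel` objects with combinatorial counts
  `h` (`n` for unary channels, `n_a n_b` or `C(n, 2)` for pairs),
  propensities `alpha = h c`, waiting times `ln(1/r)/Σalpha` and
  cumulative-sum channel selection in stable insertion order. After each
  event only channels touching the affected species are recomputed;
  `Simulation.audit()` compares the incremental table against a
  from-scratch recomputation and is exercised in property tests.
* **Compiled core** (`pararep._core`, numba): the production path. It
  holds simplex counts densely over the `4^L` sequence space, duplex
  species behind an open-addressing hash, and performs every weighted
  selection through Fenwick trees (O(log) per event). Association fires
  by exact thinning: the envelope propensity `c_a C(A, 2)` covers all
  simplex strand pairs and a sampled pair that cannot form a stable
  duplex is a null event that only advances time — by
  superposition/thinning of Poisson processes this is distribution-exact,
  not an approximation. In the cross-hybridization-disabled mode (where
  the envelope would be almost entirely null) association instead splits
  into an exact master+own-complement channel plus channels for pairs
  involving at least one mutant strand. No tau-leaping or other
  approximate acceleration is used anywhere.

The two engines are cross-validated statistically on small systems, and
the core's ledgers (strand counts, monomer balance) are checked exactly in
closed-system runs. Floating-point drift in the running propensity sums is
bounded by periodic from-scratch refreshes (every 2^20 events); species
capacities are 2^16 active simplex and duplex species, with compaction of
extinct duplex species and explicit truncation flags on overflow.

Runs are seeded once: a `numpy.random.SeedSequence` over the run seed
yields the master-set seed and the core's RNG seed, so a (config, seed)
pair reproduces bit-identically. Replicate seeds in sweeps derive from a
master seed the same way and are shared across grid cells, making cell
contrasts paired.

Termination is by replication-event count (default `10^7`), with sampling
every `survival_cadence` replication events. A master type *survives* a
run when its relative strand frequency (strands equal to the master or its
complement, free or duplex-resident, over all strands) is at least `1e-3`
in more than one of the six samples spanning the final
`survival_window = 5 * cadence` events.

## Deterministic quasispecies analysis

The single-peak landscape has one master genotype with reproductive value
`A`, a lumped mutant class with value `a = 1`, copying fidelity `Q`, and
optional back mutation `pB`. Under constant organization (`x + y = 1`):

    exponential:  dx/dt = A Q x + a pB y − x Ē,   Ē = A x + a y
    parabolic:    dx/dt = A Q √x + a pB √y − x Ē_p,  Ē_p = A √x + a √y

For `pB = 0` the exponential master equilibrium is
`x̂ₑ = (A Q − a)/(A − a)` clipped at zero — an error threshold at
`Q* = a/A`. The parabolic equilibrium is strictly positive for every
`Q > 0` (no threshold), and `pB > 0` removes the exponential threshold as
well. Equilibria are found by bracketed root finding on the master rate
function evaluated on a 2049-point grid; near `Q = 1` the parabolic flow
can hold several rest points, so the root finder returns the attractor
reached from `x₀ = 0.5`, which matches the independent cross-check by
long-time stiff integration (`solve_ivp`, LSODA, `rtol = 1e-10`,
`atol = 1e-10`; the `x + y = 1` constraint is monitored to `1e-8`).
Agreement between the two routes is asserted to `1e-6` on an `(A, Q)`
grid. Whether the normalization is enforced by an outflow term or a
constraint is immaterial for the equilibria under constant organization.

## Synthetic study conditions and desk-scale reductions

All inputs are generated. Master sets come in three kinds: `random`
(pairwise Hamming distance >= 2, avoiding source-sink coupling),
`gc_gradient` (master `i` holds exactly `i` G/C bases, equal
replicabilities 0.005), and `balanced_gc` (50% GC everywhere,
replicability gradient). The GC-controlled kinds reshuffle loci until all
master-master, master-other-complement and master-own-complement distances
exceed 3 (the last excludes palindromes); generation is bounded rejection
sampling (default 10^6 attempts) that fails loudly rather than silently
relaxing a constraint.

The full-scale designs run `10^7` replication events per trajectory
(`2·10^6` for the balanced-GC control). The package's reproduction
harness (`pararep.experiments`) runs reduced versions sized for minutes on
one core; the reductions divide the event horizon and the survival
window/cadence by a common factor (preserving the 6-sample window
structure) and are as follows:

| design | full scale | reduced default |
|---|---|---|
| N × delta survivor grid | N ∈ {10³,10⁴,10⁵}, 10⁷ events, 50 runs | N ∈ {300, 1000}, δ ∈ {0.001, 0.01}, 2·10⁴ events, 20 runs |
| mutation series | N = 10⁴, 10⁷ events, 20 runs | N = 500, 10⁴ events, 20 runs |
| balanced-GC control | N = 10⁴, 2·10⁶ events | N = 10⁴, 2·10⁴ events, 10 runs |
| chemostat inflow series | 10⁷ events, 20 runs | horizon ∝ c_in (≤ 2·10⁴ events), 4–5 runs |

Reduced runs preserve the *directions* of the full-scale effects (more
survivors at larger N and smaller δ; fewer survivors and lower summed
master frequency at higher p_mut; order-of-magnitude drop of N̄ per
ten-fold drop of c_in; duplex dominance at large f with a simplex shift at
small c_in), and the tests assert exactly those directions. The absolute
survivor percentages at reduced scale are *not* expected to equal the
full-scale percentages — shorter horizons leave less time for
extinction, smaller populations more drift.

One finding from designing the balanced-GC control: at these kinetics the
within-type free-simplex fraction scales as `1/sqrt(n_i)`, so the Moran
steady state distributes master frequencies approximately as
`phi_i² / Σ phi²` rather than linearly in `phi_i`. The weakest type then
holds only ~0.26% of the population, which at `N = 10³` is a handful of
strands that drift below the survival cutoff. The all-types-alive property
of this control therefore genuinely requires the full-scale `N = 10⁴`,
which the reduced design keeps, shortening only the horizon.

The parabolic-growth signature uses a closed resource-rich chemostat (no
inflow, decay or outflow; pools of 10^7) with a single all-G master whose
all-C complement forms the maximum-stability duplex (`Eb = 20`,
`p_mut = 0`): ensemble-mean growth from 10 strands is compared between the
square-root closed form `N(t) = (k t/2 + √N0)²` (one fitted parameter)
and the best two-parameter exponential, by RMSE.

What the generators do not emulate: real nucleotide chemistry (no
nearest-neighbor thermodynamics — `kappa` is an abstract inverse
temperature), secondary structure and folding, sequence-length change,
spatial structure or compartments, and growth orders between 0.5 and 1.
Passing tests therefore speak to the model's internal consistency and to
the qualitative physics of parabolic coexistence, not to quantitative
predictions for laboratory RNA systems.

## Parameter summary

| parameter | meaning | default / range |
|---|---|---|
| `L` | sequence length | 10 |
| `T` | master types | 10 |
| `phi_min` | weakest master replicability | 0.005 (time⁻¹, arbitrary units) |
| `delta` | replicability spacing | 0.001–0.01 (0.005) |
| `eps1, eps2` | 1-, 2-error factors | 0.2, 0.05 |
| `p_mut` | per-base substitution probability | 0.01–0.15 (0.01) |
| `c_a` | association rate constant | 1 |
| `kappa` | dissociation scale (normalized form) | 0.15 |
| `c_dss` | simplex decay (chemostat) | 1e-4 |
| `f` | duplex decay factor | 0.01–1 |
| `c_in` | monomer inflow per base | 0.01–1 |
| `c_out` | per-molecule outflow | [1.75e-6, 1e-5]; pinned per condition (1e-5) |
| cutoff | survival frequency | 1e-3, >1 of 6 window samples |

Time is in arbitrary units; only rate ratios matter.

## Known limitations

* The compiled core requires `L <= 12` (dense arrays over `4^L`); the
  reference engine has no such limit but is ~1000× slower.
* Species capacities (2^16) bound extremely mutation-rich regimes; runs
  flag truncation rather than failing silently.
* The Moran victim-exclusion rule and the unstable-product release are
  interpretations of under-specified corners of the reaction scheme (both
  flagged above); alternative readings would change results only through
  O(1/N) effects.
* Wilcoxon rank-sum significance testing of survivor GC content is out of
  scope; `scipy.stats.ranksums` applied to the sweep output columns
  (`gc_survived`, `gc_extinct`) covers that use.
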