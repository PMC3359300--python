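# Methods

## The model

`dynloop` simulates a single interphase chromosome as a coarse-grained
polymer on a simple cubic lattice. One monomer represents 150 kb of genomic
content — safely above the chromatin persistence length, so the chain is
treated as freely jointed. Monomers occupy one lattice site each (excluded
volume); backbone bonds and transient loop bonds must be one of the 26
displacement vectors with components in {−1, 0, +1} (lengths 1, √2, √3).
Dynamics are single-site Monte-Carlo trial moves: a uniformly chosen monomer
is displaced to a uniformly chosen one of its 6 nearest-neighbour sites, and
the move is accepted iff the target site is free and every bond of the
monomer stays an allowed vector. One Monte-Carlo step (MCS) is N trial
moves. The lattice is periodic; positions are stored unwrapped for
observables while excluded volume acts on wrapped sites, and L must be much
larger than the radius of gyration (default L = 600) so the chain never
meets its periodic image.

The distinguishing mechanism is *dynamic looping*: when a move brings a
monomer into the proximity cutoff of another monomer — the cutoff equals the
maximum bond length √3, so non-adjacent monomers must be at least as close
as chain neighbours can be — the pair may form a transient bond. The pair
probability is built from per-monomer interaction affinities `a_i` as the
geometric mean

    p_ij = sqrt(a_i a_j),

chosen because it is symmetric, collapses to the common affinity on a
homogeneous fibre, and vanishes when either side is zero (the combination is
pluggable: `product` and `min` are available). A formed bond receives a
lifetime drawn from a Poisson distribution (mean 8000 MCS by default) and
dissociates when it expires; expiry is checked once per MCS, inclusively.
A monomer holds at most one loop bond at a time (configurable by design in
principle; the single-partner rule keeps the pair probability well defined
and caps loops at N/2). There is no interaction potential and no Metropolis
weight: looping is probabilistic by construction and strictly short-ranged.

### When is a formation attempt made?

Attempts are tied to motion: after each accepted move of monomer i, one
eligible neighbour (within the cutoff, loop-free, not a chain neighbour) is
chosen uniformly and the Bernoulli trial with probability `p_ij` is run. Two
rules decide who is eligible:

* `new_contact` (default): only neighbours that *entered* the cutoff sphere
  with this move, i.e. pairs newly brought into proximity by diffusion;
* `per_move`: every current neighbour, retried on each accepted move while
  the pair stays co-localized.

The default matters. Under `per_move` the attempt rate while co-localized is
so high that, at the affinity and lifetime scales used here, bonding
saturates: nearly all monomers are bonded in *both* high- and low-affinity
regions, and the expression-dependent contrast disappears. Tying the trial
to the proximity-entry event keeps the formation/dissociation balance in the
regime where affinity differences translate into structural differences,
and matches the physical picture of a contact-formation event. Both rules
are exposed via `SimParams.formation_rule`.

## Expression → affinity

Expression tables (tab-delimited chromosome/start/end/value, 0-based
half-open) are projected onto the monomer grid by length-weighted averaging;
monomers without data get level 0, i.e. are treated as unexpressed. The
affinity map is linear between two anchored endpoints:

    a_i = a_max − (a_max − a_min) · (e_i − e_min) / (e_max − e_min)

so the most highly expressed monomer receives the *minimum* affinity
(default a_min = 0.01) and unexpressed monomers the *maximum*
(default a_max = 0.065, within the 0.06–0.07 range that best reproduces
experimental mean-square distances at full scale). The inversion encodes
that heavily transcribed chromatin is coated with transcription machinery
and therefore less available for direct chromatin–chromatin contacts. The
map is monotone non-increasing by construction and pluggable — only the two
endpoints are anchored; a rank-based map would be a legitimate alternative
and can be passed via the `mapping` argument.

## Simulation protocol

1. A random self-avoiding chain is grown (biased growth with restarts —
   any growth bias is removed by the next phase).
2. Loop-free equilibration: `equilibration_mcs` MCS (default 2×10⁵) with
   loop formation rejected, randomizing the conformation. A
   Mann-Kendall-style trend test on the late R_g² series (thinned by its
   autocorrelation time, because consecutive MCS values are strongly
   correlated) serves as the stationarity gate.
3. Looped equilibration: the same number of MCS with loops allowed.
4. Production: snapshots every `2τ` MCS until at least `n_conformations`
   (default 1000) are collected. τ is the autocorrelation time of R_g²,
   estimated on a pilot segment by a least-squares exponential fit to the
   initial ACF decay. The fit window runs to the first crossing of 1/e²
   (minimum 5 lags): for a clean exponential this is identical to any
   shorter window, while for the multi-exponential R_g² relaxation of a
   looped chain it weights the slow modes enough that 2τ spacing actually
   decorrelates (lag-1 autocorrelation of sampled R_g² ≈ e⁻² ≈ 0.14). If
   the ACF drops below 1/e at lag 1 the decay is sub-lag and τ < 1. A fixed
   snapshot interval can be set instead (`sample_interval`).

All randomness flows from one numpy Generator seeded by `SimParams.seed`;
the numba kernels draw a fresh sub-seed (< 2³¹) from that stream per
invocation, in a fixed order (monomer pick, direction, candidate choice,
loop coin, lifetime inside the kernel), so runs are bit-reproducible given
(seed, parameters). Replicate chains started from different seeds are
statistically independent; `merge_ensembles` pools them, which is the
preferred way to build large ensembles of genuinely uncorrelated
conformations (it mirrors averaging over many cells).

## Observables

* **MSD** — mean square spatial distance between monomer pairs at contour
  separation n, averaged over pairs and conformations; the locus-specific
  variant restricts to given index pairs, mirroring FISH. Lattice units;
  `lattice_scaling` fits the factor s (µm per lattice unit) minimizing
  Σ(s²·MSD_lattice − MSD_µm)² against an experimental (Mb, µm²) table,
  interpolating the simulated curve to the experimental separations.
* **Loop-size distribution** — histogram of g = j − i over active bonds in
  the snapshots (a lifetime-weighted bond-event log is an alternative
  estimator with different weighting; the snapshot estimator is primary).
  The short-loop exponent α is the least-squares slope of
  log(P(g)/(N−g)) vs log g over 0.5–7 Mb by default (0.15 Mb per monomer);
  (N−g) is the number of ways a loop of length g fits on the chain.
* **Local density** — per conformation, a 3-D Gaussian KDE (Scott's rule;
  the bandwidth factor is recorded in the output) fitted to the N monomer
  positions and evaluated at those positions, then averaged per monomer
  over the ensemble (averaging before correlating; correlating
  per-conformation and averaging the coefficients is a different, noisier
  estimator). The volume ratio of region classes is the inverse density
  ratio V_high/V_low = ρ̄_low/ρ̄_high.
* **Shape** — gyration tensor Q_ab = (1/M)Σ(r_a−r̄_a)(r_b−r̄_b); normalized
  asphericity A = [(λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²] / [2(λ₁+λ₂+λ₃)²],
  0 for spheres, 1 for rods, scale-invariant.
* **Radial positioning** — per conformation, squared distance of each
  monomer to the chain center of mass and to the territory surface, then
  ensemble-averaged. The surface is the convex hull of the conformation
  (parameter-free and deterministic; an α-shape would hug concavities
  better and is a noted extension), and the surface distance is the minimum
  absolute distance to the hull facet planes.
* **MSMD** — mean square monomer displacement relative to the chain center
  of mass over lag t, averaged over time origins and region monomers, from
  a densely sampled trajectory. 5% of monomers at each chain end are
  excluded by default (chain ends diffuse differently). MSMD(t)/t is the
  normal-diffusion diagnostic: constant for free diffusion, decaying under
  the confinement of the territory. Center-of-mass subtraction can be
  disabled to measure absolute displacements.
* **Correlations** — Pearson and Spearman of any per-monomer metric against
  the expression profile, with two-sided p-values.

## Synthetic expression profiles

`synth_expression_profile` emulates the structure of real per-bin
expression data: contiguous blocks of high/low mean expression plus
truncated Gaussian noise, with a matching high/low region annotation
(blocks above/below the profile median). It reproduces the feature that
drives the model — contiguous stretches of strongly differing
transcriptional activity — but not the heavy-tailed level distribution,
probe-level noise structure, or the irregular block lengths of microarray
data, so passing desk-scale tests demonstrates the mechanism, not
quantitative agreement with any particular cell type. Default desk-scale
conditions used in the tests: N = 300, two equal blocks (means 10 and 1,
noise SD 0.5), a_min = 0.01, a_max = 0.07, lifetime 2000 MCS.

## Numerical choices and problem sizes

* Desk-scale runs use L = 96–128 (still ≫ R_g at N ≤ 300) so the occupancy
  grid stays small; production-scale defaults keep L = 600.
* The expression-dependence tests pool 6 replicate chains × 40 snapshots
  (240 conformations) with 3×10⁵ MCS equilibration per phase: the slowest
  observable is the territory *topology* (which region sits inside), which
  relaxes far more slowly than R_g², so independence comes from replicates
  rather than within-run spacing.
* The excluded-volume control fits the internal-MSD exponent over
  n ∈ [3, 50] (≤ N/4, above the bond scale) on a chain equilibrated for
  10⁶ MCS; the measured ν ≈ 0.59 matches the Flory value. Shorter
  equilibration visibly depresses ν — the chain remembers its compact
  grown state.
* Eigenvalues are clipped at 0 before the asphericity (they can be −1e-17
  numerically); a zero tensor raises rather than returning a shape.
* Convex hulls fall back to joggled input (`QJ`) on degenerate point sets.
* The loop-exponent fit requires ≥ 4 distinct loop lengths in range and
  excludes g with zero probability.

## Known limitations

* Single chain only: no inter-chromosomal intermingling, no confining
  nucleus; whole-chromosome asphericities are therefore lower than measured
  for territories packed among neighbours.
* No strand passage: topology changes only through the free chain ends.
* The affinity map and pair-probability combiner are modelling choices
  anchored only at their endpoints; results at intermediate expression
  levels depend on them.
* Lattice units throughout; physical units exist only through the MSD
  scaling fit against external data.
* Below the 150 kb monomer scale the model makes no predictions (loop
  lengths g < 2 monomers do not exist by construction).
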