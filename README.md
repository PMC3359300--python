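# dynloop

Expression-dependent dynamic-loop chromatin simulator.

`dynloop` generates ensembles of interphase chromosome conformations with a
coarse-grained lattice polymer model in which spatially proximal monomers
form *transient loops*. Each monomer represents 150 kb of chromatin and
carries an interaction affinity derived from a gene-expression profile:
highly transcribed regions get low affinity (transcription machinery blocks
direct chromatin–chromatin contacts), silent regions high affinity. Loop
bonds form probabilistically when diffusion brings two monomers within the
bond cutoff — with pair probability `p_ij = sqrt(a_i a_j)` — and dissociate
after a Poisson-distributed lifetime. This single mechanism reproduces the
hallmarks of chromosome-territory organization: the leveling-off of the
mean square spatial distance (MSD) at large genomic separation, compaction
of lowly expressed chromatin, power-law loop-size distributions
P(g) ∝ g^α (N−g), peripheral positioning of active loci within the
territory, and higher mobility of transcribed regions.

The package is aimed at polymer-physics and genome-organization researchers
who want to relate transcriptional activity to 3-D chromatin structure in
silico, at scales from desk experiments (N ≈ 10²–10³ monomers, minutes on
one core) to whole human chromosomes (N = 899 for chr11, 1634 for chr1).

## What it computes

Given an expression profile (tab-delimited chromosome/start/end/value), the
model

1. bins expression to the 150 kb monomer grid and maps it linearly onto
   affinities `a_i ∈ [a_min, a_max]` (most-expressed → a_min);
2. runs single-site Monte-Carlo dynamics on a periodic cubic lattice with
   excluded volume, bond vectors of length ≤ √3, event-driven loop
   formation and Poisson bond expiry; one Monte-Carlo step (MCS) = N trial
   moves;
3. equilibrates in two phases (loop-free, then looped) and samples
   conformations every 2τ MCS, τ being the autocorrelation time of R_g²;
4. computes the observable suite: MSD curves (total and locus-specific),
   loop-size distribution and exponent α, 3-D Gaussian-KDE local density,
   high/low volume ratio, gyration-tensor asphericity, distance to
   territory center/surface, mean square monomer displacement (MSMD), the
   correlations of each per-monomer metric with expression, and the
   µm-per-lattice-unit scaling factor against an experimental MSD table.

See `docs/methods.md` for the model and every numerical choice.

## Worked example

```python
from dynloop import DynamicLoopModel, synth_expression_profile

# synthetic chromosome: an active half (mean level 8) and a silent half
profile, regions = synth_expression_profile(
    120, [(0, 60, 8.0), (60, 120, 1.0)], noise_sd=0.5, seed=7)

model = DynamicLoopModel(profile, a_min=0.01, a_max=0.07,
                         mean_lifetime=2000.0, lattice_size=64)
result = model.simulate(n_conformations=100, equilibration_mcs=100_000,
                        sample_interval=1000, seed=1)
print(result.summary(regions).round(3))
```

which prints (about a minute on one core):

```
n_conformations           100.000
loops_per_length_pct       43.058
asphericity_total           0.139
loop_exponent_total        -0.841
asphericity_high            0.185
loop_exponent_high         -0.683
asphericity_low             0.174
loop_exponent_low          -0.784
volume_ratio_high_low       1.080
pearson_density            -0.507
spearman_density           -0.457
pearson_dist2_center        0.258
spearman_dist2_center       0.213
pearson_dist2_surface      -0.328
spearman_dist2_surface     -0.275
```

Reading the numbers: on average 43 loops are active per 100 monomers; the
chain is mildly aspherical (0.14) with the active half less spherical than
the silent one; the active half occupies 8% more volume per monomer
(volume ratio > 1); local density anticorrelates with expression
(r = −0.51), active loci sit farther from the territory center (+0.26) and
closer to its surface (−0.33) — the qualitative structure seen in imaging
and contact-mapping experiments. At this reduced scale the magnitudes are
smaller than for full chromosomes; pooling replicate simulations
(`dynloop.engine.merge_ensembles`) sharpens them.

## Command line

```
dynloop synth-profile --n-monomers 300 --block 0:150:10 --block 150:300:1 \
        --noise-sd 0.5 --seed 42 --out-expression expr.tsv --out-regions regions.bed
dynloop simulate --config run.yaml --out ensemble.h5 --trajectory traj.h5
dynloop analyze --ensemble ensemble.h5 --expression expr.tsv \
        --regions regions.bed --trajectory traj.h5 --out report/
```

`run.yaml` holds the schema-validated simulation parameters (unknown keys
rejected); `analyze` writes tab-delimited tables (msd.tsv, loops.tsv,
density.tsv, shape.tsv, radial.tsv, msmd.tsv, correlations.tsv) plus the
resolved provenance.

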