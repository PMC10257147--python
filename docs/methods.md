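# Methods

This note documents the simulation model, its parameters, the numerical
choices behind the implementation, and what the synthetic benchmarks do and
do not demonstrate.

## Model

### Geometry and diffusion

Oligomer entities ("molecules") are point-like random walkers on a periodic
square cell of side `L` (default 21 µm) at a surface density of 100
entities/µm² (44 100 molecules). Starting positions are uniform on the
cell. Per time step `Δt`, each coordinate receives an independent Gaussian
increment with mean 0 and variance `2·D·Δt`; molecules leaving the cell
re-enter on the opposite side. Results are insensitive to the cell size
once `L` comfortably exceeds the illuminated footprint plus the diffusion
length of a run (the default leaves a ≥ 6 µm margin); molecule number,
species identity and oligomeric state are conserved exactly.

Each molecule carries a fixed oligomeric state `m` (number of subunits) and
a fluorescent state `n` (subunits with an active fluorophore); labeling
efficiency is 1, so initially `n = m`. Association/dissociation dynamics,
anomalous diffusion and molecular interactions are out of scope.

### Photobleaching

Measured bleach curves of membrane-anchored monomeric GFP are biexponential,

    b(t_ill) = A·e^(−α·t_ill) + B·e^(−β·t_ill),

with defaults α = 235 s⁻¹, β = 30 s⁻¹, A = 0.782, B = 0.218 (normalized
weights). The simulator reproduces this by assigning each subunit to the
fast component with probability A (else slow), fixed for the whole run.
During the bleach pulse, at each step every active subunit of a molecule at
relative intensity `I` is cleared with probability `1 − e^(−rate·I·Δt)`
(comparison `p ≥ u` against a uniform draw, ties bleaching). Per-subunit
survival is thus monoexponential in the accumulated illumination dose while
the subunit population averages to the measured biexponential.

Laser profiles (aperture side `d_ap = 7 µm`, centered on the cell):

- **ideal** — bleach probability 1 per step inside the aperture, 0 outside;
- **uniform** — `I = 1` inside, 0 outside (sharp edge);
- **diffraction_affected** — plateau `I = 1` inside; along each axis the
  intensity decays as `exp(−(|x| − d_ap/2)² / σ²)` with σ = 0.5 µm for up
  to `d_edge = 1 µm` beyond the edge and is 0 farther out; the 2D profile
  is the separable product `X(x)·Y(y)`.

The typography of the edge-decay formula admits a second reading with
`2σ²` in the denominator. We ship both (`LaserProfile.edge_exponent`), with
`/σ²` as the default: it decays essentially to zero within the stated edge
width (1.8% residual at truncation, versus 13.5% for the `2σ²` reading,
which would introduce a visible discontinuity), and it reproduces the
reference apparent-fraction benchmarks, which the `2σ²` reading misses by
producing too narrow a partial-bleach zone.

Bleach time steps: 0.002 s for the uniform profile (the sharp edge needs a
fine illumination-time resolution), 0.01 s for the diffraction-affected and
ideal profiles. Halving these leaves the pooled fractions unchanged within
the bootstrap confidence intervals (tested). Within one step the bleach
probability is evaluated at the molecule's position after that step's
diffusion update; the alternative (position before the update) is a
sub-step-level detail without measurable effect at these step sizes.

### Recovery

No bleaching occurs during recovery, so the sum of per-step Gaussian
increments is itself Gaussian with per-axis variance `2·D·t_rec`, and
wrapping commutes with summation on the torus. Recovery is therefore
advanced in a single composite step — an exact shortcut, not an
approximation. (The step-by-step equivalent is available through
`diffuse`.)

### Detection and the analysis region

Diffraction-limited imaging cannot separate molecules closer than the
resolution limit. Visible molecules (`n ≥ 1`) with pairwise distance
≤ R = 300 nm are grouped by single-linkage connected components; each
component is one **apparent n-mer** with `n = Σ nᵢ`. A component is counted
if at least one member lies inside the analysis region (members may chain
beyond its boundary), and discarded if `n > 5·m_max` (m_max = largest
oligomeric state present). Dark molecules never participate. Boundary ties
(distance exactly R, radius exactly r_analysis) are inclusive.

The random-colocalization probability at local density ρ is
`p_coloc = 1 − e^(−πR²ρ)`; bounding it by 20% gives the cutoff density
`ρ_crit ≈ 0.79 µm⁻²`. The analysis region is a central disk: radial
densities of visible molecules are accumulated in 10 nm concentric rings
(up to 1.5·d_ap; half-open intervals, innermost ring the full 10 nm disk),
averaged over runs, and fitted for r ≤ (d_ap + d_edge)/2 with the
erf-shaped recovery profile

    ρ(r) = ρ0·[1 − ½·erf((r + d′/2)/τ) + ½·erf((r − d′/2)/τ)],

which is monotone in r, so the cutoff crossing `ρ(r_analysis) = ρ_crit` is
unique (bracketed root search). Initial guesses: ρ0 from the outer end of
the fit range, d′ = d_ap, τ from the 16–84% rise width; all parameters
bounded positive; the fit is unweighted, by design.
If the fitted curve never reaches ρ_crit the region is capped at the
fit-range boundary (warning); if even the center exceeds ρ_crit the region
degenerates to radius 0 (warning).

### Recovery-time optimization

For each recovery time on a grid, the analysis region is determined as
above (from `runs_per_point` simulations, default 100) and the mean number
of visible molecules inside it recorded; a cubic polynomial fit over the
grid locates the count maximum, restricted to the sampled interval
(boundary maxima raise a warning). Grid points whose region degenerated to
radius 0 carry no count information and are excluded from the cubic fit
when at least four informative points remain. The default grid spans
0.1–2.8 s for D = 0.5 µm²/s and is scaled by `0.5/D_max` for other
mobilities (diffusion lengths go as √(D·t), so this probes a comparable
range of recovery patterns). Optionally the optimization metric can be
detection events instead of molecules (`opt_metric`); molecule counts are
the default.

Because the bleach phase is independent of `t_rec`, the same post-bleach
states feed every grid point (`share_bleach=True`); each point's estimate
is unchanged and the expensive pulse is simulated once per run. At the
optimum, the region is either re-determined from dedicated confirmation
runs (default 300, `region_source="confirm"`) or taken from the pooled
density profile of the analysis runs themselves
(`region_source="pooled"`) — the latter is preferable at reduced replicate
counts, where the analysis runs are the largest available sample.

### Fractions and uncertainty

Pooling events over runs, `f_n = 100·ν_n / Σ_n ν_n` for n = 1…5·m_max,
random colocalizations included. The **true-detection** fraction for m
counts only events that are a single, nonphotobleached molecule
(one member, `n = m`): partially bleached higher-order oligomers and
colocalization events are excluded, so `f_m(true) ≤ f_{n=m}` always.
Confidence intervals are percentile bootstrap (default 10 000 samples,
95%), resampling whole runs with replacement — the run, not the event, is
the independent unit.

## Numerical and performance choices

- The bleach stepper works in single precision (position resolution ~1 µm
  × 2⁻²⁰; irrelevant against the 10 nm ring binning) with a (2, N) memory
  layout, and replaces modulo wrapping by conditional shifts.
- Molecules whose probability of reaching the illuminated footprint within
  the remaining pulse is below ~10⁻⁸ (6σ reflection-principle bound on the
  maximal excursion) are advanced by one composite Gaussian step instead of
  stepwise; exact for their final position.
- Molecules that lose their last fluorophore leave the hot loop; dark
  molecules are invisible to every downstream analysis, so their positions
  are not advanced further.
- Component search for detection is a KD-tree pair query plus sparse
  connected components, restricted to a disk of radius
  `r_analysis + (5·m_max + 1)·R`: any chain reaching farther necessarily
  exceeds the n-cap and would be discarded anyway (the truncation is
  exact, verified against an O(N²) oracle).
- Seeding: every random stage of a scenario draws from
  `SeedSequence(master_seed, spawn_key=(stage_tag, run_index))`; runs are
  independent, replayable and stable under refactoring. One master seed
  determines the entire experiment byte-for-byte.
- Bleach-curve fitting is nonlinear least squares (a biexponential cannot
  be fitted linearly without transformation), components ordered so α > β,
  initial rates from the head/tail slopes of log b.

## Benchmark protocol and replicate counts

The test suite and the acceptance script re-run the benchmark scenarios at
reduced replicate counts: 200 pooled analysis runs for dimer benchmarks
(120 for the slower mobility/tetramer sweeps), 25 runs per recovery-time
grid point for scenarios with a 4 s bleach pulse and 100 (the reference
count) where the pulse is short, with the analysis region taken from the
pooled analysis runs. Event totals that the reference protocol reports as
sums over 1000 runs are scaled proportionally. At these counts the
bootstrap 95% CI of a mid-range fraction is about ±3–4 percentage points.

## What the synthetic benchmarks do not show

The simulator treats molecules as ideal point emitters: camera noise,
point-spread-function overlap in brightness space, localization error, and
imperfect labeling are all absent, as are oligomer association/dissociation
dynamics and two-color variants. Passing benchmarks therefore validates
the geometry, kinetics and statistics of the method — not the additional
detection-noise terms a real microscopy experiment adds. The
recovery-time optimum rides on a broad plateau of the count-versus-t_rec
curve; because the apparent fractions vary along that plateau, the pooled
fractions for short bleach pulses carry a procedure-level uncertainty of a
few percentage points beyond the bootstrap CI.
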