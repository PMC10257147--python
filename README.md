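# toccsl-sim

Monte Carlo simulation of **TOCCSL** experiments — *thinning out clusters
while conserving stoichiometry of labeling* — a single-molecule fluorescence
microscopy modality for measuring the oligomeric state of membrane proteins
and lipids at physiologically high surface densities.

In a TOCCSL experiment an aperture-restricted region of the plasma membrane
is irreversibly photobleached by a high-intensity laser pulse; during a dark
recovery time, unbleached molecules diffuse back into the bleached region,
where they can be imaged as well-separated diffraction-limited spots and
their stoichiometry read out. Two systematic error sources distort the
result: **partial photobleaching** of oligomers at the aperture edges (an
*m*-mer losing some fluorophores is detected as a lower-order species) and
**random colocalization** of independent molecules within the optical
resolution limit (detected as a higher-order species). This package
quantifies both by simulating the full experiment *in silico*, for
researchers designing or correcting TOCCSL measurements.

## Model

- **Diffusion.** Point-like oligomer entities on a periodic square cell
  (default 21 × 21 µm² at 100 entities/µm²) perform 2D Brownian motion:
  per time step Δt each coordinate takes an independent Gaussian step with
  variance σ² = 2 D Δt.
- **States.** Each molecule has a fixed oligomeric state *m* (subunits) and
  a fluorescent state *n* ≤ *m* (active fluorophores), initially *n* = *m*.
- **Photobleaching.** Each subunit belongs to the fast or slow component of
  the biexponential bleach law b(t) = A e^(−αt) + B e^(−βt) (defaults
  α = 235 s⁻¹, β = 30 s⁻¹, A = 0.782, fitted to mGFP-GPI in CHO cells).
  During the bleach pulse a subunit at relative laser intensity I bleaches
  per step with probability 1 − e^(−rate·I·Δt). Three laser profiles:
  *ideal* (p = 1 inside the 7 µm aperture), *uniform* (stochastic, sharp
  edge), *diffraction-affected* (plateau with a Gaussian-shaped decay over
  1 µm beyond each edge).
- **Detection.** After recovery, visible molecules within R = 300 nm of
  each other merge into one "apparent *n*-mer" (single-linkage), *n* being
  the summed fluorescent state. Analysis is restricted to a central disk
  whose radius is fitted so that the recovered density stays below
  ρ_crit = −ln(1 − p_coloc)/(πR²) ≈ 0.79 µm⁻² (for an accepted
  colocalization probability of 20%).
- **Read-out.** Apparent n-mer fractions f_n = 100·ν_n/Σν_n pooled over
  independent runs, with 95% bootstrap confidence intervals (resampling
  whole runs). The recovery time can be auto-optimized to maximize the
  number of analyzable molecules (cubic fit of count vs. t_rec).

## Worked example

```python
from toccsl_sim import standard_scenario, run_scenario
from dataclasses import replace

# Pure dimers (D = 0.5 um^2/s), diffraction-affected profile, 4 s bleach,
# auto-optimized recovery time; 100 runs for a quick look.
cfg = replace(standard_scenario("diffraction_affected"),
              n_runs=100, runs_per_point=16, region_source="pooled", seed=11)
res = run_scenario(cfg, verbose=True)
print(f"t_rec = {res.t_rec_used:.2f} s, r_analysis = {res.region.r_analysis:.2f} um")
for n in (1, 2, 3, 4):
    lo, hi = res.fractions.ci_n[:, n - 1]
    print(f"f_{n} = {res.fractions.fraction(n):5.1f}%  [{lo:.1f}, {hi:.1f}]")
```

Output (seed 11):

```
t_rec = 0.89 s, r_analysis = 2.76 um
f_1 =  37.9%  [33.0, 42.6]
f_2 =  54.3%  [49.6, 59.3]
f_3 =   4.3%  [2.4, 6.3]
f_4 =   1.8%  [0.7, 3.0]
```

Although every simulated molecule is a dimer, only ~54% of detections are
apparent dimers: ~37% are apparent monomers (dimers that lost one
fluorophore at the aperture edge during bleaching) and a few percent are
apparent trimers/tetramers (random colocalizations). The confidence
intervals are 95% bootstrap intervals over the 100 runs.

The same pipeline is scriptable from the shell:

```bash
toccsl-sim simulate --profile diffraction_affected --t-bleach 4 --t-rec auto \
    --runs 200 --seed 1 --out results/dimer_run
toccsl-sim sweep --preset mobility_sweep_dimer --runs 200 --out results/mobility
toccsl-sim fixtures --noise-sd 0.005 --seed 7 --out curve.tsv
toccsl-sim fit-bleach curve.tsv
```

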