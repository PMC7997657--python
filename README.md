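# switchquant

Quantification pipeline for light-inducible site-specific recombination
(Cre/LoxP) experiments: a reusable, tested implementation of the four
measurement computations such studies rely on, with seeded synthetic
data generators so every stage can be exercised and verified on a
desktop, without simulation clusters or wet-lab data.

**Who it is for.**  Groups characterizing engineered recombinases (or
any switch-like reporter) who need the analysis side of the experiment
— free-energy profiles from biased simulations, cytometry switch
fractions, qPCR excision fractions, microscopy intensities — as
auditable, deterministic code rather than one-off scripts.

## What it computes

**1. Potential of mean force (PMF), `switchquant.pmf`.**
From umbrella-sampling windows (harmonic bias ½k(x−c)², k = 20
kcal mol⁻¹ Å⁻², 13 centers on 4–10 Å), each 30 ns series is stripped
of a 5 ns equilibration and cut into 5 ns blocks; the weighted
histogram analysis method (WHAM)

&nbsp;&nbsp;&nbsp;&nbsp;p̄ᵢ = ⟨pᵢ⟩_blocks,&nbsp;&nbsp;
Fᵢ = −kT ln p̄ᵢ,&nbsp;&nbsp;
σ_Fᵢ = kT σ_p̄ᵢ / p̄ᵢ,&nbsp;&nbsp;
σ_p̄ᵢ = 2·SEM over blocks

is solved per block on 13 bins (3.75–10.25 Å) at 310 K to a tolerance
of 0.01 kcal mol⁻¹, and the profile is offset so its minimum is zero.

**2. Flow cytometry, `switchquant.cyto`.**
A 2-D kernel-density gate over (FSC-H, SSC-H) enclosing exactly 40% of
the 10,000 events per sample; median/MAD screening of gate positions
across an experiment; an ON/OFF threshold at the 99.9th percentile of
a gated negative control; fraction-ON per sample; mean ± s.e.m.
summaries, Welch t-tests and exact rank-sum tests.

**3. qPCR excision fraction, `switchquant.qpcr`.**
Log-linear standard curves Ct = a + b·log₁₀(q) from calibration
mixtures (0–100% edited), amplification efficiency 10^(−1/b) − 1, and
the excision fraction N_Lox/N_Total with each quantity inverted
through its own assay's curve.

**4. Microscopy, `switchquant.imaging`.**
Per-cell mean gray values from an image plus label mask, corrected by
a shared background estimated from eight random cell-sized regions
outside all cells.  For integer images the subtraction is exact
integer arithmetic, so a constant offset leaves results bit-identical.

**Synthetic data, `switchquant.synth`.**
Overdamped Langevin dynamics on a known 1-D potential (ground truth
available in closed form), log-normal cytometry mixtures with debris,
a noisy log-linear Ct model, and disk-on-background images — all pure
functions of their spec including the seed.

## Worked example

Recover the double-well free-energy landscape from simulated umbrella
windows and compare with the analytic profile:

```python
import numpy as np
from switchquant import synth, pmf

thermo = pmf.Thermo()                      # 310 K
well = synth.double_well()                 # 3 kcal/mol barrier, minima at 5 and 9 A
grid = pmf.make_grid(3.75, 10.25, 13)
ladder = [(c, 20.0) for c in np.linspace(4.0, 10.0, 13)]

windows = synth.simulate_umbrella(well, ladder, synth.LangevinSpec(seed=1), thermo)
profile = pmf.estimate_pmf(windows, grid, thermo)   # 5 ns equil, 5 ns blocks, tol 0.01

truth = synth.analytic_pmf(well, grid, thermo)
for x, F, s, Ft in zip(profile.bin_centers, profile.F, profile.sigma_F, truth.F):
    print(f"{x:5.1f}  {F:6.3f} +/- {s:5.3f}   (analytic {Ft:6.3f})")
```

```
  4.0   3.513 +/- 0.270   (analytic  3.497)
  4.5   0.743 +/- 0.228   (analytic  0.747)
  5.0   0.026 +/- 0.179   (analytic  0.000)
  5.5   0.558 +/- 0.159   (analytic  0.476)
  6.0   1.648 +/- 0.115   (analytic  1.538)
  6.5   2.582 +/- 0.189   (analytic  2.518)
  7.0   3.079 +/- 0.138   (analytic  2.908)
  7.5   2.711 +/- 0.112   (analytic  2.518)
  8.0   1.656 +/- 0.162   (analytic  1.538)
  8.5   0.554 +/- 0.132   (analytic  0.476)
  9.0   0.000 +/- 0.180   (analytic  0.000)
  9.5   0.783 +/- 0.215   (analytic  0.747)
 10.0   3.558 +/- 0.309   (analytic  3.497)
```

Each line is a reaction-coordinate bin: the estimated free energy with
its block-averaged error bar, against the exact Boltzmann value.  The
3 kcal/mol barrier at 7 Å is recovered as 3.08 ± 0.14, and the whole
profile agrees with the analytic one to 0.095 kcal/mol RMSE.

The same pipeline runs from the shell over CSV files:

```bash
switchquant all --outdir out --seed 1       # every stage, synthetic inputs
switchquant pmf --windows-manifest out/umbrella/windows_manifest.csv --outdir out
switchquant gate --events my_events.csv --negative my_negative.csv --outdir out
```

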