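# fretsort

Quantitative analysis tools for genetically encoded FRET biosensors of the
bacterial second messenger c-di-GMP, and for FRET-based FACS enrichment
screens ("sort-seq") of barcoded transposon mutant libraries.

The package covers three connected problems:

1. **Calibrated FRET efficiency from flow cytometry.** A 1:1 donor–acceptor
   fusion (mTurquoise2–mNeonGreen around a c-di-GMP-binding PilZ domain) is
   measured in three channels: donor (*I₁*, 445 ex / 470 em), FRET
   (*I₂*, 445 ex / 520 em) and acceptor (*I₃*, 488 ex / 520 em). After
   subtracting autofluorescence background, the transfer efficiency is

   ```
   E = (I₂ − S₂·I₃ − S₁·I₁) / (I₂ − S₂·I₃ + (α − S₁)·I₁) × 100 %
   ```

   with bleed-through corrections *S₁* = *I₂*/*I₁* (donor-only cells) and
   *S₂* = *I₂*/*I₃* (acceptor-only cells), and the calibration factor *α*
   obtained as the slope-to-intercept ratio of the line
   *y* = 1/(R_F − 1) vs *x* = 1/R₁ fitted over one-to-one samples spanning
   different efficiencies (fallback constant: α = 0.739). An independent
   estimate comes from acceptor photobleaching:
   *E* = (F_AB − F_BB)/F_AB × 100 %, with the donor levels before (F_BB) and
   after (F_AB) the bleach read off linear fits extrapolated to the bleach
   instant.

2. **Biosensor characterization.** Dose responses of permeabilized cells are
   fit with the allosteric sigmoidal (Hill) model
   *E(c) = E₀ + (E∞ − E₀)·cʰ/(K_Dʰ + cʰ)* — both FRET-increasing and
   -decreasing sensors are supported — plus linear occupancy interpolation
   between apo and saturated reference strains, and single-exponential
   dissociation kinetics (k_off) after ligand washout.

3. **Sort-seq screen analysis.** Barcodes flanked by the adapters
   U1 = `GTCGACCTGCAGCGTACG` and U2 = `AGAGACCTCGTGGACATC` are extracted from
   (gzip) FASTQ after 3′ quality trimming (Q20), reverse-complemented,
   counted, and summed per gene via a transposon library map. Per-gene
   enrichment is the depth-normalized read fraction of a sorted pool over its
   unsorted reference; genes below 200 reads in every sample are excluded;
   the statistic is log₂(e_high/e_low) tested across replicates with a
   Bayesian-regularized unpaired t-test (Cyber-T, prior 6) so that two
   biological replicates suffice.

A synthetic-data module generates all inputs from explicit generative models
with known ground truth — cytometry events from a photophysical model in
which the efficiency formula is exact by construction, Hill titrations,
washout traces, and complete FACS screens written as FASTQ + library map +
sample sheet + truth table — so every estimator in the package can be tested
for parameter recovery.

## Worked example

```python
import numpy as np
from fretsort import simulate, cytofret, binding

# calibrate S1, S2 and alpha from simulated control samples (30,000 events each)
cfg = simulate.PhotophysicsConfig()
cs = simulate.simulate_calibration_set(cfg, np.linspace(0.05, 0.6, 10), 30000, seed=42)
cal = cytofret.calibrate_from_event_tables(
    list(cs.fusion_samples), cs.donor_only, cs.acceptor_only, cs.background)
print(cal.factors.S1, cal.factors.S2, cal.alpha)   # 0.5496  0.2999  0.7319

# efficiency of one noisy sample with true E = 25 %
rng = np.random.default_rng(42)
fus = simulate.simulate_cytometry(cfg, 0.25, 30000, "fusion", rng=rng, sample_id="wt")
bg = simulate.simulate_cytometry(cfg, 0.0, 30000, "background", rng=rng)
summary, ratio, eff = cytofret.efficiency_from_events(fus, bg, cal)
print(ratio, eff.E)                                # 1.396  25.28

# K_D of a high-affinity sensor from a noisy titration (sigma = 0.5 pp)
t = simulate.simulate_titration(8.9, 1.0, 19.0, 38.0,
                                np.logspace(0, 4, 12), noise_sd=0.5, seed=42)
fit = binding.fit_dose_response(t)
print(fit.K_D, fit.h, fit.direction)               # 7.71  0.84  increasing
```

The calibration recovers the generator's bleed-through factors
(S₁ = 0.55, S₂ = 0.30) and calibration factor (α = 0.739) from noisy data to
within ~1 %; the sample's efficiency estimate (25.28 %) sits within 0.3
percentage points of the 25 % ground truth; the fitted K_D (7.71 nM, true
8.9 nM) is within the uncertainty expected at this noise level.

The same steps are available from the shell via the `fretsort` console
script (`calibrate`, `fret`, `titrate`, `kinetics`, `sortseq-count`,
`sortseq-enrich`, `simulate`); every command writes a `.meta.json` sidecar
recording version, parameters and seed.

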