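# digichamber

Image analysis for **digital nucleic-acid amplification assays in
femtoliter microchamber arrays**, with a synthetic chip-image generator
for validation.

In a digital assay the sample is partitioned over thousands of
micrometer-scale chambers (here: cylinders of diameter ~4.2 µm, depth
~3.15 µm, volume ~43.6 fL, on a 9 µm pitch) so that each chamber traps 0
or a few template molecules. After isothermal amplification, chambers
that held a template fluoresce; counting them gives the absolute template
concentration with no calibration curve. `digichamber` turns two-channel
fluorescence images of such a chip into that number, for assay developers
and analysts who need a reproducible, scriptable replacement for
by-hand/ImageJ workflows.

## What it computes

1. **Chamber detection** in the reference channel (all chambers stained):
   difference-of-Gaussians band-pass at the ~10 px chamber scale +
   local-maximum picking.
2. **Per-chamber features** from the signal channel: mean intensity over
   a 10-px circular ROI, and the **radius of gyration (ROG)** of a
   16×16 px crop,

   ```
   ROG = sqrt((m20 + m02) / m00),
   m20 = Σ (x − (N−1)/2)² g(x,y),  m02 = Σ (y − (M−1)/2)² g(x,y),  m00 = Σ g(x,y)
   ```

   A chamber-sized bright spot has ROG ≈ 3.5–4.2 px; a blank or
   artifact-filled crop sits near the uniform-crop value √42.5 ≈ 6.52 px.
3. **Two-gate classification**: ROG > threshold (default 5.5 px) →
   negative (rejects diffuse autofluorescent bubbles/aggregates);
   otherwise positive iff mean intensity > mean + 15·SD of a negative
   control (SD from a Gaussian fit to the intensity histogram).
4. **Concentration**: with positive fraction λ_exp and chamber volume
   V = π(d/2)²h,

   ```
   cE = λ_exp / (V · N_A)                 (default, linear)
   c  = −ln(1 − λ_exp) / (V · N_A)        (Poisson-corrected, flagged)
   ```

5. **Time-lapse metrics**: detection time (positive count per image,
   initially ≤ 2, first exceeds 10) and quantification time (first time
   after detection that the count change between consecutive 2-min frames
   drops below 20%).

The synthetic module simulates the whole forward process — Poisson
loading at mean occupancy λ = c·V·N_A, sigmoidal fluorescence onset,
soft-edged disks, shot/read noise, and large diffuse artifacts — with a
per-chamber ground-truth table, so every analysis stage can be scored
against truth.

## Worked example

```python
import digichamber as dc

# simulate a default 100x100-chamber chip loaded at 3.6 pM,
# plus a matched zero-concentration chip as the negative control
cfg = dc.RunConfig(simulation=dc.SimulationConfig(concentration_M=3.6e-12), seed=42)
truth, frames, times = dc.run_simulation(cfg)
neg_cfg = dc.RunConfig(simulation=dc.SimulationConfig(concentration_M=0.0), seed=43)
_, neg_frames, _ = dc.run_simulation(neg_cfg)

res = dc.analyze_image(frames, cfg, negative_control_image=neg_frames)
q = res.quant
print(f"chambers detected : {q.n_total}")
print(f"true positives    : {truth.n_positive}")
print(f"called positive   : {q.n_positive}")
print(f"positive fraction : {q.positive_fraction:.4f}")
print(f"chamber volume    : {q.chamber_volume_L:.3e} L")
print(f"linear estimate   : {q.concentration_estimate_M*1e12:.2f} pM")
print(f"Poisson-corrected : {q.concentration_poisson_M*1e12:.2f} pM")
```

prints

```
chambers detected : 10000
true positives    : 898
called positive   : 898
positive fraction : 0.0898
chamber volume    : 4.364e-14 L
linear estimate   : 3.42 pM
Poisson-corrected : 3.58 pM
```

All 10,000 chambers are found and every genuinely amplified chamber —
and nothing else — is called positive. The Poisson-corrected estimate
(3.58 pM) recovers the simulated 3.6 pM input within sampling error; the
linear estimator reads ~5% lower because it ignores chambers that
received more than one template. At this geometry one positive chamber in
10,000 corresponds to ≈ 4 fM and full occupancy to ≈ 40 pM — the
measurable range of the chip.

## Command line

```
digichamber simulate  --config config.yaml --out sim/
digichamber analyze   --image chip.tif --config config.yaml \
                      --negative-control neg.tif --out results/ [--exclude ids.txt]
digichamber timelapse --series chip_t.tif --config config.yaml --out results/
```

TIFF stacks are 16-bit multi-page, interleaved (reference, signal) per
time point. Outputs are per-chamber CSV, time-course CSV, and a summary
JSON carrying counts, thresholds, both concentration estimates, the time
metrics, and a provenance block (config hash, seed, versions).

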