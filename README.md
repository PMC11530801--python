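# ldflim

Fluorescence-lifetime filtering for accurate lipid-droplet quantification in
BODIPY vital-stained *C. elegans*.

## The problem

BODIPY 493/503 is the workhorse vital dye for lipid droplets (LDs), but in
the worm intestine it also stains lysosome-related organelles (LROs) —
acidic gut granules that are not fat stores and that additionally
autofluoresce with age. Raw fluorescence intensity therefore overestimates
fat storage, and the bias differs between genotypes (a worm without LROs
looks "leaner" than an equally fat wild-type). The two compartments differ
in fluorescence *lifetime*: BODIPY photons from LROs decay fast (a narrow
arrival-time structure, lifetime ≈ 1.5 ns), while LD photons arrive late and
broadly. Lifetime is set by the local chemical environment, not by dye
concentration, which makes it a robust discriminator.

The **fluorescence lifetime filter (FLF)** exploits this: form the intensity
image only from photons arriving in the long-pass gate **4–11.5 ns** (the
unfiltered image uses the instrument's full −1–11.5 ns window). For an ideal
monoexponential emitter with lifetime τ and a delta instrument response, the
fraction of in-window signal surviving a gate [a, b] is

    S(τ; a, b) = (e^(−a/τ) − e^(−b/τ)) / (e^(−t₀/τ) − e^(−t₁/τ)),

with [t₀, t₁] the recording window, and the *fluorescence loss rate* is
(1 − ⟨I_f⟩/⟨I_uf⟩) × 100 %. At τ = 1.5 ns the FLF gate removes 93.1 % of LRO
signal while a calibrated LD-class decay loses only 58.3 % — the filter
trades some LD brightness for the near-removal of LRO interference. The
package quantifies that trade-off with the **RLL** (ratio of mean LD to mean
LRO intensity, ⟨I_LDs⟩/⟨I_LROs⟩) and control-group normalization
(I_normalized = I_unnormalized / I_control,average).

No public FLIM images of stained worms exist, so the package includes a
seeded synthetic-worm generator: TCSPC photon-count stacks (time-bin × y × x)
with ground-truth organelle labels, genotype presets (wild-type; *glo-1*
without LROs; *daf-22* with enlarged LDs; high/low-fat; aged unstained),
dye-concentration-dependent brightness, and short-lifetime autofluorescence.
Everything downstream — fast per-pixel lifetime images, n-exponential
reconvolution fitting, gating, gate-threshold scans, ROI quantification,
group comparisons, and a simulated nine-plus-one forward-genetic screen —
runs on these stacks and is scored against the generator's ground truth.

## Worked example

```python
import numpy as np
import ldflim as L

# a wild-type worm stained at 8 uM, ~4e5 photons
stack, labels = L.generate_worm(L.preset_config("WT", seed=11, concentration=8))

print(L.gate_scan(stack, labels).records.round(3))
```

```
 t_min_ns   rll  ld_loss_pct  lro_loss_pct
     -1.0 0.672        0.000         0.000
      0.0 0.689        1.363         3.771
      1.0 1.041       20.184        48.478
      2.0 1.635       35.798        73.616
      3.0 2.570       48.274        86.476
      4.0 4.047       58.453        93.102
      5.0 6.409       66.924        96.532
      6.0 9.708       74.105        98.208
```

Each row applies the long-pass gate [t_min, 11.5 ns]: raising the threshold
monotonically raises the RLL (less LRO interference) at the cost of LD
brightness. At the chosen 4 ns threshold this worm loses 58.5 % of LD and
93.1 % of LRO signal, matching the closed-form class predictions, and the
RLL improves from 0.67 (LROs outshine LDs) to 4.05:

```python
uf = L.apply_gate(stack, L.UNFILTERED_GATE).values
ff = L.apply_gate(stack, L.FLF_GATE).values
ld  = np.isin(labels.labels, labels.labels_of_class("LD"))
lro = np.isin(labels.labels, labels.labels_of_class("LRO"))
print(L.rll(uf[ld].mean(), uf[lro].mean()))   # 0.67  unfiltered
print(L.rll(ff[ld].mean(), ff[lro].mean()))   # 4.05  under FLF

report = L.screen("screen_daf22", base_seed=3)
print(report.identified_mutants)              # {'large_LD_mutant': [8]}
```

The screen generates nine wild-type worms plus one planted *daf-22* mutant
at 8 µM, classifies each at a 4×-downsampled "low magnification" scale, and
flags exactly the planted worm.

A command-line interface mirrors the library
(`ldflim simulate | tau | gate | scan | quantify | compare | screen`).

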