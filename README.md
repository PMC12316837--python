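# hotspotmon

Hotspot detection for microwave breast-hyperthermia monitoring.

During microwave hyperthermia the tumor is heated to 40–45 °C, and any
healthy tissue driven above 40 °C is at risk. Tissue dielectric properties
drift with temperature (relative permittivity ≈ −0.25 %/°C, effective
conductivity ≈ +1.25 %/°C, both relative to the cold reference), so the
differential microwave scattering between the heated and unheated breast
carries a temperature signature. `hotspotmon` implements, end to end, a
direct-learning approach to reading that signature:

* a 2-D breast phantom (skin / fat / fibroglandular / tumor) with
  per-class Debye dispersion in a lossy coupling medium (ε_r = 20,
  σ = 0.6 S/m);
* a seeded generator of random layered heating scenarios (rise bounded by
  24 °C over the 37 °C baseline);
* a TM method-of-moments forward solver (Richmond-style equivalent-circle
  cells, closed-form self terms) producing multi-static, multi-frequency
  scattered fields E_s(r_r, r_t, ω) = k_0² ∫_D G χ E dr, validated against
  the analytic cylinder series;
* independent AWGN on hot and cold measurements at a prescribed SNR;
* a convolutional encoder-decoder trained with BCE + SGD (momentum 0.8,
  η(t) = 0.01·0.1^{t/v}) that maps the differential tensor
  (n_ant × n_ant × 2·n_freq) directly to the hotspot image
  1[T > 40 °C] on the phantom grid;
* evaluation: pixel accuracy s_acc = (TP+TN)/total, overlap
  s_Dice = 2TP/(2TP+FP+FN), and scenario-level danger recall
  (a scenario is dangerous when a hotspot lies outside the tumor);
* a conventional comparator: distorted-Born iterative inversion of the
  same data for the temperature map, with Tikhonov, TSVD, CGLS and FISTA
  regularization.

The network and optimizer are self-contained NumPy implementations with
finite-difference-verified gradients; everything else builds on
numpy/scipy.

## Worked example

```bash
python examples/03_train_detector.py
```

builds a seconds-scale dataset (24×24 grid, 4 antennas, 2 frequencies, 50
scenarios at 40 dB SNR), trains the detector for 3 epochs and prints:

```
50 scenarios; hotspot prevalence 0.147
epoch 1: train BCE 0.7036, val BCE 0.6935
epoch 2: train BCE 0.7002, val BCE 0.6895
epoch 3: train BCE 0.6990, val BCE 0.6878
7 scenarios | pixel acc 0.817 | mean s_acc 0.817 | mean s_Dice 0.195 (7 defined) | danger acc 1.000 (7 positive)
```

`mean s_acc` is the average per-scenario pixel accuracy of the thresholded
(α_dec = 0.5) prediction, `mean s_Dice` the average hotspot overlap, and
`danger acc` the fraction of truly dangerous scenarios (hotspot outside
the tumor) that were flagged. Three epochs on 35 samples only begins to
learn; at the desk scale (2,000 scenarios, 15 epochs, ~4 min of training)
the same pipeline reaches mean accuracy ≈ 0.92 against an all-zeros
baseline of ≈ 0.88, with the Born-iterative regularizers trailing on Dice
— see `examples/04_sweeps.py` and `examples/05_bim_baseline.py` for the
SNR/threshold sweeps and the comparison.

A thin CLI wraps the same pipeline:

```bash
hotspotmon generate-data --preset desk --seed 1 --out runs/desk
hotspotmon train --preset desk --dataset runs/desk/dataset.npz --out runs/desk
hotspotmon evaluate --dataset runs/desk/dataset.npz --checkpoint runs/desk/checkpoint.npz --snr-test 30
hotspotmon baseline --preset desk --dataset runs/desk/dataset.npz
```

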