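"""Test-SNR, decision-threshold and model-mismatch sweeps of a detector.

The SNR sweep re-noises the stored clean fields of the test scenarios at
each level: accuracy should be flat for SNR above the training level and
degrade below it.  The threshold sweep shows the safety trade-off: lowering
alpha_dec raises danger recall at the cost of pixel accuracy.  The
nonlinearity sweep re-solves the physics with a quadratic thermo-dielectric
truth of increasing degree while the detector stays linear-trained.
"""

import numpy as np

from hotspotmon import make_preset, run_generate, run_train, sweep_nonlinearity
from hotspotmon.trainer import sweep_alpha, sweep_snr

cfg = make_preset("fixture", seed=0)
ds = run_generate(cfg)
model, _ = run_train(cfg, ds)

print("SNR_test (dB) -> mean accuracy")
table = sweep_snr(model, ds, [10, 20, 30, 40, 50], seed=1)
for snr, acc in zip(table["snr_db"], table["mean_accuracy"]):
    print(f"  {snr:4.0f}  {acc:.3f}")

print("alpha_dec -> mean accuracy, danger recall")
table = sweep_alpha(model, ds, np.linspace(0.1, 0.9, 5))
for a, acc, d in zip(table["alpha"], table["mean_accuracy"], table["danger_accuracy"]):
    print(f"  {a:.1f}  {acc:.3f}  {d:.3f}")

print("nonlinearity degree -> mean accuracy (linear-trained detector)")
table = sweep_nonlinearity(cfg, ds, model, [0.0, 0.5, 1.0], n_scenarios=4, seed=1)
for a, acc in zip(table["degree"], table["mean_accuracy"]):
    print(f"  {a:.2f}  {acc:.3f}")
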