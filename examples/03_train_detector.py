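"""Train the encoder-decoder hotspot detector on a tiny synthetic dataset.

Generates 50 scenarios at the fixture scale (24x24 grid, 4 antennas, 2
frequencies, 40 dB SNR), trains for 3 epochs and prints the loss curve and
the held-out scores.  The fixture scale is for demonstration; the desk
preset (2,000 scenarios, 15 epochs) reaches mean accuracy above 0.9.
"""

from hotspotmon import evaluate, make_preset, run_generate, run_train

cfg = make_preset("fixture", seed=0)
ds = run_generate(cfg)
print(f"{len(ds)} scenarios; hotspot prevalence {ds.labels.mean():.3f}")

model, history = run_train(cfg, ds)
for e, (tl, vl) in enumerate(zip(history.train_loss, history.val_loss)):
    print(f"epoch {e + 1}: train BCE {tl:.4f}, val BCE {vl:.4f}")

report = evaluate(model, ds, "test")
print(report.summary())
# mean s_acc is the per-scenario pixel accuracy; s_Dice measures hotspot
# overlap only, so it is the harder score; danger accuracy is the recall of
# "any hotspot outside the tumor" at scenario level
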