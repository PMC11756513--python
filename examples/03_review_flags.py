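"""Route uncertain calls to manual review with the flag interval.

Trains on noisy synthetic data so borderline curves occur, then shows that
flags (probability in [0.1, 0.9]) concentrate on the calls the model gets
wrong — the triage behaviour the flag was designed for.
"""

import tacall

cfg = tacall.SimConfig(n_reactions=6000, noise_sd=0.5, seed=101)
traces, labels = tacall.simulate_dataset(cfg)
dataset = tacall.assemble(tacall.normalize_batch(traces), labels)
train, test = tacall.split(dataset, 0.8, seed=101)
model = tacall.fit(train, seed=101)
calls = tacall.predict(model, test)
report = tacall.evaluate(calls, test.labels())

n_mis = report.n_misclassified
n_ok = report.confusion_matrix.total - n_mis
print(f"held-out accuracy {report.accuracy:.3f}; "
      f"{n_mis} misclassified of {test.n}")
print(f"flagged among misclassified: {report.n_flagged_misclassified}/{n_mis} "
      f"({100 * report.n_flagged_misclassified / n_mis:.0f}%)")
print(f"flagged among correct:       {report.n_flagged_correct}/{n_ok} "
      f"({100 * report.n_flagged_correct / n_ok:.1f}%)")

flagged = [c for c in calls if c.flagged]
print(f"\nfirst 10 of {len(flagged)} flagged calls to review:")
for c in flagged[:10]:
    ct = f"{c.ct:.1f}" if c.ct is not None else "-"
    print(f"  {c.reaction_id}: p={c.probability:.2f} "
          f"amplified={c.amplified} ct={ct}")
# A lab would re-inspect only the flagged curves instead of all of them.
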