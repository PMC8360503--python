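# cpdecode

Time-resolved neural decoding of a /ba/–/da/ speech continuum from
MEG-like sensor data.

## The problem

When listeners hear a 10-step acoustic continuum morphing /ba/ into /da/,
they perceive two discrete categories with a sharp boundary — categorical
perception. Multivariate pattern analysis of 306-channel MEG can track, at
millisecond resolution, how the brain's representation of such a continuum
evolves: when stimulus identity is decodable, when the subjective percept
is decodable, whether the representational geometry follows the *perceived
category structure* or the *ambiguity* of each token, and how an active
labeling task (vs. passive listening) changes how long that information is
maintained.

`cpdecode` is a tested, reusable implementation of that analysis for
researchers doing sensor-space MEG/EEG decoding:

* **Decoding** — pairwise linear-SVM classification of all 45 stimulus
  pairs per time point, with epoch-method multivariate noise normalization
  (shrinkage covariance, symmetric whitening), fold-wise summary trials,
  and percept (*ba* vs. *da*) decoding; hemisphere sensor subsets; the
  Haufe transform of classifier weights into activation patterns.
* **Statistics** — one-sided sign-flip permutation tests with
  cluster-size familywise-error control over the epoch.
* **RSA** — Perceptual and Ambiguity behavioral model RDMs, partial
  Spearman correlation time courses, and subject-bootstrap window tests of
  task × model effects (α = 0.017).
* **Geometry** — 80-ms sliding-window nonmetric MDS (Kruskal stress-1)
  with k-means and silhouette validation of the embedding.
* **Synthetic data** — a generator that plants a configurable
  representational geometry (early category structure, late ambiguity
  structure, task-dependent maintenance) in spatially correlated sensor
  noise, so the entire pipeline is testable without any recording.

The core quantity is the time-resolved representational dissimilarity
matrix: for each subject, task, and time point t the 10 × 10 matrix
`RDM(t)[i, j]` = cross-validated decoding accuracy (%) of steps i vs. j,
and its comparison with the two behavioral models
`Perceptual[i, j] = |%ba_i − %ba_j|` and
`Ambiguity[i, j] = |c_i − c_j|`, `c = 200·|prop_ba − ½|`,
via partial Spearman correlation. See `docs/methods.md` for the full model
description.

## Worked example

```python
import numpy as np
from cpdecode import (GeometrySpec, build_trial_schedule, decode_pair,
                      make_sensor_layout, simulate_epochs, simulate_identification)
from cpdecode.preprocess import preprocess_epochs

layout = make_sensor_layout()                      # 306 channels, 102 locations
behavior = simulate_identification(boundary=5.5, slope=0.5, n_subjects=1, seed=0)
print("prop_ba per step:", np.round(behavior.prop_ba("S01"), 2))

schedule = build_trial_schedule("active", seed=1)  # 400 trials, 40 per step
epochs = simulate_epochs(schedule, behavior, GeometrySpec.active_like(), layout,
                         seed=2, sfreq=50.0)
clean, _ = preprocess_epochs(epochs)               # baseline, 15 Hz low-pass, z-norm
tc = decode_pair(clean, 1, 10, k=5, n_reps=5, seed=3)
peak = tc.times[np.argmax(tc.values)]
print(f"pair 1 vs 10: peak {tc.values.max():.1f}% at {peak:.0f} ms; "
      f"prestimulus mean {tc.values[tc.times < 0].mean():.1f}%")
```

Output:

```
prop_ba per step: [1.   1.   1.   0.95 0.62 0.3  0.02 0.   0.   0.  ]
pair 1 vs 10: peak 80.0% at 760 ms; prestimulus mean 46.4%
```

The identification function shows the categorical boundary between steps 5
and 6 (steps 1–5 mostly labeled *ba*). Decoding the two continuum
endpoints is well above the 50% chance level after stimulus onset — still
high at 760 ms because the "active-like" preset maintains stimulus
information late into the epoch — and fluctuates around chance before
onset.

The full analysis (simulate → preprocess → decode → cluster statistics →
RSA → MDS/k-means) runs from one config:

```bash
cpdecode run-all --seed 1 --outdir results/run1          # defaults
cpdecode run-all --config my.yaml                        # custom scale
```

which writes per-stage CSV/JSON results plus a `manifest.json` with
parameter echo and SHA-256 checksums; identical configs reproduce
byte-identical results. Individual stages are exposed as `cpdecode
simulate | preprocess | decode | cluster-test | rsa | geometry`.

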