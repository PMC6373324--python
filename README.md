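# arcseg

Semantic segmentation of one- and multi-dimensional time series via
matrix-profile arc curves — a batch pipeline (`fluss`) and a streaming
driver (`run_floss`) that maintains the segmentation curve online over a
sliding window.

The idea: compute, for every subsequence of length `L`, its z-normalized
nearest neighbor; draw an "arc" between the two positions; count the arcs
crossing each position (the Arc Curve); divide by the expected count under
a structureless null model and clamp to `[0, 1]` (the Corrected Arc Curve,
CAC). Deep minima of the CAC mark boundaries between internally consistent
regimes — walking vs stair-climbing in accelerometry, posture changes in
arterial blood pressure, and so on. No domain model is required; the only
meaningful parameter is the subsequence length, which can itself be learned
from unlabeled data.

## Features

- **Matrix profile substrate** (`arcseg.mp_core`): MASS-style FFT distance
  profiles, exact batch matrix profile (bidirectional or left-only),
  trivial-match exclusion zones, temporal arc constraints, and a streaming
  sliding-window state with O(1) egress.
- **Arc-curve segmentation** (`arcseg.segmentation`): arc-crossing counts,
  three null models (closed-form parabola, empirical one-directional,
  constrained-uniform), CAC computation, and multi-channel fusion by
  curve averaging.
- **Regime extraction** (`arcseg.regimes`): iterative minimum selection
  with a 5L exclusion zone, plus alert-threshold learning
  (mean − 3·std of negative-training minima) and snippet classification.
- **Online segmentation** (`arcseg.streaming`): per-sample ingest, window
  CAC maintenance, boundary events and debounced alerts.
- **Evaluation** (`arcseg.evaluation`): normalized boundary-error score in
  `[0, 1]` and subsequence-length learning from a snippet concatenated with
  a 95%-rescaled copy of itself.
- **Synthetic fixtures** (`arcseg.synthetic`): seeded regime-change
  generators, unstructured transition gaps, and a six-way distortion
  battery (downsampling, 8-bit quantization, linear trend, 20 dB noise,
  smoothing, 3% deletion + interpolation).

## Library quick start

```python
import numpy as np
from arcseg import (RegimeSpec, SubseqParams, extract_regimes, fluss,
                    make_regime_series, score_segmentation)

series, truth = make_regime_series([
    RegimeSpec("sine", period=25, duration=500, noise_db=20, seed=1),
    RegimeSpec("sawtooth", period=33, duration=500, noise_db=20, seed=2),
])
cac = fluss(series, SubseqParams(L=25))
found = extract_regimes(cac, num_boundaries=1, L=25)
print(found.positions, truth.positions)
print(score_segmentation(found.positions, truth.positions, series.n).value)
```

Multi-channel data is a list of equal-length channels: `fluss([ch1, ch2], params)`
averages the per-channel curves. A temporal constraint
(`SubseqParams(L=..., tc_samples=...)`) caps arc lengths so repeated but
disconnected regimes do not blur interior boundaries.

## CLI

All positions in output files are 0-based sample indices into the input.

```sh
# generate a labeled synthetic series
arcseg synth --spec spec.yaml --out data.csv --truth truth.txt

# batch segmentation (CAC TSV + boundaries JSON)
arcseg segment --input data.csv --subseq 25 --num-boundaries 2 \
    --out-cac cac.tsv --out-boundaries bounds.json

# with a temporal constraint of 30 s at 100 Hz
arcseg segment --input data.csv --rate 100 --subseq-seconds 0.65 --tc 30 ...

# streaming events as JSON lines
arcseg floss --input stream.csv --window 2000 --subseq 65 --out events.jsonl

# score predictions against ground truth
arcseg score --pred pred.txt --truth truth.txt --n 100000

# learn the subsequence length from an unlabeled snippet
arcseg learn-length --input snippet.csv --grid 13,25,50,100,200

# learn an alert threshold from negative-only snippets
arcseg learn-threshold neg1.csv neg2.csv neg3.csv --subseq 187
```

The `synth` spec file is a YAML list of regimes:

```yaml
regimes:
  - {pattern_kind: sine, period: 25, duration: 500, noise_db: 20, seed: 1}
  - {pattern_kind: square, period: 33, duration: 500, noise_db: 20, seed: 2}
```

## Conventions

- Indexing is 0-based; subsequence `i` covers samples `[i, i + L)`.
- The trivial-match exclusion half-width defaults to `⌊L/2⌋`.
- Left-only profile entries with no admissible neighbor store index −1 and
  distance +inf and are skipped when counting arcs.
- Flat (zero-variance) windows z-normalize to the all-zeros vector (with a
  warning) so distances stay finite.
- The first/last `min(5L, n/4)` CAC positions are hard-coded to 1: arcs
  only start at subsequence positions, so the raw counts there are
  uninformative.
- Seconds-denominated CLI parameters convert as `floor(seconds × rate)`.
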