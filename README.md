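# flockstream

Hybrid offline/online behaviour classification for livestock IMU streams
under concept drift.

A frozen nearest-prototype classifier (an emulated associative memory of up
to 128 byte-quantised labelled feature vectors, K=1) runs alongside a
streaming three-centre 1-D k-means over a windowed activity index (mean
acceleration magnitude, gravity-subtracted and discretised into 0–20 bins).
Their outputs — a behaviour label and a high/medium/low activity level —
are fused through a 9-cell decision-rule grid, learnable from labelled
data. Because the online clustering keeps re-centring as the activity
distribution shifts, the fused classifier keeps working when the frozen
classifier degrades.

The package also ships a synthetic IMU/behaviour generator (semi-Markov
bout timelines, calibrated per-behaviour activity distributions, piecewise
regime drift), so the full pipeline is testable end to end without field
data.

## Layout

| module | role |
| --- | --- |
| `flockstream.signals` | sample streams, windowing, observation logs, ground-truth alignment, CSV I/O |
| `flockstream.features` | the 4 window variables × 5 characteristics (20 features) + activity index |
| `flockstream.prototype` | byte quantisation, capacity-limited 1-NN prototype model, model file I/O |
| `flockstream.online_kmeans` | streaming predict-then-update k-means over the activity index |
| `flockstream.fusion` | rule tables (literal + learned), full per-window pipeline |
| `flockstream.metrics` | one-vs-rest metrics, macro "overall" rows, method comparison |
| `flockstream.simulate` | behaviour/IMU generator with drift schedules and calibration |
| `flockstream.experiments` | the end-to-end train-on-A / deploy-on-drifted-B experiment |
| `flockstream.cli` | `flockstream` command-line entry point |

## CLI

```sh
# generate a labelled synthetic dataset (IMU + observations + truth CSVs)
flockstream simulate --out-dir data/ --seed 1 --duration 1800

# per-window feature table
flockstream extract-features --imu data/imu.csv --out data/features.csv

# fit prototypes and learn fusion rules from a labelled stream
flockstream train --imu data/imu.csv --observations data/observations.csv \
    --model-out model.json --rules-out rules.txt --seed 1

# run the combined pipeline (records, centre trajectory, optional metrics)
flockstream run --imu data/imu.csv --model model.json --rules rules.txt \
    --observations data/observations.csv --out-dir out/ --seed 1

# score an existing records file
flockstream evaluate --records out/records.csv \
    --observations data/observations.csv --out out/metrics.csv

# the drift experiment (prints the four method accuracies)
flockstream drift-experiment --seed 1
```

`--priors HIGH MED LOW` initialises the online centres from previously
collected data instead of the stream's first 100 windows. Outputs are never
overwritten without `--force`.

## Notes on conventions

- Acceleration is in g, so gravity subtraction is the constant 1; the
  activity index discretises at 0.1 g per bin, clipped to [0, 20].
- The rule grid's two ambiguous cells default to: (lying, low) → lying,
  (lying, high) → KNN passthrough; both are configurable.
- "Overall" metric rows are unweighted (macro) means of the three
  per-class values; comparisons are computed on unrounded values and
  rounded half-up to 2 decimals only for presentation.
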