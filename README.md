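# ng2circuit

Simulation and analysis toolkit for interneuron→glial-progenitor (NG2 cell)
synaptic microcircuits in developing cortex. The package pairs seeded
synthetic-data generators with the analysis stages they feed, so every
pipeline can be validated closed-loop against known ground truth:

- **`synthetic`** — generators for current-clamp spike trains of two
  interneuron phenotypes (fast-spiking / non-fast-spiking), paired-pulse
  postsynaptic-current sweeps under a 1- or 2-site binomial quantal release
  model, 3D synaptic puncta clouds, photostimulation trial rasters,
  distance-dependent connectivity fields, and a developmental time course
  with a connectivity peak at postnatal day 10.
- **`ephys_features`** — extraction of the 19 spike-train/waveform
  parameters (firing rates, accommodation, threshold, amplitudes,
  Gaussian-fit spike durations, AHP metrics, AP slopes, input resistance)
  and a transparent 3-feature majority rule classifying cells as FSI/NFSI.
- **`synaptic_quantal`** — 2×SD event detection in paired sweeps,
  paired-pulse ratio / CV / response-probability summaries, rise/decay
  kinetics fitting, recovery curves, single- vs double-release-site
  classification (KS on non-failure amplitude distributions + chi-square on
  response probabilities), and amplitude/PPR comparison between
  pharmacological conditions.
- **`mapping`** — photostimulation rasters, evoked-occurrence enrichment
  within a 100-ms window, the two-criterion connection call,
  spot-displacement / pulse-duration controls, and distance-resolved
  connectivity profiles.
- **`puncta_spatial`** — fluorescence-profile overlap colocalization
  (23% contact rule), soma/branch assignment with geodesic distances,
  distance distributions, and puncta densities in eccentric spherical
  shells clipped analytically to the imaging stack.
- **`connectivity_stats`** — Wilson score intervals, the interval-overlap
  decision rule, Pearson chi-square (no continuity correction),
  reconstruction of integer 2×2 tables from rounded published summaries,
  per-group probability tables, Pearson correlation.
- **`pipeline`** / **`cli`** — an end-to-end seeded study producing CSV/JSON
  reports (classification confusion, quantal recovery, distance profiles,
  per-day probabilities, and the reproduction block of the headline
  connectivity statistics).

## CLI

```bash
ng2circuit run --seed 42 --out results/study        # full synthetic study
ng2circuit simulate traces --seed 1 --n-per-class 5 --out results/traces
ng2circuit simulate sweeps --seed 1 --n-sites 2 --out results/sweeps
ng2circuit features --seed 1 --n-per-class 10 --out features.csv
ng2circuit quantal --seed 3 --n-sites 1 --out quantal.json
ng2circuit map --seed 5 --kind NG2 --n-maps 10 --out profile.csv
ng2circuit stats wilson 15 35
ng2circuit stats chi2 15 20 23 89
ng2circuit stats reconstruct --p-a 0.43 --p-b 0.21 \
    --total-pairs 147 --total-connected 38 --chi2-value 6.93
```

`ng2circuit run` accepts a YAML config (see
`ng2circuit.pipeline.DEFAULT_CONFIG` for the schema); CLI flags override
config values. Exit codes: 0 ok, 2 invalid configuration, 3 stage failure.

## Layout

```
src/ng2circuit/
  core.py               sampled traces, pulse protocols
  synthetic/            seeded generators (ephys, release, puncta, field,
                        photostim, timecourse)
  ephys_features.py     19-parameter extraction + FSI/NFSI classifier
  synaptic_quantal.py   PSC detection and quantal analysis
  mapping.py            photostimulation connectivity mapping
  puncta_spatial.py     3D puncta spatial statistics
  connectivity_stats.py Wilson / chi-square / reconstruction / correlation
  pipeline.py, cli.py   study orchestration and command line
tests/                  unit, property and acceptance suites
scripts/acceptance.py   acceptance report
```
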