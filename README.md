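# glomplast

Analysis pipeline for go/no-go olfactory discrimination behavior and
intrinsic-optical-signal (IOS) glomerular imaging, together with a
ground-truth synthetic data generator that makes every stage testable
without any recorded data.

## What it does

- **`glomplast.synthetic_data`** — generates behavioral sessions
  (pseudo-randomized odor sequences with exact 150/150 daily balance and no
  3-runs, lick-bin patterns consistent with the scoring rule, beam-break
  traces diverging at a programmed latency), IOS trial stacks (disk-shaped
  glomerular responses in permil reflectance change, dilution attenuation,
  group amplitude/count effects, vessel artifacts, single-frame transients),
  and quasi-periodic respiration traces — all with recorded ground truth and
  bit-reproducible seeding.
- **`glomplast.behavior`** — trial scoring (S+ hit = licking in ≥3 of four
  500 ms bins; S− correct rejection = ≤1 bin), windowed and block-wise
  percent correct, discrimination-threshold bracketing over a dilution
  series, and sequence validity checks.
- **`glomplast.reaction_time`** — time-resolved bootstrap comparison of S+
  vs S− beam-break fractions; reaction time as the last sustained downward
  crossing of the p = 0.05 line, with a log-p curvature fallback.
- **`glomplast.imaging`** — ΔR/R maps in permil, repetition averaging,
  automated reference-map ROI detection at the lowest dilution (with
  single-frame and vessel-elongation exclusions), per-ROI amplitude
  quantification across dilutions, and activated-glomerulus counting.
- **`glomplast.respiration`** — zero-crossing breathing-frequency
  estimation and the amplitude-versus-frequency independence analysis with
  normalization to a reference frequency bin.
- **`glomplast.linkage`** — hierarchical group summaries (ROIs → mouse →
  group), naive-normalized amplitudes, count fold-changes by dilution
  class, two-sample KS comparison of pooled ROI amplitude distributions,
  rewarded/non-rewarded splits, Boltzmann psychometric fits of accuracy vs
  input strength, and near-threshold paired contrasts.

## CLI

```sh
glomplast synth behavior   --config cfg.yaml --out out/ --seed 1
glomplast synth imaging    --config cfg.yaml --out stacks/ --seed 1
glomplast synth respiration --out out/ --seed 1

glomplast behavior-score --in out/session.csv --window 300 --criterion 70
glomplast rt             --in out/beam.h5 --nboot 1000 --alpha 0.05 --seed 1
glomplast imaging-run    --in stacks/ --out results/
glomplast resp           --in out/respiration.csv
glomplast link-fit       --in points.csv
glomplast link-summarize --amplitudes results/amplitudes.csv --counts results/counts.csv
```

Sessions are CSV (one row per trial), beam-break matrices HDF5, trial
stacks multi-page float32 TIFF with a JSON metadata sidecar, respiration
traces CSV.

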