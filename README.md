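# microstab

Metabolic niche metrics and wavelet-variance temporal stability for bacterial
microcosm experiments.

Given binary species × substrate affinity profiles (Biolog-GN-style, 95
substrates), multi-probe redox-potential (Eh) time series, and per-microcosm
activity/decomposition endpoints, the package computes:

- **Niche metrics** (`microstab.niche_profiles`) — per-species niche breadth,
  community metabolic diversity (CMD, the union of member substrate sets),
  Jaccard niche overlap, community redundancy (1 − CMD/Σ breadths), and the
  fixed 17-consortium nested assembly design (7 richness levels × compositions
  A–C from a 12-species pool).
- **Temporal stability** (`microstab.wavelet_stability`) — continuous Morlet
  wavelet transform W(a, x_j) = (1/a) Σ_i f(x_i) g*((x_i−x_j)/a) of each Eh
  probe trace, per-scale wavelet variance V(a) = (1/n) Σ_j |W(a, x_j)|²,
  probe-averaged V_t(a), scale-averaged overall variance V_t, and temporal
  stability 1/V_t. The literal 1/a prefactor is the default; 1/√a and a
  real-part-squared variance are config options.
- **Synthetic microcosms** (`microstab.synthetic_microcosm`) — a truth-known
  generator for affinity matrices (shared substrate-popularity sampling),
  overlap-coupled species-abundance dynamics with compensatory buffering,
  composite multi-probe Eh traces, and CMD-linear endpoints, so the whole
  pipeline is testable without laboratory data.
- **Association statistics** (`microstab.association_stats`) — the six-pair
  Pearson battery ({ETSA, DOC, stability} × {richness, CMD}) at replicate and
  consortium-mean level, plus a cubic trend fit of CMD against richness.
- **Pipeline** (`microstab.pipeline_cli`) — one-command simulate/analyze runs
  producing a schema-validated JSON report with full provenance.

## CLI

```sh
# generate a synthetic experiment (TSV/CSV/JSON files)
microstab simulate --seed 42 --outdir out/data

# wavelet-variance stability per microcosm from an Eh CSV
microstab stability --eh out/data/eh.csv --dt 900 --voices 8 \
    --normalization paper --omega0 6 --out out/stability.json

# full pipeline, simulate mode
microstab run --mode simulate --seed 42 --outdir out/run

# full pipeline on existing files
microstab run --mode analyze --eh eh.csv --affinity affinity.tsv \
    --design design.json --endpoints endpoints.csv --outdir out/run
```

File formats: affinity matrix as TSV (first column `species_id`, one column
per substrate, cells 0/1); Eh as long-format CSV with columns
`microcosm_id, probe_depth_mm, time_s, eh_mV` (uniform 15-min sampling by
default; irregular input is rejected); endpoints as CSV with
`microcosm_id, consortium_label, richness, cmd, etsa, doc`; design and reports
as JSON.

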