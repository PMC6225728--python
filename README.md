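# telotrack

Single-particle tracking and mean-squared-displacement (MSD) analysis of
fluorescent nuclear foci (e.g. CRISPR-labeled telomeres), built as a tested,
reusable pipeline:

1. **`telotrack.simulate`** — synthetic trajectories with known diffusion
   laws (Brownian; exact fractional Brownian motion with tunable anomalous
   exponent; confined Ornstein–Uhlenbeck plus macroscopic diffusion), movie
   rendering with realistic noise, whole-field drift injection, and
   two-channel 3D foci fixtures with planted clusters/colocalization.
2. **`telotrack.detect`** — Laplacian-of-Gaussian spot detection in 2D
   frames and anisotropic 3D stacks, sub-pixel centroid (or Gaussian-fit)
   refinement, spot-diameter (FWHM) estimation.
3. **`telotrack.track`** — greedy nearest-neighbour linking with gap
   closing (default radius 198.9 nm = 3 px), presence and per-nucleus foci
   filters, nucleus drift correction by cell-centre subtraction.
4. **`telotrack.msd`** — time-averaged MSD (gap-aware; two normalization
   modes), ensemble mean ± SE, anomalous (`4 D_α t^α`) and confined
   (`A(1−e^(−t/τ)) + 4 D_macro t`) least-squares fits with derived
   `D_micro = A/4τ` and confinement size `L = √(A/2)`, per-group α
   distributions, Welch two-sided t-test.
5. **`telotrack.foci`** — 3D aggregation counting (single-linkage at half a
   spot diameter) and one-to-one greedy colocalization.
6. **`telotrack.pipeline` / `telotrack.cli`** — end-to-end orchestration
   with deterministic per-stage seeding and provenance-stamped outputs.

Units: coordinates in nm, time in s, MSD in µm²; pixel/frame conversions
happen only at I/O boundaries.

## CLI

```sh
telotrack simulate --model fbm --alpha 0.18 --n-traj 100 --render --outdir out/
telotrack detect out/movie.tif --sigma-px 1.3 --threshold 5 --out spots.csv
telotrack track spots.csv --max-link-nm 198.9 --out trajectories.csv
telotrack msd trajectories.csv --out msd.csv --ensemble-out ensemble.csv
telotrack fit msd.csv --model anomalous --fit-fraction 0.25 --out fits.json
telotrack aggregate foci.csv --spot-diameter-nm 200 --out aggregation.csv
telotrack coloc foci.csv --coloc-threshold-nm 200 --out coloc.csv
telotrack report --config run.yaml --seed 1 --outdir run/
telotrack validate --alphas 0.18,0.28,0.5,1.0 --n-traj 200 --out recovery.csv
```

`telotrack report` consumes a YAML config describing simulated groups,
acquisition geometry, linking/fitting options and foci fixtures; it writes
per-stage CSVs (each with a provenance header: version, seed, config hash),
`report.json` and `report.md`.

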