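# plumetrack

Analysis of history dependence in insect plume-tracking flight, driven
entirely by synthetic data: plume-crossing extraction and
crossing-triggered statistics from 3D wind-tunnel trajectories, three
trajectory-generating tracking strategies (surge-cast,
centerline-inferring, lattice infotaxis), and a hybrid crossing
analysis that mixes surge-cast and infotaxis responses.

## Layout

| Module | Purpose |
| --- | --- |
| `plumetrack.geometry` | Wind-tunnel geometry, Gaussian plume, trajectory data model, heading |
| `plumetrack.io` | Trajectory table I/O (CSV/HDF5), YAML experiment configs |
| `plumetrack.synthetic` | Synthetic trajectory generator with injectable concentration/history effects |
| `plumetrack.crossings` | Crossing segmentation, exclusion rules, detection-threshold scan |
| `plumetrack.stats` | Partial correlations, binary vs. threshold-linear model F-test, early/late history analysis |
| `plumetrack.walkers` | Correlated-random-walk base model, distribution-matching fit, surge-cast and centerline-inferring simulators |
| `plumetrack.infotaxis` | 3D lattice infotaxis (turbulent-plume likelihood, greedy expected-entropy moves) |
| `plumetrack.hybrid` | Surge-cast/infotaxis crossing mixtures and mixing-fraction matching |
| `plumetrack.heatmap` | Occupancy heatmaps |
| `plumetrack.cli` | `plumetrack` command-line pipeline |

## CLI

```bash
# synthetic data with known injected effects
plumetrack synth --seed 1 --out runs/synth --n-traj 200 \
    --conc-gain 1.0 --history-factor 0.5

# simulate a tracking model
plumetrack simulate --model surge-cast --seed 1 --out runs/sc --n-traj 150
plumetrack simulate --model infotaxis --seed 1 --out runs/it \
    --n-traj 50 --lattice-spacing 0.04

# crossing statistics on any trajectory table
plumetrack analyze --analysis history \
    --trajectories runs/synth/trajectories.csv --out runs/hist

# hybrid mixing fraction against a target late-minus-early difference
plumetrack hybrid --surge-cast runs/sc/trajectories.csv \
    --infotaxis runs/it/trajectories.csv --target 10.0 --out runs/hybrid

# occupancy heatmap of all timepoints
plumetrack heatmap --trajectories runs/sc/trajectories.csv --out runs/hm
```

Every subcommand writes a `*_manifest.yaml` with the resolved
configuration so artifacts are reproducible from the manifest alone.
Tunnel/plume parameters come from a YAML config (`--config`); see
`plumetrack.io.load_config` for the schema.

## Conventions

- +x points downwind, x = 0 at the upwind wall; y, z centred on the
  tunnel midline; the upwind unit vector is (-1, 0, 0).
- Heading is the angle (degrees, 0-180) between velocity and upwind;
  0 means flying straight upwind.
- Concentrations are in arbitrary, dataset-relative units; all
  thresholds share those units.
- A crossing is a maximal above-threshold excursion, aligned to its
  concentration peak (t = 0); crossing numbers count all crossings of a
  trajectory before exclusions are applied.
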