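# tomospat

Spatial and orientational statistics for subtomogram particle tables.

Cryo-electron tomography with subtomogram averaging yields, for every
detected macromolecule in a cell, a 3D centre position and an orientation.
`tomospat` turns those particle tables into the spatial statistics used to
characterise the in-cell organisation of the chaperonin TRiC/CCT and its
relation to ribosomes:

- **Cluster tracing** — groups of ≥ 2 particles connected under a
  centre-to-centre distance cut-off (default 20 nm) within one tomogram,
  with threshold sweeps (15–40 nm, ±0.5 nm windows), per-length
  link-spacing statistics, linear/circular topology labels, and proximity
  to filament tracks.
- **Relative-orientation analysis** — each cluster member's rotation
  relative to its nearest in-cluster neighbour, `R_ref⁻¹·R_nb`, applied to
  the reference vector (0, 0, 1) and mapped to hemisphere discs by
  stereographic projection, with a Monte-Carlo Rayleigh-type test of
  orientation uniformity.
- **Ribosome exit-tunnel-side (ETS) enrichment** — particles are paired to
  their nearest ribosome, expressed in the ribosome's zero-rotation frame
  with the exit tunnel at the origin, and split by the plane through the
  ribosome centre facing the tunnel; the ETS fraction carries a seeded
  bootstrap confidence interval.
- **Duty-cycle accounting** — per-class particle tallies (open chaperonin
  with 0/1/2 prefoldin, closed) converted to state percentages and
  condition comparisons with two-proportion z-tests.
- **Synthetic fields** — a generator producing multi-tomogram particle
  fields with hard-core (15 nm) backgrounds, injected cluster chains and
  rings with a truncated-normal spacing law, uniform or concentrated
  orientations, and ribosome scenes with a tunable ETS placement bias —
  ground truth included, so every statistic can be calibrated end to end.

Input tables are read from the RELION STAR dialect (single data block,
`rlnCoordinateX/Y/Z`, `rlnAngleRot/Tilt/Psi`, …) or plain TSV/CSV;
positions are normalised to nanometres on ingest.

## Worked example

```python
from dataclasses import replace
import tomospat as ts

# a synthetic 50-tomogram field at the untreated-cell preset
cfg = replace(ts.preset("untreated"), n_tomograms=50)
particles, truth = ts.generate_field(cfg, seed=11)

res = ts.ClusterModel(particles, state="closed", threshold=20).fit()
print(res.summary())

ores = ts.OrientationModel(particles, res.clusters, dedup=True).fit(n_boot=999, seed=12)
print(ores.summary())
```

```
Cluster analysis
  state filter        : closed
  threshold (nm)      : 20
  particles analysed  : 540
  clusters (>=2)      : 54
  clustered fraction  : 0.272
  topologies          : {'other': 14, 'linear': 37, 'circular': 3}

 length  n_clusters  n_links   mean_nm    sd_nm  single_link
      2          28       28 17.590745 0.887700        False
      3          16       32 17.429033 0.867448        False
      4           7       20 16.994762 0.897221        False
      5           3       10 16.852514 0.875173        False

Relative-orientation analysis
  samples             : 74 (deduplicated pairs)
  resultant length    : 0.0888
  Monte-Carlo p-value : 0.6370 (999 null draws, seed=12)
  interpretation      : no evidence against random relative orientation
```

Of 540 closed particles, 27% sit in 54 clusters (mostly linear chains)
whose nearest-neighbour spacing is ~17–17.6 nm — close to the configured
truncated-Normal(17.35, 1.18) law — and the relative orientations of
clustered neighbours are consistent with uniformity (resultant 0.089,
p = 0.64): clustering without preferred contact interfaces.

State accounting runs directly from published tallies:

```python
print(ts.state_distribution(ts.UNTREATED_COUNTS).summary())
```

```
State distribution (untreated, n=7407)
     state  count percent
open_noPFD   2395    32.3
 open_1PFD    875    11.8
 open_2PFD     83     1.1
    closed   4054    54.7
  open total   : 45.3%
  closed total : 54.7%
```

The same analyses are available from the shell:

```sh
tomospat simulate --preset untreated --n-tomograms 100 --seed 7 --out sim/
tomospat clusters --in sim/particles.star --state closed --threshold 20 --out clusters.tsv
tomospat sweep --in sim/particles.star --tmin 15 --tmax 40 --window 0.5 --out sweep.tsv
tomospat run --preset untreated --seed 7 --out run/      # full pipeline + summary.yaml
```

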