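# gastruquant

Quantification toolkit for collective cell migration during zebrafish
gastrulation, built around the measurements used to characterise prechordal
plate (ppl) migration and optogenetic Frizzled-receptor engineering:

- **Movement-correlation order parameter** between two cell populations
  (e.g. ppl and overlying neuroectoderm) from 3D cell tracks. Per time
  point, 3D velocity vectors are averaged in 50 × 50 μm xy sectors (full z)
  of a grid centred on the ppl leading edge; for every sector occupied by
  both populations the directional correlation is the cosine between the
  two sector-mean velocities,

  `c_s = (v̄_A · v̄_B) / (|v̄_A| |v̄_B|)  ∈ [−1, 1]`,

  and the order parameter is the mean of `c_s` over sectors: +1 when the
  tissues co-move, −1 when they move in opposition. Animal-pole-directed
  velocity time series of the leading-edge cells come from the same tracks.
- **Protrusion statistics**: per-type protrusion rates (events per cell per
  minute, mean ± SD over cells), rose histograms of protrusion orientation
  (animal pole = 0°), and circular summaries (mean direction, resultant
  length R).
- **Expression-domain morphometry**: length-to-width ratio of an in-situ
  expression domain (maximum Feret diameter over the perpendicular extent),
  minimum boundary distance between two domains with scale-bar calibration,
  membrane/cytosol intensity ratios from line profiles, and per-nucleus mean
  intensities under a DAPI-derived mask.
- **Receptor structural compatibility** for chimera design: Kabsch
  superposition RMSD over paired transmembrane (TM1–7) CA atoms and
  inter-helical residue contact networks (heavy-atom pairs within the van
  der Waals sum + 0.5 Å), with per-helix-pair contact distributions.
- **Group comparison** following the normality-gated decision tree common in
  quantitative embryology: D'Agostino–Pearson per group, then unpaired
  t-test / Mann-Whitney (2 groups) or ANOVA + Tukey / Kruskal-Wallis + Dunn
  (more groups).

Because raw imaging data of this kind are rarely shareable, the package
ships first-class synthetic generators (`gastruquant.simulate`) for every
input — correlated biased-random-walk tracks, Poisson protrusion streams
with von Mises orientations, two-domain label images, membrane line
profiles, and idealised helix bundles — each recording the ground truth its
downstream estimator must recover.

## Worked example

Simulate two populations migrating animal-ward at 2.5 μm/min with coupling
0.8 and 1 μm step noise, then quantify their movement correlation and the
leading-edge animal-pole velocity:

```sh
gastruquant simulate-tracks --n-cells 100 --n-frames 30 \
    --coupling 0.8 --noise-sigma 1.0 --seed 42 --out tracks.csv
gastruquant correlate --tracks tracks.csv --out corr.csv
gastruquant ap-velocity --tracks tracks.csv --out apv.csv
```

`corr.csv` holds the order-parameter time series (`t_min,value,sd,sem,n`;
`n` = sectors):

```
t_min,value,sd,sem,n
0.0,0.9851574427968457,0.007328862837101577,0.0032775671003062185,5
1.0,0.9707754797267775,0.03013058219776976,0.012300758672920409,6
```

The mean order parameter over the movie is 0.972 — the two populations
co-move almost perfectly, as expected at coupling 0.8 with modest noise —
and the mean animal-pole velocity in `apv.csv` is 2.51 μm/min, recovering
the configured 2.5 μm/min drift.

The same library calls are available in Python (`gastruquant.kinematics`,
`.protrusions`, `.morphometry`, `.structure`, `.stats`), and
`gastruquant run config.yaml` executes a multi-stage pipeline with a JSON
provenance log (seeds, parameters, output hashes).

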