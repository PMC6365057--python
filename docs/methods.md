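# Methods notes

## Track kinematics and the order parameter

Velocities are forward differences between consecutive observed positions of
a track, `v = Δx / Δt`, with the actual Δt of the interval, so gaps in a
track contribute one sample at the correct scale rather than being
interpolated. Single-observation tracks contribute nothing.

The movement-correlation order parameter between populations A and B at one
time point is computed by (1) anchoring an xy grid of square sectors
(default 50 μm, the tissue scale at which local flow is meaningful for this
system) at the leading edge of the reference population, (2) averaging 3D
velocity vectors per sector and population with z collapsed, (3) taking the
cosine between the two sector means wherever both populations are present,
and (4) averaging the cosines over sectors without occupancy weighting.
Sector intervals are half-open `[low, high)` and the grid axes are aligned
with the oriented animal–pole (+y) and lateral (+x) axes, so boundary points
are assigned deterministically.

The *leading edge* is defined operationally as the centroid of the cells at
or beyond the 0.95 quantile of the animal-axis coordinate of the reference
population (the anterior ~5%); the quantile is a parameter.

**Minimum sector occupancy.** Sectors where either population has fewer than
3 cells (default `min_occupancy=3`, configurable) are excluded from the
order parameter. A "sector-averaged velocity" computed from one or two cells
is dominated by single-cell fluctuation rather than tissue flow, and
including such sectors makes the order parameter systematically depend on
how densely the tissue was tracked: in simulations at 200 tracked cells per
population roughly half the occupied sectors are 1–2-cell slivers and pull
the order parameter from 0.97 down to 0.91 for a coupling of 1, an artefact
that vanishes at 10× tracking density. Requiring 3 cells per population
restores density stability (grid recovery within 0.05 of a 10×-density run)
while discarding only sectors that carry no tissue-level information. An
occupancy-weighted mean is available as an option.

When several embryos are supplied the per-embryo sector means are reduced
first and the across-embryo mean ± SEM is reported per time point; both
reductions (across sectors, across embryos) are available, across-embryo
SEM being the default for multi-embryo input.

`orient_axes` applies a proper rotation only. With just the animal direction
the spin about the resulting +y axis is a least-squares choice and therefore
arbitrary; because the sector grid is axis-aligned, analyses that must be
reproducible across re-orientations should also pass `lateral_direction` to
pin the full frame.

## Synthetic tracks

Two populations of biased random walks: per step,
`Δx = dt·v·(c·d_shared + (1−c)·d_pop) + ε`, with `ε ~ N(0, σ²I)` per axis.
The coupling `c ∈ [0, 1]` is a convex mixing weight, giving a monotone,
interpretable dial between fully shared and fully private drift; isotropic
Gaussian step noise is the simplest model with analytic expectations.
Defaults: drift speed 2.5 μm/min (the middle of the 2–3 μm/min range typical
of animal-ward ppl migration), dt = 1 min (the frame interval of such
time-lapse data is not standardised, so dt is a free parameter), noise
σ = 1 μm per step, and a 100 μm starting box for 100–200 cells per
population, which reproduces the ~15–20 μm nuclear spacing of packed
gastrula tissue. The generator writes the same CSV dialect the readers
consume, so synthetic and real tracks are interchangeable.

What the generator does *not* emulate: cell–cell exclusion volumes,
neighbour-correlated noise, cell division/loss, stage drift, or tracking
errors. Passing recovery tests therefore shows the estimators are correct
and density-stable for independent-noise flows, not that they are robust to
tracking artefacts.

## Protrusion statistics

Events are Poisson per cell and type; orientations are von Mises around the
animal pole (κ default 2, a clearly oriented but broad distribution; κ = ∞
degenerates to exactly 0°). Rates are per-cell counts normalised by each
cell's observed minutes; the cohort value is mean ± SD over cells, matching
how such scatter plots are reported. The angle convention is 0° = animal,
counterclockwise positive, unfolded range [0, 360) (published rose plots do
not always state whether angles were folded; unfolded is the lossless
choice). Rose bins are half-open with boundary angles assigned to the higher
bin; the default 30° width divides 360 and matches common rose-plot
granularity.

## Morphometry

Pixel model: pixel centers at integer coordinates; a boundary pixel is a
mask pixel 4-adjacent to background. Calibration is isotropic μm/px from an
annotated scale bar.

- **LWR**: length is the maximum Feret diameter of the mask (computed on
  convex-hull vertices); width is the maximal extent of the mask projected
  perpendicular to that axis — the closest operationalisation of "the axis
  perpendicular to the longest axis" for a blob, and ≥ 1 by construction.
  Rotation/translation/scale invariance holds to ~2% discretisation error.
- **Domain distance**: minimum Euclidean distance between boundary pixel
  centers of the two masks (KD-tree), × μm/px. Overlapping domains return 0
  with a warning. An along-axis projected variant was considered and left
  out: the minimum boundary distance is symmetric, parameter-free and
  matches how a gap is read off an image.
- **Membrane/cytosol ratio**: membrane peaks are prominence-filtered local
  maxima with a minimum spacing; membrane intensity is the mean peak value,
  cytosol intensity the mean of samples strictly farther than
  `peak_halfwidth` (default half the minimum spacing) from every peak, and
  the reported ratio is cytosol/membrane. "Background" is interpreted as the
  cytosolic plateau along the line, not extracellular background — the
  quantity of interest is how much receptor sits in the cytosol relative to
  the membrane; to normalise to an external reference instead, divide the
  reported membrane mean by that reference. The ratio is invariant under
  multiplicative gain but not additive offset, which is tested.
- **Segmentation**: interactive ROI selection is replaced by threshold +
  largest 8-connected component (with a dark-stain mode for chromogenic
  signal below background). Nuclear intensities are plain per-label means.

The profile generator uses raised-cosine membrane peaks whose support is
exactly `peak_width` px, so outside ±`peak_width`/2 of each peak the profile
is exactly the cytosolic plateau; noise-free recovery of the stored ratio is
therefore exact, and noisy recovery is tested at 5%. The domain-image
generator tests pixel-center membership against the analytic ellipse/bar, so
with integer semi-axes and no rotation the stored LWR and gap are recovered
exactly; rotated geometry carries ≤ 1 px quantisation.

## Structure

Parsing keeps the first model, one chain, altloc '' or 'A', heavy atoms
only; fusion-construct residues are dropped via config ranges. Superposition
is least-squares rigid (Kabsch; proper rotations only, no outlier pruning by
default — pruning tools shrink RMSD in ways that depend on their thresholds,
so the default reports the honest all-pair value). Residue pairing is either
by shared generic position labels or, without them, index-by-index per
segment after trimming the longer segment symmetrically (odd excess dropped
from the C-terminal end).

Contacts: residues on *different* annotated segments are in contact when any
heavy-atom pair lies within `r_vdw(i) + r_vdw(j) + 0.5 Å` (Bondi radii;
unknown elements get 1.7 Å with a warning). Each unordered residue pair
counts once, tagged with its minimal atom distance. Counts are invariant
under rigid motion and monotone in the tolerance. Segment definitions
(TM1–7, H8) are curated configuration, not computed; the bundled ranges for
rhodopsin and Smoothened structures are literature-based and approximate at
helix termini. Residues with missing heavy atoms participate with the atoms
present.

The helix-bundle generator produces ideal α-helical CA traces (1.5 Å rise,
100° twist, 2.3 Å radius) on a circle; a copy can be Gaussian-perturbed
(stored ground-truth RMSD = direct RMS of the displacement vectors, ≈ σ√3)
and rigidly moved. With `helix_radius=0` inter-helix distances equal center
spacing, which lets tests construct bundles whose contact network is exactly
the ring of adjacent pairs.

## Statistics

The comparison test is a pure function of (group count, per-group
normality verdicts, paired flag): D'Agostino–Pearson per group at α = 0.05
(the customary level; configurable), then t-test/Mann-Whitney or
ANOVA + Tukey / Kruskal-Wallis + Dunn. The omnibus test is undefined below
8 observations; such groups get verdict `None`, the nonparametric branch is
used, and the reason is recorded. Dunn's pairwise comparisons use pooled
mid-ranks with tie correction and Bonferroni adjustment by default (Holm and
unadjusted available) — Bonferroni is the conservative reading of "Dunn's
multiple comparison test" when the adjustment is unnamed.

## Problem sizes and determinism

All generators take integer seeds and are bit-reproducible. The recovery
checks run at 50–200 cells × 10–50 frames, 15 cells × 60 min event streams
(50 cohorts), 50 noisy profiles, and 175-residue bundles — sizes at which
every stated tolerance is comfortably resolved while the whole suite stays
interactive. The pipeline runner records versions, seeds, parameters and
SHA-256 output hashes; identical config + seed gives byte-identical outputs.

## Known limitations

- The order parameter's absolute value depends mildly on sector size and
  minimum occupancy at low tracking density; comparisons should hold these
  fixed.
- LWR and distance carry ~1 px discretisation error; at the 1–2 μm/px
  calibrations typical of whole-embryo images this is well under 2%.
- The contact criterion approximates atlas-style definitions; absolute
  counts shift by a few percent per 0.1 Å of tolerance, so cross-structure
  comparisons should use one tolerance throughout.
- Superposition RMSD between real receptor pairs depends on the segment
  annotation and pairing mode; the bundled literature-based ranges are
  adequate for state-matched comparisons but not for residue-level claims.
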