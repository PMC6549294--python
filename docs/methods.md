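# Methods

This note documents the models, parameters and design decisions behind
`morphofun`: what each stage assumes, which knobs matter, what the synthetic
generator does and does not emulate, and where the design was genuinely open.

## Imaging model and units

Fields are 4-channel (nuclear, dendrite, presynaptic, postsynaptic),
multi-z intensity stacks with a default lateral pixel size of 0.149 µm/px,
the sampling of a 40x/NA 1.1 water-immersion confocal at 488 nm. At this
resolution individual synaptic markers cannot be localised within a synapse;
the pipeline deliberately exploits that: pre- and postsynaptic puncta of a
real synapse partially overlap in the image, so a synapse is *defined
operationally* as a presynaptic spot whose segmented footprint shares at
least one pixel with a postsynaptic spot. Calcium recordings default to
2 frames/s for 180 s (360 frames), the standard configuration for
spontaneous-activity assays with a fast indicator.

## Morphological pipeline

**Projections.** Nuclear and dendrite channels are max-projected over z.
Spot detection instead uses the single sharpest slice (highest intensity
standard deviation, ties to the lowest index) of the presynaptic channel and
the *same* slice of the postsynaptic channel, because projecting would stack
out-of-focus puncta onto in-focus ones.

**Nuclei.** Foreground is a user-set intensity threshold (all thresholds in
this pipeline are data-dependent and exposed in the config; the defaults are
calibrated on the synthetic renderer's intensity scale). Touching nuclei are
split by a watershed on the Euclidean distance transform with
markers at distance maxima at least `nucleus_split_min_distance` (12 px)
apart; components under `min_nucleus_area_px` (120 px) are dropped.
Classification as neuronal requires all three of: projected area ≤
`max_nucleus_area_um2` (40 µm²), circularity 4πA/P² ≥ 0.6, and occupancy ≥
0.02. Occupancy is the fraction of the *ring* (a 2-px dilation of the
nucleus minus the nucleus itself) covered by the dendrite mask: neurons have
dendrites crossing that ring, glia do not. Occupancy could equally be
defined on the full dilated footprint, but that dilutes the overlap to a few
percent for any nucleus and has almost no discriminative power, so the ring
is used. The texture score is the variance of a
Laplacian-of-Gaussian response (σ = 2 px) inside the nucleus, normalised by
squared mean intensity — it captures the bright chromocenter spots typical
of neuronal nuclei. Border-touching nuclei are counted but excluded from
area/circularity/texture statistics, which would otherwise be biased by
truncation.

**Dendrites.** The mask is the union of a rough intensity threshold and a
fine threshold on the Frangi vesselness response at scales {1, 2, 3} px
(bright ridges). Whether the two passes should be unioned or cascaded was
unspecified; the union is used because either pass alone misses either faint
thin neurites (rough) or wide bundles (Frangi at small scales). Skeleton
length counts unique 8-neighbour skeleton edges with √2 weight for
diagonals, which removes most of the systematic overestimate of naive
pixel counting; a straight ridge of L px measures L ± a few percent. Branch
nodes are skeleton pixels with ≥ 3 skeleton neighbours, clustered so that
adjacent junction pixels count once.

**Search region and spots.** Spots are only detected inside
`dilate(dendrites, 3 px) \ dilate(neuronal nuclei, 2 px)`: synapses sit on
or near dendrites but not over somata. Spot enhancement is a
difference-of-Gaussians with σ = (1, 3) px; components of the thresholded
response with ≤ 4 px are discarded as noise (exactly: ≥ 5 px survive).
8-connectivity is used for all components, the common high-content
convention.

**Synapse counting.** All (pre, post) label pairs with ≥ `min_overlap_px`
(default 1) shared pixels are recorded with their overlap. The *synapse
count* is the number of distinct presynaptic spots participating in at least
one pair; this prevents double counting when one presynaptic spot overlaps
two postsynaptic spots, a multiplicity the overlap definition alone leaves
open. Densities are reported both per 100 µm of skeleton length and per µm²
of dendrite area, since a density change can otherwise be an artefact of a
dendrite-density change.

## Functional pipeline

Somata are segmented from the max projection of the nuclear-reporter
reference stack with the nucleus machinery. The raw trace of a soma is its
mean activity-channel intensity per frame; normalisation is ΔF/F₀ with F₀
the 10th percentile of the raw trace — a robust baseline that bursts cannot
inflate (the normalisation in the original assay lives in an unpublished
script; this detector is a documented, config-exposed stand-in). Burst
onsets are upward crossings of `median + 3 × 1.4826 × MAD`, merged within
2 s; the amplitude is the trace maximum within the burst. A neuron is active
iff it bursts at least once. Network bursts are 1-s bins in which ≥ 50% of
active neurons have an onset (the participation threshold and bin are
configurable; "synchronous" has no canonical definition). Burst correlation
is computed on the normalised continuous traces, not on binarised trains:
the pairwise Pearson matrix applies most naturally to traces, and constant
traces contribute 0. The reported statistic is the off-diagonal mean.

## Integration

Morphology fields lacking nuclei or dendrites are removed; per-nucleus
records whose projected area exceeds the per-plate mean by > 5 sd are
dropped as debris (segmentation artefacts) before well averaging. Wells are
the technical replicate for morphology (field rows averaged per well);
functional recordings are already the technical replicate and are not
averaged, to preserve data points. Z-scores use the mean and sd within each
(experiment, replicate) group; zero-variance descriptors become missing, as
do single-row groups.

The score model's inter-correlation (step 2) is computed on z-scored values
rather than raw ones; z-scores make the Pearson
inter-correlation scale-free and consistent with the scoring space. Ranking
uses |average DIV correlation| while the weights keep their sign: a
descriptor that *declines* with maturation (neuronal count) carries real
information and must pull the score down when it fails to decline. The score
renormalises by Σ|w| over the descriptors actually present in a row so that
missing values do not shrink the scale. Pearson correlation is used both for
DIV correlation and inter-correlation, matching the z-score framework.

The age classifier is a random forest; the hyperparameter search covers tree
count {100, 250, 500, 1000} and features-per-split {√p, 0.3p, 0.6p} by
stratified 10-fold CV on a stratified 2/3 training split, with the split/CV
seed recorded. ("Number of descriptors" as a tuned quantity is implemented
as features-per-split, the standard random-forest knob.) Group comparisons
use pairwise two-sided Wilcoxon rank-sum tests with a Bonferroni multiplier
equal to the number of pairwise comparisons for that descriptor, with
Shapiro-Wilk and Bartlett checks reported alongside.

## Synthetic ground truth

The renderer emulates the features the pipeline measures, not
photorealism:

* neuronal nuclei: soft-edged discs, radius 16–20 px, with 6 internal
  Gaussian "chromocenters" (texture); glial: flat discs, radius 28–34 px.
  With pixel size 0.149 µm/px this puts the two area populations cleanly on
  either side of the 40 µm² classification threshold.
* dendrites: curvature-perturbed random trees grown from each neuronal soma
  (3 primaries, step 2 px, Gaussian heading noise, stochastic branching),
  rendered as tubes of Gaussian cross-section σ = 2 px — the structure the
  Frangi filter targets. Truth records total polyline length and branching
  events.
* puncta: 2-D Gaussians (σ = 1.4 px, detected footprint ≈ 13 px, safely
  above the 4-px filter) centred on dendrite centrelines outside somata. A
  true synapse places the post centre ≤ 1 px from its pre partner;
  non-synaptic puncta keep ≥ 8 px from every opposite-channel punctum and
  ≥ 9 px from same-channel neighbours, so the ≥ 1-px-overlap truth is
  unambiguous even under a 1-px chromatic shift.
* per-z defocus (focus weights 0.55/1.0/0.7 with blur on the off-focus
  slices, making the middle slice the sharpest), Poisson shot noise on the
  signal plus Gaussian read noise (sd 3) — the standard fluorescence noise
  model.
* calcium: burst transients with instantaneous rise and exponential decay
  τ = 1.5 s (fast-indicator kinetics), per-neuron rate 0.05 Hz. Each neuron
  adopts each shared network event with probability equal to the synchrony
  fraction and adds an independent Poisson train at the complementary rate,
  so the expected burst rate is constant across synchrony levels and full
  synchrony yields identical trains. Burst trains are thinned to a minimum
  3-s gap so that individual transients remain resolvable at 2 frames/s.

The default maturation model ramps dendrite length up (saturating), synapse
count up (saturating, halfway at pseudo-age 8), neuron count linearly down,
and synchrony up along a logistic with onset at pseudo-age 10 — the
qualitative trajectories of maturing cortical cultures.

`simulate_descriptor_table` additionally simulates per-well descriptor
tables directly from the ramps, with noise at 30% of each descriptor's
dynamic range of which half is a latent per-well, per-class factor:
descriptors of one class co-fluctuate (as shared staining or culture-state
variation makes them do), while different classes remain only
ramp-correlated. This reproduces the inter-correlation structure the
0.75-pruning step is designed for. Because the renderer and the placement
margins are chosen for unambiguous ground truth, passing tests demonstrate
the correctness of the *algorithms*; they do not certify performance on real
data with autofluorescence, uneven illumination, overlapping somata or
staining variability, where every threshold must be re-tuned.

## Numerical choices and degenerate inputs

Identical parameters and seed give bit-identical outputs; all randomness
flows from one seeded generator per call, and placement retries (when a
random dendrite layout leaves too few puncta sites) use seed-derived
substreams. Sharpest-slice ties resolve to the lowest index. Pearson
quantities on constant inputs are defined as 0; correlations of missing
pairs and scores of all-missing rows are NaN. Empty segmentations are valid
results (zero labels), and fields without dendrites emit missing densities
and are removed by the field filter. Problem sizes in the test-suite and the
acceptance script (20-field recovery runs, 150-row classification tables,
5 × 20-recording synchrony sweeps) were chosen as the smallest sizes at
which the statistical checks are stable.

## Known limitations

No point-spread-function or chromatic-aberration simulation (aberration is
covered only as a pixel-shift robustness check); no 3-D segmentation (the
assay projects or picks slices by design); no spike inference — burst
detection is threshold-based; morphological and functional rows are only
ever combined at the replicate level, as they come from different wells.
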