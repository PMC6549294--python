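# morphofun

Morphofunctional profiling of primary neuronal cultures from high-content
microscopy: segmentation-based morphological descriptors, calcium-trace
functional descriptors, and their integration into a single weighted
**connectivity score** with culture-age classification.

## The problem

Neuronal network connectivity in dissociated cultures is usually gauged by a
single readout — neuron number, neurite outgrowth, or synapse density. Each
one alone is ambiguous: a change in synapse density can reflect real synapse
loss, but equally a change in dendrite density with preserved synapse count;
morphologically intact networks can be functionally silent. `morphofun`
implements an integrative pipeline that quantifies all major correlates at
once and condenses them into one interpretable scalar:

* **Nuclei** (DAPI): threshold + watershed segmentation on the max
  projection; nuclei are classified as neuronal vs non-neuronal (glial) by
  maximal projected area, minimal circularity and minimal occupancy of the
  dilated-nucleus ring in the dendrite mask — glial nuclei are larger,
  flatter, and lack emanating dendrites.
* **Dendrites** (MAP2): union of a rough intensity threshold and a fine
  threshold on Frangi vesselness; skeletonisation yields network density,
  length, branch-node count and mean width.
* **Synapses** (synaptophysin / PSD-95): difference-of-Gaussians spot
  detection on the sharpest z-slice, restricted to a *search region* (dilated
  dendrites minus dilated neuronal nuclei); spots of ≤ 4 px are discarded as
  noise; a synapse is a presynaptic spot whose footprint overlaps a
  postsynaptic spot by ≥ 1 pixel. Pearson correlation of the two channels is
  reported as an intensity-based colocalization complement.
* **Function** (GCaMP + nuclear reporter): per-soma ΔF/F₀ traces, robust
  MAD-threshold burst detection, percent active neurons, burst rates and
  amplitudes, network-burst frequency, and the *burst correlation* — the mean
  off-diagonal pairwise Pearson correlation of the traces.

### The connectivity score

Per-well descriptors are z-scored within experiment and replicate
(`z = (x − μ)/σ`). The score model is fitted in four steps: (1) Pearson
correlation of each descriptor with culture age (DIV) on controls, averaged
across experiments; (2) pairwise descriptor inter-correlation on the merged
data; (3) ranking by |average DIV correlation|; (4) top-down pruning of any
descriptor with |inter-correlation| > 0.75 to an already retained one.
Intensity-derived descriptors are excluded as outlier-sensitive. The score
of a replicate is the weighted average

```
score = Σᵢ wᵢ zᵢ / Σᵢ |wᵢ| ,   wᵢ = average corr(descriptorᵢ, DIV)
```

over the retained descriptors present in that row. A random-forest (or LDA)
classifier trained on a stratified 2/3–1/3 split with 10-fold CV predicts
culture age from the descriptor set and reports the misclassification rate.

Because no raw microscopy data ships with the package, a synthetic renderer
(`morphofun.synth`) generates 4-channel multi-z fields, calcium recordings
and descriptor tables with fully known ground truth (nucleus populations,
branched dendrite trees, pre/post puncta with controlled true-synapse
overlap, burst trains with controlled synchrony), so every stage is testable
end to end.

## Worked example

```python
from morphofun import generate_field, segment_field
from morphofun.morpho import compute_morphological_descriptors, count_synapses

img, truth = generate_field(seed=42)        # 4-channel, 3-z synthetic field
seg = segment_field(img)                    # full morphological pipeline
desc = compute_morphological_descriptors(seg, img)
```

prints, when the counts are compared with the ground truth:

```
truth: 8 neuronal + 3 glial nuclei, 55/55 pre/post spots, 30 synapses
found: 11 nuclei (8 neuronal), 55/55 spots, 30 synapses
skeleton length: 485.5 um, synapse density: 6.18 per 100 um
```

i.e. at the default (mild) noise level the pipeline recovers every nucleus,
spot and synapse of this field; the synapse density is 30 synapses × 100 /
485.5 µm of dendrite skeleton.

The same workflow runs from the shell on a simulated plate:

```bash
morphofun simulate --config config.yaml --output sim --seed 1
morphofun profile  --config config.yaml --input sim  --output prof
morphofun score    --config config.yaml --input prof --output scored
```

which reports, for a small 3-age plate,

```
wrote 6 fields and metadata to sim
wrote 6 morphology and 6 functional rows to prof
scored 12 replicates; selected descriptors: nuclei_count, burst_correlation, ...
```

and the mean connectivity score in `scored/scores.csv` rises with culture
age (−0.83 at DIV 3, +0.04 at DIV 10, +0.79 at DIV 18 for that run): the
score recovers the maturation trajectory it was built to track.

## Layout

```
src/morphofun/
  synth.py      synthetic fields, calcium recordings, descriptor tables
  morpho.py     segmentation + morphological descriptors
  calcium.py    trace extraction, burst detection, functional descriptors
  integrate.py  filtering, z-scores, score model, PCA, classifier, statistics
  config.py     structured run configuration (YAML)
  cli.py        simulate / profile / score subcommands
docs/methods.md  model, parameter and design documentation
```
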