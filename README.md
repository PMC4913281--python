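# azpunct

Quantification of presynaptic active-zone protein puncta in dual-color
STED super-resolution images of neuromuscular junctions (NMJs), together
with a ground-truthed synthetic image simulator that makes every stage of
the analysis verifiable.

At adult mouse NMJs the scaffold proteins Bassoon and Piccolo and the
P/Q-type voltage-gated calcium channel (VGCC) appear as diffraction-shaped
fluorescent puncta of ~100–130 nm full width at half maximum (FWHM).
Bassoon colocalizes with VGCC, while Piccolo sits *beside* Bassoon: two
Piccolo puncta ~100 nm apart flank one Bassoon punctum in a
Piccolo–Bassoon–Piccolo "sandwich". Quantifying this architecture — and
its selective degradation in aged animals — requires segmenting puncta
inside the synapse (AChR-cluster) mask, measuring their size, intensity
and density, and scoring each Bassoon punctum into categorical
colocalization classes across channels. This package implements that
pipeline end to end for users analysing STED puncta or benchmarking
puncta-analysis methods.

## What it computes

- **Auto-threshold for light objects** — gray-value histogram rule: the
  background is the histogram's largest peak, the objects form a peak on
  its bright side, and the threshold sits at the trough between the two.
- **Segmentation** — 8-connected components above threshold whose
  centroid lies in the synapse mask, optionally watershed-split between
  comparable intensity maxima (needed to separate ~100 nm flank pairs
  after deconvolution).
- **Richardson–Lucy deconvolution** — Gaussian PSF, reflective
  boundaries, flux-conserving; iterations = 0 is the identity.
- **Per-punctum metrics** — line-profile FWHM (half height between
  background and peak, crossings by linear interpolation), intensity per
  area (integrated punctum signal / mask area), mean intensity per
  punctum, puncta density (count / mask area).
- **Colocalization categories** — per Bassoon punctum:
  `1V:1B, 2V:1B, ≥3V:1B, B only, V only` (Bassoon–VGCC scheme) and
  `1P:1B, 2P:1B, ≥3P:1B, 1P:2B, B only, P only` (Piccolo–Bassoon scheme),
  with association by centroid distance (default 150 nm) *or* pixel
  overlap, plus explicit sandwich-motif detection (flank separation and
  Piccolo–Bassoon–Piccolo angle).
- **Group statistics** — mean ± SEM (SD for FWHM), two-tailed unpaired
  pooled t-tests, FWHM frequency distributions, hierarchical sampling of
  10 puncta per synapse, 5 synapses per animal, 5 animals per group.
- **Simulator** — scenes of Gaussian puncta in sandwich / tandem /
  colocalized-pair / solitary motifs with per-protein FWHM distributions
  (VGCC 103.4 ± 8.5, Bassoon 126.4 ± 11.8, Piccolo 107.6 ± 9.7 nm), 20 nm
  pixels, Poisson shot noise + Gaussian read noise, and full ground truth.

## Worked example

Simulate one dual-channel synapse (5 sandwiches, 3 colocalized pairs,
3 solitary puncta per channel), segment both channels on 80-iteration
deconvolved images with peak splitting, and score the Piccolo–Bassoon
categories:

```sh
$ azpunct simulate --config scene.json --out sim --seed 11
wrote 27 puncta over 2 channel(s) to sim
$ azpunct segment --image sim/bassoon.tif --mask sim/mask.tif \
      --deconvolve-iters 80 --split --out seg
threshold 68.149; 11 puncta -> seg
$ azpunct segment --image sim/piccolo.tif --mask sim/mask.tif \
      --deconvolve-iters 80 --split --out seg
threshold 70.893; 16 puncta -> seg
$ azpunct coloc --puncta-a seg/bassoon_puncta.csv \
      --puncta-b seg/piccolo_puncta.csv --scheme piccolo_bassoon --out col
{'1P:1B': 3, '2P:1B': 5, '>=3P:1B': 0, '1P:2B': 0, 'B_only': 3, 'P_only': 3} (5 sandwich hits) -> col
```

The scene contained 27 ground-truth puncta: 5 sandwiches (10 Piccolo
flanks + 5 Bassoon centers), 3 colocalized pairs and 3 + 3 solitary
puncta. The pipeline recovered every punctum (16 Piccolo, 11 Bassoon) and
every category: the 5 sandwich Bassoon are `2P:1B`, the 3 pairs `1P:1B`,
the solitary puncta `B only`/`P only`, and all 5 sandwiches were detected
explicitly — e.g. the first hit pairs Piccolo 8 and 9 around Bassoon 5 at
104.7 nm flank separation and a 179.8° flanking angle, the collinear
~100 nm geometry of the motif.

`azpunct run --config pipeline.json --out DIR` executes a whole
simulated two-group study (or a list of image files) and writes
`puncta.csv`, `synapse_summary.csv`, `coloc_categories.csv`,
`sandwich_hits.csv`, `group_stats.csv` and a `manifest.json`; identical
config and seed give byte-identical outputs. The same functionality is
available as a library (`azpunct.pipeline.run_pipeline` and the
per-stage modules).

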