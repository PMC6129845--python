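# prebotseq

Cell-type-resolved activation-sequence analysis of rhythmic bursting in
the preBötzinger complex (preBötC), the medullary microcircuit that
generates the inspiratory respiratory rhythm in brainstem slices.

The package turns a calcium-indicator movie (multi-page TIFF, ~10 Hz), a
multispectral reporter reference stack, and a local field potential trace
(CSV, ~10 kHz) into:

- a per-pixel **maxCC image** — the maximum over lags 0–40 frames of the
  Pearson correlation between each pixel's band-passed fluorescence and
  the rectified-integrated LFP — with 7×7 px ROIs placed on suprathreshold
  cells (maxCC > 0.2);
- a five-way **cell typing**: excitatory vs glycinergic vs co-transmitting
  by EGFP/tdTomato reporter expression (separated from the calcium dye by
  guided non-negative matrix factorization of a 3-excitation × 3-emission
  reference stack), crossed with a Regular/Irregular split at a
  data-driven maxCC cutoff;
- per-cycle **activation sequences**: for every accepted LFP burst
  (amplitude and prominence > 0.8 × SD of the detrended integrated LFP,
  sigh-like outlier bursts excluded), each cell's activation timing is its
  calcium-peak time within ±24 frames of the LFP peak, cycles with < 50%
  of cells active are excluded, and activation orders are rescaled to
  percent ranks in (0, 100];
- **group statistics** across slices: per-type rank-bin occupancies,
  cumulative activation curves, leader fractions, early-activation
  fractions and mean timings (mean ± SE, n = slices), with one-way ANOVA +
  Tukey HSD on slice-level values and pairwise Kolmogorov–Smirnov tests on
  the distributions.

Because raw recordings of this kind are not publicly deposited, the
package includes a first-class synthetic-data generator
(`prebotseq.synthetic_data`) that emulates the experiment — jittered burst
train with occasional sighs, five neuron classes differing in activation
probability, amplitude and timing offset, calcium kernel dynamics, imaging
noise and a known spectral mixing matrix — and returns the ground truth,
so every stage of the pipeline is scored quantitatively
(`prebotseq.benchmark`).

## Worked example

Run a three-slice synthetic study (scaled down for a quick demo) and read
the machine-readable summary:

```python
from prebotseq.pipeline import PipelineConfig, SliceSpec, run_pipeline
import json

cfg = PipelineConfig(
    slices=[SliceSpec(label=str(i), seed=i) for i in (1, 2, 3)],
    synth={"n_bursts": 60, "frame_shape": (64, 64),
           "n_cells_per_type": {"R-Ex": 5, "R-Gly": 2, "Irr-Ex": 5,
                                "Irr-Gly": 2, "Irr-Cotrans": 1,
                                "NonRhythmic": 3}},
)
out = run_pipeline(cfg, "demo_run")
print(json.dumps(json.loads((out / "summary.json").read_text()), indent=2))
```

prints (abridged):

```json
{
  "cutoffs": {"1": 0.443048, "2": 0.479042, "3": 0.492954},
  "leader_fraction": {
    "Irr-Cotrans": 0.053234, "Irr-Ex": 0.314614, "Irr-Gly": 0.234147,
    "R-Ex": 0.189772, "R-Gly": 0.208233
  },
  "mean_timing_ms": {
    "Irr-Cotrans": 242.744, "Irr-Ex": 89.78, "Irr-Gly": 84.87,
    "R-Ex": 219.771, "R-Gly": 178.737
  },
  "n_accepted_bursts": {"1": 55, "2": 50, "3": 57},
  "n_cells": {"1": 14, "2": 13, "3": 15},
  "n_slices": 3
}
```

Reading this: each slice's Regular/Irregular maxCC cutoff landed in the
0.44–0.49 range; irregular excitatory and glycinergic cells activate
~85–90 ms after the LFP peak on average versus ~180–240 ms for the regular
and co-transmitting types, and together lead over half of all cycles
despite being a minority of cells — the central cell-type-dependent
ordering this analysis is built to expose. The run directory also holds
`cells.csv`, `activations.csv`, `cycles.csv`, `composition.csv` (counts
and percentages per slice in the standard layout), `tests.csv`
(ANOVA/Tukey and the three KS families), `summary.csv` and PNG figure
panels.

The same pipeline runs from the shell:

```sh
prebotseq simulate --seed 1 --out slice1/           # write one synthetic recording
prebotseq unmix --stack slice1/reference_stack.tiff --out unmixed/
prebotseq condition --movie slice1/movie.tiff --lfp slice1/lfp.csv --out cond/
prebotseq run --config cfg.yaml --out run/          # full study from a YAML config
```

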