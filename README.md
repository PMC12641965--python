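# flowintern

Internalization scoring for imaging flow cytometry: did a fluorescently
labelled compound (an antisense oligonucleotide, a peptide, a nanoparticle)
actually get *inside* the cell, or is it just stuck to the plasma membrane?

Conventional flow cytometry measures total fluorescence per cell and cannot
tell the two apart; microscopy can, but not at thousands of cells per sample.
Imaging flow cytometers record a small multichannel image of every event, and
`flowintern` turns those images into per-cell internalization scores and
population statistics, using only open formats (TIFF stacks + JSON channel
maps + tab-separated report tables). A seeded synthetic-gallery generator
emulating round suspension cells makes the entire pipeline testable without
any instrument data.

## What it computes

For each cell the package builds a morphological mask partition from the
brightfield silhouette:

* **object** — Otsu segmentation of the brightfield channel;
* **cytoplasm** — the object shrunk by *adaptive erosion* to a percentage of
  its area (default 70, the percent retained);
* **membrane** — the tight object minus the cytoplasm: the plasma-membrane
  ring;
* **nucleus** (optional) — the nuclear-channel object eroded by 3 px.

Two statistics then quantify where the compound sits:

* **Internalization coefficient**
  `IC = log10( mean I(cytoplasm) / mean I(object) )`, clamped to ±6.
  IC > 0 means per-pixel signal concentrates inside the cell; cells with
  IC > 0 are counted as internalized.
* **Signal-distribution entropy** `H = −Σᵢⱼ p(i,j) log₂ p(i,j)` over the
  gray-level co-occurrence matrix (GLCM) of the 8-bit-quantized cytoplasm
  signal at 1 µm granularity. High entropy = uniformly spread compound; low
  entropy = punctate, endosome-like foci.

Cells pass a fixed six-step gating cascade before scoring — focus (gradient
RMS), acquisition time (≥ 20 s, excluding carryover), singlets (area ×
aspect-ratio), viability (PI total < 10⁴, after optional spillover
compensation estimated from single-stain controls), compound uptake, and
internalization (IC > 0). Per-sample summaries are written as tab-separated
report tables keyed by `<object>_<Num>.daf` names, and the statistics layer
compares objects and time points: one-way ANOVA with ω² (95% CI by
noncentral-F inversion), Tukey HSD with Cohen's *d*, repeated-measures ANOVA
with generalized eta-squared (bootstrap CI), paired *t*-tests with Cohen's
*d*z, Benjamini–Hochberg correction throughout, Excel/CSV export and dot
plots.

## Worked example

```python
from flowintern import SynthConfig, generate_gallery
from flowintern.gating import run_pipeline

cfg = SynthConfig(seed=7)                  # 70% internalizing cells by default
records, truth = generate_gallery(cfg, 500)
features, tree, summary = run_pipeline(records, sample_name="PS_1")
print(tree.counts)
print(summary.internalized_pct, summary.median_entropy_bits)
```

prints

```
{'all': 500, 'in_focus': 471, 'time_ok': 290, 'singlets': 273,
 'viable': 253, 'uptake': 253, 'internalized': 168}
66.40316205533597 9.405603486761462
```

Reading: of 500 synthetic events, 471 were in focus (the generator defocuses
5%), 290 arrived after the 20 s carryover window, 273 were singlets, 253 were
viable (10% dead by construction) and all of those carried compound. 168/253
= 66.4% scored IC > 0 — recovering the generated 70% internalizer fraction to
within binomial error — and the median cytoplasm entropy of 9.4 bits reflects
the diffuse (non-punctate) default signal mode.

The same flow is available from the shell:

```bash
flowintern simulate --n 500 --seed 7 --out gallery/
flowintern analyze --in gallery/ --sample-name PS_1 --out t4.txt
flowintern stats --reports t1.txt t4.txt --times 1h 4h --order 1h,4h --out results/
```

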