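# hcmito

Quantification and classification pipeline for mitochondrial-reporter
imaging of zebrafish lateral-line hair cells. It is written for
researchers who measure cumulative mitochondrial state with ratiometric
red:green reporters (mitoTimer, JC-1), record stimulus-evoked calcium
responses (cytoRGECO / mitoGCaMP), and ask whether a cell's
mitochondrial history predicts whether it survives aminoglycoside
(neomycin) exposure.

The package covers three linked analyses, each exercised end to end on a
synthetic-data generator with known ground truth:

1. **Trace kinetics.** Raw fluorescence F(t) is normalized to the mean
   pre-stimulus baseline F₀, and each response is summarized by its
   integrated area Σ(F/F₀ − 1) over the stimulus window, its peak F/F₀,
   and its 75% rise time — the time from stimulus onset to the first
   crossing of 1 + 0.75·(peak − 1), sub-frame located by linear
   interpolation.
2. **Ratiometric quantification.** Two/three-channel z-stacks are
   max-projected; the mean background from a cell-free 30 × 30 µm square
   is subtracted from each cell's channel means; the red:green ratio of
   each cell is normalized to the median ratio of its neuromast (so every
   neuromast's median is exactly 1). Hoechst label retention is called
   when nuclear intensity exceeds background mean + 1 SD.
3. **Median-split classification.** Cells with normalized ratio > 1 are
   "red", the rest "green". Against the live/die outcome this yields a
   2×2 table with sensitivity tp/(tp+fn), specificity tn/(fp+tn),
   diagnostic odds ratio (tp·tn)/(fn·fp), a two-sided Fisher exact test
   (log-factorial hypergeometric summation), and the probability of
   superiority P(ratio_live < ratio_die) = U/(n_A·n_B), computed both
   empirically and as Φ((μ_B − μ_A)/√(σ_A² + σ_B²)) from group summaries.

## Worked example

The classification statistics need only the 2×2 counts. With the
bundled example (58 of 74 dying cells above their neuromast median, 42
of 142 living cells):

```sh
hcmito classify --counts examples/neomycin_counts.csv --out results/demo
```

prints

```
Median-split red/green classification vs live/die outcome
  counts: tp=58 fn=16 fp=42 tn=100 (n=216)
  sensitivity: 0.78
  specificity: 0.70
  diagnostic odds ratio: 8.63
  Fisher exact (two-sided) p: 5.48e-12
```

i.e. a redder-than-median cell is strongly enriched among dying cells
(8.6-fold odds), and the association is far beyond chance. From the
group summaries (live 0.77 ± 0.37, die 1.30 ± 0.34) the normal
reconstruction gives a 0.85 probability that a surviving cell has a
lower ratio than a dying one.

The full synthetic study is reproduced by the numbered drivers:

```sh
python analysis/01_simulate.py        # traces, cohort, rendered stack
python analysis/02_trace_kinetics.py  # area / peak / 75% rise time
python analysis/03_ratiometric.py     # project, background, ratios
python analysis/04_classification.py  # median split + statistics
```

whose tables land under `results/`. The same stages are available as
`hcmito simulate | traces | ratios | classify | report` subcommands for
use on real exported data (OME-TIFF stacks, TIFF label maps, CSV
tables).

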