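# eegdecide

An EEG analysis pipeline for studying how induced emotion modulates
spatial decision-making. It covers the full analysis chain used in
emotion–decision EEG studies — ERP microstate segmentation, prefrontal P2
component statistics, phase-slope-index (PSI) effective connectivity,
percolation-sparsified directed graph metrics, and the behavioral /
subjective statistics layer — together with a synthetic-cohort generator
that plants known structure so every stage can be validated against
ground truth.

It is written for EEG methods researchers who want a tested, scriptable
re-implementation of this analysis stack, and for anyone who needs its
individual pieces: a T-AAHC microstate clustering with CV model
selection, an un-normalized PSI estimator, or directed-weighted graph
metrics checked against brute-force oracles.

## The methods in brief

* **Global field power** GFP(t) = √(1/n Σᵢ uᵢ(t)²) over average-referenced
  electrodes; topographies at GFP peaks are clustered with
  **T-AAHC** (atomize-and-agglomerate hierarchical clustering), and the
  number of microstate classes K is chosen by the predictive
  residual-variance criterion CV(K) = σ̂²·((n−1)/(n−1−K))².
* **Phase slope index** per band F:
  Ψᵢⱼ = Im Σ_{f∈F} K̄ᵢⱼ(f)·Kᵢⱼ(f+δf), with K the complex coherency from
  50%-overlap Hamming-window Welch cross-spectra. Ψᵢⱼ > 0 means channel i
  leads j; positive entries become directed edge weights.
* **Percolation sparsification**: the largest weight threshold at which
  the giant (weakly) connected component keeps its full size.
* **Directed weighted graph metrics**: characteristic path length and
  global efficiency on 1/w shortest paths; Fagiolo cube-root-weighted
  clustering coefficient; directed local efficiency on neighbor-induced
  subgraphs.
* **Statistics layer**: matched-samples t on pre/post valence, one-way
  ANOVA on behavior, top/bottom-16 accuracy split with Welch t on local
  measures, Pearson correlation of graph metrics with decision accuracy,
  and topographic (midline-aware) summaries.

See `docs/methods.md` for assumptions, defaults, and design choices.

## Worked example

```python
import pandas as pd
from eegdecide import PipelineConfig, SynthConfig, run_all

cfg = PipelineConfig(
    synth=SynthConfig(n_subjects=8, trials_per_block=12),
    bands=("delta", "theta"), behavior_band="theta", split_k=8)
manifest = run_all(cfg, "demo_out", seed=7)
stats = pd.read_csv("demo_out/stats_results.tsv", sep="\t")
print(stats.round(4).to_string(index=False))
```

prints (seed 7):

```
    test  band     metric  statistic      p       r  n        detail
paired_t   NaN    valence     9.1652 0.0000     NaN  8             H
paired_t   NaN    valence    -7.5144 0.0001     NaN  8             Q
paired_t   NaN    valence    -5.3379 0.0011     NaN  8             T
   anova   NaN    correct     1.5518 0.2231     NaN 32           NaN
   anova   NaN      rt_ms     0.1052 0.9564     NaN 32           NaN
 pearson delta        cpl     0.0255 0.8898  0.0255 32           NaN
 pearson delta         ge     0.1781 0.3294  0.1781 32           NaN
 pearson theta        cpl    -0.0767 0.6764 -0.0767 32           NaN
 pearson theta         ge     0.1373 0.4535  0.1373 32           NaN
 welch_t delta    cc_mean     0.1482 0.8845     NaN 16 group1-group2
 welch_t delta    le_mean     0.5011 0.6242     NaN 16 group1-group2
 welch_t theta    cc_mean    -2.6288 0.0231     NaN 16 group1-group2
 welch_t theta    le_mean    -1.8051 0.0967     NaN 16 group1-group2
 pearson delta cc_midline     0.0690 0.7076  0.0690 32           NaN
 pearson delta le_midline     0.1049 0.5679  0.1049 32           NaN
 pearson theta cc_midline    -0.7378 0.0000 -0.7378 32           NaN
 pearson theta le_midline    -0.6143 0.0002 -0.6143 32           NaN
```

Reading the output: the paired t-tests confirm the planted valence shifts
(positive film raises valence, fear and sad films lower it); accuracy and
reaction time do not differ across conditions (as planted — accuracy is
tied to connectivity, not to condition); and the planted negative coupling
between block accuracy and midline theta clustering (ρ = −0.6) is
recovered through the entire connectivity → percolation → graph-metric
chain as a strongly negative Pearson correlation (r = −0.74 at n = 32
blocks) and a negative Welch t between the high- and low-accuracy block
groups, while the delta band — where nothing was planted — stays flat.
Other stage outputs (microstate templates and segments, ERP component
tables, pointwise-ANOVA intervals, per-block metric tables) are written
next to `stats_results.tsv`; `manifest.json` records the config hash,
seed, timings and per-condition selected K.

The same stages are scriptable from a shell:

```sh
eegdecide run --seed 7 --out demo_out          # full pipeline, defaults
eegdecide synth --seed 3 --out synth_out       # just the generator
eegdecide network --adjacency adj_dir --out m  # just the graph metrics
```

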