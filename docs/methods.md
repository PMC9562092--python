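# Methods

`eegdecide` re-implements, as a tested and reusable pipeline, an EEG
analysis of how induced emotion modulates spatial decision-making: ERP
microstate segmentation, prefrontal P2 component statistics, phase-slope-
index (PSI) effective connectivity, percolation-sparsified directed graph
metrics, and the behavioral/subjective statistics layer. Because no raw
cohort data is publicly deposited, the pipeline is exercised end-to-end on
synthetic EEG with planted, parameterized structure; every downstream
stage therefore has a known ground truth against which recovery can be
measured.

## Synthetic cohort

The generator emulates the experimental protocol: continuous EEG at
250 Hz, four blocks per subject (no stimulus, positive film H, fear film
Q, sad film T), 40 trials per block, 6.5 s per trial, 16 subjects. Each
channel is the sum of:

* **Background noise** — Gaussian noise spectrally shaped to an amplitude
  spectrum ∝ f^(−β/2) inside 1–40 Hz (zero outside), so the power spectral
  density falls as f^(−β); β defaults to 1 and the per-channel standard
  deviation defaults to 10 µV. Shaping is done by FFT filtering,
  independently per channel, before coupling.
* **Evoked templates** — per condition, three components built as
  Gaussian-windowed half-sine bumps (unit peak at the nominal latency)
  times a spatial profile that is a 2-D Gaussian over the flattened
  10-20 montage: a positive prefrontal P2 (condition-dependent amplitude
  and latency; defaults H 8 µV > None 6 > T 5 > Q 4 µV, with Q delayed to
  205 ms), a positive fronto-central P3 at 350 ms, and a negative-frontal/
  positive-posterior N3 at 3,350 ms (350 ms after the second-picture onset
  at 3,000 ms). The spatial profile is normalized so the peak channel
  carries exactly the configured amplitude, which makes component recovery
  exactly checkable.
* **Lagged coupling** — `target += gain · source(t − lag)`, with sources
  taken from the *pre*-coupling signal so chained couplings do not
  compound. A pure transmission delay has a linearly increasing phase
  lead, which guarantees the planted PSI sign. Defaults: Fz→Cz and Cz→Pz,
  lag 5 samples (20 ms), gain 0.8.

The stored ground-truth templates are the templates *after* coupling, so
with the noise scale set to zero the per-condition epoch average equals
the ground truth to machine precision — the generator's strongest internal
consistency check.

Behavioral accuracy (correct decisions out of 40 per block) is drawn from
a latent Gaussian that mixes the standardized per-block network metric
with independent noise at weight ρ (default −0.6, matching the direction
of the negative accuracy–connectivity association the statistics layer is
meant to detect), mapped to counts as `round(32 + 4.5·latent)` and clipped
to [0, 40]; 32/40 matches the reported mean accuracy level, and the spread
keeps clipping rare so the realized correlation is barely attenuated.
Reaction times are drawn independently around 470 ms. Valence self-reports
(1–9 integers) get planted pre→post shifts of +3 (H), −3 (Q), −2 (T) plus
unit rating noise before rounding and clipping.

What the generator deliberately does **not** emulate: forward-modeled
cortical sources, volume conduction, ocular/muscular artifacts, bad
channels, line noise, inter-subject topographic variability, and
non-stationarity within a block. Passing tests therefore demonstrate that
the *algorithms* recover planted structure under realistic noise levels,
not that the pipeline is robust to real-world artifacts — on real data the
omitted cleaning steps (artifact-subspace reconstruction, ICA) would be
needed and are intentionally out of scope.

## Preprocessing

Resampling uses polyphase anti-aliased filtering; band-pass filtering is a
4th-order Butterworth applied forward–backward (zero phase, so ERP
latencies are preserved; effective order 8 gives > 40 dB attenuation an
octave outside the 1–40 Hz band). Average referencing subtracts the
instantaneous channel mean. Epochs cover 0–3.5 s after trial onset
(875 samples at 250 Hz) with no baseline correction — the window starts at
stimulus onset and the band-pass has already removed DC. Trial rejection
is a peak-to-peak amplitude threshold (default 200 µV on any channel),
a deterministic stand-in for the data-driven artifact-removal steps that
synthetic data does not need.

## Microstates

GFP(t) is the RMS across average-referenced electrodes. Topographies at
strict local GFP maxima (thinned to a minimum separation, keeping the
larger peak) feed **T-AAHC**: every map starts as a singleton cluster; at
each step the cluster contributing least GEV is dissolved and its members
are individually re-assigned to the surviving cluster of highest spatial
correlation; a solution is recorded at every K in the scanned range.
Spatial correlation is the cosine between average-referenced maps.
Design choices made where the method is genuinely open:

* **Polarity.** ERP topographies carry meaningful sign, so comparisons
  default to polarity-*sensitive* (signed correlation, mean template). A
  polarity-invariant mode (absolute correlation, first-principal-component
  template) is available for spontaneous-EEG use.
* **GEV** is GFP²-weighted squared correlation,
  GEV = Σ_t GFP(t)²·corr²(u_t, T_label(t)) / Σ_t GFP(t)².
* **Model selection** uses the predictive residual-variance criterion
  CV(K) = σ̂²·((n−1)/(n−1−K))², with σ̂² the mean variance left
  unexplained by the assigned unit-norm templates and n the channel
  count; the K minimizing CV is selected, per condition independently.
* Segmentation is run on the per-condition grand-average ERP (not on
  concatenated single trials); back-fitting labels every timepoint with
  the best-matching template (ties to the lowest index, which also absorbs
  zero-field timepoints) and merges runs into segments. Template sets are
  matched across conditions by greedy one-to-one pairing on descending
  absolute correlation against the first condition as reference.

## ERP statistics

Condition averages are pointwise means over kept trials. Component
measures take the windowed extremum (positive for P2/P3, negative for N3)
and its latency, earliest sample on ties. Default windows — P2 150–275 ms,
P3 275–450 ms, N3 3,250–3,450 ms (250–450 ms after the second-picture
onset) — are standard component latencies and config-exposed, since the
experiment fixes only the picture onsets. The pointwise one-way ANOVA runs
at every sample across conditions on per-trial amplitudes; timepoints with
p ≤ α (default 0.05, uncorrected; Benjamini–Hochberg across timepoints is
optional) are merged into runs and runs shorter than 20 ms discarded, so
isolated false positives do not become "significant periods". Degenerate
timepoints (zero within-group variance) report p = 1 when the means agree
and p → 0 otherwise.

## Connectivity

Cross-spectra are Welch averages over 50%-overlapping, Hamming-tapered,
per-segment-demeaned segments; epochs are pooled as independent segments
into one estimate per block. The default segment length of 1 s gives
δf = 1 Hz, so even the narrowest band (delta, 1–4 Hz) holds enough
consecutive bins. Coherency is K_ij = S_ij/√(S_ii·S_jj), and

    Ψ_ij = Im Σ_{f∈F} K̄_ij(f) · K_ij(f+δf),   F = {f : f, f+δf ∈ [lo, hi)}

per canonical band (delta 1–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–40 Hz). Ψ is exactly antisymmetric; Ψ_ij > 0 means channel i leads j.
Ψ is left un-normalized (the jackknife standard-deviation normalization is
available as an option); the directed adjacency keeps positive entries
only, W_ij = max(Ψ_ij, 0) — by antisymmetry, dropping negative edges and
reversing them are equivalent, and dropping is the single stated rule.

## Graph metrics

Sparsification uses the percolation threshold: candidates are the sorted
unique positive weights, the giant component is the largest *weakly*
connected component (the permissive reading for directed graphs), and τ*
is the largest candidate at which the giant component still has its
τ→0⁺ size. Because the giant size is non-increasing in τ, τ* is found by
bisection; edges ≥ τ* are kept.

Edge lengths are d = 1/w; all-pairs distances are directed Dijkstra. CPL
averages finite ordered-pair distances only (PSI digraphs are rarely
strongly connected; the number of finite pairs is reported alongside),
GE averages inverse distances with 1/∞ = 0. The clustering coefficient is
the Fagiolo directed-weighted form with cube-root weights,

    CC_i = ½[(W^⅓+(Wᵀ)^⅓)³]_ii / [(k_in+k_out)(k_in+k_out−1) − 2Σ_j a_ij·a_ji],

and local efficiency uses the same denominator with inverse shortest
paths computed on each node's neighbor-induced subgraph (node removed,
lengths 1/w). The reciprocal-edge term is a_ij·a_ji. Both are zero when
the denominator is non-positive. All four metrics are verified against
independently coded brute-force implementations (Floyd–Warshall, naive
triple loops) to 1e−12 on random graphs.

## Statistics layer

Matched-samples t on pre/post valence, one-way ANOVA on accuracy and
reaction time across conditions, Pearson correlation (t-transform p,
n−2 df) of global measures with accuracy, a deterministic top-16/bottom-16
accuracy split (ties broken lexicographically by subject, block), Welch
(unequal-variance) t on whole-brain-averaged local measures between the
groups — Welch because group variances are not guaranteed equal and the
choice is otherwise open — and per-electrode topographic summaries with
the midline chain (labels ending in "z") reported separately, optionally
rendered as inverse-distance-interpolated scalp maps. P-values are
reported uncorrected across bands and metrics, with a Benjamini–Hochberg
helper exposed. Degenerate inputs (zero-variance differences or groups)
return flagged p ∈ {0, 1} rather than NaN.

## Pipeline and problem sizes

`run_all` executes acquisition → preprocessing → microstates / ERP /
connectivity → graph metrics → behavior → statistics from one YAML
config, processing subjects one at a time so raw recordings never
accumulate in memory, and writes TSV tables plus a manifest (config hash,
seed, timings, counts). All outputs are pure functions of (config, seed).

The accuracy–metric loop is genuinely end-to-end: per-block network
metrics are first *measured* by the connectivity and graph stages, and
block accuracy is then drawn against those measured values, so the
recovered correlation has passed through every stage of the pipeline.

Problem sizes used by the shipped checks: the template-recovery and
model-selection simulations use 60 maps × 32 channels × 20 seeds; PSI
direction recovery uses 40 s records at SNR 1 × 100 seeds per band; null
calibrations use 2,000 replicates; the end-to-end sign-recovery study uses
50 pipeline runs of a 16-subject cohort with blocks shortened to 10 trials
— the planted correlation structure is unchanged by the shorter blocks,
which simply widen the per-block metric noise the statistics must
overcome.

## Known limitations

* The percolation threshold is defined on weak connectivity; strongly
  connected readings would prune more aggressively.
* CPL over finite pairs only makes CPL values comparable across graphs
  with different disconnection patterns only together with the reported
  finite-pair count.
* The CV criterion assumes spatially white residuals; with few GFP-peak
  maps and strongly overlapping templates it can prefer neighboring K.
* Component windows are fixed, not data-driven; shifted latencies outside
  the configured windows would be mis-measured.
* EDF files can be read (via MNE) but not written; the package's native
  recording format is a delimited matrix with a JSON sidecar.
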