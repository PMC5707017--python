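# Methods

## Signal model

A recording is a set of per-ROI fura-2 ratio traces r(t) = F340/F380 sampled
uniformly (default dt = 3 s, duration 3600 s). The ratio is a dimensionless,
monotone proxy for cytosolic [Ca²⁺]; no calibration to molar units is
attempted, so all amplitudes are in ratio units. ROIs are treated as cells,
with the caveat that an ROI may cover part of a cell or parts of two — no
correction is applied.

The synthetic generator models an agonist-evoked response as

r(t) = b + m·t + Σₖ K(t − oₖ) + ε(t),  ε ~ iid N(0, σ²)

with baseline b (default 1.0), optional linear drift m (default 0), spike
kernel K and onsets oₖ. Per cell, responder status is a Bernoulli draw
(probability `responder_prob`); a responder's first onset is
`stimulus_time` + latency with latency ~ Normal(`latency_mean`,
`latency_sd`) truncated below at one sample, and later onsets follow gamma
inter-spike intervals (`isi_shape`, `isi_scale`), floored at the kernel's
time-to-peak plus one sample as a refractory period, until the recording
ends or `max_spikes` is reached. Overlapping kernels add linearly. Each
cell draws from an independent RNG substream keyed by (seed, cell index),
so cohorts are bit-reproducible and insensitive to simulation order.

### Spike kernel

Each transient is a linear *pacemaker* ramp reaching
`pacemaker_fraction`·A over `pacemaker_duration` (defaults: 0.25·A over
15 s), then a saturating exponential upstroke with time constant `rise_tau`
(2 s) truncated when it reaches 99.9% of the nominal amplitude A, then an
exponential decay (`decay_tau` = 25 s). The explicit 99.9% hand-over makes
the kernel peak a closed-form 0.999·A at a known time, which is what allows
amplitude- and latency-recovery tests to assert tight tolerances. A
pure product-of-exponentials kernel was rejected because its peak is only
~77–83% of A for realistic time constants, which would make "amplitude"
ill-defined relative to the configured value.

A spike is injected only when its peak falls inside the recording: an event
log must never promise a transient that no analysis of the trace could
count, since the log is the ground-truth oracle for the detection chain.

### Phenotype presets

Both presets share dt = 3 s, 3600-s duration, stimulus at 300 s, baseline
1.0 and noise SD 0.01 ratio units. The published recordings give only
means ± SE, so preset parameters are qualitative choices reproducing the
contrast, not fits:

| parameter | `n_like` | `bc_like` |
|---|---|---|
| responder probability | 0.99 | 0.37 |
| latency mean ± sd (s) | 50 ± 15 | 120 ± 40 |
| ISI gamma (shape, scale) | (4, 75 s) → mean 300 s | (4, 100 s) |
| max spikes | unbounded | 2 |
| kernel amplitude (ratio units) | 0.45 | 0.30 |

The `bc_like` cap of two transients mirrors the short trains seen when
store-operated entry is absent or blocked. The add-back generator is flat
baseline plus a release transient (instant rise at the CPA time, exponential
decay, default 0.5 ratio units / 90 s) and a saturating entry rise after
Ca²⁺ restoration (0.4 ratio units, τ = 30 s).

What the generator does **not** emulate: photobleaching and dye loss,
baseline ramps tied to focus drift, non-Gaussian shot noise, amplitude
run-down across a train, inter-cell correlation, and any mechanistic
InsP₃/SERCA/SOCE dynamics. Passing tests therefore certify the analysis
chain (detection, metrics, wavelet index, statistics) under the stated
statistical structure — not robustness to every artefact of real recordings.

## Spike detection

The trace is smoothed with a centered moving average (3 samples). The
baseline level is the median of the minute preceding the stimulus (or the
first minute when no stimulus is annotated). The noise scale is
σ = 1.4826·MAD(Δr)/√2 computed from the first differences of the **raw**
trace: differences during spikes are a minority and the MAD ignores them, so
this estimator is far better conditioned than the MAD of a 20-sample
baseline window, whose sampling error was found to dominate the false-event
rate. A σ floor of 1e−12 handles noise-free traces.

Candidate peaks must exceed baseline + `k_peak`·σ (default k = 5) **and**
have prominence ≥ `k_peak`·σ; the prominence condition is what separates a
regenerative spike from a noise bump riding on the previous spike's decaying
tail, which can clear an absolute threshold while rising only ~2σ above its
local surroundings. Peaks closer than `min_isi` (9 s) keep only the larger.
The onset is back-tracked on the raw trace to the last sample at baseline +
`pacemaker_back_k`·σ before the peak (never crossing the previous peak; for
a spike riding on an elevated tail the inter-spike minimum is used), so
latency is measured from the foot of the pacemaker ramp. The event ends at
the return below baseline + `k_onset`·σ/2. Reported peak time/value are
refined to the raw-trace argmax within the smoother's half-window, removing
the one-sample bias the smoother introduces on sharp peaks. A transient
clipped by the end of the recording (fresh upstroke that leaves the final
sample above the peak threshold) is counted, because events are scored by
onset time.

All constants live in `DetectionParams`. Raising `k_peak` can only remove
events (tested property). Detection is invariant to adding a constant to the
trace.

## Wavelet activity index

For each frequency ν on a log-spaced grid (default 64 points, 0.002–0.1 Hz,
i.e. periods 10–500 s, inside the 1/6 Hz Nyquist limit of 3-s sampling) the
scale is a = s/(2πν) with Morlet central frequency s = 6 (admissibility-
respecting default, exposed as a parameter). The transform is the Riemann
sum with step dt of |a|^(−1/2) ψ\*((tₖ−b)/a) f(tₖ) over all samples,
evaluated for every b on the sample grid by FFT convolution. The detrended
signal (least-squares line removed by default; pre-stimulus-mean subtraction
and no-op variants available) is treated as **zero outside the recording**,
so the fast path equals the direct per-(t, ν) quadrature everywhere to FFT
round-off (~1e−13 relative); reflective padding was rejected because a
reflected tail perturbs coefficients near the edges by ~1e−3 relative,
breaking any tight equivalence with the plain quadrature. Edge distortion is
instead handled explicitly: the cone-of-influence mask flags points within
√2·a of an edge, and the activity average excludes edges.

J(t) integrates |W(t,ν)|²·ν over the analysed band by the trapezoidal rule;
⟨J⟩ averages J(t) over samples at least `edge_exclusion` from both ends
(default 3/ν_min = 1500 s for the default band, capped at 45% of the span so
an interior window always exists). J is non-negative, quadratically
homogeneous in the signal, and approximately shift-invariant away from
edges. Units are ratio²·Hz²; only relative comparisons are meaningful.

## Group statistics

Summaries are mean ± SE (SD with n−1; SE = 0 for n = 1). Two conditions are
compared with the unpaired pooled-variance Student's t (two-tailed,
df = n₁+n₂−2); zero-pooled-variance degeneracies are guarded (t = 0, p = 1
for equal means, an explicit infinite-t flag otherwise). Multi-group
comparisons use one-way ANOVA followed by the Student-Newman-Keuls
procedure: means ranked, pairs tested with the studentized range
q = Δ/√(MSW/2·(1/nᵢ+1/nⱼ)) against span-dependent critical values from
`scipy.stats.studentized_range` (no hard-coded tables), with the stepwise
stopping rule that a non-significant span blocks all nested pairs. Ties in
means are broken by input order.

Responder fractions are compared at the **recording** level: each
microscopic field contributes one percentage, conditions are summarised as
mean ± SE over recordings and compared by unpaired t. The unit of
replication in pooled single-cell studies is ambiguous (cells, fields or
donors); fields were chosen because responder percentages are reported as
mean ± SE across experiments, and cell-level inference would pretend n of
several hundred. The pipeline accordingly simulates `n_recordings` (default
3, echoing the three donors typical of such studies) independent cohorts per
condition, using recordings for responder inference and cells for latency /
amplitude / count / ⟨J⟩ tests.

ΔCt = Ct[gene] − Ct[reference]; higher ΔCt means lower expression. No
multiple-testing correction beyond SNK is applied, and no nonparametric
alternatives are offered.

## Problem sizes and numerical choices

Default analysis sizes — cohorts of tens of cells, 1201-sample traces, a
64-point frequency grid — keep a full two-condition pipeline run in seconds
on one core while leaving every statistical contrast far from marginal
(p ≪ 0.01 between presets). The acceptance script uses 3 recordings × 30
cells per condition, a 20-cell recovery check per preset and 10,000 null
simulations for t-test calibration. Trace CSVs are written with 17
significant digits (bit-exact round trip); pipeline outputs use 12
significant digits and contain no timestamps, so identical configurations
produce byte-identical files.

## Known limitations

- Detection thresholds are tuned for spike amplitudes well above noise
  (A/σ ≳ 20, as in fura-2 recordings of these cells); low-SNR regimes would
  need different `DetectionParams`.
- ⟨J⟩ is reported without any within-trace smoothing of J(t); software
  variants of the activity index sometimes smooth before averaging, which
  would change absolute values but not group contrasts.
- The generator's event log stores continuous onset times while analyses
  operate on the 3-s grid, so one-sample quantisation error is inherent to
  every latency/peak-time comparison.
- `responder_fraction` requires ≥ 2 recordings per condition for inference;
  with a single field it degrades to summaries with a warning.
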