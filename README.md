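# furawave

Quantification of agonist-evoked intracellular Ca²⁺ oscillations in fura-2
ratiometric recordings of single cells, built around the workflow used to
contrast endothelial colony forming cells (ECFCs) from healthy donors with
those from breast-cancer patients: healthy-donor cells respond to VEGF
almost uniformly with sustained, asynchronous Ca²⁺ spike trains, while
tumour-derived cells respond rarely, late, and with only one or two
transients.

The package takes per-ROI time series of the dimensionless F340/F380 ratio
(sampled every 3 s over ~1 h recordings) and computes:

- **Spike metrics** per cell — latency from agonist application to the onset
  of the slow *pacemaker* rise preceding the first regenerative spike; the
  first-spike amplitude, defined as the peak ratio minus the mean ratio over
  the minute of baseline before the pacemaker onset; the number of spikes in
  the one-hour window; and responder status (≥ 1 spike after the stimulus).
  The same peak-minus-baseline convention yields the ER-release and
  store-operated-entry amplitudes of Ca²⁺ *add-back* protocols.
- **Wavelet activity index** — the Morlet continuous wavelet transform
  W(a,b) = |a|^(−1/2) ∫ ψ\*((t−b)/a) f(t) dt with
  ψ(t) = π^(−1/4) exp(−t²/2) exp(ist), mapped to frequency via
  ν = s/(2πa), the frequency-weighted index J(t) ≈ ∫ |W(t,ν)|² ν dν, and its
  per-cell time average ⟨J⟩ — a single number sensitive to both the amplitude
  and the frequency of the oscillatory components.
- **Group statistics** — mean ± SE summaries, unpaired pooled-variance
  Student's *t*, recording-level responder-fraction comparisons, one-way
  ANOVA with the Newman-Keuls studentized-range post-hoc test, and the
  qRT-PCR ΔCt = Ct[gene] − Ct[β-actin] helper.
- **A seeded synthetic generator** that emulates the two phenotypes
  (`n_like`, `bc_like` presets) and the add-back protocol, complete with
  ground-truth event logs for validating the detection chain.

## Worked example

```python
import furawave as fw

cohort = fw.simulate_cohort(fw.preset("n_like", n_cells=8, seed=3))
print(fw.cohort_metrics(cohort).head(3).to_string(index=False))
```

```
 roi_id condition  latency_s  first_amplitude  spike_count  is_responder
cell000      None       12.0         0.453755           13          True
cell001      None       39.0         0.435590           14          True
cell002      None       27.0         0.444891           13          True
```

Each row is one cell: it first spiked 12–39 s after the stimulus, the first
transient rose ~0.45 ratio units above its one-minute baseline, and the cell
kept spiking (7–14 spikes/hour) — the sustained-train phenotype. The wavelet
route condenses each trace to one activity number:

```python
res = fw.trace_activity(cohort.traces[0])
print(res.mean_J)          # 6.0e-05 ratio^2 Hz^2 for a spiking cell
```

A silent cell scores ~2e-06 on the same scale; only relative comparisons of
⟨J⟩ are meaningful. The full two-condition pipeline
(`fw.run_pipeline(fw.PipelineConfig())`, or `furawave run` from a shell)
writes per-cell metric tables and a report comparing responder fraction,
latency, amplitude, spike count and ⟨J⟩ between conditions.

Short narrative scripts for every capability live in `examples/`.

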