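"""Spike detection and per-cell oscillation metrics.

The metrics mirror how agonist-evoked Ca2+ oscillations are scored cell by
cell: (1) the latency from agonist application to the onset of the slow
pacemaker rise leading to the first regenerative spike; (2) the amplitude of
the first spike, peak ratio minus the mean ratio over the minute of baseline
preceding the pacemaker onset; (3) the number of spikes within the analysis
window (one hour by default); plus, for store-depletion/add-back protocols,
the ER-release and store-operated-entry amplitudes measured with the same
peak-minus-one-minute-baseline convention.

Detection itself uses a robust threshold scheme: the trace is lightly
smoothed, the baseline level is the median of a pre-stimulus window and the
noise scale sigma is the spike-robust estimate 1.4826 * MAD of the trace's
first differences / sqrt(2) (the whole recording contributes, so sigma does
not hinge on a handful of baseline samples). Candidate peaks must exceed the
baseline by ``k_peak`` noise SDs, events are delimited by an upward crossing
at ``k_onset`` SDs and a return below half that threshold, and the onset is
back-tracked to the last sample at the baseline (within ``pacemaker_back_k``
SDs) so that latency is measured from the foot of the pacemaker ramp. All
constants are exposed in :class:`DetectionParams`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ConfigError, InsufficientDataError, ProtocolError
from .io import Cohort, RatioTrace

__all__ = [
    "DetectionParams",
    "SpikeEvent",
    "SpikeMetrics",
    "AddBackMetrics",
    "detect_spikes",
    "first_spike_latency",
    "first_spike_amplitude",
    "count_spikes",
    "addback_amplitudes",
    "compute_spike_metrics",
    "cohort_metrics",
]

#: noise-scale floor applied when a noise-free baseline makes MAD vanish
_SIGMA_FLOOR = 1e-12


@dataclass(frozen=True)
class DetectionParams:
    """Tunable constants of the threshold-based spike detector."""

    baseline_window: float = 60.0   # s of data used to estimate baseline/noise
    smoothing_window: int = 3       # samples, centered moving average
    k_onset: float = 3.0            # event-delimiting threshold, noise SDs
    k_peak: float = 5.0             # minimum peak height, noise SDs
    min_isi: float = 9.0            # s; closer peaks are merged (larger kept)
    pacemaker_back_k: float = 1.0   # onset back-tracking level, noise SDs

    def __post_init__(self) -> None:
        for name in ("baseline_window", "smoothing_window", "k_onset",
                     "k_peak", "min_isi", "pacemaker_back_k"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"invalid {name}: must be > 0")
        if self.k_peak < self.k_onset:
            raise ConfigError("invalid k_peak: must be >= k_onset")


@dataclass(frozen=True)
class SpikeEvent:
    """One detected Ca2+ spike."""

    onset_time: float   # s; foot of the pacemaker ramp
    peak_time: float    # s
    peak_value: float   # ratio units (raw trace value at the peak sample)
    end_time: float     # s; return to near-baseline


@dataclass
class SpikeMetrics:
    """Per-cell oscillation parameters over the analysis window."""

    roi_id: str
    latency: float | None          # s from stimulus to first pacemaker onset
    first_amplitude: float | None  # ratio units
    spike_count: int
    is_responder: bool
    events: list[SpikeEvent] = field(default_factory=list)


@dataclass(frozen=True)
class AddBackMetrics:
    """Amplitudes of the two phases of a Ca2+ add-back protocol."""

    release_amplitude: float  # ER mobilization in 0Ca2+, ratio units
    entry_amplitude: float    # store-operated entry on Ca2+ restoration


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values.astype(float)
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")[: values.size]


def _refine_peak(raw: np.ndarray, pk: int, window: int) -> int:
    """Move a smoothed-trace peak index to the raw argmax in its neighbourhood.

    The centered smoother can shift a sharp peak by up to half its window, so
    the reported peak time/value come from the raw trace nearby.
    """
    h = max(window // 2 + 1, 1)
    lo, hi = max(pk - h, 0), min(pk + h + 1, raw.size)
    return lo + int(np.argmax(raw[lo:hi]))


def _baseline_window_mask(trace: RatioTrace, baseline_window: float) -> np.ndarray:
    t = trace.times
    if trace.span < baseline_window:
        raise InsufficientDataError(
            f"trace {trace.roi_id!r} spans {trace.span:.0f} s, "
            f"shorter than the {baseline_window:.0f} s baseline window"
        )
    if trace.stimulus_time is not None and trace.stimulus_time - t[0] >= baseline_window:
        return (t >= trace.stimulus_time - baseline_window) & (t < trace.stimulus_time)
    return t < t[0] + baseline_window


def detect_spikes(trace: RatioTrace, params: DetectionParams | None = None) -> list[SpikeEvent]:
    """Detect Ca2+ spikes in one ratio trace.

    Returns events in onset order. The baseline is estimated from the minute
    preceding the stimulus when a stimulus time is annotated (falling back to
    the first minute otherwise); detection thresholds are expressed relative
    to that baseline, so adding a constant to the whole trace leaves the
    result unchanged.
    """
    p = params or DetectionParams()
    x = _smooth(trace.values, int(p.smoothing_window))
    win = _baseline_window_mask(trace, p.baseline_window)
    base = float(np.median(x[win]))
    # per-sample noise SD from first differences of the raw trace: robust to
    # the spikes themselves (they affect a minority of the differences) and
    # far better conditioned than the MAD of a short baseline window
    d = np.diff(trace.values)
    sigma = 1.4826 * float(np.median(np.abs(d - np.median(d)))) / math.sqrt(2.0)
    if sigma < _SIGMA_FLOOR:
        sigma = _SIGMA_FLOOR

    thr_on = base + p.k_onset * sigma
    thr_peak = base + p.k_peak * sigma
    thr_end = base + 0.5 * p.k_onset * sigma
    back = base + p.pacemaker_back_k * sigma
    dt = trace.dt

    distance = max(int(round(p.min_isi / dt)), 1)
    # prominence, not just height, separates regenerative spikes from noise
    # bumps riding on the decaying tail of the previous spike: a real spike
    # rises by many noise SDs above the saddle on at least one side
    peaks, _ = find_peaks(x, height=thr_peak, distance=distance,
                          prominence=p.k_peak * sigma)

    events: list[SpikeEvent] = []
    prev_pk = -1
    for pk in peaks:
        pk = int(pk)
        lo = prev_pk + 1  # never back-track past the previous spike's peak
        # back-track to the foot of the pacemaker ramp on the raw trace (the
        # centered smoother leaks the ramp into the pre-onset sample); for a
        # spike riding on the previous one's decay, fall back to the saddle
        raw = trace.values
        at_base = np.flatnonzero(raw[lo:pk] <= back)
        if at_base.size:
            onset_idx = lo + int(at_base[-1])
        elif pk > lo:
            onset_idx = lo + int(np.argmin(raw[lo : pk + 1]))
        else:
            onset_idx = lo
        # forward to the return below thr_end
        after = np.flatnonzero(x[pk:] < thr_end)
        end_idx = pk + int(after[0]) if after.size else len(x) - 1
        prev_pk = pk
        pk = _refine_peak(trace.values, pk, int(p.smoothing_window))
        events.append(
            SpikeEvent(
                onset_time=float(trace.times[onset_idx]),
                peak_time=float(trace.times[pk]),
                peak_value=float(trace.values[pk]),
                end_time=float(trace.times[end_idx]),
            )
        )

    # a transient clipped by the end of the recording never forms an interior
    # local maximum; since events are scored by onset time, count it when a
    # fresh upstroke (upward crossing of thr_on after the last counted peak)
    # leaves the final sample above the peak threshold
    lo = prev_pk + 1
    if lo < len(x) and float(x[-1]) >= thr_peak:
        below = np.flatnonzero(x[lo:] <= thr_on)
        if below.size:
            cross = lo + int(below[-1]) + 1
            if cross < len(x):
                pk = cross + int(np.argmax(x[cross:]))
                if prev_pk < 0 or pk - prev_pk >= distance:
                    raw = trace.values
                    at_base = np.flatnonzero(raw[lo:pk] <= back)
                    onset_idx = (lo + int(at_base[-1]) if at_base.size
                                 else lo + int(np.argmin(raw[lo : pk + 1])))
                    pk = _refine_peak(raw, pk, int(p.smoothing_window))
                    events.append(
                        SpikeEvent(
                            onset_time=float(trace.times[onset_idx]),
                            peak_time=float(trace.times[pk]),
                            peak_value=float(trace.values[pk]),
                            end_time=float(trace.times[-1]),
                        )
                    )
    return events


def first_spike_latency(
    trace: RatioTrace,
    events: list[SpikeEvent],
    stimulus_time: float | None = None,
) -> float | None:
    """Latency from agonist application to the first pacemaker onset, seconds.

    Returns ``None`` when no spike was detected. A first onset preceding the
    stimulus raises a spontaneous-activity warning (latency is then negative).
    """
    if not events:
        return None
    stim = trace.stimulus_time if stimulus_time is None else stimulus_time
    if stim is None:
        raise ProtocolError(f"trace {trace.roi_id!r}: no stimulus time annotated")
    onset = events[0].onset_time
    if onset < stim:
        warnings.warn(
            f"trace {trace.roi_id!r}: first spike onset ({onset:.0f} s) precedes "
            f"the stimulus ({stim:.0f} s) — spontaneous activity?",
            stacklevel=2,
        )
    return onset - stim


def first_spike_amplitude(
    trace: RatioTrace,
    events: list[SpikeEvent],
    baseline_window: float = 60.0,
) -> float | None:
    """Amplitude of the first spike: peak ratio minus the mean ratio over the
    minute of baseline ending at the pacemaker onset.

    Returns ``None`` when no spike was detected. With less than one minute of
    pre-onset data the available stretch is used and a truncation warning is
    emitted.
    """
    if not events:
        return None
    ev = events[0]
    t = trace.times
    mask = (t >= ev.onset_time - baseline_window) & (t <= ev.onset_time)
    if ev.onset_time - t[0] < baseline_window:
        warnings.warn(
            f"trace {trace.roi_id!r}: only {ev.onset_time - t[0]:.0f} s of "
            "pre-onset baseline available; amplitude baseline truncated",
            stacklevel=2,
        )
        mask = t <= ev.onset_time
    if not mask.any():
        mask = t <= ev.onset_time
    return float(ev.peak_value - trace.values[mask].mean())


def count_spikes(
    trace: RatioTrace,
    events: list[SpikeEvent],
    window: float = 3600.0,
    stimulus_time: float | None = None,
) -> int:
    """Number of spikes with onset in ``(stimulus, stimulus + window]``.

    The window is clamped to the end of the trace (with a truncation
    warning) when the recording is shorter.
    """
    stim = trace.stimulus_time if stimulus_time is None else stimulus_time
    if stim is None:
        stim = float(trace.times[0])
    end = stim + window
    if end > trace.times[-1]:
        warnings.warn(
            f"trace {trace.roi_id!r}: analysis window ends at {end:.0f} s but the "
            f"recording stops at {trace.times[-1]:.0f} s; counting to the end",
            stacklevel=2,
        )
        end = float(trace.times[-1])
    return sum(1 for ev in events if stim < ev.onset_time <= end)


def _phase_amplitude(trace: RatioTrace, peak_lo: float, peak_hi: float,
                     baseline_end: float, baseline_window: float) -> float:
    t, v = trace.times, trace.values
    peak_mask = (t >= peak_lo) & (t <= peak_hi)
    base_mask = (t >= baseline_end - baseline_window) & (t < baseline_end)
    if not peak_mask.any() or not base_mask.any():
        raise InsufficientDataError(
            f"trace {trace.roi_id!r}: empty peak or baseline window in add-back analysis"
        )
    return float(v[peak_mask].max() - v[base_mask].mean())


def addback_amplitudes(
    trace: RatioTrace,
    cpa_time: float | None = None,
    readdition_time: float | None = None,
    baseline_window: float = 60.0,
) -> AddBackMetrics:
    """Release and entry amplitudes of a Ca2+ add-back protocol trace.

    Each amplitude is the phase's peak ratio minus the mean ratio over the
    minute of baseline preceding that phase: the release amplitude is the
    maximum over ``[cpa_time, readdition_time)`` minus the pre-CPA baseline,
    and the entry amplitude is the maximum after ``readdition_time`` minus
    the baseline just before Ca2+ restoration. Event times default to the
    trace's ``cpa`` / ``ca_readdition`` protocol annotations.
    """
    annot = dict(trace.protocol_events)
    cpa = annot.get("cpa") if cpa_time is None else cpa_time
    readd = annot.get("ca_readdition") if readdition_time is None else readdition_time
    if cpa is None or readd is None:
        raise ProtocolError(
            f"trace {trace.roi_id!r}: add-back analysis needs 'cpa' and "
            "'ca_readdition' times (annotated or passed explicitly)"
        )
    release = _phase_amplitude(trace, cpa, readd - trace.dt / 2, cpa, baseline_window)
    entry = _phase_amplitude(trace, readd, trace.times[-1], readd, baseline_window)
    return AddBackMetrics(release_amplitude=release, entry_amplitude=entry)


def compute_spike_metrics(
    trace: RatioTrace,
    params: DetectionParams | None = None,
    window: float = 3600.0,
    stimulus_time: float | None = None,
) -> SpikeMetrics:
    """All per-cell oscillation parameters for one trace.

    A cell is a responder when at least one spike onset falls in the analysis
    window after the stimulus; latency and first-spike amplitude refer to the
    first such spike and are absent for non-responders.
    """
    stim = trace.stimulus_time if stimulus_time is None else stimulus_time
    if stim is None:
        stim = float(trace.times[0])
    events = detect_spikes(trace, params)
    end = min(stim + window, float(trace.times[-1]))
    in_window = [ev for ev in events if stim < ev.onset_time <= end]
    count = len(in_window)
    latency = amplitude = None
    if count:
        latency = first_spike_latency(trace, in_window, stimulus_time=stim)
        amplitude = first_spike_amplitude(trace, in_window)
    return SpikeMetrics(
        roi_id=trace.roi_id,
        latency=latency,
        first_amplitude=amplitude,
        spike_count=count,
        is_responder=count >= 1,
        events=events,
    )


def cohort_metrics(
    cohort: Cohort,
    params: DetectionParams | None = None,
    window: float = 3600.0,
) -> pd.DataFrame:
    """Per-cell metrics table for a cohort.

    Columns: roi_id, condition, latency_s, first_amplitude, spike_count,
    is_responder.
    """
    rows = []
    for tr in cohort:
        m = compute_spike_metrics(tr, params, window=window)
        rows.append({
            "roi_id": m.roi_id,
            "condition": tr.condition if tr.condition is not None else cohort.condition,
            "latency_s": m.latency,
            "first_amplitude": m.first_amplitude,
            "spike_count": m.spike_count,
            "is_responder": m.is_responder,
        })
    return pd.DataFrame(rows)
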