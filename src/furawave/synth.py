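"""Seeded generator of fura-2-like ratio traces.

Emulates the statistical structure of agonist-evoked Ca2+ oscillations in
endothelial colony forming cells (ECFCs): a responder subpopulation whose
first spike follows a per-cell random latency after the stimulus (cells do
not oscillate in phase with their neighbours), spikes shaped as a slow
pacemaker ramp followed by a fast upstroke and an exponential decay, and
gamma-distributed inter-spike intervals. Two named presets contrast the
phenotypes of interest: ``n_like`` (healthy-donor-like, nearly all cells
respond with sustained spike trains) and ``bc_like`` (breast-cancer-like,
a minority responds with at most 1-2 transients and longer latency).

A separate generator emulates the store-depletion "Ca2+ add-back" protocol:
an ER-release transient under 0Ca2+ after SERCA blockade, then a
store-operated entry plateau once external Ca2+ is restored.

All randomness is seeded; each cell draws from an independent substream
derived from ``(seed, cell_index)``, so traces are reproducible bit-for-bit
and independent of cohort size or simulation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .errors import ConfigError
from .io import Cohort, RatioTrace

__all__ = [
    "SpikeKernelParams",
    "CohortConfig",
    "AddBackConfig",
    "simulate_trace",
    "simulate_cohort",
    "simulate_addback_trace",
    "preset",
    "PRESETS",
    "load_config",
]

#: fraction of the nominal amplitude at which the saturating upstroke is
#: handed over to the decay phase; makes the kernel peak a closed-form
#: 0.999*amplitude instead of an asymptote that is never reached
_RISE_CUTOFF = 1e-3


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"invalid {name}: {msg}")


@dataclass(frozen=True)
class SpikeKernelParams:
    """Shape of one Ca2+ spike added to the baseline.

    The kernel is a linear pacemaker ramp reaching ``pacemaker_fraction *
    amplitude`` over ``pacemaker_duration`` seconds, then a saturating
    exponential upstroke with time constant ``rise_tau`` toward ``amplitude``
    (truncated at 99.9%), then an exponential decay with ``decay_tau``. The
    slow ramp models the pacemaker [Ca2+] rise that precedes each
    regenerative transient.
    """

    pacemaker_duration: float = 15.0   # s
    pacemaker_fraction: float = 0.25   # of amplitude, reached at ramp end
    rise_tau: float = 2.0              # s
    decay_tau: float = 25.0            # s
    amplitude: float = 0.45            # ratio units

    def __post_init__(self) -> None:
        _require(self.pacemaker_duration > 0, "pacemaker_duration", "must be > 0")
        _require(0 <= self.pacemaker_fraction < 1, "pacemaker_fraction", "must be in [0, 1)")
        _require(self.rise_tau > 0, "rise_tau", "must be > 0")
        _require(self.decay_tau > 0, "decay_tau", "must be > 0")
        _require(self.amplitude > 0, "amplitude", "must be > 0")

    @property
    def rise_duration(self) -> float:
        """Time from ramp end to the kernel peak, seconds."""
        return self.rise_tau * math.log((1.0 - self.pacemaker_fraction) / _RISE_CUTOFF)

    @property
    def time_to_peak(self) -> float:
        """Time from pacemaker onset to the kernel peak, seconds."""
        return self.pacemaker_duration + self.rise_duration

    @property
    def peak_value(self) -> float:
        """Kernel maximum in ratio units (0.999 * amplitude)."""
        return self.amplitude * (1.0 - _RISE_CUTOFF)

    def evaluate(self, tau: np.ndarray) -> np.ndarray:
        """Kernel value at times ``tau`` (seconds since pacemaker onset)."""
        tau = np.asarray(tau, float)
        d, a, pf = self.pacemaker_duration, self.amplitude, self.pacemaker_fraction
        r = self.rise_duration
        out = np.zeros_like(tau)
        ramp = (tau >= 0) & (tau < d)
        out[ramp] = pf * a * tau[ramp] / d
        rise = (tau >= d) & (tau < d + r)
        out[rise] = a * (1.0 - (1.0 - pf) * np.exp(-(tau[rise] - d) / self.rise_tau))
        decay = tau >= d + r
        out[decay] = self.peak_value * np.exp(-(tau[decay] - d - r) / self.decay_tau)
        return out


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one simulated recording (cohort of ROI traces)."""

    n_cells: int = 20
    duration: float = 3600.0          # s; one-hour recording
    dt: float = 3.0                   # s; on-line ratio sampling period
    stimulus_time: float = 300.0      # s; agonist application
    responder_prob: float = 1.0
    latency_mean: float = 60.0        # s after stimulus, truncated normal
    latency_sd: float = 20.0
    isi_shape: float = 4.0            # gamma inter-spike-interval shape
    isi_scale: float = 75.0           # gamma scale, s (mean = shape*scale)
    max_spikes: int | None = None     # None = unbounded within the recording
    baseline_level: float = 1.0       # ratio units
    baseline_drift: float = 0.0       # ratio units / s
    noise_sd: float = 0.01            # ratio units, iid Gaussian
    kernel: SpikeKernelParams = field(default_factory=SpikeKernelParams)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_cells >= 0, "n_cells", "must be >= 0")
        _require(self.dt > 0, "dt", "must be > 0")
        _require(self.duration >= self.dt, "duration", "must be >= dt")
        _require(0 <= self.responder_prob <= 1, "responder_prob", "must be in [0, 1]")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")
        _require(self.latency_mean > 0, "latency_mean", "must be > 0")
        _require(self.latency_sd >= 0, "latency_sd", "must be >= 0")
        _require(self.isi_shape > 0, "isi_shape", "must be > 0")
        _require(self.isi_scale > 0, "isi_scale", "must be > 0")
        _require(self.max_spikes is None or self.max_spikes >= 0,
                 "max_spikes", "must be >= 0 or None")
        _require(0 <= self.stimulus_time < self.duration,
                 "stimulus_time", "must lie within the recording")


@dataclass(frozen=True)
class AddBackConfig:
    """Parameters of a simulated Ca2+ add-back protocol trace.

    The trace is flat baseline until ``cpa_time`` (SERCA blockade in 0Ca2+),
    then shows an ER-release transient of height ``release_amplitude``
    decaying with ``release_decay_tau``; at ``readdition_time`` external
    Ca2+ is restored and a store-operated entry plateau of height
    ``entry_amplitude`` rises with time constant ``entry_rise_tau``.
    """

    cpa_time: float = 120.0
    readdition_time: float = 900.0
    release_amplitude: float = 0.5
    release_decay_tau: float = 90.0
    entry_amplitude: float = 0.4
    entry_rise_tau: float = 30.0
    baseline_level: float = 1.0
    noise_sd: float = 0.01
    duration: float = 1500.0
    dt: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.dt > 0, "dt", "must be > 0")
        _require(self.duration >= self.dt, "duration", "must be >= dt")
        _require(0 <= self.cpa_time <= self.duration, "cpa_time",
                 "must lie within [0, duration]")
        _require(0 <= self.readdition_time <= self.duration, "readdition_time",
                 "must lie within [0, duration]")
        _require(self.cpa_time < self.readdition_time < self.duration,
                 "readdition_time", "must satisfy cpa_time < readdition_time < duration")
        _require(self.release_amplitude >= 0, "release_amplitude", "must be >= 0")
        _require(self.entry_amplitude >= 0, "entry_amplitude", "must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd", "must be >= 0")


def _cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    # independent, order-invariant substream per cell
    return np.random.default_rng([int(seed), int(cell_index)])


def _draw_latency(rng: np.random.Generator, cfg: CohortConfig) -> float:
    """Normal latency truncated below at one sampling step."""
    lo = cfg.dt
    if cfg.latency_sd == 0:
        return max(cfg.latency_mean, lo)
    for _ in range(1000):
        x = rng.normal(cfg.latency_mean, cfg.latency_sd)
        if x >= lo:
            return float(x)
    return lo


def _simulate_cell(cfg: CohortConfig, cell_index: int) -> tuple[RatioTrace, list[dict]]:
    rng = _cell_rng(cfg.seed, cell_index)
    n = int(math.floor(cfg.duration / cfg.dt)) + 1
    times = np.arange(n) * cfg.dt
    values = cfg.baseline_level + cfg.baseline_drift * times

    is_responder = bool(rng.random() < cfg.responder_prob)
    events: list[dict] = []
    if is_responder and (cfg.max_spikes is None or cfg.max_spikes > 0):
        # gamma ISIs floored at the kernel's time-to-peak (refractory period)
        isi_floor = cfg.kernel.time_to_peak + cfg.dt
        onset = cfg.stimulus_time + _draw_latency(rng, cfg)
        # a spike is injected only if its peak lies inside the recording, so
        # the event log never contains partial transients that no analysis of
        # the trace could count
        while onset + cfg.kernel.time_to_peak <= cfg.duration:
            events.append({
                "onset": float(onset),
                "peak_time": float(onset + cfg.kernel.time_to_peak),
                "amplitude": float(cfg.kernel.peak_value),
            })
            if cfg.max_spikes is not None and len(events) >= cfg.max_spikes:
                break
            onset += max(float(rng.gamma(cfg.isi_shape, cfg.isi_scale)), isi_floor)
        for ev in events:
            values = values + cfg.kernel.evaluate(times - ev["onset"])

    if cfg.noise_sd > 0:
        values = values + rng.normal(0.0, cfg.noise_sd, size=n)

    trace = RatioTrace(times=times, values=values, roi_id=f"cell{cell_index:03d}",
                       stimulus_time=cfg.stimulus_time)
    return trace, events


def simulate_trace(config: CohortConfig, cell_index: int) -> RatioTrace:
    """Simulate one cell's ratio trace; deterministic given (seed, cell_index)."""
    if not (0 <= cell_index < config.n_cells):
        raise ConfigError(
            f"invalid cell_index: {cell_index} not in [0, {config.n_cells})"
        )
    trace, _ = _simulate_cell(config, cell_index)
    return trace


def simulate_cohort(config: CohortConfig, condition: str | None = None) -> Cohort:
    """Simulate a cohort of traces plus its ground-truth spike event log.

    The returned cohort's ``ground_truth`` maps each roi_id to the list of
    injected spike events (onset, peak time, amplitude) — the oracle against
    which spike detection can be validated.
    """
    if config.n_cells == 0:
        raise ConfigError("invalid n_cells: cohort would be empty")
    traces, log = [], {}
    for i in range(config.n_cells):
        tr, events = _simulate_cell(config, i)
        tr.condition = condition
        traces.append(tr)
        log[tr.roi_id] = events
    return Cohort(traces=traces, condition=condition,
                  provenance=f"simulated (seed={config.seed})", ground_truth=log)


def simulate_addback_trace(config: AddBackConfig, roi_id: str = "addback") -> RatioTrace:
    """Simulate one Ca2+ add-back trace with annotated protocol events."""
    rng = np.random.default_rng([int(config.seed), 0])
    n = int(math.floor(config.duration / config.dt)) + 1
    times = np.arange(n) * config.dt
    values = np.full(n, config.baseline_level)
    rel = times >= config.cpa_time
    values[rel] += config.release_amplitude * np.exp(
        -(times[rel] - config.cpa_time) / config.release_decay_tau
    )
    ent = times >= config.readdition_time
    values[ent] += config.entry_amplitude * (
        1.0 - np.exp(-(times[ent] - config.readdition_time) / config.entry_rise_tau)
    )
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=n)
    return RatioTrace(
        times=times, values=values, roi_id=roi_id,
        protocol_events=[("cpa", config.cpa_time),
                         ("ca_readdition", config.readdition_time)],
    )


# ---------------------------------------------------------------------------
# Named presets for the two oscillation phenotypes

PRESETS: dict[str, dict[str, Any]] = {
    # healthy-donor-like: nearly every cell responds with a sustained train
    # of large spikes (gamma ISI mean ~300 s), short latency
    "n_like": dict(
        responder_prob=0.99,
        latency_mean=50.0, latency_sd=15.0,
        isi_shape=4.0, isi_scale=75.0,
        max_spikes=None,
        kernel=SpikeKernelParams(amplitude=0.45),
    ),
    # breast-cancer-like: a minority responds, with at most 1-2 smaller
    # transients and a longer latency
    "bc_like": dict(
        responder_prob=0.37,
        latency_mean=120.0, latency_sd=40.0,
        isi_shape=4.0, isi_scale=100.0,
        max_spikes=2,
        kernel=SpikeKernelParams(amplitude=0.30),
    ),
}


def preset(name: str, **overrides) -> CohortConfig:
    """Return a named phenotype preset as a :class:`CohortConfig`.

    ``overrides`` (e.g. ``n_cells``, ``seed``) replace preset fields.
    """
    if name not in PRESETS:
        raise ConfigError(f"invalid preset: {name!r}; known: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return CohortConfig(**params)


def load_config(path: str | Path) -> CohortConfig | AddBackConfig:
    """Load a cohort or add-back configuration from a YAML file.

    The file holds the dataclass fields; a ``kernel`` sub-mapping builds
    :class:`SpikeKernelParams`. Files containing ``cpa_time`` are read as
    :class:`AddBackConfig`.
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"invalid config file {path}: expected a mapping")
    if "cpa_time" in data:
        return AddBackConfig(**data)
    if "preset" in data:
        name = data.pop("preset")
        return preset(name, **_parse_kernel(data))
    return CohortConfig(**_parse_kernel(data))


def _parse_kernel(data: dict) -> dict:
    if isinstance(data.get("kernel"), dict):
        data = dict(data)
        data["kernel"] = SpikeKernelParams(**data["kernel"])
    return data
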