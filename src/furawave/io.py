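"""Trace containers and tabular I/O for fura-2 ratio recordings.

A recording is a set of per-ROI time series of the dimensionless F340/F380
emission ratio, sampled on a uniform grid (typically every 3 s). Traces are
interchanged as plain CSV — one ``time_s`` column plus one column per ROI —
with an optional JSON sidecar holding per-ROI metadata (condition label,
stimulus time, protocol events), which keeps the trace table rectangular.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import TraceFormatError

__all__ = ["RatioTrace", "Cohort", "compute_ratio", "read_traces", "write_traces"]

#: absolute tolerance for the sampling step being uniform, in seconds
_DT_ATOL = 1e-9

#: float format used when writing trace tables; 17 significant digits
#: round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


@dataclass
class RatioTrace:
    """One ROI's ratio time series with protocol annotations.

    Parameters
    ----------
    times : array of float
        Sample times in seconds from recording start, strictly increasing
        with a uniform step.
    values : array of float
        F340/F380 ratio at each sample (dimensionless). An increase in the
        ratio is read as an increase in cytosolic [Ca2+].
    roi_id : str
        Identifier of the region of interest.
    condition : str, optional
        Experimental condition label shared by the cohort.
    stimulus_time : float, optional
        Agonist application time, seconds, on the same clock as `times`.
    protocol_events : list of (label, time)
        Additional protocol landmarks (e.g. CPA application, Ca2+
        re-addition) on the same clock.
    """

    times: np.ndarray
    values: np.ndarray
    roi_id: str
    condition: str | None = None
    stimulus_time: float | None = None
    protocol_events: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise TraceFormatError(f"trace {self.roi_id!r}: times and values must be 1-D")
        if self.times.size != self.values.size:
            raise TraceFormatError(
                f"trace {self.roi_id!r}: times ({self.times.size}) and values "
                f"({self.values.size}) differ in length"
            )
        if self.times.size < 2:
            raise TraceFormatError(f"trace {self.roi_id!r}: need at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise TraceFormatError(f"trace {self.roi_id!r}: non-finite value at sample {bad}")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise TraceFormatError(f"trace {self.roi_id!r}: times must be strictly increasing")
        if np.max(np.abs(steps - steps[0])) > _DT_ATOL:
            raise TraceFormatError(
                f"trace {self.roi_id!r}: non-uniform sampling step "
                f"(max deviation {np.max(np.abs(steps - steps[0])):.3g} s)"
            )

    @property
    def dt(self) -> float:
        """Sampling step in seconds."""
        return float(self.times[1] - self.times[0])

    @property
    def span(self) -> float:
        """Total duration covered by the trace, seconds."""
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class Cohort:
    """Traces sharing one condition label and time base (one field/recording)."""

    traces: list[RatioTrace]
    condition: str | None = None
    provenance: str = ""
    ground_truth: dict | None = None  # generator event log, when simulated

    def __post_init__(self) -> None:
        ids = [t.roi_id for t in self.traces]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TraceFormatError(f"duplicate roi_id(s): {dupes}")
        if self.traces:
            ref = self.traces[0].times
            for t in self.traces[1:]:
                if t.times.size != ref.size or np.max(np.abs(t.times - ref)) > _DT_ATOL:
                    raise TraceFormatError(
                        f"trace {t.roi_id!r} does not share the cohort time base"
                    )

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[RatioTrace]:
        return iter(self.traces)

    @property
    def roi_ids(self) -> list[str]:
        return [t.roi_id for t in self.traces]


def compute_ratio(
    f340: Sequence[float],
    f380: Sequence[float],
    times: Sequence[float] | None = None,
    dt: float = 3.0,
    roi_id: str = "roi",
    **metadata,
) -> RatioTrace:
    """Build a ratio trace from dual-excitation fluorescence channels.

    The ratio is the element-wise quotient of the 340-nm-excited emission by
    the 380-nm-excited emission (both detected at 510 nm). No calibration to
    molar [Ca2+] is applied; ordering is preserved, so a rise in the ratio
    means a rise in [Ca2+].

    Parameters
    ----------
    f340, f380 : sequences of float
        Background-corrected mean ROI fluorescence for each excitation
        wavelength. Must be equal length; ``f380`` strictly positive.
    times : sequence of float, optional
        Sample times; defaults to a uniform grid with step `dt`.
    dt : float
        Sampling step in seconds used when `times` is omitted.
    metadata
        Passed through to :class:`RatioTrace` (condition, stimulus_time, ...).
    """
    a340 = np.asarray(f340, dtype=float)
    a380 = np.asarray(f380, dtype=float)
    if a340.shape != a380.shape:
        raise TraceFormatError(
            f"channel shapes differ: f340 {a340.shape} vs f380 {a380.shape}"
        )
    nonpos = np.flatnonzero(a380 <= 0)
    if nonpos.size:
        raise ValueError(
            f"f380 must be positive; first non-positive value at sample {int(nonpos[0])}"
        )
    if times is None:
        times = np.arange(a340.size) * float(dt)
    return RatioTrace(times=np.asarray(times, float), values=a340 / a380,
                      roi_id=roi_id, **metadata)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_traces(cohort: Cohort, destination: str | Path,
                 sidecar: str | Path | None = None) -> None:
    """Write a cohort as CSV (``time_s`` + one column per ROI) plus JSON sidecar.

    Values are formatted with 17 significant digits so a write→read round
    trip reproduces them bit-exactly. The sidecar records per-ROI condition,
    stimulus time and protocol events; it is written next to the CSV as
    ``<name>.csv.meta.json`` unless `sidecar` overrides the location.
    """
    if not cohort.traces:
        raise ValueError("cannot write an empty cohort")
    destination = Path(destination)
    df = pd.DataFrame({"time_s": cohort.traces[0].times})
    for tr in cohort.traces:
        df[str(tr.roi_id)] = tr.values
    df.to_csv(destination, index=False, float_format=_FLOAT_FMT)

    meta: dict = {
        "condition": cohort.condition,
        "provenance": cohort.provenance,
        "rois": {
            str(tr.roi_id): {
                "condition": tr.condition,
                "stimulus_time": tr.stimulus_time,
                "protocol_events": [[lbl, t] for lbl, t in tr.protocol_events],
            }
            for tr in cohort.traces
        },
    }
    if cohort.ground_truth is not None:
        meta["ground_truth"] = cohort.ground_truth
    sidecar = _sidecar_path(destination) if sidecar is None else Path(sidecar)
    sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_traces(source: str | Path, sidecar: str | Path | None = None) -> Cohort:
    """Read a cohort from the CSV dialect written by :func:`write_traces`.

    The first column is time in seconds; every remaining column is one ROI.
    Times must be strictly increasing with a uniform step. A JSON sidecar
    (``<name>.csv.meta.json``) is loaded when present.
    """
    source = Path(source)
    df = pd.read_csv(source)
    if df.shape[1] < 2:
        raise TraceFormatError(f"{source}: need a time column and at least one ROI column")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna() & df[col].notna()]
        if len(bad) or df[col].isna().any():
            row = int(bad[0]) if len(bad) else int(df.index[df[col].isna()][0])
            raise TraceFormatError(
                f"{source}: non-numeric or missing cell at row {row}, column {col!r}"
            )
        df[col] = vals

    meta: dict = {}
    sidecar = _sidecar_path(source) if sidecar is None else Path(sidecar)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    roi_meta = meta.get("rois", {})

    times = df.iloc[:, 0].to_numpy(float)
    traces = []
    for col in df.columns[1:]:
        m = roi_meta.get(str(col), {})
        events = [(str(lbl), float(t)) for lbl, t in m.get("protocol_events", [])]
        traces.append(
            RatioTrace(
                times=times,
                values=df[col].to_numpy(float),
                roi_id=str(col),
                condition=m.get("condition", meta.get("condition")),
                stimulus_time=m.get("stimulus_time"),
                protocol_events=events,
            )
        )
    gt = meta.get("ground_truth")
    return Cohort(traces=traces, condition=meta.get("condition"),
                  provenance=meta.get("provenance", f"read from {source.name}"),
                  ground_truth=gt)
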