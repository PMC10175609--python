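"""Spike detection, trial segmentation, and Bernoulli bin counting.

Raw intracellular voltage traces are reduced to spike times by
subtracting a running-median baseline (500 ms window) and applying a
manually chosen threshold to the residual; events closer than the
~2 ms refractory period are merged. Trial-event tables are segmented
into (motion, stationary) phase pairs, with adaptation phases discarded
and repeated series of the same direction pooled. Spikes are then
counted as bin occupancies in 2 ms bins over the first 5 s of each
phase, yielding the (k, n) Bernoulli counts the selectivity analysis
consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BIN_WIDTH_S, PHASE_S, TRIAL_COUNT_COLUMNS

PHASES = ("adaptation", "motion", "stationary")


@dataclass
class VoltageTrace:
    """A single-electrode voltage recording in millivolts."""

    samples: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class TrialWindow:
    """One trial: a motion phase and its immediately following stationary phase."""

    direction: str
    motion: tuple[float, float]
    stationary: tuple[float, float]
    series_index: int = 0


@dataclass
class TrialCounts:
    """Pooled Bernoulli counts for one neuron and motion direction.

    ``k`` counts 2 ms bins containing at least one spike, ``n`` counts
    bins in total, summed over trials; the per-trial quadruples are
    retained for descriptive reporting.
    """

    neuron_id: str
    direction: str
    k_motion: int
    n_motion: int
    k_stationary: int
    n_stationary: int
    per_trial: list[tuple[int, int, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for k, n in ((self.k_motion, self.n_motion),
                     (self.k_stationary, self.n_stationary)):
            if not 0 <= k <= n:
                raise ValueError(f"invalid counts: k={k}, n={n}")


def running_median(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running median with edge-replication padding."""
    if window < 1:
        raise ValueError("window must be >= 1")
    window = min(window, x.size) | 1  # odd, no larger than the trace
    half = window // 2
    padded = np.concatenate([np.full(half, x[0]), x, np.full(half, x[-1])])
    return (
        pd.Series(padded).rolling(window, center=True).median()
        .to_numpy()[half:-half]
    )


def detect_spikes(
    trace: VoltageTrace,
    threshold: float,
    median_window: float = 0.5,
    refractory: float = 0.002,
) -> np.ndarray:
    """Spike times from a voltage trace (seconds, sorted).

    The running-median baseline (``median_window`` seconds wide) is
    subtracted and upward threshold crossings of the residual are taken
    as spikes; each suprathreshold run is timed at its amplitude peak,
    and events closer than ``refractory`` are merged into one.
    """
    if median_window <= 0:
        raise ValueError("median_window must be positive")
    x = trace.samples
    if x.size == 0:
        raise ValueError("empty voltage trace")
    if not np.all(np.isfinite(x)):
        raise ValueError("voltage trace contains non-finite samples")
    win = int(round(median_window * trace.sample_rate))
    resid = x - running_median(x, max(win, 1))
    above = resid >= threshold
    if not above.any():
        return np.array([], dtype=float)
    # contiguous suprathreshold runs -> peak sample of each run
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    peaks = np.array([s + np.argmax(resid[s:e]) for s, e in zip(starts, ends)])
    times = trace.start_time + peaks / trace.sample_rate
    # refractory merge: collapse events closer than the refractory period
    merged = [times[0]]
    for t in times[1:]:
        if t - merged[-1] >= refractory:
            merged.append(t)
    return np.asarray(merged)


def segment_trials(events: pd.DataFrame) -> list[TrialWindow]:
    """Trial (motion, stationary) windows from a trial-event table.

    The table has columns ``direction, phase, t_start, t_end,
    series_index``. Adaptation phases are discarded. Each motion phase
    must be immediately followed by a stationary phase of the same
    direction. Trials from repeated series of one direction are all
    returned and treated downstream as belonging to a single series.
    """
    required = {"direction", "phase", "t_start", "t_end", "series_index"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    ev = events.sort_values("t_start", kind="stable").reset_index(drop=True)
    bad = ev[~ev["phase"].isin(PHASES)]
    if len(bad):
        raise ValueError(f"unknown phase label in rows {list(bad.index)}")
    if (ev["t_end"] <= ev["t_start"]).any():
        raise ValueError("phases must have t_end > t_start")
    overlap = ev["t_start"].to_numpy()[1:] < ev["t_end"].to_numpy()[:-1] - 1e-12
    if overlap.any():
        row = int(np.flatnonzero(overlap)[0]) + 1
        raise ValueError(f"overlapping phases at row {row}")

    windows: list[TrialWindow] = []
    i = 0
    while i < len(ev):
        row = ev.iloc[i]
        if row.phase == "adaptation":
            i += 1
            continue
        if row.phase == "stationary":
            raise ValueError(
                f"stationary phase without preceding motion phase at row {i}")
        if i + 1 >= len(ev):
            raise ValueError(f"motion phase without following stationary phase at row {i}")
        nxt = ev.iloc[i + 1]
        if nxt.phase != "stationary" or nxt.direction != row.direction:
            raise ValueError(
                f"motion phase at row {i} not followed by a stationary phase "
                f"of direction {row.direction!r}")
        windows.append(TrialWindow(
            direction=row.direction,
            motion=(float(row.t_start), float(row.t_end)),
            stationary=(float(nxt.t_start), float(nxt.t_end)),
            series_index=int(row.series_index),
        ))
        i += 2
    return windows


def bin_counts(
    spikes: np.ndarray | list[float],
    window: tuple[float, float],
    bin_width: float = BIN_WIDTH_S,
    analysis_span: float = PHASE_S,
) -> tuple[int, int]:
    """Occupied-bin count over the first ``analysis_span`` of a window.

    Bins are half-open ``[t0 + i*bin_width, t0 + (i+1)*bin_width)``,
    0-based from the window onset; ``k`` counts bins containing at least
    one spike (not spikes), ``n = analysis_span / bin_width`` (2500 for
    the defaults). Windows longer than the span (e.g. 6 s phases) are
    truncated to its first ``analysis_span`` seconds.
    """
    t0, t1 = window
    if t1 - t0 < analysis_span - 1e-9:
        raise ValueError(
            f"window of {t1 - t0:.3f} s is shorter than the {analysis_span} s analysis span")
    n = round(analysis_span / bin_width)
    s = np.asarray(spikes, dtype=float)
    idx = np.floor((s - t0) / bin_width).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    return int(np.unique(idx).size), n


def pool_direction(
    trials: list[tuple[str, tuple[int, int, int, int]]] | list[TrialCounts],
    neuron_id: str = "",
) -> TrialCounts:
    """Pool per-trial (direction, (k_m, n_m, k_s, n_s)) counts over trials.

    All trials must share one direction; counts are summed per phase and
    the per-trial quadruples retained.
    """
    if not trials:
        raise ValueError("cannot pool an empty trial list")
    directions = {t[0] for t in trials}
    if len(directions) != 1:
        raise ValueError(f"mixed directions in pooled input: {sorted(directions)}")
    quads = [tuple(int(v) for v in t[1]) for t in trials]
    km, nm, ks, ns = (sum(q[i] for q in quads) for i in range(4))
    return TrialCounts(
        neuron_id=neuron_id, direction=directions.pop(),
        k_motion=km, n_motion=nm, k_stationary=ks, n_stationary=ns,
        per_trial=quads,
    )


def counts_from_trace(
    trace: VoltageTrace,
    events: pd.DataFrame,
    threshold: float,
    neuron_id: str = "",
    median_window: float = 0.5,
    bin_width: float = BIN_WIDTH_S,
    analysis_span: float = PHASE_S,
) -> dict[str, TrialCounts]:
    """Full path from a raw trace + event table to pooled per-direction counts."""
    spikes = detect_spikes(trace, threshold, median_window=median_window)
    windows = segment_trials(events)
    by_direction: dict[str, list] = {}
    for w in windows:
        km, nm = bin_counts(spikes, w.motion, bin_width, analysis_span)
        ks, ns = bin_counts(spikes, w.stationary, bin_width, analysis_span)
        by_direction.setdefault(w.direction, []).append((w.direction, (km, nm, ks, ns)))
    return {
        d: pool_direction(trials, neuron_id=neuron_id)
        for d, trials in by_direction.items()
    }


# ---------------------------------------------------------------------------
# tabular input/output (same delimited schema the synthetic generator emits)

def counts_table_to_trialcounts(table: pd.DataFrame) -> dict[str, dict[str, TrialCounts]]:
    """Nested {neuron_id: {direction: TrialCounts}} from a trial-count table."""
    missing = set(TRIAL_COUNT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    out: dict[str, dict[str, TrialCounts]] = {}
    for (nid, direction), g in table.groupby(["neuron_id", "direction"], sort=False):
        trials = [
            (direction, (r.k_motion, r.n_motion, r.k_stationary, r.n_stationary))
            for r in g.sort_values("trial_index").itertuples()
        ]
        out.setdefault(str(nid), {})[str(direction)] = pool_direction(trials, str(nid))
    return out


def read_trial_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_trial_counts_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_voltage_trace(path: str | Path) -> VoltageTrace:
    """Read a two-column (time_s, mV) delimited text trace."""
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] < 2:
        raise ValueError("expected two columns: time_s, voltage_mv")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    v = df.iloc[:, 1].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("time column must be uniformly sampled")
    return VoltageTrace(samples=v, sample_rate=1.0 / dt[0], start_time=float(t[0]))


def write_voltage_trace(path: str | Path, trace: VoltageTrace) -> None:
    pd.DataFrame({"time_s": trace.times, "voltage_mv": trace.samples}).to_csv(
        path, sep="\t", index=False)


def read_event_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
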