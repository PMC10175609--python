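"""Synthetic-data generators with known ground truth.

Emulates the structure of intracellular recordings from central-complex
neurons under visual self-motion stimulation: trial-structured spike
counts in 2 ms bins (alternating 5 s motion / 5 s stationary phases,
2-5 trials per motion direction, eight directions in four categories),
raw voltage traces with superimposed spikes, labeled neuron populations,
and discrete heading trajectories for the compass-model simulation.

Every generator is deterministic for a fixed seed; generated datasets
carry their ground-truth Bernoulli rates so recovery can be tested.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DIRECTIONS: tuple[str, ...] = (
    "forward",
    "backward",
    "yaw_left",
    "yaw_right",
    "lift_up",
    "lift_down",
    "roll_ccw",
    "roll_cw",
)

#: Four self-motion categories, each a pair of opposing directions (A, B).
CATEGORIES: dict[str, tuple[str, str]] = {
    "translation": ("forward", "backward"),
    "yaw": ("yaw_left", "yaw_right"),
    "lift": ("lift_up", "lift_down"),
    "roll": ("roll_ccw", "roll_cw"),
}

NEURON_CLASSES: tuple[str, ...] = (
    "TL", "CL1a", "CL2", "TB1", "CPU1", "CPU2", "CPU5", "CP1", "CP2", "PoU", "TU",
)

CHIRALITIES = ("left", "right", "unknown")

#: Analysis constants: 2 ms bins over the 5 s analysis window of each phase.
BIN_WIDTH_S = 0.002
PHASE_S = 5.0
BINS_PER_PHASE = round(PHASE_S / BIN_WIDTH_S)  # 2500

TRIAL_COUNT_COLUMNS = [
    "neuron_id", "class_label", "chirality", "direction", "trial_index",
    "k_motion", "n_motion", "k_stationary", "n_stationary",
]


@dataclass(frozen=True)
class GroundTruthRates:
    """Per-2-ms-bin firing probabilities for one motion direction.

    ``r_motion`` / ``r_stationary`` are the probabilities of observing at
    least one spike in a 2 ms bin during the motion / stationary phase.
    """

    direction_label: str
    r_motion: float
    r_stationary: float

    def __post_init__(self) -> None:
        if self.direction_label not in DIRECTIONS:
            raise ValueError(f"unknown direction: {self.direction_label!r}")
        for name in ("r_motion", "r_stationary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SyntheticNeuronSpec:
    """Ground-truth description of one synthetic neuron."""

    neuron_id: str
    class_label: str
    rates: dict[str, GroundTruthRates]
    n_trials: int = 3
    chirality: str = "unknown"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron class: {self.class_label!r}")
        if self.chirality not in CHIRALITIES:
            raise ValueError(f"unknown chirality: {self.chirality!r}")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        for d, r in self.rates.items():
            if d not in DIRECTIONS:
                raise ValueError(f"unknown direction key: {d!r}")
            if r.direction_label != d:
                raise ValueError(f"rates key {d!r} holds rates for {r.direction_label!r}")


@dataclass(frozen=True)
class TrajectorySpec:
    """Ordered (command, n_steps) segments of a discrete heading trajectory."""

    segments: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        total = 0
        for cmd, n in self.segments:
            if cmd not in ("forward", "turn_left", "turn_right"):
                raise ValueError(f"unknown command: {cmd!r}")
            if n < 0:
                raise ValueError("segment length must be >= 0")
            total += n
        if total < 1:
            raise ValueError("trajectory must contain at least one step")


def _direction_rng(spec: SyntheticNeuronSpec, direction: str) -> np.random.Generator:
    # independent, reproducible substream per (neuron seed, direction)
    return np.random.default_rng([spec.seed, DIRECTIONS.index(direction)])


def gen_trial_counts(
    spec: SyntheticNeuronSpec,
    direction: str,
    *,
    refractory_rho: float = 0.0,
) -> list[tuple[int, int, int, int]]:
    """Per-trial Bernoulli bin counts (k_motion, n_motion, k_stat, n_stat).

    Each phase contributes ``n = 2500`` bins (5 s at 2 ms); ``k`` is
    binomially distributed with the neuron's ground-truth rate. Bins are
    independent by default, matching the Bernoulli observation model of
    the analysis. ``refractory_rho`` in (0, 1] optionally suppresses the
    spike probability in the bin following a spike bin by that factor,
    for robustness testing of the independence assumption.
    """
    if direction not in spec.rates:
        raise KeyError(f"direction {direction!r} not present for neuron {spec.neuron_id}")
    rates = spec.rates[direction]
    rng = _direction_rng(spec, direction)
    n = BINS_PER_PHASE
    out = []
    for _ in range(spec.n_trials):
        ks = []
        for r in (rates.r_motion, rates.r_stationary):
            if refractory_rho > 0.0 and r > 0.0:
                bins = np.empty(n, dtype=bool)
                prev = False
                draws = rng.random(n)
                for i in range(n):
                    p = r * (1.0 - refractory_rho) if prev else r
                    prev = bins[i] = draws[i] < p
                ks.append(int(bins.sum()))
            else:
                ks.append(int(rng.binomial(n, r)))
        out.append((ks[0], n, ks[1], n))
    return out


def spike_waveform(sample_rate: float, amplitude_mv: float, width_s: float = 0.0015) -> np.ndarray:
    """Stereotyped biphasic spike waveform (~1.5 ms), peak-normalized."""
    n = max(int(round(width_s * sample_rate)), 3)
    t = np.linspace(0.0, 1.0, n)
    # fast positive lobe followed by a shallower negative lobe
    w = np.sin(2 * np.pi * t) * np.exp(-3.0 * t)
    return amplitude_mv * w / np.abs(w).max()


def gen_voltage_trace(
    spike_times: np.ndarray | list[float],
    duration: float,
    sample_rate: float = 20_000.0,
    spike_amplitude: float = 30.0,
    noise_sd: float = 1.0,
    drift_amplitude: float = 3.0,
    drift_period: float = 4.0,
    baseline_mv: float = -55.0,
    seed: int | None = 0,
):
    """Synthetic intracellular trace: drift + noise + biphasic spikes.

    Returns ``(trace, spike_times)`` where ``trace`` is a
    :class:`cxcompass.spikes.VoltageTrace` and ``spike_times`` the
    ground-truth times actually embedded (sorted, seconds).
    """
    from .spikes import VoltageTrace  # local import to avoid cycle

    if sample_rate < 5_000.0:
        raise ValueError("sample_rate must be >= 5 kHz to resolve 1-2 ms spikes")
    spike_times = np.sort(np.asarray(spike_times, dtype=float))
    if spike_times.size and (spike_times.min() < 0 or spike_times.max() > duration):
        raise ValueError("spike times must lie within [0, duration]")
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    trace = np.full(n, baseline_mv)
    if drift_amplitude > 0:
        trace = trace + drift_amplitude * np.sin(2 * np.pi * t / drift_period)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n)
    w = spike_waveform(sample_rate, spike_amplitude)
    for ts in spike_times:
        i0 = int(round(ts * sample_rate))
        i1 = min(i0 + w.size, n)
        trace[i0:i1] += w[: i1 - i0]
    return VoltageTrace(samples=trace, sample_rate=sample_rate), spike_times


@dataclass(frozen=True)
class RateProfile:
    """How a class's synthetic rates are drawn: baseline plus modulation."""

    baseline_low: float = 0.02
    baseline_high: float = 0.06
    excited_factor: float = 2.5
    inhibited_factor: float = 0.4


def _flat_rates(baseline: float) -> dict[str, GroundTruthRates]:
    return {d: GroundTruthRates(d, baseline, baseline) for d in DIRECTIONS}


def mirrored_cl2_pair(
    baseline_a: float,
    baseline_b: float,
    profile: RateProfile,
    n_trials: int,
    seed_a: int,
    seed_b: int,
) -> tuple[SyntheticNeuronSpec, SyntheticNeuronSpec]:
    """A CL2 pair with mirrored yaw-direction selectivity.

    Neuron A (right-hemisphere PB arbor) fires more during simulated
    right turns and less during left turns; neuron B is its mirror
    image — emulating the opposite-polarity yaw tuning of the two
    recorded CL2 cells.
    """
    def build(neuron_id, chirality, baseline, up_dir, down_dir, seed):
        rates = _flat_rates(baseline)
        rates[up_dir] = GroundTruthRates(
            up_dir, min(1.0, baseline * profile.excited_factor), baseline)
        rates[down_dir] = GroundTruthRates(
            down_dir, baseline * profile.inhibited_factor, baseline)
        return SyntheticNeuronSpec(
            neuron_id=neuron_id, class_label="CL2", rates=rates,
            n_trials=n_trials, chirality=chirality, seed=seed)

    a = build("CL2_mirror_R", "right", baseline_a, "yaw_right", "yaw_left", seed_a)
    b = build("CL2_mirror_L", "left", baseline_b, "yaw_left", "yaw_right", seed_b)
    return a, b


def gen_population(
    n_per_class: dict[str, int],
    rate_profiles: dict[str, RateProfile] | None = None,
    seed: int = 0,
    n_trials: int = 3,
) -> list[SyntheticNeuronSpec]:
    """Deterministic labeled population of synthetic neurons.

    Most neurons are non-responsive (motion rate equals stationary rate,
    drawn uniformly from the class's baseline range). Whenever at least
    two CL2 neurons are requested, the first two form a
    direction-selective pair with mirrored yaw preferences.
    """
    rate_profiles = rate_profiles or {}
    rng = np.random.default_rng(seed)
    population: list[SyntheticNeuronSpec] = []
    for cls in NEURON_CLASSES:  # fixed order => determinism
        count = n_per_class.get(cls, 0)
        if count <= 0:
            continue
        profile = rate_profiles.get(cls, RateProfile())
        baselines = rng.uniform(profile.baseline_low, profile.baseline_high, size=count)
        seeds = rng.integers(0, 2**31 - 1, size=count)
        start = 0
        if cls == "CL2" and count >= 2:
            a, b = mirrored_cl2_pair(
                baselines[0], baselines[1], profile, n_trials,
                int(seeds[0]), int(seeds[1]))
            population.extend([a, b])
            start = 2
        for i in range(start, count):
            chirality = "left" if rng.random() < 0.5 else "right"
            population.append(SyntheticNeuronSpec(
                neuron_id=f"{cls}_{i:02d}",
                class_label=cls,
                rates=_flat_rates(float(baselines[i])),
                n_trials=n_trials,
                chirality=chirality,
                seed=int(seeds[i]),
            ))
    return population


def gen_trajectory(spec: TrajectorySpec) -> list[str]:
    """Flatten a trajectory spec into a per-step command list."""
    out: list[str] = []
    for cmd, n in spec.segments:
        out.extend([cmd] * n)
    return out


def default_trajectory(forward_steps: int = 4, turn_steps: int = 8) -> TrajectorySpec:
    """Forward motion interrupted by a right turn then an equal left turn.

    The default turn block of 8 steps, started from column L4, carries
    the compass bump across the lateral ends of the PB in both
    directions, and the equal-magnitude turns return it to its starting
    column.
    """
    return TrajectorySpec(segments=(
        ("forward", forward_steps),
        ("turn_right", turn_steps),
        ("forward", forward_steps),
        ("turn_left", turn_steps),
        ("forward", forward_steps),
    ))


# ---------------------------------------------------------------------------
# tabular output

def population_counts_frame(population: list[SyntheticNeuronSpec]) -> pd.DataFrame:
    """Trial-count table for a whole population (analysis input schema)."""
    rows = []
    for spec in population:
        for direction in DIRECTIONS:
            if direction not in spec.rates:
                continue
            for ti, (km, nm, ks, ns) in enumerate(gen_trial_counts(spec, direction)):
                rows.append((spec.neuron_id, spec.class_label, spec.chirality,
                             direction, ti, km, nm, ks, ns))
    return pd.DataFrame(rows, columns=TRIAL_COUNT_COLUMNS)


def ground_truth_frame(population: list[SyntheticNeuronSpec]) -> pd.DataFrame:
    rows = []
    for spec in population:
        for direction, r in spec.rates.items():
            rows.append((spec.neuron_id, spec.class_label, spec.chirality,
                         direction, r.r_motion, r.r_stationary))
    return pd.DataFrame(rows, columns=[
        "neuron_id", "class_label", "chirality", "direction",
        "r_motion", "r_stationary"])


def write_trial_counts(path: str | Path, population: list[SyntheticNeuronSpec]) -> None:
    population_counts_frame(population).to_csv(path, sep="\t", index=False)


def write_ground_truth(path: str | Path, population: list[SyntheticNeuronSpec]) -> None:
    ground_truth_frame(population).to_csv(path, sep="\t", index=False)


def population_from_config(config: dict, seed: int | None = None) -> list[SyntheticNeuronSpec]:
    """Build a population from a plain dict (JSON/YAML config block)."""
    profiles = {
        cls: RateProfile(**kwargs)
        for cls, kwargs in config.get("rate_profiles", {}).items()
    }
    return gen_population(
        n_per_class=dict(config.get("n_per_class", {})),
        rate_profiles=profiles,
        seed=config.get("seed", 0) if seed is None else seed,
        n_trials=config.get("n_trials", 3),
    )
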