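"""Agent simulation: integrate heading commands with the compass model.

Each simulation step applies the maintenance matrix ``M`` (forward
motion) or a modulated matrix ``M + dM`` (turns) to the network state.
Because the linear fixed points are only numerically approximate, the
state is by default rescaled after every step so the bump peak stays at
amplitude 1; bump positions are scale-invariant, so renormalization
never changes the position trace (tested), it only prevents slow
amplitude drift on long runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .columns import circular_delta, index_to_label, label_to_index
from .network import (
    CompassModel,
    ModulationSet,
    N_UNITS,
    bump_index,
    make_targets,
)

COMMANDS = ("forward", "turn_left", "turn_right")


@dataclass
class SimulationResult:
    """Time-indexed network states and bump traces for a command sequence."""

    commands: list[str]
    states: np.ndarray                      # (len(commands) + 1, 32)
    bump_trace: list[str]                   # CL1a bump column per time point
    bump_trace_cl2: list[str]
    renormalized: bool

    @property
    def bump_indices(self) -> np.ndarray:
        return np.array([label_to_index(lab) for lab in self.bump_trace])

    def states_frame(self) -> pd.DataFrame:
        from .columns import PB_LABELS
        cols = [f"CL1a_{lab}" for lab in PB_LABELS] + [f"CL2_{lab}" for lab in PB_LABELS]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "command", ["start"] + list(self.commands))
        df.insert(1, "bump_cl1a", self.bump_trace)
        df.insert(2, "bump_cl2", self.bump_trace_cl2)
        return df


def simulate(
    model: CompassModel,
    modulations: ModulationSet,
    trajectory: list[str],
    start_column: str = "L4",
    x0: np.ndarray | None = None,
    renormalize: bool = True,
) -> SimulationResult:
    """Run a commanded trajectory from a bump target at ``start_column``.

    ``trajectory`` is a flat list of ``forward`` / ``turn_left`` /
    ``turn_right`` commands (see ``synthetic.gen_trajectory``).
    """
    if x0 is None:
        targets = make_targets(model.mask.matrix.shape[0] // 2)
        x0 = targets.target(start_column)
    x = np.asarray(x0, dtype=float).copy()
    if x.shape[0] != N_UNITS:
        raise ValueError(f"x0 must have {N_UNITS} components")
    matrices = {
        "forward": model.weights,
        "turn_left": model.weights + modulations.left.delta,
        "turn_right": model.weights + modulations.right.delta,
    }
    states = [x.copy()]
    for cmd in trajectory:
        if cmd not in COMMANDS:
            raise ValueError(f"unknown command: {cmd!r}")
        x = matrices[cmd] @ x
        if renormalize:
            peak = np.abs(x).max()
            if peak > 0:
                x = x / peak
        states.append(x.copy())
    states = np.asarray(states)
    trace_cl1a, trace_cl2 = [], []
    for s in states:
        trace_cl1a.append(index_to_label(bump_index(s, "CL1a")[0]))
        trace_cl2.append(index_to_label(bump_index(s, "CL2")[0]))
    return SimulationResult(
        commands=list(trajectory), states=states,
        bump_trace=trace_cl1a, bump_trace_cl2=trace_cl2,
        renormalized=renormalize,
    )


def bump_displacement(result: SimulationResult, step: int) -> int:
    """Signed circular bump movement (columns) at simulation step ``step``.

    ``step`` is 1-based over the command sequence; positive means
    movement toward higher column index (the L8 -> R8 direction), and a
    transition across the lateral ends (e.g. L8 -> R8) counts as the
    single-column wrap it is, -1.
    """
    if not 1 <= step <= len(result.commands):
        raise ValueError(f"step must be in [1, {len(result.commands)}]")
    idx = result.bump_indices
    return circular_delta(int(idx[step]), int(idx[step - 1]))


def net_displacement(result: SimulationResult) -> int:
    """Total signed circular displacement from start to end of the run."""
    idx = result.bump_indices
    return sum(bump_displacement(result, s) for s in range(1, len(result.commands) + 1)) \
        if len(idx) else 0
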