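"""Protocerebral-bridge column bookkeeping.

The PB is modeled with 16 columns labeled, from left to right,
``L8, L7, ..., L1, R1, ..., R8``. Internally these map to 0-based
positions 0..15. The bridge is an open structure (no anatomical
adjacency between L8 and R8); circular arithmetic is nevertheless
used for bump displacements because the heading variable itself is
circular and the network realizes the wrap functionally.
"""

from __future__ import annotations

N_COLUMNS = 16

PB_LABELS: tuple[str, ...] = tuple(
    [f"L{i}" for i in range(8, 0, -1)] + [f"R{i}" for i in range(1, 9)]
)

_LABEL_TO_INDEX = {lab: i for i, lab in enumerate(PB_LABELS)}


def label_to_index(label: str) -> int:
    """0-based PB position of a column label (L8 -> 0, ..., R8 -> 15)."""
    try:
        return _LABEL_TO_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown PB column label: {label!r}") from None


def index_to_label(index: int) -> str:
    if not 0 <= index < N_COLUMNS:
        raise ValueError(f"PB position out of range [0, {N_COLUMNS}): {index}")
    return PB_LABELS[index]


def hemisphere(label: str) -> str:
    label_to_index(label)
    return "left" if label.startswith("L") else "right"


def circular_delta(pos_to: int, pos_from: int, n: int = N_COLUMNS) -> int:
    """Signed circular column difference in (-n/2, n/2].

    Positive = movement toward higher index (L8 -> R8 direction).
    """
    d = (pos_to - pos_from) % n
    if d > n // 2:
        d -= n
    return d
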