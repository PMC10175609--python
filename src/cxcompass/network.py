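"""The CL1a-CL2 compass network: masked linear recurrence and optimization.

The model holds 16 CL1a and 16 CL2 neurons, one per protocerebral-
bridge column (L8..L1, R1..R8), with state vector ``x`` (components
0..15 CL1a, 16..31 CL2) evolving linearly, ``x_{t+1} = M x_t``. The
connectivity ``M`` is constrained by reported arborization widths
through a boolean mask:

* CL1a -> CL2 (in the PB): same column only (identity pattern);
* CL1a -> CL1a and CL2 -> CL2: self plus adjacent PB columns, with no
  wrap between L8 and R8 (the bridge is open);
* CL2 -> CL1a (in the CBL): bands of configurable half-width (default
  2, i.e. a five-column footprint) around both the same-column diagonal
  and the hemisphere-mirror anti-diagonal, abstracting the intercalated
  contralateral projection scheme;
* the ``"noduli"`` variant additionally allows every same-hemisphere
  CL2 -> CL2 pair (putative coupling through the noduli).

Weights are found in two phases, both deterministic L-BFGS runs from a
fixed sign-template initialization (+0.5 excitatory, -0.5 inhibitory):
a structure phase minimizing the mean-squared deviation of 16
sinusoidal bump targets from their one- and two-step network images
plus a quadratic weight penalty (weight ``lam``, which selects the
essential connectivity), then a fit-only polish that drives the
residual to numerical precision without disturbing that structure.
Signs are never constrained during optimization; the excitatory /
inhibitory layout of the solution is emergent. Turn dynamics are
additive mask-respecting modulations ``M + dM`` optimized against
cyclically shifted targets; a constant feed-forward input is optimized
the same way as a control.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .columns import N_COLUMNS, PB_LABELS, index_to_label, label_to_index

N_UNITS = 2 * N_COLUMNS
VARIANTS = ("default", "noduli")
POPULATION_SLICES = {"CL1a": slice(0, N_COLUMNS), "CL2": slice(N_COLUMNS, N_UNITS)}


class DegenerateStateError(ValueError):
    """Raised when a network state has no usable activity maximum."""


@dataclass(frozen=True)
class ConnectivityMask:
    """Boolean allowed-synapse matrix; entry [i, j] permits j -> i."""

    matrix: np.ndarray
    variant: str
    band_halfwidth: int = 2

    def __post_init__(self) -> None:
        if self.matrix.shape != (N_UNITS, N_UNITS):
            raise ValueError(f"mask must be {N_UNITS}x{N_UNITS}")

    @property
    def n_free(self) -> int:
        return int(self.matrix.sum())


def build_mask(variant: str = "default", band_halfwidth: int = 2) -> ConnectivityMask:
    """Anatomically constrained synapse mask for a model variant."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    n = N_COLUMNS
    i = np.arange(n)
    col_i, col_j = np.meshgrid(i, i, indexing="ij")
    same_type = np.abs(col_i - col_j) <= 1  # self + adjacent column, open ends
    mask = np.zeros((N_UNITS, N_UNITS), dtype=bool)
    mask[:n, :n] = same_type                  # CL1a -> CL1a
    mask[n:, n:] = same_type                  # CL2 -> CL2
    mask[n:, :n] = np.eye(n, dtype=bool)      # CL1a -> CL2, same PB column
    # CL2 -> CL1a: five-column CBL footprint as same-column and mirror bands
    mirror_j = n - 1 - col_j
    band = (np.abs(col_i - col_j) <= band_halfwidth) | \
           (np.abs(col_i - mirror_j) <= band_halfwidth)
    mask[:n, n:] = band
    if variant == "noduli":
        hemi = np.zeros((n, n), dtype=bool)
        hemi[: n // 2, : n // 2] = True       # left-hemisphere CL2 pool
        hemi[n // 2:, n // 2:] = True         # right-hemisphere CL2 pool
        mask[n:, n:] |= hemi
    return ConnectivityMask(matrix=mask, variant=variant,
                            band_halfwidth=band_halfwidth)


@dataclass(frozen=True)
class TargetSet:
    """16 sinusoidal bump states, one activity maximum per PB column.

    Column ``c`` of ``matrix`` (shape 32 x 16) is the target with its
    bump at PB position ``c``; the CL1a and CL2 subvectors are equal.
    """

    matrix: np.ndarray
    n_columns: int = N_COLUMNS

    def target(self, column: int | str) -> np.ndarray:
        c = label_to_index(column) if isinstance(column, str) else int(column)
        return self.matrix[:, c].copy()

    def shifted(self, steps: int) -> np.ndarray:
        """Target matrix with every bump moved ``steps`` columns (cyclic)."""
        cols = (np.arange(self.n_columns) + steps) % self.n_columns
        return self.matrix[:, cols]


def make_targets(n_columns: int = N_COLUMNS, profile: str = "cosine") -> TargetSet:
    """Sinusoidal bump targets spanning one full period across the PB.

    ``x_c(j) = cos(2*pi*(j - c) / n_columns)`` for CL1a positions ``j``,
    duplicated for the CL2 subvector — a single 360-degree heading
    representation across the bridge.
    """
    if n_columns < 4:
        raise ValueError("need at least 4 columns for a meaningful bump")
    if profile != "cosine":
        raise ValueError(f"unknown profile: {profile!r}")
    j = np.arange(n_columns)
    half = np.cos(2 * np.pi * (j[:, None] - j[None, :]) / n_columns)
    return TargetSet(matrix=np.vstack([half, half]), n_columns=n_columns)


@dataclass
class CompassModel:
    """Optimized masked connectivity with its fitting metadata."""

    weights: np.ndarray
    mask: ConnectivityMask
    lam: float
    metadata: dict = field(default_factory=dict)

    @property
    def variant(self) -> str:
        return self.mask.variant

    def __post_init__(self) -> None:
        off = ~self.mask.matrix
        if np.any(self.weights[off] != 0.0):
            raise ValueError("weights present outside the connectivity mask")


@dataclass
class ShiftModulation:
    """Additive connectivity modulation realizing one turn direction."""

    delta: np.ndarray
    direction: str
    fit_loss: float
    metadata: dict = field(default_factory=dict)

    @property
    def shift_steps(self) -> int:
        return +1 if self.direction == "left" else -1


@dataclass
class ModulationSet:
    left: ShiftModulation
    right: ShiftModulation


@dataclass
class FeedforwardResult:
    """Best constant input vector against shifted targets (control)."""

    u: np.ndarray
    direction: str
    fit_loss: float
    baseline_loss: float


def step(model: CompassModel | np.ndarray, x: np.ndarray) -> np.ndarray:
    """One linear update ``x_{t+1} = M x_t``."""
    m = model.weights if isinstance(model, CompassModel) else np.asarray(model)
    x = np.asarray(x, dtype=float)
    if m.shape[1] != x.shape[0]:
        raise ValueError(f"dimension mismatch: M is {m.shape}, x has {x.shape[0]}")
    return m @ x


def init_template(mask: ConnectivityMask) -> np.ndarray:
    """Uniform signed initialization: CL1a output and same-type synapses
    +0.5 (excitatory), CL2 -> CL1a synapses -0.5 (inhibitory)."""
    n = N_COLUMNS
    m0 = np.where(mask.matrix, 0.5, 0.0)
    m0[:n, n:] = np.where(mask.matrix[:n, n:], -0.5, 0.0)
    return m0


def _two_step_objective(idx, X, Y1, Y2, w_fit, w_reg):
    """Closure computing loss and gradient over free (masked) weights."""

    def fun(m_free):
        m = np.zeros((N_UNITS, N_UNITS))
        m[idx] = m_free
        mx = m @ X
        r1 = mx - Y1
        r2 = m @ mx - Y2
        f = w_fit * ((r1 ** 2).sum() + (r2 ** 2).sum()) + w_reg * (m_free ** 2).sum()
        g = w_fit * 2.0 * (r1 @ X.T + m.T @ r2 @ X.T + r2 @ mx.T)
        return f, g[idx] + 2.0 * w_reg * m_free

    return fun


def _optimize_masked(
    mask: ConnectivityMask,
    X: np.ndarray,
    Y1: np.ndarray,
    Y2: np.ndarray,
    m_init: np.ndarray,
    lam: float,
    maxiter: int = 5000,
    polish: bool = True,
) -> tuple[np.ndarray, dict]:
    """Two-phase L-BFGS over the masked entries; returns (M, info)."""
    idx = np.where(mask.matrix)
    n_comp = X.size
    w_fit = 1.0 / (2.0 * n_comp)  # mean over targets, steps, components

    info: dict = {"lam": lam, "losses": {}}
    fun = _two_step_objective(idx, X, Y1, Y2, w_fit, lam / mask.n_free)
    res = minimize(fun, m_init[idx], jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12})
    info["losses"]["structure"] = float(res.fun)
    info["iterations"] = int(res.nit)
    m_free = res.x
    if polish:
        fun2 = _two_step_objective(idx, X, Y1, Y2, w_fit, 0.0)
        res2 = minimize(fun2, m_free, jac=True, method="L-BFGS-B",
                        options={"maxiter": 4 * maxiter, "ftol": 1e-18,
                                 "gtol": 1e-14})
        info["losses"]["polish"] = float(res2.fun)
        info["iterations"] += int(res2.nit)
        m_free = res2.x
        converged = res.success or res2.success
    else:
        converged = res.success
    if not converged:
        warnings.warn(
            "L-BFGS did not report convergence; loss trace: "
            f"{info['losses']}", RuntimeWarning)
    info["converged"] = bool(converged)
    m = np.zeros((N_UNITS, N_UNITS))
    m[idx] = m_free
    fit_only = _two_step_objective(idx, X, Y1, Y2, w_fit, 0.0)
    info["fit_loss"] = float(fit_only(m_free)[0])
    return m, info


def maintenance_fit_loss(weights: np.ndarray, targets: TargetSet) -> float:
    """Mean-squared deviation of the targets over one and two steps."""
    X = targets.matrix
    r1 = weights @ X - X
    r2 = weights @ weights @ X - X
    return float(((r1 ** 2).sum() + (r2 ** 2).sum()) / (2.0 * X.size))


def optimize_maintenance(
    mask: ConnectivityMask,
    targets: TargetSet,
    lam: float = 0.15,
    init: np.ndarray | None = None,
    maxiter: int = 5000,
    polish: bool = True,
) -> CompassModel:
    """Optimize the masked connectivity so every bump target is a fixed point.

    Minimizes the mean-squared one- and two-step deviation of all 16
    targets plus ``lam`` times the mean squared free weight (structure
    phase), then polishes the fit alone. The returned model's metadata
    records both losses, the iteration count, and the emergent sign
    structure of the solution.
    """
    X = targets.matrix
    m_init = init if init is not None else init_template(mask)
    m, info = _optimize_masked(mask, X, X, X, m_init, lam,
                               maxiter=maxiter, polish=polish)
    info["max_fixed_point_error"] = float(np.abs(m @ X - X).max())
    info["sign_structure"] = sign_structure_report(m)
    return CompassModel(weights=m, mask=mask, lam=lam, metadata=info)


def optimize_shift(
    model: CompassModel,
    targets: TargetSet,
    direction: str,
    lam_mod: float | None = None,
    maxiter: int = 5000,
    polish: bool = True,
) -> ShiftModulation:
    """Optimize an additive modulation shifting every bump one column per step.

    For a left turn the bump moves toward higher column index (the
    L8 -> R8 direction), for a right turn the opposite; targets wrap
    cyclically across the open lateral ends of the bridge, so the
    network must realize the wrap through its internal structure.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    s = +1 if direction == "left" else -1
    lam_mod = model.lam if lam_mod is None else lam_mod
    X = targets.matrix
    Y1 = targets.shifted(s)
    Y2 = targets.shifted(2 * s)
    idx = np.where(model.mask.matrix)
    n_comp = X.size
    w_fit = 1.0 / (2.0 * n_comp)

    def fun_factory(w_reg):
        def fun(dm_free):
            a = model.weights.copy()
            a[idx] += dm_free
            ax = a @ X
            r1 = ax - Y1
            r2 = a @ ax - Y2
            f = w_fit * ((r1 ** 2).sum() + (r2 ** 2).sum()) + w_reg * (dm_free ** 2).sum()
            g = w_fit * 2.0 * (r1 @ X.T + a.T @ r2 @ X.T + r2 @ ax.T)
            return f, g[idx] + 2.0 * w_reg * dm_free
        return fun

    res = minimize(fun_factory(lam_mod / model.mask.n_free), np.zeros(len(idx[0])),
                   jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12})
    dm_free = res.x
    info = {"losses": {"structure": float(res.fun)}, "iterations": int(res.nit),
            "lam_mod": lam_mod}
    if polish:
        res2 = minimize(fun_factory(0.0), dm_free, jac=True, method="L-BFGS-B",
                        options={"maxiter": 4 * maxiter, "ftol": 1e-18,
                                 "gtol": 1e-14})
        dm_free = res2.x
        info["losses"]["polish"] = float(res2.fun)
        info["iterations"] += int(res2.nit)
    fit_loss = float(fun_factory(0.0)(dm_free)[0])
    if not (res.success or polish):
        warnings.warn("shift optimization did not report convergence",
                      RuntimeWarning)
    delta = np.zeros((N_UNITS, N_UNITS))
    delta[idx] = dm_free
    return ShiftModulation(delta=delta, direction=direction,
                           fit_loss=fit_loss, metadata=info)


def optimize_modulations(model: CompassModel, targets: TargetSet,
                         lam_mod: float | None = None) -> ModulationSet:
    return ModulationSet(
        left=optimize_shift(model, targets, "left", lam_mod),
        right=optimize_shift(model, targets, "right", lam_mod),
    )


def optimize_feedforward(
    model: CompassModel,
    targets: TargetSet,
    direction: str,
    lam_mod: float | None = None,
    maxiter: int = 5000,
) -> FeedforwardResult:
    """Best constant input ``u`` under ``x_{t+1} = M x_t + u`` (control).

    Optimized against the same shifted targets as the modulatory
    mechanism; its loss quantifies how far a purely feed-forward drive
    falls short of shifting the bump.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    s = +1 if direction == "left" else -1
    lam_mod = model.lam if lam_mod is None else lam_mod
    X = targets.matrix
    Y1 = targets.shifted(s)
    Y2 = targets.shifted(2 * s)
    M = model.weights
    MX = M @ X
    M2X = M @ MX
    B = M + np.eye(N_UNITS)
    n_comp = X.size
    w_fit = 1.0 / (2.0 * n_comp)
    n_t = X.shape[1]

    def fun_factory(w_reg):
        def fun(u):
            r1 = MX + u[:, None] - Y1
            r2 = M2X + (B @ u)[:, None] - Y2
            f = w_fit * ((r1 ** 2).sum() + (r2 ** 2).sum()) + w_reg * (u ** 2).sum()
            g = w_fit * 2.0 * (r1.sum(axis=1) + B.T @ r2.sum(axis=1))
            return f, g + 2.0 * w_reg * u
        return fun

    res = minimize(fun_factory(lam_mod / N_UNITS), np.zeros(N_UNITS), jac=True,
                   method="L-BFGS-B",
                   options={"maxiter": maxiter, "ftol": 1e-15, "gtol": 1e-12})
    res2 = minimize(fun_factory(0.0), res.x, jac=True, method="L-BFGS-B",
                    options={"maxiter": 4 * maxiter, "ftol": 1e-18, "gtol": 1e-14})
    baseline = float(fun_factory(0.0)(np.zeros(N_UNITS))[0])
    return FeedforwardResult(u=res2.x, direction=direction,
                             fit_loss=float(res2.fun), baseline_loss=baseline)


def bump_index(
    x: np.ndarray,
    population: str = "CL1a",
    degeneracy_tol: float = 1e-9,
) -> tuple[int, bool]:
    """Argmax PB position of a population subvector, plus a degeneracy flag.

    Ties break toward the lower index; the flag marks a non-unique
    maximum (within ``degeneracy_tol``). An all-equal state raises
    :class:`DegenerateStateError`.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[0] != N_UNITS:
        raise ValueError(f"state must have {N_UNITS} components")
    sub = x[POPULATION_SLICES[population]]
    if np.ptp(sub) <= degeneracy_tol:
        raise DegenerateStateError("state has no activity maximum (all-equal)")
    imax = int(np.argmax(sub))
    degenerate = bool(np.sum(sub >= sub[imax] - degeneracy_tol) > 1)
    return imax, degenerate


def bump_position(x: np.ndarray, population: str = "CL1a") -> str:
    """PB column label of the activity maximum of the chosen population."""
    imax, _ = bump_index(x, population)
    return index_to_label(imax)


# ---------------------------------------------------------------------------
# structure reporting and symmetry helpers

def sign_structure_report(weights: np.ndarray) -> dict:
    """Emergent excitation/inhibition layout of an optimized matrix.

    Reported, not enforced: whether all CL1a -> CL2 synapses came out
    excitatory, and whether the CL2 -> CL1a same-column band is
    excitatory while the mirror (anti-diagonal) band is inhibitory.
    Entries below ``tol`` are treated as absent.
    """
    n = N_COLUMNS
    tol = 1e-6
    cl1a_to_cl2 = weights[n:, :n]
    cl2_to_cl1a = weights[:n, n:]
    i = np.arange(n)
    col_i, col_j = np.meshgrid(i, i, indexing="ij")
    main_band = np.abs(col_i - col_j) <= 2
    anti_band = np.abs(col_i - (n - 1 - col_j)) <= 2
    main_only = main_band & ~anti_band
    anti_only = anti_band & ~main_band
    return {
        "cl1a_to_cl2_all_excitatory": bool(
            (cl1a_to_cl2[np.abs(cl1a_to_cl2) > tol] > 0).all()),
        "cl2_to_cl1a_main_band_excitatory": bool(
            (cl2_to_cl1a[main_only & (np.abs(cl2_to_cl1a) > tol)] > 0).all()),
        "cl2_to_cl1a_mirror_band_inhibitory": bool(
            (cl2_to_cl1a[anti_only & (np.abs(cl2_to_cl1a) > tol)] < 0).all()),
    }


def quadrant_rotated(matrix: np.ndarray) -> np.ndarray:
    """Each 16x16 quadrant rotated by 180 degrees (left/right turn symmetry)."""
    n = N_COLUMNS
    out = np.empty_like(matrix)
    for r in (slice(0, n), slice(n, N_UNITS)):
        for c in (slice(0, n), slice(n, N_UNITS)):
            out[r, c] = matrix[r, c][::-1, ::-1]
    return out


# ---------------------------------------------------------------------------
# persistence: delimited weights + JSON header

def save_model(directory: str | Path, model: CompassModel,
               modulations: ModulationSet | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    np.savetxt(d / "weights.tsv", model.weights, delimiter="\t")
    meta = {
        "variant": model.variant,
        "band_halfwidth": model.mask.band_halfwidth,
        "lam": model.lam,
        "labels": list(PB_LABELS),
        "metadata": _jsonable(model.metadata),
    }
    if modulations is not None:
        np.savetxt(d / "delta_left.tsv", modulations.left.delta, delimiter="\t")
        np.savetxt(d / "delta_right.tsv", modulations.right.delta, delimiter="\t")
        meta["shift_fit_loss"] = {
            "left": modulations.left.fit_loss,
            "right": modulations.right.fit_loss,
        }
    (d / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> tuple[CompassModel, ModulationSet | None]:
    d = Path(directory)
    meta = json.loads((d / "model.json").read_text())
    mask = build_mask(meta["variant"], meta.get("band_halfwidth", 2))
    weights = np.loadtxt(d / "weights.tsv", delimiter="\t")
    weights[~mask.matrix] = 0.0  # clip text round-off outside the mask
    model = CompassModel(weights=weights, mask=mask, lam=meta["lam"],
                         metadata=meta.get("metadata", {}))
    mods = None
    if (d / "delta_left.tsv").exists():
        left = np.loadtxt(d / "delta_left.tsv", delimiter="\t")
        right = np.loadtxt(d / "delta_right.tsv", delimiter="\t")
        losses = meta.get("shift_fit_loss", {})
        mods = ModulationSet(
            left=ShiftModulation(left, "left", losses.get("left", float("nan"))),
            right=ShiftModulation(right, "right", losses.get("right", float("nan"))),
        )
    return model, mods


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
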