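"""Deterministic integration of the toggle-switch ODEs.

The system is awkward for off-the-shelf steady-state detection: it
relaxes quickly onto a slow manifold and then drifts, sometimes
non-monotonically, for very long times before settling — a "false
convergence" trap for solvers that equate a small instantaneous
derivative with stationarity.  Every scheme here therefore assesses
convergence over a trailing time *window*: the run is declared converged
only when the per-species excursion (max minus min) across an entire
window falls below a tolerance, which a slowly drifting state cannot
satisfy.

Three interchangeable schemes share that criterion:

* ``euler`` — fixed-step forward Euler (the reference scheme),
* ``rk4``   — classical fourth-order Runge-Kutta at the same step,
* ``lsoda`` — adaptive stiff/non-stiff solver, continued across windows
  without restarts; the fast choice for large initial-condition grids.

``cross_check`` integrates the same problem with independent schemes and
reports the terminal-state discrepancy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import _kernels
from .model import ModelSpec

__all__ = [
    "SolverSettings",
    "Trajectory",
    "TerminalState",
    "integrate",
    "run_to_convergence",
    "cross_check",
]

log = logging.getLogger("finetoggle")

METHODS = ("euler", "rk4", "lsoda")


@dataclass(frozen=True)
class SolverSettings:
    """Integration and convergence-assessment controls.

    dt
        Fixed step (s) for euler/rk4.  The default 0.01 s resolves the
        fastest default process (promoter unbinding, cd2 = 1.04 s^-1).
    t_max
        Hard cap on simulated time (s).  The slow late-time drift means
        convergence can take upward of 10^6 s, hence the large default.
    window
        Span (s) of the trailing convergence-assessment window.
    tol
        Per-species absolute excursion over one full window below which
        the state counts as converged.
    method
        "euler" (default), "rk4" or "lsoda".
    cross_check
        When True, run_to_convergence also integrates with RK4 and logs
        the terminal discrepancy.
    rtol, atol
        Local error control for the lsoda scheme only.  Tight values keep
        the adaptive solver honest through the slow-drift phase.
    """

    dt: float = 0.01
    t_max: float = 1e7
    window: float = 1e5
    tol: float = 1e-6
    method: str = "euler"
    cross_check: bool = False
    stride: int = 1000
    rtol: float = 1e-9
    atol: float = 1e-12
    window_samples: int = 16

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.window < 100 * self.dt:
            raise ValueError("window must span at least 100 steps (window >= 100*dt)")
        if self.t_max < self.window:
            raise ValueError("t_max must be >= window")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")

    def replace(self, **changes) -> "SolverSettings":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


@dataclass
class Trajectory:
    """Recorded time series of the full state."""

    times: np.ndarray
    states: np.ndarray  # shape (n_times, n_species)
    species: tuple
    clipped: int = 0
    absorbed_at: float = -1.0  # stochastic runs: time total propensity hit 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)

    def __len__(self) -> int:
        return len(self.times)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.species.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df


@dataclass
class TerminalState:
    """Outcome of a run-to-convergence integration.

    Non-converged runs are returned flagged, never silently treated as
    attractors; downstream basin analysis excludes them.
    """

    state: np.ndarray
    converged: bool
    t_converged: float
    residual: float
    clipped: int = 0

    def protein_levels(self, model: ModelSpec) -> tuple:
        return (
            float(self.state[model.species_index("p1")]),
            float(self.state[model.species_index("p2")]),
        )


class IntegrationOverflow(RuntimeError):
    """A state magnitude exceeded the overflow guard (step-size instability)."""


def _check_init(model: ModelSpec, init: np.ndarray) -> np.ndarray:
    init = np.asarray(init, dtype=float).copy()
    if init.shape != (model.n_species,):
        raise ValueError(
            f"initial state has shape {init.shape}, expected ({model.n_species},)"
        )
    if (init < 0).any():
        raise ValueError("initial state must be non-negative")
    return init


def integrate(model: ModelSpec, init: np.ndarray, settings: SolverSettings) -> Trajectory:
    """Fixed-step integration over [0, t_max] with strided recording.

    Uses forward Euler (or RK4 when ``settings.method == 'rk4'``).  Tiny
    negative overshoots are clipped to zero and counted; a state beyond
    the overflow guard aborts with :class:`IntegrationOverflow`.
    """
    init = _check_init(model, init)
    n_steps = int(round(settings.t_max / settings.dt))
    stride = max(1, settings.stride)
    kernel = _kernels.rk4_record if settings.method == "rk4" else _kernels.euler_record
    out, n_rec, n_clip, status, steps_done = kernel(
        init.copy(), model.reactant_pairs, model.stoich, model.rate_vector,
        settings.dt, n_steps, stride,
    )
    if status == _kernels.OVERFLOW:
        raise IntegrationOverflow(
            f"state exceeded overflow guard at t={steps_done * settings.dt:.6g} s; "
            f"the fixed step dt={settings.dt} is likely unstable for these rates — "
            "reduce dt or use method='lsoda'"
        )
    states = out[:n_rec]
    times = np.minimum(np.arange(n_rec) * stride * settings.dt, settings.t_max)
    if (n_steps % stride) != 0:
        times[-1] = settings.t_max
    if n_clip:
        log.debug("integrate: clipped %d negative excursions to zero", n_clip)
    return Trajectory(times, states, model.species, clipped=n_clip)


def _lsoda_stepper(model: ModelSpec, init: np.ndarray, settings: SolverSettings):
    """A scipy lsoda integrator continued across calls (no restarts)."""
    from scipy.integrate import ode

    pairs, stoich, k = model.reactant_pairs, model.stoich, model.rate_vector

    def rhs(t, y):
        return _kernels.mass_action_rhs(y, pairs, stoich, k)

    r = ode(rhs)
    r.set_integrator(
        "lsoda", rtol=settings.rtol, atol=settings.atol, nsteps=10_000_000
    )
    r.set_initial_value(init, 0.0)
    return r


def run_to_convergence(
    model: ModelSpec, init: np.ndarray, settings: Optional[SolverSettings] = None
) -> TerminalState:
    """Integrate until the windowed convergence criterion is met.

    The residual of a window is the largest per-species excursion
    (max - min) across the window; convergence is declared when the
    residual of a full window is <= ``settings.tol``.  If t_max is
    reached first the terminal state is returned with converged=False.
    """
    settings = settings or SolverSettings()
    init = _check_init(model, init)
    n_windows = int(math.ceil(settings.t_max / settings.window))

    if settings.method == "lsoda":
        r = _lsoda_stepper(model, init, settings)
        t = 0.0
        n_clip = 0
        y = init
        residual = math.inf
        for w in range(n_windows):
            sample_ts = t + settings.window * (
                np.arange(1, settings.window_samples + 1) / settings.window_samples
            )
            samples = np.empty((settings.window_samples + 1, model.n_species))
            samples[0] = y
            ok = True
            for s_i, ts in enumerate(sample_ts):
                y_s = r.integrate(ts)
                if not r.successful():
                    ok = False
                    break
                samples[s_i + 1] = y_s
            if not ok:
                raise IntegrationOverflow("lsoda failed to advance the solution")
            y = samples[-1].copy()
            t = sample_ts[-1]
            residual = float((samples.max(axis=0) - samples.min(axis=0)).max())
            if residual <= settings.tol:
                return TerminalState(np.clip(y, 0, None), True, t, residual, n_clip)
        return TerminalState(np.clip(y, 0, None), False, t, residual, n_clip)

    use_rk4 = settings.method == "rk4"
    steps_per_window = int(round(settings.window / settings.dt))
    y = init.copy()
    t = 0.0
    n_clip = 0
    residual = math.inf
    for w in range(n_windows):
        y, mins, maxs, clip_w, status, steps_done = _kernels.fixed_step_window(
            y, model.reactant_pairs, model.stoich, model.rate_vector,
            settings.dt, steps_per_window, use_rk4,
        )
        n_clip += clip_w
        if status == _kernels.OVERFLOW:
            raise IntegrationOverflow(
                f"state exceeded overflow guard at t={t + steps_done * settings.dt:.6g} s; "
                "reduce dt or use method='lsoda'"
            )
        t += settings.window
        residual = float((maxs - mins).max())
        if residual <= settings.tol:
            terminal = TerminalState(y, True, t, residual, n_clip)
            break
    else:
        terminal = TerminalState(y, False, t, residual, n_clip)

    if settings.cross_check and terminal.converged:
        other = settings.replace(method="rk4" if not use_rk4 else "euler", cross_check=False)
        alt = run_to_convergence(model, init, other)
        dev = float(np.abs(alt.state - terminal.state).max())
        log.info("cross-check (%s vs %s): max terminal deviation %.3g",
                 settings.method, other.method, dev)
    return terminal


def cross_check(
    model: ModelSpec,
    init: np.ndarray,
    settings: Optional[SolverSettings] = None,
    methods: tuple = ("euler", "rk4"),
) -> Dict[str, object]:
    """Integrate the same problem with independent schemes and compare.

    Returns a report with the terminal state of each scheme, the maximum
    per-species absolute deviation, and the relative deviation of the
    protein coordinates (p1, p2) between the first scheme and each other.
    """
    settings = settings or SolverSettings()
    terminals: Dict[str, TerminalState] = {}
    for m in methods:
        terminals[m] = run_to_convergence(model, init, settings.replace(method=m, cross_check=False))
    ref = methods[0]
    ip1, ip2 = model.species_index("p1"), model.species_index("p2")
    report: Dict[str, object] = {"methods": tuple(methods), "terminals": terminals}
    max_abs: Dict[str, float] = {}
    rel_protein: Dict[str, float] = {}
    for m in methods[1:]:
        a, b = terminals[ref].state, terminals[m].state
        max_abs[m] = float(np.abs(a - b).max())
        denom = max(abs(a[ip1]), abs(a[ip2]), 1e-12)
        rel_protein[m] = float(
            max(abs(a[ip1] - b[ip1]), abs(a[ip2] - b[ip2])) / denom
        )
    report["max_abs_deviation"] = max_abs
    report["relative_protein_deviation"] = rel_protein
    return report
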