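"""Stochastic (Gillespie direct-method) simulation and switching statistics.

At the low copy numbers the toggle switch operates at, intrinsic noise is
not a perturbation but a driver of behaviour: trajectories hop between
states dominated by one protein or the other, and regimes that are
deterministically monostable can dwell persistently in asymmetric states
(noise-induced bistability).  This module simulates exact event
trajectories of the compiled reaction network and extracts the dwell
intervals between changes of the dominant protein.

State is sampled on a uniform time grid rather than at every event; the
state is piecewise constant between events, so grid samples are exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from . import _kernels
from .deterministic import Trajectory
from .model import ModelSpec

__all__ = [
    "SSARun",
    "SwitchingTimes",
    "gillespie_run",
    "extract_switch_times",
    "switching_summary",
    "switching_ensemble",
]

log = logging.getLogger("finetoggle")


@dataclass(frozen=True)
class SSARun:
    """Settings for one stochastic realization.

    ``init`` maps species names to integer initial copy numbers; species
    not named start at the standard initial condition (one free promoter
    per gene, everything else zero).  ``burn_in`` seconds are discarded
    from the returned trajectory (transient before switching statistics).
    """

    seed: int
    t_max: float = 1e6
    sample_dt: float = 100.0
    init: Mapping[str, int] = field(default_factory=dict)
    burn_in: float = 0.0

    def __post_init__(self) -> None:
        if self.t_max <= 0:
            raise ValueError("t_max must be > 0")
        if self.sample_dt <= 0:
            raise ValueError("sample_dt must be > 0")
        if not (0 <= self.burn_in < self.t_max):
            raise ValueError("burn_in must satisfy 0 <= burn_in < t_max")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a non-negative integer")


def _initial_counts(model: ModelSpec, overrides: Mapping[str, int]) -> np.ndarray:
    x0 = model.initial_state()
    for name, count in overrides.items():
        if name not in model.species:
            raise KeyError(f"unknown species {name!r} for this model variant")
        if count < 0 or int(count) != count:
            raise ValueError(f"initial count of {name!r} must be a non-negative integer")
        x0[model.species_index(name)] = count
    return x0


def gillespie_run(model: ModelSpec, run: SSARun) -> Trajectory:
    """Exact direct-method trajectory of the compiled reaction network.

    Reproducible for a fixed seed.  If total propensity reaches zero
    before ``t_max`` (an absorbing state, e.g. all expression switched
    off and every molecule degraded) the run terminates early with
    ``absorbed_at`` set; the remaining grid samples hold the frozen state.
    """
    x0 = _initial_counts(model, run.init)
    samples, n_events, t_absorbed = _kernels.gillespie_sampled(
        x0, model.reactant_pairs, model.stoich, model.rate_vector,
        float(run.t_max), float(run.sample_dt), int(run.seed) & 0x7FFFFFFF,
    )
    times = np.arange(samples.shape[0]) * run.sample_dt
    if t_absorbed >= 0:
        log.info("SSA run (seed %d) absorbed at t=%.6g s after %d events",
                 run.seed, t_absorbed, n_events)
    if run.burn_in > 0:
        keep = times >= run.burn_in
        times, samples = times[keep] - run.burn_in, samples[keep]
    return Trajectory(times, samples, model.species, absorbed_at=t_absorbed)


@dataclass
class SwitchingTimes:
    """Dwell intervals between changes of the dominant protein.

    Dominance is sign(p1 - p2) with a symmetric hysteresis band: the
    dominant gene changes only when the other protein leads by more than
    ``threshold`` molecules, which suppresses single-molecule chatter
    around ties.  ``intervals[i]`` is the time between successive
    dominance changes (the first interval is measured from the start of
    the trajectory); the trailing, censored dwell is not included.
    """

    intervals: np.ndarray
    threshold: float
    switch_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    new_dominant: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    span: float = 0.0

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if len(self.intervals) and (self.intervals <= 0).any():
            raise ValueError("dwell intervals must be strictly positive")
        if self.span and self.intervals.sum() > self.span * (1 + 1e-12):
            raise ValueError("dwell intervals exceed the trajectory span")

    def __len__(self) -> int:
        return len(self.intervals)


def extract_switch_times(traj: Trajectory, threshold: float = 10.0) -> SwitchingTimes:
    """Extract dwell intervals between dominance changes of p1 and p2.

    A switch is recorded at the first sample where the previously
    dominant protein trails the other by more than ``threshold``
    molecules.  Before any dominance is established (|p1 - p2| never yet
    above threshold) the first excursion beyond the band sets the initial
    dominant without recording a switch.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    d = traj["p1"] - traj["p2"]
    t = traj.times
    dominant = 0  # +1: p1 dominant, -1: p2 dominant, 0: not yet established
    t_last = t[0]
    switch_times = []
    dwells = []
    new_dom = []
    for i in range(len(d)):
        if dominant == 0:
            if abs(d[i]) > threshold:
                dominant = 1 if d[i] > 0 else -1
        elif dominant * d[i] < -threshold:
            dominant = -dominant
            switch_times.append(t[i])
            dwells.append(t[i] - t_last)
            new_dom.append(dominant)
            t_last = t[i]
    return SwitchingTimes(
        intervals=np.array(dwells),
        threshold=threshold,
        switch_times=np.array(switch_times),
        new_dominant=np.array(new_dom, dtype=int),
        span=float(t[-1] - t[0]),
    )


def switching_summary(
    s: SwitchingTimes,
    bins: int = 20,
    short_time_cutoff: float = 1e3,
) -> Dict[str, object]:
    """Summary statistics of a switching-time collection.

    Returns count, median, mean, a base-10 log histogram (edges in
    log10 seconds), and the fraction of intervals below
    ``short_time_cutoff`` — the short-time transient mass that makes the
    distribution bimodal when trajectories chatter around a switch.  An
    empty collection yields count 0 with NaN summaries.
    """
    x = s.intervals
    if len(x) == 0:
        return {
            "count": 0,
            "median": float("nan"),
            "mean": float("nan"),
            "log10_hist_edges": np.empty(0),
            "log10_hist_counts": np.empty(0, dtype=int),
            "short_time_fraction": float("nan"),
            "bimodal_short_time_mass": False,
        }
    logs = np.log10(x)
    counts, edges = np.histogram(logs, bins=bins)
    short_frac = float((x < short_time_cutoff).mean())
    return {
        "count": int(len(x)),
        "median": float(np.median(x)),
        "mean": float(np.mean(x)),
        "log10_hist_edges": edges,
        "log10_hist_counts": counts,
        "short_time_fraction": short_frac,
        "bimodal_short_time_mass": bool(0 < short_frac < 1),
    }


def switching_ensemble(
    model: ModelSpec,
    seeds: Sequence[int],
    t_max: float = 1e6,
    sample_dt: float = 100.0,
    burn_in: float = 1e5,
    threshold: float = 10.0,
    init: Optional[Mapping[str, int]] = None,
) -> SwitchingTimes:
    """Pool dwell intervals from independent seeded realizations."""
    all_dwells = []
    span = 0.0
    for seed in seeds:
        run = SSARun(seed=int(seed), t_max=t_max, sample_dt=sample_dt,
                     init=init or {}, burn_in=burn_in)
        traj = gillespie_run(model, run)
        st = extract_switch_times(traj, threshold)
        all_dwells.append(st.intervals)
        span += st.span
    pooled = np.concatenate(all_dwells) if all_dwells else np.empty(0)
    return SwitchingTimes(intervals=pooled, threshold=threshold, span=span)
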