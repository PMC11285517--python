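"""Attractor-basin mapping, parameter sweeps and ATP bifurcation scans.

Decision-making capacity of the network is read off the structure of its
attractor basins: a grid of initial protein levels (ip1, ip2) is relaxed
to steady state, the terminal (p1, p2) coordinates are clustered, and
the number and separation of clusters summarize how many distinct cell
states the parameterization supports.  The characteristic multistable
signature is *tripartite*: a central symmetric attractor flanked by a
high-p1 and a high-p2 attractor.

Scans wrap this basin analysis: order-of-magnitude sweeps of single
rates and of rate pairs, and ATP sweeps that expose the pitchfork
bifurcations through which increased energy availability creates (and
separates) the flanking attractors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .deterministic import SolverSettings, TerminalState, run_to_convergence
from .model import RATE_NAMES, ModelSpec, RateSet, build_model

__all__ = [
    "GridSpec",
    "BasinMap",
    "basin_map",
    "cluster_terminals",
    "parameter_scan",
    "single_parameter_sweep",
    "pairwise_parameter_sweep",
    "atp_bifurcation_scan",
]

log = logging.getLogger("finetoggle")

#: Solver settings used for scan workloads: the adaptive scheme with the
#: same windowed convergence criterion, fast enough for hundreds of grid
#: points per scan member.
SCAN_SETTINGS = SolverSettings(method="lsoda")

#: Order-of-magnitude factors for single-parameter sweeps.
DEFAULT_SINGLE_FACTORS: Tuple[float, ...] = (1e-2, 1e-1, 1.0, 1e1, 1e2)


@dataclass(frozen=True)
class GridSpec:
    """Initial-condition grid over initial protein levels (ip1, ip2)."""

    n: int = 21
    ip_min: float = 0.0
    ip_max: float = 50.0
    rna1: float = 0.0
    rna2: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("grid must contain at least one point per axis")
        if self.ip_max < self.ip_min:
            raise ValueError("ip_max must be >= ip_min")

    def axis(self) -> np.ndarray:
        return np.linspace(self.ip_min, self.ip_max, self.n)

    def points(self) -> List[Tuple[float, float]]:
        ax = self.axis()
        return [(float(a), float(b)) for a in ax for b in ax]


def cluster_terminals(
    terminals: Sequence[Tuple[float, float]], tol: float = 1.0
) -> Tuple[np.ndarray, np.ndarray]:
    """Single-linkage clustering of terminal (p1, p2) coordinates.

    Points whose single-linkage (minimum spanning) distance is <= ``tol``
    share a cluster.  Returns (labels, centroids); labels index the
    centroid array and are stable under permutation of the input because
    clusters are relabelled by lexicographically sorted centroid.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    pts = np.asarray(terminals, dtype=float)
    if pts.size == 0:
        raise ValueError("no terminal states to cluster")
    pts = pts.reshape(len(pts), -1)
    if len(pts) == 1:
        return np.zeros(1, dtype=int), pts.copy()
    raw = fcluster(linkage(pts, method="single"), t=tol, criterion="distance")
    centroids = np.array([pts[raw == lab].mean(axis=0) for lab in np.unique(raw)])
    order = np.lexsort((centroids[:, 1], centroids[:, 0]))
    rank = np.empty(len(order), dtype=int)
    rank[order] = np.arange(len(order))
    labels = np.array([rank[lab - 1] for lab in raw])
    return labels, centroids[order]


@dataclass
class BasinMap:
    """Terminal states and attractor clusters over an initial-condition grid.

    ``table`` has one row per grid point: ip1, ip2, p1, p2, converged,
    cluster (-1 for unconverged points, which never receive a label).
    ``attractors`` holds one row per cluster: p1, p2 (centroid),
    n_points, asymmetric (|p1 - p2| > tol).
    """

    table: pd.DataFrame
    attractors: pd.DataFrame
    tol: float

    @property
    def n_attractors(self) -> int:
        return len(self.attractors)

    @property
    def n_asymmetric(self) -> int:
        return int(self.attractors["asymmetric"].sum())

    @property
    def n_unconverged(self) -> int:
        return int((~self.table["converged"]).sum())

    def attractor_coordinates(self) -> np.ndarray:
        return self.attractors[["p1", "p2"]].to_numpy()

    def separation(self) -> float:
        """Distance between the two asymmetric centroids (NaN if < 2)."""
        asym = self.attractors[self.attractors["asymmetric"]]
        if len(asym) < 2:
            return float("nan")
        pts = asym[["p1", "p2"]].to_numpy()
        return float(
            max(np.linalg.norm(a - b) for a, b in itertools.combinations(pts, 2))
        )

    def central_fraction(self) -> float:
        """Fraction of converged grid points in a symmetric cluster."""
        conv = self.table[self.table["converged"]]
        if len(conv) == 0:
            return float("nan")
        sym_clusters = set(self.attractors.index[~self.attractors["asymmetric"]])
        return float(conv["cluster"].isin(sym_clusters).mean())


def basin_map(
    model: ModelSpec,
    grid: Optional[GridSpec] = None,
    settings: Optional[SolverSettings] = None,
    cluster_tol: float = 1.0,
    use_symmetry: bool = True,
) -> BasinMap:
    """Relax every grid initial condition to steady state and cluster.

    Each point starts from the standard initial condition with protein
    levels (ip1, ip2) (and optional uniform initial mRNA from the grid
    spec).  Unconverged points are flagged and excluded from clustering.
    Because the network is symmetric under exchange of gene labels, the
    terminal state of (b, a) is the coordinate swap of (a, b); with
    ``use_symmetry`` only the lower triangle is integrated (disabled
    automatically when asymmetric initial mRNA breaks the symmetry).
    """
    grid = grid or GridSpec()
    settings = settings if settings is not None else SCAN_SETTINGS
    symmetric = use_symmetry and grid.rna1 == grid.rna2
    ip1_idx, ip2_idx = model.species_index("p1"), model.species_index("p2")

    cache: Dict[Tuple[float, float], TerminalState] = {}
    rows = []
    for ip1, ip2 in grid.points():
        key = (ip1, ip2)
        if key in cache:
            terminal = cache[key]
        else:
            init = model.initial_state(p1=ip1, p2=ip2, rna1=grid.rna1, rna2=grid.rna2)
            terminal = run_to_convergence(model, init, settings)
            cache[key] = terminal
            if symmetric and ip1 != ip2:
                mirrored = TerminalState(
                    state=terminal.state[model.swap_permutation()],
                    converged=terminal.converged,
                    t_converged=terminal.t_converged,
                    residual=terminal.residual,
                    clipped=terminal.clipped,
                )
                cache[(ip2, ip1)] = mirrored
        rows.append(
            {
                "ip1": ip1,
                "ip2": ip2,
                "p1": float(terminal.state[ip1_idx]),
                "p2": float(terminal.state[ip2_idx]),
                "converged": bool(terminal.converged),
            }
        )
    table = pd.DataFrame(rows)

    conv_mask = table["converged"].to_numpy()
    table["cluster"] = -1
    if conv_mask.any():
        labels, centroids = cluster_terminals(
            table.loc[conv_mask, ["p1", "p2"]].to_numpy(), tol=cluster_tol
        )
        table.loc[conv_mask, "cluster"] = labels
        attractors = pd.DataFrame(centroids, columns=["p1", "p2"])
        attractors["n_points"] = [
            int((labels == lab).sum()) for lab in range(len(centroids))
        ]
        attractors["asymmetric"] = (
            np.abs(attractors["p1"] - attractors["p2"]) > cluster_tol
        )
    else:
        attractors = pd.DataFrame(columns=["p1", "p2", "n_points", "asymmetric"])
    n_unconv = int((~table["converged"]).sum())
    if n_unconv:
        log.info("basin_map: %d/%d grid points failed to converge", n_unconv, len(table))
    return BasinMap(table=table, attractors=attractors, tol=cluster_tol)


def _scan_row(bm: BasinMap) -> Dict[str, object]:
    coords = ";".join(
        f"({p1:.6g},{p2:.6g})" for p1, p2 in bm.attractor_coordinates()
    )
    return {
        "n_attractors": bm.n_attractors,
        "n_asymmetric": bm.n_asymmetric,
        "centroids": coords,
        "n_unconverged": bm.n_unconverged,
    }


def parameter_scan(
    base: RateSet,
    params: Sequence[str],
    factors: Sequence,
    grid: Optional[GridSpec] = None,
    settings: Optional[SolverSettings] = None,
    oligomer_order: int = 2,
    cluster_tol: float = 1.0,
) -> pd.DataFrame:
    """Basin analysis along a scan of one or two rate constants.

    ``params`` names one or two RateSet fields.  For a single parameter,
    ``factors`` is a sequence of positive scale factors; for a pair, a
    sequence of (factor1, factor2) tuples.  Each scan member scales the
    base rates, rebuilds the model and maps its attractor basins.
    """
    params = list(params)
    if not 1 <= len(params) <= 2:
        raise ValueError("params must name one or two rate constants")
    for p in params:
        if p not in RATE_NAMES:
            raise KeyError(f"unknown rate name {p!r}")
    rows = []
    for f in factors:
        fs = (float(f),) if len(params) == 1 else tuple(float(x) for x in f)
        if len(fs) != len(params):
            raise ValueError(f"factor entry {f!r} does not match params {params}")
        if any(x <= 0 for x in fs):
            raise ValueError("scale factors must be > 0")
        scaled = base.scaled_by(dict(zip(params, fs)))
        model = build_model(oligomer_order, scaled)
        bm = basin_map(model, grid=grid, settings=settings, cluster_tol=cluster_tol)
        row = {
            "params": "+".join(params),
            "factors": ";".join(f"{x:g}" for x in fs),
            "atp": base.atp,
            **_scan_row(bm),
        }
        rows.append(row)
        log.info("scan %s x %s: %d attractors (%d asymmetric)",
                 row["params"], row["factors"], bm.n_attractors, bm.n_asymmetric)
    return pd.DataFrame(rows)


def single_parameter_sweep(
    base: Optional[RateSet] = None,
    factors: Sequence[float] = DEFAULT_SINGLE_FACTORS,
    params: Sequence[str] = RATE_NAMES,
    **kwargs,
) -> pd.DataFrame:
    """Order-of-magnitude sweep of each rate constant in turn."""
    base = base or RateSet()
    return pd.concat(
        [parameter_scan(base, [p], factors, **kwargs) for p in params],
        ignore_index=True,
    )


def pairwise_parameter_sweep(
    base: Optional[RateSet] = None,
    factor_set: Sequence[float] = (0.1, 10.0),
    params: Sequence[str] = RATE_NAMES,
    **kwargs,
) -> pd.DataFrame:
    """Sweep all unordered pairs of rates over factor combinations.

    Each of the 36 pairs of the nine rates is scanned over every
    (f1, f2) combination from ``factor_set`` (default the large
    order-of-magnitude perturbation {1/10, 10}; use (0.5, 2.0) for the
    small-perturbation variant).
    """
    base = base or RateSet()
    combos = list(itertools.product(factor_set, repeat=2))
    frames = [
        parameter_scan(base, [p1, p2], combos, **kwargs)
        for p1, p2 in itertools.combinations(params, 2)
    ]
    return pd.concat(frames, ignore_index=True)


def atp_bifurcation_scan(
    base: RateSet,
    atp_values: Sequence[float],
    grid: Optional[GridSpec] = None,
    settings: Optional[SolverSettings] = None,
    oligomer_order: int = 2,
    cluster_tol: float = 1.0,
) -> pd.DataFrame:
    """Basin analysis along an increasing ATP sweep.

    For each ATP multiplier the expression rates are scaled per the
    base ``atp_mode``, the basins remapped, and the table records the
    terminal p1 values over the grid, the cluster count, the separation
    between the asymmetric centroids and the central-basin width
    (fraction of converged grid points in a symmetric cluster).  A
    pitchfork bifurcation appears as the cluster count stepping from
    1 to 3 at a finite ATP threshold.
    """
    atp_values = [float(a) for a in atp_values]
    if any(a <= 0 for a in atp_values):
        raise ValueError("atp values must be > 0")
    if any(b <= a for a, b in zip(atp_values, atp_values[1:])):
        raise ValueError("atp values must be strictly increasing")
    rows = []
    for atp in atp_values:
        model = build_model(oligomer_order, base.replace(atp=atp))
        bm = basin_map(model, grid=grid, settings=settings, cluster_tol=cluster_tol)
        conv = bm.table[bm.table["converged"]]
        rows.append(
            {
                "atp": atp,
                "n_clusters": bm.n_attractors,
                "n_asymmetric": bm.n_asymmetric,
                "p1_values": ";".join(f"{v:.6g}" for v in conv["p1"]),
                "separation": bm.separation(),
                "central_fraction": bm.central_fraction(),
                "n_unconverged": bm.n_unconverged,
            }
        )
        log.info("atp=%g: %d clusters, separation %.3g",
                 atp, bm.n_attractors, rows[-1]["separation"])
    return pd.DataFrame(rows)
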