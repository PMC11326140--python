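"""Core in-memory containers shared across the pipeline.

Graphs are held as networkx objects; tabular data as numpy arrays or pandas
frames. Node identifiers are opaque strings (gene symbols for real data,
generated ids for synthetic data). Time is always integer minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

#: Activity states a protein can occupy at a time point.
ACTIVATED = "activated"
INHIBITED = "inhibited"
INACTIVE = "inactive"
STATES = (ACTIVATED, INHIBITED, INACTIVE)

#: The western-blot sampling grid, in minutes after stimulation.
DEFAULT_TIME_GRID = (0, 5, 15, 30, 60, 120, 180, 240, 360)


def _check_time_grid(time_grid: tuple[int, ...]) -> tuple[int, ...]:
    grid = tuple(int(t) for t in time_grid)
    if len(grid) < 2:
        raise ConfigError("time grid needs at least two points")
    if grid[0] != 0:
        raise ConfigError("time grid must start at 0 minutes")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigError("time grid must be strictly increasing")
    return grid


@dataclass
class PhosphoTimeSeries:
    """Replicate fold-change trajectories for one protein.

    ``values`` has shape (n_replicates, n_timepoints); entries are
    dimensionless fold changes relative to the signal at time zero, so the
    first column is exactly 1 for every replicate.
    """

    protein: str
    time_grid: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time_grid = _check_time_grid(self.time_grid)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError(f"{self.protein}: values must be replicate x time")
        if self.values.shape[1] != len(self.time_grid):
            raise DataError(
                f"{self.protein}: {self.values.shape[1]} columns for "
                f"{len(self.time_grid)} time points"
            )
        if self.values.shape[0] < 1:
            raise DataError(f"{self.protein}: need >= 1 replicate")
        if not np.all(self.values > 0):
            raise DataError(f"{self.protein}: fold changes must be positive")
        if not np.allclose(self.values[:, 0], 1.0, rtol=0, atol=1e-12):
            raise DataError(f"{self.protein}: fold change at t=0 must be 1")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]


@dataclass
class PhosphoDataset:
    """A collection of time series on a shared grid, keyed by protein."""

    time_grid: tuple[int, ...]
    series: dict[str, PhosphoTimeSeries]

    def __post_init__(self) -> None:
        self.time_grid = _check_time_grid(self.time_grid)
        for name, ts in self.series.items():
            if ts.time_grid != self.time_grid:
                raise DataError(f"{name}: time grid differs from dataset grid")

    def proteins(self) -> list[str]:
        return sorted(self.series)

    def __getitem__(self, protein: str) -> PhosphoTimeSeries:
        return self.series[protein]

    def __contains__(self, protein: str) -> bool:
        return protein in self.series

    def __len__(self) -> int:
        return len(self.series)


@dataclass
class SignificanceScores:
    """Per-time p-values for one protein.

    ``firstscores[k]`` compares time point k+1 with time zero,
    ``prevscores[k]`` with the preceding point; both have T-1 entries.
    ``flags`` records degenerate tests ('zero-diff' or 'zero-sd').
    """

    protein: str
    firstscores: np.ndarray
    prevscores: np.ndarray
    threshold: float = 0.05
    flags: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.firstscores = np.asarray(self.firstscores, dtype=float)
        self.prevscores = np.asarray(self.prevscores, dtype=float)
        for arr in (self.firstscores, self.prevscores):
            if np.any((arr < 0) | (arr > 1)):
                raise DataError(f"{self.protein}: p-values outside [0,1]")
        if self.firstscores.shape != self.prevscores.shape:
            raise DataError(f"{self.protein}: score vectors differ in length")

    def min_p(self) -> float:
        return float(min(self.firstscores.min(), self.prevscores.min()))


@dataclass
class ActivityProfile:
    """Discrete activity state of one protein at every time point."""

    protein: str
    time_grid: tuple[int, ...]
    states: tuple[str, ...]

    def __post_init__(self) -> None:
        self.time_grid = _check_time_grid(self.time_grid)
        self.states = tuple(self.states)
        if len(self.states) != len(self.time_grid):
            raise DataError(f"{self.protein}: one state per time point required")
        bad = set(self.states) - set(STATES)
        if bad:
            raise DataError(f"{self.protein}: unknown states {sorted(bad)}")

    def first_change(self) -> float:
        """Earliest time with a non-inactive state; +inf if never."""
        for t, s in zip(self.time_grid, self.states):
            if s != INACTIVE:
                return float(t)
        return float("inf")

    def first_direction(self) -> int:
        """+1 if the first change is an activation, -1 if inhibition, 0 if none."""
        for s in self.states:
            if s == ACTIVATED:
                return 1
            if s == INHIBITED:
                return -1
        return 0


class Interactome:
    """Background network: undirected PPIs plus directed kinase-substrate edges.

    The PPI layer is an ``nx.Graph`` with a ``confidence`` attribute in (0,1]
    on every edge and an ``is_kinase`` flag on every node. The
    kinase-substrate layer is an ``nx.DiGraph`` whose edges may carry a
    ``sign`` attribute (+1, -1 or None) and whose sources must be kinases.
    """

    def __init__(self, ppi: nx.Graph, ks: nx.DiGraph) -> None:
        self.ppi = ppi
        self.ks = ks
        self.validate()

    def validate(self) -> None:
        for u, v, d in self.ppi.edges(data=True):
            if u == v:
                raise DataError(f"self-loop on {u}")
            c = d.get("confidence")
            if c is None or not (0 < c <= 1):
                raise DataError(f"edge {u}-{v}: confidence must be in (0,1]")
        for n in self.ppi.nodes:
            if "is_kinase" not in self.ppi.nodes[n]:
                raise DataError(f"node {n}: missing is_kinase flag")
        for k, s in self.ks.edges:
            if k == s:
                raise DataError(f"self-loop on {k} in kinase-substrate layer")
            if k not in self.ppi.nodes or not self.ppi.nodes[k]["is_kinase"]:
                raise DataError(f"kinase-substrate edge {k}->{s}: source not a kinase")

    def kinases(self) -> set[str]:
        return {n for n, d in self.ppi.nodes(data=True) if d["is_kinase"]}

    def nodes(self) -> set[str]:
        return set(self.ppi.nodes)


@dataclass
class SubNetwork:
    """Undirected source-connected subnetwork extracted from the interactome."""

    graph: nx.Graph
    source: str

    def __post_init__(self) -> None:
        if self.source not in self.graph:
            raise DataError(f"source {self.source} not in subnetwork")
        reachable = nx.node_connected_component(self.graph, self.source)
        stranded = set(self.graph.nodes) - reachable
        if stranded:
            raise DataError(f"nodes unreachable from source: {sorted(stranded)}")

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return sorted(tuple(sorted(e)) for e in self.graph.edges)


class PartialModel:
    """Directed kinase->substrate prior edges, optionally signed.

    Restricts which orientations and signs the synthesis stage may consider.
    """

    def __init__(self, edges: Iterable[tuple[str, str, int | None]] = ()) -> None:
        self.graph = nx.DiGraph()
        for u, v, sign in edges:
            if sign not in (1, -1, None):
                raise DataError(f"edge {u}->{v}: sign must be +1, -1 or None")
            self.graph.add_edge(u, v, sign=sign)

    def restrict_to(self, nodes: set[str]) -> tuple["PartialModel", int]:
        """Drop edges with endpoints outside ``nodes``; return (model, n_dropped)."""
        kept, dropped = [], 0
        for u, v, d in self.graph.edges(data=True):
            if u in nodes and v in nodes:
                kept.append((u, v, d["sign"]))
            else:
                dropped += 1
        return PartialModel(kept), dropped

    def edges(self) -> list[tuple[str, str, int | None]]:
        return sorted(
            (u, v, d["sign"]) for u, v, d in self.graph.edges(data=True)
        )


class SummaryNetwork:
    """Consolidated directed network; a subset of edges also carries a sign.

    Every emitted edge is direction-resolved (it lies on at least one valid
    source-rooted path). ``sign`` is +1/-1 only when all valid paths through
    the node pair agree on direction and sign, else None. ``n_paths`` counts
    the valid paths using the edge.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_edge(self, u: str, v: str, sign: int | None, n_paths: int) -> None:
        if sign not in (1, -1, None):
            raise DataError(f"edge {u}->{v}: bad sign {sign!r}")
        self.graph.add_edge(u, v, sign=sign, n_paths=int(n_paths))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges)

    def signed_edges(self) -> list[tuple[str, str, int]]:
        return sorted(
            (u, v, d["sign"])
            for u, v, d in self.graph.edges(data=True)
            if d["sign"] is not None
        )

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryNetwork):
            return NotImplemented
        mine = {(u, v): d["sign"] for u, v, d in self.graph.edges(data=True)}
        theirs = {(u, v): d["sign"] for u, v, d in other.graph.edges(data=True)}
        return mine == theirs


@dataclass
class ActivityWindows:
    """Per node and time point, the set of admissible activity states."""

    time_grid: tuple[int, ...]
    windows: dict[str, dict[int, frozenset[str]]]

    def states(self, node: str, t: int) -> frozenset[str]:
        return self.windows[node][t]


@dataclass
class KinaseNetwork:
    """Directed network restricted to kinase-kinase edges."""

    graph: nx.DiGraph

    def __post_init__(self) -> None:
        for u, v in self.graph.edges:
            if not (self.graph.nodes[u].get("is_kinase", True)
                    and self.graph.nodes[v].get("is_kinase", True)):
                raise DataError(f"edge {u}->{v}: both endpoints must be kinases")

    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)


class InhibitionMatrix:
    """Residual kinase activity (percent) per (kinase, compound).

    Backed by a DataFrame (kinases x compounds); missing pairs are NaN and
    mean 'not assayed', never zero.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        vals = frame.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise DataError("residual activity must be >= 0")
        self.frame = frame.astype(float)

    @property
    def kinases(self) -> list[str]:
        return list(self.frame.index)

    @property
    def compounds(self) -> list[str]:
        return list(self.frame.columns)

    def residual(self, kinase: str, compound: str) -> float:
        """Residual activity in percent; NaN when the pair was not assayed."""
        if compound not in self.frame.columns:
            raise DataError(f"unknown compound {compound}")
        if kinase not in self.frame.index:
            return float("nan")
        return float(self.frame.loc[kinase, compound])


@dataclass
class PermeabilityScreen:
    """Normalized permeability AUC replicates per compound, plus DMSO control."""

    compound_auc: dict[str, np.ndarray]
    dmso_auc: np.ndarray

    def __post_init__(self) -> None:
        self.dmso_auc = np.asarray(self.dmso_auc, dtype=float)
        self.compound_auc = {
            c: np.asarray(a, dtype=float) for c, a in self.compound_auc.items()
        }
        for name, arr in [("DMSO", self.dmso_auc), *self.compound_auc.items()]:
            if arr.size < 2:
                raise DataError(f"{name}: need >= 2 AUC replicates")
            if np.any(arr <= 0):
                raise DataError(f"{name}: AUC must be positive")

    def compounds(self) -> list[str]:
        return sorted(self.compound_auc)


@dataclass
class TrekingModel:
    """Functional kinase model: temporal functionality labels, pathway
    activity intervals, cluster assignments, and a background
    kinase-substrate network.

    ``functionality[kinase][t]`` is one of 'weakening', 'strengthening',
    'both', 'none'; ``intervals[kinase]`` lists closed (start, end) minute
    intervals during which a pathway containing the kinase is active.
    """

    time_grid: tuple[int, ...]
    functionality: dict[str, dict[int, str]]
    intervals: dict[str, list[tuple[float, float]]]
    clusters: dict[str, int]
    background: nx.DiGraph
    n_clusters: int = 36

    FUNCTIONALITIES = ("weakening", "strengthening", "both", "none")

    def __post_init__(self) -> None:
        self.time_grid = _check_time_grid(self.time_grid)
        for k, per_t in self.functionality.items():
            for t, f in per_t.items():
                if f not in self.FUNCTIONALITIES:
                    raise DataError(f"{k}@{t}: unknown functionality {f!r}")
        for k, c in self.clusters.items():
            if not (1 <= c <= self.n_clusters):
                raise DataError(f"{k}: cluster {c} outside 1..{self.n_clusters}")

    def kinases(self) -> list[str]:
        return sorted(self.functionality)


@dataclass
class NullEnsemble:
    """Accuracy distribution from randomized model iterations.

    ``accuracies`` holds one value per iteration; NaN marks iterations whose
    accuracy was undefined (no positive predictions) — recorded, not dropped.
    """

    arm: str
    accuracies: np.ndarray
    seeds: list[int]
    n_iterations: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.arm not in ("tps", "treking"):
            raise ConfigError(f"unknown ensemble arm {self.arm!r}")
        if len(self.accuracies) != self.n_iterations:
            raise DataError("one accuracy per iteration required")
        defined = self.accuracies[~np.isnan(self.accuracies)]
        if defined.size and (defined.min() < 0 or defined.max() > 1):
            raise DataError("accuracies must lie in [0,1]")

    def defined(self) -> np.ndarray:
        return self.accuracies[~np.isnan(self.accuracies)]

    def percentile(self, q: float) -> float:
        d = self.defined()
        return float(np.percentile(d, q)) if d.size else float("nan")

    def empirical_p(self, true_accuracy: float) -> float:
        """Fraction of null iterations with accuracy >= the true model's.

        Undefined iterations count as not exceeding.
        """
        d = self.defined()
        return float(np.sum(d >= true_accuracy)) / self.n_iterations
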