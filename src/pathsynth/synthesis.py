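"""Temporal pathway synthesis: the core inference step.

Each undirected subnetwork edge is considered in both orientations and both
signs (restricted by the directed, optionally signed kinase-substrate
partial model). A signed directed source-rooted simple path is *valid* when
(i) first-change times are non-decreasing along the path over measured
nodes, (ii) it terminates at a measured protein that changes, and (iii) for
every measured node on it, the cumulative product of edge signs from the
source matches the direction of that node's first observed change
(+ for activation, - for inhibition). Unmeasured intermediates impose no
timing constraint but contribute their edge sign.

All valid paths are consolidated by union into a summary network whose
edges are directed; an edge also carries a sign only when every valid path
through that node pair agrees on one (direction, sign) — with sparse
measurements most directions are resolvable but few signs are, so signed
edges are a small subset. Activity windows report, per node and time point,
the set of admissible activity states.
"""

from __future__ import annotations

from .containers import (
    ACTIVATED,
    INACTIVE,
    INHIBITED,
    STATES,
    ActivityProfile,
    ActivityWindows,
    PartialModel,
    SubNetwork,
    SummaryNetwork,
)
from .errors import ConfigError, DataError

DEFAULT_MAX_PATH_LEN = 8  # edges per path; bounds the enumeration

Event = tuple[str, str, int]  # (u, v, sign): signed directed edge candidate


def candidate_events(sub: SubNetwork, pm: PartialModel) -> set[Event]:
    """All signed directed edge candidates allowed by the partial model.

    An undirected edge {u, v} yields u->v and v->u in both signs. If the
    partial model directs u->v and not v->u, the v->u candidates are
    dropped; a signed prior additionally drops the opposite sign for its
    direction.
    """
    pm_local, _ = pm.restrict_to(sub.nodes())
    pmg = pm_local.graph
    events: set[Event] = set()
    for u, v in sub.graph.edges:
        for a, b in ((u, v), (v, u)):
            if pmg.has_edge(b, a) and not pmg.has_edge(a, b):
                continue
            if pmg.has_edge(a, b) and pmg.edges[a, b]["sign"] is not None:
                events.add((a, b, pmg.edges[a, b]["sign"]))
            else:
                events.add((a, b, 1))
                events.add((a, b, -1))
    return events


def first_change_map(profiles: dict[str, ActivityProfile]) -> dict[str, float]:
    """Earliest non-inactive time per measured protein (+inf if none)."""
    return {p: prof.first_change() for p, prof in profiles.items()}


def first_direction_map(profiles: dict[str, ActivityProfile]) -> dict[str, int]:
    return {p: prof.first_direction() for p, prof in profiles.items()}


def is_valid_path(
    path: list[Event],
    profiles: dict[str, ActivityProfile],
    source: str,
    first_change: dict[str, float] | None = None,
) -> bool:
    """Check one signed directed simple path against the temporal data."""
    if not path:
        return False
    if path[0][0] != source:
        raise DataError(f"path must start at source {source}")
    if first_change is None:
        first_change = first_change_map(profiles)
    direction = first_direction_map(profiles)

    last_time = 0.0  # the source responds at t=0 by definition
    sign_product = 1
    for u, v, s in path:
        sign_product *= s
        if v in profiles:
            t = first_change[v]
            if t == float("inf"):
                return False  # measured but never changes: cannot explain it
            if t < last_time:
                return False  # signal cannot arrive before its cause
            last_time = t
            if sign_product != direction[v]:
                return False
    terminal = path[-1][1]
    return terminal in profiles and first_change[terminal] < float("inf")


def _changing_nodes(profiles: dict[str, ActivityProfile]) -> set[str]:
    return {p for p, prof in profiles.items() if prof.first_change() < float("inf")}


class _Consolidator:
    """Accumulates valid paths into summary-network edge annotations."""

    def __init__(self) -> None:
        # per unordered pair: set of (u, v, sign) seen on valid paths
        self.variants: dict[frozenset, set[Event]] = {}
        self.path_counts: dict[tuple[str, str], int] = {}

    def add_path(self, path: list[Event]) -> None:
        for u, v, s in path:
            self.variants.setdefault(frozenset((u, v)), set()).add((u, v, s))
            self.path_counts[(u, v)] = self.path_counts.get((u, v), 0) + 1

    def build(self) -> SummaryNetwork:
        net = SummaryNetwork()
        for pair, evs in self.variants.items():
            directions = {(u, v) for u, v, _ in evs}
            unique_sign = len(evs) == 1
            for u, v in sorted(directions):
                sign = next(iter(evs))[2] if unique_sign else None
                net.add_edge(u, v, sign, self.path_counts[(u, v)])
        return net


def _enumerate_valid_paths(
    events: set[Event],
    profiles: dict[str, ActivityProfile],
    source: str,
    max_path_len: int,
    collect,
) -> None:
    """DFS over candidate edges with timing/sign pruning.

    Prefix pruning is sound because both constraints are monotone along a
    path: a timing violation or a sign mismatch at a measured node can never
    be repaired by extending the path.
    """
    first_change = first_change_map(profiles)
    direction = first_direction_map(profiles)
    by_source: dict[str, list[Event]] = {}
    for e in sorted(events):
        by_source.setdefault(e[0], []).append(e)

    path: list[Event] = []
    visited = {source}

    def dfs(node: str, last_time: float, sign_product: int) -> None:
        if len(path) >= max_path_len:
            return
        for u, v, s in by_source.get(node, ()):
            if v in visited:
                continue
            sp = sign_product * s
            if v in profiles:
                t = first_change[v]
                if t == float("inf") or t < last_time or sp != direction[v]:
                    continue
                new_time = t
            else:
                new_time = last_time
            path.append((u, v, s))
            visited.add(v)
            if v in profiles:  # measured changing node: a complete valid path
                collect(list(path))
            dfs(v, new_time, sp)
            visited.remove(v)
            path.pop()

    dfs(source, 0.0, 1)


def synthesize(
    sub: SubNetwork,
    pm: PartialModel,
    profiles: dict[str, ActivityProfile],
    source: str,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
) -> tuple[SummaryNetwork, ActivityWindows]:
    """Consolidate all valid paths into a summary network + activity windows.

    Paths terminate at measured changing proteins; unmeasured (Steiner)
    nodes may appear only as intermediates. Returns an empty summary, with
    the unexplained proteins listed in the windows' diagnostics, when no
    changing protein admits a valid path.
    """
    if source not in sub.nodes():
        raise DataError(f"source {source} not in subnetwork")
    profiles = {p: pr for p, pr in profiles.items() if p in sub.nodes()}
    changing = _changing_nodes(profiles)
    if not changing:
        raise DataError("no measured protein changes; nothing to synthesize")

    events = candidate_events(sub, pm)
    cons = _Consolidator()
    _enumerate_valid_paths(events, profiles, source, max_path_len, cons.add_path)
    summary = cons.build()
    windows = _activity_windows(sub, profiles, source, summary)
    return summary, windows


def _activity_windows(
    sub: SubNetwork,
    profiles: dict[str, ActivityProfile],
    source: str,
    summary: SummaryNetwork,
) -> ActivityWindows:
    """Measured nodes get their observed state; the source is 'activated';
    unmeasured nodes are unconstrained (all states admissible)."""
    grids = {tuple(p.time_grid) for p in profiles.values()}
    if len(grids) != 1:
        raise DataError("profiles disagree on the time grid")
    (grid,) = grids
    win: dict[str, dict[int, frozenset]] = {}
    allstates = frozenset(STATES)
    for n in sorted(sub.nodes()):
        if n == source:
            win[n] = {t: frozenset({ACTIVATED}) for t in grid}
        elif n in profiles:
            win[n] = {
                t: frozenset({s})
                for t, s in zip(grid, profiles[n].states)
            }
        else:
            win[n] = {t: allstates for t in grid}
    return ActivityWindows(grid, win)


def brute_force_summary(
    sub: SubNetwork,
    pm: PartialModel,
    profiles: dict[str, ActivityProfile],
    source: str,
    max_nodes: int = 12,
    max_path_len: int | None = None,
) -> SummaryNetwork:
    """Independent oracle: exhaustive path enumeration without pruning.

    Enumerates every signed directed simple path from the source over the
    candidate events and filters with is_valid_path; consolidation rule is
    identical. Limited to small instances.
    """
    if len(sub.nodes()) > max_nodes:
        raise ConfigError(f"brute force limited to {max_nodes} nodes")
    profiles = {p: pr for p, pr in profiles.items() if p in sub.nodes()}
    events = sorted(candidate_events(sub, pm))
    limit = max_path_len if max_path_len is not None else len(sub.nodes()) - 1
    first_change = first_change_map(profiles)
    cons = _Consolidator()

    def extend(path: list[Event], visited: set[str]) -> None:
        node = path[-1][1] if path else source
        if path and len(path) <= limit and is_valid_path(
            path, profiles, source, first_change
        ):
            cons.add_path(path)
        if len(path) >= limit:
            return
        for u, v, s in events:
            if u == node and v not in visited:
                extend(path + [(u, v, s)], visited | {v})

    extend([], {source})
    return cons.build()
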