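"""Synthetic data with planted ground truth.

Emulates every pipeline input: a background interactome (PPI + directed
kinase-substrate edges), a signed signaling cascade rooted at a designated
receptor, replicate fold-change time courses, a kinase x compound
residual-activity matrix, a permeability screen, and a functional
(TREKING-style) kinase model. The planted cascade is the recoverable ground
truth every downstream stage is tested against.

Defaults mirror the western-blot study design: nine time points over six
hours (0, 5, 15, 30, 60, 120, 180, 240, 360 min), three biological
replicates, 28 measured proteins, and a 29-compound inhibitor panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .containers import (
    DEFAULT_TIME_GRID,
    InhibitionMatrix,
    Interactome,
    PartialModel,
    PermeabilityScreen,
    PhosphoDataset,
    PhosphoTimeSeries,
    TrekingModel,
    _check_time_grid,
)
from .errors import ConfigError, DataError

SOURCE_NODE = "RCPT"  # the stimulated receptor; signal entry point


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    noise_cv is the coefficient of variation of the multiplicative lognormal
    replicate noise on fold changes. cascade_depth bounds the planted cascade
    at 8 edges so activation times fit strictly increasing on the nine-point
    grid. step_fold is the fold change a fully activated protein settles at
    (its reciprocal for inhibition).
    """

    n_proteins: int = 140
    n_kinases: int = 70
    n_measured: int = 28
    time_grid: tuple[int, ...] = DEFAULT_TIME_GRID
    n_replicates: int = 3
    noise_cv: float = 0.1
    n_compounds: int = 29
    seed: int = 0
    cascade_size: int = 20
    cascade_depth: int = 4
    inhibition_fraction: float = 0.25
    step_fold: float = 2.0
    edge_density: float = 1.6  # extra PPI edges per node beyond the spanning tree
    pulse: bool = False  # optional pulse (return-to-baseline) response shape

    def __post_init__(self) -> None:
        self.time_grid = _check_time_grid(self.time_grid)
        if self.n_kinases < 2 or self.n_proteins < self.n_kinases:
            raise ConfigError("need n_proteins >= n_kinases >= 2")
        if self.n_replicates < 2:
            raise ConfigError("need >= 2 replicates")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.cascade_depth >= len(self.time_grid):
            raise ConfigError("cascade depth must fit inside the time grid")
        if not 1 < self.step_fold:
            raise ConfigError("step_fold must exceed 1")
        if self.n_measured > self.n_proteins + 1:
            raise ConfigError("cannot measure more proteins than exist")


@dataclass
class GroundTruth:
    """The planted cascade and its phenotype coupling.

    cascade_edges are signed directed edges of a DAG rooted at source_node;
    activation_times give each cascade node's first-response time (minutes on
    the grid), non-decreasing along every edge; barrier_kinases are the
    cascade kinases coupled to the permeability phenotype.
    """

    source_node: str
    cascade_edges: list[tuple[str, str, int]]
    activation_times: dict[str, int]
    barrier_kinases: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        g = nx.DiGraph((u, v) for u, v, _ in self.cascade_edges)
        g.add_node(self.source_node)
        if not nx.is_directed_acyclic_graph(g):
            raise DataError("cascade must be acyclic")
        if self.activation_times.get(self.source_node) != 0:
            raise DataError("source activation time must be 0")
        for n in g.nodes:
            if n != self.source_node and not nx.has_path(g, self.source_node, n):
                raise DataError(f"cascade node {n} not reachable from source")
        for u, v, _ in self.cascade_edges:
            if self.activation_times[v] < self.activation_times[u]:
                raise DataError(f"activation time decreases along {u}->{v}")

    def nodes(self) -> set[str]:
        out = {self.source_node}
        for u, v, _ in self.cascade_edges:
            out |= {u, v}
        return out

    def cumulative_signs(self) -> dict[str, int]:
        """Sign of each node's response: product of edge signs from source."""
        signs = {self.source_node: 1}
        order = list(nx.topological_sort(
            nx.DiGraph((u, v) for u, v, _ in self.cascade_edges)))
        edge_sign = {(u, v): s for u, v, s in self.cascade_edges}
        for v in order:
            if v == self.source_node:
                continue
            # all planted parents agree by construction (tree-shaped cascade)
            for u, s in ((u, s) for (u, w), s in edge_sign.items() if w == v):
                signs[v] = signs[u] * s
        return signs


def _protein_names(cfg: SimulationConfig) -> tuple[list[str], list[str]]:
    kinases = [f"K{i:03d}" for i in range(cfg.n_kinases)]
    others = [f"P{i:03d}" for i in range(cfg.n_proteins - cfg.n_kinases)]
    return kinases, others


def generate_interactome(cfg: SimulationConfig) -> Interactome:
    """Random connected background network.

    The PPI layer is a random spanning tree over all proteins plus the
    receptor, densified with extra random edges; confidences are uniform.
    Directed kinase-substrate edges are drawn from PPI adjacencies whose one
    endpoint is a kinase, oriented out of the kinase, with a random sign.
    """
    rng = np.random.default_rng(cfg.seed)
    kinases, others = _protein_names(cfg)
    nodes = [SOURCE_NODE] + kinases + others

    ppi = nx.Graph()
    for n in nodes:
        ppi.add_node(n, is_kinase=(n in set(kinases)))

    # random spanning tree: attach each node to a random earlier node
    for i in range(1, len(nodes)):
        j = int(rng.integers(0, i))
        ppi.add_edge(nodes[i], nodes[j])
    n_extra = int(cfg.edge_density * len(nodes)) - (len(nodes) - 1)
    attempts = 0
    while n_extra > 0 and attempts < 50 * len(nodes):
        u, v = (str(x) for x in rng.choice(nodes, size=2, replace=False))
        attempts += 1
        if not ppi.has_edge(u, v):
            ppi.add_edge(u, v)
            n_extra -= 1
    for u, v in ppi.edges:
        ppi.edges[u, v]["confidence"] = float(rng.uniform(0.4, 0.7))

    ks = nx.DiGraph()
    kin_set = set(kinases)
    for u, v in sorted(map(tuple, map(sorted, ppi.edges))):
        for a, b in ((u, v), (v, u)):
            if a in kin_set and rng.random() < 0.6:
                sign = int(rng.choice([1, -1], p=[0.8, 0.2]))
                ks.add_edge(a, b, sign=sign)
    return Interactome(ppi, ks)


def plant_cascade(net: Interactome, cfg: SimulationConfig) -> GroundTruth:
    """Plant a signed tree-shaped cascade rooted at the receptor.

    Grown by breadth-limited expansion over existing PPI adjacencies so
    every cascade edge is an orientation of an interactome edge. Each node's
    activation time is the grid point at its depth, hence strictly
    increasing along every root-to-leaf path. Cascade edges get their PPI
    confidence raised: true signaling edges are the well-supported ones.
    """
    if SOURCE_NODE not in net.ppi:
        raise DataError(f"source node {SOURCE_NODE} absent from interactome")
    rng = np.random.default_rng(cfg.seed + 1)
    grid = cfg.time_grid

    edges: list[tuple[str, str, int]] = []
    times = {SOURCE_NODE: 0}
    depth = {SOURCE_NODE: 0}
    frontier = [SOURCE_NODE]
    in_cascade = {SOURCE_NODE}
    while frontier and len(in_cascade) < cfg.cascade_size + 1:
        u = frontier.pop(0)
        if depth[u] >= cfg.cascade_depth:
            continue
        nbrs = [n for n in sorted(net.ppi.neighbors(u)) if n not in in_cascade]
        if not nbrs:
            continue
        n_children = min(len(nbrs), int(rng.integers(2, 5)),
                         cfg.cascade_size + 1 - len(in_cascade))
        # signal relays preferentially through kinases
        weights = np.array(
            [3.0 if net.ppi.nodes[n]["is_kinase"] else 1.0 for n in nbrs]
        )
        picked = [str(x) for x in rng.choice(
            nbrs, size=n_children, replace=False, p=weights / weights.sum()
        )]
        for v in sorted(picked):
            sign = int(rng.choice([1, -1], p=[0.75, 0.25]))
            # keep kinase-substrate priors consistent with the planted sign
            if net.ks.has_edge(u, v):
                net.ks.edges[u, v]["sign"] = sign
            if net.ks.has_edge(v, u):
                net.ks.remove_edge(v, u)
            edges.append((u, v, sign))
            depth[v] = depth[u] + 1
            times[v] = grid[depth[v]]
            in_cascade.add(v)
            frontier.append(v)
            net.ppi.edges[u, v]["confidence"] = float(rng.uniform(0.95, 0.99))

    barrier = {n for n in in_cascade
               if net.ppi.nodes[n]["is_kinase"] and n != SOURCE_NODE}
    return GroundTruth(SOURCE_NODE, edges, times, barrier)


def measured_proteins(truth: GroundTruth, cfg: SimulationConfig) -> list[str]:
    """Cascade nodes plus enough off-cascade proteins to reach n_measured.

    Off-cascade picks favor kinases: a blot panel like the motivating one is
    kinase-dominated, and kinases with no thrombin response anchor the
    negative side of the time-resolved validation.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    kinases, others = _protein_names(cfg)
    cascade = sorted(truth.nodes() - {truth.source_node})
    pool_kin = [p for p in kinases if p not in set(cascade)]
    pool_oth = [p for p in others if p not in set(cascade)]
    n_extra = max(0, cfg.n_measured - len(cascade))
    take_kin = min(n_extra, len(pool_kin))
    extra = sorted(
        str(x) for x in rng.choice(pool_kin, size=take_kin, replace=False)
    )
    if n_extra > take_kin:
        extra += sorted(str(x) for x in rng.choice(
            pool_oth, size=min(n_extra - take_kin, len(pool_oth)), replace=False
        ))
    return cascade + sorted(extra)


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean exactly 1 and the requested CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def generate_timeseries(truth: GroundTruth, cfg: SimulationConfig) -> PhosphoDataset:
    """Fold-change trajectories for the measured proteins.

    Cascade proteins follow a sustained step beginning at their activation
    time — up to step_fold if the cumulative edge sign from the source is +,
    down to 1/step_fold if it is - (a pulse returning to baseline after two
    grid steps when cfg.pulse). Off-cascade proteins fluctuate around a mean
    of exactly 1. Noise is multiplicative lognormal with CV = noise_cv;
    every replicate is exactly 1 at t=0 (data are normalized to time zero).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    grid = np.asarray(cfg.time_grid)
    measured = measured_proteins(truth, cfg)
    missing = truth.nodes() - {truth.source_node} - set(measured)
    if missing:
        raise DataError(f"cascade nodes not in measured set: {sorted(missing)}")
    signs = truth.cumulative_signs()

    series = {}
    for prot in measured:
        base = np.ones(len(grid))
        if prot in truth.activation_times:
            t_on = truth.activation_times[prot]
            target = cfg.step_fold if signs[prot] > 0 else 1.0 / cfg.step_fold
            on = grid >= t_on
            if cfg.pulse:
                idx = int(np.searchsorted(grid, t_on))
                on = np.zeros(len(grid), bool)
                on[idx:idx + 2] = True
            base[on] = target
        vals = base * _lognormal_noise(rng, cfg.noise_cv,
                                       (cfg.n_replicates, len(grid)))
        vals[:, 0] = 1.0
        series[prot] = PhosphoTimeSeries(prot, cfg.time_grid, vals)
    return PhosphoDataset(cfg.time_grid, series)


def partial_model_from_interactome(net: Interactome) -> PartialModel:
    """Directed signed priors: the interactome's kinase-substrate layer."""
    return PartialModel(
        (u, v, d.get("sign")) for u, v, d in net.ks.edges(data=True)
    )


def generate_inhibition_matrix(
    truth: GroundTruth, cfg: SimulationConfig, net: Interactome
) -> InhibitionMatrix:
    """Kinase x compound residual activities in [0, 100].

    The panel spans the selectivity spectrum of real kinase-inhibitor
    libraries, each class planted with a known relationship to the cascade:

    - broad hitters (~1/3): residual under 30% on most barrier kinases,
      nearly inert elsewhere — the compounds that truly perturb the
      phenotype;
    - selective decoys (~1/4): near-complete inhibition of a handful of
      specific kinases, at most one of them a barrier kinase held below the
      50% phenotype threshold — phenotype-silent but dominant on small
      kinase sets;
    - cluster decoys (~1/10): roughly 45% inhibition of three specific
      barrier kinases and nothing else — phenotype-silent, and their bounded
      score can only clear the cutoff of a small network;
    - promiscuous binders (~1/5): moderate inhibition across most
      non-barrier kinases — phenotype-silent ballast that accumulates over
      any large kinase set;
    - inert controls: residual 95-100% everywhere.

    Residuals for a random ~10% of unplanted pairs are left unmeasured
    (NaN), never zero.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed + 4)
    kinases = sorted(net.kinases())
    compounds = [f"C{i:02d}" for i in range(cfg.n_compounds)]
    n = cfg.n_compounds
    n_hit = max(1, round(0.31 * n))
    n_decoy = round(0.28 * n)
    n_cluster = round(0.10 * n)
    n_prom = round(0.21 * n)
    hitters = compounds[:n_hit]
    decoys = compounds[n_hit:n_hit + n_decoy]
    cluster_decoys = compounds[n_hit + n_decoy:n_hit + n_decoy + n_cluster]
    promiscuous = compounds[
        n_hit + n_decoy + n_cluster:n_hit + n_decoy + n_cluster + n_prom
    ]
    barrier = sorted(truth.barrier_kinases)
    non_barrier = [k for k in kinases if k not in truth.barrier_kinases]

    mat = rng.uniform(95, 100, size=(len(kinases), len(compounds)))
    frame = pd.DataFrame(mat, index=kinases, columns=compounds)
    planted = np.zeros(frame.shape, dtype=bool)

    def plant(k, c, residual):
        frame.loc[k, c] = residual
        planted[frame.index.get_loc(k), frame.columns.get_loc(c)] = True

    for c in hitters:
        for k in barrier:
            if rng.random() < 0.85:
                plant(k, c, rng.uniform(0, 30))
    barrier_cycle = list(rng.permutation(barrier)) if barrier else []
    for i, c in enumerate(decoys):
        if barrier_cycle:
            plant(barrier_cycle[i % len(barrier_cycle)], c, rng.uniform(52, 58))
        if non_barrier:
            idx = rng.choice(len(non_barrier), size=min(4, len(non_barrier)),
                             replace=False)
            for j in idx:
                plant(non_barrier[j], c, rng.uniform(5, 15))
    for i, c in enumerate(cluster_decoys):
        for j in range(3):
            if barrier_cycle:
                k = barrier_cycle[(len(decoys) + 3 * i + j) % len(barrier_cycle)]
                plant(k, c, rng.uniform(52, 58))
    for c in promiscuous:
        for k in non_barrier:
            if rng.random() < 0.9:
                plant(k, c, rng.uniform(62, 72))
    mask = (rng.random(frame.shape) < 0.10) & ~planted
    frame = frame.mask(mask)
    return InhibitionMatrix(frame)


def generate_permeability_screen(
    truth: GroundTruth,
    matrix: InhibitionMatrix,
    cfg: SimulationConfig,
    auc_cv: float = 0.03,
    shift_per_kinase: float = 0.06,
) -> PermeabilityScreen:
    """Per-compound permeability AUC replicates against a DMSO control.

    The planted effect couples the phenotype to the cascade: each compound's
    mean AUC is shifted up by shift_per_kinase for every barrier kinase it
    inhibits by at least 50%, so compounds hitting several barrier kinases
    clear the 10% detection threshold in every replicate. Null compounds
    match DMSO up to replicate noise.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    if not truth.barrier_kinases:
        warnings.warn("no barrier kinases planted; screen is unperturbed")
    dmso = rng.normal(1.0, auc_cv, size=cfg.n_replicates)
    dmso = np.clip(dmso, 0.5, None)
    out = {}
    for c in matrix.compounds:
        n_hit = sum(
            1 for k in truth.barrier_kinases
            if k in matrix.frame.index
            and np.isfinite(matrix.residual(k, c))
            and (100.0 - matrix.residual(k, c)) >= 50.0
        )
        mean = 1.0 + shift_per_kinase * n_hit
        reps = rng.normal(mean, auc_cv * mean, size=cfg.n_replicates)
        out[c] = np.clip(reps, 0.5, None)
    return PermeabilityScreen(out, dmso)


def generate_treking_fixture(
    truth: GroundTruth, cfg: SimulationConfig, net: Interactome
) -> TrekingModel:
    """Functional kinase model consistent with the planted cascade.

    Barrier kinases are labelled functional in a window spanning their
    activation time (weakening for net-activating, strengthening for
    net-inhibiting responses, matching the barrier-disruption phenotype of
    an activating cascade); other kinases are 'none' throughout. Kinases are
    assigned to clusters; the background network reuses the interactome's
    kinase-substrate layer.
    """
    rng = np.random.default_rng(cfg.seed + 6)
    grid = cfg.time_grid
    signs = truth.cumulative_signs()
    n_clusters = 36
    functionality: dict[str, dict[int, str]] = {}
    intervals: dict[str, list[tuple[float, float]]] = {}
    clusters: dict[str, int] = {}

    for k in sorted(net.kinases()):
        clusters[k] = int(rng.integers(1, n_clusters + 1))
        per_t = {t: "none" for t in grid}
        intervals[k] = []
        if k in truth.barrier_kinases:
            t_on = truth.activation_times[k]
            label = "weakening" if signs[k] > 0 else "strengthening"
            idx = grid.index(t_on)
            active = [t for t in grid[idx:idx + 3]]
            for t in active:
                per_t[t] = label
            intervals[k] = [(float(active[0]), float(active[-1]))]
        functionality[k] = per_t
    return TrekingModel(
        time_grid=grid,
        functionality=functionality,
        intervals=intervals,
        clusters=clusters,
        background=net.ks.copy(),
        n_clusters=n_clusters,
    )


@dataclass
class SyntheticStudy:
    """Everything one simulated experiment produces, bundled."""

    cfg: SimulationConfig
    truth: GroundTruth
    interactome: Interactome
    dataset: PhosphoDataset
    partial_model: PartialModel
    inhibition: InhibitionMatrix
    screen: PermeabilityScreen
    treking: TrekingModel

    @property
    def source(self) -> str:
        return self.truth.source_node


def simulate_study(cfg: SimulationConfig) -> SyntheticStudy:
    """Run the full generator chain for one seed."""
    net = generate_interactome(cfg)
    truth = plant_cascade(net, cfg)
    data = generate_timeseries(truth, cfg)
    pm = partial_model_from_interactome(net)
    inh = generate_inhibition_matrix(truth, cfg, net)
    screen = generate_permeability_screen(truth, inh, cfg)
    treking = generate_treking_fixture(truth, cfg, net)
    return SyntheticStudy(cfg, truth, net, data, pm, inh, screen, treking)


def generate_synthesis_instance(
    rng: np.random.Generator,
) -> tuple["SubNetwork", PartialModel, dict]:
    """A random small synthesis problem: subnetwork, priors, profiles.

    Used for oracle-equivalence checks of the synthesis core: instances are
    small enough (<= 9 nodes) for exhaustive path enumeration.
    """
    from .containers import ACTIVATED, INHIBITED, ActivityProfile, SubNetwork

    grid = (0, 5, 15, 30, 60)
    n = int(rng.integers(3, 9))
    nodes = ["S"] + [f"N{i}" for i in range(n)]
    g = nx.Graph()
    g.add_node("S")
    for i in range(1, len(nodes)):
        g.add_edge(nodes[i], nodes[int(rng.integers(0, i))])
    for _ in range(int(rng.integers(0, n))):
        u, v = rng.choice(nodes, size=2, replace=False)
        if u != v:
            g.add_edge(str(u), str(v))
    sub = SubNetwork(g, "S")
    pm_edges = []
    for u, v in g.edges:
        if rng.random() < 0.4:
            sign = rng.choice([1, -1, 0])
            pm_edges.append((u, v, int(sign) if sign else None))
    profs = {}
    for nd in nodes[1:]:
        if rng.random() < 0.7:
            states = ["inactive"]
            for _ in grid[1:]:
                r = rng.random()
                states.append(
                    ACTIVATED if r < 0.3 else INHIBITED if r < 0.5 else "inactive"
                )
            profs[nd] = ActivityProfile(nd, grid, tuple(states))
    return sub, PartialModel(pm_edges), profs
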