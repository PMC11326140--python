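"""Randomization null models.

Two 100-iteration ensembles quantify how much of each arm's validation
accuracy survives destruction of the real structure. The phospho-network
null shuffles node labels of the subnetwork and partial model and globally
shuffles the time-series values and significance scores, then reruns the
synthesis and validation unchanged. The functional-model null rebuilds the
background network with a degree-preserving directed configuration model,
shuffles kinases onto nodes, resamples per-time functionality labels with
the true model's per-time probabilities from the inhibitor-screen kinase
pool, assigns sampled kinases to random clusters, and reconnects each
cluster by unweighted shortest paths in the random background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np

from .containers import (
    NullEnsemble,
    PartialModel,
    PhosphoDataset,
    PhosphoTimeSeries,
    SignificanceScores,
    SubNetwork,
    TrekingModel,
)
from .errors import DataError
from .preprocess import discretize_activity
from .synthesis import DEFAULT_MAX_PATH_LEN, synthesize
from .validation import ValidationConfig, validate_tps_arm, validate_treking_arm


@dataclass
class TrekingNullConfig:
    """Sampling frame of the functional-model null.

    n_kir_kinases is the size of the kinase pool the screen models draw
    from (300 in the motivating study); n_clusters the number of
    self-organizing-map clusters (36). The kinase pool itself is passed at
    call time so synthetic studies can use their own kinase universe.
    """

    n_kir_kinases: int = 300
    n_clusters: int = 36

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_kir_kinases < 1:
            raise DataError("cluster and pool sizes must be >= 1")


# ---------------------------------------------------------------- shuffles


def shuffle_network_nodes(graph: nx.Graph | nx.DiGraph, seed: int):
    """Uniformly random relabeling; structure preserved exactly."""
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    perm = [str(x) for x in rng.permutation(nodes)]
    return nx.relabel_nodes(graph, dict(zip(nodes, perm)), copy=True)


def relabel_from_universe(
    graph: nx.Graph | nx.DiGraph,
    universe: list[str],
    seed: int,
    fixed: tuple[str, ...] = (),
):
    """Relabel ``graph``'s nodes with a random draw from a label universe.

    A uniformly random injection of the graph's nodes into ``universe``
    (labels in ``fixed`` map to themselves), so edge structure — degree
    sequence, edge count, connectivity pattern — is preserved exactly while
    node identities are randomized over the whole network's vocabulary.
    Falls back to a within-graph permutation when the universe is smaller
    than the graph.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    pool = sorted(set(universe) - set(fixed)) or nodes
    movable = [n for n in nodes if n not in fixed]
    if len(pool) < len(movable):
        pool = movable
    targets = [str(x) for x in rng.choice(pool, size=len(movable), replace=False)]
    mapping = dict(zip(movable, targets))
    mapping.update({n: n for n in fixed if n in graph})
    return nx.relabel_nodes(graph, mapping, copy=True)


def shuffle_subnetwork(
    sub: SubNetwork, seed: int, universe: list[str] | None = None
) -> SubNetwork:
    """Node-label shuffle of the subnetwork, source held fixed.

    Labels are drawn from ``universe`` (the background network's node set)
    when given, so the randomized subnetwork's membership — not merely its
    wiring — is random; with no universe the permutation is within the
    subnetwork's own labels. Connectivity from the source is preserved
    because relabeling is an isomorphism.
    """
    if universe is None:
        g = relabel_from_universe(sub.graph, sorted(sub.graph.nodes), seed,
                                  fixed=(sub.source,))
    else:
        g = relabel_from_universe(sub.graph, universe, seed, fixed=(sub.source,))
    return SubNetwork(g, sub.source)


def shuffle_partial_model(pm: PartialModel, seed: int) -> PartialModel:
    g = shuffle_network_nodes(pm.graph, seed)
    return PartialModel((u, v, d["sign"]) for u, v, d in g.edges(data=True))


def shuffle_timeseries(
    data: PhosphoDataset,
    scores: dict[str, SignificanceScores],
    seed: int,
    per_protein: bool = False,
) -> tuple[PhosphoDataset, dict[str, SignificanceScores]]:
    """Global value shuffle of the dataset and (independently) the scores.

    The multiset of fold-change values (t > 0) and of p-values is preserved
    exactly; only their assignment to (protein, replicate, time) cells is
    randomized. Time-zero columns stay at 1 (they are definitional, not
    measurements). per_protein restricts the shuffle to within each
    protein's own cells.
    """
    rng = np.random.default_rng(seed)
    proteins = data.proteins()

    new_series: dict[str, PhosphoTimeSeries] = {}
    if per_protein:
        for p in proteins:
            vals = data[p].values.copy()
            body = vals[:, 1:].ravel()
            vals[:, 1:] = rng.permutation(body).reshape(vals[:, 1:].shape)
            new_series[p] = PhosphoTimeSeries(p, data.time_grid, vals)
    else:
        pool = np.concatenate([data[p].values[:, 1:].ravel() for p in proteins])
        pool = rng.permutation(pool)
        i = 0
        for p in proteins:
            vals = data[p].values.copy()
            block = vals[:, 1:]
            vals[:, 1:] = pool[i:i + block.size].reshape(block.shape)
            i += block.size
            new_series[p] = PhosphoTimeSeries(p, data.time_grid, vals)
    new_data = PhosphoDataset(data.time_grid, new_series)

    new_scores: dict[str, SignificanceScores] = {}
    firsts = np.concatenate([scores[p].firstscores for p in proteins])
    prevs = np.concatenate([scores[p].prevscores for p in proteins])
    firsts = rng.permutation(firsts)
    prevs = rng.permutation(prevs)
    i = 0
    for p in proteins:
        n = scores[p].firstscores.size
        new_scores[p] = SignificanceScores(
            p, firsts[i:i + n], prevs[i:i + n], scores[p].threshold
        )
        i += n
    return new_data, new_scores


# --------------------------------------------------------- phospho-arm null


def random_tps_ensemble(
    sub: SubNetwork,
    pm: PartialModel,
    data: PhosphoDataset,
    scores: dict[str, SignificanceScores],
    matrix,
    screen,
    kinases: set[str],
    source: str,
    n: int = 100,
    base_seed: int = 0,
    cfg: ValidationConfig | None = None,
    max_path_len: int = DEFAULT_MAX_PATH_LEN,
    universe: list[str] | None = None,
) -> NullEnsemble:
    """Accuracy distribution of randomized phospho-network models.

    Each iteration shuffles network node labels and data/score values, reruns
    the synthesis from the fixed source, and scores the resulting network's
    kinases with the inhibitor-validation arm. Iterations whose synthesis or
    validation is undefined (no changing protein, no positive prediction)
    record NaN rather than being dropped.
    """
    cfg = cfg or ValidationConfig()
    accs = np.full(n, np.nan)
    seeds = [int(np.random.default_rng([base_seed, i]).integers(0, 2**31))
             for i in range(n)]
    for i, s in enumerate(seeds):
        try:
            rsub = shuffle_subnetwork(
                sub, s, universe=universe or sorted(kinases | sub.nodes())
            )
            rpm = shuffle_partial_model(pm, s + 1)
            rdata, rscores = shuffle_timeseries(data, scores, s + 2)
            profiles = {
                p: discretize_activity(rdata[p], rscores[p])
                for p in rdata.proteins()
            }
            summary, _ = synthesize(rsub, rpm, profiles, source,
                                    max_path_len=max_path_len)
            net_kinases = summary.nodes() & kinases
            if not net_kinases:
                continue
            report = validate_tps_arm(net_kinases, matrix, screen, cfg)
            if report["accuracy"] is not None:
                accs[i] = report["accuracy"]
        except DataError:
            continue  # undefined iteration stays NaN, recorded in the ensemble
    return NullEnsemble("tps", accs, seeds, n)


# ------------------------------------------------------ functional-arm null


def configuration_model_network(
    net: nx.DiGraph, seed: int, collapse: bool = True
) -> nx.DiGraph | nx.MultiDiGraph:
    """Directed configuration-model randomization of ``net``.

    The multigraph realization preserves every node's in- and out-degree
    exactly. With collapse=True (default) self-loops and parallel edges are
    removed afterwards, which may perturb degrees slightly; pass
    collapse=False to get the raw multigraph.
    """
    if net.number_of_nodes() == 0:
        raise DataError("cannot randomize an empty network")
    nodes = sorted(net.nodes)
    din = [net.in_degree(n) for n in nodes]
    dout = [net.out_degree(n) for n in nodes]
    rng = np.random.default_rng(seed)
    multi = nx.directed_configuration_model(din, dout, seed=int(rng.integers(2**31)))
    multi = nx.relabel_nodes(multi, dict(enumerate(nodes)), copy=True)
    if not collapse:
        return multi
    simple = nx.DiGraph()
    simple.add_nodes_from(nodes)
    simple.add_edges_from((u, v) for u, v in multi.edges() if u != v)
    return simple


def random_treking_model(
    cfg: TrekingNullConfig,
    true_model: TrekingModel,
    background: nx.DiGraph,
    seed: int,
    kinase_pool: list[str] | None = None,
) -> tuple[TrekingModel, int, nx.DiGraph]:
    """One randomized functional model.

    Returns (model, n_unreachable_pairs, random_background): the model's
    ``background`` holds the per-cluster shortest-path network; the raw
    configuration-model background is returned alongside so callers can
    audit the path construction.

    Per time point, weakening/strengthening labels are resampled from the
    kinase pool with the true model's selection probabilities; sampled
    kinases get uniform random clusters; each cluster's network is the union
    of all unweighted shortest paths between its kinase pairs in the
    configuration-model background (unreachable pairs are counted, not
    fatal). Pathway activity intervals are rebuilt from the sampled labels
    exactly as for the true model: maximal runs of non-'none' labels.
    """
    rng = np.random.default_rng(seed)
    grid = true_model.time_grid
    pool = sorted(kinase_pool) if kinase_pool is not None else sorted(
        true_model.functionality
    )
    n_pool = max(len(pool), 1)

    rnd_bg = configuration_model_network(background, int(rng.integers(2**31)))
    # shuffle kinases onto the nodes of the random network
    nodes = sorted(rnd_bg.nodes)
    perm = [str(x) for x in rng.permutation(nodes)]
    rnd_bg = nx.relabel_nodes(rnd_bg, dict(zip(nodes, perm)), copy=True)

    functionality: dict[str, dict[int, str]] = {
        k: {t: "none" for t in grid} for k in pool
    }
    for t in grid:
        for label in ("weakening", "strengthening"):
            n_true = sum(
                1 for k in true_model.functionality
                if true_model.functionality[k].get(t) in (label, "both")
            )
            p_select = n_true / n_pool
            picks = [k for k in pool if rng.random() < p_select]
            for k in picks:
                cur = functionality[k][t]
                if cur == "none":
                    functionality[k][t] = label
                elif cur not in (label, "both"):
                    functionality[k][t] = "both"

    selected = [k for k in pool
                if any(f != "none" for f in functionality[k].values())]
    clusters = {k: int(rng.integers(1, cfg.n_clusters + 1)) for k in selected}

    cluster_net = nx.DiGraph()
    n_unreachable = 0
    for cid in sorted(set(clusters.values())):
        members = sorted(k for k, c in clusters.items() if c == cid)
        for a, b in combinations(members, 2):
            for s, t2 in ((a, b), (b, a)):
                if s not in rnd_bg or t2 not in rnd_bg:
                    n_unreachable += 1
                    continue
                try:
                    for path in nx.all_shortest_paths(rnd_bg, s, t2):
                        nx.add_path(cluster_net, path)
                except nx.NetworkXNoPath:
                    n_unreachable += 1

    intervals: dict[str, list[tuple[float, float]]] = {k: [] for k in pool}
    for k in pool:
        run_start = None
        prev_t = None
        for t in grid:
            active = functionality[k][t] != "none"
            if active and run_start is None:
                run_start = t
            if not active and run_start is not None:
                intervals[k].append((float(run_start), float(prev_t)))
                run_start = None
            if active:
                prev_t = t
        if run_start is not None:
            intervals[k].append((float(run_start), float(prev_t)))

    model = TrekingModel(
        time_grid=grid,
        functionality=functionality,
        intervals=intervals,
        clusters={k: clusters.get(k, 1) for k in pool},
        background=cluster_net,
        n_clusters=cfg.n_clusters,
    )
    return model, n_unreachable, rnd_bg


def random_treking_ensemble(
    cfg: TrekingNullConfig,
    true_model: TrekingModel,
    background: nx.DiGraph,
    data: PhosphoDataset,
    n: int = 100,
    base_seed: int = 0,
    vcfg: ValidationConfig | None = None,
    kinase_pool: list[str] | None = None,
) -> NullEnsemble:
    """Accuracy distribution of randomized functional models."""
    vcfg = vcfg or ValidationConfig()
    accs = np.full(n, np.nan)
    seeds = [int(np.random.default_rng([base_seed, 7, i]).integers(0, 2**31))
             for i in range(n)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, s in enumerate(seeds):
            model, _, _ = random_treking_model(cfg, true_model, background, s,
                                               kinase_pool)
            report = validate_treking_arm(model, data, vcfg)
            if report["accuracy"] is not None:
                accs[i] = report["accuracy"]
    return NullEnsemble("treking", accs, seeds, n)


def ensemble_summary(ens: NullEnsemble, true_accuracy: float | None) -> dict:
    """JSON-ready summary: moments, percentiles, and the empirical p-value."""
    d = ens.defined()
    return {
        "arm": ens.arm,
        "n_iterations": ens.n_iterations,
        "n_defined": int(d.size),
        "mean": float(d.mean()) if d.size else None,
        "sd": float(d.std(ddof=1)) if d.size > 1 else None,
        "p5": ens.percentile(5) if d.size else None,
        "p50": ens.percentile(50) if d.size else None,
        "p95": ens.percentile(95) if d.size else None,
        "true_accuracy": true_accuracy,
        "empirical_p": (
            ens.empirical_p(true_accuracy) if true_accuracy is not None else None
        ),
    }
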