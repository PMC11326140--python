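"""Readers and writers for the pipeline's plain-text formats.

All files are UTF-8 TSV (or JSON for models and reports). Writers emit a
header comment block naming the producing stage, its parameters and seed;
readers skip '#' lines. Numeric values are written with repr-faithful
formatting so write(read(x)) is byte-identical for canonical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    InhibitionMatrix,
    Interactome,
    PartialModel,
    PermeabilityScreen,
    PhosphoDataset,
    PhosphoTimeSeries,
    SubNetwork,
    SummaryNetwork,
    TrekingModel,
    ActivityWindows,
)
from .errors import DataError

_SIGN_TO_STR = {1: "+", -1: "-", None: "?"}
_STR_TO_SIGN = {"+": 1, "-": -1, "?": None}


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def _header(stage: str, params: dict | None = None, seed: int | None = None) -> str:
    lines = [f"# stage={stage}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    if params:
        kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
        lines.append(f"# params: {kv}")
    return "\n".join(lines) + "\n"


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Return (header fields, [(line number, fields), ...]) skipping comments."""
    header = None
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append((lineno, fields))
    if header is None:
        raise DataError(f"{path}: empty file")
    return header, rows


# -------------------------------------------------------------- time series


def write_timeseries(data: PhosphoDataset, path: str | Path,
                     stage: str = "simulate", seed: int | None = None) -> None:
    """One row per protein x replicate; columns are minutes on the grid."""
    cols = "\t".join(str(t) for t in data.time_grid)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, {"n_proteins": len(data)}, seed))
        fh.write(f"protein\treplicate\t{cols}\n")
        for p in data.proteins():
            ts = data[p]
            for r in range(ts.n_replicates):
                vals = "\t".join(_fmt(v) for v in ts.values[r])
                fh.write(f"{p}\t{r + 1}\t{vals}\n")


def read_timeseries(path: str | Path,
                    expect_grid: tuple[int, ...] | None = None) -> PhosphoDataset:
    """Read a time-series TSV; optionally enforce an expected time grid."""
    header, rows = _read_rows(path)
    if header[:2] != ["protein", "replicate"]:
        raise DataError(f"{path}: expected columns protein, replicate, <minutes...>")
    try:
        grid = tuple(int(t) for t in header[2:])
    except ValueError as e:
        raise DataError(f"{path}: non-integer time column: {e}") from None
    if expect_grid is not None and grid != tuple(expect_grid):
        raise DataError(
            f"{path}: time grid {grid} does not match required grid "
            f"{tuple(expect_grid)}"
        )
    per_protein: dict[str, list[list[float]]] = {}
    for lineno, fields in rows:
        if len(fields) != 2 + len(grid):
            raise DataError(f"{path}:{lineno}: wrong column count")
        per_protein.setdefault(fields[0], []).append(
            [float(v) for v in fields[2:]]
        )
    series = {
        p: PhosphoTimeSeries(p, grid, np.array(vals))
        for p, vals in per_protein.items()
    }
    return PhosphoDataset(grid, series)


# -------------------------------------------------------------- score files


def write_scores(scores: dict, path: str | Path, stage: str = "preprocess",
                 seed: int | None = None) -> None:
    """Rows: protein, track (first|prev), then T-1 p-values."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("protein\ttrack\tscores\n")
        for p in sorted(scores):
            sc = scores[p]
            for track, arr in (("first", sc.firstscores), ("prev", sc.prevscores)):
                vals = "\t".join(_fmt(v) for v in arr)
                fh.write(f"{p}\t{track}\t{vals}\n")


def read_scores(path: str | Path, threshold: float = 0.05) -> dict:
    from .containers import SignificanceScores

    _, rows = _read_rows(path)
    first: dict[str, list[float]] = {}
    prev: dict[str, list[float]] = {}
    for lineno, fields in rows:
        p, track, vals = fields[0], fields[1], [float(v) for v in fields[2:]]
        if track == "first":
            first[p] = vals
        elif track == "prev":
            prev[p] = vals
        else:
            raise DataError(f"{path}:{lineno}: unknown track {track!r}")
    if set(first) != set(prev):
        raise DataError(f"{path}: first/prev tracks cover different proteins")
    return {
        p: SignificanceScores(p, np.array(first[p]), np.array(prev[p]), threshold)
        for p in first
    }


# -------------------------------------------------------------- interactome


def write_interactome(net: Interactome, path: str | Path,
                      stage: str = "simulate", seed: int | None = None) -> None:
    """SIF-like rows: node1, type (pp|ks), node2, confidence, sign."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("node1\tinteraction\tnode2\tconfidence\tsign\n")
        for u, v in sorted(map(tuple, map(sorted, net.ppi.edges))):
            c = net.ppi.edges[u, v]["confidence"]
            fh.write(f"{u}\tpp\t{v}\t{_fmt(c)}\t?\n")
        for u, v in sorted(net.ks.edges):
            s = _SIGN_TO_STR[net.ks.edges[u, v].get("sign")]
            fh.write(f"{u}\tks\t{v}\t1\t{s}\n")
        fh.write("#nodes\n")
        for n in sorted(net.ppi.nodes):
            flag = "kinase" if net.ppi.nodes[n]["is_kinase"] else "protein"
            fh.write(f"#node\t{n}\t{flag}\n")


def read_interactome(path: str | Path) -> Interactome:
    ppi = nx.Graph()
    ks = nx.DiGraph()
    kinds: dict[str, bool] = {}
    seen: set[tuple] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#node\t"):
                _, n, flag = line.split("\t")
                kinds[n] = flag == "kinase"
                continue
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "node1":
                continue
            if len(fields) != 5:
                raise DataError(f"{path}:{lineno}: expected 5 columns")
            u, kind, v, conf, sign = fields
            key = (kind, u, v) if kind == "ks" else (kind, *sorted((u, v)))
            if key in seen:
                raise DataError(f"{path}:{lineno}: duplicate edge {u}-{v}")
            seen.add(key)
            if kind == "pp":
                ppi.add_edge(u, v, confidence=float(conf))
            elif kind == "ks":
                ks.add_edge(u, v, sign=_STR_TO_SIGN[sign])
            else:
                raise DataError(f"{path}:{lineno}: unknown interaction {kind!r}")
    for n in set(ppi.nodes) | set(ks.nodes) | set(kinds):
        if n not in ppi:
            ppi.add_node(n)
        ppi.nodes[n]["is_kinase"] = kinds.get(n, False)
    return Interactome(ppi, ks)


# --------------------------------------------------- subnetwork / partial model


def write_subnetwork(sub: SubNetwork, path: str | Path,
                     stage: str = "extract", seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, {"source": sub.source}, seed))
        fh.write("node1\tnode2\n")
        for u, v in sub.edges():
            fh.write(f"{u}\t{v}\n")


def read_subnetwork(path: str | Path, source: str) -> SubNetwork:
    _, rows = _read_rows(path)
    g = nx.Graph()
    g.add_node(source)
    seen = set()
    for lineno, fields in rows:
        if len(fields) != 2:
            raise DataError(f"{path}:{lineno}: expected 2 columns")
        key = tuple(sorted(fields))
        if key in seen:
            raise DataError(f"{path}:{lineno}: duplicate edge {fields[0]}-{fields[1]}")
        seen.add(key)
        g.add_edge(*fields)
    return SubNetwork(g, source)


def write_partial_model(pm: PartialModel, path: str | Path,
                        stage: str = "simulate", seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("kinase\tsubstrate\tsign\n")
        for u, v, s in pm.edges():
            fh.write(f"{u}\t{v}\t{_SIGN_TO_STR[s]}\n")


def read_partial_model(path: str | Path) -> PartialModel:
    _, rows = _read_rows(path)
    edges = []
    seen = set()
    for lineno, fields in rows:
        if len(fields) != 3:
            raise DataError(f"{path}:{lineno}: expected 3 columns")
        u, v, s = fields
        if (u, v) in seen:
            raise DataError(f"{path}:{lineno}: duplicate directed edge {u}->{v}")
        seen.add((u, v))
        edges.append((u, v, _STR_TO_SIGN[s]))
    return PartialModel(edges)


# ----------------------------------------------------------- summary network


def write_summary(net: SummaryNetwork, path: str | Path,
                  stage: str = "synthesize", seed: int | None = None) -> None:
    """Columns: source, target, directed flag, sign, number of valid paths."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("source\ttarget\tdirected\tsign\tn_paths\n")
        for u, v in net.edges():
            d = net.graph.edges[u, v]
            fh.write(f"{u}\t{v}\t1\t{_SIGN_TO_STR[d['sign']]}\t{d['n_paths']}\n")


def read_summary(path: str | Path) -> SummaryNetwork:
    _, rows = _read_rows(path)
    net = SummaryNetwork()
    seen = set()
    for lineno, fields in rows:
        if len(fields) != 5:
            raise DataError(f"{path}:{lineno}: expected 5 columns")
        u, v, _, sign, n_paths = fields
        if (u, v) in seen:
            raise DataError(f"{path}:{lineno}: duplicate directed edge {u}->{v}")
        seen.add((u, v))
        net.add_edge(u, v, _STR_TO_SIGN[sign], int(n_paths))
    return net


def write_windows(win: ActivityWindows, path: str | Path,
                  stage: str = "synthesize", seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("node\ttime\tstates\n")
        for n in sorted(win.windows):
            for t in win.time_grid:
                states = ",".join(sorted(win.windows[n][t]))
                fh.write(f"{n}\t{t}\t{states}\n")


# ------------------------------------------------------------ kinase network


def write_kinase_network(edges: Iterable[tuple[str, str, str]], path: str | Path,
                         stage: str = "compare", seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("kinase1\tkinase2\tfunctionality\n")
        for u, v, f in sorted(edges):
            fh.write(f"{u}\t{v}\t{f}\n")


def read_kinase_network(path: str | Path) -> list[tuple[str, str, str]]:
    _, rows = _read_rows(path)
    out = []
    seen = set()
    for lineno, fields in rows:
        if len(fields) != 3:
            raise DataError(f"{path}:{lineno}: expected 3 columns")
        if tuple(fields[:2]) in seen:
            raise DataError(f"{path}:{lineno}: duplicate edge")
        seen.add(tuple(fields[:2]))
        out.append(tuple(fields))
    return out


# --------------------------------------------------------- validation inputs


def write_inhibition_matrix(m: InhibitionMatrix, path: str | Path,
                            stage: str = "simulate", seed: int | None = None) -> None:
    """Matrix TSV: kinases x compounds; blank cells mean 'not assayed'."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("kinase\t" + "\t".join(m.compounds) + "\n")
        for k in m.kinases:
            cells = [
                "" if np.isnan(m.frame.loc[k, c]) else _fmt(m.frame.loc[k, c])
                for c in m.compounds
            ]
            fh.write(k + "\t" + "\t".join(cells) + "\n")


def read_inhibition_matrix(path: str | Path) -> InhibitionMatrix:
    header, rows = _read_rows(path)
    compounds = header[1:]
    index, values = [], []
    for lineno, fields in rows:
        if len(fields) != len(header):
            raise DataError(f"{path}:{lineno}: wrong column count")
        index.append(fields[0])
        values.append([float(v) if v else np.nan for v in fields[1:]])
    frame = pd.DataFrame(values, index=index, columns=compounds)
    return InhibitionMatrix(frame)


def write_screen(screen: PermeabilityScreen, path: str | Path,
                 stage: str = "simulate", seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, None, seed))
        fh.write("compound\treplicate\tauc\n")
        for r, a in enumerate(screen.dmso_auc, start=1):
            fh.write(f"DMSO\t{r}\t{_fmt(a)}\n")
        for c in screen.compounds():
            for r, a in enumerate(screen.compound_auc[c], start=1):
                fh.write(f"{c}\t{r}\t{_fmt(a)}\n")


def read_screen(path: str | Path) -> PermeabilityScreen:
    _, rows = _read_rows(path)
    per: dict[str, list[float]] = {}
    for lineno, fields in rows:
        if len(fields) != 3:
            raise DataError(f"{path}:{lineno}: expected 3 columns")
        per.setdefault(fields[0], []).append(float(fields[2]))
    if "DMSO" not in per:
        raise DataError(f"{path}: no DMSO control rows")
    dmso = np.array(per.pop("DMSO"))
    return PermeabilityScreen({c: np.array(v) for c, v in per.items()}, dmso)


# ---------------------------------------------------------------- JSON blobs


def write_treking_model(model: TrekingModel, path: str | Path) -> None:
    blob = {
        "time_grid": list(model.time_grid),
        "n_clusters": model.n_clusters,
        "functionality": {
            k: {str(t): f for t, f in per.items()}
            for k, per in model.functionality.items()
        },
        "intervals": {k: [list(i) for i in v] for k, v in model.intervals.items()},
        "clusters": model.clusters,
        "background_edges": sorted(model.background.edges),
    }
    Path(path).write_text(json.dumps(blob, indent=1, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_treking_model(path: str | Path) -> TrekingModel:
    blob = json.loads(Path(path).read_text(encoding="utf-8"))
    bg = nx.DiGraph()
    bg.add_edges_from(blob["background_edges"])
    return TrekingModel(
        time_grid=tuple(blob["time_grid"]),
        functionality={
            k: {int(t): f for t, f in per.items()}
            for k, per in blob["functionality"].items()
        },
        intervals={
            k: [tuple(i) for i in v] for k, v in blob["intervals"].items()
        },
        clusters=blob["clusters"],
        background=bg,
        n_clusters=blob["n_clusters"],
    )


def write_report(report: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, tuple):
            return list(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(report, indent=1, sort_keys=True, default=default) + "\n",
        encoding="utf-8",
    )


def write_ensemble(ens, path: str | Path, stage: str = "nullmodel",
                   seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(stage, {"arm": ens.arm}, seed))
        fh.write("iteration\tseed\taccuracy\n")
        for i, (s, a) in enumerate(zip(ens.seeds, ens.accuracies)):
            val = "NA" if np.isnan(a) else _fmt(a)
            fh.write(f"{i}\t{s}\t{val}\n")
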