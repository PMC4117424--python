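"""File formats: FISH count tables, probe maps, trees (TSV + DOT), fixtures.

Everything is tab-separated text.  Configurations serialize as comma-joined
counts in canonical probe order; that string is the node identifier in tree
files.  Newick is avoided deliberately: these trees carry labeled internal
nodes and inferred Steiner nodes, which Newick represents poorly.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import networkx as nx

from .core import Bounds, ChromosomeMap, Config, Event, EventKind, as_config

logger = logging.getLogger("cnvphylo")


def config_to_str(c: Config) -> str:
    return ",".join(str(v) for v in c)


def str_to_config(s: str) -> Config:
    return as_config(s.split(","))


# ---------------------------------------------------------------------------
# FISH tables and probe maps
# ---------------------------------------------------------------------------


def read_fish_table(
    path: str | Path, bounds: Bounds = Bounds()
) -> tuple[list[Config], list[str]]:
    """Read a cell-by-probe count table (TSV, header = probe names).

    Counts outside the bounds are clamped with a warning (FISH scoring
    saturates: a count of "9+" is recorded as 9).
    """
    path = Path(path)
    lines = path.read_text().strip("\n").split("\n")
    if not lines or not lines[0].strip():
        raise ValueError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    G = len(header)
    cells: list[Config] = []
    clamped = 0
    for ln, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != G:
            raise ValueError(f"{path}:{ln}: expected {G} fields, got {len(fields)}")
        try:
            raw = [int(f) for f in fields]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-integer count") from exc
        cfg = tuple(min(max(v, bounds.lb), bounds.ub) for v in raw)
        if cfg != tuple(raw):
            clamped += 1
        cells.append(cfg)
    if clamped:
        logger.warning("%s: clamped counts in %d cells to bounds", path, clamped)
    if not cells:
        raise ValueError(f"{path}: no cell rows")
    return cells, header


def write_fish_table(
    path: str | Path, cells: Sequence[Config], probe_names: Sequence[str]
) -> None:
    lines = ["\t".join(probe_names)]
    lines += ["\t".join(str(v) for v in c) for c in cells]
    Path(path).write_text("\n".join(lines) + "\n")


def read_probe_map(path: str | Path) -> ChromosomeMap:
    """Probe-name TAB chromosome-label file; line order fixes probe order."""
    names: list[str] = []
    chroms: list[str] = []
    for ln, line in enumerate(Path(path).read_text().strip("\n").split("\n"), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}:{ln}: expected 'probe<TAB>chromosome'")
        names.append(fields[0].strip())
        chroms.append(fields[1].strip())
    return ChromosomeMap(names, chroms)


def write_probe_map(path: str | Path, m: ChromosomeMap) -> None:
    lines = [f"{p}\t{c}" for p, c in zip(m.probe_names, m.chromosomes)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# inferred trees
# ---------------------------------------------------------------------------


def write_tree(path: str | Path, tree: nx.DiGraph) -> None:
    """Edge-list TSV with node records; round-trips exactly."""
    lines = [f"#root\t{config_to_str(tree.graph['root'])}"]
    model = tree.graph.get("model")
    if model is not None:
        lines.append(f"#model\t{getattr(model, 'value', model)}")
    for nd in sorted(tree.nodes):
        a = tree.nodes[nd]
        flag = "observed" if a.get("observed") else "steiner"
        lines.append(f"N\t{config_to_str(nd)}\t{flag}\t{a.get('weight', 0.0):.6g}")
    for p, c in sorted(tree.edges):
        lines.append(f"E\t{config_to_str(p)}\t{config_to_str(c)}\t{tree[p][c]['weight']}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tree(path: str | Path) -> nx.DiGraph:
    T = nx.DiGraph()
    for ln, line in enumerate(Path(path).read_text().strip("\n").split("\n"), 1):
        if line.startswith("#root\t"):
            T.graph["root"] = str_to_config(line.split("\t")[1])
        elif line.startswith("#model\t"):
            T.graph["model"] = line.split("\t")[1]
        elif line.startswith("N\t"):
            _, cfg, flag, w = line.split("\t")
            T.add_node(str_to_config(cfg), observed=flag == "observed", weight=float(w))
        elif line.startswith("E\t"):
            _, p, c, w = line.split("\t")
            p, c = str_to_config(p), str_to_config(c)
            if p not in T or c not in T:
                raise ValueError(f"{path}:{ln}: edge references unknown node")
            T.add_edge(p, c, weight=int(w))
        elif line.strip():
            raise ValueError(f"{path}:{ln}: malformed line")
    if "root" not in T.graph:
        raise ValueError(f"{path}: missing #root record")
    if T.number_of_nodes() > 1 and not nx.is_weakly_connected(T):
        raise ValueError(f"{path}: edge set is disconnected")
    return T


def tree_to_dot(tree: nx.DiGraph) -> str:
    """Graphviz DOT: solid borders for observed cells, dotted for Steiner
    nodes; green edges for net gains, red for net losses."""
    out = ["digraph phylogeny {"]
    for nd in sorted(tree.nodes):
        a = tree.nodes[nd]
        style = "solid" if a.get("observed") else "dotted"
        label = f"{config_to_str(nd)}\\n{a.get('weight', 0.0):.3g}"
        out.append(f'  "{config_to_str(nd)}" [label="{label}", style={style}];')
    for p, c in sorted(tree.edges):
        diff = sum(ci - pi for pi, ci in zip(p, c))
        color = "green" if diff > 0 else ("red" if diff < 0 else "black")
        out.append(
            f'  "{config_to_str(p)}" -> "{config_to_str(c)}"'
            f' [label="{tree[p][c]["weight"]}", color={color}];'
        )
    out.append("}")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# ground-truth clone trees
# ---------------------------------------------------------------------------


def write_truth_tree(path: str | Path, tree: nx.DiGraph) -> None:
    """Clone tree with integer node ids, configs, depths and events."""
    lines = []
    for nd in sorted(tree.nodes):
        a = tree.nodes[nd]
        ev = a.get("event")
        kind = ev.kind.value if ev else "-"
        target = "-" if ev is None or ev.target is None else str(ev.target)
        lines.append(
            f"N\t{nd}\t{config_to_str(a['config'])}\t{a['depth']}\t{kind}\t{target}"
        )
    for p, c in sorted(tree.edges):
        lines.append(f"E\t{p}\t{c}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth_tree(path: str | Path) -> nx.DiGraph:
    T = nx.DiGraph()
    for line in Path(path).read_text().strip("\n").split("\n"):
        if line.startswith("N\t"):
            _, nid, cfg, depth, kind, target = line.split("\t")
            ev = None
            if kind != "-":
                k = EventKind(kind)
                tgt: int | str | None = None
                if k in (EventKind.SD_GAIN, EventKind.SD_LOSS):
                    tgt = int(target)
                elif k in (EventKind.CD_GAIN, EventKind.CD_LOSS):
                    tgt = target
                ev = Event(k, tgt)
            T.add_node(int(nid), config=str_to_config(cfg), depth=int(depth), event=ev)
        elif line.startswith("E\t"):
            _, p, c = line.split("\t")
            T.add_edge(int(p), int(c))
    return T


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def make_fixtures(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Write small deterministic datasets for examples and tests.

    Covers SD-only data, GD-rich data, depth-skewed sampling, and the
    eight-probe layout with two two-probe chromosomes.
    """
    from .simulate import (
        SamplingScheme,
        SimulationParams,
        event_probabilities,
        sample_cells,
        simulate_tree,
        table_layout,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name, m, p_sd, p_cd, p_gd, scheme, sub_seed, min_nodes=12, max_nodes=60):
        params = SimulationParams(
            m, p_sd=p_sd, p_cd=p_cd, p_gd=p_gd, min_nodes=min_nodes, max_nodes=max_nodes
        )
        T = simulate_tree(params, seed=seed * 1000 + sub_seed)
        cells, _ = sample_cells(T, scheme, seed=seed * 1000 + sub_seed + 1)
        map_path = outdir / f"{name}.probes.tsv"
        cells_path = outdir / f"{name}.cells.tsv"
        truth_path = outdir / f"{name}.truth.tsv"
        write_probe_map(map_path, m)
        write_fish_table(cells_path, cells, m.probe_names)
        write_truth_tree(truth_path, T)
        written[name] = cells_path

    six = table_layout(6, 1)
    emit("sd_only", six, 1.0 / 6, 0.0, 0.0, SamplingScheme("uniform", 60), 1)
    emit("gd_rich", six, 0.125, 0.05, 0.2, SamplingScheme("uniform", 120), 2)
    emit(
        "skewed",
        six,
        0.125,
        0.05,
        0.2,
        SamplingScheme("depth_geometric", 120, beta=0.5),
        3,
    )
    eight = table_layout(8, 2)
    p8 = event_probabilities(eight, 0.1166, 0.18, 0.12)
    emit("two_pairs", eight, *p8, SamplingScheme("uniform", 120), 4)
    return written
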