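"""File formats, run configuration, solution manifests and fixtures.

Graphs travel either as edge-list TSV (columns ``src  dst  weight``,
1-based labels; edge u → v is stored at state-matrix entry A[v-1, u-1])
or as dense adjacency CSV holding the state matrix A itself (row i,
col j = A[i][j] = weight of edge j → i). The orientation rule is tested
by a round-trip identity. Model configs are YAML with a scalar·I shorthand
for Σ0 and B1 (the forms these matrices take in practice).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from itnet.graphs import WeightedDigraph, build_base_topology, random_connected_digraph
from itnet.neuro import OscillatorNetwork, WilsonCowanParams
from itnet.optimize import TopologySolution

__all__ = [
    "read_graph",
    "write_graph",
    "write_ground_set",
    "read_config",
    "write_solution",
    "read_solution",
    "make_fixture",
    "FIXTURES",
    "read_oscillator_network",
    "write_oscillator_network",
]

_VERSION = "0.1.0"


def read_graph(
    path, fmt: str | None = None, n: int | None = None, cooperative: bool = True
) -> WeightedDigraph:
    """Read a graph from edge-list TSV or adjacency CSV (inferred from the
    extension unless ``fmt`` is given). For an edge list, ``n`` may extend
    the vertex set beyond the largest label seen (required for edgeless
    graphs). Self-loop rows and (in cooperative mode) negative weights are
    rejected with the offending line."""
    path = Path(path)
    if fmt is None:
        fmt = "edgelist-tsv" if path.suffix.lower() in (".tsv", ".txt") else "adjacency-csv"
    if fmt == "edgelist-tsv":
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"src", "dst", "weight"}.issubset(df.columns):
            raise ValueError("edge list needs columns src, dst, weight")
        weights = {}
        for line, row in enumerate(df.itertuples(index=False), start=2):
            u, v, w = int(row.src), int(row.dst), float(row.weight)
            if u == v:
                raise ValueError(f"{path}:{line}: self-loop ({u},{v})")
            if w < 0 and cooperative:
                raise ValueError(f"{path}:{line}: negative weight {w}")
            weights[(u, v)] = w
        n_seen = max([u for u, _ in weights] + [v for _, v in weights], default=0)
        return WeightedDigraph(max(n or 0, n_seen), weights)
    if fmt == "adjacency-csv":
        A = np.loadtxt(path, delimiter=",", ndmin=2)
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got {A.shape}")
        if cooperative and np.any(A - np.diag(np.diag(A)) < 0):
            raise ValueError("negative off-diagonal entries in cooperative mode")
        if np.any(np.diag(A) != 0):
            raise ValueError("nonzero diagonal: self-loops are not allowed in graphs")
        weights = {
            (u + 1, v + 1): float(A[v, u])
            for v in range(A.shape[0])
            for u in range(A.shape[1])
            if u != v and A[v, u] != 0
        }
        return WeightedDigraph(A.shape[0], weights)
    raise ValueError(f"unknown graph format {fmt!r}")


def write_graph(graph: WeightedDigraph, path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "edgelist-tsv" if path.suffix.lower() in (".tsv", ".txt") else "adjacency-csv"
    if fmt == "edgelist-tsv":
        rows = [
            {"src": u, "dst": v, "weight": f"{w:.12g}"}
            for (u, v), w in sorted(graph.weights.items())
        ]
        pd.DataFrame(rows, columns=["src", "dst", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    elif fmt == "adjacency-csv":
        np.savetxt(path, graph.state_matrix(), delimiter=",", fmt="%.12g")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def write_ground_set(ground, path) -> None:
    """Candidate-edge list as TSV (columns src, dst), selection order."""
    rows = [{"src": u, "dst": v} for (u, v) in ground]
    pd.DataFrame(rows, columns=["src", "dst"]).to_csv(path, sep="\t", index=False)


def _parse_matrix_shorthand(value, n: int) -> np.ndarray:
    """Scalar (or 'xI' string) → scalar·I; a path string → dense CSV."""
    if isinstance(value, (int, float)):
        return float(value) * np.eye(n)
    if isinstance(value, str):
        s = value.strip()
        if s.endswith("I"):
            return float(s[:-1] or 1.0) * np.eye(n)
        return np.loadtxt(s, delimiter=",", ndmin=2)
    return np.asarray(value, dtype=float)


def read_config(path) -> dict:
    """Model/run config: keys n, t_eval, Sigma0, B1, mu0 plus free-form
    problem fields (j, i, k, w_max, w_ub, seed...). Σ0/B1 accept the
    scalar·I shorthand."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = dict(raw)
    n = cfg.get("n")
    if n is not None:
        for key in ("Sigma0", "B1"):
            if key in cfg:
                cfg[key] = _parse_matrix_shorthand(cfg[key], int(n))
        if "mu0" in cfg and np.isscalar(cfg["mu0"]):
            cfg["mu0"] = float(cfg["mu0"]) * np.ones(int(n))
    cfg.setdefault("t_eval", 10.0)
    return cfg


def write_solution(
    solution: TopologySolution, path, config: dict | None = None, seed=None
) -> dict:
    """Serialize a solution with a reproducibility manifest (config echo,
    seed, package version). Deterministic key order; returns the payload."""
    payload = {
        "edges": [list(e) for e in solution.selected_edges],
        "weights": [
            {"src": u, "dst": v, "weight": w}
            for (u, v), w in solution.weights.items()
        ],
        "removed_edges": [list(e) for e in solution.removed_edges],
        "trace": [
            {"src": e[0], "dst": e[1], "gain": None if g != g else g}
            for e, g in solution.trace
        ],
        "achieved_T": solution.achieved_T,
        "base_T": solution.base_T,
        "manifest": {
            "seed": seed,
            "version": _VERSION,
            "config": _jsonable(config or {}),
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return payload


def read_solution(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# fixtures


def _fixture_fig1(outdir: Path, seed: int):
    """6-node / 9-edge demonstration network (synthetic stand-in topology,
    seed-generated) with Σ0 = I6, B1 = 0.1 I6, evaluated at t = 10."""
    g = random_connected_digraph(6, 9, seed=seed)
    write_graph(g, outdir / "fig1_6node.tsv")
    write_graph(g, outdir / "fig1_6node.csv")
    (outdir / "fig1_6node.yaml").write_text(
        "n: 6\nt_eval: 10.0\nSigma0: 1.0\nB1: 0.1\nj: 3\ni: 1\n"
    )


def _fixture_design15(outdir: Path, seed: int):
    """Design instance: 15-node base topology for T_{3→1}, Σ0 = 5I, B = 0.1I."""
    g = build_base_topology(15, j=3, i=1)
    write_graph(g, outdir / "design_15node.tsv")
    (outdir / "design_15node.yaml").write_text(
        "n: 15\nt_eval: 10.0\nSigma0: 5.0\nB1: 0.1\nj: 3\ni: 1\nw_ub: 1.0\n"
    )


def _fixture_update_batch(outdir: Path, seed: int, count: int = 100):
    """100 random connected 6-node/10-edge unit-weight networks for the
    update experiment (add 5 edges maximizing T_{5→2}; Σ0 = 5I6, B = 0.1I6,
    w_max = 4.2, w_ub = 1)."""
    rng = np.random.default_rng(seed)
    sub = outdir / "update_6node_batch"
    sub.mkdir(exist_ok=True)
    for idx in range(count):
        g = random_connected_digraph(6, 10, seed=rng.integers(0, 2**31))
        write_graph(g, sub / f"net_{idx:03d}.tsv")
    (outdir / "update_6node_batch.yaml").write_text(
        "n: 6\nt_eval: 10.0\nSigma0: 5.0\nB1: 0.1\n"
        "j: 5\ni: 2\nk: 5\nw_max: 4.2\nw_ub: 1.0\n"
    )


def _neuro_8node_edges() -> list[tuple[int, int, float]]:
    """Synthetic 8-oscillator wiring (two coupling-strength classes, 0.015
    and 0.1): a complete bipartite digraph between clusters {1,3,5,7} and
    {2,4,6,8} in which every node receives exactly one strong (0.1) and
    three weak (0.015) inputs. Equal weighted in-strength makes the
    two-cluster anti-phase configuration an exact, stable phase-locked
    state of the reduced dynamics. Synthetic benchmark wiring (no
    reference circuit is reproduced)."""
    odd, even = [1, 3, 5, 7], [2, 4, 6, 8]
    strong = {(2, 1), (4, 3), (6, 5), (8, 7), (1, 2), (3, 4), (5, 6), (7, 8)}
    out = []
    for a in odd:
        for b in even:
            for u, v in ((a, b), (b, a)):
                out.append((u, v, 0.1 if (u, v) in strong else 0.015))
    return sorted(out)


NEURO_8NODE_EDGES = _neuro_8node_edges()


def _fixture_neuro8(outdir: Path, seed: int):
    payload = {
        "n": 8,
        "params": vars(WilsonCowanParams()),
        "edges": [list(e) for e in NEURO_8NODE_EDGES],
        "noise": 0.001,
        "Sigma0": 0.1,
        "B1": 0.001,
        "target": [8, 7],
    }
    with open(outdir / "neuro_8node.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


FIXTURES = {
    "fig1-6node": _fixture_fig1,
    "design-15node": _fixture_design15,
    "update-6node-batch": _fixture_update_batch,
    "neuro-8node": _fixture_neuro8,
}


def make_fixture(name: str, seed: int, outdir) -> Path:
    """Regenerate a registered experiment input set under ``outdir``."""
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; known: {sorted(FIXTURES)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    FIXTURES[name](outdir, seed)
    return outdir


def read_oscillator_network(path) -> OscillatorNetwork:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    n = int(raw["n"])
    g = WeightedDigraph(n, {(int(u), int(v)): float(w) for u, v, w in raw["edges"]})
    params = WilsonCowanParams(**raw.get("params", {}))
    return OscillatorNetwork(coupling=g, params=params, noise=raw.get("noise", 0.0))


def write_oscillator_network(net: OscillatorNetwork, path) -> None:
    payload = {
        "n": net.n,
        "params": vars(net.params[0]),
        "edges": [[u, v, w] for (u, v), w in sorted(net.coupling.weights.items())],
        "noise": float(np.asarray(net.noise).ravel()[0]),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
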