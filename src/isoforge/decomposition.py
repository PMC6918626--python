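"""Decompose a splice graph into weighted source-to-target paths.

The decomposition pursues three objectives, in priority order: (1) preserve
every phasing path — each read-derived vertex chain must appear contiguously
inside some output path; (2) minimise the L1 deviation between edge weights
and the path abundances explaining them, via linear programming; (3) keep
the number of output paths small.

The realisation here is seed / fit / peel:

* ``seed_paths`` turns every maximal phasing path into one candidate s-t path
  by greedy extension that never contradicts other phasing paths;
* ``fit_abundances`` solves ``min Σ_e |w_e − Σ_{p∋e} x_p|, x ≥ 0`` exactly as
  a linear program (absolute values split into slack variables, HiGHS);
* ``peel_residual`` adds maximum-bottleneck paths through under-explained
  edges until every positive residual falls below a floor.

All tie-breaks are by lowest vertex index then lexicographic path order, so
identical inputs and configuration give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linprog

from .splice_graph import PhasingPath, SpliceGraph

DEFAULT_MIN_TRANSCRIPT_COVERAGE = 1.0
DEFAULT_PEEL_FLOOR = 1.0

Path = tuple[int, ...]


class DecompositionError(RuntimeError):
    pass


@dataclass(frozen=True)
class TranscriptPath:
    """An s-to-t vertex chain with its fitted abundance."""

    vertices: Path
    abundance: float


@dataclass
class DecompositionResult:
    paths: list[TranscriptPath]
    l1_deviation: float
    phasing_coverage: dict[Path, int]  # phasing vertex chain -> covering path index


def contains_contiguous(seq: Sequence[int], sub: Sequence[int]) -> bool:
    """True iff ``sub`` occurs as a contiguous run inside ``seq``."""
    n, m = len(seq), len(sub)
    if m == 0:
        return True
    if m > n:
        return False
    sub = tuple(sub)
    return any(tuple(seq[i : i + m]) == sub for i in range(n - m + 1))


def maximal_phasing_paths(paths: Sequence[PhasingPath]) -> list[PhasingPath]:
    """Phasing paths that are not contiguous subchains of a longer one."""
    out = []
    for p in paths:
        absorbed = any(
            q is not p
            and len(q.vertices) > len(p.vertices)
            and contains_contiguous(q.vertices, p.vertices)
            for q in paths
        )
        if not absorbed:
            out.append(p)
    return out


def _pick_edge(
    candidates: list[tuple[int, float]], allowed: set[int]
) -> int:
    """Largest-weight neighbour, preferring phasing-consistent ones; ties to
    the lower vertex index."""
    pool = [c for c in candidates if c[0] in allowed] if allowed else []
    if not pool:
        pool = candidates
    pool.sort(key=lambda c: (-c[1], c[0]))
    return pool[0][0]


def seed_paths(
    graph: SpliceGraph, phasing_paths: Sequence[PhasingPath]
) -> list[Path]:
    """One candidate s-t path per maximal phasing path (greedy extension).

    At each frontier vertex the extension follows the incident edge of
    largest weight that does not contradict any phasing path through that
    vertex; when no phasing path exists at all, a single heaviest s-t path
    (maximum bottleneck, ties by total weight then lexicographic order) is
    seeded instead.
    """
    if graph.n_vertices == 0:
        return []
    if not phasing_paths:
        path = _best_from_s(graph, lambda u, v, e: e.weight)[graph.t][2]
        return [path]

    seeds: list[Path] = []
    for pp in sorted(maximal_phasing_paths(phasing_paths), key=lambda p: p.vertices):
        chain = list(pp.vertices)
        # extend left toward s
        left: list[int] = []
        cur = chain[0]
        while cur != graph.s:
            preds = [(u, e.weight) for u, e in graph.in_edges(cur)]
            if not preds:
                raise DecompositionError(
                    f"vertex {cur} unreachable from source (invariant violation)"
                )
            required = {
                q.vertices[i - 1]
                for q in phasing_paths
                for i, x in enumerate(q.vertices)
                if x == cur and i > 0
            }
            cur = _pick_edge(preds, required)
            left.append(cur)
        # extend right toward t
        right: list[int] = []
        cur = chain[-1]
        while cur != graph.t:
            succs = [(v, e.weight) for v, e in graph.out_edges(cur)]
            if not succs:
                raise DecompositionError(
                    f"vertex {cur} cannot reach target (invariant violation)"
                )
            required = {
                q.vertices[i + 1]
                for q in phasing_paths
                for i, x in enumerate(q.vertices)
                if x == cur and i < len(q.vertices) - 1
            }
            cur = _pick_edge(succs, required)
            right.append(cur)
        seed = tuple(reversed(left)) + tuple(chain) + tuple(right)
        if seed not in seeds:
            seeds.append(seed)
    return seeds


def _best_from_s(
    graph: SpliceGraph, weight_fn: Callable
) -> dict[int, tuple[float, float, Path]]:
    """Maximum-bottleneck DP from s; value = (bottleneck, total, path).

    Ties broken toward larger total weight, then lexicographically smaller
    path.
    """
    best: dict[int, tuple[float, float, Path]] = {graph.s: (np.inf, 0.0, (graph.s,))}
    for v in graph.topological_order()[1:]:
        cand = None
        for u, e in graph.in_edges(v):
            if u not in best:
                continue
            b, tot, path = best[u]
            w = weight_fn(u, v, e)
            c = (min(b, w), tot + w, path + (v,))
            if cand is None or (c[0], c[1]) > (cand[0], cand[1]) or (
                (c[0], c[1]) == (cand[0], cand[1]) and c[2] < cand[2]
            ):
                cand = c
        if cand is not None:
            best[v] = cand
    return best


def _best_to_t(
    graph: SpliceGraph, weight_fn: Callable
) -> dict[int, tuple[float, float, Path]]:
    best: dict[int, tuple[float, float, Path]] = {graph.t: (np.inf, 0.0, (graph.t,))}
    for u in reversed(graph.topological_order()[:-1]):
        cand = None
        for v, e in graph.out_edges(u):
            if v not in best:
                continue
            b, tot, path = best[v]
            w = weight_fn(u, v, e)
            c = (min(b, w), tot + w, (u,) + path)
            if cand is None or (c[0], c[1]) > (cand[0], cand[1]) or (
                (c[0], c[1]) == (cand[0], cand[1]) and c[2] < cand[2]
            ):
                cand = c
        if cand is not None:
            best[u] = cand
    return best


def _edge_matrix(graph: SpliceGraph, paths: Sequence[Path]):
    edges = [(u, v) for u, v, _ in graph.edges()]
    index = {uv: i for i, uv in enumerate(edges)}
    w = np.array([graph.edge(u, v).weight for u, v in edges], dtype=float)
    A = np.zeros((len(edges), len(paths)))
    for j, path in enumerate(paths):
        for uv in zip(path, path[1:]):
            if uv not in index:
                raise DecompositionError(f"path uses missing edge {uv}")
            A[index[uv], j] = 1.0
    return edges, w, A


def fit_abundances(
    graph: SpliceGraph, paths: Sequence[Path]
) -> tuple[np.ndarray, float]:
    """LP fit of non-negative path abundances to edge weights (L1 objective)."""
    if not paths:
        total = sum(e.weight for _, _, e in graph.edges())
        return np.zeros(0), float(total)
    _, w, A = _edge_matrix(graph, paths)
    m, k = A.shape
    # variables: x (k path abundances), d (m absolute deviations)
    c = np.concatenate([np.zeros(k), np.ones(m)])
    eye = np.eye(m)
    A_ub = np.vstack([np.hstack([A, -eye]), np.hstack([-A, -eye])])
    b_ub = np.concatenate([w, -w])
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=(0, None), method="highs")
    if not res.success:
        raise DecompositionError(f"LP solver failed: {res.message}")
    x = np.clip(res.x[:k], 0.0, None)
    deviation = float(np.abs(w - A @ x).sum())
    return x, deviation


def peel_residual(
    graph: SpliceGraph,
    paths: Sequence[Path],
    abundances: np.ndarray,
    floor: float = DEFAULT_PEEL_FLOOR,
) -> tuple[list[Path], np.ndarray, float]:
    """Add maximum-bottleneck paths through under-explained edges.

    While some edge's positive residual (weight minus assigned abundance) is
    at least ``floor``, route one new s-t path through the largest-residual
    edge, maximising the minimum residual along the way, and re-fit. The
    iteration count is capped by the edge count and stops early when the
    chosen path already exists.
    """
    if floor <= 0:
        raise ValueError("peel floor must be > 0")
    paths = list(paths)
    x = np.asarray(abundances, dtype=float)
    if not paths:
        return paths, x, fit_abundances(graph, paths)[1]
    edges, w, A = _edge_matrix(graph, paths)
    deviation = float(np.abs(w - A @ x).sum())
    for _ in range(len(edges)):
        resid = w - A @ x
        i = int(np.argmax(resid))
        if resid[i] < floor:
            break
        rmap = {uv: resid[j] for j, uv in enumerate(edges)}
        weight_fn = lambda u, v, e: rmap[(u, v)]
        u, v = edges[i]
        head = _best_from_s(graph, weight_fn).get(u)
        tail = _best_to_t(graph, weight_fn).get(v)
        if head is None or tail is None:
            break
        new_path = head[2] + tail[2]
        if new_path in paths:
            break
        paths.append(new_path)
        x, deviation = fit_abundances(graph, paths)
        edges, w, A = _edge_matrix(graph, paths)
    return paths, x, deviation


def decompose(
    graph: SpliceGraph,
    phasing_paths: Sequence[PhasingPath],
    min_transcript_coverage: float = DEFAULT_MIN_TRANSCRIPT_COVERAGE,
    peel_floor: float = DEFAULT_PEEL_FLOOR,
) -> DecompositionResult:
    """Full decomposition: seed, fit, peel, then drop weak candidates.

    Candidates with abundance below ``min_transcript_coverage`` are dropped
    unless the drop would leave a phasing path uncovered, in which case the
    highest-abundance covering candidate is retained. Abundances are re-fit
    on the surviving set.
    """
    if graph.n_vertices == 0:
        return DecompositionResult(paths=[], l1_deviation=0.0, phasing_coverage={})
    candidates = seed_paths(graph, phasing_paths)
    x, _ = fit_abundances(graph, candidates)
    candidates, x, _ = peel_residual(graph, candidates, x, floor=peel_floor)

    keep = {i for i in range(len(candidates)) if x[i] >= min_transcript_coverage}
    for pp in phasing_paths:
        covering = [
            i for i, p in enumerate(candidates) if contains_contiguous(p, pp.vertices)
        ]
        if not covering:
            raise DecompositionError(
                f"phasing path {pp.vertices} not covered by any candidate"
            )
        if not keep.intersection(covering):
            keep.add(max(covering, key=lambda i: (x[i], -i)))

    kept_paths = [candidates[i] for i in sorted(keep)]
    if kept_paths:
        x_final, deviation = fit_abundances(graph, kept_paths)
    else:
        x_final, deviation = fit_abundances(graph, [])

    result_paths = [
        TranscriptPath(vertices=p, abundance=float(a))
        for p, a in zip(kept_paths, x_final)
    ]
    coverage: dict[Path, int] = {}
    for pp in phasing_paths:
        covering = [
            i
            for i, tp in enumerate(result_paths)
            if contains_contiguous(tp.vertices, pp.vertices)
        ]
        coverage[pp.vertices] = max(
            covering, key=lambda i: (result_paths[i].abundance, -i)
        )
    return DecompositionResult(
        paths=result_paths, l1_deviation=deviation, phasing_coverage=coverage
    )


def dump_paths(result: DecompositionResult) -> str:
    """TSV dump: path id, vertex chain, abundance, covered phasing paths."""
    lines = ["path_id\tvertices\tabundance\tphasing_paths"]
    covered: dict[int, list[Path]] = {}
    for chain, idx in result.phasing_coverage.items():
        covered.setdefault(idx, []).append(chain)
    for i, tp in enumerate(result.paths):
        chains = ";".join(
            ",".join(map(str, c)) for c in sorted(covered.get(i, []))
        )
        lines.append(
            f"p{i}\t{','.join(map(str, tp.vertices))}\t{tp.abundance:.4f}\t{chains}"
        )
    return "\n".join(lines)
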