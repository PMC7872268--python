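"""Rotamer-graph combinatorial optimization.

A :class:`RotamerGraph` holds per-position candidate self energies and
sparse pairwise energy matrices. Solvers: exhaustive enumeration (test
oracle), Goldstein dead-end elimination, edge decomposition,
tree-decomposition dynamic programming, A* enumeration within an energy
window, and simulated-annealing Monte Carlo.
"""

from __future__ import annotations

import heapq
import itertools
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np
from networkx.algorithms.approximation import treewidth_min_fill_in

__all__ = [
    "RotamerGraph", "solve_brute_force", "dee_goldstein", "edge_decompose",
    "solve_treepack", "solve_astar", "solve_monte_carlo",
]


class RotamerGraph:
    """Positions × candidate rotamers with self and pairwise energies.

    ``edges`` maps ``(i, j)`` with ``i < j`` to a ``|cand_i| × |cand_j|``
    matrix; an absent edge is an all-zero matrix.
    """

    def __init__(self, self_energies: List[np.ndarray],
                 edges: Optional[Dict[Tuple[int, int], np.ndarray]] = None,
                 residue_ids: Optional[list] = None):
        self.self_energies = [np.asarray(e, float) for e in self_energies]
        self.edges: Dict[Tuple[int, int], np.ndarray] = {}
        for (i, j), m in (edges or {}).items():
            if i > j:
                i, j, m = j, i, np.asarray(m).T
            m = np.asarray(m, float)
            expected = (len(self.self_energies[i]), len(self.self_energies[j]))
            if m.shape != expected:
                raise ValueError(f"edge ({i},{j}) matrix shape {m.shape}, "
                                 f"expected {expected}")
            self.edges[(i, j)] = m
        self.residue_ids = residue_ids or list(range(len(self_energies)))
        # original candidate indices (identity unless pruned)
        self.orig_indices = [np.arange(len(e)) for e in self.self_energies]

    @property
    def n_positions(self) -> int:
        return len(self.self_energies)

    def n_candidates(self, i: int) -> int:
        return len(self.self_energies[i])

    def pair(self, i: int, j: int, r: int, s: int) -> float:
        if i > j:
            i, j, r, s = j, i, s, r
        m = self.edges.get((i, j))
        return float(m[r, s]) if m is not None else 0.0

    def energy(self, assignment) -> float:
        e = sum(float(self.self_energies[i][r])
                for i, r in enumerate(assignment))
        for (i, j), m in self.edges.items():
            e += float(m[assignment[i], assignment[j]])
        return e

    def copy(self) -> "RotamerGraph":
        g = RotamerGraph([e.copy() for e in self.self_energies],
                         {k: m.copy() for k, m in self.edges.items()},
                         list(self.residue_ids))
        g.orig_indices = [a.copy() for a in self.orig_indices]
        return g

    def to_original(self, assignment) -> List[int]:
        """Map an assignment in pruned indices back to original indices."""
        return [int(self.orig_indices[i][r]) for i, r in enumerate(assignment)]


def solve_brute_force(g: RotamerGraph, cap: int = 10 ** 7):
    """Exhaustive minimum (test oracle); ties broken lexicographically."""
    sizes = [g.n_candidates(i) for i in range(g.n_positions)]
    space = int(np.prod(sizes, dtype=np.int64)) if sizes else 0
    if space > cap:
        raise ValueError(f"search space {space} exceeds cap {cap}")
    best = None
    best_e = np.inf
    for assignment in itertools.product(*(range(s) for s in sizes)):
        e = g.energy(assignment)
        if e < best_e - 1e-15:
            best, best_e = assignment, e
    return list(best), float(best_e)


def dee_goldstein(g: RotamerGraph) -> RotamerGraph:
    """Goldstein dead-end elimination to a fixed point.

    Removes rotamer r at position i when some r' satisfies
    ``E(i,r) − E(i,r') + Σ_j min_s [E(ir, js) − E(ir', js)] > 0``; the
    global optimum is preserved. Returns a pruned copy (``orig_indices``
    maps back to input candidate numbering).
    """
    g = g.copy()
    n = g.n_positions
    changed = True
    while changed:
        changed = False
        for i in range(n):
            ni = g.n_candidates(i)
            if ni <= 1:
                continue
            doomed = []
            for r in range(ni):
                for rp in range(ni):
                    if rp == r:
                        continue
                    val = g.self_energies[i][r] - g.self_energies[i][rp]
                    for j in range(n):
                        if j == i:
                            continue
                        key = (i, j) if i < j else (j, i)
                        m = g.edges.get(key)
                        if m is None:
                            continue
                        diff = (m[r] - m[rp]) if i < j else (m[:, r] - m[:, rp])
                        val += diff.min()
                    if val > 1e-12:
                        doomed.append(r)
                        break
            if doomed and len(doomed) < ni:
                keep = np.array([r for r in range(ni) if r not in doomed])
                g.self_energies[i] = g.self_energies[i][keep]
                g.orig_indices[i] = g.orig_indices[i][keep]
                for key in list(g.edges):
                    a, b = key
                    if a == i:
                        g.edges[key] = g.edges[key][keep, :]
                    elif b == i:
                        g.edges[key] = g.edges[key][:, keep]
                changed = True
    return g


def edge_decompose(g: RotamerGraph, eps: float = 0.0):
    """Fold approximately-additive edges into self energies.

    An edge matrix M is removed when ``M − row-mins − col-mins`` leaves a
    residual with range ≤ ``eps``; the row/column minima are added to the
    incident self energies. The total energy of any full assignment changes
    by at most ``eps`` per removed edge. Returns ``(graph, offset)``.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    g = g.copy()
    offset = 0.0
    for key in list(g.edges):
        m = g.edges[key]
        u = m.min(axis=1)
        resid = m - u[:, None]
        v = resid.min(axis=0)
        resid = resid - v[None, :]
        if resid.max() <= eps + 1e-12:
            i, j = key
            g.self_energies[i] = g.self_energies[i] + u
            g.self_energies[j] = g.self_energies[j] + v
            del g.edges[key]
    return g, offset


def _interaction_graph(g: RotamerGraph) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(g.n_positions))
    G.add_edges_from(g.edges.keys())
    return G


def solve_treepack(g: RotamerGraph, width_cap: int = 12):
    """Exact optimum by dynamic programming over a tree decomposition
    (min-fill heuristic). Raises if the decomposition width exceeds
    ``width_cap``."""
    n = g.n_positions
    if n == 0:
        return [], 0.0
    width, tree = treewidth_min_fill_in(_interaction_graph(g))
    if width > width_cap:
        raise ValueError(
            f"tree width {width} exceeds cap {width_cap}; "
            f"use solve_astar or solve_monte_carlo")
    bags = {node: tuple(sorted(node)) for node in tree.nodes}
    if not bags:
        assignment = [int(np.argmin(e)) for e in g.self_energies]
        return assignment, g.energy(assignment)

    root = min(tree.nodes, key=lambda b: bags[b])
    bfs = nx.bfs_tree(tree, root)
    order = list(bfs.nodes)
    parent = {root: None}
    children = {b: [] for b in tree.nodes}
    for b in order[1:]:
        p = next(iter(bfs.predecessors(b)))
        parent[b] = p
        children[p].append(b)

    # home each vertex / edge in exactly one bag (first containing it, BFS)
    vert_home = {}
    edge_home = {}
    for b in order:
        for v in bags[b]:
            vert_home.setdefault(v, b)
        for (i, j) in g.edges:
            if i in bags[b] and j in bags[b]:
                edge_home.setdefault((i, j), b)
    uncovered = set(range(n)) - set(vert_home)
    if uncovered:  # isolated vertices missing from the decomposition
        extra = tuple(sorted(uncovered))
        for v in extra:
            vert_home[v] = None  # handled separately below

    messages: Dict[object, Dict[tuple, Tuple[float, dict]]] = {}

    def bag_assignments(vars_):
        return itertools.product(*(range(g.n_candidates(v)) for v in vars_))

    for b in reversed(order):
        vars_ = bags[b]
        sep = () if parent[b] is None else tuple(
            v for v in vars_ if v in bags[parent[b]])
        table: Dict[tuple, Tuple[float, dict]] = {}
        for assign in bag_assignments(vars_):
            amap = dict(zip(vars_, assign))
            e = 0.0
            for v in vars_:
                if vert_home[v] == b:
                    e += float(g.self_energies[v][amap[v]])
            for (i, j), home in edge_home.items():
                if home == b:
                    e += float(g.edges[(i, j)][amap[i], amap[j]])
            ok = True
            for ch in children[b]:
                ch_sep = tuple(v for v in bags[ch] if v in vars_)
                key = tuple(amap[v] for v in ch_sep)
                sub = messages[ch].get(key)
                if sub is None:
                    ok = False
                    break
                e += sub[0]
            if not ok:
                continue
            skey = tuple(amap[v] for v in sep)
            cur = table.get(skey)
            if cur is None or e < cur[0] - 1e-15:
                table[skey] = (e, amap)
        messages[b] = table

    best_e, root_amap = messages[root][()]

    # backtrack
    assignment = [None] * n
    def descend(b, fixed):
        vars_ = bags[b]
        sep = () if parent[b] is None else tuple(
            v for v in vars_ if v in bags[parent[b]])
        if parent[b] is None:
            amap = root_amap
        else:
            key = tuple(fixed[v] for v in sep)
            amap = messages[b][key][1]
        for v in vars_:
            assignment[v] = amap[v]
        for ch in children[b]:
            descend(ch, amap)

    descend(root, {})
    for v in range(n):
        if assignment[v] is None:
            assignment[v] = int(np.argmin(g.self_energies[v]))
    total = g.energy(assignment)
    return [int(a) for a in assignment], float(total)


def solve_astar(g: RotamerGraph, window: float = 0.0,
                solution_cap: int = 100000):
    """Best-first enumeration of all assignments within ``window`` of the
    optimum, sorted by ascending energy.

    Positions are expanded by increasing candidate count. The heuristic adds,
    for each unassigned position, its best self + interaction-to-assigned
    energy, plus the minimum entry of every edge among unassigned positions
    (zero when all energies are non-negative). Returns
    ``(solutions, truncated)`` where each solution is ``(assignment, energy)``.
    """
    n = g.n_positions
    if n == 0:
        return [([], 0.0)], False
    order = sorted(range(n), key=lambda i: (g.n_candidates(i), i))

    def heuristic(k, partial):
        """Lower bound for completing ``partial`` (first k ordered positions)."""
        h = 0.0
        assigned = {order[t]: partial[t] for t in range(k)}
        unassigned = order[k:]
        for u in unassigned:
            best = np.inf
            for r in range(g.n_candidates(u)):
                val = float(g.self_energies[u][r])
                for i, ri in assigned.items():
                    val += g.pair(u, i, r, ri)
                best = min(best, val)
            h += best
        un_set = set(unassigned)
        for (i, j), m in g.edges.items():
            if i in un_set and j in un_set:
                mn = float(m.min())
                if mn < 0:
                    h += mn
        return h

    def gcost(k, partial):
        assigned = [(order[t], partial[t]) for t in range(k)]
        e = sum(float(g.self_energies[i][r]) for i, r in assigned)
        for a in range(k):
            for b in range(a + 1, k):
                e += g.pair(assigned[a][0], assigned[b][0],
                            assigned[a][1], assigned[b][1])
        return e

    counter = itertools.count()
    heap = [(heuristic(0, ()), next(counter), (), 0.0)]
    solutions = []
    optimum = None
    truncated = False
    while heap:
        f, _, partial, gval = heapq.heappop(heap)
        if optimum is not None and f > optimum + window + 1e-12:
            break
        k = len(partial)
        if k == n:
            if optimum is None:
                optimum = f
            assignment = [0] * n
            for t, r in enumerate(partial):
                assignment[order[t]] = r
            solutions.append((assignment, float(f)))
            if len(solutions) >= solution_cap:
                truncated = True
                break
            continue
        pos = order[k]
        for r in range(g.n_candidates(pos)):
            npart = partial + (r,)
            ng = gcost(k + 1, npart)
            nh = heuristic(k + 1, npart)
            heapq.heappush(heap, (ng + nh, next(counter), npart, ng))
    return solutions, truncated


def solve_monte_carlo(g: RotamerGraph, steps: int = 5000, t0: float = 5.0,
                      cool: float = 0.95, seed: int = 0, restarts: int = 5):
    """Metropolis single-flip annealing with geometric cooling per sweep.

    The step budget is split over ``restarts`` independent annealing runs
    (the first starts from the per-position self-energy minimum, later ones
    from random assignments); the best assignment seen is returned.
    Reproducible for a fixed seed.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    restarts = max(1, min(restarts, steps))
    rng = np.random.default_rng(seed)
    best_overall = None
    for r in range(restarts):
        assignment, energy = _anneal(g, steps // restarts or 1, t0, cool,
                                     rng, greedy_start=(r == 0))
        if best_overall is None or energy < best_overall[1] - 1e-12:
            best_overall = (assignment, energy)
    return best_overall[0], float(g.energy(best_overall[0]))


def _anneal(g: RotamerGraph, steps: int, t0: float, cool: float, rng,
            greedy_start: bool):
    n = g.n_positions
    if n == 0:
        return [], 0.0
    if greedy_start:
        assignment = [int(np.argmin(e)) for e in g.self_energies]
    else:
        assignment = [int(rng.integers(g.n_candidates(i))) for i in range(n)]
    energy = g.energy(assignment)
    best, best_e = list(assignment), energy
    temp = t0
    for step in range(steps):
        i = int(rng.integers(n))
        ni = g.n_candidates(i)
        if ni <= 1:
            continue
        r_new = int(rng.integers(ni - 1))
        if r_new >= assignment[i]:
            r_new += 1
        delta = float(g.self_energies[i][r_new] - g.self_energies[i][assignment[i]])
        for j in range(n):
            if j != i:
                delta += (g.pair(i, j, r_new, assignment[j])
                          - g.pair(i, j, assignment[i], assignment[j]))
        if delta <= 0 or rng.random() < np.exp(-delta / max(temp, 1e-9)):
            assignment[i] = r_new
            energy += delta
            if energy < best_e - 1e-12:
                best, best_e = list(assignment), energy
        if (step + 1) % n == 0:
            temp *= cool
    return best, float(g.energy(best))
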