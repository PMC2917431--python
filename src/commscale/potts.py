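"""Potts-model community detection across a resolution-parameter grid.

Communities are found by minimizing the energy

    H(s; lambda) = - sum_{i != j} (B_ij - lambda * k_i k_j / (2W)) * delta(s_i, s_j)

over assignments ``s`` of nodes to communities, where ``B`` is the adjacency
matrix, ``k_i`` the degree of node ``i``, ``W`` the number of edges, and the
sum runs over ordered pairs of distinct nodes.  The null term ``k_i k_j /
(2W)`` is the Newman-Girvan configuration null model (it preserves expected
degrees); at ``lambda = 1`` the energy is ``-2W`` times Newman-Girvan
modularity, so lambda acts as a resolution dial: lambda -> 0 merges everything
into one community, and once every pair interaction ``B_ij - lambda * k_i
k_j/(2W)`` is negative the optimum is all singletons.

Minimization is NP-hard, so we use a seeded Louvain-style greedy heuristic
(single-node moves to the best neighboring community, then aggregation of
communities into super-nodes, iterated to a local minimum).  Because
near-optimal partitions are massively degenerate, downstream analyses compare
energies and recovered structure, never exact label sets.

Self-loops are excluded throughout: delta(s_i, s_i) = 1 makes their
contribution partition-independent, so they cannot change any optimum.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Mapping

import networkx as nx

from commscale.network_io import Network

Assignment = dict[Hashable, int]


@dataclass
class Partition:
    """A node -> community-label map at one resolution."""

    assignment: Assignment
    lam: float
    energy: float

    @property
    def communities(self) -> dict[int, set]:
        out: dict[int, set] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, set()).add(node)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def compact(self) -> "Partition":
        """Relabel communities 0..k-1 in order of first appearance (sorted nodes)."""
        mapping: dict[int, int] = {}
        for node in sorted(self.assignment, key=str):
            lab = self.assignment[node]
            if lab not in mapping:
                mapping[lab] = len(mapping)
        return Partition(
            assignment={n: mapping[l] for n, l in self.assignment.items()},
            lam=self.lam,
            energy=self.energy,
        )


@dataclass
class PartitionSweep:
    """Optimized partitions over a strictly increasing log10(lambda) grid."""

    log_grid: list[float]
    partitions: dict[float, Partition]  # keyed by log10(lambda)

    def __post_init__(self) -> None:
        if any(b - a <= 0 for a, b in zip(self.log_grid, self.log_grid[1:])):
            raise ValueError("log-lambda grid must be strictly increasing")

    def __len__(self) -> int:
        return len(self.log_grid)

    def __getitem__(self, log_lam: float) -> Partition:
        return self.partitions[log_lam]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["protein", "log10_lambda", "community_label"])
            for ll in self.log_grid:
                part = self.partitions[ll]
                for node in sorted(part.assignment, key=str):
                    writer.writerow([node, f"{ll:.6g}", part.assignment[node]])

    def energies_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["log10_lambda", "lambda", "energy", "n_communities"])
            for ll in self.log_grid:
                part = self.partitions[ll]
                writer.writerow([f"{ll:.6g}", f"{part.lam:.8g}", repr(part.energy), part.n_communities])

    @classmethod
    def from_csv(cls, path: str | Path, energies: Mapping[float, float] | None = None) -> "PartitionSweep":
        parts: dict[float, Assignment] = {}
        with open(path) as fh:
            reader = csv.reader(fh)
            next(reader)
            for protein, ll, label in reader:
                parts.setdefault(float(ll), {})[protein] = int(label)
        grid = sorted(parts)
        partitions = {
            ll: Partition(
                assignment=parts[ll],
                lam=10.0**ll,
                energy=(energies or {}).get(ll, float("nan")),
            )
            for ll in grid
        }
        return cls(log_grid=grid, partitions=partitions)


# ---------------------------------------------------------------------------
# energy
# ---------------------------------------------------------------------------

def energy(net: Network, assignment: Mapping[Hashable, int], lam: float) -> float:
    """Exact Potts energy of an assignment (ordered distinct pairs, no self-pairs)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    simple = net.simple()
    missing = [v for v in simple.nodes() if v not in assignment]
    if missing:
        raise ValueError(f"assignment missing {len(missing)} nodes, e.g. {missing[0]!r}")
    two_w = 2.0 * simple.number_of_edges()
    if two_w == 0:
        return 0.0
    degree = dict(simple.degree())
    internal_edges: dict[int, int] = {}
    for u, v in simple.edges():
        if assignment[u] == assignment[v]:
            internal_edges[assignment[u]] = internal_edges.get(assignment[u], 0) + 1
    deg_sum: dict[int, float] = {}
    deg_sq_sum: dict[int, float] = {}
    for node, lab in assignment.items():
        if node not in degree:
            continue
        k = degree[node]
        deg_sum[lab] = deg_sum.get(lab, 0.0) + k
        deg_sq_sum[lab] = deg_sq_sum.get(lab, 0.0) + k * k
    h = 0.0
    for lab in deg_sum:
        b_term = 2.0 * internal_edges.get(lab, 0)
        null_term = lam * (deg_sum[lab] ** 2 - deg_sq_sum[lab]) / two_w
        h -= b_term - null_term
    return h


# ---------------------------------------------------------------------------
# greedy optimizer (Louvain-style two-phase local search)
# ---------------------------------------------------------------------------

class _Level:
    """Weighted working graph for one aggregation level.

    ``adj[u][v]`` is the inter-node weight (original edge multiplicity),
    ``self_w[u]`` the weight already internal to super-node ``u``, and
    ``strength[u] = sum_v adj[u][v] + 2*self_w[u]`` the aggregated degree.
    """

    def __init__(self, adj, self_w, strength, two_w):
        self.adj = adj
        self.self_w = self_w
        self.strength = strength
        self.two_w = two_w

    @classmethod
    def from_graph(cls, g: nx.Graph) -> "_Level":
        adj = {u: {v: 1.0 for v in g.neighbors(u) if v != u} for u in g.nodes()}
        self_w = {u: 0.0 for u in g.nodes()}
        strength = {u: float(g.degree(u)) for u in g.nodes()}
        return cls(adj, self_w, strength, 2.0 * g.number_of_edges())


def _local_moves(level: _Level, labels: dict, lam: float, rng: random.Random) -> bool:
    """One-level greedy pass: repeat node sweeps until no move lowers H.

    Candidate communities for a node are its neighbors' communities plus a
    fresh singleton; ties among equal best gains break to the lowest label.
    Returns True if any move was made.
    """
    two_w = level.two_w
    comm_strength: dict[int, float] = {}
    for u, lab in labels.items():
        comm_strength[lab] = comm_strength.get(lab, 0.0) + level.strength[u]
    nodes = sorted(level.adj, key=str)
    improved_ever = False
    eps = 1e-12
    while True:
        rng.shuffle(nodes)
        improved = False
        for u in nodes:
            a = labels[u]
            k_u = level.strength[u]
            # weight from u to each neighboring community
            w_to: dict[int, float] = {}
            for v, w in level.adj[u].items():
                w_to[labels[v]] = w_to.get(labels[v], 0.0) + w
            k_a_rest = comm_strength[a] - k_u
            w_ua = w_to.get(a, 0.0)
            # gain of moving u from a to b:
            #   dH = 2*[(w_ua - w_ub) - lam * k_u * (K_a' - K_b) / (2W)]
            best_gain = -eps
            best_lab = a
            fresh = max(comm_strength, default=-1) + 1
            candidates = sorted(w_to) + [fresh]
            for b in candidates:
                if b == a:
                    continue
                k_b = comm_strength.get(b, 0.0)
                w_ub = w_to.get(b, 0.0)
                gain = 2.0 * ((w_ua - w_ub) - lam * k_u * (k_a_rest - k_b) / two_w)
                if gain < best_gain - eps or (abs(gain - best_gain) <= eps and gain < -eps and b < best_lab):
                    best_gain = gain
                    best_lab = b
            if best_lab != a:
                labels[u] = best_lab
                comm_strength[a] -= k_u
                if comm_strength[a] <= eps:
                    comm_strength.pop(a, None)
                comm_strength[best_lab] = comm_strength.get(best_lab, 0.0) + k_u
                improved = True
                improved_ever = True
        if not improved:
            return improved_ever


def _aggregate(level: _Level, labels: dict) -> tuple[_Level, dict]:
    """Collapse communities to super-nodes; returns the new level and the
    map old-node -> new super-node id."""
    comm_ids = sorted(set(labels.values()))
    remap = {lab: i for i, lab in enumerate(comm_ids)}
    node_map = {u: remap[labels[u]] for u in labels}
    adj: dict[int, dict[int, float]] = {c: {} for c in range(len(comm_ids))}
    self_w = {c: 0.0 for c in range(len(comm_ids))}
    strength = {c: 0.0 for c in range(len(comm_ids))}
    for u in level.adj:
        cu = node_map[u]
        strength[cu] += level.strength[u]
        self_w[cu] += level.self_w[u]
        for v, w in level.adj[u].items():
            cv = node_map[v]
            if cu == cv:
                self_w[cu] += 0.5 * w  # each internal edge seen from both ends
            elif cu < cv:
                adj[cu][cv] = adj[cu].get(cv, 0.0) + w
                adj[cv][cu] = adj[cv].get(cu, 0.0) + w
    return _Level(adj, self_w, strength, level.two_w), node_map


def optimize(
    net: Network,
    lam: float,
    seed: int = 0,
    init: Mapping[Hashable, int] | None = None,
) -> Partition:
    """Greedy Potts-energy minimization at one resolution.

    Node visit order is shuffled by ``seed``; ``init`` (node -> label) warm
    starts the search, otherwise every node begins in its own community.  The
    returned :class:`Partition` carries the exact recomputed energy.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    simple = net.simple()
    rng = random.Random(seed)
    if simple.number_of_edges() == 0:
        assignment = {v: i for i, v in enumerate(sorted(simple.nodes(), key=str))}
        return Partition(assignment=assignment, lam=lam, energy=0.0).compact()

    level = _Level.from_graph(simple)
    if init is not None:
        labels = {u: int(init[u]) for u in level.adj}
    else:
        labels = {u: i for i, u in enumerate(sorted(level.adj, key=str))}
    # composite map original node -> current-level node
    node_of: dict[Hashable, Hashable] = {u: u for u in level.adj}
    while True:
        _local_moves(level, labels, lam, rng)
        n_comms = len(set(labels.values()))
        if n_comms == len(level.adj):
            break
        level, node_map = _aggregate(level, labels)
        node_of = {orig: node_map[cur] for orig, cur in node_of.items()}
        labels = {u: u for u in level.adj}
    assignment = {orig: labels[cur] for orig, cur in node_of.items()}
    part = Partition(assignment=assignment, lam=lam, energy=0.0).compact()
    part.energy = energy(net, part.assignment, lam)
    return part


def singleton_lambda_bound(net: Network) -> float:
    """Smallest lambda beyond which every pair interaction is negative.

    For lambda > max over edges of ``2W / (k_i k_j)`` all J_ij < 0 and the
    optimum is all singletons.
    """
    simple = net.simple()
    two_w = 2.0 * simple.number_of_edges()
    deg = dict(simple.degree())
    return max(two_w / (deg[u] * deg[v]) for u, v in simple.edges())


# ---------------------------------------------------------------------------
# resolution sweep
# ---------------------------------------------------------------------------

def make_log_grid(log_min: float, log_max: float, step: float) -> list[float]:
    if log_min >= log_max:
        raise ValueError("log_lambda_min must be < log_lambda_max")
    if step <= 0:
        raise ValueError("step must be positive")
    n = int(round((log_max - log_min) / step))
    grid = [log_min + k * step for k in range(n + 1)]
    return [g for g in grid if g <= log_max + 1e-12]


def sweep(
    net: Network,
    log_lambda_min: float = -1.0,
    log_lambda_max: float = 3.0,
    step: float = 0.01,
    seed: int = 0,
    warm_start: bool = True,
    relabel: bool = True,
) -> PartitionSweep:
    """Optimize one partition per grid point of log10(lambda).

    With ``warm_start`` each grid point is optimized twice — once initialized
    from the previous (next-lower-lambda) partition and once from singletons —
    and the lower-energy result is kept.  The warm run smooths the partition
    trajectory across resolutions, while the cold run guards against the
    warm start's known failure mode (greedy single-node moves cannot split a
    too-coarse inherited community).  Set ``warm_start=False`` for fully
    independent cold runs.  Labels are made consistent across adjacent
    resolutions by :func:`relabel_sweep` unless ``relabel`` is False.
    """
    grid = make_log_grid(log_lambda_min, log_lambda_max, step)
    partitions: dict[float, Partition] = {}
    prev: Partition | None = None
    for i, ll in enumerate(grid):
        part = optimize(net, 10.0**ll, seed=seed + i, init=None)
        if warm_start and prev is not None:
            warm = optimize(net, 10.0**ll, seed=seed + i, init=prev.assignment)
            if warm.energy < part.energy:
                part = warm
        partitions[ll] = part
        prev = part
    result = PartitionSweep(log_grid=grid, partitions=partitions)
    return relabel_sweep(result) if relabel and len(grid) >= 2 else result


# ---------------------------------------------------------------------------
# cross-resolution label convention
# ---------------------------------------------------------------------------

def match_labels(
    fine: Assignment,
    coarse: Assignment,
    overlap: str = "jaccard",
) -> Assignment:
    """Relabel the finer partition's communities with the coarser one's labels.

    For every community pair (K_i in the finer partition, L_j in the coarser)
    the overlap ``W_ij`` is computed — Jaccard ``|K∩L| / |K∪L|`` by default, or
    raw intersection size with ``overlap="intersection"`` (a link-based variant
    of the same idea gives nearly identical matchings).  Pairs are matched
    greedily in decreasing ``W_ij`` (ties: larger intersection first, then
    lower coarse label, then lower fine label), each community matched at most
    once.  Finer communities left unmatched (the finer partition usually has
    more communities) receive fresh labels.
    """
    if overlap not in ("jaccard", "intersection"):
        raise ValueError("overlap must be 'jaccard' or 'intersection'")
    fine_comms: dict[int, set] = {}
    for node, lab in fine.items():
        fine_comms.setdefault(lab, set()).add(node)
    coarse_comms: dict[int, set] = {}
    for node, lab in coarse.items():
        coarse_comms.setdefault(lab, set()).add(node)

    scored = []
    for ki, knodes in fine_comms.items():
        for lj, lnodes in coarse_comms.items():
            inter = len(knodes & lnodes)
            if inter == 0:
                continue
            w = inter / len(knodes | lnodes) if overlap == "jaccard" else float(inter)
            scored.append((-w, -inter, lj, ki))
    scored.sort()

    rename: dict[int, int] = {}
    used_coarse: set[int] = set()
    for _negw, _neginter, lj, ki in scored:
        if ki in rename or lj in used_coarse:
            continue
        rename[ki] = lj
        used_coarse.add(lj)
    fresh = max(list(coarse_comms) + list(rename.values()), default=-1) + 1
    for ki in sorted(fine_comms):
        if ki not in rename:
            rename[ki] = fresh
            fresh += 1
    return {node: rename[lab] for node, lab in fine.items()}


def relabel_sweep(sw: PartitionSweep, overlap: str = "jaccard") -> PartitionSweep:
    """Make community labels comparable across resolutions.

    Working from the highest resolution downward pair by pair, each finer
    partition's communities take the labels of their best-overlap match in the
    adjacent coarser partition (fresh labels where the finer partition has
    more communities).  To keep the chained labels globally consistent, the
    coarsest partition anchors the naming and matches propagate up the grid.
    Only label names change; co-clustering is untouched.
    """
    if len(sw.log_grid) < 2:
        raise ValueError("relabeling needs at least two partitions")
    new_parts: dict[float, Partition] = {}
    coarsest = sw.log_grid[0]
    new_parts[coarsest] = sw.partitions[coarsest].compact()
    for ll_coarse, ll_fine in zip(sw.log_grid, sw.log_grid[1:]):
        fine = sw.partitions[ll_fine]
        relabeled = match_labels(fine.assignment, new_parts[ll_coarse].assignment, overlap)
        new_parts[ll_fine] = Partition(assignment=relabeled, lam=fine.lam, energy=fine.energy)
    return PartitionSweep(log_grid=list(sw.log_grid), partitions=new_parts)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def nmi(assignment: Mapping[Hashable, int], reference: Mapping[Hashable, int]) -> float:
    """Normalized mutual information between a partition and reference labels
    (computed over the nodes present in both)."""
    from sklearn.metrics import normalized_mutual_info_score

    common = sorted(set(assignment) & set(reference), key=str)
    if not common:
        raise ValueError("no common nodes between assignment and reference")
    a = [assignment[n] for n in common]
    b = [reference[n] for n in common]
    return float(normalized_mutual_info_score(a, b))
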