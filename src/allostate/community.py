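"""Machine-learning community analysis of residue importance graphs.

The protein is an undirected graph: nodes are residues, edge weights
are the random-forest importances of the corresponding pairwise Cα
distance features. A good community partition concentrates the
discriminating signal *between* groups: the objective T — the total
edge weight falling inside communities — is minimized by a
Kernighan–Lin-style local search (single-node insertions and
cross-community swaps, best move first, strict descent) restarted from
many random initial partitions. An elbow criterion over the community
count selects the final partition, and accumulation tables report how
importance distributes over community pairs.

Edges are counted once per unordered pair throughout; every incremental
move delta equals the full objective difference by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .ml_importance import ImportanceTable


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ImportanceGraph:
    """Symmetric nonnegative residue–residue weight matrix, zero diagonal."""

    weights: np.ndarray
    residue_labels: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and nonnegative")
        w = w.copy()
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def total_weight(self) -> float:
        """Sum of all edge weights, each unordered pair counted once."""
        return float(self.weights.sum() / 2.0)


@dataclass
class CommunityPartition:
    """Residue → community assignment with its within-community objective T."""

    assignment: np.ndarray
    n: int
    objective: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if np.any(self.assignment < 0) or np.any(self.assignment >= self.n):
            raise ValueError("assignment labels must lie in 0..n-1")

    def members(self, c: int) -> np.ndarray:
        return np.where(self.assignment == c)[0]

    def to_tsv(self, path, residue_labels=None, graph: ImportanceGraph | None = None):
        letters = community_letters(self, graph) if graph is not None else {
            c: chr(ord("A") + c) for c in range(self.n)
        }
        labels = residue_labels or [str(i) for i in range(self.assignment.size)]
        pd.DataFrame({
            "residue": labels,
            "community": [letters[c] for c in self.assignment],
        }).to_csv(path, sep="\t", index=False)


def community_letters(p: CommunityPartition, g: ImportanceGraph) -> dict[int, str]:
    """Letter communities A, B, ... by descending external importance."""
    ext = []
    for c in range(p.n):
        mask = p.assignment == c
        ext.append(float(g.weights[mask][:, ~mask].sum()))
    order = np.argsort([-e for e in ext], kind="stable")
    return {int(c): chr(ord("A") + rank) for rank, c in enumerate(order)}


# ---------------------------------------------------------------------------
# graph construction and objective


def build_graph(
    importance: np.ndarray,
    pair_map: Sequence[tuple[int, int]],
    n_residues: int | None = None,
    residue_labels=None,
) -> ImportanceGraph:
    """Importance vector + pair map → symmetric residue graph.

    E_ij is the importance of the feature for pair (i, j); pairs absent
    from the map get weight 0.
    """
    importance = np.asarray(importance, dtype=float)
    if importance.shape[0] != len(pair_map):
        raise ValueError("importance length must match pair_map")
    if n_residues is None:
        n_residues = max(max(i, j) for i, j in pair_map) + 1
    w = np.zeros((n_residues, n_residues))
    for val, (i, j) in zip(importance, pair_map):
        w[i, j] = w[j, i] = val
    return ImportanceGraph(weights=w, residue_labels=residue_labels)


def partition_objective(assignment: np.ndarray, g: ImportanceGraph) -> float:
    """T = Σ_l Σ_{i<j in C_l} E_ij — total edge weight inside communities."""
    assignment = np.asarray(assignment, dtype=int)
    if assignment.shape[0] != g.n_nodes:
        raise ValueError("every node must be assigned")
    same = assignment[:, None] == assignment[None, :]
    return float(g.weights[same].sum() / 2.0)


def edge_sums(node: int, assignment: np.ndarray, g: ImportanceGraph,
              n_communities: int | None = None) -> tuple[float, dict[int, float]]:
    """(In_i, {community: Ex_i,C}) — internal and external edge sums of a node."""
    assignment = np.asarray(assignment, dtype=int)
    n_comm = n_communities or int(assignment.max()) + 1
    own = assignment[node]
    w = g.weights[node]
    internal = float(w[assignment == own].sum())
    external = {
        c: float(w[assignment == c].sum()) for c in range(n_comm) if c != own
    }
    return internal, external


def move_benefit(
    move: tuple, assignment: np.ndarray, g: ImportanceGraph,
    n_communities: int | None = None,
) -> tuple[float, float]:
    """ΔT and benefit (−ΔT) of an insertion or swap.

    ``move`` is ``("insert", node, target_community)`` or
    ``("swap", node_i, node_j)``. Insertion: ΔT = Ex_{i,Ck} − In_i.
    Swap: ΔT = (Ex_{i,Ck} + Ex_{j,Cm}) − (In_i + In_j) − 2 E_ij.
    A move is worth taking only when the benefit is positive
    (T strictly decreases).
    """
    assignment = np.asarray(assignment, dtype=int)
    kind = move[0]
    if kind == "insert":
        _, node, target = move
        if target == assignment[node]:
            raise ValueError("insertion target must differ from current community")
        internal, external = edge_sums(node, assignment, g, n_communities)
        delta = external.get(target, 0.0) - internal
    elif kind == "swap":
        _, i, j = move
        if assignment[i] == assignment[j]:
            raise ValueError("swap nodes must be in different communities")
        in_i, ex_i = edge_sums(i, assignment, g, n_communities)
        in_j, ex_j = edge_sums(j, assignment, g, n_communities)
        delta = (ex_i[assignment[j]] + ex_j[assignment[i]]
                 - (in_i + in_j) - 2.0 * g.weights[i, j])
    else:
        raise ValueError(f"unknown move kind {kind!r}")
    return float(delta), float(-delta)


# ---------------------------------------------------------------------------
# Kernighan–Lin local search


def _local_search(
    w: np.ndarray, assignment: np.ndarray, n: int,
    trace: list | None = None, max_iter: int = 100_000,
) -> tuple[np.ndarray, float]:
    """Strict-descent best-move local search; returns (assignment, T)."""
    n_nodes = w.shape[0]
    idx = np.arange(n_nodes)
    # S[i, c] = total edge weight between node i and community c
    S = np.zeros((n_nodes, n), dtype=float)
    for c in range(n):
        members = assignment == c
        if members.any():
            S[:, c] = w[:, members].sum(axis=1)
    T = 0.5 * float(S[idx, assignment].sum())
    for _ in range(max_iter):
        own = S[idx, assignment]                       # In_i
        ins_delta = S - own[:, None]                   # ΔT of moving i -> column
        ins_delta[idx, assignment] = np.inf            # no-op moves excluded
        ins_flat = int(np.argmin(ins_delta))
        best_ins = float(ins_delta.flat[ins_flat])

        cross = S[:, assignment]                       # cross[i, j] = Ex_{i, C_j}
        swap_delta = cross + cross.T - own[:, None] - own[None, :] - 2.0 * w
        same = assignment[:, None] == assignment[None, :]
        swap_delta[same] = np.inf
        swap_delta[np.tril_indices(n_nodes)] = np.inf  # keep i < j ordering
        swap_flat = int(np.argmin(swap_delta))
        best_swap = float(swap_delta.flat[swap_flat])

        # best improvement; exact ties favor insertion, then lowest node index
        if best_ins <= best_swap:
            best, kind = best_ins, "insert"
        else:
            best, kind = best_swap, "swap"
        if not best < 0:
            break
        if kind == "insert":
            i, target = divmod(ins_flat, n)
            src = assignment[i]
            S[:, src] -= w[:, i]
            S[:, target] += w[:, i]
            assignment[i] = target
        else:
            i, j = divmod(swap_flat, n_nodes)
            ci, cj = assignment[i], assignment[j]
            S[:, ci] += w[:, j] - w[:, i]
            S[:, cj] += w[:, i] - w[:, j]
            assignment[i], assignment[j] = cj, ci
        T += best
        if trace is not None:
            trace.append(T)
    return assignment, T


def kl_search(
    g: ImportanceGraph, n: int, restarts: int = 10_000, seed: int = 0,
    return_trace: bool = False,
) -> CommunityPartition:
    """Multi-restart Kernighan–Lin minimization of the within-community T.

    Each restart draws a uniform random n-way assignment and descends by
    repeatedly applying the single insertion or swap with the largest
    objective reduction until no move reduces T. The lowest-T partition
    over all restarts wins; the whole search is deterministic given the
    seed. Communities may end up empty — the requested n is an upper
    bound, which is what makes the best T non-increasing in n.
    """
    if not 1 <= n <= g.n_nodes:
        raise ValueError("need 1 <= n <= number of nodes")
    w = g.weights
    ss = np.random.SeedSequence(seed)
    best_assign, best_T = None, np.inf
    traces: list[list[float]] | None = [] if return_trace else None
    for child in ss.spawn(restarts):
        rng = np.random.default_rng(child)
        assignment = rng.integers(0, n, size=g.n_nodes)
        trace: list[float] | None = [] if return_trace else None
        assignment, T = _local_search(w, assignment, n, trace=trace)
        if return_trace:
            traces.append(trace)
        if T < best_T - 1e-15:
            best_T, best_assign = T, assignment.copy()
    # re-evaluate from scratch: the incremental value agrees to 1e-12 but can
    # drift below zero by float epsilon on zero-objective optima
    best_T = partition_objective(best_assign, g)
    part = CommunityPartition(assignment=best_assign, n=n, objective=float(best_T))
    if return_trace:
        part.traces = traces  # type: ignore[attr-defined]
    return part


def scan_elbow(
    g: ImportanceGraph, n_range: Sequence[int], restarts: int = 10_000,
    seed: int = 0, select: int | None = None,
) -> tuple[pd.DataFrame, int]:
    """Best partition quality over a range of community counts.

    For each n reports the minimized within-community importance T_n and
    the among-community fraction 1 − T_n / total. The selected n is the
    point of maximum discrete second difference of the T curve (the
    automated elbow); pass ``select`` to override manually.
    """
    n_range = list(n_range)
    if not n_range:
        raise ValueError("empty community-count range")
    total = g.total_weight
    rows = []
    partitions = {}
    for i, n in enumerate(n_range):
        part = kl_search(g, n, restarts=restarts, seed=seed + i)
        within = part.objective
        among = total - within
        rows.append({
            "n_communities": n,
            "within_importance": within,
            "within_pct": 100.0 * within / total if total > 0 else 0.0,
            "among_pct": 100.0 * among / total if total > 0 else 100.0,
        })
        partitions[n] = part
    df = pd.DataFrame(rows)
    if select is not None:
        chosen = select
    elif len(n_range) < 3:
        chosen = n_range[-1]
    else:
        T = df["within_importance"].to_numpy()
        second = T[:-2] - 2 * T[1:-1] + T[2:]
        chosen = n_range[1 + int(np.argmax(second))]
    return df, int(chosen)


# ---------------------------------------------------------------------------
# community accumulation tables


def community_matrix(
    p: CommunityPartition, importance: np.ndarray,
    pair_map: Sequence[tuple[int, int]], g: ImportanceGraph | None = None,
) -> pd.DataFrame:
    """Accumulated importance between each community pair, in percent.

    Entry (X, Y) sums the importance of every feature whose two residues
    fall in X and Y; the diagonal is within-community mass. The matrix
    total is 100% of the importance (features partition over pairs).
    """
    importance = np.asarray(importance, dtype=float)
    assign = p.assignment
    letters = community_letters(p, g) if g is not None else {
        c: chr(ord("A") + c) for c in range(p.n)
    }
    mat = np.zeros((p.n, p.n))
    for val, (i, j) in zip(importance, pair_map):
        if i >= assign.size or j >= assign.size:
            raise ValueError("residue in pair_map missing from partition")
        a, b = sorted((assign[i], assign[j]))
        mat[a, b] += val
    order = sorted(range(p.n), key=lambda c: letters[c])
    names = [f"Commu. {letters[c]}" for c in order]
    sym = mat + np.triu(mat, 1).T  # symmetrize for reindexing below
    out = np.full((p.n, p.n), np.nan)
    for ri, a in enumerate(order):
        for rj, b in enumerate(order):
            if rj >= ri:
                out[ri, rj] = 100.0 * sym[a, b]
    return pd.DataFrame(out, index=names, columns=names)


def group_pair_fraction(
    vector: np.ndarray, pair_map, assignment, group_x, group_y
) -> float:
    """Fraction of a vector's importance on features spanning two node groups.

    ``group_x``/``group_y`` are community labels or collections of
    labels; a feature counts when one residue falls in each group.
    """
    gx = {group_x} if np.isscalar(group_x) else set(group_x)
    gy = {group_y} if np.isscalar(group_y) else set(group_y)
    vector = np.asarray(vector, dtype=float)
    total = vector.sum()
    acc = 0.0
    for val, (i, j) in zip(vector, pair_map):
        ci, cj = assignment[i], assignment[j]
        if (ci in gx and cj in gy) or (ci in gy and cj in gx):
            acc += val
    return float(acc / total) if total > 0 else 0.0


def state_pair_community_report(
    table: ImportanceTable, p: CommunityPartition,
    comparisons: dict[str, tuple] | None = None,
    g: ImportanceGraph | None = None,
) -> pd.DataFrame:
    """Per macrostate pair, the importance fraction on community-group pairs.

    By default reports, for each state pair, the fraction of that
    pair's importance carried by features linking community A with
    C∪D-style remainder groups: ``{"A with C and D": (A, {C, D}), ...}``
    in the paper-table layout. Communities are lettered by descending
    external importance when a graph is supplied.
    """
    letters = community_letters(p, g) if g is not None else {
        c: chr(ord("A") + c) for c in range(p.n)
    }
    by_letter = {v: k for k, v in letters.items()}
    if comparisons is None:
        ls = sorted(by_letter)
        rest = [by_letter[l] for l in ls[2:]] or [by_letter[ls[-1]]]
        rest_name = " and ".join(ls[2:]) or ls[-1]
        comparisons = {
            f"{ls[0]} with {rest_name}": (by_letter[ls[0]], set(rest)),
            f"{ls[1]} with {rest_name}": (by_letter[ls[1]], set(rest)),
        }
    rows = []
    for s1, s2 in table.state_pairs:
        row: dict = {"states": f"State {s1 + 1} -> State {s2 + 1}"}
        vec = table.per_pair[(s1, s2)]
        for name, (gx, gy) in comparisons.items():
            frac = group_pair_fraction(vec, table.pair_map, p.assignment, gx, gy)
            row[name] = 100.0 * frac
        rows.append(row)
    return pd.DataFrame(rows)
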