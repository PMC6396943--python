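"""Transition path theory on the macrostate Markov model.

Given a reversible transition matrix, its stationary distribution and
disjoint source (A) and target (B) macrostate sets, this module solves
the forward committor linear system, builds effective and net reactive
flux matrices, computes the total A→B flux per lag time, and decomposes
the net flux into individual pathways by repeatedly extracting the
widest (maximum-bottleneck) path and subtracting its flux. Pathways
with identical state sequences aggregate into channels whose
probabilities are their flux share.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TPTProblem:
    """Transition matrix, stationary distribution and the A/B state sets."""

    T: np.ndarray
    pi: np.ndarray
    A: frozenset
    B: frozenset
    lag_ps: float = 1.0

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = frozenset(int(a) for a in self.A)
        self.B = frozenset(int(b) for b in self.B)
        n = self.T.shape[0]
        if self.T.shape != (n, n):
            raise ValueError("T must be square")
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("T must be row-stochastic")
        if not self.A or not self.B or (self.A & self.B):
            raise ValueError("A and B must be disjoint and non-empty")
        if any(s < 0 or s >= n for s in self.A | self.B):
            raise ValueError("A/B states out of range")

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    @property
    def intermediates(self) -> list[int]:
        return [i for i in range(self.n_states) if i not in self.A | self.B]


@dataclass
class FluxNetwork:
    """Committors, flux matrices, and the decomposed pathway ensemble."""

    q_plus: np.ndarray
    q_minus: np.ndarray
    f: np.ndarray                 # effective flux per lag time
    f_plus: np.ndarray            # net flux per lag time
    total_flux: float
    pathways: list[tuple[tuple[int, ...], float]] = field(default_factory=list)
    channels: list[tuple[tuple[int, ...], float, float]] = field(default_factory=list)
    residual_flux: float = 0.0

    def channel_table(self, one_based: bool = True) -> pd.DataFrame:
        """Channels sorted by probability descending (sequence, flux, probability)."""
        off = 1 if one_based else 0
        rows = [{
            "channel": "State " + "-".join(str(s + off) for s in seq),
            "flux_per_tau": flux,
            "probability_pct": 100.0 * prob,
        } for seq, flux, prob in self.channels]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# committors and fluxes


def committors(problem: TPTProblem) -> tuple[np.ndarray, np.ndarray]:
    """Forward committor by linear solve; backward committor as 1 − q⁺.

    q⁺ is 0 on A, 1 on B, and on intermediates solves
    −q_i + Σ_{k∈I} T_ik q_k = −Σ_{k∈B} T_ik. The backward committor
    uses the reversible-chain identity q⁻ = 1 − q⁺ (the transition
    matrices produced by the reversible estimator satisfy this).
    """
    T = problem.T
    inter = problem.intermediates
    q_plus = np.zeros(problem.n_states)
    for b in problem.B:
        q_plus[b] = 1.0
    if inter:
        idx = np.asarray(inter)
        lhs = T[np.ix_(idx, idx)] - np.eye(len(inter))
        rhs = -T[np.ix_(idx, list(problem.B))].sum(axis=1)
        try:
            sol = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                "singular committor system: an intermediate cannot reach A or B"
            ) from err
        q_plus[idx] = sol
    q_minus = 1.0 - q_plus
    return q_plus, q_minus


def fluxes(problem: TPTProblem, q_plus: np.ndarray,
           q_minus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Effective flux f_ij = π_i q⁻_i T_ij q⁺_j and net flux max(0, f−fᵀ)."""
    f = problem.pi[:, None] * q_minus[:, None] * problem.T * q_plus[None, :]
    np.fill_diagonal(f, 0.0)
    f_plus = np.maximum(0.0, f - f.T)
    return f, f_plus


def total_flux(problem: TPTProblem, q_plus: np.ndarray) -> float:
    """Total A→B reactive flux per lag time: Σ_{i∈A} Σ_{j∉A} π_i T_ij q⁺_j."""
    A = sorted(problem.A)
    notA = [j for j in range(problem.n_states) if j not in problem.A]
    sub = problem.pi[A, None] * problem.T[np.ix_(A, notA)] * q_plus[notA][None, :]
    return float(sub.sum())


# ---------------------------------------------------------------------------
# pathway decomposition


def _widest_path(f_net: np.ndarray, A: frozenset, B: frozenset):
    """Maximum-bottleneck A→B path; ties by lexicographically smallest sequence.

    Dijkstra-style search maximizing the minimum edge flux along the
    path. Returns (path, bottleneck) or None when no positive-flux path
    remains.
    """
    n = f_net.shape[0]
    # heap entries: (-bottleneck, path) — tuples compare lexicographically,
    # so equal-bottleneck ties pop the smallest state sequence first.
    heap = [(-np.inf, (a,)) for a in sorted(A)]
    heapq.heapify(heap)
    done = set()
    while heap:
        neg_b, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node in B:
            return path, -neg_b
        for j in range(n):
            if j in done or f_net[node, j] <= 0:
                continue
            b = min(-neg_b, f_net[node, j])
            heapq.heappush(heap, (-b, path + (j,)))
    return None


def decompose_pathways(
    f_plus: np.ndarray, A, B, F: float | None = None,
    residual_tol: float = 1e-8, max_paths: int = 10_000,
) -> tuple[list[tuple[tuple[int, ...], float]],
           list[tuple[tuple[int, ...], float, float]], float]:
    """Greedy widest-path decomposition of the net flux field.

    Repeatedly extracts the maximum-bottleneck A→B path, assigns it its
    bottleneck flux and subtracts that flux from every edge on the
    path, until the remaining extractable flux drops below
    ``residual_tol`` times the total (or the path cap is hit).
    Identical state sequences aggregate into channels; channel
    probability is channel flux over total decomposed flux.

    Returns (pathways, channels, residual_flux).
    """
    A = frozenset(int(a) for a in A)
    B = frozenset(int(b) for b in B)
    resid = np.array(f_plus, dtype=float)
    if F is None:
        F = float(resid[sorted(A), :].sum())
    if F <= 0:
        raise ValueError("no positive net flux out of A")
    pathways: list[tuple[tuple[int, ...], float]] = []
    cutoff = residual_tol * F
    while len(pathways) < max_paths:
        found = _widest_path(resid, A, B)
        if found is None:
            break
        path, flux = found
        if flux <= cutoff:
            break
        for u, v in zip(path[:-1], path[1:]):
            resid[u, v] -= flux
        pathways.append((path, float(flux)))
    agg: dict[tuple[int, ...], float] = {}
    for path, flux in pathways:
        agg[path] = agg.get(path, 0.0) + flux
    total = sum(agg.values())
    if total <= 0:
        raise ValueError("no A->B pathway with positive flux")
    channels = sorted(
        ((seq, fl, fl / total) for seq, fl in agg.items()),
        key=lambda t: (-t[1], t[0]),
    )
    residual = float(max(0.0, F - total))
    return pathways, channels, residual


def analyze(problem: TPTProblem, residual_tol: float = 1e-8,
            max_paths: int = 10_000) -> FluxNetwork:
    """Full TPT pass: committors → fluxes → total flux → pathway channels."""
    q_plus, q_minus = committors(problem)
    f, f_plus = fluxes(problem, q_plus, q_minus)
    F = total_flux(problem, q_plus)
    pathways, channels, residual = decompose_pathways(
        f_plus, problem.A, problem.B, F=F,
        residual_tol=residual_tol, max_paths=max_paths,
    )
    return FluxNetwork(
        q_plus=q_plus, q_minus=q_minus, f=f, f_plus=f_plus,
        total_flux=F, pathways=pathways, channels=channels,
        residual_flux=residual,
    )
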