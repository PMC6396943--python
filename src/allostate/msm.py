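"""Markov state model estimation and validation.

Microstates are k-means clusters in the 2D-RMSD collective-variable
plane; transitions are counted with a sliding window at a chosen lag,
restricted to the largest strongly connected set of the count graph
(ergodic trimming), and the transition matrix is the reversible
maximum-likelihood estimate. Macrostates come from a crisp PCCA-style
spectral lumping. Validation covers implied-timescale convergence, a
Chapman–Kolmogorov test (with both a standard multinomial error bar and
a count-ratio-scaled variant) and the within-microstate structural
dispersion check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import CVMatrix, TrajectoryEnsemble, rmsd, superpose, _iterative_mean


# ---------------------------------------------------------------------------
# domain types


@dataclass
class MicrostateModel:
    centers: np.ndarray          # k × 2 CV coordinates
    labels: np.ndarray           # per-frame microstate index (pooled order)
    k: int
    frame_index: list[tuple[int, int]]

    def labels_per_trajectory(self) -> list[np.ndarray]:
        """Split the pooled label vector back into per-trajectory sequences."""
        out: dict[int, list[int]] = {}
        for lab, (ti, _) in zip(self.labels, self.frame_index):
            out.setdefault(ti, []).append(int(lab))
        return [np.asarray(out[ti]) for ti in sorted(out)]


@dataclass
class TransitionModel:
    """Reversible row-stochastic transition matrix at a fixed lag.

    ``T`` and ``pi`` are indexed over ``active_set`` (the retained
    microstates); ``counts`` is the trimmed count matrix. The stationary
    distribution is the eigenvalue-1 left eigenvector of ``T``.
    """

    lag_frames: int
    lag_ps: float
    counts: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    active_set: np.ndarray
    reversible: bool = True

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def eigenvalues(self) -> np.ndarray:
        ev = np.linalg.eigvals(self.T)
        order = np.argsort(-ev.real)
        return ev[order]


@dataclass
class MacroModel:
    membership: np.ndarray       # microstate (active-set position) -> macrostate
    n_macro: int
    macro_T: dict = field(default_factory=dict)    # condition -> row-stochastic matrix
    macro_pi: dict = field(default_factory=dict)   # condition -> stationary distribution

    def map_labels(self, micro_labels: np.ndarray, active_set: np.ndarray) -> np.ndarray:
        """Map microstate labels to macrostate labels; inactive frames -> -1."""
        lut = -np.ones(int(np.max(active_set)) + 1, dtype=int)
        lut[active_set] = self.membership
        micro = np.asarray(micro_labels, dtype=int)
        out = -np.ones_like(micro)
        mask = micro <= lut.shape[0] - 1
        out[mask] = lut[micro[mask]]
        return out


# ---------------------------------------------------------------------------
# microstate clustering


def cluster_microstates(cv: CVMatrix | np.ndarray, k: int, seed: int,
                        n_init: int = 10) -> MicrostateModel:
    """k-means microstates on the CV plane (10 restarts, best inertia)."""
    from sklearn.cluster import KMeans

    values = cv.values if isinstance(cv, CVMatrix) else np.asarray(cv, dtype=float)
    frame_index = (
        cv.frame_index if isinstance(cv, CVMatrix)
        else [(0, i) for i in range(values.shape[0])]
    )
    n_distinct = np.unique(values, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct CV points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(values)
    return MicrostateModel(
        centers=km.cluster_centers_,
        labels=km.labels_.astype(int),
        k=k,
        frame_index=list(frame_index),
    )


# ---------------------------------------------------------------------------
# counting, trimming, reversible estimation


def count_transitions(labels_list: Sequence[np.ndarray], lag: int,
                      n_states: int | None = None) -> np.ndarray:
    """Sliding-window (stride 1) transition counts pooled within trajectories.

    Transitions never cross trajectory boundaries.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    labels_list = [np.asarray(l, dtype=int) for l in labels_list]
    if n_states is None:
        n_states = int(max(l.max() for l in labels_list if l.size)) + 1
    counts = np.zeros((n_states, n_states), dtype=np.int64)
    any_pair = False
    for labels in labels_list:
        if labels.shape[0] > lag:
            any_pair = True
            np.add.at(counts, (labels[:-lag], labels[lag:]), 1)
    if not any_pair:
        raise ValueError("all trajectories shorter than the lag")
    return counts


def largest_scc(counts: np.ndarray) -> np.ndarray:
    """Vertex set of the dominant strongly connected component.

    Components of the positive-count digraph are ranked by total
    transition count within the component, then by vertex count, then by
    lowest vertex index.
    """
    adj = csr_matrix((counts > 0).astype(np.int8))
    n_comp, assignment = connected_components(adj, directed=True, connection="strong")
    best_key, best_nodes = None, None
    for c in range(n_comp):
        nodes = np.where(assignment == c)[0]
        total = int(counts[np.ix_(nodes, nodes)].sum())
        key = (total, len(nodes), -int(nodes.min()))
        if best_key is None or key > best_key:
            best_key, best_nodes = key, nodes
    return np.sort(best_nodes)


def count_and_trim(labels_list: Sequence[np.ndarray], lag: int,
                   n_states: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Transition counts plus the ergodically trimmed active set."""
    counts = count_transitions(labels_list, lag, n_states)
    active = largest_scc(counts)
    return counts, active


def _reversible_mle(counts: np.ndarray, tol: float = 1e-10,
                    max_iter: int = 10_000) -> np.ndarray:
    """Self-consistent fixed-point iteration for the reversible MLE.

    Iterates x_ij <- (c_ij + c_ji) / (c_i/x_i + c_j/x_j) on the
    unnormalized symmetric flux matrix x until the log-likelihood
    changes by less than ``tol``.
    """
    c = np.asarray(counts, dtype=float)
    c_row = c.sum(axis=1)
    if np.any(c_row <= 0):
        raise ValueError("every state must have outgoing counts after trimming")
    csym = c + c.T
    x = csym.copy()
    mask = csym > 0
    ll_prev = -np.inf
    for _ in range(max_iter):
        x_row = x.sum(axis=1)
        denom = (c_row / x_row)[:, None] + (c_row / x_row)[None, :]
        x_new = np.where(mask, csym / np.where(denom > 0, denom, 1.0), 0.0)
        x = x_new
        T = x / x.sum(axis=1)[:, None]
        with np.errstate(divide="ignore"):
            ll = float(np.sum(c[mask] * np.log(T[mask])))
        if abs(ll - ll_prev) < tol:
            return T
        ll_prev = ll
    raise RuntimeError("reversible MLE did not converge within iteration cap")


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Left eigenvector of T at eigenvalue 1, renormalized to sum 1."""
    ev, vec = np.linalg.eig(T.T)
    idx = int(np.argmin(np.abs(ev - 1.0)))
    pi = np.real(vec[:, idx])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_T(counts: np.ndarray, active_set: np.ndarray | None = None,
               reversible: bool = True, lag_frames: int = 1,
               save_interval_ps: float = 100.0) -> TransitionModel:
    """Transition-matrix estimate on the active set (zero prior counts).

    Reversible estimation uses the self-consistent MLE iteration and
    yields a matrix in detailed balance with its stationary
    distribution; the non-reversible estimate is plain row
    normalization.
    """
    counts = np.asarray(counts)
    if active_set is None:
        active_set = np.arange(counts.shape[0])
    active_set = np.asarray(active_set, dtype=int)
    sub = counts[np.ix_(active_set, active_set)]
    if np.any(sub.sum(axis=1) == 0):
        raise ValueError("zero-count row inside active set")
    if reversible:
        T = _reversible_mle(sub)
    else:
        T = sub / sub.sum(axis=1, keepdims=True)
    pi = stationary_distribution(T)
    return TransitionModel(
        lag_frames=lag_frames,
        lag_ps=lag_frames * save_interval_ps,
        counts=sub,
        T=T,
        pi=pi,
        active_set=active_set,
        reversible=reversible,
    )


def detailed_balance_error(model: TransitionModel) -> float:
    """max_ij |pi_i T_ij - pi_j T_ji| — zero for an exactly reversible chain."""
    flux = model.pi[:, None] * model.T
    return float(np.max(np.abs(flux - flux.T)))


# ---------------------------------------------------------------------------
# implied timescales


def implied_timescales(labels_list: Sequence[np.ndarray], lags: Sequence[int],
                       n_timescales: int | None = None,
                       save_interval_ps: float = 100.0,
                       reversible: bool = True) -> pd.DataFrame:
    """Relaxation timescales t_i(τ) = -τ / ln λ_i(τ) over a lag grid.

    Eigenvalues are sorted descending; the stationary eigenvalue 1 is
    excluded. Nonpositive or complex eigenvalues give NaN (undefined),
    unit eigenvalues give +inf; nothing is silently dropped.
    """
    rows = []
    for lag in lags:
        counts, active = count_and_trim(labels_list, lag)
        model = estimate_T(counts, active, reversible=reversible,
                           lag_frames=lag, save_interval_ps=save_interval_ps)
        ev = model.eigenvalues()[1:]
        if n_timescales is not None:
            ev = ev[:n_timescales]
        row: dict = {"lag_frames": lag, "lag_ps": lag * save_interval_ps}
        for i, lam in enumerate(ev, start=2):
            row[f"t{i}_ps"] = timescale_from_eigenvalue(lam, lag * save_interval_ps)
        rows.append(row)
    return pd.DataFrame(rows)


def timescale_from_eigenvalue(lam: complex, lag_ps: float) -> float:
    if abs(lam.imag) > 1e-12 or lam.real <= 0:
        return float("nan")
    if lam.real >= 1.0:
        return float("inf")
    return -lag_ps / np.log(lam.real)


# ---------------------------------------------------------------------------
# PCCA macrostate lumping


def pcca(model: TransitionModel, n_macro: int, seed: int = 0) -> MacroModel:
    """Crisp PCCA-style lumping of microstates into metastable macrostates.

    k-means (fixed seed, 10 restarts) on the rows of the leading
    ``n_macro`` right eigenvectors of T; the constant Perron vector is
    included but does not affect the clustering. Macrostate labels are
    renumbered by first occurrence so the result is deterministic.
    """
    k = model.n_states
    if not 2 <= n_macro <= k:
        raise ValueError("need 2 <= n_macro <= number of microstates")
    ev, vec = np.linalg.eig(model.T)
    order = np.argsort(-ev.real)
    ev, vec = ev[order], vec[:, order]
    lead = ev[:n_macro]
    if np.any(np.abs(lead.imag) > 1e-8):
        raise ValueError("leading eigenvalues not real; cannot lump reliably")
    basis = np.real(vec[:, 1:n_macro])
    # scale each eigenvector to unit max-abs so no single process dominates
    scale = np.max(np.abs(basis), axis=0)
    scale[scale == 0] = 1.0
    basis = basis / scale
    if n_macro == k:
        membership = np.arange(k)
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_macro, n_init=10, random_state=seed).fit(basis)
        membership = km.labels_.astype(int)
    # renumber by first occurrence
    remap: dict[int, int] = {}
    out = np.empty_like(membership)
    for i, m in enumerate(membership):
        if m not in remap:
            remap[m] = len(remap)
        out[i] = remap[m]
    return MacroModel(membership=out, n_macro=n_macro)


# ---------------------------------------------------------------------------
# condition-split macrostate kinetics


def condition_macro_T(
    labels_list: Sequence[np.ndarray],
    condition_tags: Sequence[str],
    macro: MacroModel,
    active_set: np.ndarray,
    lag: int,
    condition: str | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Macrostate transition matrix from the trajectories of one condition.

    Sliding-window counts of macrostate labels at the given lag,
    row-normalized. Frames in trimmed-away microstates are dropped
    (their transitions are skipped, not bridged). Rows of macrostates
    never visited in the selection are NaN and flagged.

    Returns (macro_T, undefined_row_mask).
    """
    sel = [l for l, tag in zip(labels_list, condition_tags)
           if condition is None or tag == condition]
    if not sel:
        raise ValueError(f"no trajectories with condition {condition!r}")
    n = macro.n_macro
    counts = np.zeros((n, n), dtype=np.int64)
    for labels in sel:
        mlab = macro.map_labels(labels, active_set)
        if mlab.shape[0] > lag:
            a, b = mlab[:-lag], mlab[lag:]
            ok = (a >= 0) & (b >= 0)
            np.add.at(counts, (a[ok], b[ok]), 1)
    row = counts.sum(axis=1)
    undefined = row == 0
    T = np.full((n, n), np.nan)
    T[~undefined] = counts[~undefined] / row[~undefined, None]
    return T, undefined


# ---------------------------------------------------------------------------
# Chapman–Kolmogorov test


def ck_test(
    labels_list: Sequence[np.ndarray],
    macro: MacroModel,
    active_set: np.ndarray,
    lag: int,
    k_multiples: Sequence[int] = (1, 2, 3, 4, 5),
) -> pd.DataFrame:
    """Chapman–Kolmogorov self-transition test on the macrostate chain.

    For each macrostate A and multiple k, compares the model prediction
    [T(τ)^k]_AA against the directly estimated self-transition
    probability at lag kτ. Two error bars accompany the estimate: the
    standard multinomial bar sqrt(p(1-p)/N_A), and a count-ratio-scaled
    variant sqrt(p(1-p) · N_A / N_total) whose denominator is the ratio
    of all transition counts to the counts leaving A — less sensitive to
    the frame-save frequency.
    """
    macro_labels = [macro.map_labels(l, active_set) for l in labels_list]
    base_T, undef = _macro_count_T(macro_labels, macro.n_macro, lag)
    if np.any(undef):
        raise ValueError("macrostate never visited at base lag; cannot run CK test")
    rows = []
    for k in k_multiples:
        klag = k * lag
        if all(l.shape[0] <= klag for l in macro_labels):
            raise ValueError(f"trajectories too short for lag multiple {k}")
        est_T, est_undef = _macro_count_T(macro_labels, macro.n_macro, klag)
        counts_k = _macro_counts(macro_labels, macro.n_macro, klag)
        n_total = counts_k.sum()
        pred_Tk = np.linalg.matrix_power(base_T, k)
        for a in range(macro.n_macro):
            n_a = counts_k[a].sum()
            p = est_T[a, a] if not est_undef[a] else np.nan
            if n_a > 0 and np.isfinite(p):
                err_std = float(np.sqrt(p * (1 - p) / n_a))
                err_ratio = float(np.sqrt(p * (1 - p) * n_a / n_total))
            else:
                err_std = err_ratio = float("nan")
            rows.append({
                "macrostate": a,
                "k": k,
                "lag_frames": klag,
                "predicted": float(pred_Tk[a, a]),
                "estimated": float(p),
                "err_standard": err_std,
                "err_count_ratio": err_ratio,
                "n_transitions": int(n_a),
            })
    return pd.DataFrame(rows)


def _macro_counts(macro_labels, n, lag):
    counts = np.zeros((n, n), dtype=np.int64)
    for mlab in macro_labels:
        if mlab.shape[0] > lag:
            a, b = mlab[:-lag], mlab[lag:]
            ok = (a >= 0) & (b >= 0)
            np.add.at(counts, (a[ok], b[ok]), 1)
    return counts


def _macro_count_T(macro_labels, n, lag):
    counts = _macro_counts(macro_labels, n, lag)
    row = counts.sum(axis=1)
    undefined = row == 0
    T = np.full((n, n), np.nan)
    T[~undefined] = counts[~undefined] / row[~undefined, None]
    return T, undefined


# ---------------------------------------------------------------------------
# microstate dispersion


def microstate_dispersion(
    traj: TrajectoryEnsemble,
    micro: MicrostateModel,
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Mean member-to-mean-structure RMSD per microstate, with flags.

    Kinetic similarity inside a microstate is taken as plausible when
    the average RMSD of its member frames to the microstate mean
    structure stays below the threshold (default 2.0 Å); microstates
    above it are flagged.
    """
    frames = np.concatenate(traj.trajectories, axis=0)
    rows = []
    for s in range(micro.k):
        members = frames[micro.labels == s]
        if members.shape[0] == 0:
            rows.append({"microstate": s, "n_frames": 0,
                         "dispersion_A": float("nan"), "flagged": False})
            continue
        if members.shape[0] == 1:
            rows.append({"microstate": s, "n_frames": 1,
                         "dispersion_A": 0.0, "flagged": False})
            continue
        mean = _iterative_mean(members)
        disp = float(np.mean([rmsd(f, mean) for f in members]))
        rows.append({"microstate": s, "n_frames": int(members.shape[0]),
                     "dispersion_A": disp, "flagged": disp > threshold})
    return pd.DataFrame(rows)
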