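"""Structures, trajectories and geometric collective variables.

Everything downstream of the raw coordinates starts here: optimal rigid
superposition (Kabsch), RMSD/RMSF, the translation/rotation-invariant
pairwise Cα distance featurization, and the two-dimensional RMSD
collective variables (distance to a dark and a light reference
structure) used to discretize the conformational space.

Only Cα positions are handled; coordinates are in Å throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Structure:
    """A single Cα trace: residue labels plus an (N, 3) coordinate array.

    Labels follow the conventional one-letter-code + author-number style
    ("T38"); author numbering typically starts at 37 for the VVD-like
    systems this package targets, but any strictly increasing numbering
    is accepted.
    """

    residue_labels: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (N, 3) array")
        if len(self.residue_labels) != self.coords.shape[0]:
            raise ValueError("residue_labels length must match coordinate rows")
        if self.coords.shape[0] < 1:
            raise ValueError("structure must contain at least one residue")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class TrajectoryEnsemble:
    """A set of trajectories sharing one residue topology.

    Each trajectory is a (T_i, N, 3) array of Cα coordinates; every
    trajectory carries a condition tag (``"bonded"`` or ``"non_bonded"``,
    mirroring cofactor-adduct vs adduct-free simulations) and frames are
    saved every ``save_interval_ps`` picoseconds.
    """

    residue_labels: list[str]
    trajectories: list[np.ndarray]
    condition_tags: list[str]
    save_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        if self.save_interval_ps <= 0:
            raise ValueError("save_interval_ps must be positive")
        if len(self.trajectories) != len(self.condition_tags):
            raise ValueError("one condition tag per trajectory required")
        n = len(self.residue_labels)
        cleaned = []
        for traj in self.trajectories:
            arr = np.asarray(traj, dtype=float)
            if arr.ndim != 3 or arr.shape[1] != n or arr.shape[2] != 3:
                raise ValueError("every trajectory must be (T, N, 3) with shared N")
            cleaned.append(arr)
        self.trajectories = cleaned

    @property
    def n_residues(self) -> int:
        return len(self.residue_labels)

    @property
    def n_frames(self) -> int:
        return sum(t.shape[0] for t in self.trajectories)

    def frame(self, traj_id: int, frame_no: int) -> Structure:
        return Structure(self.residue_labels, self.trajectories[traj_id][frame_no])

    def iter_frames(self) -> Iterable[tuple[int, int, np.ndarray]]:
        for ti, traj in enumerate(self.trajectories):
            for fi in range(traj.shape[0]):
                yield ti, fi, traj[fi]


@dataclass
class FeatureMatrix:
    """Frames × P pairwise Cα distances with an explicit pair-index map.

    ``pair_map[f]`` is the unordered residue pair (i, j), i < j, in
    lexicographic order; P = N(N-1)/2.
    """

    values: np.ndarray
    pair_map: list[tuple[int, int]]
    residue_labels: list[str]
    frame_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames × pairs)")
        if self.values.shape[1] != len(self.pair_map):
            raise ValueError("pair_map length must match feature columns")
        if len(self.frame_index) != self.values.shape[0]:
            raise ValueError("frame_index length must match frame rows")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def pair_names(self) -> list[str]:
        """Feature names in the 'T38-G105' style."""
        lab = self.residue_labels
        return [f"{lab[i]}-{lab[j]}" for i, j in self.pair_map]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.pair_names())
        df.insert(0, "trajectory", [t for t, _ in self.frame_index])
        df.insert(1, "frame", [f for _, f in self.frame_index])
        df.to_csv(path, index=False)


@dataclass
class CVMatrix:
    """Frames × 2 collective variables: RMSD to the dark and light references."""

    values: np.ndarray
    references: tuple[Structure, Structure]
    frame_index: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("values must be (frames, 2)")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be nonnegative")

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.values, columns=["rmsd_dark", "rmsd_light"])
        df.insert(0, "trajectory", [t for t, _ in self.frame_index])
        df.insert(1, "frame", [f for _, f in self.frame_index])
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# superposition and deviation measures


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered ``mobile`` onto centered ``reference``.

    SVD of the 3×3 covariance with determinant correction so reflections
    are never returned.
    """
    cov = mobile.T @ reference
    u, _, vt = np.linalg.svd(cov)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Rigidly fit ``mobile`` onto ``reference`` (rotation + translation)."""
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot = kabsch_rotation(mobile - mc, reference - rc)
    return (mobile - mc) @ rot.T + rc


def _coords(x) -> np.ndarray:
    return x.coords if isinstance(x, Structure) else np.asarray(x, dtype=float)


def rmsd(mobile, reference, superpose_first: bool = True) -> float:
    """Minimum RMSD between two equal-size Cα sets over rigid motions.

    With ``superpose_first`` the mobile copy is optimally rotated and
    translated (Kabsch) before the root-mean-square deviation is taken,
    so the result is symmetric in its arguments. At least three atoms
    are required for a determined superposition; fewer raise.
    """
    a = _coords(mobile)
    b = _coords(reference)
    if a.shape != b.shape:
        raise ValueError(f"atom count mismatch: {a.shape[0]} vs {b.shape[0]}")
    if superpose_first:
        if a.shape[0] < 3:
            raise ValueError("need >= 3 atoms for a determined superposition")
        a = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _iterative_mean(frames: np.ndarray, max_iter: int = 10, tol: float = 1e-6) -> np.ndarray:
    """Mean structure refined by repeated alignment of all frames to it."""
    mean = frames[0]
    for _ in range(max_iter):
        aligned = np.stack([superpose(f, mean) for f in frames])
        new_mean = aligned.mean(axis=0)
        shift = float(np.sqrt(np.mean(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return mean


def rmsf(traj: TrajectoryEnsemble, superpose_frames: bool = True) -> np.ndarray:
    """Per-residue root-mean-square fluctuation about the mean structure.

    All frames of the ensemble are pooled. With ``superpose_frames`` the
    frames are first aligned to an iteratively refined mean structure
    (10 iterations or mean shift < 1e-6 Å); without it the raw
    coordinates are used, which is convenient for closed-form tests.
    """
    frames = np.concatenate(traj.trajectories, axis=0)
    if frames.shape[0] < 2:
        raise ValueError("RMSF requires at least two frames")
    if superpose_frames:
        mean = _iterative_mean(frames)
        frames = np.stack([superpose(f, mean) for f in frames])
    mean = frames.mean(axis=0)
    return np.sqrt(np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0))


# ---------------------------------------------------------------------------
# featurization


def pair_index_map(n_residues: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j), i < j enumeration of unordered residue pairs."""
    return [(i, j) for i in range(n_residues) for j in range(i + 1, n_residues)]


def pairwise_distances(traj: TrajectoryEnsemble) -> FeatureMatrix:
    """All unordered Cα pair distances for every frame.

    One feature per unordered residue pair in lexicographic order; the
    features are invariant under rigid motion of any frame. For N
    residues there are N(N-1)/2 features (10,878 for a 148-residue
    protein).
    """
    n = traj.n_residues
    if n < 2:
        raise ValueError("need at least 2 residues for pairwise distances")
    rows = []
    index = []
    for ti, fi, frame in traj.iter_frames():
        rows.append(pdist(frame))
        index.append((ti, fi))
    return FeatureMatrix(
        values=np.asarray(rows),
        pair_map=pair_index_map(n),
        residue_labels=list(traj.residue_labels),
        frame_index=index,
    )


def rmsd2d(traj: TrajectoryEnsemble, dark: Structure, light: Structure) -> CVMatrix:
    """Two-dimensional RMSD collective variables.

    Row f is (RMSD(frame_f, dark), RMSD(frame_f, light)) after optimal
    superposition — the projection used to discretize sampling between
    the dark-state and light-state crystal conformations.
    """
    for ref in (dark, light):
        if ref.n_residues != traj.n_residues:
            raise ValueError("reference residue set must match trajectory")
    rows = []
    index = []
    for ti, fi, frame in traj.iter_frames():
        rows.append((rmsd(frame, dark.coords), rmsd(frame, light.coords)))
        index.append((ti, fi))
    return CVMatrix(values=np.asarray(rows), references=(dark, light), frame_index=index)
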