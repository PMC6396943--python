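"""Seeded synthetic trajectory generator with planted ground truth.

The generator emulates a multi-trajectory MD study of a two-condition
(bonded / non-bonded cofactor) protein: a hidden Markov chain over a
handful of metastable macrostates, with a condition-dependent
transition matrix, drives per-frame conformations. The conformation of
a macrostate is an ideal α-helical Cα trace whose planted residue
communities are rigidly displaced by state-specific vectors; isotropic
Gaussian positional noise models thermal jitter. Because displacements
are rigid, the discriminating signal lives entirely in
inter-community Cα pair distances and is analytically known, so every
downstream stage (MSM, importance, community partition, TPT) can be
tested against the planted truth.

Defaults follow the emulated study design: 148 residues, 8
macrostates, 6 trajectories per condition of 1 μs saved every 100 ps
(10,000 frames each, 120,000 in total).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Structure, TrajectoryEnsemble, pair_index_map

CONDITIONS = ("non_bonded", "bonded")

# fixed pseudo-sequence cycled to label residues (one-letter + author number)
_SEQ = "HTLGKVEASDNQRIFPWYMC"


def residue_labels(n_residues: int, offset: int = 37) -> list[str]:
    return [f"{_SEQ[i % len(_SEQ)]}{i + offset}" for i in range(n_residues)]


def default_macro_T(n_states: int, condition: str) -> np.ndarray:
    """Ergodic metastable birth–death chain, biased by condition.

    Nearest-neighbor transitions on a line with self-transition
    probability 0.90 in the interior; the remaining 0.10 splits
    asymmetrically so the bonded condition drifts toward high-index
    (light-like) states and the non-bonded one toward low-index
    (dark-like) states — mirroring how covalent-adduct formation tilts
    the free-energy surface. Birth–death chains are reversible, so the
    planted kinetics satisfy detailed balance exactly.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    fwd, back = (0.07, 0.03) if condition == "bonded" else (0.03, 0.07)
    T = np.zeros((n_states, n_states))
    for i in range(n_states):
        up = fwd if i + 1 < n_states else 0.0
        down = back if i > 0 else 0.0
        T[i, i] = 1.0 - up - down
        if i + 1 < n_states:
            T[i, i + 1] = up
        if i > 0:
            T[i, i - 1] = down
    return T


def helix_backbone(n_residues: int, rise: float = 1.5, turn_deg: float = 100.0,
                   radius: float = 2.3) -> np.ndarray:
    """Ideal α-helix Cα trace: 1.5 Å rise and 100° turn per residue."""
    i = np.arange(n_residues)
    theta = np.deg2rad(turn_deg) * i
    return np.column_stack([radius * np.cos(theta),
                            radius * np.sin(theta),
                            rise * i])


def _default_communities(n_residues: int, n_communities: int) -> np.ndarray:
    """Contiguous residue blocks of near-equal size."""
    edges = np.linspace(0, n_residues, n_communities + 1).astype(int)
    assign = np.zeros(n_residues, dtype=int)
    for c in range(n_communities):
        assign[edges[c]:edges[c + 1]] = c
    return assign


def _default_displacements(n_macrostates: int, n_communities: int,
                           scale: float) -> np.ndarray:
    """State- and community-specific rigid translation vectors (Å).

    Community 0 is the static core (never displaced); community c ≥ 1
    translates along a fixed non-axis-aligned direction by an amplitude
    growing with the macrostate index, so every inter-community pair
    distance takes a distinct value in each macrostate.
    """
    dirs = np.zeros((n_communities, 3))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    for c in range(1, n_communities):
        phi = golden * c
        z = 1.0 - 2.0 * c / max(n_communities, 2)
        r = np.sqrt(max(0.0, 1.0 - z * z))
        dirs[c] = (r * np.cos(phi), r * np.sin(phi), z)
    disp = np.zeros((n_macrostates, n_communities, 3))
    for s in range(n_macrostates):
        for c in range(1, n_communities):
            amplitude = scale * s * (1.0 + 0.37 * c)
            disp[s, c] = amplitude * dirs[c]
    return disp


@dataclass
class SyntheticSpec:
    """Study-design parameters for one synthetic dataset.

    ``duration_us`` and ``save_interval_ps`` set the frame count per
    trajectory (duration / interval); ``displacement_scale`` (Å) sets
    the planted conformational signal and ``noise_sigma`` (Å) the
    per-coordinate Gaussian jitter around it.
    """

    n_residues: int = 148
    n_macrostates: int = 8
    n_communities: int = 4
    n_traj_per_condition: int = 6
    duration_us: float = 1.0
    save_interval_ps: float = 100.0
    displacement_scale: float = 3.0
    noise_sigma: float = 0.3
    residue_offset: int = 37
    seed: int = 0
    macro_T: dict = field(default_factory=dict)
    community_assignment: np.ndarray | None = None
    displacements: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.macro_T:
            self.macro_T = {c: default_macro_T(self.n_macrostates, c)
                            for c in CONDITIONS}
        for cond, T in self.macro_T.items():
            T = np.asarray(T, dtype=float)
            if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
                raise ValueError(f"macro_T[{cond}] must be row-stochastic")
            self.macro_T[cond] = T
        if self.community_assignment is None:
            self.community_assignment = _default_communities(
                self.n_residues, self.n_communities)
        self.community_assignment = np.asarray(self.community_assignment, dtype=int)
        if self.displacements is None:
            self.displacements = _default_displacements(
                self.n_macrostates, self.n_communities, self.displacement_scale)
        self.displacements = np.asarray(self.displacements, dtype=float)
        if self.displacements.shape != (self.n_macrostates, self.n_communities, 3):
            raise ValueError("displacements must be (n_macrostates, n_communities, 3)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def frames_per_trajectory(self) -> int:
        return int(round(self.duration_us * 1e6 / self.save_interval_ps))

    @property
    def n_trajectories(self) -> int:
        return self.n_traj_per_condition * len(CONDITIONS)

    @property
    def total_frames(self) -> int:
        return self.frames_per_trajectory * self.n_trajectories

    @property
    def n_features(self) -> int:
        return self.n_residues * (self.n_residues - 1) // 2

    @classmethod
    def test_scale(cls, **overrides) -> "SyntheticSpec":
        """Small spec for fast end-to-end exercises.

        20 residues, 4 macrostates, 4 trajectories × 2,000 frames.
        """
        defaults = dict(
            n_residues=20, n_macrostates=4, n_communities=3,
            n_traj_per_condition=2, duration_us=0.2, save_interval_ps=100.0,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def labels(self) -> list[str]:
        return residue_labels(self.n_residues, self.residue_offset)

    def macrostate_structure(self, state: int) -> Structure:
        """Noise-free Cα conformation of one macrostate."""
        coords = helix_backbone(self.n_residues).copy()
        coords += self.displacements[state][self.community_assignment]
        return Structure(self.labels(), coords)

    def discriminative_pairs(self) -> list[tuple[int, int]]:
        """Planted residue pairs whose distance varies across macrostates.

        Exactly the inter-community pairs for which the two communities'
        relative displacement differs between at least two macrostates.
        """
        assign = self.community_assignment
        moving = set()
        for c1 in range(self.n_communities):
            for c2 in range(c1 + 1, self.n_communities):
                rel = self.displacements[:, c2] - self.displacements[:, c1]
                if not np.allclose(rel, rel[0]):
                    moving.add((c1, c2))
        return [(i, j) for i, j in pair_index_map(self.n_residues)
                if (min(assign[i], assign[j]), max(assign[i], assign[j])) in moving
                and assign[i] != assign[j]]


@dataclass
class GroundTruth:
    macro_labels: list[np.ndarray]     # per trajectory
    condition_tags: list[str]
    generator_T: dict
    community_assignment: np.ndarray
    discriminative_pairs: list[tuple[int, int]]

    def to_json(self) -> dict:
        return {
            "macro_labels": [l.tolist() for l in self.macro_labels],
            "condition_tags": self.condition_tags,
            "generator_T": {k: v.tolist() for k, v in self.generator_T.items()},
            "community_assignment": self.community_assignment.tolist(),
            "discriminative_pairs": [list(p) for p in self.discriminative_pairs],
        }


# ---------------------------------------------------------------------------
# sampling


def sample_chain(T: np.ndarray, length: int, seed, start: int | None = None) -> np.ndarray:
    """Sample a Markov chain from a row-stochastic matrix, seeded.

    The start state is drawn from the stationary distribution unless
    given explicitly.
    """
    T = np.asarray(T, dtype=float)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-10) or np.any(T < 0):
        raise ValueError("T must be row-stochastic")
    rng = np.random.default_rng(seed)
    n = T.shape[0]
    cdf = np.cumsum(T, axis=1)
    states = np.empty(length, dtype=int)
    if start is None:
        from .msm import stationary_distribution

        start = int(rng.choice(n, p=stationary_distribution(T)))
    states[0] = start
    draws = rng.random(length - 1)
    for t in range(1, length):
        states[t] = np.searchsorted(cdf[states[t - 1]], draws[t - 1], side="right")
    return states


def emit_trajectories(
    labels_list, condition_tags, spec: SyntheticSpec, seed,
) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Render macrostate label sequences into noisy Cα trajectories."""
    base = helix_backbone(spec.n_residues)
    node_disp = spec.displacements[:, spec.community_assignment, :]  # (S, N, 3)
    rng = np.random.default_rng(seed)
    trajs = []
    for labels in labels_list:
        labels = np.asarray(labels, dtype=int)
        coords = base[None, :, :] + node_disp[labels]
        if spec.noise_sigma > 0:
            coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
        trajs.append(coords)
    ensemble = TrajectoryEnsemble(
        residue_labels=spec.labels(),
        trajectories=trajs,
        condition_tags=list(condition_tags),
        save_interval_ps=spec.save_interval_ps,
    )
    truth = GroundTruth(
        macro_labels=[np.asarray(l, dtype=int) for l in labels_list],
        condition_tags=list(condition_tags),
        generator_T=dict(spec.macro_T),
        community_assignment=spec.community_assignment,
        discriminative_pairs=spec.discriminative_pairs(),
    )
    return ensemble, truth


def generate(spec: SyntheticSpec, seed: int | None = None
             ) -> tuple[TrajectoryEnsemble, GroundTruth]:
    """Sample chains for every trajectory of both conditions and render them."""
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    chain_ss, coord_ss = root.spawn(2)
    chain_children = chain_ss.spawn(spec.n_trajectories)
    labels_list, tags = [], []
    i = 0
    length = spec.frames_per_trajectory
    for cond in CONDITIONS:
        for _ in range(spec.n_traj_per_condition):
            labels_list.append(sample_chain(spec.macro_T[cond], length,
                                            chain_children[i]))
            tags.append(cond)
            i += 1
    return emit_trajectories(labels_list, tags, spec, coord_ss)


def manifest(spec: SyntheticSpec, seed: int | None = None) -> dict:
    """Sampling-plan summary (frame and feature counts) without coordinates."""
    return {
        "n_residues": spec.n_residues,
        "n_macrostates": spec.n_macrostates,
        "n_communities": spec.n_communities,
        "conditions": list(CONDITIONS),
        "n_traj_per_condition": spec.n_traj_per_condition,
        "n_trajectories": spec.n_trajectories,
        "duration_us": spec.duration_us,
        "save_interval_ps": spec.save_interval_ps,
        "frames_per_trajectory": spec.frames_per_trajectory,
        "total_frames": spec.total_frames,
        "n_features": spec.n_features,
        "noise_sigma_A": spec.noise_sigma,
        "displacement_scale_A": spec.displacement_scale,
        "seed": spec.seed if seed is None else seed,
    }


def make_dataset(
    spec: SyntheticSpec, out_dir, seed: int | None = None,
    write_trajectories: bool = True, fmt: str = "pdb",
) -> dict:
    """Write a dataset to disk: trajectories, ground truth and manifest.

    With ``write_trajectories`` off, only the manifest and ground-truth
    labels are produced (useful to inspect a sampling plan cheaply).
    Returns the manifest dict.
    """
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ensemble, truth = generate(spec, seed=seed)
    man = manifest(spec, seed=seed)
    man["spec_hash"] = spec_hash(spec)
    files = []
    if write_trajectories:
        for ti, coords in enumerate(ensemble.trajectories):
            tag = ensemble.condition_tags[ti]
            if fmt == "pdb":
                name = f"traj_{ti:02d}_{tag}.pdb"
                _io.write_trajectory(coords, ensemble.residue_labels, out / name)
            elif fmt == "dcd":
                name = f"traj_{ti:02d}_{tag}.dcd"
                _io.write_trajectory(coords, ensemble.residue_labels, out / name,
                                     topology_path=out / "topology.pdb")
            else:
                raise ValueError(f"unknown trajectory format {fmt!r}")
            files.append(name)
    man["trajectory_files"] = files
    _io.write_json(truth.to_json(), out / "ground_truth.json")
    _io.write_json(man, out / "manifest.json")
    return man


def spec_hash(spec: SyntheticSpec) -> str:
    payload = json.dumps({
        "n_residues": spec.n_residues,
        "n_macrostates": spec.n_macrostates,
        "n_communities": spec.n_communities,
        "n_traj_per_condition": spec.n_traj_per_condition,
        "duration_us": spec.duration_us,
        "save_interval_ps": spec.save_interval_ps,
        "displacement_scale": spec.displacement_scale,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "macro_T": {k: np.asarray(v).tolist() for k, v in sorted(spec.macro_T.items())},
        "community_assignment": spec.community_assignment.tolist(),
        "displacements": spec.displacements.tolist(),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
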