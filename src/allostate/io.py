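"""File I/O: PDB/DCD/XTC readers and writers built on mdtraj.

Only Cα atoms are retained from input structures and trajectories;
other atoms are ignored (a notice is logged). Coordinates are converted
between mdtraj's nanometers and this package's ångströms at the
boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .geometry import Structure, TrajectoryEnsemble

log = logging.getLogger(__name__)

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


def _ca_selection(traj):
    import mdtraj as md  # noqa: F401

    ca = traj.topology.select("name CA")
    if len(ca) < traj.topology.n_atoms:
        log.info(
            "keeping %d Calpha atoms, ignoring %d other atoms",
            len(ca), traj.topology.n_atoms - len(ca),
        )
    if len(ca) == 0:
        raise ValueError("no Calpha atoms found")
    return traj.atom_slice(ca)


def _labels_from_topology(top) -> list[str]:
    labels = []
    for res in top.residues:
        one = _AA3TO1.get(res.name.upper(), "X")
        labels.append(f"{one}{res.resSeq}")
    return labels


def read_structure(path) -> Structure:
    """Read the first model of a PDB file as a Cα-only Structure (Å)."""
    import mdtraj as md

    traj = md.load(str(path))
    traj = _ca_selection(traj)
    return Structure(
        residue_labels=_labels_from_topology(traj.topology),
        coords=traj.xyz[0] * 10.0,
    )


def read_trajectories(
    paths,
    topology=None,
    condition_tags=None,
    save_interval_ps: float = 100.0,
) -> TrajectoryEnsemble:
    """Load DCD/XTC (with ``topology``) or multi-model PDB trajectories."""
    import mdtraj as md

    paths = [str(p) for p in paths]
    if condition_tags is None:
        condition_tags = ["non_bonded"] * len(paths)
    trajs = []
    labels = None
    for p in paths:
        t = md.load(p, top=str(topology)) if topology is not None else md.load(p)
        t = _ca_selection(t)
        lab = _labels_from_topology(t.topology)
        if labels is None:
            labels = lab
        elif lab != labels:
            raise ValueError(f"residue labels of {p} differ from first trajectory")
        trajs.append(t.xyz * 10.0)
    return TrajectoryEnsemble(
        residue_labels=labels,
        trajectories=trajs,
        condition_tags=list(condition_tags),
        save_interval_ps=save_interval_ps,
    )


def _build_topology(residue_labels):
    import mdtraj as md

    top = md.Topology()
    chain = top.add_chain()
    for lab in residue_labels:
        one, num = lab[0], int(lab[1:])
        res = top.add_residue(_AA1TO3.get(one, "GLY"), chain, resSeq=num)
        top.add_atom("CA", md.element.carbon, res)
    return top


def write_structure(structure: Structure, path) -> None:
    """Write a Cα Structure as a single-model PDB."""
    import mdtraj as md

    top = _build_topology(structure.residue_labels)
    md.Trajectory(structure.coords[None] / 10.0, top).save(str(path))


def write_trajectory(
    coords: np.ndarray, residue_labels, path, topology_path=None
) -> None:
    """Write one (T, N, 3) Å trajectory as multi-model PDB or DCD.

    The format follows the file suffix; for DCD a PDB topology is also
    written when ``topology_path`` is given.
    """
    import mdtraj as md

    top = _build_topology(residue_labels)
    traj = md.Trajectory(np.asarray(coords) / 10.0, top)
    traj.save(str(path))
    if topology_path is not None:
        traj[0].save(str(topology_path))


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
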