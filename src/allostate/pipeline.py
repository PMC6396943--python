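"""End-to-end orchestration: featurize → MSM → importance → community → TPT.

A RunConfig (constructible from YAML) pins every setting and one root
seed; named substreams derive per-stage seeds so reruns are numerically
identical. Each stage writes its artifacts into the output directory
and the final summary records the config hash, the seeds and the key
numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import community as comm
from . import geometry, io, ml_importance as mli, msm, synthetic, tpt

log = logging.getLogger(__name__)

_STAGES = ("data", "featurize", "msm", "importance", "community", "tpt")


@dataclass
class RunConfig:
    """Declarative settings for one full analysis run (schema version 1)."""

    schema_version: int = 1
    # input: synthetic spec (None -> trajectory files must be given)
    synthetic: dict | None = None
    trajectory_files: list[str] = field(default_factory=list)
    topology_file: str | None = None
    condition_tags: list[str] = field(default_factory=list)
    dark_reference: str | None = None
    light_reference: str | None = None
    save_interval_ps: float = 100.0
    # msm
    n_microstates: int = 300
    lag_frames: int = 300            # 30 ns at 100 ps/frame
    implied_timescale_lags: list[int] = field(default_factory=lambda: [1, 2, 5, 10])
    n_macrostates: int = 8
    ck_multiples: list[int] = field(default_factory=lambda: [1, 2, 3])
    dispersion_threshold: float = 2.0
    # machine learning
    n_trees: int = 100
    max_depth: int | None = None
    folds: int = 12
    train_baseline_models: bool = False
    coverage_threshold: float = 0.9
    # community
    n_communities: int | None = 4    # None -> elbow-select over scan range
    community_scan: list[int] = field(default_factory=lambda: [2, 3, 4, 5, 6])
    restarts: int = 10_000
    # tpt (macrostate indices, 0-based)
    tpt_source: int = 0
    tpt_target: int = 1
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic and isinstance(self.synthetic, dict):
            d["synthetic"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.synthetic.items()
            }
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def validate(self) -> None:
        if self.synthetic is None and not self.trajectory_files:
            raise ValueError("either a synthetic spec or trajectory files required")
        if self.lag_frames < 1:
            raise ValueError("lag_frames must be >= 1")
        if self.synthetic is not None:
            spec = synthetic.SyntheticSpec(**self.synthetic)
            if self.lag_frames >= spec.frames_per_trajectory:
                raise ValueError("lag must be shorter than the trajectories")
            if self.tpt_source == self.tpt_target:
                raise ValueError("TPT source and target must differ")
            if max(self.tpt_source, self.tpt_target) >= self.n_macrostates:
                raise ValueError("TPT states out of macrostate range")


def _stage_seeds(root_seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(root_seed).spawn(len(_STAGES))
    return {name: int(child.generate_state(1)[0] % (2**31))
            for name, child in zip(_STAGES, children)}


def run(config: RunConfig, out_dir) -> dict:
    """Execute all stages and write the report bundle; returns the summary."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "stage_seeds": seeds,
        "stages": {},
    }

    def _stage(name):
        t0 = time.time()
        log.info("stage %s started", name)
        return t0

    def _done(name, t0, **info):
        summary["stages"][name] = {"seconds": round(time.time() - t0, 3), **info}
        log.info("stage %s finished in %.2fs", name, time.time() - t0)

    # -- data -------------------------------------------------------------
    t0 = _stage("data")
    truth = None
    if config.synthetic is not None:
        spec = synthetic.SyntheticSpec(**config.synthetic)
        ensemble, truth = synthetic.generate(spec, seed=seeds["data"])
        dark = spec.macrostate_structure(0)
        light = spec.macrostate_structure(spec.n_macrostates - 1)
        io.write_json(synthetic.manifest(spec, seed=seeds["data"]),
                      out / "manifest.json")
        summary["data_points"] = spec.total_frames
        summary["n_features"] = spec.n_features
    else:
        ensemble = io.read_trajectories(
            config.trajectory_files, topology=config.topology_file,
            condition_tags=config.condition_tags or None,
            save_interval_ps=config.save_interval_ps)
        dark = io.read_structure(config.dark_reference)
        light = io.read_structure(config.light_reference)
        summary["data_points"] = ensemble.n_frames
        summary["n_features"] = ensemble.n_residues * (ensemble.n_residues - 1) // 2
    if config.lag_frames >= min(t.shape[0] for t in ensemble.trajectories):
        raise ValueError("lag must be shorter than the shortest trajectory")
    _done("data", t0, n_frames=ensemble.n_frames, n_residues=ensemble.n_residues)

    # -- featurize ---------------------------------------------------------
    t0 = _stage("featurize")
    features = geometry.pairwise_distances(ensemble)
    cv = geometry.rmsd2d(ensemble, dark, light)
    cv.to_csv(out / "cv.csv")
    _done("featurize", t0, n_features=features.n_features)

    # -- msm ----------------------------------------------------------------
    t0 = _stage("msm")
    micro = msm.cluster_microstates(cv, k=config.n_microstates, seed=seeds["msm"])
    per_traj = micro.labels_per_trajectory()
    its = msm.implied_timescales(per_traj, config.implied_timescale_lags,
                                 save_interval_ps=ensemble.save_interval_ps)
    its.to_csv(out / "implied_timescales.csv", index=False)
    counts, active = msm.count_and_trim(per_traj, config.lag_frames,
                                        n_states=config.n_microstates)
    model = msm.estimate_T(counts, active, reversible=True,
                           lag_frames=config.lag_frames,
                           save_interval_ps=ensemble.save_interval_ps)
    macro = msm.pcca(model, config.n_macrostates, seed=seeds["msm"])
    macro_labels = [macro.map_labels(l, active) for l in per_traj]
    for cond in sorted(set(ensemble.condition_tags)):
        mT, undef = msm.condition_macro_T(per_traj, ensemble.condition_tags,
                                          macro, active, config.lag_frames,
                                          condition=cond)
        macro.macro_T[cond] = mT
        ok = ~np.any(np.isnan(mT), axis=1)
        pi = (msm.stationary_distribution(mT) if ok.all()
              else np.full(macro.n_macro, np.nan))
        macro.macro_pi[cond] = pi
        pd.DataFrame(mT).to_csv(out / f"macro_T_{cond}.csv", index=False)
        if np.any(undef):
            log.warning("condition %s: macrostates never visited: %s",
                        cond, np.where(undef)[0].tolist())
    ck = msm.ck_test(per_traj, macro, active, config.lag_frames,
                     k_multiples=config.ck_multiples)
    ck.to_csv(out / "ck_test.csv", index=False)
    disp = msm.microstate_dispersion(ensemble, micro,
                                     threshold=config.dispersion_threshold)
    disp.to_csv(out / "microstate_dispersion.csv", index=False)
    if disp["flagged"].any():
        log.warning("microstates above the dispersion threshold: %s",
                    disp.loc[disp.flagged, "microstate"].tolist())
    dropped = config.n_microstates - active.size
    if dropped:
        log.warning("%d microstates trimmed from the active set", dropped)
    summary["stationary"] = {c: macro.macro_pi[c]
                             for c in sorted(macro.macro_pi)}
    _done("msm", t0, n_active=int(active.size), n_trimmed=int(dropped),
          n_macrostates=macro.n_macro)

    # -- importance ----------------------------------------------------------
    t0 = _stage("importance")
    frame_macro = macro.map_labels(micro.labels, active)
    keep = frame_macro >= 0
    data = mli.LabeledFeatures(
        features=geometry.FeatureMatrix(
            values=features.values[keep],
            pair_map=features.pair_map,
            residue_labels=features.residue_labels,
            frame_index=[fi for fi, k in zip(features.frame_index, keep) if k],
        ),
        labels=frame_macro[keep],
    )
    clf_spec = mli.ClassifierSpec(n_trees=config.n_trees,
                                  max_depth=config.max_depth,
                                  folds=config.folds,
                                  seed=seeds["importance"])
    if config.train_baseline_models:
        baselines = mli.train_baselines(data, clf_spec)
        baselines.to_csv(out / "baseline_accuracies.csv", index=False)
    ovo, table = mli.train_ovo(data, clf_spec)
    table.to_tsv(out / "importance.tsv")
    table.ranked_report().to_csv(out / "top_features.csv", index=False)
    n_cover = mli.cumulative_coverage(table.overall, config.coverage_threshold)
    summary["n_pairwise_classifiers"] = ovo.n_classifiers
    summary["coverage_features"] = n_cover
    _done("importance", t0, n_classifiers=ovo.n_classifiers)

    # -- community ------------------------------------------------------------
    t0 = _stage("community")
    graph = comm.build_graph(table.overall, table.pair_map,
                             n_residues=len(table.residue_labels),
                             residue_labels=table.residue_labels)
    curve, elbow_n = comm.scan_elbow(graph, config.community_scan,
                                     restarts=config.restarts,
                                     seed=seeds["community"])
    curve.to_csv(out / "community_scan.csv", index=False)
    n_comm = config.n_communities or elbow_n
    part = comm.kl_search(graph, n_comm, restarts=config.restarts,
                          seed=seeds["community"])
    part.to_tsv(out / "communities.tsv",
                residue_labels=table.residue_labels, graph=graph)
    cmat = comm.community_matrix(part, table.overall, table.pair_map, g=graph)
    cmat.to_csv(out / "community_matrix.tsv", sep="\t")
    report = comm.state_pair_community_report(table, part, g=graph)
    report.to_csv(out / "state_pair_communities.tsv", sep="\t", index=False)
    total = graph.total_weight
    summary["community"] = {
        "n": n_comm, "elbow_n": int(elbow_n),
        "within_pct": 100.0 * part.objective / total if total else 0.0,
        "among_pct": 100.0 * (total - part.objective) / total if total else 100.0,
        "restarts": config.restarts, "seed": seeds["community"],
    }
    _done("community", t0, n=n_comm)

    # -- tpt -------------------------------------------------------------------
    t0 = _stage("tpt")
    cond = "bonded" if "bonded" in macro.macro_T else sorted(macro.macro_T)[0]
    mT = macro.macro_T[cond]
    if np.any(np.isnan(mT)):
        log.warning("condition %s has undefined macrostate rows; "
                    "running TPT on the pooled matrix", cond)
        mT, _ = msm.condition_macro_T(per_traj, ensemble.condition_tags, macro,
                                      active, config.lag_frames, condition=None)
        cond = "all"
    pi = msm.stationary_distribution(mT)
    problem = tpt.TPTProblem(T=mT, pi=pi, A={config.tpt_source},
                             B={config.tpt_target},
                             lag_ps=config.lag_frames * ensemble.save_interval_ps)
    net = tpt.analyze(problem)
    net.channel_table().to_csv(out / "channels.tsv", sep="\t", index=False)
    pd.DataFrame(net.f_plus).to_csv(out / "net_flux.csv", index=False)
    summary["tpt"] = {
        "condition": cond,
        "total_flux_per_tau": net.total_flux,
        "n_pathways": len(net.pathways),
        "n_channels": len(net.channels),
    }
    _done("tpt", t0, n_channels=len(net.channels))

    if truth is not None:
        io.write_json(truth.to_json(), out / "ground_truth.json")
    io.write_json(summary, out / "summary.json")
    return summary
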