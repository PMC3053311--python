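"""End-to-end orchestration of the ensemble and trajectory workflows.

``run_xray_pipeline`` chains structure reading → subunit extraction →
ensemble assembly → invariant-core detection → superposition → PCA →
conformer scores (and, when state groups are configured, the X-ray DCM
panels).  ``run_traj_pipeline`` runs the per-trajectory observables (RMSd
series, clustering, RMSF comparison, DCCM, entropy, H-bonds, projection
summaries) over labeled replicate trajectories.  Both write their artifacts
to an output directory with a manifest recording the configuration and a
content hash per file, so a rerun with the same config is reproducible and
verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .structure_io import read_pdb, read_trajectory, extract_subunits, build_ensemble
from .superpose import CoreDefinition, find_invariant_core, superpose_ensemble
from .ensemble_pca import fit_pca, project, variance_captured
from .traj_metrics import (rmsd_series, compare_rmsf, cluster_average_linkage,
                           dccm, quasiharmonic_entropy)
from .contacts import dcm_xray_panels, dcm_to_frame

logger = logging.getLogger("ensdyn")

__all__ = ["RunConfig", "run_xray_pipeline", "run_traj_pipeline",
           "setup_logging"]


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Timestamped leveled logging to stderr and optionally a file."""
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    logger.setLevel(level)
    logger.handlers.clear()
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


@dataclass
class RunConfig:
    """Flat key/value configuration for both pipelines (YAML-compatible)."""

    # inputs
    ensemble_dir: str | None = None          # directory of PDB files
    trajectories: list[dict] = field(default_factory=list)
    # each: {path, condition, replicate}
    group_map: dict[str, list[str]] = field(default_factory=dict)
    # state label -> list of pdb stems, for DCM panels
    # parameters
    min_length: int = 500
    max_missing_fraction: float = 0.1
    core_stop_volume: float = 0.5
    n_modes: int = 10
    n_clusters: int = 5
    contact_cutoff: float = 4.0
    min_occupancy: float = 0.5
    min_diff: float = 0.5
    alpha: float = 0.05
    dccm_threshold: float = 0.5
    temperature: float = 300.0
    rmsf_window: tuple[int, int] | None = None
    seed: int = 0
    output_dir: str = "ensdyn-out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "rmsf_window" in data and data["rmsf_window"] is not None:
            data["rmsf_window"] = tuple(data["rmsf_window"])
        return cls(**data)

    def validate_xray(self) -> None:
        if not self.ensemble_dir:
            raise ValueError("ensemble_dir is required for the X-ray pipeline")
        d = Path(self.ensemble_dir)
        if not d.is_dir() or not any(d.glob("*.pdb")):
            raise ValueError(f"{d} is not a directory with PDB files")

    def validate_traj(self) -> None:
        if not self.trajectories:
            raise ValueError("trajectories list is required")
        for entry in self.trajectories:
            if not Path(entry["path"]).exists():
                raise ValueError(f"missing trajectory {entry['path']}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(outdir: Path, config: RunConfig, stage: str) -> None:
    files = sorted(p for p in outdir.rglob("*")
                   if p.is_file() and p.name != "manifest.json")
    manifest = {
        "stage": stage,
        "ensdyn_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))


def run_xray_pipeline(config: RunConfig) -> dict:
    """Ensemble workflow: extract subunits, find the core, PCA, projections.

    Writes eigenvalue spectrum, conformer scores, core definition and the PCA
    bundle to ``config.output_dir``; returns the in-memory artifacts.
    """
    config.validate_xray()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        logger.info("x-ray pipeline stage: %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as e:
            raise RuntimeError(f"stage {name!r} failed: {e}") from e

    models = []
    for path in sorted(Path(config.ensemble_dir).glob("*.pdb")):
        models.extend(stage(f"read {path.name}", read_pdb, path))
    subunits = stage("extract_subunits", extract_subunits, models,
                     config.min_length, config.max_missing_fraction)
    if len(subunits) < 2:
        raise RuntimeError("stage 'extract_subunits' failed: <2 subunits")
    ensemble = stage("build_ensemble", build_ensemble, subunits)
    core = stage("find_invariant_core", find_invariant_core, ensemble,
                 config.core_stop_volume)
    fitted = stage("superpose_ensemble", superpose_ensemble, ensemble, core)
    n_modes = min(config.n_modes, fitted.n_conformers - 1, 3 * fitted.n_residues)
    model = stage("fit_pca", fit_pca, fitted, core, n_modes)
    scores = stage("project", project, model, fitted, min(2, n_modes),
                   fit=False)

    spectrum = pd.DataFrame({
        "mode": np.arange(1, model.n_modes + 1),
        "eigenvalue": model.eigenvalues,
        "variance_fraction": model.variance_fractions(),
        "cumulative_fraction": [variance_captured(model, k)
                                for k in range(1, model.n_modes + 1)],
    })
    spectrum.to_csv(outdir / "eigenvalue_spectrum.csv", index=False)
    scores.to_frame().to_csv(outdir / "conformer_scores.csv", index=False)
    (outdir / "core.txt").write_text(core.to_ranges() + "\n")
    model.save(outdir / "pca_model")

    panels = {}
    if config.group_map:
        groups = {}
        for label, stems in config.group_map.items():
            members = [s for s in subunits
                       if any(s.label.startswith(stem) for stem in stems)]
            groups[label] = members
        panels = stage("dcm_xray_panels", dcm_xray_panels, groups,
                       cutoff=config.contact_cutoff,
                       min_occupancy=config.min_occupancy,
                       min_diff=config.min_diff)
        for (a, b), panel in panels.items():
            dcm_to_frame(panel).to_csv(
                outdir / f"dcm_{a}_vs_{b}.csv", index=False)

    _write_manifest(outdir, config, "xray")
    return {"core": core, "model": model, "scores": scores,
            "spectrum": spectrum, "panels": panels, "ensemble": fitted}


def run_traj_pipeline(config: RunConfig, pca_model=None,
                      references: dict | None = None) -> dict:
    """Trajectory workflow over labeled replicates.

    Per trajectory: RMSd series vs each reference, clustering table; across
    conditions: replicate-level RMSF comparison (needs ≥2 replicates per
    condition), DCCM, entropy curves; plus PC-projection summaries
    (mean/median/last frame per simulation) when a PCA model is supplied.
    """
    config.validate_traj()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    trajs = []
    for entry in config.trajectories:
        trajs.append(read_trajectory(entry["path"],
                                     replicate=entry.get("replicate", ""),
                                     condition=entry.get("condition", "")))
    n_atoms = {t.topology.n_atoms for t in trajs}
    if len(n_atoms) != 1:
        raise RuntimeError("inconsistent topologies across trajectories")

    results: dict = {"rmsd": {}, "clusters": {}, "projections": {}}
    for traj in trajs:
        key = traj.replicate
        if references:
            for name, ref in references.items():
                series = rmsd_series(traj, ref)
                series.to_csv(outdir / f"rmsd_{key}_vs_{name}.csv", index=False)
                results["rmsd"][(key, name)] = series
        cl = cluster_average_linkage(traj, n_clusters=min(config.n_clusters,
                                                          traj.n_frames),
                                     references=references)
        table = cl.rmsd_table.copy()
        table.insert(0, "simulation", key)
        table.to_csv(outdir / f"clusters_{key}.csv", index=False)
        results["clusters"][key] = cl
        if pca_model is not None:
            sc = project(pca_model, traj, k=min(2, pca_model.n_modes))
            s = sc.scores
            results["projections"][key] = pd.DataFrame({
                "statistic": ["mean", "median", "last"],
                "pc1": [s[:, 0].mean(), np.median(s[:, 0]), s[-1, 0]],
                "pc2": [s[:, 1].mean(), np.median(s[:, 1]), s[-1, 1]]
                        if s.shape[1] > 1 else [np.nan] * 3,
            })
            results["projections"][key].to_csv(
                outdir / f"projection_summary_{key}.csv", index=False)

    by_condition: dict[str, list] = {}
    for t in trajs:
        by_condition.setdefault(t.condition, []).append(t)
    conditions = sorted(by_condition)
    if len(conditions) == 2:
        a, b = conditions
        comparison = compare_rmsf(by_condition[a], by_condition[b],
                                  window=config.rmsf_window,
                                  alpha=config.alpha)
        comparison.to_csv(outdir / f"rmsf_{a}_vs_{b}.csv", index=False)
        results["rmsf_comparison"] = comparison

    first = trajs[0]
    n = first.n_frames
    windows = [(i * n // 3, (i + 1) * n // 3) for i in range(3)] if n >= 9 else None
    cmap = dccm(first, windows=windows,
                consistency_threshold=config.dccm_threshold)
    pd.DataFrame(cmap.matrix, index=cmap.residue_ids,
                 columns=cmap.residue_ids).to_csv(outdir / "dccm.csv")
    results["dccm"] = cmap

    checkpoints = [max(3 * len(first.topology.residue_ids) // 2, n // 4),
                   n // 2, n]
    checkpoints = sorted({min(c, n) for c in checkpoints if c >= 2})
    curves = {}
    for traj in trajs:
        curve = quasiharmonic_entropy(traj, temperature=config.temperature,
                                      checkpoints=checkpoints)
        curve.to_frame().to_csv(outdir / f"entropy_{traj.replicate}.csv",
                                index=False)
        curves[traj.replicate] = curve
    results["entropy"] = curves

    _write_manifest(outdir, config, "traj")
    return results
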