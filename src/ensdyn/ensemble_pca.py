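"""Covariance-based principal component analysis of structure ensembles.

The covariance matrix of Cα positional deviations is built over a
core-superposed ensemble (C_ij = ⟨(x_i − ⟨x_i⟩)(x_j − ⟨x_j⟩)⟩, ensemble
average over conformers) and diagonalized; the leading eigenvectors are the
dominant collective deformations of the ensemble, and projections of other
conformers (e.g. trajectory frames) onto them yield 'conformer plots'.  Also
provides PC interpolation for mode visualization and RMSIP/overlap for
comparing two mode subspaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .structure_io import StructureModel, SubunitEnsemble, Trajectory
from .superpose import CoreDefinition, fit_frames

__all__ = [
    "PCAModel",
    "ConformerScores",
    "fit_pca",
    "variance_captured",
    "project",
    "interpolate_along_pc",
    "rmsip",
]


@dataclass
class PCAModel:
    """PCA of a fitted ensemble: mean, orthonormal modes, eigenvalues (Å²)."""

    mean: np.ndarray            # (3N,)
    eigenvectors: np.ndarray    # (3N, m), orthonormal columns
    eigenvalues: np.ndarray     # (m,), descending
    residue_ids: np.ndarray     # (N,) coordinate ordering
    core: CoreDefinition | None = None

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).ravel()
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.eigenvectors.shape[0] != self.mean.size:
            raise ValueError("eigenvector dimension != mean dimension")
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def mean_structure(self) -> np.ndarray:
        return self.mean.reshape(-1, 3)

    def variance_fractions(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    # -- text/CSV serialization bundle ------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"residue_id": self.residue_ids,
                      "x": self.mean_structure[:, 0],
                      "y": self.mean_structure[:, 1],
                      "z": self.mean_structure[:, 2]}
                     ).to_csv(directory / "mean.csv", index=False)
        pd.DataFrame({"eigenvalue": self.eigenvalues}
                     ).to_csv(directory / "eigenvalues.csv", index=False)
        np.savetxt(directory / "eigenvectors.csv", self.eigenvectors,
                   delimiter=",")
        if self.core is not None:
            (directory / "core.txt").write_text(self.core.to_ranges() + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "PCAModel":
        directory = Path(directory)
        mean_df = pd.read_csv(directory / "mean.csv")
        core = None
        if (directory / "core.txt").exists():
            core = CoreDefinition.from_ranges(
                (directory / "core.txt").read_text().strip())
        return cls(
            mean=mean_df[["x", "y", "z"]].to_numpy().ravel(),
            eigenvectors=np.loadtxt(directory / "eigenvectors.csv",
                                    delimiter=",", ndmin=2),
            eigenvalues=pd.read_csv(directory / "eigenvalues.csv")
                          ["eigenvalue"].to_numpy(),
            residue_ids=mean_df["residue_id"].to_numpy(int),
            core=core,
        )


@dataclass
class ConformerScores:
    """Projections of conformers onto the first k PCs (Å), with state labels."""

    conformer_ids: list[str]
    scores: np.ndarray              # (n_conf, k)
    states: list[str] = field(default_factory=list)
    ligand_states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        n = self.scores.shape[0]
        if not self.states:
            self.states = ["unknown"] * n
        if not self.ligand_states:
            self.ligand_states = ["unknown"] * n

    def to_frame(self, density: bool = True) -> pd.DataFrame:
        """Score table with a kernel-density shading column (Scott's rule KDE
        on the first two PCs), mirroring density-shaded conformer plots."""
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"pc{i+1}" for i in range(k)])
        df.insert(0, "conformer_id", self.conformer_ids)
        df.insert(1, "state", self.states)
        df.insert(2, "ligand_state", self.ligand_states)
        if density and k >= 2 and len(df) > 2:
            pts = self.scores[:, :2].T
            try:
                df["density"] = gaussian_kde(pts)(pts)
            except np.linalg.LinAlgError:   # degenerate (e.g. rank-1) clouds
                df["density"] = np.nan
        return df


def _sign_fix(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude component is positive."""
    idx = np.argmax(np.abs(vecs), axis=0)
    signs = np.sign(vecs[idx, np.arange(vecs.shape[1])])
    signs[signs == 0] = 1.0
    return vecs * signs


def fit_pca(ensemble: SubunitEnsemble, core: CoreDefinition | None = None,
            n_modes: int | None = None) -> PCAModel:
    """PCA of a core-superposed ensemble's Cα coordinates.

    The ensemble must already be superposed (``superpose_ensemble``); the
    covariance uses the ensemble-average (1/n) convention, so projecting the
    source ensemble back gives per-mode score variances equal to the
    eigenvalues.  Eigenvector signs are fixed so the largest-magnitude
    component of each mode is positive; among exactly degenerate eigenvalues
    the order is resolved by the first differing vector component.
    """
    X = ensemble.coords.reshape(ensemble.n_conformers, -1)
    if not np.all(np.isfinite(X)):
        raise ValueError("ensemble contains non-finite coordinates")
    mean = X.mean(axis=0)
    dev = X - mean
    cov = dev.T @ dev / len(X)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # deterministic order within exactly degenerate blocks
    for i in range(len(eigvals) - 1):
        if eigvals[i] == eigvals[i + 1]:
            a, b = eigvecs[:, i], eigvecs[:, i + 1]
            diff = np.nonzero(a != b)[0]
            if diff.size and a[diff[0]] > b[diff[0]]:
                eigvecs[:, [i, i + 1]] = eigvecs[:, [i + 1, i]]
    eigvecs = _sign_fix(eigvecs)
    if n_modes is not None:
        eigvals = eigvals[:n_modes]
        eigvecs = eigvecs[:, :n_modes]
    return PCAModel(mean=mean, eigenvectors=eigvecs, eigenvalues=eigvals,
                    residue_ids=ensemble.residue_ids.copy(), core=core)


def variance_captured(model: PCAModel, k: int) -> float:
    """Cumulative variance fraction of the first k modes."""
    if not 1 <= k <= model.n_modes:
        raise ValueError(f"k={k} out of range 1..{model.n_modes}")
    return float(model.eigenvalues[:k].sum() / model.eigenvalues.sum())


def _conformer_coords(conformers, model: PCAModel) -> tuple[np.ndarray, list[str], list[str], list[str]]:
    """Cα coordinate block (n, N, 3) in the model's residue order, + labels."""
    if isinstance(conformers, SubunitEnsemble):
        missing = np.setdiff1d(model.residue_ids, conformers.residue_ids)
        if missing.size:
            raise ValueError(f"conformers lack model residues {missing[:5].tolist()}")
        idx = conformers.residue_index(model.residue_ids)
        return (conformers.coords[:, idx, :], list(conformers.conformer_ids),
                list(conformers.states), list(conformers.ligand_states))
    if isinstance(conformers, Trajectory):
        ids, xyz = conformers.ca_view(model.residue_ids)
        labels = [f"{conformers.replicate}:frame{i}" for i in range(len(xyz))]
        cond = conformers.condition or "unknown"
        return xyz, labels, ["unknown"] * len(xyz), [cond] * len(xyz)
    xyz = np.asarray(conformers, dtype=float)
    if xyz.ndim == 2:
        xyz = xyz[None]
    if xyz.shape[1] != len(model.residue_ids):
        raise ValueError("coordinate block does not match model residue count")
    n = len(xyz)
    return xyz, [f"conf{i}" for i in range(n)], ["unknown"] * n, ["unknown"] * n


def project(model: PCAModel, conformers, k: int | None = None,
            fit: bool = True) -> ConformerScores:
    """Project conformers onto the model's PCs: scores = Vᵀ(x − mean).

    With ``fit=True`` (the conformer-plot convention) each conformer is first
    Kabsch-fitted to the model's mean structure on the model's core residues,
    putting e.g. trajectory frames into the experimental reference frame
    before centering on the experimental mean.  Use ``fit=False`` for
    conformers already expressed in the model frame.
    """
    k = model.n_modes if k is None else k
    if not 1 <= k <= model.n_modes:
        raise ValueError(f"k={k} out of range 1..{model.n_modes}")
    xyz, ids, states, ligands = _conformer_coords(conformers, model)
    if fit:
        if model.core is not None:
            lookup = {r: i for i, r in enumerate(model.residue_ids)}
            fit_idx = np.array([lookup[r] for r in model.core.residue_ids
                                if r in lookup], dtype=int)
        else:
            fit_idx = np.arange(len(model.residue_ids))
        xyz = fit_frames(xyz, model.mean_structure, fit_idx)
    dev = xyz.reshape(len(xyz), -1) - model.mean
    scores = dev @ model.eigenvectors[:, :k]
    return ConformerScores(conformer_ids=ids, scores=scores,
                           states=states, ligand_states=ligands)


def interpolate_along_pc(model: PCAModel, pc: int,
                         amplitudes: np.ndarray | list[float]) -> Trajectory:
    """Frames mean + a·v_pc for each amplitude a (Å), as a Cα trajectory.

    ``pc`` is 1-based.  Projecting a frame back onto the model returns its
    amplitude on that PC and zero elsewhere (within orthogonality).
    """
    if not 1 <= pc <= model.n_modes:
        raise ValueError(f"pc={pc} out of range 1..{model.n_modes}")
    amplitudes = np.asarray(amplitudes, dtype=float)
    v = model.eigenvectors[:, pc - 1]
    frames = (model.mean[None, :] + amplitudes[:, None] * v[None, :]).reshape(
        len(amplitudes), -1, 3)
    n_res = len(model.residue_ids)
    top = StructureModel(
        atom_names=np.array(["CA"] * n_res),
        residue_ids=model.residue_ids,
        residue_names=np.array(["ALA"] * n_res),
        chain_ids=np.array(["A"] * n_res),
        elements=np.array(["C"] * n_res),
        coords=frames[0],
        hetero=np.zeros(n_res, dtype=bool),
        label=f"pc{pc}-interpolation",
    )
    return Trajectory(topology=top, frames=frames,
                      replicate=f"pc{pc}", condition="interpolation")


def rmsip(model_a: PCAModel, model_b: PCAModel,
          n_modes: int = 10) -> tuple[float, np.ndarray]:
    """Root mean squared inner product of the first n modes of two models.

    RMSIP = sqrt((1/n) ΣᵢΣⱼ (vᵢ·wⱼ)²) ∈ [0, 1]; also returns the n×n
    squared-overlap matrix (the subspace-similarity map).
    """
    if model_a.mean.size != model_b.mean.size:
        raise ValueError("models have different coordinate dimensions")
    if n_modes > min(model_a.n_modes, model_b.n_modes):
        raise ValueError("n_modes exceeds available modes")
    V = model_a.eigenvectors[:, :n_modes]
    W = model_b.eigenvectors[:, :n_modes]
    overlap_sq = (V.T @ W) ** 2
    return float(np.sqrt(overlap_sq.sum() / n_modes)), overlap_sq
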