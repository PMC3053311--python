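"""Rigid-body superposition and invariant-core detection.

Least-squares (Kabsch) fitting of Cα coordinate sets, RMSd, iterative
superposition of an ensemble onto its own mean, and the iterated "invariant
core" procedure: repeatedly superpose on the current candidate residue set,
score each residue by the volume of its positional-covariance ellipsoid
across conformers, and peel off the most variable residue until the summed
volume falls below a threshold.  The surviving residues — the region of least
structural variation — define the reference frame for ensemble PCA and for
all trajectory RMSd series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import StructureModel, SubunitEnsemble

__all__ = [
    "RigidTransform",
    "CoreDefinition",
    "kabsch",
    "kabsch_fit",
    "rmsd",
    "fit_frames",
    "find_invariant_core",
    "superpose_ensemble",
]


@dataclass
class RigidTransform:
    """Proper rigid motion x ↦ R x + t (rotation then translation, Å)."""

    rotation: np.ndarray     # (3, 3), det +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-10):
            raise ValueError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass
class CoreDefinition:
    """Residue ids of the invariant core plus the per-iteration volume trace.

    ``volume_trace[k]`` is the summed covariance-ellipsoid volume (Å³) of the
    candidate set after k residues have been removed — a convergence
    diagnostic for the peeling iteration.
    """

    residue_ids: np.ndarray
    volume_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.residue_ids.size == 0:
            raise ValueError("core must be nonempty")

    def to_ranges(self) -> str:
        """Compact text form, e.g. '2-10,15,20-31'."""
        ids = np.sort(self.residue_ids)
        parts, start, prev = [], ids[0], ids[0]
        for r in ids[1:]:
            if r != prev + 1:
                parts.append(f"{start}-{prev}" if prev > start else f"{start}")
                start = r
            prev = r
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        return ",".join(parts)

    @classmethod
    def from_ranges(cls, text: str) -> "CoreDefinition":
        ids: list[int] = []
        for part in text.split(","):
            if "-" in part:
                lo, hi = part.split("-")
                ids.extend(range(int(lo), int(hi) + 1))
            else:
                ids.append(int(part))
        return cls(residue_ids=np.array(ids, dtype=int))


# ---------------------------------------------------------------------------
# Kabsch fitting
# ---------------------------------------------------------------------------

def _check_points(x: np.ndarray) -> None:
    if len(x) < 3:
        raise ValueError("need at least 3 points to define a rigid fit")
    centered = x - x.mean(axis=0)
    # rank < 2 ⇔ all points collinear ⇔ rotation about the line is free
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("points are collinear; rotation is underdetermined")


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns the transform attaining the global minimum RMSd over all proper
    rigid motions, and that RMSd (Å).  Standard SVD solution with the
    determinant correction that excludes reflections.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"shape mismatch {mobile.shape} vs {reference.shape}")
    _check_points(mobile)
    _check_points(reference)
    mu_m = mobile.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (mobile - mu_m).T @ (reference - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_r - R @ mu_m
    tr = RigidTransform(rotation=R, translation=t)
    fitted = tr.apply(mobile)
    return tr, float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))


def kabsch_fit(mobile: StructureModel, reference: StructureModel,
               subset: np.ndarray | list[int] | None = None
               ) -> tuple[RigidTransform, float]:
    """Kabsch fit of two structures on the Cα atoms of a residue subset."""
    if subset is None:
        ids_m = np.unique(mobile.residue_ids[mobile.ca_mask()])
        ids_r = np.unique(reference.residue_ids[reference.ca_mask()])
        subset = np.intersect1d(ids_m, ids_r)
    subset = np.asarray(subset, dtype=int)
    return kabsch(mobile.ca_coords(subset), reference.ca_coords(subset))


def rmsd(a: np.ndarray, b: np.ndarray, fit: bool = True) -> float:
    """RMSd between two coordinate sets; ``fit`` superposes first (Kabsch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if fit:
        return kabsch(a, b)[1]
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def fit_frames(frames: np.ndarray, reference: np.ndarray,
               fit_idx: np.ndarray | None = None) -> np.ndarray:
    """Superpose every frame onto ``reference`` using atoms ``fit_idx``.

    Batched Kabsch over (F, N, 3) frames: the transform is computed on the
    ``fit_idx`` subset and applied to all atoms.  Vectorized via batched SVD.
    """
    frames = np.asarray(frames, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_idx is None:
        fit_idx = np.arange(frames.shape[1])
    sub = frames[:, fit_idx, :]                       # (F, n, 3)
    ref = reference[fit_idx]                          # (n, 3)
    mu_f = sub.mean(axis=1, keepdims=True)            # (F, 1, 3)
    mu_r = ref.mean(axis=0)                           # (3,)
    H = np.einsum("fni,nj->fij", sub - mu_f, ref - mu_r)
    U, _, Vt = np.linalg.svd(H)
    det = np.linalg.det(np.einsum("fij,fjk->fik", np.transpose(Vt, (0, 2, 1)),
                                  np.transpose(U, (0, 2, 1))))
    D = np.tile(np.eye(3), (len(frames), 1, 1))
    D[:, 2, 2] = np.sign(det)
    R = np.einsum("fij,fjk,fkl->fil", np.transpose(Vt, (0, 2, 1)), D,
                  np.transpose(U, (0, 2, 1)))
    t = mu_r - np.einsum("fij,fj->fi", R, mu_f[:, 0, :])
    return np.einsum("fij,fnj->fni", R, frames) + t[:, None, :]


# ---------------------------------------------------------------------------
# Ensemble superposition and the invariant core
# ---------------------------------------------------------------------------

def _fit_to_mean(coords: np.ndarray, fit_idx: np.ndarray,
                 tol: float = 1e-6, max_iter: int = 50) -> np.ndarray:
    """Iteratively fit conformers to their evolving mean on ``fit_idx`` atoms."""
    fitted = fit_frames(coords, coords[0], fit_idx)
    mean = fitted.mean(axis=0)
    for _ in range(max_iter):
        fitted = fit_frames(fitted, mean, fit_idx)
        new_mean = fitted.mean(axis=0)
        shift = float(np.sqrt(np.max(np.sum((new_mean - mean) ** 2, axis=1))))
        mean = new_mean
        if shift < tol:
            break
    return fitted


def superpose_ensemble(ensemble: SubunitEnsemble,
                       core: CoreDefinition | None = None,
                       tol: float = 1e-6) -> SubunitEnsemble:
    """Fit every conformer to the ensemble mean on the core residues.

    Fit and mean are alternated until the mean moves by less than ``tol`` Å,
    so the returned ensemble is expressed in a self-consistent mean frame.
    """
    if core is None:
        fit_idx = np.arange(ensemble.n_residues)
    else:
        fit_idx = ensemble.residue_index(core.residue_ids)
    fitted = _fit_to_mean(ensemble.coords, fit_idx, tol=tol)
    return SubunitEnsemble(
        conformer_ids=list(ensemble.conformer_ids),
        residue_ids=ensemble.residue_ids.copy(),
        coords=fitted,
        states=list(ensemble.states),
        ligand_states=list(ensemble.ligand_states),
    )


def _ellipsoid_volumes(coords: np.ndarray) -> np.ndarray:
    """Per-residue positional-covariance ellipsoid volume (Å³).

    For each residue the 3×3 covariance of its position across conformers is
    diagonalized; the volume metric is the product of the eigenvalue square
    roots (proportional to the actual ellipsoid volume; the constant factor
    is irrelevant for ranking).
    """
    dev = coords - coords.mean(axis=0)                 # (n_conf, n_res, 3)
    cov = np.einsum("cri,crj->rij", dev, dev) / coords.shape[0]
    eigvals = np.linalg.eigvalsh(cov)                  # (n_res, 3) ascending
    eigvals = np.clip(eigvals, 0.0, None)
    return np.prod(np.sqrt(eigvals), axis=1)


def find_invariant_core(ensemble: SubunitEnsemble,
                        stop_volume: float = 0.5,
                        stop_fraction: float | None = None,
                        min_core: int = 3) -> CoreDefinition:
    """Iterated peeling of variable residues down to the invariant core.

    Each iteration superposes all conformers on the current candidate set,
    scores every candidate residue by its covariance-ellipsoid volume, and
    removes the single worst residue (ties broken toward the higher residue
    id, for determinism).  Iteration stops when the summed volume of the
    remaining candidates drops to ``stop_volume`` Å³ or the candidate set
    reaches ``stop_fraction`` of all residues.  Deterministic and
    permutation-invariant over conformer order.
    """
    if ensemble.n_conformers < 3:
        raise ValueError("need at least 3 conformers to locate a core")
    n_res = ensemble.n_residues
    min_keep = min_core
    if stop_fraction is not None:
        min_keep = max(min_core, int(np.ceil(stop_fraction * n_res)))

    candidate = np.arange(n_res)
    trace: list[float] = []
    while True:
        fitted = _fit_to_mean(ensemble.coords, candidate)
        volumes = _ellipsoid_volumes(fitted[:, candidate, :])
        total = float(volumes.sum())
        trace.append(total)
        if total <= stop_volume:
            break
        if len(candidate) <= min_keep:
            if stop_fraction is not None:
                break
            raise ValueError(
                "invariant core would shrink below 3 residues before "
                f"reaching stop_volume={stop_volume}")
        # worst residue; np.argmax takes the first max, so scan from the end
        # to break exact ties toward the higher residue id
        worst_rev = np.argmax(volumes[::-1])
        worst = len(volumes) - 1 - worst_rev
        candidate = np.delete(candidate, worst)
    return CoreDefinition(residue_ids=ensemble.residue_ids[candidate],
                          volume_trace=trace)
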