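"""Seeded generators for ensembles and trajectories with planted structure.

The analyses in this package assume specific statistical structure in their
inputs: crystal ensembles that are low-rank linear deformations of a mean
plus isotropic noise, equilibrium trajectories with a prescribed Gaussian
fluctuation covariance, two-state trajectories with planted contact
rearrangements, and hydrogen-bond geometries with an exact target occupancy.
These generators produce such inputs from an explicit seed, together with
machine-readable ground truth, so every analysis stage can be tested against
known answers without any structural database access.

The toy chain is an idealized extended backbone (N, CA, C, O + one CB
side-chain atom per residue, 3.8 Å Cα spacing); no excluded volume is
enforced, since the analyses under test are geometry-agnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structure_io import StructureModel, SubunitEnsemble, Trajectory
from .superpose import fit_frames, kabsch

__all__ = [
    "GeneratorSpec",
    "make_toy_chain",
    "gen_linear_ensemble",
    "gen_gaussian_traj",
    "gen_two_state_traj",
    "gen_hbond_traj",
    "random_rotation",
]

# local geometry of one residue (Å, relative to its Cα), idealized
_RESIDUE_TEMPLATE = {
    "N": np.array([-1.46, 0.0, 0.0]),
    "CA": np.array([0.0, 0.0, 0.0]),
    "C": np.array([1.52, 0.0, 0.0]),
    "O": np.array([2.15, 1.05, 0.0]),
    "CB": np.array([0.0, -1.53, 0.3]),
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


@dataclass
class GeneratorSpec:
    """Parameters shared by all generators.

    ``noise_sigma`` may be a scalar (isotropic per coordinate, Å) or a
    per-residue array; ``mode_amplitudes`` are the standard deviations (Å)
    of the planted deformation modes, which must be mutually orthogonal.
    """

    seed: int = 0
    n_residues: int = 50
    res_start: int = 1
    n_conformers: int = 100
    n_frames: int = 100
    mode_amplitudes: tuple[float, ...] = ()
    noise_sigma: float | np.ndarray = 0.0
    dt: float = 0.1        # ns between frames
    ca_spacing: float = 3.8  # Å between consecutive Cα atoms

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.mode_amplitudes):
            raise ValueError("mode amplitudes must be positive")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), int(salt)]))


def make_toy_chain(n_residues: int = 50, res_start: int = 1,
                   label: str = "toy", ca_spacing: float = 3.8) -> StructureModel:
    """Idealized extended chain: 5 atoms per residue, 3.8 Å Cα spacing.

    A small deterministic off-axis wobble keeps any ≥3 consecutive Cα atoms
    non-collinear, so rigid fits on short subsets are well conditioned.
    """
    names, rids, rnames, chains, elems, coords = [], [], [], [], [], []
    for i in range(n_residues):
        ca = np.array([ca_spacing * i, 0.8 * np.sin(0.7 * i), 0.8 * np.cos(1.3 * i)])
        for atom, offset in _RESIDUE_TEMPLATE.items():
            names.append(atom)
            rids.append(res_start + i)
            rnames.append("ALA")
            chains.append("A")
            elems.append(_ELEMENTS[atom])
            coords.append(ca + offset)
    return StructureModel(
        atom_names=np.array(names), residue_ids=np.array(rids),
        residue_names=np.array(rnames), chain_ids=np.array(chains),
        elements=np.array(elems), coords=np.array(coords),
        hetero=np.zeros(len(names), dtype=bool), label=label)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation (QR of a Gaussian matrix, det fixed)."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def rigid_body_basis(xyz: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the 6 rigid-body motions at a geometry (3N × 6).

    Three uniform translations plus three infinitesimal rotations ω × (r − r̄)
    about the centroid, orthonormalized.  Deformation modes planted by the
    generators are kept orthogonal to this subspace, so superposition leaves
    them intact.
    """
    n = len(xyz)
    centered = xyz - xyz.mean(axis=0)
    basis = np.zeros((3 * n, 6))
    for k in range(3):
        basis[k::3, k] = 1.0
    for k, omega in enumerate(np.eye(3)):
        basis[:, 3 + k] = np.cross(omega, centered).ravel()
    Q, _ = np.linalg.qr(basis)
    return Q


def _orthonormal_modes(rng: np.random.Generator, xyz: np.ndarray,
                       n_modes: int) -> np.ndarray:
    """Random orthonormal internal-deformation modes (dim 3N, m columns).

    Orthogonal to the rigid-body subspace at ``xyz``, so the planted variance
    survives ensemble superposition.
    """
    dim = xyz.size
    B = rigid_body_basis(xyz)
    A = rng.normal(size=(dim, n_modes))
    A -= B @ (B.T @ A)
    Q, _ = np.linalg.qr(A)
    return Q


def gen_linear_ensemble(spec: GeneratorSpec,
                        modes: np.ndarray | None = None,
                        rigid_residues: np.ndarray | None = None,
                        apply_rigid: bool = False
                        ) -> tuple[SubunitEnsemble, dict]:
    """Cα ensemble from a low-rank linear deformation model plus noise.

    conformer_k = base + Σᵢ a_{ki} vᵢ + ε with a_{ki} ~ N(0, ampᵢ²) and
    ε ~ N(0, σ²) per coordinate.  ``modes`` (3N × m orthonormal columns)
    defaults to seeded random orthonormal vectors.  ``rigid_residues``
    restricts the noise to the complementary residues (planting an exactly
    rigid sub-chain for core-recovery tests).  ``apply_rigid`` composites a
    random rigid motion onto each conformer to exercise superposition.

    Returns (ensemble, ground_truth) where ground_truth holds the base
    coordinates, modes, amplitudes and noise level actually used.
    """
    rng = spec.rng(salt=1)
    base = make_toy_chain(spec.n_residues, spec.res_start, ca_spacing=spec.ca_spacing)
    xyz0 = base.ca_coords()
    dim = xyz0.size
    m = len(spec.mode_amplitudes)
    if modes is None:
        modes = _orthonormal_modes(rng, xyz0, m) if m else np.zeros((dim, 0))
    else:
        modes = np.asarray(modes, dtype=float)
        if modes.shape != (dim, m):
            raise ValueError(f"modes must have shape ({dim}, {m})")
        if not np.allclose(modes.T @ modes, np.eye(m), atol=1e-8):
            raise ValueError("planted modes must be mutually orthonormal")
    amps = np.asarray(spec.mode_amplitudes, dtype=float)
    scores = rng.normal(size=(spec.n_conformers, m)) * amps

    sigma = np.asarray(spec.noise_sigma, dtype=float)
    if sigma.ndim == 0:
        sigma_res = np.full(spec.n_residues, float(sigma))
    else:
        if sigma.size != spec.n_residues:
            raise ValueError("per-residue noise_sigma length mismatch")
        sigma_res = sigma.copy()
    if rigid_residues is not None:
        rigid_pos = np.searchsorted(
            np.arange(spec.res_start, spec.res_start + spec.n_residues),
            np.asarray(rigid_residues))
        sigma_res[rigid_pos] = 0.0

    noise = rng.normal(size=(spec.n_conformers, spec.n_residues, 3))
    noise *= sigma_res[None, :, None]
    coords = (xyz0.ravel()[None, :] + scores @ modes.T).reshape(
        spec.n_conformers, spec.n_residues, 3) + noise
    if apply_rigid:
        for k in range(spec.n_conformers):
            R = random_rotation(rng)
            t = rng.normal(scale=10.0, size=3)
            coords[k] = coords[k] @ R.T + t

    ensemble = SubunitEnsemble(
        conformer_ids=[f"synth{k}" for k in range(spec.n_conformers)],
        residue_ids=np.unique(base.residue_ids),
        coords=coords)
    truth = {
        "base": xyz0, "modes": modes, "amplitudes": amps,
        "scores": scores, "noise_sigma": sigma_res, "seed": spec.seed,
    }
    return ensemble, truth


def gen_gaussian_traj(spec: GeneratorSpec, covariance: np.ndarray,
                      apply_rigid: bool = False) -> tuple[Trajectory, dict]:
    """Trajectory of i.i.d. frames from N(base, covariance) on Cα atoms.

    ``covariance`` is 3N × 3N symmetric positive semidefinite (Å²); non-Cα
    atoms ride rigidly with their residue's Cα displacement.  With
    ``apply_rigid`` each frame additionally gets a random rigid motion, which
    core fitting must remove.
    """
    cov = np.asarray(covariance, dtype=float)
    base = make_toy_chain(spec.n_residues, spec.res_start, ca_spacing=spec.ca_spacing)
    dim = 3 * spec.n_residues
    if cov.shape != (dim, dim):
        raise ValueError(f"covariance must be {dim}×{dim}")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(cov)
    if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
        raise ValueError("covariance must be positive semidefinite")
    root = eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))

    rng = spec.rng(salt=2)
    z = rng.normal(size=(spec.n_frames, dim))
    ca_disp = (z @ root.T).reshape(spec.n_frames, spec.n_residues, 3)

    frames = np.tile(base.coords, (spec.n_frames, 1, 1))
    res_of_atom = np.searchsorted(np.unique(base.residue_ids), base.residue_ids)
    frames += ca_disp[:, res_of_atom, :]
    if apply_rigid:
        for k in range(spec.n_frames):
            R = random_rotation(rng)
            t = rng.normal(scale=10.0, size=3)
            frames[k] = frames[k] @ R.T + t
    traj = Trajectory(topology=base, frames=frames,
                      times=np.arange(spec.n_frames) * spec.dt + spec.dt,
                      replicate=f"gauss-seed{spec.seed}", condition="gaussian")
    return traj, {"covariance": cov, "base": base.ca_coords(), "seed": spec.seed}


def _plant_contact(coords: np.ndarray, top: StructureModel,
                   res_i: int, res_j: int, distance: float) -> np.ndarray:
    """Reposition residue j so its minimal heavy-atom distance to residue i
    equals ``distance`` exactly, approached side-chain to side-chain.

    Residue j is flipped so its CB points back toward residue i's CB and
    placed directly 'below' it (−y), putting the CB–CB pair at the minimum;
    the backbone atoms of both residues stay ≥ 1 Å clear of every other
    residue pair, so only (i, j) changes contact state.  A final translation
    along the true closest-pair axis makes the planted distance exact.
    """
    coords = coords.copy()
    sel_i = np.nonzero((top.residue_ids == res_i) & top.heavy_mask())[0]
    sel_j = np.nonzero((top.residue_ids == res_j) & top.heavy_mask())[0]
    cb_i = coords[sel_i[np.nonzero(top.atom_names[sel_i] == "CB")[0][0]]]
    jb = sel_j[np.nonzero(top.atom_names[sel_j] == "CB")[0][0]]
    ca_j_idx = sel_j[np.nonzero(top.atom_names[sel_j] == "CA")[0][0]]
    # flip residue j about its own Cα so its CB points +y (toward residue i)
    local = coords[sel_j] - coords[ca_j_idx]
    local[:, 1] *= -1.0
    local[:, 2] *= -1.0
    coords[sel_j] = local + coords[ca_j_idx]
    # drop residue j so CB_j sits 'distance' straight below CB_i
    coords[sel_j] += (cb_i + np.array([0.0, -distance, 0.0])) - coords[jb]
    # exact correction along the realized closest-pair axis
    diff = coords[sel_i][:, None, :] - coords[sel_j][None, :, :]
    d = np.sqrt(np.sum(diff ** 2, axis=2))
    a, b = np.unravel_index(np.argmin(d), d.shape)
    axis = coords[sel_j[b]] - coords[sel_i[a]]
    axis /= np.linalg.norm(axis)
    coords[sel_j] += axis * (distance - d[a, b])
    return coords


def gen_two_state_traj(spec: GeneratorSpec,
                       schedule: np.ndarray | list[int] | None = None,
                       separation: float = 8.0,
                       jitter: float = 0.5,
                       contact_pairs: dict[tuple[int, int], tuple[float, float]] | None = None,
                       ) -> tuple[Trajectory, dict]:
    """Two-state trajectory with planted state labels and contact switches.

    State A is the toy chain; state B is A deformed by an internal (non-rigid)
    displacement field scaled so the best-fit Cα RMSd between the states is
    ``separation`` Å.  ``schedule`` gives the per-frame state (0 = A, 1 = B;
    default first half A, second half B).  ``contact_pairs`` maps a residue
    pair to its (state A, state B) minimal heavy-atom distances; the pair's
    residues are repositioned so those distances hold exactly before jitter.

    Returns (trajectory, ground_truth) with the state labels, the exact state
    coordinates, and the planted contact table.
    """
    rng = spec.rng(salt=3)
    base = make_toy_chain(spec.n_residues, spec.res_start, ca_spacing=spec.ca_spacing)
    state_a = base.coords.copy()

    # internal deformation for state B: random Cα field, rigid part removed by
    # Kabsch-fitting B back onto A, rescaled iteratively to the target RMSd
    ca_mask = base.ca_mask()
    field = rng.normal(size=(spec.n_residues, 3))
    res_of_atom = np.searchsorted(np.unique(base.residue_ids), base.residue_ids)
    disp = field[res_of_atom, :]
    state_b = state_a + disp
    if separation > 0:
        for _ in range(8):
            tr, r = kabsch(state_b[ca_mask], state_a[ca_mask])
            state_b = tr.apply(state_b)
            if abs(r - separation) < 1e-9:
                break
            state_b = state_a + (state_b - state_a) * (separation / r)
    else:
        state_b = state_a.copy()

    planted = {}
    if contact_pairs:
        for (ri, rj), (da, db) in contact_pairs.items():
            state_a = _plant_contact(state_a, base, ri, rj, da)
            state_b = _plant_contact(state_b, base, ri, rj, db)
            planted[f"{ri}-{rj}"] = {"state_a": da, "state_b": db}

    if schedule is None:
        schedule = np.zeros(spec.n_frames, dtype=int)
        schedule[spec.n_frames // 2:] = 1
    schedule = np.asarray(schedule, dtype=int)
    if len(schedule) != spec.n_frames:
        raise ValueError("schedule length != n_frames")

    states = np.stack([state_a, state_b])
    frames = states[schedule] + rng.normal(scale=jitter,
                                           size=(spec.n_frames,
                                                 base.n_atoms, 3))
    traj = Trajectory(topology=base, frames=frames,
                      times=np.arange(spec.n_frames) * spec.dt + spec.dt,
                      replicate=f"twostate-seed{spec.seed}",
                      condition="two-state")
    truth = {"schedule": schedule, "state_a": state_a, "state_b": state_b,
             "contacts": planted, "separation": separation,
             "jitter": jitter, "seed": spec.seed}
    return traj, truth


def gen_hbond_traj(spec: GeneratorSpec, occupancy_target: float,
                   d_cut: float = 3.5, angle_cut: float = 120.0
                   ) -> tuple[Trajectory, dict]:
    """Trajectory of a donor/H/acceptor triplet with exact bound occupancy.

    Exactly round(occupancy_target × n_frames) frames place the acceptor at
    ideal geometry (donor–acceptor 2.9 Å, angle 175°); the rest break the
    bond (5.5 Å).  The qualifying frames are the leading ones, so the planted
    occupancy is exact, not statistical.
    """
    if not 0.0 <= occupancy_target <= 1.0:
        raise ValueError("occupancy_target must be within [0, 1]")
    donor = np.array([0.0, 0.0, 0.0])
    hydrogen = np.array([1.0, 0.0, 0.0])
    bound_acc = np.array([2.9, 0.1, 0.0])     # ~175° at H, d = 2.90 Å
    broken_acc = np.array([5.5, 0.0, 0.0])
    top = StructureModel(
        atom_names=np.array(["N", "H", "O"]),
        residue_ids=np.array([1, 1, 2]),
        residue_names=np.array(["ASN", "ASN", "ATP"]),
        chain_ids=np.array(["A", "A", "A"]),
        elements=np.array(["N", "H", "O"]),
        coords=np.stack([donor, hydrogen, bound_acc]),
        hetero=np.array([False, False, True]),
        label="hbond-toy")
    n_bound = int(round(occupancy_target * spec.n_frames))
    frames = np.tile(top.coords, (spec.n_frames, 1, 1))
    frames[n_bound:, 2, :] = broken_acc
    traj = Trajectory(topology=top, frames=frames,
                      times=np.arange(spec.n_frames) * spec.dt + spec.dt,
                      replicate=f"hbond-seed{spec.seed}", condition="hbond")
    truth = {"occupancy": n_bound / spec.n_frames if spec.n_frames else 0.0,
             "n_bound": n_bound, "donor": 0, "hydrogen": 1, "acceptor": 2,
             "seed": spec.seed}
    return traj, truth


def write_ground_truth(path: str | Path, truth: dict) -> None:
    """Ground truth as JSON next to a generated fixture (arrays → lists)."""
    def conv(x):
        if isinstance(x, np.ndarray):
            return x.tolist()
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        if isinstance(x, StructureModel):
            return x.label
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        return x
    Path(path).write_text(json.dumps({k: conv(v) for k, v in truth.items()},
                                     indent=1))
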