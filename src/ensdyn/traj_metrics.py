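"""Per-trajectory observables for nucleotide-dependent subunit dynamics.

RMSd time series against reference conformers, per-residue RMSF with a
replicate-level group comparison (Welch test), average-linkage conformational
clustering with RMSd-to-reference tables, dynamic cross-correlation maps with
window-consistency filtering, quasi-harmonic configurational entropy as a
function of trajectory length, and hydrogen-bond occupancy.

All Cα-based observables fit frames on the invariant core first, so rigid-body
motion composited onto a trajectory does not contaminate internal
fluctuations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import constants
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind

from .structure_io import StructureModel, Trajectory
from .superpose import CoreDefinition, fit_frames, kabsch, rmsd

logger = logging.getLogger("ensdyn")

__all__ = [
    "ClusterResult",
    "CorrelationMap",
    "EntropyCurve",
    "HBondTable",
    "rmsd_series",
    "rmsf",
    "compare_rmsf",
    "cluster_average_linkage",
    "dccm",
    "quasiharmonic_entropy",
    "entropy_from_eigenvalues",
    "hbond_occupancy",
    "CA_MASS",
]

CA_MASS = 12.011  # amu; Cα carbons carry standard carbon mass


# ---------------------------------------------------------------------------
# RMSd series and RMSF
# ---------------------------------------------------------------------------

def _core_index(ids: np.ndarray, core: CoreDefinition | None) -> np.ndarray:
    if core is None:
        return np.arange(len(ids))
    lookup = {r: i for i, r in enumerate(ids)}
    missing = [r for r in core.residue_ids if r not in lookup]
    if missing:
        raise KeyError(f"core residues missing from trajectory: {missing[:5]}")
    return np.array([lookup[r] for r in core.residue_ids], dtype=int)


def rmsd_series(traj: Trajectory, reference: StructureModel,
                core: CoreDefinition | None = None) -> pd.DataFrame:
    """Per-frame all-Cα RMSd to a reference after fitting on the core.

    Columns: time (ns), rmsd (Å).  This is the trace used to follow
    closed↔open transitions along a simulation.
    """
    ids, frames = traj.ca_view()
    ref = reference.ca_coords(ids)
    fit_idx = _core_index(ids, core)
    fitted = fit_frames(frames, ref, fit_idx)
    vals = np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=2), axis=1))
    return pd.DataFrame({"time": traj.times, "rmsd": vals})


def rmsf(traj: Trajectory, window: tuple[int, int] | None = None,
         subset: np.ndarray | None = None,
         core: CoreDefinition | None = None) -> pd.DataFrame:
    """Per-residue Cα RMSF about the window-mean structure.

    Frames in ``window`` (half-open frame range; default all) are fitted to
    their own mean on the core, then RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩).
    ``subset`` restricts the reported residues (fitting still uses the core).
    """
    lo, hi = (0, traj.n_frames) if window is None else window
    if not (0 <= lo < hi <= traj.n_frames):
        raise ValueError(f"window {window} outside 0..{traj.n_frames}")
    ids, frames = traj.ca_view()
    frames = frames[lo:hi]
    fit_idx = _core_index(ids, core)
    # fit to evolving mean (two passes converge for equilibrium windows)
    fitted = fit_frames(frames, frames.mean(axis=0), fit_idx)
    for _ in range(3):
        fitted = fit_frames(fitted, fitted.mean(axis=0), fit_idx)
    dev = fitted - fitted.mean(axis=0)
    vals = np.sqrt(np.mean(np.sum(dev ** 2, axis=2), axis=0))
    df = pd.DataFrame({"residue_id": ids, "rmsf": vals})
    if subset is not None:
        df = df[df["residue_id"].isin(np.asarray(subset))].reset_index(drop=True)
    return df


def compare_rmsf(group_a: list[Trajectory], group_b: list[Trajectory],
                 window: tuple[int, int] | None = None,
                 alpha: float = 0.05, core: CoreDefinition | None = None,
                 correction: str | None = None) -> pd.DataFrame:
    """Per-residue comparison of replicate-level RMSF between two conditions.

    Each replicate contributes one RMSF value per residue; a two-sided Welch
    t-test across replicates flags residues with p < alpha (optionally after
    Benjamini–Hochberg with ``correction='bh'``).  Columns: residue_id,
    mean_a, mean_b, p_value, significant.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least 2 replicates per group")
    tables_a = [rmsf(t, window=window, core=core) for t in group_a]
    tables_b = [rmsf(t, window=window, core=core) for t in group_b]
    ids = tables_a[0]["residue_id"].to_numpy()
    for t in tables_a[1:] + tables_b:
        if not np.array_equal(t["residue_id"].to_numpy(), ids):
            raise ValueError("replicates do not share a residue set")
    A = np.stack([t["rmsf"].to_numpy() for t in tables_a])  # (reps, res)
    B = np.stack([t["rmsf"].to_numpy() for t in tables_b])
    stat, p = ttest_ind(A, B, axis=0, equal_var=False)
    p = np.nan_to_num(p, nan=1.0)
    if correction == "bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        p_adj = np.empty_like(p)
        p_adj[order] = np.clip(adj, 0, 1)
        sig = p_adj < alpha
    else:
        sig = p < alpha
    return pd.DataFrame({
        "residue_id": ids,
        "mean_a": A.mean(axis=0),
        "mean_b": B.mean(axis=0),
        "p_value": p,
        "significant": sig,
    })


# ---------------------------------------------------------------------------
# Conformational clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Average-linkage clustering of trajectory frames on pairwise RMSd."""

    labels: np.ndarray                      # (F,) cluster ids 1..n
    sizes: dict[int, int]
    averages: dict[int, np.ndarray]         # cluster -> mean Cα coords (N, 3)
    rmsd_table: pd.DataFrame                # cluster | size | rmsd_<ref>...

    def __post_init__(self) -> None:
        if sum(self.sizes.values()) != len(self.labels):
            raise ValueError("cluster sizes do not sum to frame count")


def pairwise_rmsd_matrix(frames: np.ndarray) -> np.ndarray:
    """Dense symmetric matrix of best-fit RMSd between all frame pairs."""
    F = len(frames)
    D = np.zeros((F, F))
    for i in range(F):
        fitted = fit_frames(frames[i + 1:], frames[i])
        d = np.sqrt(np.mean(np.sum((fitted - frames[i]) ** 2, axis=2), axis=1))
        D[i, i + 1:] = d
        D[i + 1:, i] = d
    return D


def cluster_average_linkage(traj: Trajectory, n_clusters: int = 5,
                            references: dict[str, StructureModel] | None = None,
                            core: CoreDefinition | None = None) -> ClusterResult:
    """Agglomerative average-linkage clustering on pairwise best-fit Cα RMSd.

    Cluster averages are the mean coordinates of members after fitting each
    member to the cluster medoid.  ``references`` (e.g. the closed t and open
    r'' crystal conformers) adds per-cluster columns of the average
    conformation's best-fit RMSd to each named reference.
    """
    if not 1 <= n_clusters <= traj.n_frames:
        raise ValueError(f"n_clusters={n_clusters} outside 1..{traj.n_frames}")
    ids, frames = traj.ca_view()
    D = pairwise_rmsd_matrix(frames)
    if traj.n_frames == 1:
        labels = np.array([1])
    else:
        Z = linkage(squareform(D, checks=False), method="average")
        labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber clusters by first occurrence for determinism
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    labels = np.array([remap[l] for l in labels])

    sizes: dict[int, int] = {}
    averages: dict[int, np.ndarray] = {}
    rows = []
    for c in sorted(set(labels.tolist())):
        members = np.nonzero(labels == c)[0]
        sizes[c] = len(members)
        sub = D[np.ix_(members, members)]
        medoid = members[np.argmin(sub.sum(axis=0))]
        fitted = fit_frames(frames[members], frames[medoid])
        avg = fitted.mean(axis=0)
        averages[c] = avg
        row: dict[str, object] = {"cluster": c, "size": len(members)}
        for name, ref in (references or {}).items():
            row[f"rmsd_{name}"] = rmsd(avg, ref.ca_coords(ids), fit=True)
        rows.append(row)
    return ClusterResult(labels=labels, sizes=sizes, averages=averages,
                         rmsd_table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Dynamic cross-correlation maps
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMap:
    """Normalized residue–residue cross-correlations in [−1, 1].

    ``matrix`` is the map of the full analysis window; ``consistent_pairs``
    lists (res_i, res_j) whose |c| clears the threshold in every sub-window —
    the filter used to call correlations robust rather than incidental.
    """

    residue_ids: np.ndarray
    matrix: np.ndarray
    consistent_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape[0] != m.shape[1] or m.shape[0] != len(self.residue_ids):
            raise ValueError("matrix shape does not match residue set")


def _dccm_matrix(frames: np.ndarray, fit_idx: np.ndarray) -> np.ndarray:
    fitted = fit_frames(frames, frames.mean(axis=0), fit_idx)
    for _ in range(2):
        fitted = fit_frames(fitted, fitted.mean(axis=0), fit_idx)
    dev = fitted - fitted.mean(axis=0)                 # (F, N, 3)
    inner = np.einsum("fni,fmi->nm", dev, dev) / len(dev)
    var = np.diag(inner).copy()
    zero = var <= 1e-15
    if zero.any():
        logger.warning("dccm: %d zero-variance residues set to NaN",
                       int(zero.sum()))
        var[zero] = np.nan
    c = inner / np.sqrt(np.outer(var, var))
    c = np.clip(c, -1.0, 1.0)   # NaN rows propagate through the clip
    np.fill_diagonal(c, np.where(zero, np.nan, 1.0))
    return c


def dccm(traj: Trajectory, subset: np.ndarray | None = None,
         windows: list[tuple[int, int]] | None = None,
         consistency_threshold: float = 0.5,
         core: CoreDefinition | None = None) -> CorrelationMap:
    """Dynamic cross-correlation map of Cα displacement vectors.

    c_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩) after fitting frames to their
    mean on the core.  If ``windows`` are given (frame intervals mimicking
    10/20/50 ns sub-trajectories), a pair is 'consistent' when |c_ij| ≥
    ``consistency_threshold`` in every window.
    """
    ids, frames = traj.ca_view(subset if subset is not None else None)
    fit_idx = _core_index(ids, core)
    full = _dccm_matrix(frames, fit_idx)
    pairs: list[tuple[int, int]] = []
    if windows:
        for lo, hi in windows:
            if not (0 <= lo < hi <= traj.n_frames):
                raise ValueError(f"window ({lo}, {hi}) outside trajectory")
        stack = np.stack([_dccm_matrix(frames[lo:hi], fit_idx)
                          for lo, hi in windows])
        with np.errstate(invalid="ignore"):
            consistent = np.all(np.abs(stack) >= consistency_threshold, axis=0)
        iu = np.triu_indices(len(ids), k=1)
        for i, j in zip(*iu):
            if consistent[i, j]:
                pairs.append((int(ids[i]), int(ids[j])))
    return CorrelationMap(residue_ids=ids, matrix=full, consistent_pairs=pairs)


# ---------------------------------------------------------------------------
# Quasi-harmonic configurational entropy
# ---------------------------------------------------------------------------

@dataclass
class EntropyCurve:
    """Entropy (J mol⁻¹ K⁻¹) vs cumulative trajectory length."""

    checkpoints: np.ndarray       # frame counts used
    times: np.ndarray             # ns at each checkpoint
    entropies: np.ndarray         # J/mol/K
    n_modes: np.ndarray           # modes retained at each checkpoint

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frames": self.checkpoints, "time": self.times,
                             "entropy": self.entropies, "modes": self.n_modes})


def entropy_from_eigenvalues(eigenvalues: np.ndarray, temperature: float = 300.0,
                             drop_modes: int = 6,
                             lambda_floor: float = 1e-8) -> tuple[float, int]:
    """Quantum harmonic-oscillator entropy from mass-weighted eigenvalues.

    ``eigenvalues`` are the eigenvalues λ_i of the mass-weighted positional
    covariance in Å²·amu.  Each mode is an oscillator of frequency
    ω_i = sqrt(k_B T / λ_i); its molar entropy contribution is
    R [α/(e^α − 1) − ln(1 − e^{−α})] with α = ħω/(k_B T).  The
    ``drop_modes`` smallest eigenvalues (residual rigid-body freedom after
    superposition) and any λ below ``lambda_floor`` are discarded.  Returns
    (entropy in J mol⁻¹ K⁻¹, number of modes retained).
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if drop_modes > 0:
        lam = lam[:-drop_modes] if drop_modes < len(lam) else lam[:0]
    kept = lam[lam > lambda_floor]
    if len(kept) < len(lam):
        logger.warning("entropy: dropped %d near-singular modes",
                       len(lam) - len(kept))
    if kept.size == 0:
        return 0.0, 0
    lam_si = kept * 1e-20 * constants.atomic_mass          # m² kg
    kT = constants.k * temperature
    omega = np.sqrt(kT / lam_si)
    # very stiff modes contribute nothing; cap alpha to avoid exp overflow
    alpha = np.minimum(constants.hbar * omega / kT, 500.0)
    s_modes = alpha / np.expm1(alpha) - np.log1p(-np.exp(-alpha))
    return float(constants.R * s_modes.sum()), int(kept.size)


def quasiharmonic_entropy(traj: Trajectory, subset: np.ndarray | None = None,
                          temperature: float = 300.0,
                          checkpoints: list[int] | None = None,
                          core: CoreDefinition | None = None,
                          masses: np.ndarray | None = None) -> EntropyCurve:
    """Configurational entropy vs simulation length, Cα quasi-harmonic model.

    At each checkpoint the first n frames are fitted to their running mean on
    the core, the mass-weighted Cα covariance σ = M^½ C M^½ is built and
    diagonalized, and the quantum quasi-harmonic entropy evaluated
    (``entropy_from_eigenvalues``).  Entropy grows with length as slow modes
    keep being discovered — the sensitivity the curve is meant to expose.
    """
    ids, frames_all = traj.ca_view(subset if subset is not None else None)
    if len(ids) == 0:
        raise ValueError("empty residue subset")
    if checkpoints is None:
        checkpoints = [traj.n_frames]
    checkpoints = list(checkpoints)
    if any(c2 <= c1 for c1, c2 in zip(checkpoints, checkpoints[1:])):
        raise ValueError("checkpoints must be strictly increasing")
    if checkpoints[-1] > traj.n_frames:
        raise ValueError("checkpoint beyond trajectory length")
    fit_idx = _core_index(ids, core)
    if masses is None:
        masses = np.full(len(ids), CA_MASS)
    w = np.repeat(np.sqrt(masses), 3)

    ent, nm, times = [], [], []
    for n in checkpoints:
        frames = frames_all[:n]
        fitted = fit_frames(frames, frames.mean(axis=0), fit_idx)
        for _ in range(2):
            fitted = fit_frames(fitted, fitted.mean(axis=0), fit_idx)
        X = fitted.reshape(n, -1)
        dev = (X - X.mean(axis=0)) * w
        cov = dev.T @ dev / n
        lam = np.linalg.eigvalsh(cov)
        s, k = entropy_from_eigenvalues(lam, temperature=temperature)
        ent.append(s)
        nm.append(k)
        times.append(traj.times[n - 1])
    return EntropyCurve(checkpoints=np.array(checkpoints),
                        times=np.array(times),
                        entropies=np.array(ent), n_modes=np.array(nm))


# ---------------------------------------------------------------------------
# Hydrogen-bond occupancy
# ---------------------------------------------------------------------------

@dataclass
class HBondTable:
    """Donor–acceptor occupancy table, sorted by occupancy descending."""

    table: pd.DataFrame   # donor | hydrogen | acceptor | occupancy

    def __len__(self) -> int:
        return len(self.table)


def _attached_hydrogens(top: StructureModel, donor_idx: np.ndarray,
                        coords: np.ndarray, bond_cut: float = 1.3) -> dict[int, list[int]]:
    """Map donor atom index -> indices of covalently attached hydrogens.

    Attachment is inferred geometrically from the supplied coordinates: a
    hydrogen of the same residue within ``bond_cut`` Å of the donor heavy atom.
    """
    h_idx = np.nonzero(top.elements == "H")[0]
    out: dict[int, list[int]] = {}
    for d in donor_idx:
        same_res = h_idx[(top.residue_ids[h_idx] == top.residue_ids[d])
                         & (top.chain_ids[h_idx] == top.chain_ids[d])]
        if len(same_res) == 0:
            continue
        dist = np.linalg.norm(coords[same_res] - coords[d], axis=1)
        near = same_res[dist <= bond_cut]
        if len(near):
            out[int(d)] = [int(i) for i in near]
    return out


def _atom_label(top: StructureModel, i: int) -> str:
    return f"{top.residue_names[i]}{top.residue_ids[i]}:{top.atom_names[i]}"


def hbond_occupancy(traj: Trajectory, donors: np.ndarray,
                    acceptors: np.ndarray, d_cut: float = 3.5,
                    angle_cut: float = 120.0) -> HBondTable:
    """Fraction of frames each donor–acceptor pair satisfies the H-bond rule.

    A frame counts when the donor–acceptor heavy-atom distance is ≤ ``d_cut``
    Å and the donor–H–acceptor angle (at the hydrogen) is ≥ ``angle_cut``
    degrees for some hydrogen attached to the donor.  These geometric cutoffs
    are a package convention (configurable), chosen at the common values for
    protein–nucleotide hydrogen bonding.
    """
    donors = np.asarray(donors, dtype=int)
    acceptors = np.asarray(acceptors, dtype=int)
    if donors.size == 0 or acceptors.size == 0:
        raise ValueError("donor and acceptor selections must be nonempty")
    top = traj.topology
    hmap = _attached_hydrogens(top, donors, traj.frames[0])
    cos_cut = np.cos(np.deg2rad(angle_cut))
    rows = []
    for d in donors:
        hs = hmap.get(int(d), [])
        if not hs:
            continue
        for a in acceptors:
            if a == d:
                continue
            da = np.linalg.norm(traj.frames[:, a] - traj.frames[:, d], axis=1)
            ok = np.zeros(traj.n_frames, dtype=bool)
            for h in hs:
                hd = traj.frames[:, d] - traj.frames[:, h]
                ha = traj.frames[:, a] - traj.frames[:, h]
                cosang = np.sum(hd * ha, axis=1) / (
                    np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1))
                # angle ≥ angle_cut  ⇔  cos(angle) ≤ cos(angle_cut)
                ok |= cosang <= cos_cut
            occ = float(np.mean((da <= d_cut) & ok))
            if occ > 0:
                rows.append({"donor": _atom_label(top, int(d)),
                             "hydrogen": _atom_label(top, hs[0]),
                             "acceptor": _atom_label(top, int(a)),
                             "occupancy": occ})
    df = pd.DataFrame(rows, columns=["donor", "hydrogen", "acceptor", "occupancy"])
    if len(df):
        df = df.sort_values("occupancy", ascending=False,
                            kind="stable").reset_index(drop=True)
    return HBondTable(table=df)
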