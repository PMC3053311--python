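"""Residue–residue contact analysis and difference contact maps (DCMs).

A contact is a residue pair, at least ``min_seq_sep`` apart in sequence,
whose minimal heavy-atom distance falls below a cutoff (default 4 Å).
Contact occupancy over an ensemble of conformers, together with mean minimal
distances, feeds the DCM: pairs in contact (≥ occupancy threshold) in exactly
one of two ensembles, plus pairs in contact in both whose mean distance
shifts by at least ``min_diff`` Å.  Signed Δd = mean_A − mean_B, so negative
values mark pairs closer in (or unique to) ensemble A — by convention the
unliganded ensemble, matching the sign convention of published DCM tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structure_io import StructureModel

logger = logging.getLogger("ensdyn")

__all__ = [
    "DistanceMatrix",
    "DifferentialContact",
    "min_distance_matrix",
    "contact_occupancy",
    "dcm",
    "dcm_to_frame",
    "dcm_xray_panels",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


@dataclass
class DistanceMatrix:
    """Minimal heavy-atom distances between residues, with a sequence mask.

    Entries for pairs closer than ``min_seq_sep`` in sequence are NaN
    (masked); so are rows of residues without heavy atoms.
    """

    residue_ids: np.ndarray
    residue_names: np.ndarray
    distances: np.ndarray        # (R, R), NaN where masked
    min_seq_sep: int

    def __post_init__(self) -> None:
        d = self.distances
        if d.shape[0] != d.shape[1] or d.shape[0] != len(self.residue_ids):
            raise ValueError("distance matrix shape mismatch")


@dataclass
class DifferentialContact:
    """One DCM row: a residue pair with per-ensemble occupancy and Δd."""

    res_i: int
    res_j: int
    name_i: str
    name_j: str
    occ_a: float
    occ_b: float
    mean_d_a: float
    mean_d_b: float
    delta_d: float               # mean_d_a − mean_d_b (Å)
    contact_class: str           # unique-to-A | unique-to-B | closer-in-A | closer-in-B
    consensus: bool = False


def _residue_atoms(structure: StructureModel, sidechain_only: bool
                   ) -> tuple[np.ndarray, np.ndarray, list[np.ndarray]]:
    """(residue_ids, residue_names, per-residue heavy-atom index lists)."""
    heavy = structure.heavy_mask()
    if sidechain_only:
        heavy &= ~np.isin(structure.atom_names, BACKBONE_ATOMS)
    ids = np.unique(structure.residue_ids[~structure.hetero])
    names = []
    groups = []
    for r in ids:
        sel = np.nonzero(heavy & (structure.residue_ids == r))[0]
        groups.append(sel)
        res_sel = np.nonzero((structure.residue_ids == r) & ~structure.hetero)[0]
        names.append(structure.residue_names[res_sel[0]] if len(res_sel) else "UNK")
    return ids, np.array(names), groups


def min_distance_matrix(structure: StructureModel, min_seq_sep: int = 4,
                        sidechain_only: bool = False) -> DistanceMatrix:
    """Minimal heavy-atom distance between every residue pair.

    Pairs with |i − j| < ``min_seq_sep`` (in residue numbering) are masked
    NaN; residues without heavy atoms give NaN rows with a logged warning.
    ``sidechain_only`` drops backbone atoms (N, CA, C, O) from the scan.
    """
    ids, names, groups = _residue_atoms(structure, sidechain_only)
    R = len(ids)
    D = np.full((R, R), np.nan)
    empty = [i for i, g in enumerate(groups) if len(g) == 0]
    if empty:
        logger.warning("min_distance_matrix: %d residues without heavy atoms",
                       len(empty))
    all_idx = np.concatenate([g for g in groups if len(g)]) if R else np.array([], int)
    if len(all_idx):
        # one cdist over all heavy atoms, then a min-reduction per residue pair
        coords = structure.coords[all_idx]
        owner = np.concatenate([[i] * len(g) for i, g in enumerate(groups) if len(g)])
        dist = cdist(coords, coords)
        big = np.inf
        for i in range(R):
            mi = owner == i
            if not mi.any():
                continue
            block = dist[mi]
            for j in range(i + 1, R):
                mj = owner == j
                if not mj.any():
                    continue
                m = block[:, mj].min()
                D[i, j] = D[j, i] = m if m < big else np.nan
    seq = np.abs(ids[:, None] - ids[None, :])
    D[seq < min_seq_sep] = np.nan
    return DistanceMatrix(residue_ids=ids, residue_names=names,
                          distances=D, min_seq_sep=min_seq_sep)


def contact_occupancy(conformers: list[StructureModel], cutoff: float = 4.0,
                      min_seq_sep: int = 4, sidechain_only: bool = False
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-pair contact occupancy and mean minimal distance over conformers.

    Returns (residue_ids, residue_names, occupancy, mean_distance); occupancy
    is the fraction of conformers with minimal distance below ``cutoff``, the
    mean distance is over all conformers regardless of contact state.  All
    conformers must share residue numbering.
    """
    if not conformers:
        raise ValueError("need at least one conformer")
    mats = [min_distance_matrix(s, min_seq_sep, sidechain_only)
            for s in conformers]
    ids = mats[0].residue_ids
    for m in mats[1:]:
        if not np.array_equal(m.residue_ids, ids):
            raise ValueError("conformers do not share residue numbering")
    stack = np.stack([m.distances for m in mats])
    with np.errstate(invalid="ignore"):
        occ = np.mean(stack < cutoff, axis=0)
    mean_d = stack.mean(axis=0)          # NaN-masked entries stay NaN
    occ[np.isnan(mean_d)] = np.nan
    return ids, mats[0].residue_names, occ, mean_d


def dcm(ensemble_a: list[StructureModel], ensemble_b: list[StructureModel],
        cutoff: float = 4.0, min_occupancy: float = 0.5,
        min_diff: float = 0.5, min_seq_sep: int = 4,
        sidechain_only: bool = False) -> list[DifferentialContact]:
    """Difference contact map between two conformer ensembles.

    Emits a pair when it is in contact (occupancy ≥ ``min_occupancy``) in
    exactly one ensemble (unique-to-A / unique-to-B), or in contact in both
    with |Δd| ≥ ``min_diff`` (closer-in-A / closer-in-B).  Δd = mean_A −
    mean_B over all conformers, so a pair that ruptures completely can show
    |Δd| far beyond the contact cutoff.  Output sorted by Δd ascending.
    """
    ids_a, names, occ_a, d_a = contact_occupancy(
        ensemble_a, cutoff, min_seq_sep, sidechain_only)
    ids_b, _, occ_b, d_b = contact_occupancy(
        ensemble_b, cutoff, min_seq_sep, sidechain_only)
    if not np.array_equal(ids_a, ids_b):
        raise ValueError("ensembles do not share residue numbering")
    out: list[DifferentialContact] = []
    R = len(ids_a)
    for i in range(R):
        for j in range(i + 1, R):
            oa, ob = occ_a[i, j], occ_b[i, j]
            if np.isnan(oa) or np.isnan(ob):
                continue
            in_a = oa >= min_occupancy
            in_b = ob >= min_occupancy
            dd = d_a[i, j] - d_b[i, j]
            if in_a and not in_b:
                cls = "unique-to-A"
            elif in_b and not in_a:
                cls = "unique-to-B"
            elif in_a and in_b and abs(dd) >= min_diff:
                cls = "closer-in-A" if dd < 0 else "closer-in-B"
            else:
                continue
            out.append(DifferentialContact(
                res_i=int(ids_a[i]), res_j=int(ids_a[j]),
                name_i=str(names[i]), name_j=str(names[j]),
                occ_a=float(oa), occ_b=float(ob),
                mean_d_a=float(d_a[i, j]), mean_d_b=float(d_b[i, j]),
                delta_d=float(dd), contact_class=cls))
    out.sort(key=lambda c: (c.delta_d, c.res_i, c.res_j))
    return out


def dcm_to_frame(contacts: list[DifferentialContact]) -> pd.DataFrame:
    """DCM rows as a table in the published layout (signed Δd, classes)."""
    return pd.DataFrame([{
        "res_i": c.res_i, "res_j": c.res_j,
        "name_i": c.name_i, "name_j": c.name_j,
        "occ_A": c.occ_a, "occ_B": c.occ_b,
        "mean_dA": c.mean_d_a, "mean_dB": c.mean_d_b,
        "delta_d": c.delta_d, "class": c.contact_class,
        "consensus_flag": c.consensus,
    } for c in contacts], columns=["res_i", "res_j", "name_i", "name_j",
                                   "occ_A", "occ_B", "mean_dA", "mean_dB",
                                   "delta_d", "class", "consensus_flag"])


def dcm_xray_panels(groups: dict[str, list[StructureModel]],
                    md_reference: list[DifferentialContact] | None = None,
                    **kwargs) -> dict[tuple[str, str], list[DifferentialContact]]:
    """All pairwise DCM panels between named conformer groups.

    ``groups`` maps a state label (e.g. 't-apo', 't-ATP', "r''-ADP") to its
    subunit conformers; one DCM is computed per ordered pair of distinct
    groups.  If ``md_reference`` is given (a DCM from simulation ensembles),
    pairs appearing in both an X-ray panel and the MD DCM get their
    ``consensus`` flag set — the cross-validation between crystallographic
    and simulated contact changes.
    """
    for name, members in groups.items():
        if not members:
            raise ValueError(f"group {name!r} is empty")
    md_pairs = ({frozenset((c.res_i, c.res_j)) for c in md_reference}
                if md_reference else set())
    panels: dict[tuple[str, str], list[DifferentialContact]] = {}
    for a, b in permutations(groups, 2):
        panel = dcm(groups[a], groups[b], **kwargs)
        for c in panel:
            if frozenset((c.res_i, c.res_j)) in md_pairs:
                c.consensus = True
        panels[(a, b)] = panel
    return panels
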