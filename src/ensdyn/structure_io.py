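"""Structure and trajectory I/O for chaperonin ensemble analysis.

Reads multi-model PDB files, extracts chaperonin-sized subunit chains, and
assembles common-atom coordinate ensembles over many conformers.  Parsing and
writing of ATOM records is delegated to biotite; this module adds the domain
containers (:class:`StructureModel`, :class:`SubunitEnsemble`,
:class:`Trajectory`), subunit extraction with a missing-coordinate filter, and
the residue-intersection logic used to align conformers with slightly
different coverage.

Residue numbering is author (PDB) numbering, 1-based, throughout; all domain
and helix ranges are interpreted in that numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger("ensdyn")

__all__ = [
    "StructureModel",
    "SubunitEnsemble",
    "Trajectory",
    "DomainMap",
    "GROEL_DOMAINS",
    "PDBParseError",
    "read_pdb",
    "write_pdb",
    "extract_subunits",
    "build_ensemble",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass
class StructureModel:
    """One conformation: per-atom identity arrays plus coordinates in Å.

    All arrays share length N (number of atoms).  ``hetero`` marks non-polymer
    atoms (nucleotide, ions, solvent); they are excluded from ensembles but
    retained for hydrogen-bond analysis.
    """

    atom_names: np.ndarray          # str, shape (N,)
    residue_ids: np.ndarray         # int, shape (N,)
    residue_names: np.ndarray       # str, shape (N,)
    chain_ids: np.ndarray           # str, shape (N,)
    elements: np.ndarray            # str, shape (N,)
    coords: np.ndarray              # float, shape (N, 3)
    hetero: np.ndarray              # bool, shape (N,)
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        n = len(self.coords)
        for name in ("atom_names", "residue_ids", "residue_names",
                     "chain_ids", "elements", "hetero"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != atom count {n}")
            setattr(self, name, arr)
        self.residue_ids = self.residue_ids.astype(int)
        self.hetero = self.hetero.astype(bool)

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    def chains(self) -> list[str]:
        """Chain ids in order of first appearance."""
        _, idx = np.unique(self.chain_ids, return_index=True)
        return [self.chain_ids[i] for i in np.sort(idx)]

    def select(self, mask: np.ndarray, label: str | None = None) -> "StructureModel":
        return StructureModel(
            atom_names=self.atom_names[mask],
            residue_ids=self.residue_ids[mask],
            residue_names=self.residue_names[mask],
            chain_ids=self.chain_ids[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
            hetero=self.hetero[mask],
            label=self.label if label is None else label,
        )

    def chain(self, chain_id: str) -> "StructureModel":
        mask = self.chain_ids == chain_id
        if not mask.any():
            raise KeyError(f"no chain {chain_id!r}")
        return self.select(mask, label=f"{self.label}:{chain_id}")

    def ca_mask(self) -> np.ndarray:
        return (self.atom_names == "CA") & ~self.hetero

    def ca_coords(self, residue_ids: Sequence[int] | None = None) -> np.ndarray:
        """Cα coordinates, optionally restricted/ordered by ``residue_ids``."""
        mask = self.ca_mask()
        if residue_ids is None:
            return self.coords[mask]
        ids = self.residue_ids[mask]
        xyz = self.coords[mask]
        lookup = {r: i for i, r in enumerate(ids)}
        try:
            order = [lookup[r] for r in residue_ids]
        except KeyError as e:
            raise KeyError(f"residue {e.args[0]} has no Cα in {self.label or 'structure'}")
        return xyz[order]

    def heavy_mask(self) -> np.ndarray:
        return (self.elements != "H") & (self.elements != "D") & ~self.hetero


@dataclass
class SubunitEnsemble:
    """Aligned per-residue Cα coordinates over many conformers.

    ``coords`` has shape (n_conformers, n_residues, 3); every conformer shares
    the identical, ascending residue set ``residue_ids``.  ``states`` /
    ``ligand_states`` carry the conformational ({t, r, r'', unknown}) and
    nucleotide ({apo, holo, unknown}) labels through the analysis.
    """

    conformer_ids: list[str]
    residue_ids: np.ndarray
    coords: np.ndarray
    states: list[str] = field(default_factory=list)
    ligand_states: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (conformers, residues, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 conformers")
        if self.coords.shape[1] != len(self.residue_ids):
            raise ValueError("coords/residue_ids mismatch")
        if not self.states:
            self.states = ["unknown"] * self.n_conformers
        if not self.ligand_states:
            self.ligand_states = ["unknown"] * self.n_conformers

    @property
    def n_conformers(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def residue_index(self, residue_ids: Sequence[int]) -> np.ndarray:
        """Positions of the given residue ids within this ensemble's ordering."""
        lookup = {r: i for i, r in enumerate(self.residue_ids)}
        missing = [r for r in residue_ids if r not in lookup]
        if missing:
            raise KeyError(f"residues not in ensemble: {missing[:5]}")
        return np.array([lookup[r] for r in residue_ids], dtype=int)


@dataclass
class Trajectory:
    """Coordinate trajectory: fixed topology plus F × N × 3 frames in Å."""

    topology: StructureModel
    frames: np.ndarray              # (F, N, 3)
    times: np.ndarray | None = None   # ns
    replicate: str = ""
    condition: str = ""             # e.g. "t-apo", "r''-holo"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (F, N, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}")
        if self.times is None:
            self.times = np.arange(self.n_frames, dtype=float)
        else:
            self.times = np.asarray(self.times, dtype=float)
            if len(self.times) != self.n_frames:
                raise ValueError("times length != frame count")
            if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def ca_view(self, residue_ids: Sequence[int] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """(residue_ids, frames_ca) restricted to Cα atoms.

        frames_ca has shape (F, n_res, 3) in the order of the returned ids.
        """
        mask = self.topology.ca_mask()
        ids = self.topology.residue_ids[mask]
        xyz = self.frames[:, mask, :]
        if residue_ids is not None:
            lookup = {r: i for i, r in enumerate(ids)}
            missing = [r for r in residue_ids if r not in lookup]
            if missing:
                raise KeyError(f"residues without Cα in trajectory: {missing[:5]}")
            order = np.array([lookup[r] for r in residue_ids], dtype=int)
            ids = ids[order]
            xyz = xyz[:, order, :]
        return np.asarray(ids), xyz

    def models(self) -> list[StructureModel]:
        top = self.topology
        return [
            StructureModel(
                atom_names=top.atom_names, residue_ids=top.residue_ids,
                residue_names=top.residue_names, chain_ids=top.chain_ids,
                elements=top.elements, coords=self.frames[i],
                hetero=top.hetero, label=f"{self.replicate}:frame{i}")
            for i in range(self.n_frames)
        ]


# ---------------------------------------------------------------------------
# GroEL domain architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainMap:
    """Named residue ranges of the GroEL subunit (author numbering).

    The three domains partition residues 1-548; helix and stem-loop ranges are
    secondary-structure landmarks used when reading core/PC locations.
    """

    domains: dict[str, tuple[tuple[int, int], ...]]
    helices: dict[str, tuple[int, int]]
    stem_loop: tuple[int, int]

    def __post_init__(self) -> None:
        spans = [s for ranges in self.domains.values() for s in ranges]
        covered: set[int] = set()
        for lo, hi in spans:
            if not (1 <= lo <= hi <= 548):
                raise ValueError(f"range {lo}-{hi} outside 1-548")
            block = set(range(lo, hi + 1))
            if block & covered:
                raise ValueError("domain ranges overlap")
            covered |= block
        if covered != set(range(min(covered), max(covered) + 1)):
            raise ValueError("domains must jointly cover a contiguous span")

    def residues(self, name: str) -> np.ndarray:
        """All residue ids of a named domain."""
        ranges = self.domains[name]
        return np.concatenate([np.arange(lo, hi + 1) for lo, hi in ranges])

    def helix(self, name: str) -> np.ndarray:
        lo, hi = self.helices[name]
        return np.arange(lo, hi + 1)


GROEL_DOMAINS = DomainMap(
    domains={
        "equatorial": ((1, 133), (409, 548)),
        "intermediate": ((134, 190), (377, 408)),
        "apical": ((191, 376),),
    },
    helices={
        "A": (8, 27), "C": (65, 85), "D": (88, 107), "E": (113, 134),
        "F": (141, 152), "G": (155, 169), "M": (386, 409), "R": (496, 514),
    },
    stem_loop=(36, 51),
)


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _locate_bad_atom_line(path: Path) -> int | None:
    """Line number (1-based) of the first unparsable ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    return lineno
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    return lineno
    return None


def read_pdb(path: str | Path, model: int | None = None) -> list[StructureModel]:
    """Read a (multi-model) PDB file into one StructureModel per MODEL record.

    Altloc conflicts keep the highest-occupancy location (biotite's
    occupancy rule; ties resolve to the first-listed, i.e. alphabetically
    lowest, altloc id).  ``model`` selects a single 1-based model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    bad = _locate_bad_atom_line(path)
    if bad is not None:
        raise PDBParseError(f"{path}: malformed ATOM/HETATM record at line {bad}")
    try:
        pdb = PDBFile.read(str(path))
        n_models = pdb.get_model_count()
    except Exception as e:  # pragma: no cover - biotite internal failures
        raise PDBParseError(f"{path}: {e}") from e
    if n_models == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    which = range(1, n_models + 1) if model is None else [model]
    out = []
    for m in which:
        atoms = pdb.get_structure(model=m, altloc="occupancy")
        out.append(_from_atom_array(atoms, label=f"{path.stem}#{m}" if n_models > 1 else path.stem))
    return out


def _from_atom_array(atoms: struc.AtomArray, label: str = "") -> StructureModel:
    return StructureModel(
        atom_names=atoms.atom_name.astype(str),
        residue_ids=atoms.res_id.astype(int),
        residue_names=atoms.res_name.astype(str),
        chain_ids=atoms.chain_id.astype(str),
        elements=atoms.element.astype(str),
        coords=np.array(atoms.coord, dtype=float),
        hetero=atoms.hetero.astype(bool),
        label=label,
    )


def _to_atom_array(model: StructureModel) -> struc.AtomArray:
    n = model.n_atoms
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(model.coords, dtype=np.float32)
    arr.chain_id = model.chain_ids.astype("U4")
    arr.res_id = model.residue_ids
    arr.res_name = model.residue_names.astype("U5")
    arr.atom_name = model.atom_names.astype("U6")
    arr.element = model.elements.astype("U2")
    arr.hetero = model.hetero
    return arr


def write_pdb(path: str | Path, models: Iterable[StructureModel]) -> None:
    """Write models as a multi-model PDB (MODEL/ENDMDL per conformer).

    Models need not share a topology; each is emitted with its own atoms.
    """
    models = list(models)
    if not models:
        raise ValueError("nothing to write")
    path = Path(path)
    blocks = []
    for m in models:
        f = PDBFile()
        f.set_structure(_to_atom_array(m))
        blocks.append([ln for ln in f.lines if ln.startswith(("ATOM", "HETATM", "TER"))])
    with open(path, "w") as fh:
        if len(blocks) == 1:
            fh.write("\n".join(blocks[0]) + "\nEND\n")
        else:
            for i, block in enumerate(blocks, start=1):
                fh.write(f"MODEL     {i:>4}\n")
                fh.write("\n".join(block) + "\n")
                fh.write("ENDMDL\n")
            fh.write("END\n")


def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Serialize a trajectory as a multi-model PDB."""
    write_pdb(path, traj.models())


def read_trajectory(path: str | Path, replicate: str = "", condition: str = "",
                    dt: float = 1.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory (frames share model-1 topology)."""
    models = read_pdb(path)
    top = models[0]
    frames = np.stack([m.coords for m in models])
    times = np.arange(len(models), dtype=float) * dt
    return Trajectory(topology=top, frames=frames, times=times,
                      replicate=replicate or Path(path).stem, condition=condition)


# ---------------------------------------------------------------------------
# Subunit extraction and ensemble assembly
# ---------------------------------------------------------------------------

def extract_subunits(models: list[StructureModel], min_length: int = 500,
                     max_missing_fraction: float = 0.1) -> list[StructureModel]:
    """Pull every qualifying protein chain out of a list of models.

    A chain qualifies when it has at least ``min_length`` residues with a Cα
    and at most ``max_missing_fraction`` of Cα positions absent relative to
    the chain's own residue-number span.  With GroEL defaults (500 / 0.1) the
    97-residue co-chaperonin chains fall below ``min_length`` and chains with
    heavy disorder are dropped — the filter behind keeping 287 of 364
    crystallographic subunits.
    """
    if min_length <= 0:
        raise ValueError("min_length must be positive")
    subunits = []
    for model in models:
        for cid in model.chains():
            chain = model.chain(cid)
            ca = chain.ca_mask()
            res_with_ca = np.unique(chain.residue_ids[ca])
            if len(res_with_ca) == 0:
                continue
            span = res_with_ca.max() - res_with_ca.min() + 1
            missing = 1.0 - len(res_with_ca) / span
            if len(res_with_ca) >= min_length and missing <= max_missing_fraction:
                subunits.append(chain)
    if not subunits:
        logger.warning("extract_subunits: no qualifying chain "
                       "(min_length=%d, max_missing_fraction=%.2f)",
                       min_length, max_missing_fraction)
    return subunits


def build_ensemble(subunits: list[StructureModel],
                   atom_mode: str = "calpha") -> SubunitEnsemble:
    """Assemble a common-atom ensemble from subunit structures.

    The residue set is the intersection of residue ids carrying a Cα in every
    subunit, in ascending order; terminal or disordered residues absent from
    any one conformer are dropped for all.  ``atom_mode='calpha'`` keeps one
    Cα per residue; ``'heavy'`` keeps the common (residue, atom-name) heavy
    atoms instead — one coordinate row per shared heavy atom.
    """
    if len(subunits) < 2:
        raise ValueError("need at least 2 subunits")
    if atom_mode not in ("calpha", "heavy"):
        raise ValueError(f"unknown atom_mode {atom_mode!r}")

    common: set[int] | None = None
    for s in subunits:
        ids = set(np.unique(s.residue_ids[s.ca_mask()]).tolist())
        common = ids if common is None else (common & ids)
    if not common:
        raise ValueError("no residue is present (with Cα) in every subunit")
    residue_ids = np.array(sorted(common), dtype=int)

    if atom_mode == "calpha":
        coords = np.stack([s.ca_coords(residue_ids) for s in subunits])
    else:
        keys: set[tuple[int, str]] | None = None
        for s in subunits:
            mask = s.heavy_mask() & np.isin(s.residue_ids, residue_ids)
            k = set(zip(s.residue_ids[mask].tolist(), s.atom_names[mask].tolist()))
            keys = k if keys is None else (keys & k)
        ordered = sorted(keys)  # (res_id, atom_name) ascending
        rows = []
        for s in subunits:
            lookup = {}
            for i, (r, a, het) in enumerate(zip(s.residue_ids.tolist(),
                                                s.atom_names.tolist(), s.hetero)):
                if not het:
                    lookup[(r, a)] = i
            rows.append(s.coords[[lookup[k] for k in ordered]])
        coords = np.stack(rows)
        residue_ids = np.array([r for r, _ in ordered], dtype=int)

    return SubunitEnsemble(
        conformer_ids=[s.label or f"conf{i}" for i, s in enumerate(subunits)],
        residue_ids=residue_ids,
        coords=coords,
    )
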