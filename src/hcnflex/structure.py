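"""Structure snapshots, ensembles, domain annotation and superposition.

Coordinates are stored as plain numpy arrays on :class:`StructureSnapshot`;
:class:`Atom` objects are lightweight views used at API boundaries.  PDB
reading and writing is delegated to biotite; only single- and multi-model
PDB files are part of the exchange contract (binary trajectory formats are
deliberately out of scope so that fixtures stay text-based).

Residue indexing is 0-based and sequential over the whole snapshot
(``residue_index``); the author-facing numbering of a construct is mapped
through :attr:`DomainAnnotation.numbering_offset`.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

import biotite.structure as struc
import biotite.structure.io.pdb as _pdb

__all__ = [
    "Atom",
    "StructureSnapshot",
    "Ensemble",
    "DomainAnnotation",
    "PDBParseError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "read_ensemble",
    "write_ensemble",
    "superpose",
    "backbone_mask",
]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class PDBParseError(ValueError):
    """Raised for malformed PDB input, carrying the offending line number."""


class TopologyError(ValueError):
    """Raised when snapshots of an ensemble disagree in topology."""


@dataclass(frozen=True)
class Atom:
    """One atom of a snapshot.

    ``residue_index`` is the internal 0-based sequential residue number;
    ``coords`` is a length-3 array in Å.
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


class StructureSnapshot:
    """Atom coordinates plus chain/residue topology for one frame.

    Parameters
    ----------
    serial, name, element, residue_index, residue_name, chain_id, res_seq :
        Per-atom annotation arrays of equal length.  ``res_seq`` is the
        per-chain residue number as written in the PDB file; it is kept so
        that domain annotations expressed in author numbering can be
        resolved.
    coords :
        (n_atoms, 3) float array, Å.
    """

    def __init__(
        self,
        serial: np.ndarray,
        name: np.ndarray,
        element: np.ndarray,
        residue_index: np.ndarray,
        residue_name: np.ndarray,
        chain_id: np.ndarray,
        res_seq: np.ndarray,
        coords: np.ndarray,
        frame_time: float | None = None,
        box: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_atoms, 3)")
        n = coords.shape[0]
        if n == 0:
            raise ValueError("snapshot must contain at least one atom")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.serial = np.asarray(serial, dtype=int)
        self.name = np.asarray(name, dtype=object)
        self.element = np.asarray([str(e).upper() for e in element], dtype=object)
        if any(e == "" for e in self.element):
            raise ValueError("every atom needs a non-empty element symbol")
        self.residue_index = np.asarray(residue_index, dtype=int)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.res_seq = np.asarray(res_seq, dtype=int)
        self.coords = coords
        self.frame_time = frame_time
        self.box = None if box is None else np.asarray(box, dtype=float)
        for arr in (self.serial, self.name, self.element, self.residue_index,
                    self.residue_name, self.chain_id, self.res_seq):
            if len(arr) != n:
                raise ValueError("annotation arrays must match coords length")
        if len(np.unique(self.serial)) != n:
            raise ValueError("atom serials must be unique within a snapshot")

    # -- basic queries -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return int(self.residue_index.max()) + 1

    @property
    def is_heavy(self) -> np.ndarray:
        return self.element != "H"

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(int(self.serial[i]), str(self.name[i]), str(self.element[i]),
                 int(self.residue_index[i]), str(self.residue_name[i]),
                 str(self.chain_id[i]), self.coords[i])
            for i in range(self.n_atoms)
        ]

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        """Atom indices of one internal residue index."""
        return np.nonzero(self.residue_index == residue_index)[0]

    def chain_of_residue(self, residue_index: int) -> str:
        return str(self.chain_id[self.residue_atoms(residue_index)[0]])

    def ca_indices(self, residues: Iterable[int] | None = None) -> np.ndarray:
        mask = self.name == "CA"
        if residues is not None:
            mask &= np.isin(self.residue_index, np.asarray(list(residues)))
        return np.nonzero(mask)[0]

    def same_topology(self, other: "StructureSnapshot") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and bool(np.all(self.name == other.name))
            and bool(np.all(self.residue_index == other.residue_index))
            and bool(np.all(self.chain_id == other.chain_id))
        )

    def copy(self) -> "StructureSnapshot":
        return copy.deepcopy(self)


@dataclass
class Ensemble:
    """A list of topology-identical snapshots plus run metadata."""

    snapshots: list[StructureSnapshot]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.snapshots:
            raise ValueError("ensemble must contain at least one snapshot")
        first = self.snapshots[0]
        for k, s in enumerate(self.snapshots[1:], start=2):
            if not first.same_topology(s):
                raise TopologyError(f"snapshot {k} does not match the topology "
                                    f"of snapshot 1")

    def __len__(self) -> int:
        return len(self.snapshots)

    def __iter__(self):
        return iter(self.snapshots)

    def __getitem__(self, i):
        return self.snapshots[i]

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([s.coords for s in self.snapshots])

    def copy(self) -> "Ensemble":
        return Ensemble([s.copy() for s in self.snapshots], dict(self.metadata))


@dataclass
class DomainAnnotation:
    """Named residue ranges of the channel plus subunit ordering.

    ``ranges`` maps a domain name (e.g. ``"S6"``, ``"CL"``, ``"S4"``,
    ``"selectivity_filter"``, ``"upper_pore"``) to a list of
    ``(chain_id, first, last)`` tuples in author numbering (inclusive).
    ``gate_residues`` and ``insertion_site`` are lists of author residue
    numbers.  ``subunit_order`` lists chain ids in counter-clockwise order
    as viewed from the extracellular side, so that "the preceding subunit"
    is a declared fact rather than a geometric inference.
    ``numbering_offset`` is subtracted from author numbers to obtain the
    per-chain ``res_seq`` stored in snapshots.
    """

    ranges: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)
    gate_residues: list[int] = field(default_factory=list)
    insertion_site: tuple[int, int] | None = None
    subunit_order: list[str] = field(default_factory=list)
    numbering_offset: int = 0

    # -- resolution against a snapshot ---------------------------------
    def residues(self, snapshot: StructureSnapshot, name: str,
                 chain: str | None = None) -> np.ndarray:
        """Internal residue indices of a named range (optionally one chain)."""
        if name not in self.ranges:
            raise KeyError(f"annotation has no range named {name!r}")
        hits: list[int] = []
        for cid, lo, hi in self.ranges[name]:
            if chain is not None and cid != chain:
                continue
            lo_i = lo - self.numbering_offset
            hi_i = hi - self.numbering_offset
            mask = ((snapshot.chain_id == cid)
                    & (snapshot.res_seq >= lo_i)
                    & (snapshot.res_seq <= hi_i))
            hits.extend(np.unique(snapshot.residue_index[mask]).tolist())
        return np.asarray(sorted(set(hits)), dtype=int)

    def atom_mask(self, snapshot: StructureSnapshot, name: str,
                  chain: str | None = None) -> np.ndarray:
        res = self.residues(snapshot, name, chain)
        return np.isin(snapshot.residue_index, res)

    def preceding_subunit(self, chain: str) -> str:
        """Counter-clockwise preceding chain in the declared subunit cycle."""
        if chain not in self.subunit_order:
            raise KeyError(f"chain {chain!r} not in subunit_order")
        i = self.subunit_order.index(chain)
        return self.subunit_order[i - 1]

    # -- config file I/O ----------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "DomainAnnotation":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ranges = {
            name: [(str(c), int(lo), int(hi)) for c, lo, hi in entries]
            for name, entries in raw.get("ranges", {}).items()
        }
        ins = raw.get("insertion_site")
        return cls(
            ranges=ranges,
            gate_residues=[int(r) for r in raw.get("gate_residues", [])],
            insertion_site=None if ins is None else (int(ins[0]), int(ins[1])),
            subunit_order=[str(c) for c in raw.get("subunit_order", [])],
            numbering_offset=int(raw.get("numbering_offset", 0)),
        )

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "ranges": {k: [list(t) for t in v] for k, v in self.ranges.items()},
            "gate_residues": list(self.gate_residues),
            "insertion_site": None if self.insertion_site is None
            else list(self.insertion_site),
            "subunit_order": list(self.subunit_order),
            "numbering_offset": self.numbering_offset,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh)


# ---------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------

def _validate_atom_lines(path: str | Path) -> tuple[int, list[str]]:
    """Pre-scan ATOM/HETATM records; return their count plus normalized
    lines (short records padded with default occupancy/B-factor).

    Raises :class:`PDBParseError` naming the first malformed line.
    """
    n = 0
    out: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith(("ATOM", "HETATM")):
                n += 1
                if len(line) < 54:
                    raise PDBParseError(f"line {lineno}: ATOM record too short")
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                except ValueError as exc:
                    raise PDBParseError(
                        f"line {lineno}: unparsable coordinates") from exc
                if len(line) < 60:  # occupancy/B-factor columns absent
                    line = line[:54] + "  1.00  0.00"
            out.append(line)
    return n, out


def _atom_array_to_snapshot(arr: struc.AtomArray,
                            serial: np.ndarray | None = None) -> StructureSnapshot:
    element = np.array([e if e else "" for e in arr.element], dtype=object)
    missing = np.array([e == "" for e in element])
    if missing.any():
        inferred = struc.infer_elements(arr.atom_name[missing])
        element[missing] = inferred
    starts = struc.get_residue_starts(arr)
    residue_index = np.searchsorted(starts, np.arange(arr.array_length()),
                                    side="right") - 1
    if serial is None:
        serial = np.arange(1, arr.array_length() + 1)
    return StructureSnapshot(
        serial=serial,
        name=arr.atom_name.astype(object),
        element=element,
        residue_index=residue_index,
        residue_name=arr.res_name.astype(object),
        chain_id=arr.chain_id.astype(object),
        res_seq=arr.res_id,
        coords=arr.coord,
    )


def read_pdb(path: str | Path) -> StructureSnapshot:
    """Read a single-model PDB file.

    Elements are taken from the element column when present and inferred
    from the atom name otherwise.  Malformed ATOM records raise
    :class:`PDBParseError` naming the line; a file without ATOM records
    is rejected.
    """
    n, lines = _validate_atom_lines(path)
    if n == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    pdbfile = _pdb.PDBFile.read(io.StringIO("\n".join(lines) + "\n"))
    arr = pdbfile.get_structure(model=1, extra_fields=["atom_id"])
    return _atom_array_to_snapshot(arr, serial=arr.atom_id)


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a (possibly multi-model) PDB file as an ensemble.

    One snapshot per MODEL, order preserved; models with differing
    topology raise :class:`TopologyError`.
    """
    n, lines = _validate_atom_lines(path)
    if n == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    pdbfile = _pdb.PDBFile.read(io.StringIO("\n".join(lines) + "\n"))
    try:
        stack = pdbfile.get_structure(extra_fields=["atom_id"])
    except Exception as exc:  # biotite raises on inconsistent models
        raise TopologyError(f"{path}: models disagree in topology: {exc}") from exc
    snapshots = []
    for k in range(stack.stack_depth()):
        arr = stack[k]
        snapshots.append(_atom_array_to_snapshot(arr, serial=arr.atom_id))
    return Ensemble(snapshots, metadata={"source": str(path)})


def _snapshot_to_atom_array(s: StructureSnapshot) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = s.coords.astype(np.float32)
    arr.chain_id = s.chain_id.astype("U4")
    arr.res_id = s.res_seq
    arr.res_name = s.residue_name.astype("U5")
    arr.atom_name = s.name.astype("U6")
    arr.element = s.element.astype("U2")
    arr.set_annotation("atom_id", s.serial)
    arr.hetero = np.zeros(s.n_atoms, dtype=bool)
    return arr


def write_pdb(snapshot: StructureSnapshot, path: str | Path) -> None:
    pdbfile = _pdb.PDBFile()
    pdbfile.set_structure(_snapshot_to_atom_array(snapshot))
    pdbfile.write(str(path))


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model PDB file."""
    arrays = [_snapshot_to_atom_array(s) for s in ensemble]
    stack = struc.stack(arrays)
    pdbfile = _pdb.PDBFile()
    pdbfile.set_structure(stack)
    pdbfile.write(str(path))


# ---------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------

def backbone_mask(snapshot: StructureSnapshot,
                  residues: Sequence[int] | None = None) -> np.ndarray:
    """Boolean atom mask of backbone heavy atoms (N, CA, C, O)."""
    mask = np.isin(snapshot.name, BACKBONE_NAMES)
    if residues is not None:
        mask &= np.isin(snapshot.residue_index, np.asarray(list(residues)))
    return mask


def _as_index_array(selection, n_atoms: int) -> np.ndarray:
    sel = np.asarray(selection)
    if sel.dtype == bool:
        if sel.shape != (n_atoms,):
            raise ValueError("boolean selection must have one entry per atom")
        return np.nonzero(sel)[0]
    return sel.astype(int)


def superpose(ensemble: Ensemble, selection,
              reference: StructureSnapshot | None = None) -> Ensemble:
    """Least-squares rigid-body superposition of every snapshot.

    Each snapshot is rotated/translated so that the RMSD of the selected
    atoms to the reference (default: the first snapshot) is minimal; the
    transformation is applied to *all* atoms, so internal geometry is
    untouched.  ``selection`` is a boolean atom mask or an array of atom
    indices — typically the backbone of the pore domain, the most
    invariant region of the channel.
    """
    if reference is None:
        reference = ensemble[0]
    if not reference.same_topology(ensemble[0]):
        raise TopologyError("reference does not share the ensemble topology")
    idx = _as_index_array(selection, reference.n_atoms)
    if len(idx) < 3:
        raise ValueError("superposition needs at least 3 selection atoms")
    ref_sel = reference.coords[idx]
    ref_centroid = ref_sel.mean(axis=0)
    ref_centered = ref_sel - ref_centroid
    # collinearity check: centered selection must span a plane
    if np.linalg.matrix_rank(ref_centered, tol=1e-8) < 2:
        raise ValueError("selection atoms are collinear; superposition is "
                         "underdetermined")
    out = []
    for s in ensemble:
        mob_sel = s.coords[idx]
        mob_centroid = mob_sel.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, mob_sel - mob_centroid)
        new = s.copy()
        new.coords = rot.apply(s.coords - mob_centroid) + ref_centroid
        out.append(new)
    return Ensemble(out, dict(ensemble.metadata))
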