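"""Constraint-network construction for rigidity analysis.

A snapshot is turned into a body-bar network: every atom is a rigid body
and interactions become bars of fixed multiplicity,

* covalent bonds — 5 bars (dihedral rotation left free) or 6 bars when
  the bond is non-rotatable (peptide bonds, double/aromatic bonds, ring
  bonds),
* hydrogen bonds and salt bridges — 5 bars, carrying a Mayo-type energy
  ``E_HB`` so that the network can be diluted by bond strength,
* hydrophobic tethers between apolar C/S atoms — 2 bars.

Covalent topology comes from the Chemical Component Dictionary residue
templates shipped with biotite plus peptide links between consecutive
residues and distance-detected disulfides; no bond-order perception from
chemistry toolkits is attempted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

import biotite.structure.info as _info
from biotite.structure import BondType

from hcnflex.constants import HYDROPHOBIC_DCUT, VDW_RADII
from hcnflex.structure import StructureSnapshot

logger = logging.getLogger(__name__)

__all__ = [
    "HydrogenBond",
    "HydrophobicTether",
    "Bar",
    "ConstraintNetwork",
    "HBondParams",
    "covalent_bonds",
    "detect_hydrogen_bonds",
    "detect_hydrophobic_tethers",
    "build_network",
    "hbond_energy",
]

_LOCKED_TYPES = {
    BondType.DOUBLE,
    BondType.TRIPLE,
    BondType.AROMATIC_SINGLE,
    BondType.AROMATIC_DOUBLE,
    BondType.AROMATIC_TRIPLE,
    BondType.AROMATIC,
}

#: atoms of negatively charged carboxylate groups (salt-bridge acceptors)
_ANION_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
#: donor heavy atoms of positively charged groups (salt-bridge donors)
_CATION_ATOMS = {("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
                 ("LYS", "NZ"), ("HIS", "ND1"), ("HIS", "NE2")}


@dataclass(frozen=True)
class HydrogenBond:
    """A scored donor–hydrogen···acceptor interaction (atom indices)."""

    donor: int
    hydrogen: int
    acceptor: int
    E_HB: float
    is_salt_bridge: bool = False


@dataclass(frozen=True)
class HydrophobicTether:
    """A C/S–C/S apolar contact within the vdW + offset cutoff."""

    atom_a: int
    atom_b: int
    distance: float


@dataclass(frozen=True)
class Bar:
    atom_a: int
    atom_b: int
    multiplicity: int
    kind: str  # covalent-locked | covalent-rotatable | hbond | hydrophobic
    energy: float | None = None


@dataclass
class ConstraintNetwork:
    """Bodies (atom indices) and bars of one snapshot at one ``E_cut``."""

    n_bodies: int
    bars: list[Bar] = field(default_factory=list)
    E_cut: float | None = None

    def __post_init__(self):
        for bar in self.bars:
            if bar.multiplicity not in (2, 5, 6):
                raise ValueError(f"bar multiplicity must be 2, 5 or 6, "
                                 f"got {bar.multiplicity}")
            if not (0 <= bar.atom_a < self.n_bodies
                    and 0 <= bar.atom_b < self.n_bodies):
                raise ValueError("bar endpoint outside the body set")
            if bar.kind == "hbond" and bar.energy is None:
                raise ValueError("hydrogen-bond bars must carry an energy")

    # -- edge-list exchange format (debugging / oracle testing) --------
    def to_edgelist(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("atom_a\tatom_b\tmultiplicity\tkind\tenergy\n")
            for b in self.bars:
                e = "" if b.energy is None else f"{b.energy:.9g}"
                fh.write(f"{b.atom_a}\t{b.atom_b}\t{b.multiplicity}\t"
                         f"{b.kind}\t{e}\n")

    @classmethod
    def from_edgelist(cls, path: str | Path, n_bodies: int,
                      E_cut: float | None = None) -> "ConstraintNetwork":
        bars = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("atom_a"):
                raise ValueError("edge list must start with a header line")
            for line in fh:
                a, b, m, kind, e = line.rstrip("\n").split("\t")
                bars.append(Bar(int(a), int(b), int(m), kind,
                                None if e == "" else float(e)))
        return cls(n_bodies=n_bodies, bars=bars, E_cut=E_cut)


# ---------------------------------------------------------------------
# Covalent topology
# ---------------------------------------------------------------------

def covalent_bonds(snapshot: StructureSnapshot) -> list[tuple[int, int, bool]]:
    """Covalent bonds as ``(i, j, locked)`` atom-index triples.

    Intra-residue bonds come from CCD residue templates; consecutive
    residues of a chain are joined by the peptide C–N bond (locked);
    disulfides are detected as SG–SG pairs within 2.3 Å (rotatable).
    Double/aromatic bonds and bonds inside rings are locked.
    """
    bonds: list[tuple[int, int, bool]] = []
    n_res = snapshot.n_residues
    res_atom_maps: list[dict[str, int]] = []
    for r in range(n_res):
        idx = snapshot.residue_atoms(r)
        res_atom_maps.append({str(snapshot.name[i]): int(i) for i in idx})

    for r in range(n_res):
        idx = snapshot.residue_atoms(r)
        res_name = str(snapshot.residue_name[idx[0]])
        try:
            template = _info.bonds_in_residue(res_name)
        except KeyError as exc:
            raise ValueError(
                f"no covalent template for residue {res_name!r} "
                f"(residue index {r})") from exc
        if not template:
            raise ValueError(
                f"empty covalent template for residue {res_name!r} "
                f"(residue index {r})")
        amap = res_atom_maps[r]
        intra = []
        for (n1, n2), btype in template.items():
            if n1 in amap and n2 in amap:
                intra.append((amap[n1], amap[n2], BondType(btype)))
        if len(amap) > 1 and not intra:
            raise ValueError(
                f"covalent template for residue {res_name!r} matches none of "
                f"its atoms (residue index {r})")
        # ring bonds are locked: cycles of the residue's bond graph
        g = nx.Graph((a, b) for a, b, _ in intra)
        ring_edges = set()
        for cycle in nx.cycle_basis(g):
            for k in range(len(cycle)):
                e = frozenset((cycle[k], cycle[(k + 1) % len(cycle)]))
                ring_edges.add(e)
        for a, b, btype in intra:
            locked = btype in _LOCKED_TYPES or frozenset((a, b)) in ring_edges
            bonds.append((a, b, locked))
        # peptide link to the next residue of the same chain
        if r + 1 < n_res:
            nxt = snapshot.residue_atoms(r + 1)
            if (snapshot.chain_id[idx[0]] == snapshot.chain_id[nxt[0]]
                    and "C" in amap and "N" in res_atom_maps[r + 1]):
                bonds.append((amap["C"], res_atom_maps[r + 1]["N"], True))

    # disulfides
    sg = np.nonzero((snapshot.element == "S") & (snapshot.name == "SG"))[0]
    if len(sg) > 1:
        tree = cKDTree(snapshot.coords[sg])
        for ia, ib in tree.query_pairs(2.3):
            bonds.append((int(sg[ia]), int(sg[ib]), False))
    return bonds


def _adjacency(snapshot: StructureSnapshot,
               bonds: list[tuple[int, int, bool]]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(snapshot.n_atoms)]
    for a, b, _ in bonds:
        adj[a].add(b)
        adj[b].add(a)
    return adj


# ---------------------------------------------------------------------
# Hydrogen bonds (Mayo-type energy)
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class HBondParams:
    """Geometric screens and energy parameters of the H-bond model.

    The defaults follow the convention of pebble-game rigidity codes:
    a candidate D–H···A triple must satisfy H···A ≤ 2.6 Å, D–A ≤ 3.6 Å
    (3.8 Å for salt bridges) and a D–H···A angle ≥ 100° before it is
    scored.  ``v0`` (well depth, kcal/mol) and ``d0`` (equilibrium
    donor–acceptor distance, Å) enter the 12-10 radial term; salt
    bridges are scored with the radial term only, using ``d0_salt``.
    """

    v0: float = 8.0
    d0: float = 2.8
    d0_salt: float = 3.287
    max_ha: float = 2.6
    max_da: float = 3.6
    max_da_salt: float = 3.8
    min_dha_deg: float = 100.0
    e_threshold: float = 0.0  # keep bonds strictly below this energy


def hbond_energy(d: float, angular: float = 1.0, *, v0: float = 8.0,
                 d0: float = 2.8) -> float:
    """Mayo 12-10 hydrogen-bond energy (kcal/mol).

    ``E = v0 * [5 (d0/d)^12 - 6 (d0/d)^10] * angular`` with ``d`` the
    donor–acceptor distance.  At ``d = d0`` with unit angular factor the
    radial term is at its minimum, ``-v0``.
    """
    ratio = d0 / d
    return v0 * (5.0 * ratio**12 - 6.0 * ratio**10) * angular


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle at b (degrees) of the triple a-b-c."""
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


def _hybridization(snapshot: StructureSnapshot, adj: list[set[int]],
                   i: int) -> str:
    """sp2/sp3 assignment of a protein N/O/S atom from its environment."""
    el = snapshot.element[i]
    if el == "S":
        return "sp3"
    h_nb = [j for j in adj[i] if snapshot.element[j] == "H"]
    heavy_nb = [j for j in adj[i] if snapshot.element[j] != "H"]
    if el == "O":
        if h_nb:
            return "sp3"  # hydroxyl
        # carbonyl / carboxylate oxygens are sp2 (single heavy neighbour C)
        return "sp2" if len(heavy_nb) <= 1 else "sp3"
    # nitrogen: amide/guanidinium/aromatic are sp2; ammonium-type sp3
    if len(h_nb) >= 3 or str(snapshot.name[i]) == "NZ":
        return "sp3"
    return "sp2"


def _sp2_normal(snapshot: StructureSnapshot, adj: list[set[int]],
                i: int) -> np.ndarray | None:
    """Unit normal of the sp2 plane at atom i, if definable."""
    nb = [j for j in adj[i]]
    if len(nb) >= 2:
        v1 = snapshot.coords[nb[0]] - snapshot.coords[i]
        v2 = snapshot.coords[nb[1]] - snapshot.coords[i]
    elif len(nb) == 1:
        b = nb[0]
        nb2 = [k for k in adj[b] if k != i]
        if not nb2:
            return None
        v1 = snapshot.coords[b] - snapshot.coords[i]
        v2 = snapshot.coords[nb2[0]] - snapshot.coords[b]
    else:
        return None
    n = np.cross(v1, v2)
    norm = np.linalg.norm(n)
    return None if norm < 1e-8 else n / norm


def _angular_factor(snapshot: StructureSnapshot, adj: list[set[int]],
                    d: int, h: int, a: int, hyb_d: str, hyb_a: str) -> float:
    """Hybridization-dependent angular factor F(θ, φ, γ) ∈ [0, 1].

    θ is the D–H···A angle, φ the H···A–AB angle at the acceptor (AB =
    acceptor base) and γ the out-of-plane angle at an sp2 acceptor.
    """
    coords = snapshot.coords
    theta = _angle(coords[d], coords[h], coords[a])
    cos2_theta = math.cos(math.radians(theta)) ** 2
    base = [j for j in adj[a] if snapshot.element[j] != "H"] or list(adj[a])
    phi = _angle(coords[h], coords[a], coords[base[0]]) if base else 180.0

    if hyb_d == "sp2" and hyb_a == "sp3":
        return cos2_theta**2  # cos^4(theta)
    if hyb_d == "sp3" and hyb_a == "sp3":
        return cos2_theta * math.cos(math.radians(phi - 109.5)) ** 2
    if hyb_d == "sp3" and hyb_a == "sp2":
        return cos2_theta * math.cos(math.radians(phi)) ** 2
    # sp2-sp2: penalize the larger of the in-plane and out-of-plane angles
    normal = _sp2_normal(snapshot, adj, a)
    gamma = phi
    if normal is not None:
        ah = coords[h] - coords[a]
        ah /= np.linalg.norm(ah)
        # angle between H->A direction and the acceptor plane
        out_of_plane = math.degrees(math.asin(abs(float(np.dot(ah, normal)))))
        gamma = 180.0 - out_of_plane
    worst = min(phi, gamma)  # larger deviation from 180 = smaller angle
    return cos2_theta * math.cos(math.radians(180.0 - worst)) ** 2


def detect_hydrogen_bonds(
    snapshot: StructureSnapshot,
    params: HBondParams | None = None,
    covalent: list[tuple[int, int, bool]] | None = None,
) -> list[HydrogenBond]:
    """Detect and score hydrogen bonds including salt bridges.

    Donors are N/O/S atoms with a covalently bound hydrogen (structures
    are expected to be protonated, as MD-derived snapshots are); donors
    without hydrogens are skipped with a logged warning.  Acceptors are
    O/S atoms and bare ring nitrogens.  Candidate triples pass geometric
    screens and are scored with the Mayo 12-10 energy times the
    hybridization-dependent angular factor; salt bridges between charged
    side-chain groups get the radial term with ``d0_salt``.  Only bonds
    with negative energy are returned.
    """
    p = params or HBondParams()
    if covalent is None:
        covalent = covalent_bonds(snapshot)
    adj = _adjacency(snapshot, covalent)
    coords = snapshot.coords
    elements = snapshot.element

    is_h = elements == "H"
    polar = np.isin(elements, ("N", "O", "S"))

    donors = []  # (donor_idx, [hydrogens])
    for i in np.nonzero(polar)[0]:
        hyds = [j for j in adj[i] if is_h[j]]
        if hyds:
            donors.append((int(i), hyds))

    acceptors = []
    for i in np.nonzero(polar)[0]:
        el = elements[i]
        has_h = any(is_h[j] for j in adj[i])
        heavy_deg = sum(1 for j in adj[i] if not is_h[j])
        if el in ("O", "S"):
            acceptors.append(int(i))
        elif el == "N" and not has_h and heavy_deg <= 2:
            acceptors.append(int(i))  # e.g. unprotonated His ring nitrogen
    if not acceptors:
        return []
    acc_arr = np.asarray(acceptors)
    tree = cKDTree(coords[acc_arr])

    # warn about polar heavy atoms that could donate but carry no H
    for i in np.nonzero(polar)[0]:
        if elements[i] == "N" and not any(is_h[j] for j in adj[i]):
            heavy_deg = sum(1 for j in adj[i] if not is_h[j])
            if heavy_deg >= 3:
                logger.warning(
                    "donor %s/%d has no hydrogen; skipped",
                    snapshot.name[i], int(snapshot.serial[i]))

    max_da = max(p.max_da, p.max_da_salt)
    bonds: list[HydrogenBond] = []
    for d_idx, hyds in donors:
        res_d = (str(snapshot.residue_name[d_idx]), str(snapshot.name[d_idx]))
        cationic = res_d in _CATION_ATOMS
        near = tree.query_ball_point(coords[d_idx], max_da)
        for k in near:
            a_idx = int(acc_arr[k])
            if a_idx == d_idx or a_idx in adj[d_idx]:
                continue
            if adj[d_idx] & adj[a_idx]:
                continue  # 1-3 neighbours share a covalent partner
            res_a = (str(snapshot.residue_name[a_idx]),
                     str(snapshot.name[a_idx]))
            salt = cationic and res_a in _ANION_ATOMS
            dda = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
            if dda > (p.max_da_salt if salt else p.max_da):
                continue
            best: tuple[float, int] | None = None
            for h_idx in hyds:
                dha_dist = float(np.linalg.norm(coords[h_idx] - coords[a_idx]))
                if dha_dist > p.max_ha:
                    continue
                theta = _angle(coords[d_idx], coords[h_idx], coords[a_idx])
                if theta < p.min_dha_deg:
                    continue
                if salt:
                    e = hbond_energy(dda, 1.0, v0=p.v0, d0=p.d0_salt)
                else:
                    hyb_d = _hybridization(snapshot, adj, d_idx)
                    hyb_a = _hybridization(snapshot, adj, a_idx)
                    f = _angular_factor(snapshot, adj, d_idx, h_idx, a_idx,
                                        hyb_d, hyb_a)
                    e = hbond_energy(dda, f, v0=p.v0, d0=p.d0)
                if best is None or e < best[0]:
                    best = (e, h_idx)
            if best is not None and best[0] < p.e_threshold:
                bonds.append(HydrogenBond(d_idx, best[1], a_idx, best[0],
                                          is_salt_bridge=salt))
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


# ---------------------------------------------------------------------
# Hydrophobic tethers
# ---------------------------------------------------------------------

def detect_hydrophobic_tethers(
    snapshot: StructureSnapshot,
    covalent: list[tuple[int, int, bool]] | None = None,
    dcut: float = HYDROPHOBIC_DCUT,
    apolar_only: bool = True,
) -> list[HydrophobicTether]:
    """Inter-residue C/S atom pairs within vdW-sum + ``dcut``.

    The cutoff is the sum of the van der Waals radii (C 1.7 Å, S 1.8 Å)
    plus the offset (0.25 Å by default), boundary inclusive; covalently
    bonded pairs (e.g. disulfides) and intra-residue pairs are excluded.
    With ``apolar_only`` (the default, matching the convention of the
    rigidity codes this network model follows) carbons and sulfurs that
    are covalently bonded to nitrogen or oxygen — backbone Cα and
    carbonyl carbons in particular — do not form tethers; otherwise
    polar-backbone contacts would double-count interactions already
    captured by hydrogen bonds and over-rigidify helices.
    """
    if covalent is None:
        covalent = covalent_bonds(snapshot)
    bonded = {frozenset((a, b)) for a, b, _ in covalent}
    apolar = np.nonzero(np.isin(snapshot.element, ("C", "S")))[0]
    if apolar_only:
        adj = _adjacency(snapshot, covalent)
        apolar = np.array([
            i for i in apolar
            if not any(snapshot.element[j] in ("N", "O") for j in adj[i])
        ], dtype=int)
    if len(apolar) < 2:
        return []
    coords = snapshot.coords[apolar]
    max_cut = 2 * VDW_RADII["S"] + dcut
    tree = cKDTree(coords)
    tethers = []
    for ia, ib in sorted(tree.query_pairs(max_cut)):
        i, j = int(apolar[ia]), int(apolar[ib])
        if snapshot.residue_index[i] == snapshot.residue_index[j]:
            continue
        if frozenset((i, j)) in bonded:
            continue
        cutoff = (VDW_RADII[str(snapshot.element[i])]
                  + VDW_RADII[str(snapshot.element[j])] + dcut)
        dist = float(np.linalg.norm(snapshot.coords[i] - snapshot.coords[j]))
        if dist <= cutoff:
            a, b = min(i, j), max(i, j)
            tethers.append(HydrophobicTether(a, b, dist))
    return tethers


# ---------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------

def build_network(
    snapshot: StructureSnapshot,
    bonds: list[HydrogenBond],
    tethers: list[HydrophobicTether],
    E_cut: float,
    covalent: list[tuple[int, int, bool]] | None = None,
) -> ConstraintNetwork:
    """Assemble the constraint network at one energy cutoff.

    Hydrogen bonds are retained only when ``E_HB <= E_cut``; covalent
    bars and hydrophobic tethers are always present.
    """
    if E_cut > 0:
        raise ValueError("E_cut must be <= 0 kcal/mol")
    if covalent is None:
        covalent = covalent_bonds(snapshot)
    bars = [
        Bar(min(a, b), max(a, b), 6 if locked else 5,
            "covalent-locked" if locked else "covalent-rotatable")
        for a, b, locked in covalent
    ]
    bars.extend(
        Bar(min(hb.donor, hb.acceptor), max(hb.donor, hb.acceptor), 5,
            "hbond", hb.E_HB)
        for hb in bonds if hb.E_HB <= E_cut
    )
    bars.extend(
        Bar(t.atom_a, t.atom_b, 2, "hydrophobic", None) for t in tethers
    )
    return ConstraintNetwork(n_bodies=snapshot.n_atoms, bars=bars, E_cut=E_cut)
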