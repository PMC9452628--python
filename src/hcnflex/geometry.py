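"""Conformational-ensemble observables.

Residue-wise RMSF after superposition, the vertical displacement between
the S6 C-terminus and the C-linker of the preceding subunit (d_z), the
S6–A' kink angle, inter-domain contact counts, and a Kabsch–Sander-style
secondary-structure assignment with per-region content.

The z-axis convention: ensembles are assumed superposed onto a reference
whose pore axis is aligned with z (synthetic fixtures are built
axis-aligned); d_z is then a plain difference of z centers of mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from hcnflex.constants import CONTACT_CUTOFF, atomic_mass
from hcnflex.structure import DomainAnnotation, Ensemble, StructureSnapshot

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryReport",
    "rmsf",
    "dz_displacement",
    "kink_angle",
    "count_contacts",
    "assign_secondary_structure",
    "ss_content",
]

SS_STRUCTURED = ("H", "G", "I", "E")  # helix/strand count as structure


@dataclass
class GeometryReport:
    """Container for the ensemble observables of one construct."""

    rmsf: np.ndarray | None = None
    rmsf_sem: np.ndarray | None = None
    dz_series: np.ndarray | None = None       # (n_frames, n_subunits)
    kink_series: np.ndarray | None = None     # (n_frames, n_subunits)
    contact_series: np.ndarray | None = None  # (n_frames,) or (n_frames, n_subunits)
    ss_content: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------
# RMSF
# ---------------------------------------------------------------------

def rmsf(ensemble: Ensemble, atom_level: bool = False) -> np.ndarray:
    """Per-residue root-mean-square fluctuation (Å).

    The ensemble must already be superposed (e.g. onto the pore-domain
    backbone).  By default the residue representative is its Cα; with
    ``atom_level=True`` the RMSF is averaged over all heavy atoms of
    the residue instead.
    """
    first = ensemble[0]
    coords = ensemble.coords  # (n_frames, n_atoms, 3)
    mean = coords.mean(axis=0)
    sq_dev = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per atom
    atom_rmsf = np.sqrt(sq_dev)
    n_res = first.n_residues
    out = np.full(n_res, np.nan)
    if atom_level:
        heavy = first.is_heavy
        for r in range(n_res):
            mask = (first.residue_index == r) & heavy
            if mask.any():
                out[r] = np.sqrt(sq_dev[mask].mean())
    else:
        ca = first.name == "CA"
        for r in range(n_res):
            mask = (first.residue_index == r) & ca
            if mask.any():
                out[r] = atom_rmsf[np.nonzero(mask)[0][0]]
    return out


# ---------------------------------------------------------------------
# Vertical CL displacement
# ---------------------------------------------------------------------

def _z_com(snapshot: StructureSnapshot, atom_idx: np.ndarray) -> float:
    masses = np.array([atomic_mass(str(snapshot.element[i]))
                       for i in atom_idx])
    return float(np.average(snapshot.coords[atom_idx, 2], weights=masses))


def dz_displacement(snapshot: StructureSnapshot,
                    annotation: DomainAnnotation,
                    n_terminal_residues: int = 4) -> dict[str, float]:
    """Vertical S6→CL displacement per subunit (Å).

    For each chain *s*: the z center of mass (heavy atoms,
    mass-weighted) of the ``n_terminal_residues`` C-terminal residues of
    its S6 helix minus the z center of mass of the C-linker of the
    counter-clockwise preceding subunit, as declared in the annotation's
    subunit cycle.  Larger values mean the CL has moved further down.
    """
    for needed in ("S6", "CL"):
        if needed not in annotation.ranges:
            raise KeyError(f"annotation lacks required range {needed!r}")
    heavy = snapshot.is_heavy
    out: dict[str, float] = {}
    for chain in annotation.subunit_order:
        s6_res = annotation.residues(snapshot, "S6", chain=chain)
        if s6_res.size == 0:
            raise KeyError(f"no S6 residues found for chain {chain!r}")
        tail = s6_res[-n_terminal_residues:]
        s6_mask = np.isin(snapshot.residue_index, tail) & heavy
        prev = annotation.preceding_subunit(chain)
        cl_mask = annotation.atom_mask(snapshot, "CL", chain=prev) & heavy
        if not cl_mask.any():
            raise KeyError(f"no CL residues found for chain {prev!r}")
        out[chain] = (_z_com(snapshot, np.nonzero(s6_mask)[0])
                      - _z_com(snapshot, np.nonzero(cl_mask)[0]))
    return out


# ---------------------------------------------------------------------
# Kink angle
# ---------------------------------------------------------------------

def _cylinder_polish(coords: np.ndarray, axis0: np.ndarray) -> np.ndarray:
    """Refine a helix-axis estimate by a full parametric helix fit.

    Starting from the bisector-based axis, fits the ideal-helix model
    ``r_i = q + s·rise·v + R·(cos(ω·i+φ)·f1 + sin(ω·i+φ)·f2)`` to the
    Cα coordinates by least squares over axis tilt, anchor, radius,
    rise, twist and phase.  This uses both the radial and the phase
    information of every point.  Falls back to the initial estimate if
    the local fit fails.
    """
    from scipy.optimize import least_squares

    n = len(coords)
    idx = np.arange(n) - (n - 1) / 2.0
    axis0 = axis0 / np.linalg.norm(axis0)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, axis0)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis0, seed)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis0, e1)
    c0 = coords.mean(axis=0)

    # initial radius, rise, twist and phase from the projection onto
    # the initial frame
    d = coords - c0
    axial = d @ axis0
    radial = d - np.outer(axial, axis0)
    r0 = float(np.linalg.norm(radial, axis=1).mean())
    rise0 = float(np.polyfit(idx, axial, 1)[0])
    phases = np.unwrap(np.arctan2(radial @ e2, radial @ e1))
    omega0, phi0 = np.polyfit(idx, phases, 1)

    def model(params):
        a, b, px, py, R, rise, omega, phi = params
        v = axis0 + a * e1 + b * e2
        v = v / np.linalg.norm(v)
        f1 = e1 - np.dot(e1, v) * v
        f1 /= np.linalg.norm(f1)
        f2 = np.cross(v, f1)
        q = c0 + px * e1 + py * e2
        ang = omega * idx + phi
        return (q[None, :] + np.outer(rise * idx, v)
                + R * (np.outer(np.cos(ang), f1)
                       + np.outer(np.sin(ang), f2)))

    p0 = np.array([0.0, 0.0, 0.0, 0.0, r0, rise0, omega0, phi0])
    try:
        fit = least_squares(lambda p: (model(p) - coords).ravel(), p0,
                            method="lm")
        v = axis0 + fit.x[0] * e1 + fit.x[1] * e2
        return v / np.linalg.norm(v)
    except Exception:
        return axis0


def _helix_axis(coords: np.ndarray) -> np.ndarray:
    """Axis of a helix's Cα trace, oriented N→C.

    Uses local axis estimates from consecutive Cα bisectors (the
    bisector at residue i points toward the helix axis; the cross
    product of neighbouring bisectors is parallel to the axis), which
    is exact for an ideal helix of any length and free of the phase
    bias a raw principal component has for partial turns.  For traces
    without curvature (near-collinear Cα) the leading principal
    component is used instead.
    """
    n = len(coords)
    nc = coords[-1] - coords[0]
    bis = coords[:-2] + coords[2:] - 2.0 * coords[1:-1]
    norms = np.linalg.norm(bis, axis=1)
    if n >= 5 and np.all(norms > 0.3):
        # bisectors of a helix are radial, i.e. perpendicular to the
        # axis: the axis is the null direction of the bisector set,
        # provided the bisectors actually span a plane
        unit = bis / norms[:, None]
        _, s, vt = np.linalg.svd(unit, full_matrices=False)
        if s[1] > 0.25 * s[0]:
            axis = _cylinder_polish(coords, vt[2])
            if np.dot(nc, axis) < 0:
                axis = -axis
            return axis
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-8 or (len(s) > 1 and s[0] - s[1] < 1e-8):
        raise ValueError("degenerate Cα geometry: no unique helix axis")
    axis = vt[0]
    if np.dot(nc, axis) < 0:
        axis = -axis
    return axis


def kink_angle(snapshot: StructureSnapshot, helix_a, helix_b) -> float:
    """Angle (degrees) between the N→C axes of two helices.

    Each helix is given as a residue-index range; its axis is the
    principal component of the Cα coordinates oriented from N to C
    terminus.  0° means the second helix continues the first collinearly
    and the angle grows with bending.
    """
    angles = []
    for rng in (helix_a, helix_b):
        res = np.asarray(list(rng), dtype=int)
        if res.size < 6:
            raise ValueError("each helix range needs >= 6 residues")
        ca_idx = snapshot.ca_indices(res)
        if len(ca_idx) < 6:
            raise ValueError("each helix range needs >= 6 Cα atoms")
        # preserve N->C order
        order = np.argsort(snapshot.residue_index[ca_idx])
        angles.append(_helix_axis(snapshot.coords[ca_idx[order]]))
    cosang = float(np.clip(np.dot(angles[0], angles[1]), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------

def count_contacts(snapshot: StructureSnapshot, group_a, group_b,
                   cutoff: float = CONTACT_CUTOFF) -> int:
    """Number of residue pairs (a ∈ A, b ∈ B) with at least one
    heavy-atom pair within ``cutoff`` Å (inclusive)."""
    res_a = set(int(r) for r in group_a)
    res_b = set(int(r) for r in group_b)
    if res_a & res_b:
        raise ValueError("contact groups must be disjoint")
    heavy = snapshot.is_heavy
    mask_a = np.isin(snapshot.residue_index, list(res_a)) & heavy
    mask_b = np.isin(snapshot.residue_index, list(res_b)) & heavy
    idx_a, idx_b = np.nonzero(mask_a)[0], np.nonzero(mask_b)[0]
    if len(idx_a) == 0 or len(idx_b) == 0:
        return 0
    tree_b = cKDTree(snapshot.coords[idx_b])
    pairs = set()
    neighbors = tree_b.query_ball_point(snapshot.coords[idx_a], cutoff)
    for k, nb in enumerate(neighbors):
        ra = int(snapshot.residue_index[idx_a[k]])
        for m in nb:
            pairs.add((ra, int(snapshot.residue_index[idx_b[m]])))
    return len(pairs)


# ---------------------------------------------------------------------
# Secondary structure (Kabsch–Sander style)
# ---------------------------------------------------------------------

_Q1Q2_332 = 0.084 * 332.0  # electrostatic H-bond prefactor, kcal/mol*Å
_HBOND_CUT = -0.5


def _backbone_hbond_energies(snapshot: StructureSnapshot) -> dict[tuple[int, int], float]:
    """Backbone C=O(i)···H-N(j) energies for all residue pairs.

    E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol.
    The amide hydrogen is taken from the structure when present and
    otherwise placed 1.0 Å from N opposite the preceding carbonyl.
    """
    n_res = snapshot.n_residues
    pos: dict[str, list[np.ndarray | None]] = {
        a: [None] * n_res for a in ("N", "CA", "C", "O", "H")}
    chain = [None] * n_res
    for r in range(n_res):
        idx = snapshot.residue_atoms(r)
        chain[r] = str(snapshot.chain_id[idx[0]])
        for i in idx:
            nm = str(snapshot.name[i])
            if nm in pos:
                pos[nm][r] = snapshot.coords[i]

    # synthesize missing amide hydrogens from the peptide geometry
    for r in range(n_res):
        if pos["H"][r] is not None or pos["N"][r] is None:
            continue
        if r > 0 and chain[r - 1] == chain[r] \
                and pos["C"][r - 1] is not None and pos["O"][r - 1] is not None:
            d = pos["C"][r - 1] - pos["O"][r - 1]
            d = d / np.linalg.norm(d)
            pos["H"][r] = pos["N"][r] + d  # 1.0 Å along C=O direction

    energies: dict[tuple[int, int], float] = {}
    donors = [r for r in range(n_res)
              if pos["N"][r] is not None and pos["H"][r] is not None]
    acceptors = [r for r in range(n_res)
                 if pos["C"][r] is not None and pos["O"][r] is not None]
    if not donors or not acceptors:
        return energies
    acc_arr = np.asarray(acceptors)
    tree = cKDTree(np.stack([pos["O"][r] for r in acceptors]))
    for j in donors:  # donor residue j provides N-H
        for k in tree.query_ball_point(pos["N"][j], 5.2):
            i = int(acc_arr[k])  # acceptor residue i provides C=O
            if chain[i] == chain[j] and abs(i - j) < 2:
                continue  # skip self and peptide-bonded neighbours
                # (inter-chain pairs are all allowed: sheets span chains)
            r_on = np.linalg.norm(pos["O"][i] - pos["N"][j])
            r_ch = np.linalg.norm(pos["C"][i] - pos["H"][j])
            r_oh = np.linalg.norm(pos["O"][i] - pos["H"][j])
            r_cn = np.linalg.norm(pos["C"][i] - pos["N"][j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue
            e = _Q1Q2_332 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
            if e < _HBOND_CUT:
                energies[(i, j)] = float(e)
    return energies


def assign_secondary_structure(snapshot: StructureSnapshot) -> np.ndarray:
    """Per-residue secondary-structure labels.

    Labels: H (α-helix), G (3₁₀-helix), I (π-helix), E (β-strand),
    T (turn), C (coil).  Assignment follows the Kabsch–Sander scheme:
    backbone H-bonds below -0.5 kcal/mol define n-turns (i→i+3/4/5) and
    bridges; two consecutive n-turns make a minimal helix, bridge
    ladders make strands.  Precedence: H > E > G > I > T.  Residues with
    missing backbone atoms are labeled C with a logged warning.
    """
    n_res = snapshot.n_residues
    labels = np.array(["C"] * n_res, dtype=object)
    have_backbone = np.zeros(n_res, dtype=bool)
    for r in range(n_res):
        idx = snapshot.residue_atoms(r)
        names = set(str(n) for n in snapshot.name[idx])
        have_backbone[r] = {"N", "CA", "C", "O"} <= names
        if not have_backbone[r]:
            logger.warning("residue %d lacks backbone atoms; labeled C", r)

    hb = _backbone_hbond_energies(snapshot)
    bonded = set(hb)

    # n-turns: C=O(i) ... H-N(i+n)
    turn = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(n_res - n):
            if (i, i + n) in bonded:
                turn[n][i] = True

    helix = {n: np.zeros(n_res, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(1, n_res - n):
            if turn[n][i] and turn[n][i - 1]:
                helix[n][i:i + n] = True

    # bridges: parallel / antiparallel patterns between non-local pairs
    bridge = np.zeros(n_res, dtype=bool)
    bridge_partner: dict[int, list[int]] = {}
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            para = (((i - 1, j) in bonded and (j, i + 1) in bonded)
                    or ((j - 1, i) in bonded and (i, j + 1) in bonded))
            anti = (((i, j) in bonded and (j, i) in bonded)
                    or ((i - 1, j + 1) in bonded and (j - 1, i + 1) in bonded))
            if para or anti:
                bridge[i] = bridge[j] = True
                bridge_partner.setdefault(i, []).append(j)

    # ladders: adjacent bridges -> E; isolated bridges also mapped to E
    strand = bridge.copy()

    # precedence H > E > G > I > T
    for i in range(n_res):
        if not have_backbone[i]:
            continue
        if helix[4][i]:
            labels[i] = "H"
        elif strand[i]:
            labels[i] = "E"
        elif helix[3][i]:
            labels[i] = "G"
        elif helix[5][i]:
            labels[i] = "I"
        elif any(turn[n][max(0, i - n):i + 1].any() for n in (3, 4, 5)):
            labels[i] = "T"
    return labels


def ss_content(ensemble: Ensemble, region) -> tuple[float, float]:
    """Structured fraction of a residue region over all frames.

    Counts the fraction of (residue, frame) cells labeled helix or
    strand (H/G/I/E); turns and bends do not count as structure.
    Returns (fraction, SEM across frames).
    """
    region = np.asarray(list(region), dtype=int)
    if region.size == 0:
        raise ValueError("region is empty")
    per_frame = []
    for snap in ensemble:
        lab = assign_secondary_structure(snap)[region]
        per_frame.append(np.isin(lab, SS_STRUCTURED).mean())
    per_frame = np.asarray(per_frame)
    sem = (per_frame.std(ddof=1) / np.sqrt(len(per_frame))
           if len(per_frame) > 1 else 0.0)
    return float(per_frame.mean()), float(sem)
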