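"""Shared fixtures: tiny PDB files, ideal chains, sheet and multimer
fixtures built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from hcnflex.structure import StructureSnapshot
from hcnflex.synth import EnsembleSpec, _build_polyala_helix, \
    generate_hinged_multimer

TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


def chains_to_snapshot(chains) -> StructureSnapshot:
    """Assemble (coords, meta) chain blocks from the poly-Ala builder
    into one snapshot (chains named A, B, ...)."""
    serial, name, elem, ridx, rname, cid, rseq, xyz = ([] for _ in range(8))
    roff, s = 0, 1
    for ci, (coords, meta) in enumerate(chains):
        r = -1
        for k, (nm, el) in enumerate(meta):
            if nm == "N":
                r += 1
            serial.append(s)
            s += 1
            name.append(nm)
            elem.append(el)
            ridx.append(roff + r)
            rname.append("ALA")
            cid.append("ABCDEFGH"[ci])
            rseq.append(r + 1)
            xyz.append(coords[k])
        roff += r + 1
    return StructureSnapshot(
        np.asarray(serial), np.asarray(name, object), np.asarray(elem, object),
        np.asarray(ridx), np.asarray(rname, object), np.asarray(cid, object),
        np.asarray(rseq), np.asarray(xyz))


def bare_atom_snapshot(coords, elements) -> StructureSnapshot:
    """One atom per residue (name CB of ALA), for geometric rule tests
    free of covalent context."""
    n = len(elements)
    return StructureSnapshot(
        serial=np.arange(1, n + 1),
        name=np.asarray(["CB"] * n, object),
        element=np.asarray(list(elements), object),
        residue_index=np.arange(n),
        residue_name=np.asarray(["ALA"] * n, object),
        chain_id=np.asarray(["A"] * n, object),
        res_seq=np.arange(1, n + 1),
        coords=np.asarray(coords, dtype=float))


@pytest.fixture(scope="session")
def ideal_helix_snapshot():
    """A 12-residue ideal α-helix (single chain)."""
    return chains_to_snapshot([_build_polyala_helix(12)])


@pytest.fixture(scope="session")
def beta_sheet_snapshot():
    """Two-strand antiparallel β fixture (8 residues per strand).

    Strand B is strand A flipped 180° about z and translated so that the
    backbone hydrogen-bond ladder forms without steric clashes.
    """
    cA, mA = _build_polyala_helix(8, phi=-139.0, psi=135.0)
    axis = (cA[-1] - cA[0]) / np.linalg.norm(cA[-1] - cA[0])
    rot = Rotation.align_vectors([[1.0, 0.0, 0.0]], [axis])[0]
    a = rot.apply(cA)
    a -= a.mean(axis=0)
    b = a @ np.diag([-1.0, -1.0, 1.0]).T + np.array([-2.0, -6.0, -0.5])
    return chains_to_snapshot([(a, mA), (b, mA)])


@pytest.fixture(scope="session")
def small_multimer():
    """A small rigid 4-chain two-segment fixture plus its spec."""
    spec = EnsembleSpec(helix_lengths=(8, 8), n_frames=3, seed=11)
    ens, truth = generate_hinged_multimer(spec)
    return spec, ens, truth
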