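"""Synthetic ensembles and recordings with known ground truth.

The structural generator builds an idealized C_n-symmetric multimer of
poly-alanine helices: each chain is one continuous ideal α-helix whose
junction between an "S6-like" segment and a "C-linker-like" segment can
be turned into a flexible hinge, mimicking the effect of glycine
insertions between the gate helix and the A'-helix.  Frames sample the
hinge bending angle from a wrapped normal distribution and optionally
translate the post-hinge segment down the pore axis by a planted
amount, so that downstream analyses (RMSF, d_z, kink angle, rigidity
dilution) can be validated against the planted truth.

Chemical realism is deliberately limited: backbone + Cβ and ideal amide
hydrogens are enough to exercise hydrogen-bond scoring, hydrophobic
tethers and the pebble game; there is no force field and no solvent.

The trace generators forward-simulate the Boltzmann, exponential and
Hill models with additive i.i.d. Gaussian noise.  Every generator is a
pure function of its spec including the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from hcnflex.constants import PhysicalConstants
from hcnflex.fits import (ActivationCurve, ActivationTrace, BindingCurve,
                          boltzmann_model, hill_model)
from hcnflex.structure import DomainAnnotation, Ensemble, StructureSnapshot

__all__ = [
    "EnsembleSpec",
    "TraceSpec",
    "generate_hinged_multimer",
    "annotation_for",
    "generate_activation_data",
    "generate_activation_curve",
    "generate_activation_trace",
    "generate_binding_curve",
    "generate_binding_image",
    "write_ground_truth",
]

# ideal backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB, _B_N_H, _B_CA_HA = (
    1.458, 1.525, 1.329, 1.231, 1.530, 1.010, 1.090)
_A_CA_C_N, _A_C_N_CA, _A_N_CA_C, _A_CA_C_O = 116.2, 121.7, 111.2, 120.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0

_CHAIN_IDS = "ABCDEFGH"


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """NeRF placement: position d with |cd| = bond, angle(b,c,d) and
    dihedral(a,b,c,d) as given."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class EnsembleSpec:
    """Study conditions of one synthetic ensemble.

    ``helix_lengths`` gives the residue counts of the S6-like and
    C-linker-like segments of every chain (one continuous ideal helix,
    so the unbent kink angle is ~0°).  ``hinge_flexibility`` is the
    angular SD (degrees) of the per-frame, per-chain hinge bend;
    ``planted_dz_shift`` translates the post-hinge segment down the
    pore (z) axis by the given amount (Å).
    """

    n_chains: int = 4
    helix_lengths: tuple[int, int] = (10, 10)
    hinge_site: int | None = None  # first residue of the post-hinge segment
    hinge_flexibility: float = 0.0
    planted_dz_shift: float = 0.0
    n_frames: int = 50
    seed: int = 0
    radius: float = 9.0
    label: str = "synthetic"

    def __post_init__(self):
        if self.hinge_flexibility < 0:
            raise ValueError("hinge_flexibility must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_chains < 1 or self.n_chains > len(_CHAIN_IDS):
            raise ValueError("n_chains out of range")
        if min(self.helix_lengths) < 6:
            raise ValueError("each helix segment needs >= 6 residues")
        if self.hinge_site is None:
            self.hinge_site = self.helix_lengths[0]

    @property
    def n_residues_per_chain(self) -> int:
        return sum(self.helix_lengths)


def _build_polyala_helix(n_res: int, phi: float = _PHI,
                         psi: float = _PSI) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """One ideal poly-alanine chain at fixed backbone dihedrals.

    Defaults build an α-helix; other (φ, ψ) pairs give extended or
    strand geometry.  Returns coordinates plus per-atom (name, element)
    in residue blocks of N, H, CA, HA, CB, C, O (the N-terminal residue
    has no amide H).
    """
    bb: list[dict[str, np.ndarray]] = []
    for i in range(n_res):
        res: dict[str, np.ndarray] = {}
        if i == 0:
            res["N"] = np.zeros(3)
            res["CA"] = np.array([_B_N_CA, 0.0, 0.0])
            res["C"] = _place_atom(np.array([0.0, 1.0, 0.0]), res["N"],
                                   res["CA"], _B_CA_C, _A_N_CA_C, 60.0)
        else:
            prev = bb[i - 1]
            res["N"] = _place_atom(prev["N"], prev["CA"], prev["C"],
                                   _B_C_N, _A_CA_C_N, psi)
            res["CA"] = _place_atom(prev["CA"], prev["C"], res["N"],
                                    _B_N_CA, _A_C_N_CA, _OMEGA)
            res["C"] = _place_atom(prev["C"], res["N"], res["CA"],
                                   _B_CA_C, _A_N_CA_C, phi)
        bb.append(res)
    for i, res in enumerate(bb):
        nxt_n = bb[i + 1]["N"] if i + 1 < n_res else None
        # carbonyl O: trans to the next amide N (psi + 180)
        res["O"] = _place_atom(res["N"], res["CA"], res["C"],
                               _B_C_O, _A_CA_C_O, psi + 180.0)
        res["CB"] = _place_atom(res["C"], res["N"], res["CA"],
                                _B_CA_CB, 110.4, -120.0)
        res["HA"] = _place_atom(res["C"], res["N"], res["CA"],
                                _B_CA_HA, 109.0, 120.0)
        if i > 0:
            prev_c = bb[i - 1]["C"]
            u = res["N"] - prev_c
            v = res["N"] - res["CA"]
            h_dir = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            res["H"] = res["N"] + h_dir / np.linalg.norm(h_dir) * _B_N_H
        _ = nxt_n
    coords = []
    meta = []
    for i, res in enumerate(bb):
        order = ["N", "H", "CA", "HA", "CB", "C", "O"] if i > 0 else \
                ["N", "CA", "HA", "CB", "C", "O"]
        for nm in order:
            coords.append(res[nm])
            meta.append((nm, "H" if nm in ("H", "HA") else nm[0]))
    return np.asarray(coords), meta


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    x, y, z = axis
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])


def generate_hinged_multimer(spec: EnsembleSpec) -> tuple[Ensemble, dict]:
    """Build the hinged multimer ensemble plus its ground-truth record."""
    n_res = spec.n_residues_per_chain
    coords0, meta = _build_polyala_helix(n_res)

    # align the helix axis with -z (N terminus up, C terminus down)
    ca_rows = [k for k, (nm, _) in enumerate(meta) if nm == "CA"]
    ca = coords0[ca_rows]
    centered = ca - ca.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    target = np.array([0.0, 0.0, -1.0])
    v = np.cross(axis, target)
    sv = np.linalg.norm(v)
    if sv > 1e-12:
        R = _rotation_matrix(v / sv, math.asin(min(1.0, sv))
                             if np.dot(axis, target) >= 0
                             else math.pi - math.asin(min(1.0, sv)))
        coords0 = (coords0 - ca.mean(axis=0)) @ R.T
    else:
        coords0 = coords0 - ca.mean(axis=0)
    coords0 = coords0 + np.array([spec.radius, 0.0, 0.0])

    # residue bookkeeping (per-chain local indices repeated per chain)
    res_local = []
    atom_names = []
    elements = []
    k = 0
    for i in range(n_res):
        n_atoms_res = 7 if i > 0 else 6
        res_local.extend([i] * n_atoms_res)
        atom_names.extend(meta[k + j][0] for j in range(n_atoms_res))
        elements.extend(meta[k + j][1] for j in range(n_atoms_res))
        k += n_atoms_res
    res_local = np.asarray(res_local)
    n_atoms_chain = len(res_local)

    hinge = spec.hinge_site
    post_mask_chain = res_local >= hinge
    # hinge pivot: the peptide junction between the two segments, so that
    # every post-hinge residue (the first one included) moves when bending
    names_arr = np.asarray(atom_names)
    c_row = int(np.nonzero((res_local == hinge - 1) & (names_arr == "C"))[0][0])
    n_row = int(np.nonzero((res_local == hinge) & (names_arr == "N"))[0][0])
    pivot_point = 0.5 * (coords0[c_row] + coords0[n_row])

    rng = np.random.default_rng(spec.seed)
    snapshots = []
    for frame in range(spec.n_frames):
        chains = []
        for c in range(spec.n_chains):
            xyz = coords0.copy()
            if spec.hinge_flexibility > 0:
                bend = math.radians(rng.normal(0.0, spec.hinge_flexibility))
                azim = rng.uniform(0.0, 2.0 * math.pi)
            else:
                bend, azim = 0.0, 0.0
            if bend != 0.0:
                axis_b = np.array([math.cos(azim), math.sin(azim), 0.0])
                R = _rotation_matrix(axis_b, bend)
                xyz[post_mask_chain] = ((xyz[post_mask_chain] - pivot_point)
                                        @ R.T + pivot_point)
            if spec.planted_dz_shift:
                xyz[post_mask_chain, 2] -= spec.planted_dz_shift
            Rc = _rotation_matrix(np.array([0.0, 0.0, 1.0]),
                                  2.0 * math.pi * c / spec.n_chains)
            chains.append(xyz @ Rc.T)
        all_xyz = np.concatenate(chains)
        n_tot = n_atoms_chain * spec.n_chains
        snapshots.append(StructureSnapshot(
            serial=np.arange(1, n_tot + 1),
            name=np.tile(np.asarray(atom_names, dtype=object), spec.n_chains),
            element=np.tile(np.asarray(elements, dtype=object), spec.n_chains),
            residue_index=np.concatenate(
                [res_local + c * n_res for c in range(spec.n_chains)]),
            residue_name=np.asarray(["ALA"] * n_tot, dtype=object),
            chain_id=np.repeat(
                np.asarray(list(_CHAIN_IDS[:spec.n_chains]), dtype=object),
                n_atoms_chain),
            res_seq=np.tile(res_local + 1, spec.n_chains),
            coords=all_xyz,
            frame_time=float(frame),
        ))
    truth = asdict(spec)
    ensemble = Ensemble(snapshots, metadata={"construct": spec.label,
                                             "seed": spec.seed,
                                             "ground_truth": truth})
    return ensemble, truth


def annotation_for(spec: EnsembleSpec) -> DomainAnnotation:
    """Domain annotation matching :func:`generate_hinged_multimer` output.

    The pre-hinge segment is annotated as S6 (gate helix) and the
    post-hinge segment as CL (C-linker); author numbering is 1-based
    per chain.  The subunit cycle follows the construction order, which
    places successive chains counter-clockwise around z.
    """
    chains = list(_CHAIN_IDS[:spec.n_chains])
    hinge = spec.hinge_site
    n_res = spec.n_residues_per_chain
    return DomainAnnotation(
        ranges={
            "S6": [(c, 1, hinge) for c in chains],
            "CL": [(c, hinge + 1, n_res) for c in chains],
        },
        insertion_site=(hinge, hinge + 1),
        subunit_order=chains,
        numbering_offset=0,
    )


# ---------------------------------------------------------------------
# Recording generators
# ---------------------------------------------------------------------

@dataclass
class TraceSpec:
    """Spec for a synthetic recording.

    ``kind`` selects the forward model: "boltzmann" (steady-state
    activation curve), "exponential" (activation time course) or "hill"
    (concentration–binding curve).  ``params`` holds the model's ground
    truth; missing entries fall back to the defaults of the dedicated
    generator functions.
    """

    kind: str
    params: dict = field(default_factory=dict)
    noise_sd: float = 0.0
    n: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.kind not in ("boltzmann", "exponential", "hill"):
            raise ValueError(f"unknown trace kind {self.kind!r}")


def generate_activation_curve(
    V_half: float = -119.6,
    z_delta: float = 4.0,
    rel_I_satV: float = 1.0,
    voltages=None,
    noise_sd: float = 0.0,
    seed: int = 0,
    T: float | None = None,
) -> tuple[ActivationCurve, dict]:
    """Steady-state activation curve from the Boltzmann model.

    Default voltages span -150 to -70 mV in 10 mV steps, the protocol
    used for the activation families; the default V_half is the
    wildtype half-activation voltage.
    """
    if voltages is None:
        voltages = np.arange(-150.0, -60.0, 10.0)
    V = np.asarray(voltages, dtype=float)
    constants = PhysicalConstants() if T is None else PhysicalConstants(T=T)
    y = boltzmann_model(V, V_half, z_delta, rel_I_satV, constants)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=V.shape)
    truth = {"V_half": V_half, "z_delta": z_delta, "rel_I_satV": rel_I_satV,
             "noise_sd": noise_sd, "seed": seed, "T": constants.T}
    return ActivationCurve(V=V, rel_I=y), truth


def generate_activation_trace(
    tau: float = 120.0,
    A: float = 1.0,
    delay: float = 20.0,
    I_inf: float = 1.0,
    t_max: float = 800.0,
    dt: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[ActivationTrace, dict]:
    """Activation time course: flat until ``delay``, then a rising
    exponential relaxation toward ``I_inf`` with time constant τ (ms)."""
    t = np.arange(0.0, t_max, dt)
    y = np.where(t < delay, I_inf - A,
                 I_inf - A * np.exp(-(t - delay) / tau))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    truth = {"tau": tau, "A": A, "delay": delay, "I_inf": I_inf,
             "noise_sd": noise_sd, "seed": seed}
    return ActivationTrace(t=t, I=y, delay=delay), truth


def generate_binding_curve(
    BC50: float = 0.51,
    H_b: float = 1.4,
    concentrations=None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[BindingCurve, dict]:
    """Concentration–binding curve from the Hill model (µM).

    Defaults mirror the wildtype channel at rest: BC50 = 0.51 µM,
    H_b = 1.4, concentrations log-spaced between 0.05 and 2.5 µM.
    """
    if concentrations is None:
        concentrations = np.geomspace(0.05, 2.5, 8)
    x = np.asarray(concentrations, dtype=float)
    y = hill_model(x, BC50, H_b)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    truth = {"BC50": BC50, "H_b": H_b, "noise_sd": noise_sd, "seed": seed}
    return BindingCurve(x=x, rel_F=y), truth


def generate_activation_data(spec: TraceSpec):
    """Dispatch on :class:`TraceSpec.kind`; returns (data, ground_truth)."""
    p = dict(spec.params)
    if spec.kind == "boltzmann":
        if spec.n is not None:
            p.setdefault("voltages",
                         np.linspace(-150.0, -70.0, spec.n))
        return generate_activation_curve(noise_sd=spec.noise_sd,
                                         seed=spec.seed, **p)
    if spec.kind == "exponential":
        if spec.n is not None:
            p.setdefault("t_max", float(spec.n))
        return generate_activation_trace(noise_sd=spec.noise_sd,
                                         seed=spec.seed, **p)
    if spec.n is not None:
        p.setdefault("concentrations", np.geomspace(0.05, 2.5, spec.n))
    return generate_binding_curve(noise_sd=spec.noise_sd, seed=spec.seed, **p)


def generate_binding_image(
    bound_amplitude: float,
    shape: tuple[int, int] = (64, 64),
    free_scale: float = 0.6,
    free_level: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Two-channel confocal image pair with a planted bound signal.

    The red channel records the free dye only; the green channel is
    ``free_scale`` times the free-dye field plus ``bound_amplitude``
    inside the patch mask.  Returns (green, red, masks, truth) where
    masks contains disjoint ``bath``, ``patch`` and ``border`` regions.
    """
    if bound_amplitude < 0:
        raise ValueError("bound_amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # smooth free-dye field with mild vignetting
    free = free_level * (1.0 - 0.3 * ((yy - h / 2) ** 2 + (xx - w / 2) ** 2)
                         / (h * h / 4 + w * w / 4))
    border = (yy < 2) | (yy >= h - 2) | (xx < 2) | (xx >= w - 2)
    free = np.where(border, 0.0, free)
    patch = ((yy - h / 2) ** 2 + (xx - w / 2) ** 2) < (min(h, w) / 6) ** 2
    bath = (~patch) & (~border) & (xx < w / 2 - min(h, w) / 6)
    red = free.copy()
    green = free_scale * free + np.where(patch, bound_amplitude, 0.0)
    if noise_sd > 0:
        green = green + rng.normal(0.0, noise_sd, size=shape)
        red = red + rng.normal(0.0, noise_sd, size=shape)
    masks = {"bath": bath, "patch": patch, "border": border}
    truth = {"bound_amplitude": bound_amplitude, "free_scale": free_scale,
             "noise_sd": noise_sd, "seed": seed}
    return green, red, masks, truth


def write_ground_truth(truth: dict, path: str | Path) -> None:
    """Write a ground-truth sidecar as key = value text."""
    with open(path, "w") as fh:
        for k, v in truth.items():
            fh.write(f"{k} = {v}\n")
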