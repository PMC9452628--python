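"""Body-bar pebble game, hydrogen-bond dilution and stability energies.

The rigidity core is a (6,6) pebble game on the body-bar network: every
body (atom) starts with 6 pebbles, a bar of multiplicity *m* is inserted
as *m* parallel edge copies, and a copy is accepted as an independent
constraint when 7 pebbles can be gathered on its two endpoints (6 are
reserved for the trivial rigid-body motions of the pair).  Rigid
clusters — maximal body sets with no internal degree of freedom — are
maintained online with the standard component-detection rule: after an
accepted insertion on (u, v), if only 6 pebbles can be gathered on the
pair, the set of bodies that cannot reach any free pebble outside the
pair's reach forms a new rigid cluster.  Because mutual rigidity of
full 6-DOF bodies is an equivalence relation, clusters form a partition
of the bodies.

Dilution exploits that raising the energy cutoff only *adds* hydrogen
bonds: one incremental game run from the strongest cutoff upward yields
the decomposition at every grid value (the pebble game is matroidal, so
insertion order cannot change ranks or clusters).

From the per-cutoff partitions, neighbor stability maps assign each
in-contact residue pair the most negative cutoff at which the two
residues are still part of one rigid cluster (``rc_ij``); summing these
per residue gives the local chemical potential energies ``E_i`` whose
total over pairs is the network's stability energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import cKDTree

from hcnflex.constants import CONTACT_CUTOFF
from hcnflex.network import Bar, ConstraintNetwork, HydrogenBond, \
    HydrophobicTether, build_network
from hcnflex.structure import StructureSnapshot

__all__ = [
    "RigidClusterDecomposition",
    "StabilityMap",
    "StabilityProfile",
    "DeltaStability",
    "pebble_game",
    "dilute",
    "default_ecut_grid",
    "stability_map",
    "average_stability_maps",
    "stability_profile",
    "delta_stability",
    "region_average",
]


# ---------------------------------------------------------------------
# Decomposition container
# ---------------------------------------------------------------------

@dataclass
class RigidClusterDecomposition:
    """Partition of bodies into rigid clusters at one energy cutoff.

    ``cluster_of[i]`` is the cluster id of body ``i``; ids are contiguous
    from 0 and canonicalized so that clusters are numbered by their
    lowest body index.  ``floppy_modes`` counts internal degrees of
    freedom (6 trivial motions subtracted once per connected component).
    """

    cluster_of: np.ndarray
    n_clusters: int
    floppy_modes: int
    E_cut: float | None = None

    @property
    def n_bodies(self) -> int:
        return len(self.cluster_of)

    def cluster_members(self, cid: int) -> np.ndarray:
        return np.nonzero(self.cluster_of == cid)[0]

    def largest_cluster_size(self) -> int:
        return int(np.bincount(self.cluster_of).max())


def _canonical_labels(raw: list[int]) -> tuple[np.ndarray, int]:
    """Relabel arbitrary cluster representatives to contiguous ids ordered
    by lowest member index."""
    raw_arr = np.asarray(raw)
    order: dict[int, int] = {}
    for rep in raw_arr:  # first occurrence = lowest body index
        if rep not in order:
            order[int(rep)] = len(order)
    return np.array([order[int(r)] for r in raw_arr]), len(order)


# ---------------------------------------------------------------------
# Pebble game engine
# ---------------------------------------------------------------------

class _PebbleGame:
    """Incremental (6,6) body-bar pebble game with cluster maintenance."""

    K = 6  # pebbles per body; also the count reserved for trivial motions

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [self.K] * n
        self.out: list[dict[int, int]] = [dict() for _ in range(n)]
        self.rank = 0  # number of independent bars
        self._rigid_parent = list(range(n))  # union-find over rigid clusters
        self._conn_parent = list(range(n))   # union-find over connectivity

    # -- union-find helpers -------------------------------------------
    @staticmethod
    def _find(parent: list[int], x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    def same_cluster(self, u: int, v: int) -> bool:
        return self._find(self._rigid_parent, u) == self._find(self._rigid_parent, v)

    # -- pebble moves ---------------------------------------------------
    def _find_pebble(self, root: int, other: int) -> bool:
        """DFS from ``root`` for a free pebble, excluding ``other``;
        on success reverse the path and move the pebble to ``root``."""
        visited = {root, other}
        parent: dict[int, int] = {}
        stack = [root]
        while stack:
            x = stack.pop()
            for y in self.out[x]:
                if y in visited:
                    continue
                visited.add(y)
                parent[y] = x
                if self.pebbles[y] > 0:
                    # reverse edges along root -> ... -> y, move pebble
                    self.pebbles[y] -= 1
                    self.pebbles[root] += 1
                    node = y
                    while node != root:
                        prev = parent[node]
                        cnt = self.out[prev][node] - 1
                        if cnt:
                            self.out[prev][node] = cnt
                        else:
                            del self.out[prev][node]
                        self.out[node][prev] = self.out[node].get(prev, 0) + 1
                        node = prev
                    return True
                stack.append(y)
        return False

    def _gather(self, u: int, v: int, target: int) -> bool:
        while self.pebbles[u] + self.pebbles[v] < target:
            if not (self._find_pebble(u, v) or self._find_pebble(v, u)):
                return False
        return True

    # -- component detection (Lee–Streinu style) -----------------------
    def _detect_component(self, u: int, v: int) -> None:
        """Called when only 6 pebbles can be gathered on (u, v): identify
        the new rigid cluster and union its members."""
        # forward reach of {u, v}
        reach = {u, v}
        stack = [u, v]
        while stack:
            x = stack.pop()
            for y in self.out[x]:
                if y not in reach:
                    reach.add(y)
                    stack.append(y)
        # reverse search from free-pebbled bodies outside the reach
        rev: list[list[int]] = [[] for _ in range(self.n)]
        for x in range(self.n):
            for y in self.out[x]:
                rev[y].append(x)
        marked = [False] * self.n
        stack = [w for w in range(self.n)
                 if self.pebbles[w] > 0 and w not in reach]
        for w in stack:
            marked[w] = True
        while stack:
            x = stack.pop()
            for y in rev[x]:
                if not marked[y]:
                    marked[y] = True
                    stack.append(y)
        members = [w for w in range(self.n) if not marked[w]]
        root = self._find(self._rigid_parent, members[0])
        for w in members[1:]:
            self._rigid_parent[self._find(self._rigid_parent, w)] = root

    # -- public API -----------------------------------------------------
    def add_bar(self, u: int, v: int, multiplicity: int) -> None:
        if multiplicity not in (2, 5, 6):
            raise ValueError(f"bar multiplicity must be 2, 5 or 6, "
                             f"got {multiplicity}")
        if u == v:
            raise ValueError("bar endpoints must differ")
        cu, cv = self._find(self._conn_parent, u), self._find(self._conn_parent, v)
        if cu != cv:
            self._conn_parent[cu] = cv
        if self.same_cluster(u, v):
            return  # every copy is redundant inside a rigid cluster
        accepted = 0
        for _ in range(multiplicity):
            if not self._gather(u, v, self.K + 1):
                break
            self.pebbles[u] -= 1
            self.out[u][v] = self.out[u].get(v, 0) + 1
            self.rank += 1
            accepted += 1
        # a rejected copy, or exhausting the pair's freedom, signals that
        # (u, v) may now be mutually rigid
        if not self._gather(u, v, self.K + 1):
            self._detect_component(u, v)

    def n_connected_components(self) -> int:
        return len({self._find(self._conn_parent, x) for x in range(self.n)})

    def decomposition(self, E_cut: float | None = None) -> RigidClusterDecomposition:
        labels, n_clusters = _canonical_labels(
            [self._find(self._rigid_parent, x) for x in range(self.n)])
        floppy = (self.K * self.n
                  - self.K * self.n_connected_components()
                  - self.rank)
        return RigidClusterDecomposition(
            cluster_of=labels, n_clusters=n_clusters,
            floppy_modes=max(0, floppy), E_cut=E_cut)


def pebble_game(network: ConstraintNetwork) -> RigidClusterDecomposition:
    """Rigid-cluster decomposition of a constraint network.

    The result is deterministic and independent of bar order (the
    underlying independence system is a matroid); cluster ids are
    canonicalized by lowest body index.
    """
    game = _PebbleGame(network.n_bodies)
    for bar in network.bars:
        game.add_bar(bar.atom_a, bar.atom_b, bar.multiplicity)
    return game.decomposition(E_cut=network.E_cut)


# ---------------------------------------------------------------------
# Dilution
# ---------------------------------------------------------------------

def default_ecut_grid(start: float = -0.1, stop: float = -6.0,
                      step: float = 0.1) -> np.ndarray:
    """Descending energy-cutoff grid, -0.1 to -6.0 kcal/mol in 0.1 steps."""
    n = int(round((start - stop) / step)) + 1
    return np.round(start - step * np.arange(n), 10)


def dilute(
    snapshot: StructureSnapshot,
    bonds: list[HydrogenBond],
    tethers: list[HydrophobicTether],
    ecut_grid,
    covalent: list[tuple[int, int, bool]] | None = None,
) -> list[RigidClusterDecomposition]:
    """Constraint-dilution trajectory over a descending cutoff grid.

    At each grid value only hydrogen bonds with ``E_HB <= E_cut`` are
    retained, so walking the grid from weakest to strongest cutoff
    removes bonds in order of increasing strength.  Internally a single
    pebble game is run from the most negative cutoff upward, adding
    bonds incrementally; the returned list follows the grid order.
    """
    grid = np.asarray(list(ecut_grid), dtype=float)
    if grid.size == 0:
        raise ValueError("E_cut grid must not be empty")
    if np.any(grid > 0):
        raise ValueError("E_cut grid values must be <= 0")
    if grid.size > 1 and not np.all(np.diff(grid) < 0):
        raise ValueError("E_cut grid must be strictly decreasing")

    base = build_network(snapshot, [], tethers, E_cut=0.0, covalent=covalent)
    game = _PebbleGame(base.n_bodies)
    for bar in base.bars:
        game.add_bar(bar.atom_a, bar.atom_b, bar.multiplicity)

    hbonds = sorted(bonds, key=lambda b: b.E_HB)  # strongest first
    pos = 0
    decomps: list[RigidClusterDecomposition] = []
    for e_cut in grid[::-1]:  # most negative cutoff first
        while pos < len(hbonds) and hbonds[pos].E_HB <= e_cut:
            hb = hbonds[pos]
            game.add_bar(hb.donor, hb.acceptor, 5)
            pos += 1
        decomps.append(game.decomposition(E_cut=float(e_cut)))
    decomps.reverse()
    return decomps


# ---------------------------------------------------------------------
# Stability maps and energies
# ---------------------------------------------------------------------

@dataclass
class StabilityMap:
    """Neighbor stability map: rc_ij over in-contact residue pairs.

    ``rc[(i, j)]`` (i < j, internal residue indices) is the most negative
    grid cutoff at which residues i and j still share a rigid cluster;
    pairs that are in spatial contact but never co-rigid carry the
    ``sentinel`` value (one grid step above the weakest cutoff), so they
    contribute the weakest possible stability instead of being dropped.
    """

    n_residues: int
    rc: dict[tuple[int, int], float] = field(default_factory=dict)
    sentinel: float = 0.0
    grid: np.ndarray | None = None
    averaged: bool = False

    def value(self, i: int, j: int) -> float | None:
        if i == j:
            return None
        key = (min(i, j), max(i, j))
        return self.rc.get(key)

    def to_triplets(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("res_i\tres_j\trc_kcal_mol\n")
            for (i, j), v in sorted(self.rc.items()):
                fh.write(f"{i}\t{j}\t{v:.9g}\n")


def residue_contacts(snapshot: StructureSnapshot,
                     cutoff: float = CONTACT_CUTOFF) -> set[tuple[int, int]]:
    """Residue pairs with >= 1 heavy-atom pair within ``cutoff`` (inclusive)."""
    heavy = np.nonzero(snapshot.is_heavy)[0]
    tree = cKDTree(snapshot.coords[heavy])
    pairs = set()
    res = snapshot.residue_index
    for ia, ib in tree.query_pairs(cutoff):
        ri, rj = int(res[heavy[ia]]), int(res[heavy[ib]])
        if ri != rj:
            pairs.add((min(ri, rj), max(ri, rj)))
    return pairs


def stability_map(
    dilution: list[RigidClusterDecomposition],
    snapshot: StructureSnapshot,
    contact_cutoff: float = CONTACT_CUTOFF,
) -> StabilityMap:
    """rc_ij map from a dilution trajectory of one snapshot.

    A residue belongs to a cluster when at least one of its heavy atoms
    does; a pair is co-rigid when both residues put a heavy atom into
    the same cluster.
    """
    if not dilution:
        raise ValueError("dilution trajectory is empty")
    grid = np.array([d.E_cut for d in dilution], dtype=float)
    order = np.argsort(grid)  # most negative first
    step = float(grid.max() - np.sort(grid)[-2]) if grid.size > 1 else 0.1
    sentinel = float(grid.max() + step)

    contacts = residue_contacts(snapshot, contact_cutoff)
    heavy = snapshot.is_heavy
    res_index = snapshot.residue_index
    n_res = snapshot.n_residues

    unresolved = set(contacts)
    rc: dict[tuple[int, int], float] = {}
    for k in order:
        if not unresolved:
            break
        labels = dilution[k].cluster_of
        res_clusters: dict[int, set[int]] = {}

        def clusters_of(r: int) -> set[int]:
            if r not in res_clusters:
                mask = (res_index == r) & heavy
                res_clusters[r] = set(labels[mask].tolist())
            return res_clusters[r]

        found = []
        for pair in unresolved:
            i, j = pair
            if clusters_of(i) & clusters_of(j):
                rc[pair] = float(grid[k])
                found.append(pair)
        unresolved.difference_update(found)
    for pair in unresolved:
        rc[pair] = sentinel
    return StabilityMap(n_residues=n_res, rc=rc, sentinel=sentinel,
                        grid=np.sort(grid)[::-1])


def average_stability_maps(maps: list[StabilityMap]) -> StabilityMap:
    """Snapshot-averaged map: mean rc over the snapshots in which a pair
    is in contact (the default aggregation order: average rc first, then
    form energies)."""
    if not maps:
        raise ValueError("no maps to average")
    n_res = maps[0].n_residues
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for m in maps:
        if m.n_residues != n_res:
            raise ValueError("maps disagree in residue count")
        for pair, v in m.rc.items():
            sums[pair] = sums.get(pair, 0.0) + v
            counts[pair] = counts.get(pair, 0) + 1
    rc = {pair: sums[pair] / counts[pair] for pair in sums}
    return StabilityMap(n_residues=n_res, rc=rc, sentinel=maps[0].sentinel,
                        grid=maps[0].grid, averaged=True)


@dataclass
class StabilityProfile:
    """Per-residue chemical potential energies E_i and their total.

    ``E_i = 1/2 * sum_j rc_ij`` over in-contact neighbors; the halving
    makes the per-residue values sum exactly to the total over pairs,
    ``E_total = sum_{i<j} rc_ij``.
    """

    E_i: np.ndarray
    E_total: float
    uncertainty: np.ndarray | None = None


def stability_profile(stability: StabilityMap) -> StabilityProfile:
    E_i = np.zeros(stability.n_residues)
    total = 0.0
    for (i, j), v in stability.rc.items():
        E_i[i] += 0.5 * v
        E_i[j] += 0.5 * v
        total += v
    return StabilityProfile(E_i=E_i, E_total=total)


# ---------------------------------------------------------------------
# Construct-vs-reference differences
# ---------------------------------------------------------------------

@dataclass
class DeltaStability:
    """Per-residue stability differences, reference minus construct.

    ``dE_i`` is the reported map with non-significant residues zeroed
    (negative values = destabilized construct); ``dE_i_raw`` keeps the
    unfiltered differences.  Significance is a per-residue Welch t-test
    across (subunit x run) replicates at level ``alpha``.
    """

    dE_i: np.ndarray
    dE_i_raw: np.ndarray
    p_i: np.ndarray
    significant_i: np.ndarray
    alpha: float = 0.05


def delta_stability(reference, construct, alpha: float = 0.05,
                    exclude: np.ndarray | None = None) -> DeltaStability:
    """Compare per-residue stability energies of two replicate groups.

    ``reference`` and ``construct`` are (n_replicates, n_residues)
    arrays or lists of per-replicate E_i vectors (replicates are the
    subunit x run combinations).  Residues listed in ``exclude`` (e.g.
    insertion positions absent from the reference) are reported as 0
    with p = 1.
    """
    ref = np.atleast_2d(np.asarray(reference, dtype=float))
    con = np.atleast_2d(np.asarray(construct, dtype=float))
    if ref.shape[0] < 2 or con.shape[0] < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    if ref.shape[1] != con.shape[1]:
        raise ValueError("replicate groups disagree in residue count")
    dE_raw = ref.mean(axis=0) - con.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant columns
        _, p = stats.ttest_ind(ref, con, axis=0, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    # identical groups: zero variance and zero difference -> p = 1
    same = (ref.std(axis=0) == 0) & (con.std(axis=0) == 0)
    p = np.where(same & (dE_raw == 0), 1.0, p)
    if exclude is not None:
        excl = np.asarray(exclude, dtype=int)
        p[excl] = 1.0
        dE_raw = dE_raw.copy()
        dE_raw[excl] = 0.0
    significant = p < alpha
    dE = np.where(significant, dE_raw, 0.0)
    return DeltaStability(dE_i=dE, dE_i_raw=dE_raw, p_i=p,
                          significant_i=significant, alpha=alpha)


def region_average(delta: DeltaStability, region,
                   use_raw: bool = False) -> tuple[float, float]:
    """Mean ± SD of dE_i over a residue region (internal indices)."""
    region = np.asarray(list(region), dtype=int)
    if region.size == 0:
        raise ValueError("region is empty")
    if region.min() < 0 or region.max() >= len(delta.dE_i):
        raise ValueError("region outside the annotated residue range")
    vals = (delta.dE_i_raw if use_raw else delta.dE_i)[region]
    return float(vals.mean()), float(vals.std())
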