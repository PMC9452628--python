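"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: the rigidity
oracle builds and ranks an explicit generic body-bar rigidity matrix,
the superposition oracle uses Horn's closed-form quaternion method, and
the brute-force enumerations use plain nested loops.
"""

from __future__ import annotations

import numpy as np
import networkx as nx


# ---------------------------------------------------------------------
# Generic body-bar rigidity matrix
# ---------------------------------------------------------------------

def bar_rows(u: int, v: int, m: int, rng: np.random.Generator,
             n: int) -> list[np.ndarray]:
    """m generic bar rows between bodies u and v.

    A bar connects random attachment points a_u (on body u) and a_v (on
    body v); its direction is a_v - a_u.  Body velocities are (v, ω)
    per body, so the row for body u is [-d, -(a_u × d)] and for body v
    [d, a_v × d].
    """
    rows = []
    for _ in range(m):
        au, av = rng.normal(size=3), rng.normal(size=3)
        d = av - au
        row = np.zeros(6 * n)
        row[6 * u:6 * u + 3] = -d
        row[6 * u + 3:6 * u + 6] = -np.cross(au, d)
        row[6 * v:6 * v + 3] = d
        row[6 * v + 3:6 * v + 6] = np.cross(av, d)
        rows.append(row)
    return rows


def rank_oracle(n: int, bars: list[tuple[int, int, int]],
                rng: np.random.Generator) -> tuple[int, list[int]]:
    """Floppy modes and rigid-cluster labels from matrix ranks.

    ``bars`` is a list of (u, v, multiplicity).  Floppy modes are
    6n - 6c - rank with c the number of connected components; bodies
    u, v are mutually rigid when appending one more generic bar between
    them does not increase the rank.  Labels are canonicalized by first
    occurrence (lowest body index).
    """
    rows = []
    for (u, v, m) in bars:
        rows.extend(bar_rows(u, v, m, rng, n))
    R0 = np.array(rows) if rows else np.zeros((0, 6 * n))
    r0 = np.linalg.matrix_rank(R0, tol=1e-8)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((u, v) for u, v, _ in bars)
    c = nx.number_connected_components(g)
    floppy = 6 * n - 6 * c - r0

    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(n):
        for v in range(u + 1, n):
            if find(u) == find(v):
                continue
            R1 = np.vstack([R0, bar_rows(u, v, 1, rng, n)])
            if np.linalg.matrix_rank(R1, tol=1e-8) == r0:
                parent[find(u)] = find(v)
    labels = [find(x) for x in range(n)]
    order: dict[int, int] = {}
    for x in labels:
        if x not in order:
            order[x] = len(order)
    return floppy, [order[x] for x in labels]


def random_network(rng: np.random.Generator, max_bodies: int = 12):
    """A random body-bar network (n, bars) for oracle comparisons."""
    n = int(rng.integers(2, max_bodies + 1))
    n_bars = int(rng.integers(0, 2 * n + 3))
    bars = []
    for _ in range(n_bars):
        u, v = rng.choice(n, size=2, replace=False)
        bars.append((int(u), int(v), int(rng.choice([2, 5, 6]))))
    return n, bars


# ---------------------------------------------------------------------
# Horn quaternion superposition
# ---------------------------------------------------------------------

def horn_superpose(ref: np.ndarray, mob: np.ndarray) -> float:
    """Least-squares RMSD of mob onto ref via Horn's quaternion method."""
    ref_c = ref - ref.mean(axis=0)
    mob_c = mob - mob.mean(axis=0)
    M = mob_c.T @ ref_c
    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    N = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    eigval = np.linalg.eigvalsh(N)[-1]
    sq = max(0.0, (np.sum(ref_c ** 2) + np.sum(mob_c ** 2) - 2 * eigval))
    return float(np.sqrt(sq / len(ref)))


# ---------------------------------------------------------------------
# Welch t-test by the direct formula
# ---------------------------------------------------------------------

def welch_p(a, b) -> float:
    from scipy.stats import t as tdist
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (len(a) - 1) + vb ** 2 / (len(b) - 1))
    return float(2.0 * tdist.sf(abs(t), df))
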