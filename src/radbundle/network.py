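"""Brute-force spring-network oracle for the coupled fiber bundle.

Each of the M molecules is discretized into ``n_seg`` axial springs in series
(segment stiffness ``n_seg * k_chain`` so the intact chain has stiffness
``k_chain = E*A/l``).  Lateral coupling springs of stiffness ``c`` connect the
corresponding interior nodes of adjacent chains, letting a broken molecule
keep carrying load through its neighbours.  Strand breaks remove individual
segments.  The quasi-static effective stiffness is obtained by imposing unit
displacement on every left chain end, clamping every right end, solving the
linear equilibrium of the interior nodes, and summing the reaction force at
the driven side.

The network is the independent oracle behind the exponential stiffness law:
regressing mean log(k_eff/k0) on breaks-per-fiber N/M yields the decay value
``phi`` at the operating coupling.  Only the static (elastic) response is
computed; dash-pot viscosity does not affect quasi-static stiffness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve
from scipy.stats import linregress

from .degradation import BundleGeometry, molecule_stiffness

def _seed_seq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


__all__ = [
    "NetworkModel",
    "PhiEstimate",
    "build_network",
    "apply_random_breaks",
    "effective_stiffness",
    "estimate_phi",
    "phi_sweep",
]


@dataclass(frozen=True)
class NetworkModel:
    """Discretized coupled-chain spring system with a set of broken segments.

    Segment ``(i, j)`` joins node ``j`` to node ``j+1`` of chain ``i``
    (0-based); node 0 is the driven end, node ``n_seg`` the clamped end.
    Coupling springs of stiffness ``c`` join interior node ``j`` of chains
    ``i`` and ``i+1`` for ``j = 1 .. n_seg-1``.
    """

    M: int
    n_seg: int
    k_chain: float
    c: float
    breaks: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.M < 1 or self.n_seg < 1:
            raise ValueError("M and n_seg must be >= 1")
        if self.k_chain <= 0:
            raise ValueError("k_chain must be positive")
        if self.c < 0:
            raise ValueError("coupling stiffness must be nonnegative")
        for (i, j) in self.breaks:
            if not (0 <= i < self.M and 0 <= j < self.n_seg):
                raise ValueError(f"break ({i}, {j}) outside the network")

    @property
    def k_segment(self) -> float:
        """Stiffness of one axial segment: n_seg springs in series per chain."""
        return self.n_seg * self.k_chain

    @property
    def intact_stiffness(self) -> float:
        return self.M * self.k_chain


def build_network(geom: BundleGeometry, n_seg: int, c: float) -> NetworkModel:
    """Intact network for a bundle geometry: M chains of stiffness E*A/l each."""
    return NetworkModel(
        M=int(geom.M), n_seg=int(n_seg), k_chain=molecule_stiffness(geom), c=c
    )


def apply_random_breaks(net: NetworkModel, N: int, seed) -> NetworkModel:
    """Remove N distinct segments uniformly at random (reproducible by seed)."""
    total = net.M * net.n_seg
    if not (0 <= N <= total):
        raise ValueError(f"N must be in [0, {total}], got {N}")
    if N == 0:
        return net
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=N, replace=False)
    new_breaks = {(int(f) // net.n_seg, int(f) % net.n_seg) for f in flat}
    return replace(net, breaks=frozenset(net.breaks | new_breaks))


def _springs(net: NetworkModel):
    """Yield (node_a, node_b, stiffness) with nodes as (chain, position)."""
    s = net.k_segment
    for i in range(net.M):
        for j in range(net.n_seg):
            if (i, j) not in net.breaks:
                yield (i, j), (i, j + 1), s
    if net.c > 0:
        for i in range(net.M - 1):
            for j in range(1, net.n_seg):
                yield (i, j), (i + 1, j), net.c


def effective_stiffness(net: NetworkModel) -> float:
    """Quasi-static stiffness: reaction force under unit imposed displacement.

    Interior-node equilibrium is solved as a sparse SPD system; components of
    the break-damaged graph that touch neither boundary are pruned (they are
    force-free), so isolated floating fragments never make the solve singular.
    """
    M, n = net.M, net.n_seg
    n_int = M * (n - 1)

    def idx(i: int, j: int) -> int:
        # interior node (i, j), j in 1..n-1
        return i * (n - 1) + (j - 1)

    if n_int == 0:
        # no interior nodes: chains are single segments end to end
        s = net.k_segment
        force = sum(s for i in range(M) if (i, 0) not in net.breaks)
        return float(force)

    # super-nodes for the two boundaries, appended after the interior nodes
    LEFT, RIGHT = n_int, n_int + 1
    rows, cols, vals = [], [], []
    diag = np.zeros(n_int)
    rhs = np.zeros(n_int)
    adj_r, adj_c = [], []

    def node_id(i: int, j: int) -> int:
        if j == 0:
            return LEFT
        if j == n:
            return RIGHT
        return idx(i, j)

    for (a, b, k) in _springs(net):
        na, nb = node_id(*a), node_id(*b)
        adj_r.append(na)
        adj_c.append(nb)
        a_int, b_int = na < n_int, nb < n_int
        if a_int:
            diag[na] += k
        if b_int:
            diag[nb] += k
        if a_int and b_int:
            rows.append(na); cols.append(nb); vals.append(-k)
            rows.append(nb); cols.append(na); vals.append(-k)
        elif a_int and nb == LEFT:
            rhs[na] += k  # boundary displacement u = 1
        elif b_int and na == LEFT:
            rhs[nb] += k
        # RIGHT boundary has u = 0: contributes only to the diagonal

    # prune interior components not connected to either boundary
    graph = sparse.coo_matrix(
        (np.ones(len(adj_r)), (adj_r, adj_c)), shape=(n_int + 2, n_int + 2)
    )
    _, labels = connected_components(graph, directed=False)
    anchored = np.isin(labels[:n_int], (labels[LEFT], labels[RIGHT]))
    keep = np.flatnonzero(anchored & (diag > 0))

    u = np.zeros(n_int)
    if len(keep) > 0:
        remap = -np.ones(n_int, dtype=int)
        remap[keep] = np.arange(len(keep))
        rows = np.asarray(rows, dtype=int)
        cols = np.asarray(cols, dtype=int)
        vals = np.asarray(vals, dtype=float)
        mask = (remap[rows] >= 0) & (remap[cols] >= 0) if len(rows) else np.zeros(0, bool)
        K = sparse.coo_matrix(
            (
                np.concatenate([vals[mask], diag[keep]]),
                (
                    np.concatenate([remap[rows[mask]], np.arange(len(keep))]),
                    np.concatenate([remap[cols[mask]], np.arange(len(keep))]),
                ),
            ),
            shape=(len(keep), len(keep)),
        ).tocsc()
        u[keep] = spsolve(K, rhs[keep])

    s = net.k_segment
    force = 0.0
    for i in range(M):
        if (i, 0) not in net.breaks:
            u_nb = u[idx(i, 1)] if n > 1 else 0.0
            force += s * (1.0 - u_nb)
    return max(float(force), 0.0)


@dataclass(frozen=True)
class PhiEstimate:
    """Regression estimate of the decay value phi at one operating coupling."""

    phi_hat: float
    stderr: float
    alpha_operating: float
    replicates: int
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def coupling_alpha(geom: BundleGeometry, n_seg: int, c: float) -> float:
    """Dimensionless coupling parameter of the discretized network.

    Defined as the ratio of the total lateral coupling stiffness along one
    chain, ``c * n_seg``, to the axial molecule stiffness ``E*A/l`` — i.e.
    ``alpha = c*n_seg*l/(E*A)``, the package's convention for
    ``k_int*l^2/E`` with ``k_int = c*n_seg/l`` read per unit length and
    normalised by the fiber cross-section.
    """
    return c * n_seg * geom.l / (geom.E * geom.A)


def estimate_phi(
    geom: BundleGeometry,
    n_seg: int,
    c: float,
    break_fractions,
    replicates: int,
    seed,
) -> PhiEstimate:
    """Estimate phi by regressing mean log(k_eff/k0) on breaks-per-fiber N/M.

    For each requested break fraction f, ``N = round(f*M)`` random breaks are
    applied in each of ``replicates`` seeded realisations; phi_hat is minus
    the slope of the replicate-mean log stiffness ratio against N/M.
    """
    fractions = np.asarray(break_fractions, dtype=float)
    if fractions.ndim != 1 or len(fractions) < 2:
        raise ValueError("need at least 2 break fractions")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    net0 = build_network(geom, n_seg, c)
    k0 = effective_stiffness(net0)
    ss = _seed_seq(seed)
    child_seeds = ss.spawn(len(fractions) * replicates)

    x, y = [], []
    si = 0
    for f in fractions:
        N = int(round(f * net0.M))
        logs = []
        for _ in range(replicates):
            k = effective_stiffness(apply_random_breaks(net0, N, child_seeds[si]))
            si += 1
            if k > 0:
                logs.append(math.log(k / k0))
        if logs:
            x.append(N / net0.M)
            y.append(float(np.mean(logs)))
    if len(x) < 2:
        raise ValueError("too few usable break fractions (stiffness collapsed)")
    if np.ptp(x) == 0:
        # all fractions round to the same break count (e.g. no breaks at all):
        # the regression is degenerate and the decay slope is zero by symmetry
        return PhiEstimate(
            phi_hat=0.0, stderr=0.0,
            alpha_operating=coupling_alpha(geom, n_seg, c),
            replicates=replicates, r_squared=1.0,
        )
    fit = linregress(x, y)
    return PhiEstimate(
        phi_hat=-fit.slope,
        stderr=fit.stderr,
        alpha_operating=coupling_alpha(geom, n_seg, c),
        replicates=replicates,
        r_squared=fit.rvalue**2,
    )


def phi_sweep(
    geom: BundleGeometry,
    n_seg: int,
    c_values,
    break_fractions,
    replicates: int,
    seed,
):
    """phi estimates across coupling strengths; returns a tidy DataFrame."""
    import pandas as pd

    c_values = list(c_values)
    ss = _seed_seq(seed)
    rows = []
    for c, child in zip(c_values, ss.spawn(len(c_values))):
        est = estimate_phi(geom, n_seg, c, break_fractions, replicates, child)
        rows.append(
            {
                "c": c,
                "alpha": est.alpha_operating,
                "phi_hat": est.phi_hat,
                "stderr": est.stderr,
                "r_squared": est.r_squared,
                "replicates": est.replicates,
            }
        )
    return pd.DataFrame(rows)
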