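"""Numba-jitted inner loops of the Monte-Carlo engine.

The kernels mirror the pure-Python operations in ``lattice``/``loops``
exactly: 6-direction nearest-neighbour trial moves under excluded volume,
bond-vector constraints with components in {-1,0,+1}, event-driven loop
formation against one uniformly chosen eligible neighbour, Poisson
lifetimes, and an inclusive expiry sweep once per MCS.  They operate on the
raw arrays of a ``PolymerState`` in place.

Randomness comes from numba's internal RNG, seeded explicitly before each
kernel call by the engine (which derives sub-seeds from its master numpy
Generator), so simulations are deterministic given the top-level seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# trial-move directions, same order as lattice.MOVE_DIRECTIONS
_DIRS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)

_MAX_BOND_SQ = 3


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def _bond_ok(pos, j, nx, ny, nz):
    dx = pos[j, 0] - nx
    dy = pos[j, 1] - ny
    dz = pos[j, 2] - nz
    return dx * dx + dy * dy + dz * dz <= _MAX_BOND_SQ


@njit(cache=True)
def rg2(pos):
    """Squared radius of gyration of unwrapped positions."""
    n = pos.shape[0]
    cx = cy = cz = 0.0
    for k in range(n):
        cx += pos[k, 0]
        cy += pos[k, 1]
        cz += pos[k, 2]
    cx /= n
    cy /= n
    cz /= n
    s = 0.0
    for k in range(n):
        s += (pos[k, 0] - cx) ** 2 + (pos[k, 1] - cy) ** 2 + (pos[k, 2] - cz) ** 2
    return s / n


@njit(cache=True)
def run_mcs_kernel(
    pos,            # (N,3) int64 unwrapped positions, modified in place
    occ,            # (L,L,L) int32 occupancy grid, modified in place
    partner,        # (N,) int32 loop partner or -1, modified in place
    expiry,         # (N,) int64 loop-bond expiry MCS, modified in place
    aff,            # (N,) float64 interaction affinities
    L,              # lattice size
    clock,          # current MCS clock
    n_mcs,          # number of Monte-Carlo steps to run
    mean_lifetime,  # Poisson mean bond lifetime (MCS)
    loops_enabled,  # bool
    new_contact_only,  # bool: restrict candidates to newly entered contacts
    rg2_out,        # (n_mcs,) float64 R_g^2 after each MCS, or empty to skip
    accept_out,     # (1,) int64 accumulated accepted-move count
):
    """Run ``n_mcs`` Monte-Carlo steps (N trial moves each); returns the new clock."""
    N = pos.shape[0]
    cand = np.empty(26, dtype=np.int64)
    record = rg2_out.shape[0] > 0
    for step in range(n_mcs):
        for _ in range(N):
            i = np.random.randint(0, N)
            d = np.random.randint(0, 6)
            nx = pos[i, 0] + _DIRS[d, 0]
            ny = pos[i, 1] + _DIRS[d, 1]
            nz = pos[i, 2] + _DIRS[d, 2]
            wx = nx % L
            wy = ny % L
            wz = nz % L
            if occ[wx, wy, wz] != -1:
                continue
            ox = pos[i, 0]
            oy = pos[i, 1]
            oz = pos[i, 2]
            if i > 0 and not _bond_ok(pos, i - 1, nx, ny, nz):
                continue
            if i < N - 1 and not _bond_ok(pos, i + 1, nx, ny, nz):
                continue
            pi = partner[i]
            if pi >= 0 and not _bond_ok(pos, pi, nx, ny, nz):
                continue
            # apply the move
            occ[ox % L, oy % L, oz % L] = -1
            occ[wx, wy, wz] = i
            pos[i, 0] = nx
            pos[i, 1] = ny
            pos[i, 2] = nz
            accept_out[0] += 1
            # event-driven loop formation for the monomer that just moved
            if loops_enabled and partner[i] < 0:
                cnt = 0
                for ax in range(-1, 2):
                    for ay in range(-1, 2):
                        for az in range(-1, 2):
                            if ax == 0 and ay == 0 and az == 0:
                                continue
                            j = occ[(wx + ax) % L, (wy + ay) % L, (wz + az) % L]
                            if j >= 0 and j != i - 1 and j != i + 1 and partner[j] < 0:
                                if new_contact_only:
                                    # only pairs brought into proximity by this
                                    # move: j was beyond the cutoff before
                                    dox = pos[j, 0] - ox
                                    doy = pos[j, 1] - oy
                                    doz = pos[j, 2] - oz
                                    if dox * dox + doy * doy + doz * doz <= _MAX_BOND_SQ:
                                        continue
                                cand[cnt] = j
                                cnt += 1
                if cnt > 0:
                    j = cand[np.random.randint(0, cnt)]
                    p = np.sqrt(aff[i] * aff[j])
                    if np.random.random() < p:
                        life = np.random.poisson(mean_lifetime)
                        partner[i] = j
                        partner[j] = i
                        expiry[i] = clock + life
                        expiry[j] = clock + life
        # inclusive expiry sweep, once per MCS
        for k in range(N):
            j = partner[k]
            if j > k and expiry[k] <= clock:
                partner[k] = -1
                partner[j] = -1
        clock += 1
        if record:
            rg2_out[step] = rg2(pos)
    return clock
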