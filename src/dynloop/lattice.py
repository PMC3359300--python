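"""Self-avoiding lattice chain with backbone and transient loop bonds.

The chain lives on a simple cubic lattice with periodic boundaries.  Every
monomer occupies exactly one lattice site (excluded volume).  Bonds — both
the fixed backbone bonds and the transient loop bonds — must be one of the
26 displacement vectors with components in {-1, 0, +1}, i.e. lengths 1,
sqrt(2) or sqrt(3).  Trial moves displace a single monomer to one of its 6
nearest-neighbour sites; a move is accepted iff the target site is free and
every bond of the monomer remains an allowed vector.  The loop-formation
cutoff equals the maximum bond length sqrt(3), so two non-adjacent monomers
can only bind when they are at least as close as chain neighbours can be.

Positions are stored *unwrapped* (observables need true geometry); the
occupancy grid is keyed on wrapped coordinates (excluded volume is periodic).
The lattice must be much larger than the chain's radius of gyration so the
chain never interacts with its own periodic image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np

__all__ = [
    "LatticeConfig",
    "PolymerState",
    "LoopBond",
    "MoveResult",
    "BOND_VECTORS",
    "MOVE_DIRECTIONS",
    "init_random_chain",
    "validate_state",
    "propose_and_apply_move",
    "neighbors_within_cutoff",
]

#: allowed bond displacements: components in {-1,0,+1}, excluding the null vector
BOND_VECTORS = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
     if (dx, dy, dz) != (0, 0, 0)],
    dtype=np.int64,
)

#: the 6 nearest-neighbour trial-move displacements
MOVE_DIRECTIONS = np.array(
    [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)],
    dtype=np.int64,
)

#: maximum allowed squared bond length (sqrt(3) bond -> loop cutoff)
MAX_BOND_SQ = 3


@dataclass(frozen=True)
class LatticeConfig:
    """Lattice geometry and bond rules.

    ``L`` is the linear lattice size (periodic box L^3); the loop-formation
    cutoff is fixed to the maximum bond length sqrt(3).
    """

    L: int = 600

    def __post_init__(self) -> None:
        if self.L < 4:
            raise ValueError("lattice size L must be >= 4")

    @property
    def cutoff(self) -> float:
        return math.sqrt(MAX_BOND_SQ)

    @property
    def max_bond_sq(self) -> int:
        return MAX_BOND_SQ


@dataclass(frozen=True)
class LoopBond:
    """Transient bond between monomers i < j, dissociating once expiry is reached."""

    i: int
    j: int
    expiry_mcs: int

    def __post_init__(self) -> None:
        if not (self.i < self.j):
            raise ValueError("LoopBond requires i < j")
        if self.j - self.i < 2:
            raise ValueError("loop bonds require |i - j| >= 2")


@dataclass(frozen=True)
class MoveResult:
    accepted: bool
    moved_index: int


class PolymerState:
    """Mutable state of one chain: unwrapped positions, occupancy, loop bonds.

    Loop bonds use single-partner bookkeeping: ``loop_partner[i]`` is the
    bonded partner of monomer i (or -1), ``loop_expiry[i]`` the MCS at which
    the bond dissociates (inclusive).
    """

    def __init__(self, positions: np.ndarray, config: LatticeConfig):
        positions = np.asarray(positions, dtype=np.int64)
        if positions.ndim != 2 or positions.shape[1] != 3 or positions.shape[0] < 2:
            raise ValueError("positions must be (N, 3) with N >= 2")
        self.positions = positions
        self.config = config
        self.n = positions.shape[0]
        L = config.L
        self.occupancy = np.full((L, L, L), -1, dtype=np.int32)
        for i, p in enumerate(positions % L):
            site = tuple(p)
            if self.occupancy[site] != -1:
                raise ValueError(f"monomers {self.occupancy[site]} and {i} share site {site}")
            self.occupancy[site] = i
        self.loop_partner = np.full(self.n, -1, dtype=np.int32)
        self.loop_expiry = np.zeros(self.n, dtype=np.int64)
        self.mcs_clock = 0

    # -- loop bond bookkeeping -------------------------------------------

    @property
    def loop_bonds(self) -> list[LoopBond]:
        """Active loop bonds as (i < j, expiry) records."""
        bonds = []
        for i in range(self.n):
            j = int(self.loop_partner[i])
            if j > i:
                bonds.append(LoopBond(i, j, int(self.loop_expiry[i])))
        return bonds

    @property
    def n_loop_bonds(self) -> int:
        return int(np.count_nonzero(self.loop_partner >= 0) // 2)

    def add_loop_bond(self, i: int, j: int, expiry_mcs: int) -> None:
        if self.loop_partner[i] >= 0 or self.loop_partner[j] >= 0:
            raise ValueError("monomer already loop-bonded (single-partner rule)")
        if abs(i - j) < 2:
            raise ValueError("loop bonds require |i - j| >= 2")
        self.loop_partner[i] = j
        self.loop_partner[j] = i
        self.loop_expiry[i] = expiry_mcs
        self.loop_expiry[j] = expiry_mcs

    def remove_loop_bond(self, i: int) -> None:
        j = int(self.loop_partner[i])
        if j < 0:
            return
        self.loop_partner[i] = -1
        self.loop_partner[j] = -1

    # -- geometry helpers -------------------------------------------------

    def wrapped(self, i: int) -> np.ndarray:
        return self.positions[i] % self.config.L

    def bond_vec_sq(self, i: int, j: int) -> int:
        d = self.positions[j] - self.positions[i]
        return int(d @ d)

    def snapshot_positions(self) -> np.ndarray:
        return self.positions.copy()


def init_random_chain(
    N: int,
    config: LatticeConfig,
    seed: int | np.random.Generator = 0,
    max_restarts: int = 200,
) -> PolymerState:
    """Grow a random self-avoiding chain on the lattice.

    The backbone is grown site by site, each step choosing uniformly among
    the allowed bond vectors leading to a free site; dead ends trigger a
    restart.  The result is only a valid starting conformation — the
    loop-free equilibration run removes any growth bias.  Deterministic
    given the seed.
    """
    if N < 2:
        raise ValueError("need N >= 2 monomers")
    if N > config.L**3:
        raise ValueError("chain cannot fit on the lattice")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    L = config.L
    for _ in range(max_restarts):
        occupied: set[tuple[int, int, int]] = set()
        pos = np.empty((N, 3), dtype=np.int64)
        pos[0] = (L // 2, L // 2, L // 2)
        occupied.add(tuple(pos[0] % L))
        ok = True
        for i in range(1, N):
            order = rng.permutation(len(BOND_VECTORS))
            placed = False
            for k in order:
                cand = pos[i - 1] + BOND_VECTORS[k]
                site = tuple(cand % L)
                if site not in occupied:
                    pos[i] = cand
                    occupied.add(site)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return PolymerState(pos, config)
    raise RuntimeError(
        f"failed to place chain of N={N} after {max_restarts} restarts; "
        f"try a larger lattice (L={config.L})"
    )


def validate_state(state: PolymerState, config: LatticeConfig | None = None) -> list[str]:
    """Check every structural invariant; return a list of violation messages.

    An empty list means the state is valid.  Checks: site exclusivity,
    occupancy/position consistency, backbone bond vectors, loop-bond vectors
    and separation, and partner-array symmetry.
    """
    config = config or state.config
    L = config.L
    problems: list[str] = []

    wrapped = state.positions % L
    seen: dict[tuple[int, int, int], int] = {}
    for i, site in enumerate(map(tuple, wrapped)):
        if site in seen:
            problems.append(f"monomers {seen[site]} and {i} overlap at site {site}")
        seen[site] = i
        if state.occupancy[site] != i:
            problems.append(
                f"occupancy desync at site {site}: grid says {state.occupancy[site]}, "
                f"positions say {i}"
            )
    if np.count_nonzero(state.occupancy >= 0) != state.n:
        problems.append("occupancy grid holds a different number of monomers than the chain")

    for i in range(state.n - 1):
        sq = state.bond_vec_sq(i, i + 1)
        if not (1 <= sq <= MAX_BOND_SQ):
            problems.append(f"backbone bond ({i},{i+1}) has squared length {sq}")

    for i in range(state.n):
        j = int(state.loop_partner[i])
        if j < 0:
            continue
        if not (0 <= j < state.n):
            problems.append(f"loop partner of {i} out of range: {j}")
            continue
        if int(state.loop_partner[j]) != i:
            problems.append(f"asymmetric loop bond: partner[{i}]={j} but partner[{j}]={state.loop_partner[j]}")
        if abs(i - j) < 2:
            problems.append(f"loop bond ({i},{j}) between chain neighbours")
        if j > i:
            sq = state.bond_vec_sq(i, j)
            if not (1 <= sq <= MAX_BOND_SQ):
                problems.append(f"loop bond ({i},{j}) has squared length {sq} (beyond cutoff)")
    return problems


def _bonded_neighbors(state: PolymerState, i: int) -> list[int]:
    nbs = []
    if i > 0:
        nbs.append(i - 1)
    if i < state.n - 1:
        nbs.append(i + 1)
    j = int(state.loop_partner[i])
    if j >= 0:
        nbs.append(j)
    return nbs


def propose_and_apply_move(
    state: PolymerState,
    config: LatticeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> MoveResult:
    """One elementary trial move.

    A monomer is chosen uniformly and a displacement uniformly among the 6
    nearest-neighbour directions.  The move is applied iff the (wrapped)
    target site is free and all bonds of the monomer — backbone and loop —
    remain allowed vectors; otherwise the state is unchanged.
    """
    config = config or state.config
    rng = rng or np.random.default_rng()
    L = config.L
    i = int(rng.integers(state.n))
    d = MOVE_DIRECTIONS[int(rng.integers(6))]
    new_pos = state.positions[i] + d
    site = tuple(new_pos % L)
    if state.occupancy[site] != -1:
        return MoveResult(False, i)
    for j in _bonded_neighbors(state, i):
        dv = state.positions[j] - new_pos
        if int(dv @ dv) > MAX_BOND_SQ:
            return MoveResult(False, i)
    old_site = tuple(state.positions[i] % L)
    state.occupancy[old_site] = -1
    state.occupancy[site] = i
    state.positions[i] = new_pos
    return MoveResult(True, i)


def neighbors_within_cutoff(
    state: PolymerState,
    i: int,
    config: LatticeConfig | None = None,
) -> np.ndarray:
    """Monomers within the loop cutoff of monomer i, excluding chain neighbours.

    Implemented by occupancy lookup of the 26 surrounding lattice sites (all
    sites within Euclidean distance sqrt(3)), so the cost is O(1) per call.
    """
    config = config or state.config
    L = config.L
    base = state.positions[i]
    out = []
    for v in BOND_VECTORS:
        site = tuple((base + v) % L)
        j = int(state.occupancy[site])
        if j >= 0 and j != i and abs(j - i) != 1:
            out.append(j)
    return np.array(sorted(out), dtype=np.intp)
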