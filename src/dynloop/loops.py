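"""Dynamic loop formation and dissociation.

Whenever a monomer moves into spatial proximity (within the bond cutoff) of
another monomer, the pair may form a transient bond — a chromatin loop —
with probability derived from the two monomers' interaction affinities.  A
formed bond is assigned a lifetime drawn from a Poisson distribution; once
the lifetime elapses, the bond dissociates.  No interaction potential is
involved: loop formation is probabilistic by construction, and only
short-range (pairs must already be co-localized by diffusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .expression import AffinityProfile
from .lattice import LatticeConfig, LoopBond, PolymerState, neighbors_within_cutoff

__all__ = [
    "LoopParams",
    "looping_probability",
    "sample_lifetime",
    "attempt_loop_formation",
    "expire_bonds",
]


@dataclass
class LoopParams:
    """Loop-dynamics parameters.

    ``mean_lifetime`` is the mean of the Poisson lifetime distribution in
    Monte-Carlo steps (8000 MCS by default).  ``combiner`` selects how the
    two monomer affinities combine into a pair probability; the default
    geometric mean reduces to the common affinity on a homogeneous fibre.
    """

    affinities: AffinityProfile
    mean_lifetime: float = 8000.0
    loops_enabled: bool = True
    combiner: str = "geometric"

    def __post_init__(self) -> None:
        if self.mean_lifetime < 0:
            raise ValueError("mean_lifetime must be >= 0")
        if self.combiner not in ("geometric", "product", "min"):
            raise ValueError(f"unknown affinity combiner {self.combiner!r}")


def looping_probability(a_i: float, a_j: float, combiner: str = "geometric") -> float:
    """Pair looping probability from two monomer affinities.

    The default symmetric combination is the geometric mean
    ``p_ij = sqrt(a_i * a_j)``: it equals the common affinity when the fibre
    is homogeneous and vanishes when either side has zero affinity.
    ``product`` and ``min`` are alternative combiners.
    """
    if not (0.0 <= a_i <= 1.0 and 0.0 <= a_j <= 1.0):
        raise ValueError("affinities must lie in [0, 1]")
    if combiner == "geometric":
        return math.sqrt(a_i * a_j)
    if combiner == "product":
        return a_i * a_j
    if combiner == "min":
        return min(a_i, a_j)
    raise ValueError(f"unknown affinity combiner {combiner!r}")


def sample_lifetime(mean: float, rng: np.random.Generator) -> int:
    """Draw a bond lifetime (in MCS) from a Poisson distribution."""
    if mean < 0:
        raise ValueError("mean lifetime must be >= 0")
    return int(rng.poisson(mean))


def attempt_loop_formation(
    state: PolymerState,
    moved_index: int,
    params: LoopParams,
    config: LatticeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LoopBond | None:
    """Event-driven loop-formation attempt for a monomer that just moved.

    Candidates are the loop-free monomers within the cutoff of the moved
    monomer (chain neighbours excluded).  One candidate is chosen uniformly
    and a bond formed with the pair looping probability; on success the bond
    expiry is the current MCS clock plus a Poisson lifetime.  Returns the
    bond formed, or None.
    """
    if not params.loops_enabled:
        return None
    if state.loop_partner[moved_index] >= 0:
        return None
    rng = rng or np.random.default_rng()
    candidates = neighbors_within_cutoff(state, moved_index, config)
    candidates = candidates[state.loop_partner[candidates] < 0]
    if candidates.size == 0:
        return None
    j = int(candidates[rng.integers(candidates.size)])
    aff = params.affinities.affinities
    p = looping_probability(float(aff[moved_index]), float(aff[j]), params.combiner)
    if rng.random() >= p:
        return None
    expiry = state.mcs_clock + sample_lifetime(params.mean_lifetime, rng)
    state.add_loop_bond(min(moved_index, j), max(moved_index, j), expiry)
    return LoopBond(min(moved_index, j), max(moved_index, j), expiry)


def expire_bonds(state: PolymerState) -> list[LoopBond]:
    """Dissociate every loop bond whose expiry has been reached.

    Expiry is inclusive: a bond with ``expiry_mcs <= mcs_clock`` is removed.
    Returns the removed bonds.
    """
    removed = []
    for bond in state.loop_bonds:
        if bond.expiry_mcs <= state.mcs_clock:
            state.remove_loop_bond(bond.i)
            removed.append(bond)
    return removed
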