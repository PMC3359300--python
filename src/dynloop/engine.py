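"""Monte-Carlo driver: MCS stepping, two-phase equilibration, production sampling.

One Monte-Carlo step (MCS) is N elementary trial moves, so each monomer is
translated once per MCS on average.  A simulation runs in three stages:

1. loop-free equilibration (loops rejected) — randomizes the grown chain;
2. looped equilibration (loops allowed) — relaxes into the looped ensemble;
3. production — snapshots saved every ``2*tau`` MCS, where ``tau`` is the
   autocorrelation time of the squared radius of gyration estimated from a
   pilot segment, so consecutive snapshots are effectively independent.

All randomness flows from a single numpy Generator seeded by
``SimParams.seed``; the jitted kernels draw a fresh sub-seed from that
stream at every invocation, making runs bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from scipy import stats
from statsmodels.tsa.stattools import acf as _acf

from . import _kernels
from .expression import AffinityProfile
from .lattice import LatticeConfig, PolymerState, init_random_chain
from .loops import LoopParams, attempt_loop_formation, expire_bonds
from .lattice import propose_and_apply_move

__all__ = [
    "SimParams",
    "Snapshot",
    "ConformationEnsemble",
    "Trajectory",
    "Simulation",
    "run_mcs",
    "equilibrate",
    "run_production",
    "merge_ensembles",
    "autocorrelation_time",
    "rg_squared",
    "stationarity_check",
]


@dataclass
class SimParams:
    """Parameters of one simulation run.

    Defaults follow the full-scale setup: lattice L=600, a_min=0.01,
    a_max=0.065 (calibrated range 0.06-0.07), Poisson mean bond lifetime
    8000 MCS, >=1000 conformations.  ``sample_interval=None`` selects the
    2*tau-auto policy; an integer fixes the snapshot spacing in MCS.
    """

    n_monomers: int
    lattice_size: int = 600
    a_min: float = 0.01
    a_max: float = 0.065
    mean_lifetime: float = 8000.0
    equilibration_mcs: int = 200_000
    n_conformations: int = 1000
    sample_interval: int | None = None
    pilot_mcs: int = 5000
    trajectory_every: int = 0
    formation_rule: str = "new_contact"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monomers < 2:
            raise ValueError("n_monomers must be >= 2")
        if self.equilibration_mcs <= 0:
            raise ValueError("equilibration_mcs must be > 0")
        if self.n_conformations < 1:
            raise ValueError("n_conformations must be >= 1")
        if self.sample_interval is not None and self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")
        if self.formation_rule not in ("new_contact", "per_move"):
            raise ValueError("formation_rule must be 'new_contact' or 'per_move'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Snapshot:
    """One saved conformation: MCS stamp, unwrapped coordinates, active loop bonds."""

    mcs: int
    positions: np.ndarray          # (N, 3) int64, unwrapped
    bonds: np.ndarray              # (M, 3) int64 rows (i, j, expiry_mcs), i < j


@dataclass
class ConformationEnsemble:
    """Independent conformations used for all ensemble-averaged observables."""

    snapshots: list[Snapshot]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ns = {s.positions.shape[0] for s in self.snapshots}
        if len(ns) > 1:
            raise ValueError("snapshots disagree on chain length")
        stamps = [s.mcs for s in self.snapshots]
        if any(b <= a for a, b in zip(stamps, stamps[1:])):
            raise ValueError("snapshot MCS stamps must be strictly increasing")

    @property
    def n_conformations(self) -> int:
        return len(self.snapshots)

    @property
    def n_monomers(self) -> int:
        return self.snapshots[0].positions.shape[0]

    def positions_array(self) -> np.ndarray:
        """(n_conformations, N, 3) float array of unwrapped coordinates."""
        return np.stack([s.positions for s in self.snapshots]).astype(float)

    def iter_bonds(self) -> Iterable[np.ndarray]:
        for s in self.snapshots:
            yield s.bonds


@dataclass
class Trajectory:
    """Densely sampled positions from one production run (for dynamics)."""

    times: np.ndarray              # (T,) MCS stamps
    positions: np.ndarray          # (T, N, 3) float, unwrapped
    frame_interval: int

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


def merge_ensembles(ensembles: "list[ConformationEnsemble]") -> "ConformationEnsemble":
    """Pool snapshots from independent replicate runs into one ensemble.

    MCS stamps are offset per replicate so they stay strictly increasing;
    provenance lists the replicate provenances.
    """
    if not ensembles:
        raise ValueError("nothing to merge")
    snaps: list[Snapshot] = []
    offset = 0
    for ens in ensembles:
        for s in ens.snapshots:
            snaps.append(Snapshot(mcs=s.mcs + offset, positions=s.positions, bonds=s.bonds))
        offset = snaps[-1].mcs + 1
    return ConformationEnsemble(
        snapshots=snaps,
        provenance={"replicates": [e.provenance for e in ensembles]},
    )


def rg_squared(positions: np.ndarray) -> float:
    """Squared radius of gyration of one conformation."""
    p = np.asarray(positions, dtype=float)
    return float(((p - p.mean(axis=0)) ** 2).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# stepping


def _kernel_step(
    state: PolymerState,
    affinities: np.ndarray,
    loops_enabled: bool,
    mean_lifetime: float,
    n_mcs: int,
    rng: np.random.Generator,
    record_rg2: bool = False,
    new_contact_only: bool = True,
) -> tuple[np.ndarray, int]:
    """Advance the state by n_mcs MCS with the jitted kernel."""
    _kernels.seed_kernel_rng(int(rng.integers(2**31 - 1)))
    rg2_out = np.empty(n_mcs if record_rg2 else 0, dtype=np.float64)
    accept = np.zeros(1, dtype=np.int64)
    state.mcs_clock = _kernels.run_mcs_kernel(
        state.positions,
        state.occupancy,
        state.loop_partner,
        state.loop_expiry,
        affinities,
        state.config.L,
        state.mcs_clock,
        n_mcs,
        float(mean_lifetime),
        loops_enabled,
        new_contact_only,
        rg2_out,
        accept,
    )
    return rg2_out, int(accept[0])


def run_mcs(
    state: PolymerState,
    loop_params: LoopParams | None = None,
    config: LatticeConfig | None = None,
    rng: np.random.Generator | None = None,
    n_mcs: int = 1,
    use_kernel: bool = True,
    move_log: list | None = None,
) -> PolymerState:
    """Run ``n_mcs`` Monte-Carlo steps of N trial moves each.

    After every accepted move a loop-formation attempt is made (if enabled);
    expired bonds are swept once per MCS and the clock advances by one.
    ``use_kernel=False`` selects the pure-Python reference path, which can
    log every trial move into ``move_log``.  Note the kernel implements the
    default geometric-mean affinity combiner; alternative combiners require
    the Python path.
    """
    config = config or state.config
    rng = rng or np.random.default_rng()
    loops_on = loop_params is not None and loop_params.loops_enabled
    if use_kernel and move_log is None:
        aff = (
            loop_params.affinities.affinities
            if loops_on
            else np.zeros(state.n, dtype=np.float64)
        )
        mean_life = loop_params.mean_lifetime if loop_params is not None else 0.0
        _kernel_step(state, np.ascontiguousarray(aff, dtype=np.float64),
                     loops_on, mean_life, n_mcs, rng)
        return state
    for _ in range(n_mcs):
        for _ in range(state.n):
            result = propose_and_apply_move(state, config, rng)
            if move_log is not None:
                move_log.append(result)
            if result.accepted and loops_on:
                attempt_loop_formation(state, result.moved_index, loop_params, config, rng)
        expire_bonds(state)
        state.mcs_clock += 1
    return state


# ---------------------------------------------------------------------------
# equilibration


def equilibrate(
    state: PolymerState,
    params: SimParams,
    affinities: AffinityProfile | None,
    config: LatticeConfig | None = None,
    rng: np.random.Generator | None = None,
    record_rg2: bool = False,
) -> tuple[PolymerState, np.ndarray, np.ndarray]:
    """Two-phase equilibration.

    Phase 1 runs ``equilibration_mcs`` MCS with loop formation rejected,
    yielding a random loop-free conformation; phase 2 runs the same number
    of MCS with loops allowed (skipped if no affinities are given).  Returns
    the state plus the per-MCS R_g^2 series of both phases (empty unless
    ``record_rg2``).
    """
    config = config or state.config
    rng = rng or np.random.default_rng(params.seed)
    new_contact = params.formation_rule == "new_contact"
    zeros = np.zeros(state.n, dtype=np.float64)
    rg2_a, _ = _kernel_step(
        state, zeros, False, 0.0, params.equilibration_mcs, rng, record_rg2,
        new_contact_only=new_contact,
    )
    if affinities is not None:
        aff = np.ascontiguousarray(affinities.affinities, dtype=np.float64)
        rg2_b, _ = _kernel_step(
            state, aff, True, params.mean_lifetime, params.equilibration_mcs, rng,
            record_rg2, new_contact_only=new_contact,
        )
    else:
        rg2_b = np.empty(0)
    return state, rg2_a, rg2_b


def stationarity_check(series: np.ndarray, alpha: float = 0.01) -> tuple[bool, float]:
    """Mann-Kendall-style trend test on an equilibration time series.

    Uses Kendall's tau of the series against time; returns (stationary,
    p_value) where stationary means no significant monotone trend at the
    given level.  Intended for the late part of the phase-1 R_g^2 series.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short for a trend test")
    # successive MCS values of R_g^2 are strongly autocorrelated; thin by the
    # estimated correlation time so the trend test sees ~independent samples
    try:
        tau = autocorrelation_time(x)
    except ValueError:
        tau = 1.0
    step = max(1, math.ceil(tau))
    xs = x[::step]
    if xs.size < 8:
        raise ValueError(
            "series too short relative to its correlation time "
            f"(~{tau:.0f}) for a trend test"
        )
    kt, p = stats.kendalltau(np.arange(xs.size), xs)
    return bool(p > alpha), float(p)


# ---------------------------------------------------------------------------
# autocorrelation time


def autocorrelation_time(series: np.ndarray, min_fit_lags: int = 5) -> float:
    """Autocorrelation time from an exponential fit to the initial ACF decay.

    The normalized autocorrelation function is fitted as ``C(t) ~ exp(-t/tau)``
    (least squares on log C) over lags up to the first crossing of 1/e^2,
    with a minimum window of ``min_fit_lags`` lags; the two-decade window
    leaves a pure exponential decay exact while giving slow relaxation modes
    of a multi-exponential ACF enough weight that 2*tau spacing actually
    decorrelates.  If the ACF already drops below 1/e at lag 1 the decay is
    sub-lag and tau is estimated from that single lag (white noise yields
    tau < 1).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 10:
        raise ValueError("series too short to estimate an autocorrelation time")
    if np.ptp(x) == 0:
        raise ValueError("constant series has no autocorrelation time")
    nlags = min(x.size - 2, max(min_fit_lags, x.size // 4))
    c = _acf(x, nlags=nlags, fft=True)
    inv_e = 1.0 / math.e
    if c[1] <= inv_e:
        if c[1] <= 0:
            return 0.1
        return -1.0 / math.log(c[1])
    below = np.nonzero(c[1:] < inv_e**2)[0]
    k_end = int(below[0]) + 1 if below.size else nlags
    k_end = min(max(k_end, min_fit_lags), nlags)
    lags = np.arange(1, k_end + 1)
    vals = c[1 : k_end + 1]
    keep = vals > 0
    if keep.sum() < 2:
        return float(k_end)
    slope = np.polyfit(lags[keep], np.log(vals[keep]), 1)[0]
    if slope >= 0:
        return float(k_end)
    return float(-1.0 / slope)


# ---------------------------------------------------------------------------
# production


def run_production(
    state: PolymerState,
    params: SimParams,
    affinities: AffinityProfile | None,
    config: LatticeConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ConformationEnsemble, Trajectory | None]:
    """Generate the conformation ensemble from an equilibrated state.

    Under the 2*tau-auto policy (``sample_interval=None``) tau is estimated
    from the R_g^2 series of a pilot segment and snapshots are saved every
    ``ceil(2*tau)`` MCS until ``n_conformations`` are collected.  If
    ``trajectory_every > 0`` a dense position stream is recorded alongside
    for dynamics (MSMD) analysis.
    """
    config = config or state.config
    rng = rng or np.random.default_rng(params.seed)
    loops_on = affinities is not None
    aff = (
        np.ascontiguousarray(affinities.affinities, dtype=np.float64)
        if loops_on
        else np.zeros(state.n, dtype=np.float64)
    )
    mean_life = params.mean_lifetime if loops_on else 0.0
    new_contact = params.formation_rule == "new_contact"

    if params.sample_interval is not None:
        interval = int(params.sample_interval)
        tau = None
    else:
        pilot_rg2, _ = _kernel_step(
            state, aff, loops_on, mean_life, params.pilot_mcs, rng, record_rg2=True,
            new_contact_only=new_contact,
        )
        tau = autocorrelation_time(pilot_rg2)
        interval = max(1, math.ceil(2.0 * tau))

    snapshots: list[Snapshot] = []
    traj_times: list[int] = []
    traj_pos: list[np.ndarray] = []
    t_every = int(params.trajectory_every)
    t0 = state.mcs_clock
    next_snap = t0 + interval
    next_frame = t0 + t_every if t_every > 0 else None
    while len(snapshots) < params.n_conformations:
        target = next_snap if next_frame is None else min(next_snap, next_frame)
        chunk = target - state.mcs_clock
        if chunk > 0:
            _kernel_step(state, aff, loops_on, mean_life, chunk, rng,
                         new_contact_only=new_contact)
        if next_frame is not None and state.mcs_clock >= next_frame:
            traj_times.append(state.mcs_clock)
            traj_pos.append(state.positions.astype(float).copy())
            next_frame += t_every
        if state.mcs_clock >= next_snap:
            bonds = np.array(
                [[b.i, b.j, b.expiry_mcs] for b in state.loop_bonds], dtype=np.int64
            ).reshape(-1, 3)
            snapshots.append(
                Snapshot(mcs=state.mcs_clock, positions=state.positions.copy(), bonds=bonds)
            )
            next_snap += interval

    provenance = {
        "params": params.to_dict(),
        "sample_interval": interval,
        "tau_estimate": tau,
        "loops_enabled": loops_on,
    }
    ensemble = ConformationEnsemble(snapshots=snapshots, provenance=provenance)
    trajectory = None
    if t_every > 0 and traj_times:
        trajectory = Trajectory(
            times=np.array(traj_times, dtype=np.int64),
            positions=np.stack(traj_pos),
            frame_interval=t_every,
        )
    return ensemble, trajectory


# ---------------------------------------------------------------------------
# orchestration


class Simulation:
    """End-to-end simulation of one chain.

    ``affinities`` may be an :class:`AffinityProfile`, a float (homogeneous
    fibre with that affinity), or None (pure self-avoiding chain, loops
    disabled).  The full pipeline is: grow a random chain, two-phase
    equilibration, production sampling.
    """

    def __init__(
        self,
        params: SimParams,
        affinities: AffinityProfile | float | None = None,
        config: LatticeConfig | None = None,
    ):
        if isinstance(affinities, (int, float)):
            a = float(affinities)
            affinities = AffinityProfile(
                affinities=np.full(params.n_monomers, a), a_min=a, a_max=a
            )
        if affinities is not None and affinities.n_monomers != params.n_monomers:
            raise ValueError("affinity profile length does not match n_monomers")
        self.params = params
        self.affinities = affinities
        self.config = config or LatticeConfig(L=params.lattice_size)
        self.rng = np.random.default_rng(params.seed)
        self.state: PolymerState | None = None
        self.equilibration_rg2: tuple[np.ndarray, np.ndarray] | None = None

    def initialize(self) -> PolymerState:
        self.state = init_random_chain(self.params.n_monomers, self.config, self.rng)
        return self.state

    def equilibrate(self, record_rg2: bool = False) -> PolymerState:
        if self.state is None:
            self.initialize()
        self.state, rg2_a, rg2_b = equilibrate(
            self.state, self.params, self.affinities, self.config, self.rng, record_rg2
        )
        self.equilibration_rg2 = (rg2_a, rg2_b)
        return self.state

    def run(self, record_rg2: bool = False) -> tuple[ConformationEnsemble, Trajectory | None]:
        self.equilibrate(record_rg2=record_rg2)
        return run_production(
            self.state, self.params, self.affinities, self.config, self.rng
        )
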