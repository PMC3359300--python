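"""Ensemble and trajectory observables for simulated chromosome conformations.

Everything here averages over an ensemble of independent conformations
(interpreted as averaging over many cells) or over a densely sampled
trajectory (for dynamics).  Distances are in lattice units unless converted
with a :func:`lattice_scaling` factor; genomic separations convert at
0.15 Mb per monomer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial import ConvexHull, QhullError

from .engine import ConformationEnsemble, Trajectory
from .expression import MONOMER_MB, BinnedExpression, RegionSet

__all__ = [
    "MSDCurve",
    "LoopDistribution",
    "ShapeResult",
    "DensityField",
    "RadialMetrics",
    "MSMDCurve",
    "msd_total",
    "msd_loci",
    "loop_size_distribution",
    "fit_loop_exponent",
    "local_density_gkde",
    "volume_ratio",
    "gyration_tensor",
    "asphericity",
    "shape_of",
    "radial_metrics",
    "msmd",
    "correlate_with_expression",
    "lattice_scaling",
]


# ---------------------------------------------------------------------------
# mean square spatial distance


@dataclass
class MSDCurve:
    """Mean square spatial distance vs. contour separation.

    ``separation`` is in monomers (convert to Mb at 0.15 Mb per monomer);
    ``msd`` in squared lattice units unless scaled.
    """

    separation: np.ndarray
    msd: np.ndarray

    def separation_mb(self, monomer_mb: float = MONOMER_MB) -> np.ndarray:
        return self.separation * monomer_mb


def msd_total(ensemble: ConformationEnsemble) -> MSDCurve:
    """Average squared spatial distance between monomer pairs at every
    contour separation n, over all pair positions and all conformations."""
    if ensemble.n_conformations < 2:
        raise ValueError("need at least 2 conformations")
    pos = ensemble.positions_array()          # (Nc, N, 3)
    n_mono = pos.shape[1]
    msd = np.zeros(n_mono)
    for n in range(1, n_mono):
        d = pos[:, n:, :] - pos[:, :-n, :]
        msd[n] = np.mean(np.sum(d * d, axis=2))
    return MSDCurve(separation=np.arange(n_mono), msd=msd)


def msd_loci(
    ensemble: ConformationEnsemble, loci_pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Locus-specific MSD: ensemble mean of |r_k - r_i|^2 per requested pair.

    Mirrors what FISH provides — distances only between marked loci.
    """
    pos = ensemble.positions_array()
    n_mono = pos.shape[1]
    out = np.empty(len(loci_pairs))
    for idx, (i, k) in enumerate(loci_pairs):
        if not (0 <= i < n_mono and 0 <= k < n_mono):
            raise IndexError(f"locus pair ({i}, {k}) out of range for N={n_mono}")
        d = pos[:, k, :] - pos[:, i, :]
        out[idx] = np.mean(np.sum(d * d, axis=1))
    return out


# ---------------------------------------------------------------------------
# loop-size distribution


@dataclass
class LoopDistribution:
    """Empirical distribution of loop lengths g = j - i over active bonds."""

    g: np.ndarray                  # observed loop lengths (monomers)
    counts: np.ndarray
    p: np.ndarray                  # normalized probability, sums to 1
    n_monomers: int

    def g_mb(self, monomer_mb: float = MONOMER_MB) -> np.ndarray:
        return self.g * monomer_mb


def loop_size_distribution(
    ensemble: ConformationEnsemble | None = None,
    bond_log: np.ndarray | None = None,
    n_monomers: int | None = None,
    restrict_to: np.ndarray | None = None,
) -> LoopDistribution:
    """Histogram of loop lengths over active bonds in the ensemble snapshots.

    Alternatively a bond-event log (rows ``(i, j, ...)``) may be supplied.
    ``restrict_to`` keeps only bonds with at least one endpoint in the given
    monomer index set (for region-specific distributions).
    """
    if ensemble is not None:
        n_monomers = ensemble.n_monomers
        rows = [b[:, :2] for b in ensemble.iter_bonds() if b.size]
        if not rows:
            raise ValueError("no loop bonds observed in the ensemble")
        ij = np.concatenate(rows)
    elif bond_log is not None:
        if n_monomers is None:
            raise ValueError("n_monomers required with a bond log")
        ij = np.asarray(bond_log)[:, :2]
        if ij.size == 0:
            raise ValueError("empty bond log")
    else:
        raise ValueError("supply an ensemble or a bond log")
    if restrict_to is not None:
        sel = np.isin(ij[:, 0], restrict_to) | np.isin(ij[:, 1], restrict_to)
        ij = ij[sel]
        if ij.shape[0] == 0:
            raise ValueError("no loop bonds touch the requested region")
    g = np.abs(ij[:, 1] - ij[:, 0]).astype(np.int64)
    vals, counts = np.unique(g, return_counts=True)
    p = counts / counts.sum()
    return LoopDistribution(g=vals, counts=counts, p=p, n_monomers=int(n_monomers))


def fit_loop_exponent(
    dist: LoopDistribution,
    fit_range_mb: tuple[float, float] = (0.5, 7.0),
    monomer_mb: float = MONOMER_MB,
) -> float:
    """Power-law exponent alpha of the short-loop regime.

    The raw probability carries the combinatorial factor (N - g) — the
    number of ways a loop of length g fits on a chain of N monomers — which
    is divided out before fitting ``log(P/(N-g))`` against ``log g`` by
    least squares over the given genomic range.
    """
    g_mb = dist.g * monomer_mb
    mask = (
        (g_mb >= fit_range_mb[0])
        & (g_mb <= fit_range_mb[1])
        & (dist.p > 0)
        & (dist.g < dist.n_monomers)
    )
    if mask.sum() < 4:
        raise ValueError(
            f"need >= 4 loop-length points in {fit_range_mb} Mb, got {int(mask.sum())}"
        )
    x = np.log(g_mb[mask])
    y = np.log(dist.p[mask] / (dist.n_monomers - dist.g[mask]))
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


# ---------------------------------------------------------------------------
# local density (3D Gaussian kernel density estimation)


@dataclass
class DensityField:
    """Ensemble-averaged local density at each monomer position."""

    rho: np.ndarray
    bandwidth_factor: float        # Scott factor of the last conformation


def local_density_gkde(ensemble: ConformationEnsemble) -> DensityField:
    """Local chromatin density via 3D Gaussian kernel density estimation.

    Per conformation, a Gaussian KDE (Scott's bandwidth rule) is fitted to
    the N monomer positions and evaluated at those same positions; the
    per-monomer densities are then averaged over the ensemble.  High density
    marks locally compact chromatin.
    """
    pos = ensemble.positions_array()
    rho = np.zeros(pos.shape[1])
    factor = float("nan")
    for conf in pos:
        kde = stats.gaussian_kde(conf.T)
        rho += kde(conf.T)
        factor = float(kde.factor)
    rho /= pos.shape[0]
    return DensityField(rho=rho, bandwidth_factor=factor)


def volume_ratio(density: DensityField, regions: RegionSet) -> float:
    """Occupied-volume ratio V_high / V_low of the two region classes.

    Volumes are inversely proportional to mean densities, so the ratio is
    computed as ``mean(rho_low) / mean(rho_high)``; values above 1 mean the
    highly expressed chromatin occupies more space per monomer.
    """
    if not (regions.has("high") and regions.has("low")):
        raise ValueError("need both 'high' and 'low' regions")
    hi = regions.indices("high")
    lo = regions.indices("low")
    return float(np.mean(density.rho[lo]) / np.mean(density.rho[hi]))


# ---------------------------------------------------------------------------
# shape: gyration tensor and asphericity


@dataclass
class ShapeResult:
    """Gyration tensor, its eigenvalues, asphericity and R_g^2."""

    Q: np.ndarray
    eigenvalues: np.ndarray
    asphericity: float
    rg2: float


def gyration_tensor(coords: np.ndarray) -> np.ndarray:
    """Centered second-moment (gyration) tensor of a point set.

    Q_ab = (1/M) sum_k (r_k,a - rbar_a)(r_k,b - rbar_b); symmetric PSD,
    trace(Q) = R_g^2.
    """
    r = np.asarray(coords, dtype=float)
    if r.ndim != 2 or r.shape[1] != 3 or r.shape[0] < 1:
        raise ValueError("coords must be (M, 3) with M >= 1")
    c = r - r.mean(axis=0)
    return (c.T @ c) / r.shape[0]


def asphericity(eigenvalues: np.ndarray) -> float:
    """Normalized asphericity of gyration-tensor eigenvalues.

    A = [(l1-l2)^2 + (l2-l3)^2 + (l3-l1)^2] / [2 (l1+l2+l3)^2]

    A = 0 for a perfectly spherical (isotropic) distribution, A = 1 for a
    rod; scale-invariant.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if lam.size != 3:
        raise ValueError("need exactly 3 eigenvalues")
    if np.any(lam < -1e-9 * max(1.0, lam.max())):
        raise ValueError("gyration-tensor eigenvalues must be non-negative")
    lam = np.clip(lam, 0.0, None)
    s = lam.sum()
    if s == 0:
        raise ValueError("all eigenvalues zero: shape undefined")
    num = (lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2
    return float(num / (2.0 * s * s))


def shape_of(coords: np.ndarray) -> ShapeResult:
    """Full shape analysis of one point set (or one chain region)."""
    Q = gyration_tensor(coords)
    lam = np.linalg.eigvalsh(Q)
    return ShapeResult(
        Q=Q,
        eigenvalues=lam,
        asphericity=asphericity(lam) if lam.sum() > 0 else 0.0,
        rg2=float(np.trace(Q)),
    )


def mean_asphericity(
    ensemble: ConformationEnsemble, indices: np.ndarray | None = None
) -> float:
    """Ensemble-mean asphericity of the whole chain or of a monomer subset."""
    pos = ensemble.positions_array()
    if indices is not None:
        pos = pos[:, indices, :]
    return float(np.mean([shape_of(conf).asphericity for conf in pos]))


# ---------------------------------------------------------------------------
# radial positioning inside the territory


@dataclass
class RadialMetrics:
    """Per-monomer mean squared distance to territory center and surface."""

    center_sq: np.ndarray
    surface_sq: np.ndarray


def _hull_surface_distance(points: np.ndarray) -> np.ndarray:
    """Distance from each point to the convex-hull surface of the point set."""
    try:
        hull = ConvexHull(points)
    except QhullError:
        hull = ConvexHull(points, qhull_options="QJ")
    # hull facet planes: eq . (p, 1) <= 0 inside; distance = |eq[:3].p + eq[3]|
    d = points @ hull.equations[:, :3].T + hull.equations[:, 3]
    return np.min(np.abs(d), axis=1)


def radial_metrics(ensemble: ConformationEnsemble) -> RadialMetrics:
    """Squared distance of each monomer to the territory center-of-mass and
    to the territory surface (convex hull of the conformation), averaged
    over the ensemble."""
    pos = ensemble.positions_array()
    n_c, n_m, _ = pos.shape
    center_sq = np.zeros(n_m)
    surface_sq = np.zeros(n_m)
    for conf in pos:
        com = conf.mean(axis=0)
        center_sq += np.sum((conf - com) ** 2, axis=1)
        surface_sq += _hull_surface_distance(conf) ** 2
    return RadialMetrics(center_sq=center_sq / n_c, surface_sq=surface_sq / n_c)


# ---------------------------------------------------------------------------
# mobility: mean square monomer displacement


@dataclass
class MSMDCurve:
    """Mean square monomer displacement vs. lag time, per region label."""

    lag_mcs: np.ndarray
    msmd: dict[str, np.ndarray]

    def diagnostic(self, label: str = "total") -> np.ndarray:
        """MSMD(t)/t — constant for normal diffusion, decaying if anomalous."""
        return self.msmd[label] / self.lag_mcs


def msmd(
    trajectory: Trajectory,
    regions: RegionSet | None = None,
    edge_exclusion: float = 0.05,
    max_lag_frames: int | None = None,
    relative_to_com: bool = True,
) -> MSMDCurve:
    """Mobility of monomers inside the territory.

    The displacement of monomer i over lag t is measured relative to the
    chain center-of-mass, so rigid translation of the whole territory does
    not contribute.  Averages run over all time origins and over the
    monomers of each region; a fraction ``edge_exclusion`` of monomers at
    each chain end is excluded (chain ends diffuse differently).
    ``relative_to_com=False`` measures absolute displacements instead.
    """
    frames = trajectory.positions
    n_frames, n_mono, _ = frames.shape
    if n_frames < 3:
        raise ValueError("trajectory too short for displacement analysis")
    rel = frames - frames.mean(axis=1, keepdims=True) if relative_to_com else frames

    n_edge = int(edge_exclusion * n_mono)
    interior = np.arange(n_edge, n_mono - n_edge)
    groups: dict[str, np.ndarray] = {"total": interior}
    if regions is not None:
        for label in ("high", "low"):
            if regions.has(label):
                idx = regions.indices(label)
                groups[label] = idx[(idx >= n_edge) & (idx < n_mono - n_edge)]

    n_lags = max_lag_frames or max(1, n_frames // 2)
    n_lags = min(n_lags, n_frames - 1)
    lag_mcs = np.arange(1, n_lags + 1) * trajectory.frame_interval
    per_mono = np.zeros((n_lags, n_mono))
    for ell in range(1, n_lags + 1):
        d = rel[ell:] - rel[:-ell]
        per_mono[ell - 1] = np.mean(np.sum(d * d, axis=2), axis=0)
    curves = {label: per_mono[:, idx].mean(axis=1) for label, idx in groups.items()}
    return MSMDCurve(lag_mcs=lag_mcs, msmd=curves)


# ---------------------------------------------------------------------------
# correlation with expression


def correlate_with_expression(
    metric: np.ndarray, expression: BinnedExpression | np.ndarray
) -> dict[str, float]:
    """Pearson and Spearman correlation of a per-monomer metric with the
    expression profile, with two-sided p-values."""
    levels = expression.levels if isinstance(expression, BinnedExpression) else np.asarray(expression, float)
    metric = np.asarray(metric, dtype=float)
    if metric.shape != levels.shape:
        raise ValueError("metric and expression lengths differ")
    if metric.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(metric) == 0 or np.ptp(levels) == 0:
        raise ValueError("correlation undefined for constant input")
    pr = stats.pearsonr(metric, levels)
    sr = stats.spearmanr(metric, levels)
    return {
        "pearson": float(pr.statistic),
        "pearson_p": float(pr.pvalue),
        "spearman": float(sr.statistic),
        "spearman_p": float(sr.pvalue),
    }


# ---------------------------------------------------------------------------
# lattice-to-physical scaling


def lattice_scaling(
    sim_msd: MSDCurve,
    exp_table: np.ndarray,
    monomer_mb: float = MONOMER_MB,
) -> float:
    """Scaling factor s (micrometres per lattice unit) matching simulated to
    experimental MSD.

    ``exp_table`` has rows (genomic separation in Mb, MSD in um^2).  The
    simulated curve is interpolated to the experimental separations and s
    minimizes sum (s^2 * MSD_lattice - MSD_um)^2, which has the closed form
    s^2 = sum(m_lat * m_um) / sum(m_lat^2).
    """
    exp_table = np.asarray(exp_table, dtype=float)
    if exp_table.ndim != 2 or exp_table.shape[1] < 2 or exp_table.shape[0] < 1:
        raise ValueError("exp_table must be rows of (Mb, um^2)")
    sim_mb = sim_msd.separation_mb(monomer_mb)
    mb = exp_table[:, 0]
    if mb.min() < sim_mb.min() or mb.max() > sim_mb.max():
        raise ValueError("experimental separations outside the simulated support")
    m_lat = np.interp(mb, sim_mb, sim_msd.msd)
    m_um = exp_table[:, 1]
    denom = float(np.sum(m_lat**2))
    if denom == 0:
        raise ValueError("simulated MSD vanishes on the experimental support")
    s2 = float(np.sum(m_lat * m_um)) / denom
    if s2 <= 0:
        raise ValueError("non-positive scaling; check the input tables")
    return math.sqrt(s2)
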