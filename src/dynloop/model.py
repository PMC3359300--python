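"""High-level modelling interface: build a model from expression data, run
it, and summarize the resulting conformations.

:class:`DynamicLoopModel` owns the parameters (expression-derived affinity
profile, lattice, loop dynamics); :meth:`DynamicLoopModel.simulate` runs
the full pipeline and returns a :class:`SimulationResults` whose methods
lazily compute the observables and whose :meth:`SimulationResults.summary`
prints the standard per-chromosome structural parameters (loop fraction,
volume ratio, loop exponents, asphericities, correlations).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import pandas as pd

from .engine import ConformationEnsemble, SimParams, Simulation, Trajectory
from .expression import (
    AffinityProfile,
    BinnedExpression,
    RegionSet,
    affinity_profile,
    bin_to_monomers,
    read_expression_table,
)
from . import observables as obs

__all__ = ["DynamicLoopModel", "SimulationResults"]


class DynamicLoopModel:
    """Dynamic-loop chromatin model for one chromosome.

    Parameters
    ----------
    expression
        Binned per-monomer expression levels (or None for a homogeneous
        fibre at affinity ``(a_min + a_max) / 2``).
    a_min, a_max
        Affinity bounds: the most expressed monomer gets ``a_min``, an
        unexpressed one ``a_max``.
    mean_lifetime
        Poisson mean loop-bond lifetime in MCS.
    """

    def __init__(
        self,
        expression: BinnedExpression | None,
        a_min: float = 0.01,
        a_max: float = 0.065,
        mean_lifetime: float = 8000.0,
        lattice_size: int = 600,
        n_monomers: int | None = None,
    ):
        self.expression = expression
        if expression is not None:
            self.affinities: AffinityProfile = affinity_profile(expression, a_min, a_max)
            n_monomers = expression.n_monomers
        else:
            if n_monomers is None:
                raise ValueError("n_monomers required without an expression profile")
            a = 0.5 * (a_min + a_max)
            self.affinities = AffinityProfile(
                affinities=np.full(n_monomers, a), a_min=a, a_max=a
            )
        self.n_monomers = n_monomers
        self.a_min = a_min
        self.a_max = a_max
        self.mean_lifetime = mean_lifetime
        self.lattice_size = lattice_size

    @classmethod
    def from_expression_table(
        cls,
        path: str,
        chrom_length_bp: int,
        chromosome: str | None = None,
        **kwargs,
    ) -> "DynamicLoopModel":
        profile = read_expression_table(path, chromosome)
        binned = bin_to_monomers(profile, chrom_length_bp)
        return cls(binned, **kwargs)

    def simulate(
        self,
        n_conformations: int = 1000,
        equilibration_mcs: int = 200_000,
        sample_interval: int | None = None,
        trajectory_every: int = 0,
        pilot_mcs: int = 5000,
        seed: int = 0,
    ) -> "SimulationResults":
        params = SimParams(
            n_monomers=self.n_monomers,
            lattice_size=self.lattice_size,
            a_min=self.a_min,
            a_max=self.a_max,
            mean_lifetime=self.mean_lifetime,
            equilibration_mcs=equilibration_mcs,
            n_conformations=n_conformations,
            sample_interval=sample_interval,
            pilot_mcs=pilot_mcs,
            trajectory_every=trajectory_every,
            seed=seed,
        )
        sim = Simulation(params, self.affinities)
        ensemble, trajectory = sim.run()
        return SimulationResults(self, ensemble, trajectory)


@dataclass
class SimulationResults:
    """Conformation ensemble plus lazily computed observables."""

    model: DynamicLoopModel
    ensemble: ConformationEnsemble
    trajectory: Trajectory | None = None

    @cached_property
    def msd(self) -> obs.MSDCurve:
        return obs.msd_total(self.ensemble)

    @cached_property
    def density(self) -> obs.DensityField:
        return obs.local_density_gkde(self.ensemble)

    @cached_property
    def radial(self) -> obs.RadialMetrics:
        return obs.radial_metrics(self.ensemble)

    @cached_property
    def loop_distribution(self) -> obs.LoopDistribution:
        return obs.loop_size_distribution(self.ensemble)

    def loop_fraction(self) -> float:
        """Mean number of active loops per monomer, in percent."""
        counts = [b.shape[0] for b in self.ensemble.iter_bonds()]
        return 100.0 * float(np.mean(counts)) / self.ensemble.n_monomers

    def summary(
        self,
        regions: RegionSet | None = None,
        fit_range_mb: tuple[float, float] = (0.5, 7.0),
    ) -> pd.Series:
        """Standard structural parameters of the simulated chromosome.

        With a region set, also reports region-specific loop exponents,
        asphericities, the high/low volume ratio and, if an expression
        profile is attached, density/positioning correlations.
        """
        out: dict[str, float] = {}
        out["n_conformations"] = float(self.ensemble.n_conformations)
        out["loops_per_length_pct"] = self.loop_fraction()
        out["asphericity_total"] = obs.mean_asphericity(self.ensemble)
        try:
            out["loop_exponent_total"] = obs.fit_loop_exponent(
                self.loop_distribution, fit_range_mb
            )
        except ValueError:
            out["loop_exponent_total"] = float("nan")
        if regions is not None:
            for label in ("high", "low"):
                if not regions.has(label):
                    continue
                idx = regions.indices(label)
                out[f"asphericity_{label}"] = obs.mean_asphericity(self.ensemble, idx)
                try:
                    dist = obs.loop_size_distribution(self.ensemble, restrict_to=idx)
                    out[f"loop_exponent_{label}"] = obs.fit_loop_exponent(dist, fit_range_mb)
                except ValueError:
                    out[f"loop_exponent_{label}"] = float("nan")
            if regions.has("high") and regions.has("low"):
                out["volume_ratio_high_low"] = obs.volume_ratio(self.density, regions)
        if self.model.expression is not None:
            expr = self.model.expression
            for name, metric in (
                ("density", self.density.rho),
                ("dist2_center", self.radial.center_sq),
                ("dist2_surface", self.radial.surface_sq),
            ):
                corr = obs.correlate_with_expression(metric, expr)
                out[f"pearson_{name}"] = corr["pearson"]
                out[f"spearman_{name}"] = corr["spearman"]
        return pd.Series(out, name="dynamic-loop summary")
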