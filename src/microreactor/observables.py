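"""Output quantities of a reactor simulation.

The design-relevant observables are the outflow rate of G6P through the
export membrane,

    outflow(t) = int_{Gamma_e} -D grad(y_G6P) . nu  dsigma     (mol/s),

the per-species production rate at the bead surfaces,

    production_j(t) = int_{Gamma_b} D_j grad(y_j) . nu  dsigma  (mol/s),

and the design objective J = int_0^T outflow(t) dt (mol), integrated with the
implicit-Euler-consistent right-endpoint rectangle rule on the accepted-step
grid.  All boundary integrals are evaluated from the locally conservative RT0
flux unknowns; at a converged state they coincide with the kinetics-form
boundary integrals (theta_e int r_G6P, int R_j^b) to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from microreactor.geometry import BoundaryTag

__all__ = [
    "RateTimeSeries",
    "outflow_rate",
    "outflow_rate_kinetic",
    "production_rate",
    "production_rate_vector",
    "total_outflow",
    "time_to_half_rate",
    "plot_rates",
    "global_mass_balance_residual",
    "NOT_REACHED",
]

#: Sentinel returned by :func:`time_to_half_rate` when the threshold is never met.
NOT_REACHED = float("inf")

_SE_COLUMNS = ("prod_G", "prod_F", "prod_F6P", "prod_Pi", "prod_G6P")


def outflow_rate(sim, state, species: int = None) -> float:
    """Diffusive outflow (mol/s) of one species through Gamma_e, from the
    flux unknowns.  ``species`` defaults to the last one (G6P in the SE
    ordering)."""
    facets = sim.export_facets
    if len(facets) == 0:
        raise ValueError("mesh has no export boundary (Gamma_e)")
    j = sim.n_sp - 1 if species is None else species
    q = sim.boundary_flux(state, facets)
    return float(q[j] @ sim.mesh.facet_length[facets])


def outflow_rate_kinetic(sim, state, species: int = None) -> float:
    """Outflow evaluated from the membrane kinetics, theta_e * int(-R_j^e);
    equals :func:`outflow_rate` at any converged state (boundary-condition
    identity)."""
    facets = sim.export_facets
    j = sim.n_sp - 1 if species is None else species
    Re = sim.reaction.export_rates(state.trace[:, facets])
    return float(-sim.transport.theta_e * Re[j] @ sim.mesh.facet_length[facets])


def production_rate_vector(sim, state) -> np.ndarray:
    """Net production rate (mol/s) of every species at the bead surfaces.

    On a bead-free (bulk kinetics) chamber this returns the bulk-integrated
    reaction rates instead.
    """
    if sim.bulk_scale is not None:
        R = sim.reaction.bead_rates(state.y) * sim.bulk_scale
        return R @ sim.mesh.tri_area
    facets = sim.bead_facets
    if len(facets) == 0:
        return np.zeros(sim.n_sp)
    q = sim.boundary_flux(state, facets)
    return -(q @ sim.mesh.facet_length[facets])


def production_rate(sim, state, species: int) -> float:
    return float(production_rate_vector(sim, state)[species])


@dataclass
class RateTimeSeries:
    """Production / outflow rates on the accepted-step time grid."""

    times: np.ndarray       # (n,), strictly increasing, starts at 0
    production: np.ndarray  # (n, n_species), mol/s
    outflow: np.ndarray     # (n,), mol/s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.production = np.asarray(self.production, dtype=float)
        self.outflow = np.asarray(self.outflow, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (len(self.times) == len(self.production) == len(self.outflow)):
            raise ValueError("inconsistent series lengths")

    @classmethod
    def from_result(cls, result) -> "RateTimeSeries":
        return cls(result.times, result.production, result.outflow)

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.times}
        names = _SE_COLUMNS if self.production.shape[1] == 5 else \
            tuple(f"prod_{j}" for j in range(self.production.shape[1]))
        for j, name in enumerate(names):
            cols[name] = self.production[:, j]
        cols["outflow_G6P"] = self.outflow
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def total_outflow(series: RateTimeSeries, T: float) -> float:
    """Total exported amount J = int_0^T outflow dt (mol), right-endpoint
    rectangle rule on the accepted-step grid (consistent with implicit
    Euler)."""
    t = series.times
    if t[-1] < T * (1.0 - 1e-9):
        raise ValueError(f"series ends at {t[-1]:g} < T = {T:g}")
    inside = t <= T * (1.0 + 1e-9)
    tt = t[inside]
    rr = series.outflow[inside]
    return float(np.sum(np.diff(tt) * rr[1:]))


def time_to_half_rate(series: RateTimeSeries, rate_at_T: float = None) -> float:
    """First time the outflow rate reaches half its final value, linearly
    interpolated between accepted steps; ``NOT_REACHED`` if it never does."""
    r = series.outflow
    target = 0.5 * (r[-1] if rate_at_T is None else rate_at_T)
    hit = np.flatnonzero(r >= target)
    if len(hit) == 0:
        return NOT_REACHED
    i = hit[0]
    if i == 0 or r[i] == target:
        return float(series.times[i])
    t0, t1 = series.times[i - 1], series.times[i]
    r0, r1 = r[i - 1], r[i]
    return float(t0 + (target - r0) / (r1 - r0) * (t1 - t0))


def plot_rates(series: RateTimeSeries, ax=None):
    """Quick look at the production and outflow rate histories."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    names = _SE_COLUMNS if series.production.shape[1] == 5 else \
        [f"prod_{j}" for j in range(series.production.shape[1])]
    for j, name in enumerate(names):
        ax.plot(series.times, series.production[:, j], label=name)
    ax.plot(series.times, series.outflow, "k--", label="outflow_G6P")
    ax.set_xlabel("t (s)")
    ax.set_ylabel("rate (mol/s)")
    ax.legend(fontsize=8)
    return ax


def global_mass_balance_residual(sim, state_old, state_new, dt: float) -> np.ndarray:
    """Per-species defect of the discrete global balance over one step:
    (M_new - M_old)/dt + sum of outward boundary fluxes - bulk sources.
    Zero to solver tolerance at every accepted step."""
    dM = (sim.total_mass(state_new) - sim.total_mass(state_old)) / dt
    bdry = np.flatnonzero(sim.mesh.facet_cells[:, 1] < 0)
    q = sim.boundary_flux(state_new, bdry)
    out = dM + q @ sim.mesh.facet_length[bdry]
    if sim.bulk_scale is not None:
        out -= (sim.reaction.bead_rates(state_new.y) * sim.bulk_scale) \
            @ sim.mesh.tri_area
    if sim.source is not None:
        out -= sim.source(state_new.t, sim.mesh.cell_centroids) @ sim.mesh.tri_area
    return out
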