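"""Scenario presets, configuration files, fixtures and batch drivers.

The computational arrangements of the study are

* S1 -- growing number of fully loaded beads (each bead carries the full
  binding-site concentration [E]_full);
* S2 -- fixed total enzyme budget of one fully loaded bead, spread uniformly
  over n_b beads (per-bead vmax divided by n_b) or, for n_b = 0, dissolved in
  the bulk;
* O1 / O2 -- stoichiometry optimization sweeps over the bead count at fixed
  horizon, respectively over the horizon for one bead.

All scenarios use the sucrose-excess (SE) reduction: five unknown species,
fixed sucrose/ATP/external pools, impermeable import boundary.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

import microreactor
from microreactor import kinetics as kin
from microreactor import geometry as geo
from microreactor import fem
from microreactor import observables as obs
from microreactor import sensitivity as sen

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "build_se_scenario",
    "run_batch",
    "make_fixtures",
    "SaturableSink",
]

ARRANGEMENTS = ("S1", "S2", "O1", "O2", "custom")


@dataclass
class ScenarioConfig:
    """Declarative description of one SE-scenario run.

    ``diffusivity=None`` selects the documented default
    (:data:`microreactor.fem.DEFAULT_DIFFUSIVITY`); the resolved scenario
    records that the default was used.  ``lam_rule`` is ``"uniform"``,
    ``"equal_activity"`` or an explicit 3-sequence.
    """

    arrangement: str = "S2"
    variant: str = "HsHK2"
    L: float = 500e-6
    n_b: int = 1
    lam_rule: object = "equal_activity"
    T: float = 3600.0
    dt: float = 0.25
    diffusivity: float = None
    theta_e: float = 0.15
    resolution: float = 60e-6
    bead_resolution: float = None
    grading: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.arrangement == "S1" and self.n_b < 1:
            raise ValueError("S1 needs at least one bead")

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["lam_rule"], str):
            d["lam_rule"] = [float(v) for v in d["lam_rule"]]
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Scenario:
    """Fully resolved simulation inputs for one configuration."""

    config: ScenarioConfig
    params: kin.KineticParameters
    lam: np.ndarray
    mesh: geo.TriangleMesh
    transport: fem.TransportParameters
    tstep: fem.TimeSteppingConfig
    bulk_scale: float = None
    used_default_diffusivity: bool = False

    def simulator(self) -> fem.ReactorSimulator:
        return fem.ReactorSimulator(self.mesh, kin.SEKinetics(self.params, self.lam),
                                    self.transport, self.tstep,
                                    bulk_scale=self.bulk_scale)

    def provenance(self) -> dict:
        return {"config_hash": self.config.config_hash(),
                "version": microreactor.__version__,
                "used_default_diffusivity": self.used_default_diffusivity}


def resolve_stoichiometry(rule, params: kin.KineticParameters) -> np.ndarray:
    if isinstance(rule, str):
        if rule == "uniform":
            return np.ones(3) / 3.0
        if rule == "equal_activity":
            return kin.equal_activity_stoichiometry(
                params.kcat_inv, params.kcat_hk, params.kcat_pgi).as_array()
        raise ValueError(f"unknown stoichiometry rule {rule!r}")
    lam = kin.Stoichiometry(*np.asarray(rule, dtype=float)).as_array()
    return lam


def build_se_scenario(config: ScenarioConfig) -> Scenario:
    """Resolve a configuration into mesh, kinetics and solver settings.

    Maximal velocities follow the arrangement: full bead loading for S1/O1/O2,
    the one-bead budget divided by n_b for S2, and for the bead-free case the
    full budget as a volumetric reaction scaled by |Gamma_b(one bead)|/|Omega|
    so the total maximal turnover matches one fully loaded bead.
    """
    base = kin.load_parameters(config.variant)
    if config.arrangement in ("S1", "O1", "O2", "custom") or config.n_b <= 1:
        params = base.with_loading(base.E_full)
    else:
        params = base.with_loading(base.E_full, n_b_divisor=config.n_b)
    theta_e = 0.15 if config.theta_e is None else config.theta_e
    lam = resolve_stoichiometry(config.lam_rule, params)

    spec = geo.ChamberSpec(L=config.L, n_b=config.n_b)
    mesh = geo.build_chamber_mesh(spec, config.resolution,
                                  bead_resolution=config.bead_resolution,
                                  grading=config.grading)
    bulk_scale = None
    if config.n_b == 0:
        if config.arrangement == "S1":
            raise ValueError("S1 requires beads")
        params = base.with_loading(base.E_full)
        bulk_scale = np.pi * spec.d / config.L**2

    used_default = config.diffusivity is None
    D = fem.DEFAULT_DIFFUSIVITY if used_default else config.diffusivity
    transport = fem.TransportParameters(
        D=np.full(5, D), theta_e=theta_e, theta_i=0.0, y0=np.zeros(5))
    tstep = fem.TimeSteppingConfig(T=config.T, dt=config.dt)
    return Scenario(config=config, params=params, lam=lam, mesh=mesh,
                    transport=transport, tstep=tstep, bulk_scale=bulk_scale,
                    used_default_diffusivity=used_default)


def simulate_scenario(config: ScenarioConfig, snapshot_times=()) -> dict:
    """Run one forward simulation; returns observables and summary metrics."""
    sc = build_se_scenario(config)
    sim = sc.simulator()
    result = sim.run(snapshot_times=snapshot_times)
    series = obs.RateTimeSeries.from_result(result)
    J = obs.total_outflow(series, config.T)
    prod_half = obs.time_to_half_rate(obs.RateTimeSeries(
        series.times, series.production, series.production[:, kin.Species.G6P]))
    out_half = obs.time_to_half_rate(series)
    return {
        "scenario": sc, "result": result, "series": series, "J": J,
        "summary": {
            **sc.provenance(),
            "J": J,
            "production_G6P_at_T": float(series.production[-1, kin.Species.G6P]),
            "outflow_at_T": float(series.outflow[-1]),
            "t_half_production_G6P": prod_half,
            "t_half_outflow": out_half,
            "rejections": result.rejections,
            "n_steps": len(result.step_dts),
        },
    }


def optimize_scenario(config: ScenarioConfig,
                      opt_config: sen.OptimizationConfig = None) -> dict:
    """Maximize the total G6P outflow over the stoichiometry simplex.

    The start is the better (larger J^0) of the uniform and equal-activity
    stoichiometries; returns the optimization result plus provenance.
    """
    sc = build_se_scenario(config)
    sim = sc.simulator()

    def evaluator(lam3):
        sim.set_reaction(kin.SEKinetics(sc.params, lam3))
        J, grad, _ = sen.evaluate_objective_and_gradient(sim, directions=np.eye(3))
        return J, grad

    lamU = np.ones(3) / 3.0
    lamE = kin.equal_activity_stoichiometry(
        sc.params.kcat_inv, sc.params.kcat_hk, sc.params.kcat_pgi).as_array()
    res = sen.optimize_stoichiometry(evaluator, [lamU, lamE],
                                     opt_config or sen.OptimizationConfig())
    return {"scenario": sc, "optimization": res,
            "summary": {**sc.provenance(),
                        "lam0": res.lam_init.tolist(),
                        "J0": res.J0, "k_star": res.n_iter,
                        "lam_inv": res.lam_opt[0], "lam_hk": res.lam_opt[1],
                        "lam_pgi": res.lam_opt[2],
                        "J_star": res.J_opt,
                        "rel_improvement": res.improvement}}


def run_batch(base_config: ScenarioConfig, sweep_field: str, values,
              mode: str = "simulate",
              opt_config: sen.OptimizationConfig = None) -> pd.DataFrame:
    """Sweep one configuration field; collect per-point summaries in a tidy
    table.  Failures are recorded per row and the batch continues."""
    rows = []
    for v in values:
        cfg = ScenarioConfig(**{**base_config.to_dict(), sweep_field: v})
        row = {sweep_field: v, "status": "ok"}
        try:
            if mode == "simulate":
                row.update(simulate_scenario(cfg)["summary"])
            elif mode == "optimize":
                row.update(optimize_scenario(cfg, opt_config)["summary"])
            else:
                raise ValueError(f"unknown batch mode {mode!r}")
        except Exception as exc:  # noqa: BLE001 -- batch robustness
            row["status"] = f"failed: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

class SaturableSink:
    """Single-species self-limiting bulk sink -s y^2 / (y^2 + K^2).

    The sink runs at full speed s while y >> K and shuts off quadratically
    below K, so the continuous solution stays positive.  At a large step
    size the backward-Euler equation also has negative roots (the rate law
    is even in y) and Newton lands on one, so the step is rejected and
    retried with a smaller step size -- the stiff fixture used to exercise
    the rejection logic.
    """

    n_species, n_params = 1, 0

    def __init__(self, s: float, K: float) -> None:
        self.s, self.K = s, K

    def bead_rates(self, y):
        y = np.asarray(y, dtype=float)
        return -self.s * y**2 / (y**2 + self.K**2)

    def bead_jac_y(self, y):
        y = np.asarray(y, dtype=float)
        J = np.zeros((1, 1) + y.shape[1:])
        J[0, 0] = -self.s * 2.0 * y[0] * self.K**2 / (y[0] ** 2 + self.K**2) ** 2
        return J

    def bead_jac_lam(self, y):
        y = np.asarray(y, dtype=float)
        return np.zeros((1, 0) + y.shape[1:])

    def export_rates(self, y):
        return np.zeros(np.asarray(y).shape)

    def export_jac_y(self, y):
        y = np.asarray(y, dtype=float)
        return np.zeros((1, 1) + y.shape[1:])


def make_fixtures(kind: str) -> dict:
    """Deterministic small test inputs (no downloads, built in seconds).

    Kinds: ``coarse-1-bead`` (small SE chamber), ``bulk`` (bead-free SE),
    ``manufactured`` (single-species problem with exact solution and source)
    and ``stiff-sink`` (provokes time-step rejections).
    """
    if kind == "coarse-1-bead":
        cfg = ScenarioConfig(arrangement="S2", n_b=1, T=60.0, dt=1.0,
                             resolution=120e-6,
                             bead_resolution=np.pi * 1e-5 / 16, grading=0.5)
        return {"config": cfg, "scenario": build_se_scenario(cfg)}
    if kind == "bulk":
        cfg = ScenarioConfig(arrangement="S2", n_b=0, T=60.0, dt=1.0,
                             resolution=60e-6)
        return {"config": cfg, "scenario": build_se_scenario(cfg)}
    if kind == "manufactured":
        L = 500e-6
        D = 1e-9
        tau = 5.0
        y_off, amp = 2.0, 1.0
        om = np.pi / L

        def exact(t, x):
            return (y_off + amp * np.exp(-t / tau)
                    * np.cos(om * x[:, 0]) * np.cos(om * x[:, 1]))[None, :]

        def source(t, x):
            return (amp * np.exp(-t / tau) * (2.0 * D * om**2 - 1.0 / tau)
                    * np.cos(om * x[:, 0]) * np.cos(om * x[:, 1]))[None, :]

        return {"L": L, "D": D, "exact": exact, "source": source,
                "mesh_factory": lambda n: geo.structured_square_mesh(L, n)}
    if kind == "stiff-sink":
        mesh = geo.structured_square_mesh(500e-6, 4)
        model = SaturableSink(s=0.8, K=0.02)
        transport = fem.TransportParameters(D=np.array([1e-9]), theta_e=0.0,
                                            y0=np.array([1.0]))
        tstep = fem.TimeSteppingConfig(T=8.0, dt=2.0, dt_min=2.0 / 1024.0)
        return {"mesh": mesh, "model": model, "transport": transport,
                "tstep": tstep}
    raise ValueError(f"unknown fixture kind {kind!r}")
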