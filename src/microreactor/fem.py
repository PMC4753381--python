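"""Locally conservative mixed finite element solver for the reactor PDE.

The metabolite system is

    dy_j/dt - D_j Lap(y_j) = R_j^Omega(y)        in Omega (bulk reactions,
                                                  zero when enzymes sit on beads)
    -D_j grad(y_j) . nu = -R_j^b(y)              on Gamma_b (bead surfaces)
    -D_j grad(y_j) . nu = -theta_e R_j^e(y)      on Gamma_e (export membrane)
    -D_j grad(y_j) . nu = -theta_i R_j^i(y)      on Gamma_i (import membrane)
    -D_j grad(y_j) . nu = 0                      on Gamma_0 (walls)

discretized with lowest-order Raviart-Thomas elements in hybridized form:
unknowns are elementwise-constant concentrations y_K and single-valued facet
traces tau_F; the flux q = -D grad(y) is eliminated element-locally, which
makes the scheme locally (elementwise) mass conservative.  Boundary kinetics
are evaluated at the facet traces with one-point facet quadrature.

Time integration is implicit Euler; the nonlinear step systems are solved by
Newton with a sparse LU per iteration.  A step whose converged solution has
negative concentrations (or whose Newton iteration fails) is rejected and
retried with half the step size, down to a minimum step size; after five
accepted steps the step size recovers toward its base value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from microreactor.geometry import BoundaryTag, TriangleMesh

__all__ = [
    "TransportParameters",
    "TimeSteppingConfig",
    "DiscreteState",
    "SolverError",
    "StepRejected",
    "NoReaction",
    "ReactorSimulator",
    "ForwardResult",
    "solve_linear_mixed_nonhybrid",
]

#: Documented default diffusivity (m^2/s): small metabolites in water are in
#: the 1e-9 m^2/s class.  The value is NOT part of the published parameter
#: table; quantitative conclusions should set diffusivities explicitly.
DEFAULT_DIFFUSIVITY = 1.0e-9


class SolverError(RuntimeError):
    """Hard solver failure (Newton breakdown below the minimum step size)."""


class StepRejected(Exception):
    """Internal signal: step produced negative concentrations / no convergence."""


@dataclass
class TransportParameters:
    """Per-species diffusivities (m^2/s), membrane permeabilities and initial
    concentrations (mol/m^2, constant per species)."""

    D: np.ndarray
    theta_e: float
    theta_i: float = 0.0
    y0: np.ndarray = None

    def resolve(self, n_species: int) -> "TransportParameters":
        D = np.broadcast_to(np.asarray(self.D, dtype=float), (n_species,)).copy()
        if np.any(D <= 0):
            raise ValueError("diffusivities must be positive")
        for th in (self.theta_e, self.theta_i):
            if not 0.0 <= th <= 1.0:
                raise ValueError("permeabilities must lie in [0, 1]")
        y0 = np.zeros(n_species) if self.y0 is None else \
            np.broadcast_to(np.asarray(self.y0, dtype=float), (n_species,)).copy()
        return TransportParameters(D=D, theta_e=self.theta_e,
                                   theta_i=self.theta_i, y0=y0)


@dataclass
class TimeSteppingConfig:
    T: float
    dt: float = 0.25
    dt_min: float = None
    newton_rtol: float = 1e-10
    newton_atol: float = 1e-30
    max_newton: int = 25
    halving: float = 0.5
    recovery_steps: int = 5  # accepted steps before the step size grows back

    def __post_init__(self) -> None:
        if self.dt_min is None:
            self.dt_min = self.dt / 1024.0
        if not (0 < self.dt_min <= self.dt):
            raise ValueError("need 0 < dt_min <= dt")
        if self.T <= 0:
            raise ValueError("horizon T must be positive")


class NoReaction:
    """Reaction-free model: pure diffusion with impermeable kinetics."""

    def __init__(self, n_species: int = 1) -> None:
        self.n_species = n_species
        self.n_params = 0

    def bead_rates(self, y):
        return np.zeros(np.asarray(y).shape)

    def bead_jac_y(self, y):
        y = np.asarray(y)
        return np.zeros((self.n_species, self.n_species) + y.shape[1:])

    def bead_jac_lam(self, y):
        y = np.asarray(y)
        return np.zeros((self.n_species, self.n_params) + y.shape[1:])

    export_rates = bead_rates
    export_jac_y = bead_jac_y


@dataclass
class DiscreteState:
    """Cell concentrations, facet traces and the current time for all species."""

    y: np.ndarray      # (n_species, n_cells)
    trace: np.ndarray  # (n_species, n_facets)
    t: float

    def copy(self) -> "DiscreteState":
        return DiscreteState(self.y.copy(), self.trace.copy(), self.t)


@dataclass
class ForwardResult:
    """Trajectory of observables (and optionally states) of a forward run."""

    times: np.ndarray            # accepted time levels, starting at 0
    production: np.ndarray       # (n_times, n_species) bead production, mol/s
    outflow: np.ndarray          # (n_times,) G6P outflow through Gamma_e, mol/s
    state: DiscreteState         # final state
    step_dts: np.ndarray         # dt of each accepted step (len n_times-1)
    newton_iters: list
    rejections: int
    states: list = None          # per-step (y, trace) if stored
    snapshots: dict = field(default_factory=dict)


def _rt0_local_matrices(mesh: TriangleMesh):
    """Elementwise RT0 flux mass matrices (unit D) and derived arrays.

    Basis on cell K: psi_i = (|E_i| / (2|K|)) (x - p_i) with p_i the vertex
    opposite facet i; psi_i has unit outward normal flux density on E_i.
    Returns Ainv (n_c,3,3), facet lengths per cell b (n_c,3), Gb = Ainv b,
    GC[i,l] = Ainv[i,l] |E_l| and cBB, cBG used in the cell balance.
    """
    pts = mesh.points
    tris = mesh.tris
    n_c = mesh.n_cells
    area = mesh.tri_area
    b = mesh.facet_length[mesh.cell_facets]              # (n_c, 3)
    P = pts[tris]                                        # (n_c, 3, 2)
    mids = 0.5 * (P[:, [1, 2, 0]] + P[:, [2, 0, 1]])     # midpoint opposite vertex i
    # A[i,j] = |E_i||E_j|/(4|K|^2) * (|K|/3) sum_k (m_k - p_i).(m_k - p_j)
    dm = mids[:, None, :, :] - P[:, :, None, :]          # (n_c, i, k, 2)
    S = np.einsum("nikd,njkd->nij", dm, dm) / 3.0        # (n_c, 3, 3)
    A = b[:, :, None] * b[:, None, :] * S / (4.0 * area[:, None, None] ** 2) \
        * area[:, None, None]
    Ainv = np.linalg.inv(A)
    Gb = np.einsum("nij,nj->ni", Ainv, b)
    GC = Ainv * b[:, None, :]
    cBB = np.einsum("ni,ni->n", b, Gb)
    cBG = np.einsum("ni,nil->nl", b, GC)
    return Ainv, b, Gb, GC, cBB, cBG


class ReactorSimulator:
    """Implicit-Euler / Newton integrator of the reactor system on one mesh.

    Parameters
    ----------
    mesh : TriangleMesh
    reaction : object
        Reaction model (e.g. :class:`microreactor.kinetics.SEKinetics`)
        providing vectorized ``bead_rates`` / ``export_rates`` and their
        Jacobians.  ``n_species`` must match ``transport``.
    transport : TransportParameters
    tstep : TimeSteppingConfig
    bulk_scale : float, optional
        When set (1/m), bead kinetics act as volumetric reactions
        R^Omega = bulk_scale * R^b(y) instead of bead-surface fluxes
        (bead-free chamber).
    source : callable, optional
        ``source(t, centroids) -> (n_species, n_cells)`` volumetric source
        term appended to the right-hand side (manufactured solutions).
    """

    def __init__(self, mesh: TriangleMesh, reaction, transport: TransportParameters,
                 tstep: TimeSteppingConfig, bulk_scale: float = None,
                 source=None) -> None:
        self.mesh = mesh
        self.reaction = reaction
        self.n_sp = reaction.n_species
        self.transport = transport.resolve(self.n_sp)
        self.tstep = tstep
        self.bulk_scale = bulk_scale
        self.source = source

        self.bead_facets = mesh.facets_with_tag(BoundaryTag.BEAD)
        self.export_facets = mesh.facets_with_tag(BoundaryTag.EXPORT)
        self.import_facets = mesh.facets_with_tag(BoundaryTag.IMPORT)
        if bulk_scale is not None and len(self.bead_facets):
            raise ValueError("bulk kinetics requested on a mesh with bead facets")

        (self.Ainv, self.b_loc, self.Gb, self.GC,
         self.cBB, self.cBG) = _rt0_local_matrices(mesh)
        self.n_c = mesh.n_cells
        self.n_f = mesh.n_facets
        self.n_dof = self.n_sp * (self.n_c + self.n_f)
        self._assemble_linear()
        self._precompute_reaction_pattern()

    def set_reaction(self, reaction) -> None:
        """Swap the reaction model (e.g. a new stoichiometry) without
        reassembling the lambda-independent linear operator."""
        if reaction.n_species != self.n_sp:
            raise ValueError("species count cannot change")
        self.reaction = reaction

    # -- dof numbering -------------------------------------------------------
    def _cell_rows(self, j):
        return j * self.n_c + np.arange(self.n_c)

    def _facet_rows(self, j, facets=None):
        base = self.n_sp * self.n_c + j * self.n_f
        return base + (np.arange(self.n_f) if facets is None else facets)

    def pack(self, state: DiscreteState) -> np.ndarray:
        return np.concatenate([state.y.ravel(), state.trace.ravel()])

    def unpack(self, u: np.ndarray, t: float) -> DiscreteState:
        nyc = self.n_sp * self.n_c
        return DiscreteState(u[:nyc].reshape(self.n_sp, self.n_c).copy(),
                             u[nyc:].reshape(self.n_sp, self.n_f).copy(), t)

    def initial_state(self) -> DiscreteState:
        y = np.tile(self.transport.y0[:, None], (1, self.n_c))
        tr = np.tile(self.transport.y0[:, None], (1, self.n_f))
        return DiscreteState(y, tr, 0.0)

    # -- assembly ------------------------------------------------------------
    def _assemble_linear(self) -> None:
        """Constant part: L(dt) = L0 + Mdiag/dt (diffusion + continuity)."""
        rows, cols, vals = [], [], []
        cf = self.mesh.cell_facets
        D = self.transport.D
        cells = np.arange(self.n_c)
        for j in range(self.n_sp):
            cr = self._cell_rows(j)
            # cell balance: D_j (cBB y_K - cBG . tau)
            rows.append(cr)
            cols.append(cr)
            vals.append(D[j] * self.cBB)
            for l in range(3):
                rows.append(cr)
                cols.append(self._facet_rows(j, cf[:, l]))
                vals.append(-D[j] * self.cBG[:, l])
            # facet continuity: sum of local outward fluxes
            for i in range(3):
                fr = self._facet_rows(j, cf[:, i])
                rows.append(fr)
                cols.append(j * self.n_c + cells)
                vals.append(D[j] * self.Gb[:, i])
                for l in range(3):
                    rows.append(fr)
                    cols.append(self._facet_rows(j, cf[:, l]))
                    vals.append(-D[j] * self.GC[:, i, l])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        self.L0 = sp.csr_matrix((vals, (rows, cols)),
                                shape=(self.n_dof, self.n_dof))
        mrows = np.concatenate([self._cell_rows(j) for j in range(self.n_sp)])
        mvals = np.tile(self.mesh.tri_area, self.n_sp)
        self.Mdiag = sp.csr_matrix((mvals, (mrows, mrows)),
                                   shape=(self.n_dof, self.n_dof))
        self._mass_area = mvals  # per cell row

    def _precompute_reaction_pattern(self) -> None:
        """COO index pattern of the state-dependent reaction Jacobian."""
        ns = self.n_sp
        rows, cols = [], []
        if self.bulk_scale is not None:
            cells = np.arange(self.n_c)
            for j in range(ns):
                for j2 in range(ns):
                    rows.append(j * self.n_c + cells)
                    cols.append(j2 * self.n_c + cells)
        for facets in (self.bead_facets, self.export_facets):
            for j in range(ns):
                for j2 in range(ns):
                    rows.append(self._facet_rows(j, facets))
                    cols.append(self._facet_rows(j2, facets))
        self._jr_rows = np.concatenate(rows) if rows else np.zeros(0, dtype=int)
        self._jr_cols = np.concatenate(cols) if cols else np.zeros(0, dtype=int)

    def _reaction_terms(self, u, t_new):
        """Nonlinear residual contribution N(u) and its Jacobian values."""
        ns = self.n_sp
        st = self.unpack(u, t_new)
        N = np.zeros(self.n_dof)
        jvals = []
        if self.bulk_scale is not None:
            Rb = self.reaction.bead_rates(st.y) * self.bulk_scale
            Jb = self.reaction.bead_jac_y(st.y) * self.bulk_scale
            for j in range(ns):
                N[self._cell_rows(j)] -= self.mesh.tri_area * Rb[j]
            jvals.append((-self.mesh.tri_area[None, None, :] * Jb).reshape(
                ns * ns, self.n_c))
        if self.source is not None:
            f = self.source(t_new, self.mesh.cell_centroids)
            for j in range(ns):
                N[self._cell_rows(j)] -= self.mesh.tri_area * f[j]
        if len(self.bead_facets):
            tb = st.trace[:, self.bead_facets]
            Rb = self.reaction.bead_rates(tb)
            Jb = self.reaction.bead_jac_y(tb)
            for j in range(ns):
                N[self._facet_rows(j, self.bead_facets)] += Rb[j]
            jvals.append(Jb.reshape(ns * ns, len(self.bead_facets)))
        if len(self.export_facets):
            te = st.trace[:, self.export_facets]
            Re = self.reaction.export_rates(te)
            Je = self.reaction.export_jac_y(te)
            th = self.transport.theta_e
            for j in range(ns):
                N[self._facet_rows(j, self.export_facets)] += th * Re[j]
            jvals.append(th * Je.reshape(ns * ns, len(self.export_facets)))
        vals = np.concatenate([v.ravel() for v in jvals]) if jvals else \
            np.zeros(0)
        return N, vals

    def _jacobian(self, Ldt, jac_vals):
        Jr = sp.csr_matrix((jac_vals, (self._jr_rows, self._jr_cols)),
                           shape=(self.n_dof, self.n_dof))
        return (Ldt + Jr).tocsc()

    def residual(self, u, u_old_y, dt, t_new):
        """Backward-Euler residual F(u) = L(dt) u + N(u) - M y_old / dt."""
        Ldt = self.L0 + self.Mdiag / dt
        N, _ = self._reaction_terms(u, t_new)
        F = Ldt @ u + N
        F[:self.n_sp * self.n_c] -= self._mass_area * u_old_y.ravel() / dt
        return F

    def dresidual_dlam(self, u, t_new):
        """Derivative of the step residual w.r.t. the stoichiometry vector."""
        n_p = self.reaction.n_params
        st = self.unpack(u, t_new)
        out = np.zeros((self.n_dof, n_p))
        if self.bulk_scale is not None:
            Jl = self.reaction.bead_jac_lam(st.y) * self.bulk_scale
            for j in range(self.n_sp):
                out[self._cell_rows(j), :] -= (self.mesh.tri_area * Jl[j]).T
        if len(self.bead_facets):
            Jl = self.reaction.bead_jac_lam(st.trace[:, self.bead_facets])
            for j in range(self.n_sp):
                out[self._facet_rows(j, self.bead_facets), :] += Jl[j].T
        return out

    # -- time stepping -------------------------------------------------------
    def implicit_euler_step(self, state: DiscreteState, dt: float,
                            return_lu: bool = False):
        """One Newton-solved backward-Euler step; raises StepRejected when the
        iteration fails or the converged concentrations are negative."""
        ts = self.tstep
        t_new = state.t + dt
        Ldt = self.L0 + self.Mdiag / dt
        u = self.pack(state)
        m_old = self._mass_area * state.y.ravel() / dt
        norm0 = None
        lu = None
        floor = ts.newton_atol
        for it in range(ts.max_newton + 1):
            N, jvals = self._reaction_terms(u, t_new)
            Lu = Ldt @ u
            F = Lu + N
            F[:self.n_sp * self.n_c] -= m_old
            nrm = np.linalg.norm(F)
            if not np.isfinite(nrm):
                raise StepRejected("non-finite residual")
            if norm0 is None:
                norm0 = nrm
                # roundoff floor: magnitude of the (cancelling) terms summed
                mag = abs(Ldt) @ np.abs(u) + np.abs(N)
                mag[:self.n_sp * self.n_c] += np.abs(m_old)
                floor = max(floor, 2e-15 * np.linalg.norm(mag))
            if nrm <= max(ts.newton_rtol * norm0, floor):
                break
            if it == ts.max_newton:
                raise StepRejected("Newton did not converge")
            lu = splu(self._jacobian(Ldt, jvals))
            u = u + lu.solve(-F)
        new = self.unpack(u, t_new)
        scale = max(np.abs(new.y).max(), np.abs(new.trace).max(), 1e-300)
        # physical nonnegativity is required of the cell concentrations; the
        # facet traces are hybridization multipliers and may undershoot in a
        # boundary layer, but must stay far from the kinetic singularities
        if new.y.min() < -1e-12 * scale:
            raise StepRejected("negative concentration")
        if new.trace.min() < -1e-3 * max(1.0, scale):
            raise StepRejected("facet trace strongly negative")
        # clip roundoff-level negatives so accepted states are nonnegative
        np.clip(new.y, 0.0, None, out=new.y)
        if return_lu:
            if lu is None:  # converged without an iteration (steady state)
                _, jvals = self._reaction_terms(u, t_new)
                lu = splu(self._jacobian(Ldt, jvals))
            return new, it, lu
        return new, it

    def run(self, state0: DiscreteState = None, store_states: bool = False,
            snapshot_times=(), callback=None) -> ForwardResult:
        """Integrate from t=0 to T, recording observables after every
        accepted step.  ``callback(step_index, state, dt, lu)`` is invoked
        after acceptance (used for simultaneous sensitivity propagation)."""
        from microreactor import observables as obs

        ts = self.tstep
        state = self.initial_state() if state0 is None else state0.copy()
        times = [0.0]
        production = [obs.production_rate_vector(self, state)]
        outflow = [obs.outflow_rate(self, state)]
        dts, iters = [], []
        states = [] if store_states else None
        snapshots = {}
        snap_left = sorted(snapshot_times)
        rejections = 0
        dt = ts.dt
        accepted_since_reject = 0
        while state.t < ts.T - 1e-12 * ts.T:
            dt_eff = min(dt, ts.T - state.t)
            try:
                new, it, lu = self.implicit_euler_step(state, dt_eff,
                                                       return_lu=True)
            except StepRejected as exc:
                rejections += 1
                accepted_since_reject = 0
                if dt * ts.halving < ts.dt_min:
                    raise SolverError(
                        f"step failed at t={state.t:g} below dt_min: {exc}")
                dt = dt * ts.halving
                continue
            state = new
            iters.append(it)
            dts.append(dt_eff)
            times.append(state.t)
            production.append(obs.production_rate_vector(self, state))
            outflow.append(obs.outflow_rate(self, state))
            if store_states:
                states.append((dt_eff, state.y.copy(), state.trace.copy()))
            while snap_left and state.t >= snap_left[0] - 1e-12 * ts.T:
                snapshots[snap_left.pop(0)] = state.copy()
            if callback is not None:
                callback(len(dts) - 1, state, dt_eff, lu)
            if dt < ts.dt:
                accepted_since_reject += 1
                if accepted_since_reject >= ts.recovery_steps:
                    dt = min(ts.dt, dt / ts.halving)
                    accepted_since_reject = 0
        return ForwardResult(
            times=np.asarray(times), production=np.asarray(production),
            outflow=np.asarray(outflow), state=state,
            step_dts=np.asarray(dts), newton_iters=iters,
            rejections=rejections, states=states, snapshots=snapshots)

    # -- derived quantities --------------------------------------------------
    def boundary_flux(self, state: DiscreteState, facets) -> np.ndarray:
        """Outward normal flux density q.nu (mol/(s*m)) of every species on
        the given boundary facets, from the eliminated RT0 flux unknowns."""
        K = self.mesh.facet_cells[facets, 0]
        loc = np.argmax(self.mesh.cell_facets[K] == facets[:, None], axis=1)
        tau_loc = state.trace[:, self.mesh.cell_facets[K]]     # (ns, nf, 3)
        yK = state.y[:, K]                                     # (ns, nf)
        q = (yK * self.Gb[K, loc][None, :]
             - np.einsum("fl,sfl->sf", self.GC[K, loc], tau_loc))
        return q * self.transport.D[:, None]

    def total_mass(self, state: DiscreteState) -> np.ndarray:
        return state.y @ self.mesh.tri_area


def solve_linear_mixed_nonhybrid(sim: ReactorSimulator, state: DiscreteState,
                                 dt: float, boundary_flux: dict = None):
    """One backward-Euler step of the *non-hybridized* mixed formulation.

    Reference path for cross-checking the hybridized solver on linear
    problems: unknowns are the globally oriented facet fluxes Q_F and the
    cell concentrations; prescribed outward boundary flux densities are
    supplied per tag in ``boundary_flux`` (default zero).  Returns the new
    cell concentrations per species.
    """
    mesh = sim.mesh
    n_c, n_f = sim.n_c, sim.n_f
    boundary_flux = boundary_flux or {}
    y_new = np.zeros((sim.n_sp, n_c))
    cf = mesh.cell_facets
    sgn = mesh.cell_facet_sign
    bdry = np.flatnonzero(mesh.facet_cells[:, 1] < 0)
    for j in range(sim.n_sp):
        D = sim.transport.D[j]
        A = sp.lil_matrix((n_f, n_f))
        B = sp.lil_matrix((n_f, n_c))
        for K in range(n_c):
            f = cf[K]
            s = sgn[K]
            # local flux mass matrix A (inverse of the stored Ainv), scaled by 1/D
            Aloc = np.linalg.inv(sim.Ainv[K]) / D
            for i in range(3):
                for l in range(3):
                    A[f[i], f[l]] += s[i] * s[l] * Aloc[i, l]
                B[f[i], K] += -s[i] * mesh.facet_length[f[i]]
        # mass balance rows: area/dt y + div q = area/dt y_old
        Mdt = sp.diags(mesh.tri_area / dt)
        Div = sp.lil_matrix((n_c, n_f))
        for K in range(n_c):
            for i in range(3):
                Div[K, cf[K, i]] += sgn[K, i] * mesh.facet_length[cf[K, i]]
        rhs_q = np.zeros(n_f)
        rhs_y = mesh.tri_area / dt * state.y[j]
        Asys = sp.bmat([[A, B], [Div, Mdt]]).tolil()
        rhs = np.concatenate([rhs_q, rhs_y])
        for F in bdry:
            tag = BoundaryTag(mesh.facet_tags[F])
            qval = boundary_flux.get(tag, 0.0)
            Asys[F, :] = 0.0
            Asys[F, F] = 1.0
            # stored normal is outward on the boundary; prescribe directly
            rhs[F] = qval
        sol = sp.linalg.spsolve(Asys.tocsc(), rhs)
        y_new[j] = sol[n_f:]
    return y_new
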