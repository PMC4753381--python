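"""Sensitivity equations and stoichiometry optimization.

The design objective is the total G6P outflow over the horizon,

    J(lambda) = int_0^T int_{Gamma_e} -theta_e R^e_G6P(y(lambda)) dsigma dt,

maximized over the enzyme stoichiometry lambda on the probability simplex.
Its gradient is computed with the forward (tangent) sensitivity approach:
for each parameter direction e_i the linearized reaction-diffusion system

    d/dt y~ - D Lap y~ = dR/dy(y) y~ + dR/dlambda(y) e_i   (+ boundary analogues)

is integrated on the same mesh and time grid as the forward solve, with
y~(0) = 0; each implicit-Euler step is a single linear solve with the
Jacobian of the converged forward step.  Because R^e does not depend on
lambda directly, the reduced gradient is

    J'(lambda) e_i = int_0^T int_{Gamma_e} -theta_e (dR^e_G6P/dy . y~) dsigma dt

with the same right-endpoint quadrature as J.  The parameter space is reduced
to (l_inv, l_hk) by eliminating l_pgi = 1 - l_inv - l_hk; the corresponding
full-space directions are e_inv - e_pgi and e_hk - e_pgi.

The simplex-constrained maximization uses an interior-point-type trust-region
method (scipy's ``trust-constr``) with BFGS curvature updates on the
J^0-normalized objective, mirroring the interior-point/BFGS class of
algorithms; tolerances tol_X (parameter step) and tol_fun (relative objective
stationarity) stop the iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
from scipy.sparse.linalg import splu

from microreactor.fem import ForwardResult, ReactorSimulator
from microreactor.observables import RateTimeSeries, total_outflow

__all__ = [
    "SensitivityTrajectory",
    "OptimizationConfig",
    "OptimizationResult",
    "solve_sensitivity",
    "reduced_gradient",
    "evaluate_objective_and_gradient",
    "optimize_stoichiometry",
    "REDUCED_DIRECTIONS",
]

#: Full-space parameter directions of the reduced variables (l_inv, l_hk)
#: after eliminating l_pgi through the simplex condition.
REDUCED_DIRECTIONS = np.array([[1.0, 0.0, -1.0], [0.0, 1.0, -1.0]])


@dataclass
class SensitivityTrajectory:
    """Tangent states y~ for one or more parameter directions.

    ``tilde[n]`` has shape (n_dof, n_dir) and belongs to time level
    ``times[n]``; the initial level is identically zero.
    """

    times: np.ndarray
    directions: np.ndarray    # (n_dir, n_params)
    tilde: list               # list of (n_dof, n_dir) arrays


def solve_sensitivity(sim: ReactorSimulator, forward: ForwardResult,
                      directions) -> SensitivityTrajectory:
    """Integrate the linearized (tangent) system along a stored forward
    trajectory, one linear solve per accepted step and direction.

    ``forward`` must have been produced with ``store_states=True`` so the
    converged states (and accepted step sizes) are available; the tangent
    system reuses the forward step's converged Jacobian.
    """
    if forward.states is None:
        raise ValueError("forward run must be stored (store_states=True)")
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[1] != sim.reaction.n_params:
        raise ValueError("direction dimension does not match n_params")
    n_dir = directions.shape[0]
    tilde = [np.zeros((sim.n_dof, n_dir))]
    ncell_rows = sim.n_sp * sim.n_c
    for n, (dt, y, trace) in enumerate(forward.states):
        t_new = forward.times[n + 1]
        u = np.concatenate([y.ravel(), trace.ravel()])
        Ldt = sim.L0 + sim.Mdiag / dt
        _, jvals = sim._reaction_terms(u, t_new)
        lu = splu(sim._jacobian(Ldt, jvals))
        Flam = sim.dresidual_dlam(u, t_new)          # (n_dof, n_params)
        rhs = -Flam @ directions.T
        rhs[:ncell_rows] += (sim._mass_area[:, None]
                             * tilde[-1][:ncell_rows]) / dt
        tilde.append(lu.solve(rhs))
    return SensitivityTrajectory(times=forward.times, directions=directions,
                                 tilde=tilde)


def reduced_gradient(sim: ReactorSimulator, forward: ForwardResult,
                     sens: SensitivityTrajectory, species: int = None,
                     T: float = None) -> np.ndarray:
    """Directional derivatives of J (total outflow of ``species``) for every
    direction in ``sens``, using the right-endpoint quadrature of J."""
    j = sim.n_sp - 1 if species is None else species
    T = sim.tstep.T if T is None else T
    facets = sim.export_facets
    flen = sim.mesh.facet_length[facets]
    th = sim.transport.theta_e
    ncell_rows = sim.n_sp * sim.n_c
    grad = np.zeros(len(sens.directions))
    for n, (dt, y, trace) in enumerate(forward.states):
        t_new = forward.times[n + 1]
        if t_new > T * (1.0 + 1e-9):
            break
        Je = sim.reaction.export_jac_y(trace[:, facets])   # (ns, ns, nf)
        tl = sens.tilde[n + 1][ncell_rows:].reshape(sim.n_sp, sim.n_f, -1)
        tl_e = tl[:, facets, :]                            # (ns, nf, n_dir)
        # dJ contribution: -theta_e sum_f |F| sum_j2 dRe[j,j2,f] y~[j2,f]
        contrib = -th * np.einsum("sf,f,sfd->d", Je[j], flen, tl_e)
        grad += dt * contrib
    return grad


def evaluate_objective_and_gradient(sim: ReactorSimulator,
                                    directions=REDUCED_DIRECTIONS):
    """Forward solve + tangent solves: returns (J, gradient, forward result).

    J is the total outflow of the last species (G6P) over the configured
    horizon; the gradient is w.r.t. the given parameter directions.
    """
    forward = sim.run(store_states=True)
    series = RateTimeSeries.from_result(forward)
    J = total_outflow(series, sim.tstep.T)
    sens = solve_sensitivity(sim, forward, directions)
    grad = reduced_gradient(sim, forward, sens)
    return J, grad, forward


@dataclass
class OptimizationConfig:
    """Settings of the simplex-constrained stoichiometry maximization."""

    tol_X: float = 1.0e-6
    tol_fun: float = 1.0e-4
    max_iter: int = 100
    eliminated: str = "pgi"
    feas_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.eliminated != "pgi":
            raise NotImplementedError("only elimination of lambda_pgi is supported")
        if self.tol_X <= 0 or self.tol_fun <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class OptimizationResult:
    lam_opt: np.ndarray       # optimal stoichiometry (3,)
    lam_init: np.ndarray
    J0: float
    J_opt: float
    n_iter: int
    trace: list = field(default_factory=list)   # (lam (3,), J) per iterate
    message: str = ""

    @property
    def improvement(self) -> float:
        """Relative improvement (J* - J0) / J0."""
        return (self.J_opt - self.J0) / self.J0


def _full_lambda(x) -> np.ndarray:
    lam = np.array([x[0], x[1], 1.0 - x[0] - x[1]])
    lam[2] = max(lam[2], 0.0)
    return lam


def optimize_stoichiometry(evaluator, lam0, config: OptimizationConfig = None
                           ) -> OptimizationResult:
    """Maximize J over the stoichiometry simplex from a feasible start.

    ``evaluator(lam)`` must return ``(J, grad)`` with ``grad`` the full
    3-component gradient of J w.r.t. lambda; the simplex reduction to
    (l_inv, l_hk) and the sign flip to a minimization are handled here.
    ``lam0`` may be a single start or a sequence of candidate starts, in
    which case the one with the larger J^0 is used.
    """
    config = config or OptimizationConfig()
    lam0 = np.atleast_2d(np.asarray(lam0, dtype=float))
    cand = []
    for lam in lam0:
        if np.any(lam < -config.feas_tol) or abs(lam.sum() - 1.0) > 1e-9:
            raise ValueError(f"infeasible start {lam}")
        J, g = evaluator(lam)
        cand.append((J, lam, g))
    J0, lam_init, _ = max(cand, key=lambda c: c[0])
    scale = abs(J0) if J0 != 0.0 else 1.0

    trace = []

    def fun(x):
        lam = _full_lambda(x)
        J, g = evaluator(lam)
        trace.append((lam, J))
        gred = REDUCED_DIRECTIONS @ g
        return -J / scale, -gred / scale

    lc = scipy.optimize.LinearConstraint(np.array([[1.0, 1.0]]), -np.inf, 1.0)
    res = scipy.optimize.minimize(
        fun, lam_init[:2], jac=True, method="trust-constr",
        bounds=scipy.optimize.Bounds(0.0, 1.0), constraints=[lc],
        options={"xtol": config.tol_X, "gtol": 1e-12,
                 "maxiter": config.max_iter, "verbose": 0})
    lam_opt = _full_lambda(res.x)
    J_opt, _ = evaluator(lam_opt)
    # tol_fun safeguard: the final objective may never undercut the start
    if J_opt < J0 * (1.0 - np.sign(J0) * config.tol_fun):
        best = max(trace, key=lambda c: c[1])
        lam_opt, J_opt = best
    return OptimizationResult(
        lam_opt=lam_opt, lam_init=lam_init, J0=J0, J_opt=J_opt,
        n_iter=int(res.nit), trace=trace, message=str(res.message))
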