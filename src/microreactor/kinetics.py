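"""Enzyme kinetics of the sucrose -> glucose-6-phosphate bead pathway.

The pathway running in the reactor chamber is

    (1) S -> G + F            invertase          (irreversible Michaelis-Menten)
    (2) G + ATP -> G6P + ADP  hexokinase         (irreversible bi-bi ordered)
    (3) F + ATP -> F6P + ADP  hexokinase         (irreversible bi-bi ordered)
    (4) F6P <-> G6P           phosphoglucose isomerase (reversible Michaelis-Menten)
    (5) G6P + Pi_e <-> G6P_e + Pi   G6P antiporter (reversible bi-bi ping-pong)

In the sucrose-excess (SE) reduction, sucrose [S] and [ATP] inside the chamber
and [G6P_e], [Pi_e] outside it are held constant, leaving five unknown
concentrations (G, F, F6P, Pi, G6P).  Reactions (1)-(4) run on the bead
surfaces and enter the PDE as boundary fluxes R^b; reaction (5) runs on the
export membrane and enters as the boundary flux R^e.  All enzymatic rates are
linear in the bead stoichiometry vector lambda = (l_inv, l_hk, l_pgi), a point
on the probability simplex.

Units: 2-D model -- concentrations mol/m^2, surface rates mol/(s*m),
turnover numbers 1/s, binding-site concentration mol/m.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from enum import IntEnum
from fractions import Fraction
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "Species",
    "FIXED_SPECIES",
    "KineticParameters",
    "Stoichiometry",
    "StoichiometricMatrix",
    "load_parameters",
    "rate_invertase",
    "rate_hexokinase",
    "rate_pgi",
    "rate_g6p_export",
    "bead_flux_vector",
    "export_flux_vector",
    "bulk_reaction_vector",
    "kinetics_jacobians",
    "equal_activity_stoichiometry",
    "vmax_from_loading",
    "coupled_species_count",
    "full_network_matrix",
    "se_network_matrix",
    "SEKinetics",
]


class Species(IntEnum):
    """Ordering of the five SE-scenario unknowns (one PDE each)."""

    G = 0
    F = 1
    F6P = 2
    PI = 3
    G6P = 4


#: Species held at fixed bath concentrations in the SE reduction.
FIXED_SPECIES = ("S", "ATP", "G6P_e", "Pi_e")

N_SPECIES = 5
N_ENZYMES = 3

SIMPLEX_TOL = 1e-12


class KineticsError(ValueError):
    """Invalid kinetic input (negative concentration, nonpositive constant)."""


@dataclass(frozen=True)
class KineticParameters:
    """All kinetic constants of the SE-scenario for one hexokinase variant.

    Michaelis/inhibition/equilibrium constants are surface concentrations
    (mol/m^2); vmax values are surface rates (mol/(s*m)); kcat are 1/s;
    ``E_full`` is the binding-site concentration of a fully loaded bead
    (mol/m).  ``variant`` selects the HsHK2 or ScHK2 parameter column.
    """

    # Michaelis constants (mol/m^2)
    K_mS: float
    K_mG: float
    K_mATP: float
    K_mF: float
    K_mF6P: float
    K_mG6P: float
    K_mG6PT: float
    K_mG6Pe: float
    K_mPi: float
    K_mPie: float
    # inhibition / equilibrium constants (mol/m^2)
    K_iG6P: float
    K_iPi: float
    K_eq: float
    # turnover numbers (1/s)
    kcat_inv: float
    kcat_hk: float
    kcat_pgi: float
    # surface maximal velocities (mol/(s*m))
    vmax_inv: float
    vmax_hk: float
    vmax_pgi_f: float
    vmax_pgi_b: float
    vmax_G6P_f: float
    vmax_G6P_b: float
    # fixed bath concentrations (mol/m^2)
    S: float
    ATP: float
    G6P_e: float
    Pi_e: float
    # binding-site concentration of a fully loaded bead (mol/m)
    E_full: float
    variant: str = "HsHK2"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "variant":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0.0:
                raise KineticsError(f"parameter {f.name} must be finite and >= 0, got {v!r}")
        for name in ("K_mS", "K_mG", "K_mATP", "K_mF", "K_mF6P", "K_mG6P",
                     "K_mG6PT", "K_mG6Pe", "K_mPi", "K_mPie", "K_iG6P",
                     "K_iPi", "K_eq", "vmax_G6P_b"):
            if getattr(self, name) <= 0.0:
                raise KineticsError(f"parameter {name} must be strictly positive")

    @property
    def kcats(self) -> np.ndarray:
        return np.array([self.kcat_inv, self.kcat_hk, self.kcat_pgi])

    def with_loading(self, E0: float, n_b_divisor: int = 1) -> "KineticParameters":
        """Return a copy with enzyme vmax recomputed from kcat and loading E0.

        ``n_b_divisor`` spreads the fixed enzyme budget over that many beads
        (arrangement with fixed total enzyme amount); the antiporter vmax is a
        membrane property and is left untouched.
        """
        v = [vmax_from_loading(k, E0, n_b_divisor) for k in
             (self.kcat_inv, self.kcat_hk, self.kcat_pgi)]
        return replace(self, vmax_inv=v[0], vmax_hk=v[1],
                       vmax_pgi_f=v[2], vmax_pgi_b=v[2])

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "KineticParameters":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_parameters(variant: str = "HsHK2") -> KineticParameters:
    """Load the packaged parameter table for a hexokinase variant."""
    key = variant.lower()
    if key not in ("hshk2", "schk2"):
        raise KineticsError(f"unknown hexokinase variant {variant!r}")
    ref = resources.files("microreactor.data").joinpath(f"{key}.yaml")
    with ref.open() as fh:
        return KineticParameters.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class Stoichiometry:
    """Fractions of bead binding sites per enzyme: (invertase, hexokinase, pgi).

    A point on the probability simplex; inputs within 1e-12 of the simplex are
    renormalized, anything else is rejected.
    """

    inv: float
    hk: float
    pgi: float

    def __post_init__(self) -> None:
        arr = np.array([self.inv, self.hk, self.pgi], dtype=float)
        if np.any(arr < -SIMPLEX_TOL):
            raise KineticsError(f"stoichiometry components must be >= 0, got {arr}")
        s = arr.sum()
        if abs(s - 1.0) > SIMPLEX_TOL * max(1.0, abs(s)):
            raise KineticsError(f"stoichiometry must sum to 1, got sum {s!r}")
        arr = np.clip(arr, 0.0, None) / arr.clip(0.0, None).sum()
        object.__setattr__(self, "inv", float(arr[0]))
        object.__setattr__(self, "hk", float(arr[1]))
        object.__setattr__(self, "pgi", float(arr[2]))

    def as_array(self) -> np.ndarray:
        return np.array([self.inv, self.hk, self.pgi])

    @classmethod
    def uniform(cls) -> "Stoichiometry":
        return cls(1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


def equal_activity_stoichiometry(kcat_inv: float, kcat_hk: float,
                                 kcat_pgi: float) -> Stoichiometry:
    """Stoichiometry giving every enzyme the same activity kcat_i * lambda_i.

    Solves kcat_inv*l_inv = kcat_hk*l_hk = kcat_pgi*l_pgi with the components
    summing to one, i.e. l_i proportional to 1/kcat_i.
    """
    kcats = np.array([kcat_inv, kcat_hk, kcat_pgi], dtype=float)
    if np.any(kcats <= 0.0) or not np.all(np.isfinite(kcats)):
        raise KineticsError("turnover numbers must be strictly positive")
    w = 1.0 / kcats
    w /= w.sum()
    return Stoichiometry(*w)


def vmax_from_loading(kcat: float, E0: float, n_b_divisor: int = 1) -> float:
    """Surface maximal velocity vmax = kcat * E0 / n_b_divisor.

    ``n_b_divisor`` > 1 distributes a fixed total amount of enzyme over that
    many beads.
    """
    if E0 < 0.0:
        raise KineticsError(f"binding-site concentration must be >= 0, got {E0}")
    if n_b_divisor < 1 or int(n_b_divisor) != n_b_divisor:
        raise KineticsError(f"n_b_divisor must be a positive integer, got {n_b_divisor}")
    return kcat * E0 / n_b_divisor


# ---------------------------------------------------------------------------
# rate laws
# ---------------------------------------------------------------------------

def _check_nonneg(**concs) -> None:
    for name, c in concs.items():
        if np.any(np.asarray(c) < 0.0):
            raise KineticsError(f"negative concentration for {name}")


def rate_invertase(lam_inv: float, S_conc, params: KineticParameters):
    """Invertase rate l_inv * vmax_inv * [S] / (K_mS + [S])  (irreversible MM)."""
    _check_nonneg(S=S_conc)
    S = np.asarray(S_conc, dtype=float)
    out = lam_inv * params.vmax_inv * S / (params.K_mS + S)
    return out if out.ndim else float(out)


def rate_hexokinase(lam_hk: float, X_conc, ATP_conc, substrate: str,
                    params: KineticParameters):
    """Hexokinase rate for hexose substrate ``'G'`` or ``'F'`` (bi-bi ordered).

    l_hk * vmax_hk * [X][ATP] / (K_mX K_mATP + K_mATP [X] + K_mX [ATP] + [X][ATP]).
    """
    if substrate not in ("G", "F"):
        raise KineticsError(f"substrate must be 'G' or 'F', got {substrate!r}")
    _check_nonneg(X=X_conc, ATP=ATP_conc)
    KmX = params.K_mG if substrate == "G" else params.K_mF
    X = np.asarray(X_conc, dtype=float)
    A = np.asarray(ATP_conc, dtype=float)
    den = KmX * params.K_mATP + params.K_mATP * X + KmX * A + X * A
    out = lam_hk * params.vmax_hk * X * A / den
    return out if out.ndim else float(out)


def rate_pgi(lam_pgi: float, F6P_conc, G6P_conc, params: KineticParameters):
    """Phosphoglucose isomerase net rate (reversible Michaelis-Menten).

    l_pgi * (vmax_f [F6P]/(K_mF6P+[F6P]) - vmax_b [G6P]/(K_mG6P+[G6P])).
    Positive means net F6P -> G6P.
    """
    _check_nonneg(F6P=F6P_conc, G6P=G6P_conc)
    F6P = np.asarray(F6P_conc, dtype=float)
    G6P = np.asarray(G6P_conc, dtype=float)
    out = lam_pgi * (params.vmax_pgi_f * F6P / (params.K_mF6P + F6P)
                     - params.vmax_pgi_b * G6P / (params.K_mG6P + G6P))
    return out if out.ndim else float(out)


def rate_g6p_export(G6P_conc, Pi_conc, params: KineticParameters):
    """Net G6P/Pi antiport rate of the export transporter (bi-bi ping-pong).

    The exchanger swaps internal G6P against external Pi:

        G6P + Pi_e  <->  G6P_e + Pi

    The implemented reversible ping-pong form is

        r = vmax_f * ([G6P][Pi_e] - [G6P_e][Pi]/K_eq) / den
        den = [G6P][Pi_e] + K_mPie [G6P] + K_mG6PT [Pi_e] (1 + [Pi]/K_iPi)
              + (vmax_f / (vmax_b K_eq)) *
                (K_mPi [G6P_e] (1 + [G6P]/K_iG6P) + [Pi] (K_mG6Pe + [G6P_e]))

    with bath concentrations [G6P_e], [Pi_e] taken from ``params``.  The
    numerator makes the rate vanish exactly at the exchanger's thermodynamic
    equilibrium; r > 0 means net export of G6P.
    """
    _check_nonneg(G6P=G6P_conc, Pi=Pi_conc)
    if params.K_eq <= 0.0:
        raise KineticsError("K_eq must be strictly positive")
    out = _g6p_export_raw(np.asarray(G6P_conc, dtype=float),
                          np.asarray(Pi_conc, dtype=float), params)
    return out if out.ndim else float(out)


def _g6p_export_raw(G6P, Pi, params: KineticParameters):
    p = params
    num = p.vmax_G6P_f * (G6P * p.Pi_e - p.G6P_e * Pi / p.K_eq)
    den = (G6P * p.Pi_e + p.K_mPie * G6P
           + p.K_mG6PT * p.Pi_e * (1.0 + Pi / p.K_iPi)
           + p.vmax_G6P_f / (p.vmax_G6P_b * p.K_eq)
           * (p.K_mPi * p.G6P_e * (1.0 + G6P / p.K_iG6P)
              + Pi * (p.K_mG6Pe + p.G6P_e)))
    return num / den


def _g6p_export_raw_grad(G6P, Pi, params: KineticParameters):
    """(r, dr/dG6P, dr/dPi) of the antiport rate, vectorized."""
    p = params
    num = p.vmax_G6P_f * (G6P * p.Pi_e - p.G6P_e * Pi / p.K_eq)
    c = p.vmax_G6P_f / (p.vmax_G6P_b * p.K_eq)
    den = (G6P * p.Pi_e + p.K_mPie * G6P
           + p.K_mG6PT * p.Pi_e * (1.0 + Pi / p.K_iPi)
           + c * (p.K_mPi * p.G6P_e * (1.0 + G6P / p.K_iG6P)
                  + Pi * (p.K_mG6Pe + p.G6P_e)))
    dnum_dG = p.vmax_G6P_f * p.Pi_e
    dnum_dP = -p.vmax_G6P_f * p.G6P_e / p.K_eq
    dden_dG = p.Pi_e + p.K_mPie + c * p.K_mPi * p.G6P_e / p.K_iG6P
    dden_dP = p.K_mG6PT * p.Pi_e / p.K_iPi + c * (p.K_mG6Pe + p.G6P_e)
    r = num / den
    return r, (dnum_dG - r * dden_dG) / den, (dnum_dP - r * dden_dP) / den


# ---------------------------------------------------------------------------
# assembled reaction vectors (Table of bead / export fluxes)
# ---------------------------------------------------------------------------

def _split_y(y):
    y = np.asarray(y, dtype=float)
    if y.shape[0] != N_SPECIES:
        raise KineticsError(f"expected {N_SPECIES} species, got shape {y.shape}")
    return y


def bead_flux_vector(y, lam: Stoichiometry, params: KineticParameters):
    """Bead-surface reaction vector R^b for the unknowns (G, F, F6P, Pi, G6P).

    R_G = r_inv - r_hk^G ; R_F = r_inv - r_hk^F ; R_F6P = r_hk^F - r_pgi ;
    R_Pi = 0 ; R_G6P = r_hk^G + r_pgi.
    """
    y = _split_y(y)
    _check_nonneg(y=y)
    return SEKinetics(params, lam).bead_rates(y)


def export_flux_vector(y, params: KineticParameters):
    """Export-membrane reaction vector R^e: only the G6P/Pi antiport.

    R^e_G6P = -r_G6P (G6P leaves), R^e_Pi = +r_G6P (Pi enters), others zero.
    The membrane permeability theta_e is applied by the solver, not here.
    """
    y = _split_y(y)
    _check_nonneg(y=y)
    return SEKinetics(params, Stoichiometry.uniform()).export_rates(y)


def bulk_reaction_vector(y, lam: Stoichiometry, params: KineticParameters,
                         geometry_scale: float):
    """Bulk reaction vector R^Omega = geometry_scale * R^b for bead-free chambers.

    ``geometry_scale`` (1/m) converts the per-length surface rates to per-area
    bulk rates; choosing it as |Gamma_b(one bead)| / |Omega| gives the bulk
    chamber the same total maximal turnover as a single fully loaded bead.
    """
    if geometry_scale < 0.0:
        raise KineticsError("geometry_scale must be >= 0")
    return geometry_scale * bead_flux_vector(y, lam, params)


def kinetics_jacobians(y, lam: Stoichiometry, params: KineticParameters):
    """Analytic partial derivatives (dR^b/dy, dR^b/dlam, dR^e/dy).

    Shapes (5,5), (5,3), (5,5).  dR^b/dlam is state-only dependent because
    every enzymatic rate is linear in its lambda component.
    """
    y = _split_y(y)
    _check_nonneg(y=y)
    mdl = SEKinetics(params, lam)
    return mdl.bead_jac_y(y), mdl.bead_jac_lam(y), mdl.export_jac_y(y)


class SEKinetics:
    """Vectorized SE-scenario reaction model used by the PDE solver.

    Evaluates bead and export reaction vectors and their derivatives on
    arrays of states with shape (5, n) (or (5,) for a single state) without
    input validation; negative transients occurring inside Newton iterations
    are evaluated as-is.
    """

    n_species = N_SPECIES
    n_params = N_ENZYMES

    def __init__(self, params: KineticParameters, lam) -> None:
        self.params = params
        if isinstance(lam, Stoichiometry):
            lam = lam.as_array()
        self.lam = np.asarray(lam, dtype=float)
        if self.lam.shape != (N_ENZYMES,):
            raise KineticsError("lambda must have 3 components")

    # -- unit-lambda rates (rate per unit stoichiometry fraction) -----------
    def _unit_rates(self, y):
        p = self.params
        G, F, F6P = y[Species.G], y[Species.F], y[Species.F6P]
        G6P = y[Species.G6P]
        a_inv = p.vmax_inv * p.S / (p.K_mS + p.S) * np.ones_like(G)
        den_G = p.K_mG * p.K_mATP + p.K_mATP * G + p.K_mG * p.ATP + G * p.ATP
        a_hkG = p.vmax_hk * G * p.ATP / den_G
        den_F = p.K_mF * p.K_mATP + p.K_mATP * F + p.K_mF * p.ATP + F * p.ATP
        a_hkF = p.vmax_hk * F * p.ATP / den_F
        a_pgi = (p.vmax_pgi_f * F6P / (p.K_mF6P + F6P)
                 - p.vmax_pgi_b * G6P / (p.K_mG6P + G6P))
        return a_inv, a_hkG, a_hkF, a_pgi

    def _unit_rate_grads(self, y):
        p = self.params
        G, F, F6P = y[Species.G], y[Species.F], y[Species.F6P]
        G6P = y[Species.G6P]
        den_G = p.K_mG * p.K_mATP + p.K_mATP * G + p.K_mG * p.ATP + G * p.ATP
        da_hkG = p.vmax_hk * p.ATP * p.K_mG * (p.K_mATP + p.ATP) / den_G**2
        den_F = p.K_mF * p.K_mATP + p.K_mATP * F + p.K_mF * p.ATP + F * p.ATP
        da_hkF = p.vmax_hk * p.ATP * p.K_mF * (p.K_mATP + p.ATP) / den_F**2
        da_pgi_dF6P = p.vmax_pgi_f * p.K_mF6P / (p.K_mF6P + F6P)**2
        da_pgi_dG6P = -p.vmax_pgi_b * p.K_mG6P / (p.K_mG6P + G6P)**2
        return da_hkG, da_hkF, da_pgi_dF6P, da_pgi_dG6P

    # -- bead surface --------------------------------------------------------
    def bead_rates(self, y):
        l_inv, l_hk, l_pgi = self.lam
        y = np.asarray(y, dtype=float)
        a_inv, a_hkG, a_hkF, a_pgi = self._unit_rates(y)
        R = np.zeros(y.shape)
        R[Species.G] = l_inv * a_inv - l_hk * a_hkG
        R[Species.F] = l_inv * a_inv - l_hk * a_hkF
        R[Species.F6P] = l_hk * a_hkF - l_pgi * a_pgi
        R[Species.PI] = 0.0
        R[Species.G6P] = l_hk * a_hkG + l_pgi * a_pgi
        return R

    def bead_jac_y(self, y):
        y = np.asarray(y, dtype=float)
        _, l_hk, l_pgi = self.lam
        da_hkG, da_hkF, dpF6P, dpG6P = self._unit_rate_grads(y)
        J = np.zeros((N_SPECIES, N_SPECIES) + y.shape[1:])
        J[Species.G, Species.G] = -l_hk * da_hkG
        J[Species.F, Species.F] = -l_hk * da_hkF
        J[Species.F6P, Species.F] = l_hk * da_hkF
        J[Species.F6P, Species.F6P] = -l_pgi * dpF6P
        J[Species.F6P, Species.G6P] = -l_pgi * dpG6P
        J[Species.G6P, Species.G] = l_hk * da_hkG
        J[Species.G6P, Species.F6P] = l_pgi * dpF6P
        J[Species.G6P, Species.G6P] = l_pgi * dpG6P
        return J

    def bead_jac_lam(self, y):
        y = np.asarray(y, dtype=float)
        a_inv, a_hkG, a_hkF, a_pgi = self._unit_rates(y)
        J = np.zeros((N_SPECIES, N_ENZYMES) + y.shape[1:])
        J[Species.G, 0] = a_inv
        J[Species.G, 1] = -a_hkG
        J[Species.F, 0] = a_inv
        J[Species.F, 1] = -a_hkF
        J[Species.F6P, 1] = a_hkF
        J[Species.F6P, 2] = -a_pgi
        J[Species.G6P, 1] = a_hkG
        J[Species.G6P, 2] = a_pgi
        return J

    # -- export membrane -----------------------------------------------------
    def export_rates(self, y):
        y = np.asarray(y, dtype=float)
        r = _g6p_export_raw(y[Species.G6P], y[Species.PI], self.params)
        R = np.zeros(y.shape)
        R[Species.PI] = r
        R[Species.G6P] = -r
        return R

    def export_jac_y(self, y):
        y = np.asarray(y, dtype=float)
        _, drdG, drdP = _g6p_export_raw_grad(y[Species.G6P], y[Species.PI],
                                             self.params)
        J = np.zeros((N_SPECIES, N_SPECIES) + y.shape[1:])
        J[Species.PI, Species.G6P] = drdG
        J[Species.PI, Species.PI] = drdP
        J[Species.G6P, Species.G6P] = -drdG
        J[Species.G6P, Species.PI] = -drdP
        return J


# ---------------------------------------------------------------------------
# stoichiometric bookkeeping / decoupling rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StoichiometricMatrix:
    """Integer stoichiometric matrix split into bead-surface and export blocks.

    Rows are species, columns are reactions; ``S_b`` holds the bead-surface
    reactions and ``S_e`` the membrane-transport reactions.
    """

    species: tuple
    reactions_b: tuple
    reactions_e: tuple
    S_b: np.ndarray
    S_e: np.ndarray

    def __post_init__(self) -> None:
        Sb = np.asarray(self.S_b, dtype=int)
        Se = np.asarray(self.S_e, dtype=int)
        if Sb.shape[0] != len(self.species) or Se.shape[0] != len(self.species):
            raise KineticsError("row count must equal number of species")
        if Sb.shape[1] != len(self.reactions_b) or Se.shape[1] != len(self.reactions_e):
            raise KineticsError("column count must equal number of reactions")
        object.__setattr__(self, "S_b", Sb)
        object.__setattr__(self, "S_e", Se)

    @property
    def combined(self) -> np.ndarray:
        """The matrix (S_b | S_e) whose rank counts the coupled species."""
        return np.hstack([self.S_b, self.S_e])


def _exact_rank(M: np.ndarray) -> int:
    """Rank over the rationals by Fraction-based Gaussian elimination."""
    A = [[Fraction(int(v)) for v in row] for row in np.asarray(M, dtype=int)]
    nrow, ncol = len(A), len(A[0])
    rank = 0
    row = 0
    for col in range(ncol):
        piv = next((r for r in range(row, nrow) if A[r][col] != 0), None)
        if piv is None:
            continue
        A[row], A[piv] = A[piv], A[row]
        pv = A[row][col]
        for r in range(row + 1, nrow):
            if A[r][col] != 0:
                fac = A[r][col] / pv
                A[r] = [a - fac * b for a, b in zip(A[r], A[row])]
        rank += 1
        row += 1
        if row == nrow:
            break
    return rank


def coupled_species_count(S: StoichiometricMatrix) -> int:
    """Number of species left coupled after the stoichiometric decoupling
    transform: the rank of (S_b | S_e), computed by exact elimination.

    A linear change of variables based on the image of (S_b | S_e) decouples
    the reactive system into rank-many coupled species and pure-diffusion
    remainders; full rank means no reduction is possible.
    """
    M = S.combined
    if M.size == 0:
        raise KineticsError("empty stoichiometric matrix")
    return _exact_rank(M)


def full_network_matrix() -> StoichiometricMatrix:
    """Stoichiometric matrix of the complete reaction network.

    Eleven tracked metabolites (S_e, S, G, F, ATP, ADP, G6P, F6P, Pi, G6P_e,
    Pi_e); bead-surface block = reactions (1)-(4), export block = the two
    transport reactions (0) sucrose import and (5) G6P/Pi antiport.
    """
    species = ("S_e", "S", "G", "F", "ATP", "ADP", "G6P", "F6P", "Pi",
               "G6P_e", "Pi_e")
    idx = {s: i for i, s in enumerate(species)}

    def col(changes):
        c = np.zeros(len(species), dtype=int)
        for s, v in changes.items():
            c[idx[s]] = v
        return c

    Sb = np.column_stack([
        col({"S": -1, "G": 1, "F": 1}),                       # (1) invertase
        col({"G": -1, "ATP": -1, "G6P": 1, "ADP": 1}),        # (2) hk on G
        col({"F": -1, "ATP": -1, "F6P": 1, "ADP": 1}),        # (3) hk on F
        col({"F6P": -1, "G6P": 1}),                           # (4) pgi
    ])
    Se = np.column_stack([
        col({"S_e": -1, "S": 1}),                             # (0) S import
        col({"G6P": -1, "Pi_e": -1, "G6P_e": 1, "Pi": 1}),    # (5) antiport
    ])
    return StoichiometricMatrix(species, ("inv", "hkG", "hkF", "pgi"),
                                ("S_transport", "G6P_transport"), Sb, Se)


def se_network_matrix() -> StoichiometricMatrix:
    """Stoichiometric matrix of the SE reduction over the five unknowns."""
    species = ("G", "F", "F6P", "Pi", "G6P")
    idx = {s: i for i, s in enumerate(species)}

    def col(changes):
        c = np.zeros(len(species), dtype=int)
        for s, v in changes.items():
            c[idx[s]] = v
        return c

    Sb = np.column_stack([
        col({"G": 1, "F": 1}),          # (1) invertase (S fixed)
        col({"G": -1, "G6P": 1}),       # (2) hk on G (ATP fixed)
        col({"F": -1, "F6P": 1}),       # (3) hk on F
        col({"F6P": -1, "G6P": 1}),     # (4) pgi
    ])
    Se = np.column_stack([
        col({"G6P": -1, "Pi": 1}),      # (5) antiport (external pools fixed)
    ])
    return StoichiometricMatrix(species, ("inv", "hkG", "hkF", "pgi"),
                                ("G6P_transport",), Sb, Se)
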