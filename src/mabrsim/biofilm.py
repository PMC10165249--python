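"""One-dimensional counter-diffusional biofilm solver.

The biofilm grows on the outside of a gas-permeable hollow-fibre membrane:
oxygen enters at the membrane face (x = 0) through a diffusive membrane
link from a well-mixed gas compartment, while ammonium and the other
solutes arrive from the bulk liquid across a stagnant liquid boundary
layer at the biofilm surface (x = Lf).  Solutes are treated as
quasi-steady (reaction-diffusion boundary value problem, solved by damped
Newton on a finite-volume grid); biomass volume fractions follow the
Wanner-Gujer mixed-culture formulation with growth-induced advection and
surface erosion at exactly the biofilm growth velocity, so that the
biofilm thickness stays constant.

Geometry may be planar or cylindrical (the default for hollow fibres);
all boundary fluxes are reported per unit *membrane outer area*, the
reference area used for areal removal rates throughout the package.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from . import params as P
from .exceptions import InvalidParameterError, SolverError, StepSizeError
from .params import (
    I_AOO,
    I_INERT,
    I_NH4,
    I_NO2,
    I_NOO,
    I_O2,
    KineticParameterSet,
    SOLUTES,
    TemperatureAdjusted,
    TemperatureRuleSet,
    oxygen_saturation,
    temperature_adjusted,
)

log = logging.getLogger(__name__)

N_SOL = len(SOLUTES)

# default gas-side O2 partial pressure: 21 % of (atmospheric + 235 mbar gauge)
DEFAULT_GAS_PO2 = 0.21 * (1.013 + 0.235)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiofilmGeometry:
    """Geometry of the biofilm and its external boundary layer.

    ``mode`` is ``"cylindrical"`` (biofilm on the outside of a hollow fibre
    of outer radius ``membrane_outer_radius``) or ``"planar"``.  ``Lf`` is
    the biofilm thickness and ``L_LBL`` the stagnant liquid boundary layer
    thickness, both in m.
    """

    mode: str = "cylindrical"
    Lf: float = 150e-6
    L_LBL: float = 50e-6
    membrane_outer_radius: float = 275e-6  # 550 um fibre outer diameter
    membrane_wall: float = 135e-6  # (550 - 280)/2 um

    def __post_init__(self):
        if self.mode not in ("planar", "cylindrical"):
            raise InvalidParameterError(f"unknown geometry mode {self.mode!r}")
        if not self.Lf > 0:
            raise InvalidParameterError("Lf must be positive")
        if not self.L_LBL > 0:
            raise InvalidParameterError("L_LBL must be positive")
        if self.mode == "cylindrical" and not self.membrane_outer_radius > 0:
            raise InvalidParameterError(
                "cylindrical mode requires membrane_outer_radius > 0"
            )

    @property
    def area_ratio(self) -> float:
        """Liquid-face area per unit membrane outer area."""
        if self.mode == "planar":
            return 1.0
        return (self.membrane_outer_radius + self.Lf) / self.membrane_outer_radius


@dataclass(frozen=True)
class MembraneBoundary:
    """Gas compartment seen through the membrane: O2 partial pressure in bar."""

    gas_pO2: float = DEFAULT_GAS_PO2

    def __post_init__(self):
        if self.gas_pO2 < 0:
            raise InvalidParameterError("gas_pO2 must be non-negative")


@dataclass(frozen=True)
class BulkLiquidState:
    """Bulk liquid composition (g/m3, ordered O2, NH4, NO2, NO3) and
    temperature in degC."""

    S_bulk: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 35.0, 0.0, 0.0])
    )
    temperature: float = 20.0

    def __post_init__(self):
        S = np.asarray(self.S_bulk, dtype=float)
        if S.shape != (N_SOL,):
            raise InvalidParameterError("S_bulk must have one entry per solute")
        if np.any(S < 0):
            raise InvalidParameterError("bulk concentrations must be non-negative")
        object.__setattr__(self, "S_bulk", S)


@dataclass
class BiofilmState:
    """Spatial state: grid of cell centres over [0, Lf] (membrane face at 0),
    solute profiles ``S`` (4 x n, g/m3), guild volume fractions ``eps``
    (3 x n: AOO, NOO, inerts) and elapsed biofilm time ``t`` in d."""

    x: np.ndarray
    S: np.ndarray
    eps: np.ndarray
    t: float = 0.0

    def validate(self):
        if np.any(np.diff(self.x) <= 0):
            raise InvalidParameterError("grid must be strictly increasing")
        if np.any(self.eps < 0) or np.any(self.eps.sum(axis=0) > 1 + 1e-9):
            raise InvalidParameterError("volume fractions must satisfy 0 <= eps, sum <= 1")
        if np.any(self.S < 0):
            raise InvalidParameterError("solute profiles must be non-negative")

    def copy(self) -> "BiofilmState":
        return BiofilmState(self.x.copy(), self.S.copy(), self.eps.copy(), self.t)


@dataclass(frozen=True)
class SolverOptions:
    """Numerical settings for the biofilm solver.

    ``n_nodes`` finite volumes over the film; Newton solute solves iterate
    to a residual of ``newton_tol`` relative to the boundary flux scale;
    the pseudo-time march to steady state probes every ``probe_interval``
    simulated days and stops when the relative change of each guild's total
    biomass and of the NH4 removal rate falls below ``steady_tol``.
    """

    n_nodes: int = 100
    newton_tol: float = 1e-10
    newton_max_iter: int = 60
    dt_init: float = 0.02
    dt_max: float = 2.0
    probe_interval: float = 5.0
    steady_tol: float = 1e-4
    max_time: float = 6000.0
    eps0_AOO: float = 0.15
    eps0_NOO: float = 0.15
    rate_floor: float = 1e-6  # g N m-2 d-1, below which a rate counts as zero


@dataclass
class SteadyStateResult:
    """Converged biofilm state with boundary fluxes.

    Fluxes are g/(m2 d) per *membrane outer area*, positive into the
    biofilm: ``membrane_flux`` across the membrane face (only O2 can be
    non-zero) and ``liquid_flux`` across the biofilm-bulk interface.  The
    NH4 entry of ``liquid_flux`` is the areal ammonium removal rate.
    """

    state: BiofilmState
    membrane_flux: np.ndarray
    liquid_flux: np.ndarray
    geometry: BiofilmGeometry
    bulk: BulkLiquidState
    membrane: MembraneBoundary
    converged: bool
    iterations: int
    residual: float
    trajectory: list = field(default_factory=list)

    @property
    def removal_rate(self) -> float:
        """Areal NH4-N removal rate, g N m-2 d-1 (membrane-area referenced)."""
        return float(self.liquid_flux[I_NH4])


# ---------------------------------------------------------------------------
# discretisation helpers
# ---------------------------------------------------------------------------


class _Grid:
    """Uniform finite-volume grid with planar or cylindrical metric.

    ``r_faces``/``r_cells`` are the metric weights (1 for planar, radius for
    cylindrical); cell volumes per unit membrane area are ``r_cells*dx/r0``.
    """

    def __init__(self, geometry: BiofilmGeometry, n: int):
        self.n = n
        self.dx = geometry.Lf / n
        self.x_faces = np.linspace(0.0, geometry.Lf, n + 1)
        self.x = 0.5 * (self.x_faces[:-1] + self.x_faces[1:])
        if geometry.mode == "cylindrical":
            R = geometry.membrane_outer_radius
            self.r_faces = R + self.x_faces
            self.r_cells = R + self.x
            self.r0 = R
        else:
            self.r_faces = np.ones(n + 1)
            self.r_cells = np.ones(n)
            self.r0 = 1.0
        # cell volumes per unit membrane outer area (exact for the metric)
        self.V = self.r_cells * self.dx / self.r0


def initial_state(
    geometry: BiofilmGeometry,
    bulk: BulkLiquidState,
    options: SolverOptions,
) -> BiofilmState:
    """Unbiased initial condition: uniform AOO/NOO volume fractions and
    solutes at bulk values."""
    g = _Grid(geometry, options.n_nodes)
    S = np.tile(bulk.S_bulk[:, None], (1, g.n))
    eps = np.zeros((3, g.n))
    eps[I_AOO] = options.eps0_AOO
    eps[I_NOO] = options.eps0_NOO
    return BiofilmState(x=g.x, S=S, eps=eps, t=0.0)


def _default_reaction(eps, kin: KineticParameterSet, adj: TemperatureAdjusted):
    """Build the solute reaction callback for a frozen biomass profile.

    Returns ``reaction(S) -> (q, dq)`` with ``q`` shape (4, n) volumetric
    conversion rates and ``dq`` shape (4, 4, n) the Jacobian dq_c/dS_c2.
    Negative concentrations are clipped to zero inside the rate laws (with
    zero derivative), which keeps Newton iterations well defined.
    """
    X_A = eps[I_AOO] * kin.rho_X
    X_N = eps[I_NOO] * kin.rho_X
    nu = P.stoichiometry_matrix(kin)[:, :N_SOL]  # (4 processes, 4 solutes)

    K_nh4, K_no2 = kin.K_NH4, kin.K_NO2
    K_oa, K_on = kin.K_O2_AOO, kin.K_O2_NOO

    def reaction(S):
        Sc = np.maximum(S, 0.0)
        o2, nh4, no2 = Sc[I_O2], Sc[I_NH4], Sc[I_NO2]
        m_o_a, m_o_n = o2 / (K_oa + o2), o2 / (K_on + o2)
        m_nh4, m_no2 = nh4 / (K_nh4 + nh4), no2 / (K_no2 + no2)
        # d/dS of S/(K+S) = K/(K+S)^2, zero where S was clipped
        pos = (S > 0).astype(float)
        d_o_a = K_oa / (K_oa + o2) ** 2 * pos[I_O2]
        d_o_n = K_on / (K_on + o2) ** 2 * pos[I_O2]
        d_nh4 = K_nh4 / (K_nh4 + nh4) ** 2 * pos[I_NH4]
        d_no2 = K_no2 / (K_no2 + no2) ** 2 * pos[I_NO2]

        n = S.shape[1]
        rates = np.empty((4, n))
        rates[0] = adj.mu_AOO * m_nh4 * m_o_a * X_A
        rates[1] = adj.mu_NOO * m_no2 * m_o_n * X_N
        rates[2] = adj.b_AOO * m_o_a * X_A
        rates[3] = adj.b_NOO * m_o_n * X_N

        # process-rate derivatives wrt each solute
        drates = np.zeros((4, N_SOL, n))
        drates[0, I_O2] = adj.mu_AOO * m_nh4 * d_o_a * X_A
        drates[0, I_NH4] = adj.mu_AOO * d_nh4 * m_o_a * X_A
        drates[1, I_O2] = adj.mu_NOO * m_no2 * d_o_n * X_N
        drates[1, I_NO2] = adj.mu_NOO * d_no2 * m_o_n * X_N
        drates[2, I_O2] = adj.b_AOO * d_o_a * X_A
        drates[3, I_O2] = adj.b_NOO * d_o_n * X_N

        q = np.tensordot(nu.T, rates, axes=1)  # (4 solutes, n)
        dq = np.tensordot(nu.T, drates, axes=1)  # (4, 4, n)
        return q, dq

    return reaction


# ---------------------------------------------------------------------------
# quasi-steady solute boundary value problem
# ---------------------------------------------------------------------------


def solve_solute_profiles(
    state: BiofilmState,
    bulk: BulkLiquidState,
    membrane: MembraneBoundary,
    geometry: BiofilmGeometry,
    kin: KineticParameterSet,
    rules: TemperatureRuleSet,
    options: SolverOptions = SolverOptions(),
    reaction=None,
):
    """Solve the quasi-steady reaction-diffusion profiles for all solutes.

    The biomass profile in ``state`` is frozen during the solve.  Boundary
    conditions: at the membrane face, flux = permeance * (C_sat - S) for O2
    and zero flux for the other solutes; at the liquid face, a stagnant-film
    flux law D_w * (S_bulk - S_surface) / L_LBL.  The two half-cell
    diffusive resistances adjacent to the boundaries are included in series
    with the boundary conductances.

    Returns ``(S, membrane_flux, liquid_flux, diagnostics)`` with fluxes per
    membrane outer area, positive into the biofilm.  Raises
    :class:`SolverError` on non-convergence or negative concentrations
    beyond tolerance.

    A custom ``reaction(S) -> (q, dq)`` callback may replace the built-in
    kinetics (used by closed-form oracle tests).
    """
    g = _Grid(geometry, state.eps.shape[1])
    adj = temperature_adjusted(kin, rules, bulk.temperature)
    if reaction is None:
        reaction = _default_reaction(state.eps, kin, adj)

    csat = oxygen_saturation(bulk.temperature, membrane.gas_pO2, rules)
    Df = adj.D_film  # (4,)
    Dw = adj.D_water

    n = g.n
    # interior face conductances (4, n-1), scaled by face metric
    a_int = (Df[:, None] / g.dx) * g.r_faces[None, 1:-1]
    # membrane-face conductance (O2 only), half-cell resistance in series
    g_mem = np.zeros(N_SOL)
    if adj.permeance > 0:
        g_mem[I_O2] = g.r_faces[0] / (1.0 / adj.permeance + 0.5 * g.dx / Df[I_O2])
    # liquid-face conductance (all solutes), LBL film + half cell
    g_liq = g.r_faces[-1] / (geometry.L_LBL / Dw + 0.5 * g.dx / Df)
    Vr = g.V * g.r0  # metric cell volumes (r dx)

    S = np.maximum(np.asarray(state.S, dtype=float).copy(), 0.0)
    Sb = bulk.S_bulk
    # second-order source correction of the boundary half-cell flux: within
    # the half cell the profile is quadratic in the local reaction, so the
    # effective driving force gains a term -q dx^2 / (8 D); this makes the
    # scheme exact for constant-source parabolic profiles
    qcorr = g.dx**2 / (8.0 * Df)

    def residual(S):
        q, dq = reaction(S)
        R = np.zeros_like(S)
        R[:, :-1] += a_int * (S[:, 1:] - S[:, :-1])
        R[:, 1:] -= a_int * (S[:, 1:] - S[:, :-1])
        R[:, 0] += g_mem * (csat - S[:, 0] - qcorr * q[:, 0])
        R[:, -1] += g_liq * (Sb - S[:, -1] - qcorr * q[:, -1])
        R += Vr * q
        return R, q, dq

    # residual scale: typical boundary flux magnitude (per metric area)
    scale = max(
        float(g_mem[I_O2] * max(csat, 1.0)),
        float(np.max(g_liq * np.maximum(Sb, 1.0))),
        1e-30,
    )
    tol = options.newton_tol * scale

    nun = N_SOL * n
    ab = np.zeros((9, nun))  # banded Jacobian, l = u = 4
    iters = 0
    R, q, dq = residual(S)
    rnorm = float(np.max(np.abs(R)))
    while rnorm > tol:
        if iters >= options.newton_max_iter:
            raise SolverError(
                f"solute Newton did not converge in {iters} iterations "
                f"(residual {rnorm:.3e}, tol {tol:.3e})",
                residual=rnorm,
            )
        ab[:] = 0.0
        # transport: same-solute couplings at offsets 0, +-4
        for c in range(N_SOL):
            diag = np.zeros(n)
            diag[:-1] -= a_int[c]
            diag[1:] -= a_int[c]
            diag[0] -= g_mem[c]
            diag[-1] -= g_liq[c]
            idx = np.arange(n) * N_SOL + c
            ab[4, idx] += diag
            # upper neighbour S_{i+1}: a[row, row+4]
            ab[0, idx[:-1] + N_SOL] += a_int[c]
            # lower neighbour S_{i-1}: a[row, row-4]
            ab[8, idx[1:] - N_SOL] += a_int[c]
        # reaction Jacobian: within-node solute coupling, offsets c2-c
        for c in range(N_SOL):
            rows = np.arange(n) * N_SOL + c
            for c2 in range(N_SOL):
                cols = np.arange(n) * N_SOL + c2
                ab[4 + c - c2, cols] += Vr * dq[c, c2]
                # boundary half-cell source corrections
                ab[4 + c - c2, cols[0]] -= g_mem[c] * qcorr[c] * dq[c, c2, 0]
                ab[4 + c - c2, cols[-1]] -= g_liq[c] * qcorr[c] * dq[c, c2, -1]

        delta = solve_banded((4, 4), ab, -R.T.ravel()).reshape(n, N_SOL).T
        lam, accepted = 1.0, False
        while lam >= 1.0 / 256:
            S_try = S + lam * delta
            R_try, q_try, dq_try = residual(S_try)
            r_try = float(np.max(np.abs(R_try)))
            if r_try < rnorm * (1.0 - 1e-4 * lam) or r_try < tol:
                S, R, q, dq, rnorm = S_try, R_try, q_try, dq_try, r_try
                accepted = True
                break
            lam *= 0.5
        if not accepted:  # forced step; damping exhausted
            S = S + (1.0 / 256) * delta
            R, q, dq = residual(S)
            rnorm = float(np.max(np.abs(R)))
        iters += 1

    if np.min(S) < -1e-8 * max(1.0, float(np.max(np.abs(S)))):
        raise SolverError(
            f"negative concentration beyond tolerance: min S = {np.min(S):.3e}",
            residual=rnorm,
        )
    S = np.maximum(S, 0.0)

    # boundary fluxes per membrane outer area, positive into the biofilm
    membrane_flux = g_mem * (csat - S[:, 0] - qcorr * q[:, 0]) / g.r0
    liquid_flux = g_liq * (Sb - S[:, -1] - qcorr * q[:, -1]) / g.r0
    diagnostics = {
        "iterations": iters,
        "residual": rnorm,
        "net_conversion": (Vr / g.r0) @ q.T,  # depth-integrated, per mem area
    }
    return S, membrane_flux, liquid_flux, diagnostics


# ---------------------------------------------------------------------------
# biomass dynamics (Wanner-Gujer, constant thickness)
# ---------------------------------------------------------------------------


def _growth_fields(state, kin, adj):
    """Local specific rates from the current solute profiles.

    Returns (lam, G, inert_src_coeff): per-guild net specific rates
    lam = mu_loc - b_loc (1/d, shape (2, n)); volumetric solids production
    G = sum_k (mu_k - (1-f_I) b_k) eps_k; and the per-guild decay rates
    feeding the inert pool.
    """
    Sc = np.maximum(state.S, 0.0)
    o2, nh4, no2 = Sc[I_O2], Sc[I_NH4], Sc[I_NO2]
    m_o_a = o2 / (kin.K_O2_AOO + o2)
    m_o_n = o2 / (kin.K_O2_NOO + o2)
    mu_a = adj.mu_AOO * nh4 / (kin.K_NH4 + nh4) * m_o_a
    mu_n = adj.mu_NOO * no2 / (kin.K_NO2 + no2) * m_o_n
    b_a = adj.b_AOO * m_o_a  # O2-switched endogenous respiration
    b_n = adj.b_NOO * m_o_n
    lam = np.vstack([mu_a - b_a, mu_n - b_n])
    eps_a, eps_n = state.eps[I_AOO], state.eps[I_NOO]
    G = (mu_a - (1 - kin.f_I) * b_a) * eps_a + (mu_n - (1 - kin.f_I) * b_n) * eps_n
    inert_rate = kin.f_I * (b_a * eps_a + b_n * eps_n)
    return lam, G, inert_rate


def advance_biomass(
    state: BiofilmState,
    dt: float,
    geometry: BiofilmGeometry,
    kin: KineticParameterSet,
    rules: TemperatureRuleSet,
    temperature: float,
    stability_factor: float = 20.0,
) -> BiofilmState:
    """Advance the guild volume fractions by ``dt`` days (solutes frozen).

    Wanner-Gujer update with the solid-matrix advection velocity
    ``u'(x) = sum_k (mu_k - (1 - f_I) b_k) eps_k / sum_k eps_k`` and
    first-order upwind transport, integrated with a semi-implicit
    (linearised) step that is unconditionally stable in the advection term.
    The surface cell loses biomass by advective outflow at exactly the
    growth velocity u(Lf), which is the constant-thickness detachment
    closure; when u(Lf) < 0 nothing enters from outside, so the thickness
    is constant in all regimes.  With this velocity the total solids
    fraction is conserved exactly (growth is exchanged one-for-one against
    detachment once the spatial profile is stationary).
    """
    if not dt > 0:
        raise InvalidParameterError("dt must be positive")
    adj = temperature_adjusted(kin, rules, temperature)
    lam, G, inert_rate = _growth_fields(state, kin, adj)
    lam_max = float(np.max(np.abs(lam))) if lam.size else 0.0
    if dt * lam_max > stability_factor:
        raise StepSizeError(
            f"dt = {dt} too large for local net growth rates "
            f"(max |mu - b| = {lam_max:.3g} 1/d)",
            suggested_dt=0.5 * stability_factor / lam_max,
        )

    g = _Grid(geometry, state.eps.shape[1])
    n = g.n
    Vr = g.r_cells * g.dx
    Sc = np.maximum(state.S, 0.0)
    m_o_a = Sc[I_O2] / (kin.K_O2_AOO + Sc[I_O2])
    m_o_n = Sc[I_O2] / (kin.K_O2_NOO + Sc[I_O2])
    sigma_tilde = np.vstack(  # volume production rates (inert share retained)
        [lam[0] + kin.f_I * adj.b_AOO * m_o_a, lam[1] + kin.f_I * adj.b_NOO * m_o_n]
    )

    def implicit_step(eps_guess):
        """One Picard pass: advection velocity from ``eps_guess``."""
        G = sigma_tilde[0] * eps_guess[I_AOO] + sigma_tilde[1] * eps_guess[I_NOO]
        E_safe = np.maximum(eps_guess.sum(axis=0), 1e-9)
        # metric flux potential phi(r_f) = int r G/E dr; w_f = r_f u_f = phi
        w = np.concatenate([[0.0], np.cumsum(G / E_safe * g.r_cells * g.dx)])
        w_pos = np.maximum(w, 0.0)
        w_neg = np.minimum(w, 0.0)
        # upwind divergence row i: (F_{i+1} - F_i)/Vr_i with
        # F_f = w_f^+ eps_{f-1} + w_f^- eps_f; face n admits outflow only
        diag_adv = (w_pos[1:] - w_neg[:-1]) / Vr
        upper_adv = w_neg[1:] / Vr
        lower_adv = -w_pos[:-1] / Vr

        def solve(lam_loc, rhs):
            ab = np.zeros((3, n))
            ab[1] = 1.0 / dt + diag_adv - lam_loc
            ab[0, 1:] = upper_adv[:-1]
            ab[2, :-1] = lower_adv[1:]
            return solve_banded((1, 1), ab, rhs)

        out = np.empty_like(state.eps)
        out[I_AOO] = solve(lam[0], state.eps[I_AOO] / dt)
        out[I_NOO] = solve(lam[1], state.eps[I_NOO] / dt)
        inert_src = kin.f_I * (
            adj.b_AOO * m_o_a * out[I_AOO] + adj.b_NOO * m_o_n * out[I_NOO]
        )
        out[I_INERT] = solve(np.zeros(n), state.eps[I_INERT] / dt + inert_src)
        return out

    # iterate the advection velocity to self-consistency with the updated
    # fractions; this keeps the total solids fraction exactly conserved
    # (the lagged-velocity variant lets it drift during fast transients)
    new_eps = state.eps
    for _ in range(30):
        prev = new_eps
        new_eps = implicit_step(new_eps)
        if np.max(np.abs(new_eps - prev)) < 1e-12:
            break
    else:
        raise StepSizeError(
            "advection velocity iteration did not converge; reduce dt",
            suggested_dt=0.5 * dt,
        )
    new_eps = np.maximum(new_eps, 0.0)
    return BiofilmState(x=state.x, S=state.S, eps=new_eps, t=state.t + dt)


# ---------------------------------------------------------------------------
# steady state
# ---------------------------------------------------------------------------


def _biomass_totals(state: BiofilmState, geometry: BiofilmGeometry) -> np.ndarray:
    """Depth-integrated guild volume per membrane outer area, m."""
    g = _Grid(geometry, state.eps.shape[1])
    return state.eps @ g.V


def run_to_steady_state(
    geometry: BiofilmGeometry,
    bulk: BulkLiquidState,
    membrane: MembraneBoundary,
    kin: KineticParameterSet,
    rules: TemperatureRuleSet,
    options: SolverOptions = SolverOptions(),
    state: BiofilmState | None = None,
) -> SteadyStateResult:
    """March the biofilm to steady state under constant-thickness detachment.

    Alternates quasi-steady solute solves with semi-implicit biomass steps,
    growing the pseudo-time step geometrically up to ``options.dt_max``.
    Convergence: over a probe window of ``options.probe_interval`` simulated
    days, the relative change of every guild's depth-integrated biomass and
    of the NH4 areal removal rate must fall below ``options.steady_tol``
    (guilds whose total biomass has collapsed to a negligible film fraction
    are exempt, as is the rate when below ``rate_floor``).
    """
    if state is None:
        state = initial_state(geometry, bulk, options)
    adj = temperature_adjusted(kin, rules, bulk.temperature)

    dt = options.dt_init
    # a guild whose mean volume fraction is below 0.1 % counts as washed out
    biomass_floor = 1e-3 * geometry.Lf
    next_probe = options.probe_interval
    prev_totals = _biomass_totals(state, geometry)
    prev_rate = None
    trajectory = []
    n_iter = 0
    last_diag = {"residual": np.nan}

    while state.t < options.max_time:
        S, mem_flux, liq_flux, diag = solve_solute_profiles(
            state, bulk, membrane, geometry, kin, rules, options
        )
        state.S = S
        last_diag = diag
        rate = float(liq_flux[I_NH4])

        lam, _, _ = _growth_fields(state, kin, adj)
        lam_max = float(np.max(np.abs(lam))) + 1e-12
        dt = min(dt * 1.25, options.dt_max, 8.0 / lam_max)
        for _ in range(6):
            try:
                state = advance_biomass(
                    state, dt, geometry, kin, rules, bulk.temperature
                )
                break
            except StepSizeError as exc:
                dt = exc.suggested_dt
        else:
            raise SolverError("biomass step failed at the minimum step size")
        n_iter += 1

        if state.t >= next_probe:
            totals = _biomass_totals(state, geometry)
            trajectory.append((state.t, *totals, rate))
            biomass_ok = True
            for k in (I_AOO, I_NOO):
                ref = max(totals[k], biomass_floor)
                if abs(totals[k] - prev_totals[k]) > options.steady_tol * ref:
                    biomass_ok = False
            rate_ok = prev_rate is not None and abs(rate - prev_rate) <= (
                options.steady_tol * max(abs(rate), options.rate_floor)
            )
            if biomass_ok and rate_ok:
                S, mem_flux, liq_flux, diag = solve_solute_profiles(
                    state, bulk, membrane, geometry, kin, rules, options
                )
                state.S = S
                log.info(
                    "steady state at t = %.1f d after %d steps; "
                    "NH4 removal rate %.4f g N m-2 d-1",
                    state.t, n_iter, float(liq_flux[I_NH4]),
                )
                return SteadyStateResult(
                    state=state,
                    membrane_flux=mem_flux,
                    liquid_flux=liq_flux,
                    geometry=geometry,
                    bulk=bulk,
                    membrane=membrane,
                    converged=True,
                    iterations=n_iter,
                    residual=diag["residual"],
                    trajectory=trajectory,
                )
            prev_totals, prev_rate = totals, rate
            next_probe = state.t + options.probe_interval

    raise SolverError(
        f"no steady state within {options.max_time} simulated days",
        residual=last_diag.get("residual"),
        trajectory=trajectory,
    )


def membrane_area_flux(result: SteadyStateResult, solute: str) -> float:
    """Liquid-face flux of ``solute`` per membrane outer area, positive into
    the biofilm (so the NH4 entry is the areal removal rate).

    The rescaling from the liquid-face area to the membrane outer area
    (cylindrical: factor (R_m + Lf)/R_m) is already applied by the solver;
    this accessor exposes the per-solute value by name.
    """
    if solute not in SOLUTES:
        raise KeyError(f"unknown solute {solute!r}; expected one of {SOLUTES}")
    return float(result.liquid_flux[SOLUTES.index(solute)])
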