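"""Finite-volume discretization of the distributed tissue transport model.

The peritoneal tissue is a 1-D layer of depth ``L`` (x = 0 at the peritoneal
surface, x = L the deep zero-flux boundary).  Two conserved fields live on a
graded cell-centered mesh:

* hydration ``theta`` (fractional fluid volume), with interstitial pressure
  ``P = P(theta)`` through the compliance law, obeying
  ``d(theta)/dt = -d(j_v)/dx + q_v - q_l`` where
  ``j_v = -K(theta) (dP/dx - sigma_T RT dC/dx)`` (Darcy flow with a
  crystalloid osmotic contribution);
* interstitial glucose ``C`` via ``d(theta C)/dt = -d(j_s)/dx + q_s - q_l C``
  with ``j_s = -theta D(theta) dC/dx + (1 - sigma_T) C_upwind j_v``.

``q_v`` is Starling capillary filtration (vasodilation-scaled), ``q_l``
pressure-sensitive lymphatic uptake.  The x = 0 boundary sees the cavity
pressure and glucose; x = L is zero-flux for both fields.

Explicit conservative Euler stepping with an adaptive stability-bounded time
step; every step returns an exact discrete flux ledger so that water and
solute closure can be audited to rounding error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import (
    ModelParameters,
    hydration_from_pressure,
    pressure_from_hydration,
    hydraulic_conductivity,
    solute_diffusivity,
    vasodilation_factor,
    lymph_flow,
)

__all__ = [
    "TissueState", "FluxBalance", "CavityBoundary", "init_grid", "graded_mesh",
    "fluid_flux", "solute_flux", "capillary_sources", "step", "integrate",
    "tissue_water", "tissue_glucose", "relax_dry", "StepError",
]


class StepError(RuntimeError):
    """Raised when a time step violates stability or state bounds."""


@dataclass(frozen=True)
class CavityBoundary:
    """Dirichlet data at the peritoneal surface: cavity pressure and glucose."""
    P_cavity: float   # mmHg
    C_cavity: float   # mmol/mL


@dataclass
class TissueState:
    x_centers: np.ndarray   # cm, strictly increasing cell centers
    dx: np.ndarray          # cm, cell widths (sum = L)
    theta: np.ndarray       # fractional hydration per cell
    C_glu: np.ndarray       # mmol per mL interstitial fluid, per cell
    t: float = 0.0          # min

    def copy(self) -> "TissueState":
        return TissueState(self.x_centers, self.dx,
                           self.theta.copy(), self.C_glu.copy(), self.t)

    @property
    def n_cells(self) -> int:
        return self.theta.size

    def pressure(self, params: ModelParameters) -> np.ndarray:
        return pressure_from_hydration(self.theta, params)

    def validate(self, params: ModelParameters) -> None:
        if np.any(self.theta <= params.theta_min) or np.any(self.theta >= params.theta_max):
            raise ValueError("hydration outside (theta_min, theta_max)")
        if np.any(self.C_glu < 0):
            raise ValueError("negative interstitial glucose")
        if np.any(np.diff(self.x_centers) <= 0):
            raise ValueError("grid centers must be strictly increasing")


@dataclass
class FluxBalance:
    """Discrete fluxes of one evaluation: interfaces 0..n (0 = cavity face)."""
    j_v: np.ndarray     # mL/(min cm^2), positive toward deep tissue (+x)
    j_s: np.ndarray     # mmol/(min cm^2)
    q_v: np.ndarray     # mL/min per mL tissue, capillary filtration per cell
    q_s: np.ndarray     # mmol/min per mL tissue
    q_l: np.ndarray     # mL/min per mL tissue, lymphatic uptake per cell

    @property
    def boundary_flux_cavity(self) -> tuple[float, float]:
        """(fluid, solute) flux density across x=0, positive into tissue."""
        return float(self.j_v[0]), float(self.j_s[0])


def graded_mesh(L: float, n_cells: int, grading_ratio: float = 1.05) -> tuple[np.ndarray, np.ndarray]:
    """Geometrically graded mesh, finest cell at the peritoneal surface.

    grading_ratio = 1 gives uniform spacing L/n.
    """
    if n_cells < 10:
        raise ValueError(f"n_cells must be >= 10, got {n_cells}")
    r = float(grading_ratio)
    if abs(r - 1.0) < 1e-12:
        dx = np.full(n_cells, L / n_cells)
    else:
        dx0 = L * (r - 1.0) / (r ** n_cells - 1.0)
        dx = dx0 * r ** np.arange(n_cells)
    x = np.cumsum(dx) - 0.5 * dx
    return x, dx


def init_grid(params: ModelParameters, n_cells: int, grading_ratio: float = 1.05) -> TissueState:
    """Tissue at the dry physiological equilibrium (uniform theta_phys).

    Interstitial glucose is set to its exact equilibrium value ``C_glu_eq``
    (within 0.03% of plasma glucose), so the state is a strict fixed point of
    the dynamics under an equilibrium boundary.
    """
    x, dx = graded_mesh(params.tissue_depth, n_cells, grading_ratio)
    theta = np.full(n_cells, params.theta_phys)
    c = np.full(n_cells, params.C_glu_eq)
    return TissueState(x, dx, theta, c, 0.0)


def _interface_theta(state: TissueState, params: ModelParameters,
                     boundary: CavityBoundary) -> np.ndarray:
    """Hydration averaged onto the n+1 interfaces (cavity face uses the
    hydration the surface would equilibrate to at cavity pressure)."""
    th = state.theta
    thb = np.empty(th.size + 1)
    p_cav = np.clip(boundary.P_cavity, -60.0, 60.0)
    thb[0] = 0.5 * (hydration_from_pressure(p_cav, params) + th[0])
    thb[1:-1] = 0.5 * (th[:-1] + th[1:])
    thb[-1] = th[-1]
    return thb


def fluid_flux(state: TissueState, params: ModelParameters,
               boundary: CavityBoundary) -> np.ndarray:
    """Darcy + osmotic volumetric flux at every interface (positive = +x)."""
    P = state.pressure(params)
    C = state.C_glu
    thb = _interface_theta(state, params, boundary)
    K = hydraulic_conductivity(thb, params)
    jv = np.zeros(state.n_cells + 1)
    d0 = state.x_centers[0]  # distance cavity face -> first center
    gradP = (P[0] - boundary.P_cavity) / d0
    gradC = (C[0] - boundary.C_cavity) / d0
    jv[0] = -K[0] * (gradP - params.sigma_T * params.RT * gradC)
    dxc = np.diff(state.x_centers)
    jv[1:-1] = -K[1:-1] * ((P[1:] - P[:-1]) / dxc
                           - params.sigma_T * params.RT * (C[1:] - C[:-1]) / dxc)
    jv[-1] = 0.0  # deep boundary: zero flux
    return jv


def solute_flux(state: TissueState, params: ModelParameters,
                boundary: CavityBoundary, jv: np.ndarray | None = None) -> np.ndarray:
    """Diffusive + convective (upwind, tissue-sieved) glucose flux."""
    if jv is None:
        jv = fluid_flux(state, params, boundary)
    C = state.C_glu
    thb = _interface_theta(state, params, boundary)
    D = solute_diffusivity(thb, params)
    js = np.zeros(state.n_cells + 1)
    d0 = state.x_centers[0]
    c_up0 = boundary.C_cavity if jv[0] > 0 else C[0]
    js[0] = (-thb[0] * D[0] * (C[0] - boundary.C_cavity) / d0
             + (1.0 - params.sigma_T) * c_up0 * jv[0])
    dxc = np.diff(state.x_centers)
    c_up = np.where(jv[1:-1] > 0, C[:-1], C[1:])
    js[1:-1] = (-thb[1:-1] * D[1:-1] * (C[1:] - C[:-1]) / dxc
                + (1.0 - params.sigma_T) * c_up * jv[1:-1])
    js[-1] = 0.0
    return js


def capillary_sources(state: TissueState, params: ModelParameters
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Starling capillary exchange per cell: (q_v, q_s).

    q_v > 0 is filtration from blood into tissue.  Local hyperglycemia both
    pulls fluid osmotically (sigma_g RT (C - C_blood)) and dilates the wall
    (vasodilation factor on LpS and PS).  Convected glucose crosses with
    sieving (1 - sigma_g) at the mean of plasma and interstitial levels.
    """
    P = state.pressure(params)
    C = state.C_glu
    vaso = vasodilation_factor(C, params)
    sg = params.sigma_g_eff
    q_v = vaso * params.LpS_density * (
        (params.P_blood - P)
        - params.rho_onc * params.Pi_blood_onc
        + sg * params.RT * (C - params.C_blood_glu)
    )
    q_s = (vaso * params.PS_density * (params.C_blood_glu - C)
           + (1.0 - sg) * 0.5 * (C + params.C_blood_glu) * q_v)
    return q_v, q_s


def _fused_fluxes(th, C, xc, dx, params: ModelParameters, P_cav, C_cav):
    """Single-pass evaluation of all fluxes and sources (hot path).

    Returns (jv, js, q_v, q_s, q_l); algebraically identical to composing
    fluid_flux / solute_flux / capillary_sources / lymph_flow.
    """
    lo, hi, span = params.theta_min, params.theta_max, params.theta_max - params.theta_min
    frac = (th - lo) / span
    P = params.compliance_midpoint + params.compliance_scale * np.log(frac / (1.0 - frac))
    n = th.size
    # interface-averaged hydration (cavity face equilibrates at cavity pressure)
    thb = np.empty(n + 1)
    pc = min(max(P_cav, -60.0), 60.0)
    zc = (pc - params.compliance_midpoint) / params.compliance_scale
    thb[0] = 0.5 * (lo + span / (1.0 + np.exp(-zc)) + th[0])
    thb[1:-1] = 0.5 * (th[:-1] + th[1:])
    thb[-1] = th[-1]
    K = params.K0 * np.exp(params.K_sensitivity * (thb - params.theta_phys))
    D = params.D0 * np.exp(params.D_sensitivity * (thb - params.theta_phys))
    sRT = params.sigma_T * params.RT

    jv = np.zeros(n + 1)
    js = np.zeros(n + 1)
    d0 = xc[0]
    jv[0] = -K[0] * ((P[0] - P_cav) / d0 - sRT * (C[0] - C_cav) / d0)
    dxc = xc[1:] - xc[:-1]
    jv[1:-1] = -K[1:-1] * ((P[1:] - P[:-1]) / dxc - sRT * (C[1:] - C[:-1]) / dxc)
    c_up0 = C_cav if jv[0] > 0 else C[0]
    js[0] = (-thb[0] * D[0] * (C[0] - C_cav) / d0
             + (1.0 - params.sigma_T) * c_up0 * jv[0])
    c_up = np.where(jv[1:-1] > 0, C[:-1], C[1:])
    js[1:-1] = (-thb[1:-1] * D[1:-1] * (C[1:] - C[:-1]) / dxc
                + (1.0 - params.sigma_T) * c_up * jv[1:-1])

    excess = np.maximum(C - params.C_blood_glu, 0.0)
    vaso = 1.0 + params.vaso_gain * excess / (params.vaso_half_sat + excess)
    sg = params.sigma_g_eff
    q_v = vaso * params.LpS_density * (
        (params.P_blood - P) - params.rho_onc * params.Pi_blood_onc
        + sg * params.RT * (C - params.C_blood_glu))
    q_s = (vaso * params.PS_density * (params.C_blood_glu - C)
           + (1.0 - sg) * 0.5 * (C + params.C_blood_glu) * q_v)
    q_l = (params.lymph_L0 + params.lymph_P_sensitivity
           * np.clip(P - params.P_eq - params.lymph_P_onset, 0.0, params.lymph_P_sat))
    return jv, js, q_v, q_s, q_l


def evaluate_fluxes(state: TissueState, params: ModelParameters,
                    boundary: CavityBoundary) -> FluxBalance:
    jv, js, q_v, q_s, q_l = _fused_fluxes(
        state.theta, state.C_glu, state.x_centers, state.dx, params,
        boundary.P_cavity, boundary.C_cavity)
    return FluxBalance(jv, js, q_v, q_s, q_l)


def stable_dt(state: TissueState, params: ModelParameters, safety: float = 0.4) -> float:
    """Explicit stability bound for the nonlinear diffusion of theta and C."""
    th = state.theta
    span = params.theta_max - params.theta_min
    # dP/dtheta of the logistic compliance
    dPdth = params.compliance_scale * span / ((th - params.theta_min) * (params.theta_max - th))
    D_water = hydraulic_conductivity(th, params) * dPdth
    D_sol = solute_diffusivity(th, params)
    D_tot = D_water + D_sol
    return float(safety * np.min(state.dx ** 2 / (2.0 * D_tot)))


@dataclass
class StepLedger:
    """Exact water/solute bookkeeping of one (or an accumulated run of) steps.

    Volumes in mL, glucose in mmol; positive = into tissue.
    """
    water_from_cavity: float = 0.0
    water_from_capillaries: float = 0.0
    water_to_lymph: float = 0.0
    glucose_from_cavity: float = 0.0
    glucose_from_capillaries: float = 0.0
    glucose_to_lymph: float = 0.0

    def add(self, other: "StepLedger") -> None:
        self.water_from_cavity += other.water_from_cavity
        self.water_from_capillaries += other.water_from_capillaries
        self.water_to_lymph += other.water_to_lymph
        self.glucose_from_cavity += other.glucose_from_cavity
        self.glucose_from_capillaries += other.glucose_from_capillaries
        self.glucose_to_lymph += other.glucose_to_lymph


def step(state: TissueState, params: ModelParameters, boundary: CavityBoundary,
         dt: float) -> tuple[TissueState, StepLedger]:
    """One conservative explicit Euler step of both fields.

    Raises :class:`StepError` if ``dt`` exceeds the stability bound, if the
    step would push hydration out of (theta_min, theta_max), or if the state
    turns non-finite; hydration is never clamped.
    """
    if dt <= 0:
        raise StepError(f"dt must be positive, got {dt}")
    if dt > stable_dt(state, params, safety=1.0) * (1.0 + 1e-9):
        raise StepError(f"dt={dt:g} exceeds the stability bound "
                        f"{stable_dt(state, params, safety=1.0):g} min")
    j_v, j_s, q_v, q_s, q_l = _fused_fluxes(
        state.theta, state.C_glu, state.x_centers, state.dx, params,
        boundary.P_cavity, boundary.C_cavity)
    fb = FluxBalance(j_v, j_s, q_v, q_s, q_l)
    A, dx = params.surface_area, state.dx

    dtheta = -(fb.j_v[1:] - fb.j_v[:-1]) / dx + fb.q_v - fb.q_l
    theta_new = state.theta + dt * dtheta
    if not np.all(np.isfinite(theta_new)):
        raise StepError(f"non-finite hydration at t={state.t:.4f} min; state dump: "
                        f"theta={state.theta!r} C={state.C_glu!r}")
    if np.any(theta_new <= params.theta_min) or np.any(theta_new >= params.theta_max):
        raise StepError("step would push hydration outside "
                        f"({params.theta_min}, {params.theta_max}) at t={state.t:.4f}")

    u = state.theta * state.C_glu
    du = -(fb.j_s[1:] - fb.j_s[:-1]) / dx + fb.q_s - fb.q_l * state.C_glu
    u_new = u + dt * du
    if np.any(u_new < -1e-10):
        raise StepError(f"negative glucose mass at t={state.t:.4f} min")
    C_new = np.maximum(u_new, 0.0) / theta_new

    ledger = StepLedger(
        water_from_cavity=A * fb.j_v[0] * dt,
        water_from_capillaries=A * float(np.sum(fb.q_v * dx)) * dt,
        water_to_lymph=A * float(np.sum(fb.q_l * dx)) * dt,
        glucose_from_cavity=A * fb.j_s[0] * dt,
        glucose_from_capillaries=A * float(np.sum(fb.q_s * dx)) * dt,
        glucose_to_lymph=A * float(np.sum(fb.q_l * state.C_glu * dx)) * dt,
    )
    new = TissueState(state.x_centers, state.dx, theta_new, C_new, state.t + dt)
    return new, ledger


def integrate(state: TissueState, params: ModelParameters, boundary: CavityBoundary,
              duration: float, safety: float = 0.4) -> tuple[TissueState, StepLedger]:
    """Advance the tissue for ``duration`` minutes under a fixed boundary.

    Adaptive stepping: dt follows the stability bound; a step that would leave
    the admissible hydration range is retried at half the step size.
    """
    ledger = StepLedger()
    t_end = state.t + duration
    while state.t < t_end - 1e-12:
        dt = min(stable_dt(state, params, safety), t_end - state.t)
        for _ in range(40):
            try:
                state, led = step(state, params, boundary, dt)
                break
            except StepError:
                dt *= 0.5
                if dt < 1e-12:
                    raise
        else:
            raise StepError("time step underflow")
        ledger.add(led)
    return state, ledger


def tissue_water(state: TissueState, params: ModelParameters) -> float:
    """Total interstitial water A * integral(theta dx), in mL."""
    return float(params.surface_area * np.sum(state.theta * state.dx))


def tissue_glucose(state: TissueState, params: ModelParameters) -> float:
    """Total interstitial glucose A * integral(theta C dx), in mmol."""
    return float(params.surface_area * np.sum(state.theta * state.C_glu * state.dx))


def relax_dry(state: TissueState, params: ModelParameters, duration: float
              ) -> TissueState:
    """Let the tissue drain toward physiological hydration over a dry period.

    The effectively empty cavity is a fixed boundary at zero gauge pressure
    with equilibrium glucose; excess tissue water leaves via the surface,
    the lymphatics and capillary reabsorption, and hydration decays toward
    its physiological level.  (Multi-day simulations instead co-integrate
    the daytime cavity explicitly; this is the standalone dry-rest
    operation.)
    """
    boundary = CavityBoundary(0.0, params.C_glu_eq)
    out, _ = integrate(state, params, boundary, duration)
    return out
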