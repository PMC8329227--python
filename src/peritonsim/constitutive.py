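"""Parameter set and constitutive laws for the hydrated peritoneal tissue model.

The peritoneal interstitium is treated as a deformable porous medium whose
fractional fluid content (hydration) ``theta`` responds to local interstitial
hydrostatic pressure ``P`` through a saturating compliance law, and whose
transport coefficients (Darcy hydraulic conductivity ``K``, glucose
diffusivity ``D``) stiffen or loosen with hydration.  Capillary exchange is
lumped Starling filtration with a glucose-dependent vasodilation multiplier on
the wall conductances, and lymphatic uptake rises with interstitial pressure
above its physiological baseline (an edema guard with onset and saturation).

Units used throughout the package: cm, mL, min, mmHg, mmol/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "ModelParameters",
    "load_parameters",
    "default_parameters",
    "hydration_from_pressure",
    "pressure_from_hydration",
    "hydraulic_conductivity",
    "solute_diffusivity",
    "vasodilation_factor",
    "lymph_flow",
    "glucose_pct_to_mmol_per_ml",
]

#: anhydrous glucose molar mass, g/mol (label "1.36%" = 13.6 g anhydrous/L)
GLUCOSE_MW = 180.16


def glucose_pct_to_mmol_per_ml(pct: float) -> float:
    """Convert a glucose label concentration in g/100 mL to mmol/mL.

    Uses the anhydrous-glucose convention: a "1.36%" fluid carries
    13.6 g/L / 180.16 g/mol = 0.0755 mmol/mL.
    """
    if pct < 0:
        raise ValueError(f"negative glucose concentration: {pct}")
    return pct * 10.0 / GLUCOSE_MW


@dataclass(frozen=True)
class ModelParameters:
    """Physical parameters of the distributed peritoneal transport model.

    All rate densities (``LpS_density``, ``PS_density``, ``lymph_L0``) are per
    mL of tissue.  ``rho_onc`` (effective oncotic weighting of the Starling
    balance) is derived, not user-set: it is calibrated so that at the dry
    physiological equilibrium (theta = theta_phys, interstitial glucose at its
    equilibrium value) capillary filtration exactly balances baseline
    lymphatic uptake.
    """

    version: str = "1"
    # geometry
    tissue_depth: float = 1.0          # L, cm
    surface_area: float = 12500.0      # A, cm^2 in contact with fluid
    # compliance theta(P): logistic between theta_min and theta_max
    theta_min: float = 0.17
    theta_phys: float = 0.18
    theta_max: float = 0.40
    compliance_scale: float = 2.26     # mmHg, logistic steepness
    compliance_midpoint: float = 6.0   # mmHg, logistic midpoint
    # tissue transport
    K0: float = 1.6e-6                 # cm^2/(min*mmHg) at theta_phys
    K_sensitivity: float = 5.0        # 1/theta, exponential gain of K(theta)
    D0: float = 1.8e-4                 # cm^2/min glucose diffusivity at theta_phys
    D_sensitivity: float = 6.0
    sigma_T: float = 0.0055            # tissue reflection coefficient for glucose
    # capillary wall (lumped Starling)
    LpS_density: float = 2.5e-5        # 1/(min*mmHg) per mL tissue
    sigma_g: float = 0.185             # effective osmotic reflection coeff., glucose
    PS_density: float = 0.04           # 1/min per mL tissue
    P_blood: float = 15.0              # mmHg
    Pi_blood_onc: float = 22.0         # mmHg plasma colloid osmotic pressure
    C_blood_glu: float = 0.005         # mmol/mL plasma glucose
    # optional three-pore split of the capillary wall
    three_pore: bool = False
    pore_frac_ultrasmall: float = 0.02
    pore_frac_small: float = 0.90
    pore_frac_large: float = 0.08
    sigma_g_small: float = 0.168
    sigma_g_large: float = 0.0
    # vasodilation (Hill-type in glucose excess over plasma)
    vaso_gain: float = 3.5             # dimensionless, max multiplier = 1 + gain
    vaso_half_sat: float = 0.035        # mmol/mL excess at half saturation
    # lymphatics
    lymph_L0: float = 5.0e-5           # 1/min per mL tissue, baseline uptake
    lymph_P_sensitivity: float = 7.0e-5  # 1/(min*mmHg) per mL tissue
    lymph_P_onset: float = 0.6         # mmHg above P_eq before uptake rises
    lymph_P_sat: float = 4.0           # mmHg of elevation at which uptake saturates
    # cavity mechanics
    ip_pressure_base: float = 0.95     # mmHg at residual volume
    ip_pressure_slope: float = 0.0045  # mmHg per mL above residual
    residual_volume: float = 250.0     # mL, constant per patient
    fill_rate: float = 200.0           # mL/min
    drain_rate: float = 350.0          # mL/min
    # physical constant
    RT: float = 19343.0                # mmHg per (mmol/mL), van 't Hoff at 37 C

    # derived, filled in __post_init__
    P_eq: float = field(init=False, default=math.nan)
    rho_onc: float = field(init=False, default=math.nan)
    C_glu_eq: float = field(init=False, default=math.nan)

    def __post_init__(self) -> None:
        self._validate()
        p_eq = pressure_from_hydration(self.theta_phys, self, _skip_derived=True)
        object.__setattr__(self, "P_eq", p_eq)
        # oncotic weighting s.t. q_v(P_eq, C_eq) = lymph_L0 at C near blood level;
        # the tiny glucose offset at equilibrium is neglected in this balance.
        rho = (self.P_blood - p_eq - self.lymph_L0 / self.LpS_density) / self.Pi_blood_onc
        object.__setattr__(self, "rho_onc", rho)
        # equilibrium interstitial glucose: diffusive PS exchange balances the
        # convective sieving deficit of lymph vs capillary filtration
        l0, ps, sg, cb = self.lymph_L0, self.PS_density, self.sigma_g_eff, self.C_blood_glu
        c_eq = cb * (ps + 0.5 * (1 - sg) * l0) / (ps + l0 - 0.5 * (1 - sg) * l0)
        object.__setattr__(self, "C_glu_eq", c_eq)

    def _validate(self) -> None:
        if not (0 < self.theta_min < self.theta_phys < self.theta_max < 1):
            raise ValueError(
                "require 0 < theta_min < theta_phys < theta_max < 1, got "
                f"{self.theta_min}, {self.theta_phys}, {self.theta_max}"
            )
        for name in ("K0", "D0", "LpS_density", "PS_density", "lymph_L0",
                     "lymph_P_sensitivity", "vaso_gain", "vaso_half_sat",
                     "K_sensitivity", "D_sensitivity", "compliance_scale",
                     "surface_area", "tissue_depth", "RT", "residual_volume",
                     "fill_rate", "drain_rate"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
        for name in ("sigma_g", "sigma_T", "sigma_g_small", "sigma_g_large"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.three_pore:
            s = self.pore_frac_ultrasmall + self.pore_frac_small + self.pore_frac_large
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"pore fractions must sum to 1, got {s}")

    @property
    def sigma_g_eff(self) -> float:
        """Effective capillary reflection coefficient for glucose.

        With the three-pore split enabled the wall-average reflection
        coefficient is the conductance-weighted mean over pore populations
        (ultrasmall pores reflect completely); otherwise it is ``sigma_g``.
        """
        if not self.three_pore:
            return self.sigma_g
        return (self.pore_frac_ultrasmall * 1.0
                + self.pore_frac_small * self.sigma_g_small
                + self.pore_frac_large * self.sigma_g_large)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("P_eq", "rho_onc", "C_glu_eq"):
            d.pop(k, None)
        return d


_FIELD_NAMES = {f.name for f in fields(ModelParameters) if f.init}


def load_parameters(path: str | Path) -> ModelParameters:
    """Load a flat YAML parameter file, schema-validated against ModelParameters."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: parameter file must be a mapping")
    unknown = set(raw) - _FIELD_NAMES
    if unknown:
        raise ValueError(f"{path}: unknown parameter keys {sorted(unknown)}")
    if "version" in raw:
        raw["version"] = str(raw["version"])
    return ModelParameters(**raw)


def default_parameters() -> ModelParameters:
    """The versioned default parameter set shipped with the package."""
    return load_parameters(Path(__file__).parent / "data" / "parameters_v1.yaml")


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# --------------------------------------------------------------------------
# constitutive laws
# --------------------------------------------------------------------------

def hydration_from_pressure(P, params: ModelParameters):
    """Tissue hydration theta as a function of interstitial pressure (mmHg).

    Logistic compliance saturating between ``theta_min`` (collapsed
    interstitium) and ``theta_max`` (maximal swelling, ~40%), passing through
    the physiological 18% at the dry-tissue equilibrium pressure.
    """
    P = np.asarray(P, dtype=float)
    if not np.all(np.isfinite(P)):
        raise ValueError("non-finite pressure passed to hydration_from_pressure")
    span = params.theta_max - params.theta_min
    z = (P - params.compliance_midpoint) / params.compliance_scale
    out = params.theta_min + span / (1.0 + np.exp(-np.clip(z, -700.0, 700.0)))
    return out if out.ndim else float(out)


def pressure_from_hydration(theta, params: ModelParameters, *, _skip_derived: bool = False):
    """Exact inverse of :func:`hydration_from_pressure` (mmHg)."""
    theta = np.asarray(theta, dtype=float)
    lo, hi = params.theta_min, params.theta_max
    if np.any(theta <= lo) or np.any(theta >= hi):
        raise ValueError(
            f"hydration must lie strictly inside ({lo}, {hi}); got range "
            f"[{theta.min()}, {theta.max()}]"
        )
    frac = (theta - lo) / (hi - lo)
    out = params.compliance_midpoint + params.compliance_scale * np.log(frac / (1.0 - frac))
    return out if out.ndim else float(out)


def hydraulic_conductivity(theta, params: ModelParameters):
    """Darcy hydraulic conductivity K(theta), cm^2/(min*mmHg).

    Exponential in hydration excess over the physiological level: swollen
    tissue conducts water far better than dry tissue, as observed in the
    near-surface layer during a dwell.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError("hydration outside (0, 1)")
    out = params.K0 * np.exp(params.K_sensitivity * (theta - params.theta_phys))
    return out if out.ndim else float(out)


def solute_diffusivity(theta, params: ModelParameters):
    """Glucose diffusivity in interstitial fluid D(theta), cm^2/min."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError("hydration outside (0, 1)")
    out = params.D0 * np.exp(params.D_sensitivity * (theta - params.theta_phys))
    return out if out.ndim else float(out)


def vasodilation_factor(C_glu, params: ModelParameters):
    """Multiplier (>= 1) on capillary wall conductances from local glucose.

    Hyperglycemic interstitium dilates nearby capillaries, raising the
    effective exchange surface area.  Hill-type saturation in the glucose
    excess over plasma: 1 at plasma glucose, 1 + gain at full saturation,
    1 + gain/2 at an excess of ``vaso_half_sat``.
    """
    C_glu = np.asarray(C_glu, dtype=float)
    if np.any(C_glu < 0):
        raise ValueError("negative glucose concentration")
    excess = np.maximum(C_glu - params.C_blood_glu, 0.0)
    out = 1.0 + params.vaso_gain * excess / (params.vaso_half_sat + excess)
    return out if out.ndim else float(out)


def lymph_flow(P, params: ModelParameters):
    """Lymphatic uptake density q_l(P), mL/min per mL tissue.

    The edema-guard response: uptake sits at the baseline ``lymph_L0`` until
    interstitial pressure exceeds the dry equilibrium by ``lymph_P_onset``
    mmHg, rises linearly with further elevation, and saturates once the
    elevation beyond onset reaches ``lymph_P_sat`` mmHg (lymphatic pumping
    has finite capacity).
    """
    P = np.asarray(P, dtype=float)
    dP = np.clip(P - params.P_eq - params.lymph_P_onset, 0.0, params.lymph_P_sat)
    out = params.lymph_L0 + params.lymph_P_sensitivity * dP
    return out if out.ndim else float(out)
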