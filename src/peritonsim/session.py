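"""Peritoneal cavity compartment and APD session/day scheduling.

The cavity holds dialysate volume ``V_ip`` at glucose ``C_ip``; its
intraperitoneal pressure rises linearly with fill volume.  A cycle is
fill -> dwell -> drain at finite pump rates; during every phase the cavity is
co-integrated with the tissue layer through the shared surface boundary
(water and glucose cross at x = 0), so the combined water ledger closes
exactly.  A treatment day alternates a night APD session (initial drain, then
n identical cycles) with a daytime phase: a small comfort fill on a dry-day
(DD) regimen, or a full daytime dwell on a wet-day (WD) regimen.

Net UF per exchange follows the cycler's definition: drained minus infused
volume.  The drain pump stops at the (constant) residual volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constitutive import ModelParameters, glucose_pct_to_mmol_per_ml
from .tissue import (
    TissueState, CavityBoundary, StepLedger, init_grid, step, stable_dt,
    tissue_water, tissue_glucose,
)

__all__ = [
    "CavityState", "Prescription", "CycleResult", "SessionResult", "DayResult",
    "ip_pressure", "fill", "drain", "dwell", "simulate_session",
    "simulate_days", "water_accumulated",
]


@dataclass
class CavityState:
    V_ip: float                 # mL
    C_ip_glu: float             # mmol/mL
    residual_volume: float      # mL, constant per patient

    def copy(self) -> "CavityState":
        return CavityState(self.V_ip, self.C_ip_glu, self.residual_volume)

    @property
    def glucose_mass(self) -> float:
        return self.V_ip * self.C_ip_glu


@dataclass(frozen=True)
class Prescription:
    """APD prescription: night cycles plus the daytime exchange plan."""
    n_cycles: int = 6
    fill_volume: float = 2000.0        # mL per night cycle
    glucose_pct: float = 1.36          # night fluid tonicity (g/100 mL)
    cycle_duration: float = 90.0       # min, fill + dwell + drain
    regimen: str = "DD"                # DD (dry day) or WD (wet day)
    day_fill_volume: float = 100.0     # mL (DD comfort fill or WD day dwell)
    day_glucose_pct: float = 1.36
    day_dwell_duration: float | None = None  # min; default: rest of 24 h

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.fill_volume < 0 or self.day_fill_volume < 0:
            raise ValueError("fill volumes must be >= 0")
        if self.regimen not in ("DD", "WD"):
            raise ValueError(f"regimen must be DD or WD, got {self.regimen!r}")

    @property
    def session_duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    @property
    def day_duration(self) -> float:
        if self.day_dwell_duration is not None:
            return self.day_dwell_duration
        return 1440.0 - self.session_duration

    @property
    def C_fresh(self) -> float:
        return glucose_pct_to_mmol_per_ml(self.glucose_pct)

    @property
    def C_fresh_day(self) -> float:
        return glucose_pct_to_mmol_per_ml(self.day_glucose_pct)

    @classmethod
    def dd_reference(cls) -> "Prescription":
        """The reference dry-day prescription: six 90-min cycles of 2 L
        glucose 1.36%, with a 100 mL comfort fill resting all day."""
        return cls()

    @classmethod
    def wd_reference(cls) -> "Prescription":
        """Wet-day reference: same night session, full daytime dwell.

        The daytime exchange uses 2.5 L of glucose 2.27% — a glucose-only
        stand-in for the clinical volume-maintaining day dwell, chosen so the
        cavity stays filled (and the tissue hydrated) across the day.
        """
        return cls(regimen="WD", day_fill_volume=2500.0, day_glucose_pct=2.27)


@dataclass
class CycleResult:
    infused: float
    drained: float
    tissue_water_delta: float

    @property
    def net_uf(self) -> float:
        return self.drained - self.infused


@dataclass
class PhaseLedger:
    """Water/glucose bookkeeping of one co-integrated phase (or a run of them)."""
    tissue: StepLedger = field(default_factory=StepLedger)
    pumped_in: float = 0.0       # mL of fresh fluid delivered
    pumped_out: float = 0.0      # mL drained
    glucose_pumped_in: float = 0.0
    glucose_pumped_out: float = 0.0

    def add(self, other: "PhaseLedger") -> None:
        self.tissue.add(other.tissue)
        self.pumped_in += other.pumped_in
        self.pumped_out += other.pumped_out
        self.glucose_pumped_in += other.glucose_pumped_in
        self.glucose_pumped_out += other.glucose_pumped_out


@dataclass
class SessionResult:
    cycles: list[CycleResult] = field(default_factory=list)
    initial_drained: float = 0.0
    t_series: list[float] = field(default_factory=list)
    V_series: list[float] = field(default_factory=list)
    # hydration profiles: pre-session, then end of each cycle's dwell
    tissue_snapshots: list[TissueState] = field(default_factory=list)
    # exact cumulative water/glucose ledger over the whole session
    ledger: "PhaseLedger" = None  # type: ignore[assignment]

    @property
    def per_cycle_uf(self) -> list[float]:
        return [c.net_uf for c in self.cycles]

    @property
    def session_uf(self) -> float:
        return float(sum(self.per_cycle_uf))

    @property
    def mean_uf_c3plus(self) -> float:
        tail = self.per_cycle_uf[2:]
        return float(np.mean(tail)) if tail else math.nan


@dataclass
class DayResult:
    session: SessionResult
    day_infused: float = 0.0
    day_drained: float = math.nan   # measured at the next session's initial drain
    ledger: PhaseLedger = field(default_factory=PhaseLedger)  # session + day phase

    @property
    def day_net_uf(self) -> float:
        return self.day_drained - self.day_infused


def ip_pressure(V_ip: float, params: ModelParameters) -> float:
    """Intraperitoneal hydrostatic pressure (mmHg, supine) vs fill volume.

    Linear above the residual volume; decays toward zero gauge as the cavity
    empties below residual.
    """
    if V_ip < 0:
        raise ValueError(f"negative intraperitoneal volume: {V_ip}")
    res = params.residual_volume
    if V_ip >= res:
        return params.ip_pressure_base + params.ip_pressure_slope * (V_ip - res)
    return params.ip_pressure_base * (V_ip / res) if res > 0 else params.ip_pressure_base


def fill(cavity: CavityState, volume: float, C_fresh: float) -> CavityState:
    """Instantaneous conservative mixing of fresh fluid into the cavity.

    (The finite-rate pump path used in simulations lives in the dwell
    co-integrator; this operation is the mixing arithmetic.)
    """
    if volume < 0:
        raise ValueError("fill volume must be >= 0")
    V_new = cavity.V_ip + volume
    mass = cavity.glucose_mass + volume * C_fresh
    C_new = mass / V_new if V_new > 0 else 0.0
    return CavityState(V_new, C_new, cavity.residual_volume)


def drain(cavity: CavityState, params: ModelParameters) -> tuple[CavityState, float]:
    """Instantaneous drain down to the residual volume; returns volume removed.

    The cycler stops when flow becomes too low, which the model represents as
    a stop at the constant residual volume; a cavity already at or below
    residual drains nothing.
    """
    drained = max(0.0, cavity.V_ip - cavity.residual_volume)
    return CavityState(cavity.V_ip - drained, cavity.C_ip_glu, cavity.residual_volume), drained


# --------------------------------------------------------------------------
# coupled cavity-tissue integration
# --------------------------------------------------------------------------

def dwell(cavity: CavityState, tissue: TissueState, params: ModelParameters,
          duration: float, *, pump_rate: float = 0.0, C_fresh: float = 0.0,
          stop_at_residual: bool = False, safety: float = 0.4,
          recorder=None) -> tuple[CavityState, TissueState, PhaseLedger]:
    """Co-integrate cavity and tissue for ``duration`` minutes.

    ``pump_rate`` > 0 infuses fresh fluid at ``C_fresh``; < 0 drains dialysate
    (stopping at the residual volume when ``stop_at_residual``).  The cavity
    obeys dV/dt = pump - A j_v(0) and the matching glucose mass balance, so
    that cavity + tissue + pump ledger close exactly.
    """
    cavity = cavity.copy()
    tissue = tissue.copy()
    ledger = PhaseLedger()
    t_end = tissue.t + duration
    pumping = pump_rate != 0.0
    while tissue.t < t_end - 1e-9:
        dt = min(stable_dt(tissue, params, safety), t_end - tissue.t)
        rate = pump_rate
        if pumping and rate < 0.0 and stop_at_residual:
            headroom = cavity.V_ip - cavity.residual_volume
            if headroom <= 1e-12:
                rate = 0.0
            else:
                # do not overshoot the residual volume within this step
                rate = -min(-rate, headroom / dt)
        boundary = CavityBoundary(ip_pressure(cavity.V_ip, params), cavity.C_ip_glu)
        for _ in range(40):
            try:
                tissue_new, led = step(tissue, params, boundary, dt)
                break
            except Exception:
                dt *= 0.5
                if dt < 1e-12:
                    raise
        else:
            raise RuntimeError("time step underflow in dwell")
        # cavity update from the same discrete fluxes (exact ledger closure)
        dV_pump = rate * dt
        mass = cavity.glucose_mass - led.glucose_from_cavity
        if rate > 0:
            mass += rate * C_fresh * dt
            ledger.pumped_in += dV_pump
            ledger.glucose_pumped_in += rate * C_fresh * dt
        elif rate < 0:
            mass += rate * cavity.C_ip_glu * dt
            ledger.pumped_out += -dV_pump
            ledger.glucose_pumped_out += -rate * cavity.C_ip_glu * dt
        V_new = cavity.V_ip + dV_pump - led.water_from_cavity
        if V_new < 0:
            raise RuntimeError(f"cavity volume went negative ({V_new:.3f} mL) "
                               f"at t={tissue.t:.2f} min")
        cavity.V_ip = V_new
        cavity.C_ip_glu = mass / V_new if V_new > 1e-9 else 0.0
        tissue = tissue_new
        ledger.tissue.add(led)
        if recorder is not None:
            recorder(tissue.t, cavity, tissue)
    return cavity, tissue, ledger


class _VolumeRecorder:
    """Coarse (t, V_ip) sampling during co-integration."""

    def __init__(self, result: SessionResult, every: float = 2.0):
        self.result = result
        self.every = every
        self._next = -math.inf

    def __call__(self, t, cavity, tissue):
        if t >= self._next:
            self.result.t_series.append(t)
            self.result.V_series.append(cavity.V_ip)
            self._next = t + self.every


def simulate_session(tissue: TissueState, params: ModelParameters,
                     prescription: Prescription,
                     cavity: CavityState | None = None,
                     record_volume: bool = False
                     ) -> tuple[SessionResult, CavityState, TissueState]:
    """One night APD session: initial drain, then n identical cycles.

    Each cycle is a finite-rate fill, a dwell for the remaining cycle time
    budget, and a finite-rate drain to the residual volume.  Per-cycle net UF
    (drained - infused) and tissue water change are recorded; the tissue state
    is carried across cycles.
    """
    if cavity is None:
        cavity = CavityState(params.residual_volume, params.C_glu_eq,
                             params.residual_volume)
    result = SessionResult()
    result.ledger = PhaseLedger()
    recorder = _VolumeRecorder(result) if record_volume else None

    cavity, initial_drained = drain(cavity, params)
    result.initial_drained = initial_drained
    result.tissue_snapshots.append(tissue.copy())

    C_fresh = prescription.C_fresh
    for _ in range(prescription.n_cycles):
        tw0 = tissue_water(tissue, params)
        fill_time = prescription.fill_volume / params.fill_rate
        # reserve enough drain time for the expected volume plus margin
        drain_time = min(0.25 * prescription.cycle_duration,
                         1.25 * prescription.fill_volume / params.drain_rate)
        dwell_time = prescription.cycle_duration - fill_time - drain_time
        if dwell_time <= 0:
            raise ValueError("cycle_duration too short for fill and drain phases")

        cavity, tissue, led_f = dwell(cavity, tissue, params, fill_time,
                                      pump_rate=params.fill_rate, C_fresh=C_fresh,
                                      recorder=recorder)
        infused = prescription.fill_volume
        cavity, tissue, led_d = dwell(cavity, tissue, params, dwell_time,
                                      recorder=recorder)
        result.ledger.add(led_f)
        result.ledger.add(led_d)
        # snapshot of the hydrated profile reached during this cycle
        result.tissue_snapshots.append(tissue.copy())
        cavity, tissue, led = dwell(cavity, tissue, params, drain_time,
                                    pump_rate=-params.drain_rate,
                                    stop_at_residual=True, recorder=recorder)
        drained = led.pumped_out
        result.ledger.add(led)
        result.cycles.append(CycleResult(infused, drained,
                                         tissue_water(tissue, params) - tw0))
    return result, cavity, tissue


def simulate_days(params: ModelParameters, prescription: Prescription,
                  n_days: int, n_cells: int = 50,
                  tissue: TissueState | None = None,
                  record_volume: bool = False) -> list[DayResult]:
    """Simulate ``n_days`` of treatment: night session then daytime phase.

    DD: a small comfort fill rests in the cavity all day (infused after the
    last night cycle, drained by the next session's initial drain).  WD: a
    full daytime dwell with glucose fluid.  The daytime exchange's net UF is
    measured, as the cycler does, when the following session drains the
    cavity; the run therefore appends one extra initial drain after the last
    day so every day has a complete record.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if tissue is None:
        tissue = init_grid(params, n_cells)
    cavity = CavityState(params.residual_volume, params.C_glu_eq,
                         params.residual_volume)
    days: list[DayResult] = []
    for d in range(n_days):
        res, cavity, tissue = simulate_session(
            tissue, params, prescription, cavity,
            record_volume=record_volume)
        if d > 0:
            days[-1].day_drained = res.initial_drained
        # daytime phase: fill, then rest of the 24 h as one long dwell
        day_fill = prescription.day_fill_volume
        C_day = prescription.C_fresh_day
        fill_time = day_fill / params.fill_rate if day_fill > 0 else 0.0
        day_dwell = prescription.day_duration - fill_time
        day_led = PhaseLedger()
        day_led.add(res.ledger)
        if fill_time > 0:
            cavity, tissue, led = dwell(cavity, tissue, params, fill_time,
                                        pump_rate=params.fill_rate, C_fresh=C_day)
            day_led.add(led)
        cavity, tissue, led = dwell(cavity, tissue, params, day_dwell)
        day_led.add(led)
        days.append(DayResult(session=res, day_infused=day_fill, ledger=day_led))
    cavity, final_drain = drain(cavity, params)
    days[-1].day_drained = final_drain
    return days


def water_accumulated(tissue_before: TissueState, tissue_after: TissueState,
                      params: ModelParameters) -> float:
    """Change in total tissue water (mL) between two states on the same grid."""
    if (tissue_before.n_cells != tissue_after.n_cells
            or not np.allclose(tissue_before.x_centers, tissue_after.x_centers)):
        raise ValueError("tissue states live on different grids")
    return tissue_water(tissue_after, params) - tissue_water(tissue_before, params)
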