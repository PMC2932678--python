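"""The in-silico experiments: healing, atrophic non-union, treatments.

A :class:`Scenario` bundles the domain variant, the boundary-condition
schedule, parameter overrides and an ordered list of treatment events.
The atrophic non-union is produced purely by boundary manipulation:
the MSC Dirichlet values on the stripped periosteal and/or reamed
endosteal segments are multiplied by 1e-5 while every other parameter,
initial and boundary condition is left unchanged from the healing case,
and the domain is extended distally over the stripping distance (the
intact distal end faces keep the healing-strength cell sources).

Treatments model the transplantation of cultured MSCs at a chosen
post-osteotomy time: direct injection into the callus (central or
excentral disc footprint) or delivery in a carrier adjacent to, but
outside, the callus (a time-limited Dirichlet source on the outer
soft-tissue segment).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .domain_grid import (
    SEG_ENDOSTEAL,
    SEG_MARROW_DISTAL,
    SEG_PERIOSTEAL,
    SEG_PERIOSTEAL_DISTAL,
    SEG_SOFT,
    SEG_CORTEX,
    CallusDomain,
    GeometryConfig,
    Grid,
    build_callus_domain,
    discretize,
)
from .errors import ConfigurationError
from .fv_solver import (
    BoundaryCondition,
    BoundaryConditionSpec,
    SolverSettings,
    Trajectory,
    integrate,
)
from .kinetics import KineticParameters, StateField, default_parameters

__all__ = [
    "BoundaryValues",
    "ScenarioConfig",
    "TreatmentEvent",
    "Scenario",
    "make_healing_scenario",
    "make_nonunion_scenario",
    "inject_cells",
    "run_scenario",
]

#: factor applied to the MSC Dirichlet value on stripped/reamed segments
MSC_ABLATION_FACTOR = 1e-5
#: factor applied to the growth-factor boundary estimates (model revision)
GF_BOUNDARY_SCALE = 0.1


@dataclass(frozen=True)
class BoundaryValues:
    """Dirichlet values (non-dimensional) and windows (days) of the
    healing scenario's boundary schedule.

    ``g_c_base``/``g_b_base`` are the original growth-factor boundary
    estimates; the applied values are these times ``gf_scale`` (default
    0.1, the factor-10 reduction adopted for both healing and
    non-union).
    """

    msc: float = 1.0
    fibroblast: float = 0.5
    endothelial: float = 0.5
    g_c_base: float = 1.0
    g_b_base: float = 1.0
    gf_scale: float = GF_BOUNDARY_SCALE
    cell_window: Tuple[float, float] = (0.0, 14.0)
    gf_window: Tuple[float, float] = (0.0, 7.0)
    ec_window: Tuple[float, float] = (0.0, 112.0)


@dataclass(frozen=True)
class InitialValues:
    """Initial fields: granulation tissue plus the growth-factor release
    at fracture induction."""

    m_f0: float = 0.1
    g_c0: float = 1.0
    g_b0: float = 0.1
    g_v0: float = 0.1


@dataclass(frozen=True)
class ScenarioConfig:
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    boundary: BoundaryValues = field(default_factory=BoundaryValues)
    initial: InitialValues = field(default_factory=InitialValues)
    dx_mm: float = 0.25
    end_time: float = 112.0
    #: reference thickness converting the 2-D section to a volume (mm)
    section_thickness_mm: float = 5.0
    #: non-dimensional density scale: 1.0 = 10^6 cells/ml = 10^3 cells/mm^3
    cells_per_mm3_at_unit_density: float = 1e3
    #: ceiling for the MSC density reached by an injection bolus
    injection_density_cap: float = 1.0


@dataclass(frozen=True)
class TreatmentEvent:
    """One cell-transplant event.

    ``site``: ``central`` (disc mid-gap), ``excentral`` (disc in the
    gap adjacent to one cortex) or ``external_carrier`` (time-limited
    source on the outer soft-tissue segment).  ``center_mm`` may be
    left ``None`` to use the site's default placement.
    """

    time: float = 21.0  # post-osteotomy week 3
    site: str = "central"
    volume_ml: float = 1.0
    concentration_per_ml: float = 1e6
    radius_mm: float = 0.25
    center_mm: Optional[Tuple[float, float]] = None
    carrier_duration_days: float = 7.0
    carrier_value: float = 1.0
    target_field: str = "c_m"

    def validate(self) -> None:
        if self.site not in ("central", "excentral", "external_carrier"):
            raise ConfigurationError(f"unknown treatment site {self.site!r}")
        if self.volume_ml < 0 or self.concentration_per_ml < 0:
            raise ConfigurationError("treatment volume and concentration must be >= 0")
        if self.radius_mm <= 0:
            raise ConfigurationError("treatment footprint radius must be > 0")

    @property
    def nominal_cells(self) -> float:
        """Dimensional bookkeeping: injected cell number = volume x concentration."""
        return self.volume_ml * self.concentration_per_ml


@dataclass
class Scenario:
    label: str
    variant: str
    config: ScenarioConfig
    bc: BoundaryConditionSpec
    overrides: Dict[str, float]
    treatments: List[TreatmentEvent]
    settings: SolverSettings

    def validate(self) -> None:
        times = [e.time for e in self.treatments]
        if times != sorted(times):
            raise ConfigurationError("treatment events must be sorted by time")
        for e in self.treatments:
            e.validate()
            if not (0.0 <= e.time <= self.settings.end_time):
                raise ConfigurationError("treatment time outside the simulated horizon")

    def config_dict(self) -> dict:
        return {
            "label": self.label,
            "variant": self.variant,
            "geometry": vars(self.config.geometry),
            "boundary": _bv_dict(self.config.boundary),
            "initial": vars(self.config.initial),
            "dx_mm": self.config.dx_mm,
            "end_time": self.config.end_time,
            "section_thickness_mm": self.config.section_thickness_mm,
            "overrides": dict(sorted(self.overrides.items())),
            "bc_rules": [
                (r.field, r.segment, r.value, r.t_start,
                 r.t_end if math.isfinite(r.t_end) else "inf")
                for r in self.bc.rules
            ],
            "treatments": [
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(e).items()}
                for e in self.treatments
            ],
            "solver": {
                "rtol": self.settings.rtol,
                "atol": self.settings.atol,
                "method": self.settings.method,
                "limiter": self.settings.limiter,
                "snapshot_days": list(self.settings.snapshot_days),
            },
        }

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()

    def build_domain(self) -> CallusDomain:
        return build_callus_domain(self.config.geometry, self.variant)

    def build_grid(self) -> Grid:
        return discretize(self.build_domain(), self.config.dx_mm)

    def initial_state(self, grid: Grid) -> StateField:
        ic = self.config.initial
        st = StateField.zeros(grid)
        mask = grid.in_domain
        st["m_f"] = ic.m_f0 * mask
        st["g_c"] = ic.g_c0 * mask
        st["g_b"] = ic.g_b0 * mask
        st["g_v"] = ic.g_v0 * mask
        return st

    def parameters(self) -> KineticParameters:
        return default_parameters().scale(self.overrides)


def _bv_dict(bv: BoundaryValues) -> dict:
    d = vars(bv).copy()
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _healing_rules(bv: BoundaryValues, msc_factors: Dict[str, float]) -> List[BoundaryCondition]:
    """The shared boundary schedule; ``msc_factors`` maps segment -> MSC
    Dirichlet multiplier (1.0 for intact sources)."""
    t0c, t1c = bv.cell_window
    t0g, t1g = bv.gf_window
    t0e, t1e = bv.ec_window
    gf_c = bv.g_c_base * bv.gf_scale
    gf_b = bv.g_b_base * bv.gf_scale
    rules = []
    # MSC sources: periosteum, endosteal lining, distal marrow / periosteum
    for seg in (SEG_PERIOSTEAL, SEG_ENDOSTEAL, SEG_MARROW_DISTAL, SEG_PERIOSTEAL_DISTAL):
        rules.append(BoundaryCondition("c_m", seg, bv.msc * msc_factors.get(seg, 1.0), t0c, t1c))
    # fibroblasts invade from the surrounding soft tissue
    rules.append(BoundaryCondition("c_f", SEG_SOFT, bv.fibroblast, t0c, t1c))
    # endothelial supply from periosteum and marrow (angiogenic sprouting)
    rules.append(BoundaryCondition("c_v", SEG_PERIOSTEAL, bv.endothelial, t0e, t1e))
    rules.append(BoundaryCondition("c_v", SEG_ENDOSTEAL, bv.endothelial, t0e, t1e))
    # early systemic/local growth-factor supply
    rules.append(BoundaryCondition("g_c", SEG_PERIOSTEAL, gf_c, t0g, t1g))
    rules.append(BoundaryCondition("g_c", SEG_ENDOSTEAL, gf_c, t0g, t1g))
    rules.append(BoundaryCondition("g_b", SEG_CORTEX, gf_b, t0g, t1g))
    rules.append(BoundaryCondition("g_b", SEG_ENDOSTEAL, gf_b, t0g, t1g))
    return rules


def _settings(config: ScenarioConfig) -> SolverSettings:
    snaps = tuple(float(d) for d in np.arange(0.0, config.end_time + 1e-9, 7.0))
    return SolverSettings(end_time=config.end_time, snapshot_days=snaps)


def make_healing_scenario(
    config: ScenarioConfig | None = None,
    overrides: Dict[str, float] | None = None,
    label: str = "healing",
) -> Scenario:
    """Baseline normal-healing experiment on the compact callus domain.

    ``overrides`` maps rate symbols to scale factors, e.g.
    ``{"P_cs": 0.1, "P_bs": 0.1}`` for the reduced matrix-production
    variant (tenfold slower cartilage and bone deposition).
    """
    config = config or ScenarioConfig()
    sc = Scenario(
        label=label,
        variant="healing",
        config=config,
        bc=BoundaryConditionSpec(_healing_rules(config.boundary, {})),
        overrides=dict(overrides or {}),
        treatments=[],
        settings=_settings(config),
    )
    sc.validate()
    return sc


def make_nonunion_scenario(
    config: ScenarioConfig | None = None,
    strip_periosteum: bool = True,
    ream_marrow: bool = True,
    treatments: List[TreatmentEvent] | None = None,
    overrides: Dict[str, float] | None = None,
    label: str | None = None,
) -> Scenario:
    """Non-union-type experiment on the distally extended domain.

    On stripped periosteal and/or reamed endosteal segments the MSC
    Dirichlet value is multiplied by 1e-5; everything else is identical
    to the healing scenario.  At least one flag must be set.
    """
    if not (strip_periosteum or ream_marrow):
        raise ConfigurationError(
            "non-union scenario requires strip_periosteum and/or ream_marrow "
            "(use make_healing_scenario for the unmodified case)"
        )
    config = config or ScenarioConfig()
    msc_factors: Dict[str, float] = {}
    if strip_periosteum:
        msc_factors[SEG_PERIOSTEAL] = MSC_ABLATION_FACTOR
    if ream_marrow:
        msc_factors[SEG_ENDOSTEAL] = MSC_ABLATION_FACTOR
    if label is None:
        label = {
            (True, True): "nonunion",
            (True, False): "periosteum_only",
            (False, True): "marrow_only",
        }[(strip_periosteum, ream_marrow)]
    sc = Scenario(
        label=label,
        variant="nonunion",
        config=config,
        bc=BoundaryConditionSpec(_healing_rules(config.boundary, msc_factors)),
        overrides=dict(overrides or {}),
        treatments=sorted(treatments or [], key=lambda e: e.time),
        settings=_settings(config),
    )
    sc.validate()
    return sc


def _footprint_center(event: TreatmentEvent, geom: GeometryConfig) -> Tuple[float, float]:
    if event.center_mm is not None:
        return event.center_mm
    gap_mid_x = geom.gap_mm / 4.0  # mid of the half-gap column
    y0, y1 = geom.marrow_mm, geom.marrow_mm + geom.cortex_mm
    if event.site == "central":
        return (gap_mid_x, 0.5 * (y0 + y1))
    # excentral: displaced to the periosteal side of the gap, adjacent to
    # the cortex end (the opposite, endosteal-side gap corner is then the
    # region reached last by the transplant)
    return (gap_mid_x, y1 + 0.4 * geom.cortex_mm)


def inject_cells(
    state: StateField,
    grid: Grid,
    event: TreatmentEvent,
    config: ScenarioConfig | None = None,
) -> Tuple[StateField, Dict[str, float]]:
    """Apply one injection event; returns the new state and its ledger.

    The dimensional ledger always records ``nominal_cells = volume x
    concentration`` exactly.  The field increment spreads that number
    uniformly over the disc footprint using the section-thickness
    convention (cells -> areal density -> non-dimensional density) and
    is capped at ``injection_density_cap``, the carrying density of the
    tissue; any excess is reported in the ledger as overflow rather than
    forced into the field.

    ``external_carrier`` events do not modify the state here; they are
    realised as a time-limited boundary source by :func:`run_scenario`
    (the ledger still records the nominal cell number).
    """
    event.validate()
    config = config or ScenarioConfig()
    ledger: Dict[str, float] = {
        "time": event.time,
        "site_is_carrier": float(event.site == "external_carrier"),
        "nominal_cells": event.nominal_cells,
        "added_nondim_mass": 0.0,
        "overflow_cells": 0.0,
    }
    if event.site == "external_carrier":
        return state, ledger
    if event.volume_ml == 0.0 or event.concentration_per_ml == 0.0:
        return state, ledger

    geom = grid.meta.get("geometry") or GeometryConfig()
    cx, cy = _footprint_center(event, geom)
    X, Y = np.meshgrid(grid.x_centers, grid.y_centers)
    foot = grid.in_domain & ((X - cx) ** 2 + (Y - cy) ** 2 <= event.radius_mm ** 2)
    if not foot.any():
        # fall back to the nearest in-domain cell before declaring failure
        d2 = (X - cx) ** 2 + (Y - cy) ** 2 + np.where(grid.in_domain, 0.0, np.inf)
        j, i = np.unravel_index(int(np.argmin(d2)), d2.shape)
        if d2[j, i] > (4 * event.radius_mm) ** 2:
            raise ConfigurationError(
                f"treatment footprint at ({cx:.2f}, {cy:.2f}) mm lies outside the domain"
            )
        foot = np.zeros_like(grid.in_domain)
        foot[j, i] = True

    area = float(foot.sum()) * grid.cell_area  # mm^2
    volume = area * config.section_thickness_mm  # mm^3
    density_cells_mm3 = event.nominal_cells / volume
    delta = density_cells_mm3 / config.cells_per_mm3_at_unit_density  # non-dimensional

    new = state.copy()
    fld = event.target_field
    before = new[fld][foot]
    after = np.minimum(before + delta, config.injection_density_cap)
    new[fld][foot] = after
    added = float((after - before).sum()) * grid.cell_area
    ledger["added_nondim_mass"] = added
    realized_cells = added * config.section_thickness_mm * config.cells_per_mm3_at_unit_density
    ledger["overflow_cells"] = event.nominal_cells - realized_cells
    return new, ledger


def run_scenario(scenario: Scenario, settings: SolverSettings | None = None):
    """Integrate a scenario end-to-end, pausing at each treatment event.

    Returns ``(trajectory, grid, params, ledgers)``; solver errors are
    annotated with the scenario label.  Carrier-type events are realised
    as extra Dirichlet rules before integration starts (their windows
    are known up front), injection events modify the state at their
    event time.
    """
    scenario.validate()
    settings = settings or scenario.settings
    grid = scenario.build_grid()
    params = scenario.parameters()

    carrier_rules = [
        BoundaryCondition(
            e.target_field, SEG_SOFT, e.carrier_value, e.time, e.time + e.carrier_duration_days
        )
        for e in scenario.treatments
        if e.site == "external_carrier"
    ]
    bc = scenario.bc.with_rules(carrier_rules) if carrier_rules else scenario.bc

    state = scenario.initial_state(grid)
    ledgers: List[Dict[str, float]] = []
    inject_events = [e for e in scenario.treatments if e.site != "external_carrier"]
    for e in scenario.treatments:
        if e.site == "external_carrier":
            _, led = inject_cells(state, grid, e, scenario.config)
            ledgers.append(led)

    try:
        times: List[float] = []
        states: List[StateField] = []
        log: Dict[str, object] = {}
        t_cursor = 0.0
        cut_points = [e.time for e in inject_events] + [settings.end_time]
        for k, t_next in enumerate(cut_points):
            seg_settings = replace(
                settings,
                end_time=t_next,
                snapshot_days=tuple(s for s in settings.snapshot_days if s <= t_next + 1e-9),
            )
            traj = integrate(state, grid, params, bc, seg_settings, t0=t_cursor)
            for t, st in zip(traj.times, traj.states):
                if not times or t > times[-1] + 1e-9:
                    times.append(t)
                    states.append(st)
            for key, val in traj.log.items():
                if isinstance(val, (int, float)) and key in log:
                    log[key] = log[key] + val if key != "min_value" else min(log[key], val)
                else:
                    log[key] = val
            # state at the cut: integrate to t_next even if not a snapshot
            state = _state_at(traj, grid, params, bc, seg_settings, t_cursor, t_next)
            if k < len(inject_events):
                state, led = inject_cells(state, grid, inject_events[k], scenario.config)
                ledgers.append(led)
            t_cursor = t_next
    except Exception as err:
        raise type(err)(f"[scenario {scenario.label!r}] {err}") from err

    log["scenario"] = scenario.label
    log["config_hash"] = scenario.config_hash
    log["overrides"] = dict(scenario.overrides)
    log["treatment_ledgers"] = ledgers
    return Trajectory(times=times, states=states, log=log), grid, params, ledgers


def _state_at(traj: Trajectory, grid, params, bc, settings, t0, t_next) -> StateField:
    if traj.times and abs(traj.times[-1] - t_next) <= 1e-9:
        return traj.states[-1].copy()
    # end time was not a snapshot: integrate the tail explicitly
    last_t = traj.times[-1] if traj.times else t0
    last = traj.states[-1].copy() if traj.states else None
    tail = replace(settings, end_time=t_next, snapshot_days=(t_next,))
    tt = integrate(last, grid, params, bc, tail, t0=last_t)
    return tt.states[-1].copy()
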