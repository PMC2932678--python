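"""State fields, parameter registry and local kinetics of the healing model.

Twelve coupled non-dimensional fields live on the grid:

===========  ================================================
``c_m``      mesenchymal stem cell (MSC) density
``c_f``      fibroblast density
``c_c``      chondrocyte density
``c_b``      osteoblast density
``c_v``      endothelial cell density
``m_f``      fibrous tissue matrix density
``m_c``      cartilage matrix density
``m_b``      bone matrix density
``m_v``      vascular matrix density
``g_c``      chondrogenic growth factor concentration
``g_b``      osteogenic growth factor concentration
``g_v``      vascular growth factor concentration
===========  ================================================

``m = m_f + m_c + m_b + m_v`` is the total tissue density and ``X`` the
maximum tissue density: proliferation and matrix deposition shut down as
``m`` approaches ``X`` (crowding).  The vascular matrix ``m_v`` gates
endochondral ossification and osteogenic growth-factor production and
hinders cell migration.  Growth-factor dependencies are saturating
(Hill-type).  Non-dimensional scales: cell densities against 10^6
cells/ml, matrix densities against dense tissue (0.1 g/ml), growth
factors against 100 ng/ml; time in days, lengths in mm.

Because the original supplementary parameter table is not distributed
with this package, every rate constant in :func:`default_parameters` is
a reconstructed value (``source="reconstructed"``), chosen so that the
model reproduces the published qualitative healing and non-union
phenomenology; see ``docs/methods.md`` for the calibration narrative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np

from .domain_grid import Grid
from .errors import ConfigurationError, ParameterError

__all__ = [
    "FIELDS",
    "CELL_FIELDS",
    "MATRIX_FIELDS",
    "GF_FIELDS",
    "MIGRATING_FIELDS",
    "StateField",
    "ParamEntry",
    "KineticParameters",
    "default_parameters",
    "reaction_rates",
    "taxis_velocity",
    "scale_parameters",
]

FIELDS: Tuple[str, ...] = (
    "c_m", "c_f", "c_c", "c_b", "c_v",
    "m_f", "m_c", "m_b", "m_v",
    "g_c", "g_b", "g_v",
)
FIELD_INDEX: Dict[str, int] = {name: i for i, name in enumerate(FIELDS)}
CELL_FIELDS = FIELDS[:5]
MATRIX_FIELDS = FIELDS[5:9]
GF_FIELDS = FIELDS[9:]
#: species with directed migration (diffusion + chemotaxis/haptotaxis)
MIGRATING_FIELDS = ("c_m", "c_f", "c_v")

#: proliferation-rate symbol per cell type (used by the proliferation index)
PROLIFERATION_RATES = {
    "c_m": "p_m", "c_f": "p_f", "c_c": "p_c", "c_b": "p_b", "c_v": "p_v",
}

_EPS = 1e-9  # guard in saturation denominators (non-dimensional)


@dataclass
class StateField:
    """The 12 non-dimensional fields on a grid, stored as ``(12, ny, nx)``."""

    values: np.ndarray
    grid: Grid

    @classmethod
    def zeros(cls, grid: Grid) -> "StateField":
        return cls(np.zeros((len(FIELDS),) + grid.shape), grid)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[FIELD_INDEX[name]]

    def __setitem__(self, name: str, value) -> None:
        self.values[FIELD_INDEX[name]] = value

    @property
    def total_matrix(self) -> np.ndarray:
        """m = m_f + m_c + m_b + m_v, the total tissue density."""
        return self.values[5:9].sum(axis=0)

    def copy(self) -> "StateField":
        return StateField(self.values.copy(), self.grid)

    def validate(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("state contains NaN")
        if (self.values < 0).any():
            raise ValueError("state violates non-negativity")


@dataclass(frozen=True)
class ParamEntry:
    value: float
    units: str
    source: str = "reconstructed"


class KineticParameters:
    """Named registry of every rate constant of the model.

    Lookup by symbol returns the value; a missing symbol raises
    :class:`ParameterError` naming it.  ``scale`` returns a new registry
    with selected symbols multiplied by non-negative factors and the
    override provenance recorded.
    """

    def __init__(self, entries: Mapping[str, ParamEntry], provenance: Iterable[str] = ()):
        self._entries = dict(entries)
        self.provenance = list(provenance)
        for sym, e in self._entries.items():
            if e.value < 0:
                raise ConfigurationError(f"parameter {sym!r} must be >= 0, got {e.value}")
        if self._entries.get("X") is not None and self._entries["X"].value <= 0:
            raise ConfigurationError("carrying capacity 'X' must be > 0")

    def __getitem__(self, symbol: str) -> float:
        try:
            return self._entries[symbol].value
        except KeyError:
            raise ParameterError(f"unregistered rate symbol {symbol!r}") from None

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._entries

    def entry(self, symbol: str) -> ParamEntry:
        try:
            return self._entries[symbol]
        except KeyError:
            raise ParameterError(f"unregistered rate symbol {symbol!r}") from None

    def symbols(self) -> Tuple[str, ...]:
        return tuple(self._entries)

    def items(self):
        return self._entries.items()

    def scale(self, overrides: Mapping[str, float]) -> "KineticParameters":
        return scale_parameters(self, overrides)

    def to_dict(self) -> Dict[str, float]:
        return {sym: e.value for sym, e in self._entries.items()}


def _p(value: float, units: str) -> ParamEntry:
    return ParamEntry(value, units)


def default_parameters() -> KineticParameters:
    """Reconstructed default rate constants (non-dimensional, per day, mm)."""
    e = {
        # carrying capacity
        "X": _p(1.0, "-"),
        # random motility (peak values; modulated by matrix density)
        "D_m": _p(0.35, "mm^2/day"),
        "D_f": _p(0.15, "mm^2/day"),
        "D_v": _p(0.15, "mm^2/day"),
        "K_hm": _p(0.1, "-"),  # matrix density of maximal cell motility
        "K_dense": _p(0.18, "-"),  # matrix density arresting cell migration
        # growth-factor diffusion
        "D_gc": _p(0.3, "mm^2/day"),
        "D_gb": _p(0.3, "mm^2/day"),
        "D_gv": _p(0.3, "mm^2/day"),
        # taxis coefficients (chemotaxis toward GF, haptotaxis toward matrix)
        "chi_m_gb": _p(0.05, "mm^2/day"),
        "chi_m_gc": _p(0.05, "mm^2/day"),
        "chi_m_m": _p(0.02, "mm^2/day"),
        "chi_f_m": _p(0.02, "mm^2/day"),
        "chi_v_gv": _p(0.25, "mm^2/day"),
        "chi_v_m": _p(0.01, "mm^2/day"),
        # proliferation rates
        "p_m": _p(1.0, "1/day"),
        "p_f": _p(0.55, "1/day"),
        "p_c": _p(0.25, "1/day"),
        "p_b": _p(0.15, "1/day"),
        "p_v": _p(0.4, "1/day"),
        "beta_v": _p(0.035, "-"),  # GF-independent share of endothelial proliferation
        "K_gvv": _p(0.1, "-"),  # g_v half-saturation of endothelial proliferation
        "K_allee": _p(0.05, "-"),  # minimum-density scale of the Allee limitation
        # differentiation
        "d_mf": _p(0.02, "1/day"),  # MSC -> fibroblast (default path)
        "d_mc": _p(0.35, "1/day"),  # MSC -> chondrocyte, driven by g_c
        "d_mc_av": _p(0.04, "1/day"),  # avascular chondrogenic default rate
        "d_mb": _p(0.1, "1/day"),  # MSC -> osteoblast, driven by g_b
        "alpha_bv": _p(0.3, "-"),  # vascular-niche share of osteogenic drive
        "d_cb": _p(0.15, "1/day"),  # chondrocyte -> osteoblast (endochondral), m_v-gated
        "K_gc": _p(0.1, "-"),
        "K_gb": _p(0.1, "-"),
        "K_vE": _p(0.1, "-"),  # m_v half-saturation of endochondral gating
        # cell removal
        "a_f": _p(0.4, "1/day"),  # fibroblast clearance by advancing bone (x m_b)
        "d_b": _p(0.0, "1/day"),  # osteoblast apoptosis (osteoblasts remain active)
        # matrix production / degradation
        "P_fs": _p(0.1, "1/day"),
        "P_cs": _p(0.4, "1/day"),
        "P_bs": _p(0.25, "1/day"),
        "P_vs": _p(0.3, "1/day"),
        "mv_max": _p(0.35, "-"),  # ceiling of the vascular-matrix volume fraction
        "d_fm": _p(0.08, "1/day"),  # fibrous matrix turnover
        "Q_fc": _p(0.5, "1/day"),  # fibrous degraded by chondrocytes
        "Q_fb": _p(0.5, "1/day"),  # fibrous degraded by osteoblasts
        "Q_cd": _p(0.8, "1/day"),  # cartilage resorbed during endochondral ossification
        # growth-factor production / decay
        "G_gc": _p(0.4, "1/day"),
        "G_gb": _p(1.0, "1/day"),
        "G_gv": _p(0.6, "1/day"),
        "K_hyp": _p(0.4, "-"),  # cartilage density marking hypertrophy (g_v source)
        "K_gbv": _p(0.1, "-"),  # m_v half-saturation of osteogenic GF production
        "d_gc": _p(0.5, "1/day"),
        "d_gb": _p(0.5, "1/day"),
        "d_gv": _p(0.5, "1/day"),
    }
    return KineticParameters(e, provenance=["defaults: reconstructed calibration"])


def scale_parameters(params: KineticParameters, overrides: Mapping[str, float]) -> KineticParameters:
    """Return a new registry with ``symbol -> value * factor`` applied.

    Unlisted symbols are unchanged; unknown symbols or negative factors
    are configuration errors.  Each override is logged in the returned
    registry's ``provenance``.
    """
    entries = dict(params.items())
    prov = list(params.provenance)
    for sym, factor in overrides.items():
        if sym not in entries:
            raise ParameterError(f"unregistered rate symbol {sym!r}")
        if factor < 0:
            raise ConfigurationError(f"scale factor for {sym!r} must be >= 0, got {factor}")
        old = entries[sym]
        entries[sym] = ParamEntry(old.value * factor, old.units, source="override")
        prov.append(f"override {sym} x{factor:g}")
    return KineticParameters(entries, provenance=prov)


def _hill(u: np.ndarray, K: float) -> np.ndarray:
    u = np.maximum(u, 0.0)
    return u / (K + u + _EPS)


def reaction_rates(state: StateField, params: KineticParameters) -> np.ndarray:
    """Pointwise reaction terms for all 12 fields, shape ``(12, ny, nx)``.

    Kinetics (crowding factor ``free = max(1 - m/X, 0)``):

    * cells proliferate logistically, scaled by ``free`` — proliferation
      vanishes where the total tissue density reaches ``X`` — and by an
      Allee-type low-density factor ``c/(K_allee + c)``: trace seedings
      lack the mutual paracrine support to expand on their own;
    * MSCs differentiate into osteoblasts (Hill in ``g_b``, plus a
      vascular-niche component gated by ``m_v``), chondrocytes (Hill in
      ``g_c``, plus a slow avascular default) or, at a small constant
      rate, fibroblasts; endothelial proliferation is driven by ``g_v``
      with a small stimulus-independent background;
    * endochondral ossification converts chondrocytes to osteoblasts and
      resorbs cartilage, gated by the vascular matrix (zero at ``m_v = 0``);
    * differentiation influx into a target population is limited by the
      room left there (densities stay <= 1); the source loss is not, so
      surplus differentiating cells are cleared;
    * each matrix is deposited by its cell type, scaled by ``free``;
      fibrous matrix is remodelled away by chondrocytes/osteoblasts and
      turned over by the resident cells; vascular matrix deposition
      needs the angiogenic drive and saturates at ``mv_max``;
    * growth factors: chondrocytes produce ``g_c``; hypertrophic
      chondrocytes (dense cartilage) produce ``g_v``; osteoblasts
      produce ``g_b`` only in vascularized tissue (m_v-gated);
      first-order decay for all three.
    """
    if np.isnan(state.values).any():
        raise ValueError("state contains NaN")
    s = np.maximum(state.values, 0.0)
    c_m, c_f, c_c, c_b, c_v = s[0], s[1], s[2], s[3], s[4]
    m_f, m_c, m_b, m_v = s[5], s[6], s[7], s[8]
    g_c, g_b, g_v = s[9], s[10], s[11]
    X = params["X"]
    m = m_f + m_c + m_b + m_v
    free = np.maximum(1.0 - m / X, 0.0)

    hill_gb = _hill(g_b, params["K_gb"])
    hill_gc = _hill(g_c, params["K_gc"])
    hill_mv = _hill(m_v, params["K_vE"])

    # Differentiation removes source cells at the full signalled rate; the
    # influx into the target population is limited by the room left there
    # (densities stay <= 1; surplus differentiating cells are cleared).
    room_f = np.maximum(1.0 - c_f, 0.0)
    room_c = np.maximum(1.0 - c_c, 0.0)
    room_b = np.maximum(1.0 - c_b, 0.0)
    # osteogenic drive: osteogenic GF plus the vascular niche (m_v-gated);
    # chondrogenic drive: chondrogenic GF plus a slow avascular default
    diff_mb = params["d_mb"] * (hill_gb + params["alpha_bv"] * hill_mv) * c_m
    diff_mc = (params["d_mc"] * hill_gc + params["d_mc_av"] * (1.0 - hill_mv)) * c_m
    diff_mf = params["d_mf"] * c_m
    endo = params["d_cb"] * hill_gb * hill_mv * c_c

    # low-density (Allee-type) limitation: proliferation needs a minimum
    # local population for mutual paracrine support, so trace seedings do
    # not take off on their own
    def prolif(c, p_sym):
        return params[p_sym] * c * c / (params["K_allee"] + c) * (1.0 - c) * free

    out = np.zeros_like(s)
    out[0] = prolif(c_m, "p_m") - diff_mb - diff_mc - diff_mf
    out[1] = prolif(c_f, "p_f") + diff_mf * room_f - params["a_f"] * m_b * c_f
    out[2] = prolif(c_c, "p_c") + diff_mc * room_c - endo
    out[3] = (prolif(c_b, "p_b") + (diff_mb + endo) * room_b
              - params["d_b"] * c_b)
    # angiogenic drive: mostly stimulus (g_v) dependent, with a small
    # stimulus-independent background share beta_v
    ec_drive = params["beta_v"] + (1.0 - params["beta_v"]) * _hill(g_v, params["K_gvv"])
    out[4] = prolif(c_v, "p_v") * ec_drive

    c_all = c_m + c_f + c_c + c_b + c_v
    out[5] = (params["P_fs"] * c_f * free
              - (params["Q_fc"] * c_c + params["Q_fb"] * c_b) * m_f
              - params["d_fm"] * m_f * c_all)
    out[6] = params["P_cs"] * c_c * free - params["Q_cd"] * hill_mv * c_b * m_c
    out[7] = params["P_bs"] * c_b * free
    # vascular matrix: deposition needs the angiogenic drive and saturates
    # at the volume fraction vessels can occupy (mv_max)
    out[8] = (params["P_vs"] * c_v * ec_drive
              * np.maximum(1.0 - m_v / params["mv_max"], 0.0) * free)

    out[9] = params["G_gc"] * c_c - params["d_gc"] * g_c
    out[10] = params["G_gb"] * _hill(m_v, params["K_gbv"]) * c_b - params["d_gb"] * g_b
    out[11] = params["G_gv"] * _hill(m_c, params["K_hyp"]) * c_c - params["d_gv"] * g_v

    mask = state.grid.in_domain
    out *= mask[None, :, :]
    return out


#: attractant fields and taxis-coefficient symbols per migrating species
TAXIS_TERMS: Dict[str, Tuple[Tuple[str, str], ...]] = {
    "c_m": (("g_b", "chi_m_gb"), ("g_c", "chi_m_gc"), ("m", "chi_m_m")),
    "c_f": (("m", "chi_f_m"),),
    "c_v": (("g_v", "chi_v_gv"), ("m", "chi_v_m")),
}


def motility_factor(total_matrix: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Matrix-dependence of cell motility.

    Zero without matrix to crawl on, maximal (=1) at ``m = K_hm``, and
    strongly suppressed in dense tissue: the steric factor
    ``1/(1 + (m/K_dense)^4)`` models the near-arrest of cell migration
    through mature fibrous matrix (loose granulation tissue at
    ``m ~ 0.1`` remains fully permissive).
    """
    K = params["K_hm"]
    m = np.maximum(total_matrix, 0.0)
    crawl = 2.0 * K * m / (K * K + m * m + _EPS)
    steric = 1.0 / (1.0 + (m / params["K_dense"]) ** 4)
    return crawl * steric


def migration_hindrance(m_v: np.ndarray, params: KineticParameters) -> np.ndarray:
    """Vascular matrix interferes with cell migration: factor 1 - m_v/X."""
    return np.maximum(1.0 - np.maximum(m_v, 0.0) / params["X"], 0.0)


def taxis_velocity(
    state: StateField, params: KineticParameters, species: str
) -> Tuple[np.ndarray, np.ndarray]:
    """Advective face velocities for a migrating cell type.

    Returns ``(u_x, u_y)`` with ``u_x`` on x-normal faces (shape
    ``(ny, nx+1)``) and ``u_y`` on y-normal faces (``(ny+1, nx)``):
    the sum over attractants of taxis coefficient times the attractant
    gradient normal to the face, times the vascular migration hindrance
    evaluated at the face.  Velocities on domain-boundary and outside
    faces are zero (taxis does not cross the boundary).
    """
    if species not in MIGRATING_FIELDS:
        raise ValueError(
            f"species {species!r} is not migratory (expected one of {MIGRATING_FIELDS})"
        )
    grid = state.grid
    ny, nx = grid.shape
    dx = grid.dx
    u_x = np.zeros((ny, nx + 1))
    u_y = np.zeros((ny + 1, nx))
    for attr, chi_sym in TAXIS_TERMS[species]:
        chi = params[chi_sym]
        if chi == 0.0:
            continue
        a = state.total_matrix if attr == "m" else state[attr]
        u_x[:, 1:-1] += chi * (a[:, 1:] - a[:, :-1]) / dx
        u_y[1:-1, :] += chi * (a[1:, :] - a[:-1, :]) / dx
    hind = migration_hindrance(state["m_v"], params)
    u_x[:, 1:-1] *= 0.5 * (hind[:, 1:] + hind[:, :-1])
    u_y[1:-1, :] *= 0.5 * (hind[1:, :] + hind[:-1, :])
    # zero out faces that are not interior (boundary or outside)
    interior_x = np.zeros_like(u_x, dtype=bool)
    interior_x[:, 1:-1] = grid.in_domain[:, 1:] & grid.in_domain[:, :-1]
    interior_y = np.zeros_like(u_y, dtype=bool)
    interior_y[1:-1, :] = grid.in_domain[1:, :] & grid.in_domain[:-1, :]
    u_x *= interior_x
    u_y *= interior_y
    return u_x, u_y
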