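"""Post-processing readouts, standard outputs and test-fixture generation.

All interfragmentary metrics are evaluated over the ROI mask of the
grid (the central column of the domain, identical between healing and
non-union variants):

* tissue fractions — ROI-averaged bone/cartilage/fibrous matrix
  densities normalized by the maximum tissue density ``X`` (so the
  three fractions are comparable across snapshots and do not need to
  sum to one);
* vascularized-tissue percentage — share of ROI cells whose vascular
  matrix density exceeds a configurable cutoff (the model represents
  vessels as a continuum, so a count of vessels is not defined);
* proliferation index — cell numbers weighted by their fixed
  proliferation rates, normalized to total cell number and the maximal
  rate (a theoretical capacity measure in [0, 1]);
* mean growth-factor concentrations over the ROI, optionally rescaled
  so that the initial release equals 100%.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Tuple

import numpy as np
import pandas as pd

from .domain_grid import Grid, build_rectangle_grid
from .errors import ConfigurationError
from .fv_solver import Trajectory
from .kinetics import (
    CELL_FIELDS,
    FIELDS,
    PROLIFERATION_RATES,
    KineticParameters,
    StateField,
)

__all__ = [
    "MetricsTimeseries",
    "tissue_fractions",
    "vascularized_fraction",
    "vascularization_threshold",
    "proliferation_index",
    "mean_growth_factors",
    "compute_metrics",
    "write_outputs",
    "generate_fixture",
]

#: fixed, versioned column order of the metrics CSV
CSV_COLUMNS = (
    "time_days",
    "pow",
    "frac_bone",
    "frac_cartilage",
    "frac_fibrous",
    "vasc_pct",
    "prolif_index",
    "gf_chondro",
    "gf_osteo",
    "gf_vasc",
)
CSV_HEADER_NOTE = (
    "# tissue fractions = ROI mean matrix density / X; vasc_pct = % ROI cells with "
    "m_v >= threshold; prolif_index over the whole domain; GF columns = ROI means"
)


@dataclass
class MetricsTimeseries:
    """Per-snapshot ROI metrics as a fixed-column DataFrame."""

    frame: pd.DataFrame
    vascular_threshold: float

    def at_day(self, day: float) -> pd.Series:
        f = self.frame
        row = f.loc[(f["time_days"] - day).abs() < 1e-6]
        if row.empty:
            raise KeyError(f"no metrics row at day {day}")
        return row.iloc[0]

    def series(self, column: str) -> pd.Series:
        return self.frame.set_index("time_days")[column]


def _roi_check(grid: Grid) -> np.ndarray:
    roi = grid.roi & grid.in_domain
    if not roi.any():
        raise ConfigurationError("ROI is empty on this grid")
    return roi


def tissue_fractions(
    state: StateField, grid: Grid, X: float = 1.0
) -> Tuple[float, float, float]:
    """ROI-averaged (bone, cartilage, fibrous) matrix densities / X."""
    roi = _roi_check(grid)
    mb = float(state["m_b"][roi].mean()) / X
    mc = float(state["m_c"][roi].mean()) / X
    mf = float(state["m_f"][roi].mean()) / X
    return (mb, mc, mf)


def vascularized_fraction(state: StateField, grid: Grid, threshold: float) -> float:
    """Percentage of ROI cells with vascular matrix >= threshold."""
    if threshold < 0:
        raise ConfigurationError("vascularization threshold must be >= 0")
    roi = _roi_check(grid)
    return 100.0 * float((state["m_v"][roi] >= threshold).sum()) / float(roi.sum())


def vascularization_threshold(reference: Trajectory, grid: Grid, fraction: float = 0.5) -> float:
    """Cutoff = ``fraction`` x the median end-state ROI vascular matrix
    density of a reference (normal healing) run.  The underlying model
    defines no canonical cutoff; this convention is config-exposed."""
    roi = _roi_check(grid)
    end = reference.states[-1]
    return fraction * float(np.median(end["m_v"][roi]))


def proliferation_index(
    state: StateField, grid: Grid, params: KineticParameters, region: str = "domain"
) -> float:
    """Rate-weighted proliferative capacity of the cell population.

    ``(sum_i p_i N_i) / (max_i p_i * sum_i N_i)`` with fixed per-type
    proliferation rates ``p_i`` and total cell numbers ``N_i`` over the
    requested region (whole domain by default); 0 when no cells are
    present (0/0 convention).
    """
    mask = grid.in_domain if region == "domain" else _roi_check(grid)
    rates = {f: params[sym] for f, sym in PROLIFERATION_RATES.items()}
    p_max = max(rates.values())
    num = 0.0
    tot = 0.0
    for f in CELL_FIELDS:
        n = float(state[f][mask].sum())
        num += rates[f] * n
        tot += n
    if tot == 0.0 or p_max == 0.0:
        return 0.0
    return num / (p_max * tot)


def mean_growth_factors(
    state: StateField, grid: Grid, relative_to: Tuple[float, float, float] | None = None
) -> Tuple[float, float, float]:
    """ROI means of (g_c, g_b, g_v); with ``relative_to`` (day-0 means),
    each is rescaled so the initial release reads 100."""
    roi = _roi_check(grid)
    vals = (
        float(state["g_c"][roi].mean()),
        float(state["g_b"][roi].mean()),
        float(state["g_v"][roi].mean()),
    )
    if relative_to is not None:
        vals = tuple(
            100.0 * v / r if r > 0 else 0.0 for v, r in zip(vals, relative_to)
        )
    return vals


def compute_metrics(
    trajectory: Trajectory,
    grid: Grid,
    params: KineticParameters,
    vascular_threshold_value: float = 0.1,
    prolif_region: str = "domain",
) -> MetricsTimeseries:
    """Evaluate the full readout table for every snapshot."""
    X = params["X"]
    rows = []
    for t, st in zip(trajectory.times, trajectory.states):
        fb, fc, ff = tissue_fractions(st, grid, X)
        gc, gb, gv = mean_growth_factors(st, grid)
        rows.append(
            {
                "time_days": t,
                "pow": t / 7.0,
                "frac_bone": fb,
                "frac_cartilage": fc,
                "frac_fibrous": ff,
                "vasc_pct": vascularized_fraction(st, grid, vascular_threshold_value),
                "prolif_index": proliferation_index(st, grid, params, prolif_region),
                "gf_chondro": gc,
                "gf_osteo": gb,
                "gf_vasc": gv,
            }
        )
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    return MetricsTimeseries(frame=frame, vascular_threshold=vascular_threshold_value)


# ---------------------------------------------------------------------------
# outputs


def _write_vtk_snapshot(path: Path, state: StateField, grid: Grid) -> None:
    """Legacy-ASCII VTK structured-points snapshot of all 12 fields and masks."""
    ny, nx = grid.shape
    lines = [
        "# vtk DataFile Version 3.0",
        "callussim snapshot",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        "ORIGIN 0 0 0",
        f"SPACING {grid.dx} {grid.dx} 1",
        f"POINT_DATA {nx * ny}",
    ]

    def scalars(name, arr, fmt="%.9e"):
        lines.append(f"SCALARS {name} float 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(" ".join(fmt % v for v in row) for row in arr)

    for f in FIELDS:
        scalars(f, state[f])
    scalars("in_domain", grid.in_domain.astype(float), "%.1f")
    scalars("region", grid.region.astype(float), "%.1f")
    scalars("roi", grid.roi.astype(float), "%.1f")
    path.write_text("\n".join(lines) + "\n")


def _write_hdf5(path: Path, trajectory: Trajectory, grid: Grid) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("times", data=np.asarray(trajectory.times))
        arr = np.stack([st.values for st in trajectory.states])
        h5.create_dataset("fields", data=arr, compression="gzip")
        h5.attrs["field_names"] = ",".join(FIELDS)
        h5.create_dataset("in_domain", data=grid.in_domain.astype(np.int8))
        h5.create_dataset("region", data=grid.region)
        h5.create_dataset("roi", data=grid.roi.astype(np.int8))
        h5.attrs["dx"] = grid.dx


def write_outputs(
    metrics: MetricsTimeseries,
    trajectory: Trajectory,
    grid: Grid,
    out_dir,
    config: dict | None = None,
    vtk: bool = True,
) -> Dict[str, str]:
    """Write metrics CSV, snapshots (VTK + HDF5), config and solver log.

    Returns the manifest: file name -> sha256 of its bytes; the manifest
    itself is stored as ``manifest.json``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as err:
        raise ConfigurationError(f"output directory {out} is not writable: {err}") from err

    csv_path = out / "metrics.csv"
    with open(csv_path, "w") as fh:
        fh.write(CSV_HEADER_NOTE + "\n")
        metrics.frame.to_csv(fh, index=False, float_format="%.17g")

    if vtk:
        for t, st in zip(trajectory.times, trajectory.states):
            _write_vtk_snapshot(out / f"snapshot_day{t:07.2f}.vtk", st, grid)
    _write_hdf5(out / "trajectory.h5", trajectory, grid)

    log = {k: v for k, v in trajectory.log.items() if k != "intervals"}
    (out / "solver_log.txt").write_text(
        "\n".join(f"{k}: {v}" for k, v in sorted(log.items(), key=lambda kv: kv[0])) + "\n"
    )
    if config is not None:
        (out / "config.json").write_text(json.dumps(config, indent=2, sort_keys=True, default=str))

    manifest = {}
    for p in sorted(out.iterdir()):
        if p.name == "manifest.json" or not p.is_file():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def read_metrics_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# fixtures

FIXTURE_KINDS = ("tiny-grid", "uniform-state", "gradient-state", "checkerboard")


def generate_fixture(kind: str, seed: int, n: int = 8, dx: float = 0.1):
    """Deterministic small instances with analytically known properties.

    Returns ``(state, grid, meta)``; ``meta`` documents the analytic
    handle (e.g. the gradient slope of the ``gradient-state`` fixture).
    ``n`` is capped at 32 cells per side.
    """
    if kind not in FIXTURE_KINDS:
        raise ConfigurationError(f"unknown fixture kind {kind!r} (expected one of {FIXTURE_KINDS})")
    n = min(int(n), 32)
    rng = np.random.default_rng(seed)
    grid = build_rectangle_grid(n, n, dx)
    state = StateField.zeros(grid)
    meta: Dict[str, object] = {"kind": kind, "seed": seed, "n": n, "dx": dx}
    if kind == "tiny-grid":
        pass  # all-zero state on the rectangle
    elif kind == "uniform-state":
        levels = rng.uniform(0.05, 0.2, size=len(FIELDS))
        state.values[:] = levels[:, None, None]
        meta["levels"] = levels
    elif kind == "gradient-state":
        slope = float(rng.uniform(0.1, 1.0))
        x = grid.x_centers[None, :] * np.ones((n, 1))
        for f in ("g_c", "g_b", "g_v", "m_f"):
            state[f] = slope * x
        meta["slope"] = slope
    elif kind == "checkerboard":
        level = float(rng.uniform(0.2, 1.0))
        jj, ii = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        board = ((jj + ii) % 2).astype(float) * level
        for f in FIELDS:
            state[f] = board
        meta["level"] = level
    return state, grid, meta
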