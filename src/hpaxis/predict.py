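"""Prediction analyses over GR abundance and stressor intensity.

Three simulation experiments explore how total GR abundance in HPA tissue
shapes measurable GC physiology:

* :func:`sweep_gr` — how the four standardized GC sampling classes
  (baseline, stress-induced, post-DEX, post-ACTH) respond to GR abundance;
* :func:`sweep_stressor` — GC-profile and physiological-response surfaces
  over the GR x stressor-intensity plane, including the saturation of the
  response range at high stressor intensity;
* :func:`association_analysis` — the among-individual association between
  single-timepoint plasma GC and the magnitude of the GC-mediated
  physiological response (peak GC-GR complex), which can be negative among
  individuals even though the within-individual GC -> response mapping is
  strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import HPAParameters
from .simulate import (
    SamplingScheme,
    default_events,
    default_scheme,
    measure,
    response_summary,
    simulate_response,
)

__all__ = [
    "SweepResult",
    "AssociationTable",
    "default_gr_grid",
    "default_b_grid",
    "sweep_gr",
    "sweep_stressor",
    "sensitivity_index",
    "association_analysis",
]

#: output-grid step (minutes) for sweep/association simulations; coarse
#: enough to keep full-factorial sweeps cheap, fine enough to resolve peaks
_SWEEP_DT = 0.2


def default_gr_grid(base: HPAParameters, n: int = 9, fold: float = 10.0) -> np.ndarray:
    """Log-spaced G_tot grid spanning a ``fold``-fold range around the base value."""
    half = np.sqrt(fold)
    return np.geomspace(base.G_tot / half, base.G_tot * half, n)


def default_b_grid(base: HPAParameters, n: int = 6, fold: float = 8.0) -> np.ndarray:
    """Log-spaced stressor-intensity grid spanning a ``fold``-fold range."""
    half = np.sqrt(fold)
    return np.geomspace(base.b / half, base.b * half, n)


@dataclass
class SweepResult:
    """Tidy table of per-grid-point readouts from a parameter sweep."""

    frame: pd.DataFrame
    swept: tuple[str, ...]
    base_params: HPAParameters

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    def midpoint_slopes(self, columns) -> dict[str, float]:
        """Central-difference slope d(column)/d(swept value) at the grid midpoint.

        Defined for single-variable sweeps with at least three grid points.
        """
        if len(self.swept) != 1:
            raise ValueError("midpoint slopes are defined for single-variable sweeps")
        x = self.frame[self.swept[0]].to_numpy()
        if x.size < 3:
            raise ValueError("need at least 3 grid points for a midpoint slope")
        i = x.size // 2
        out = {}
        for c in columns:
            y = self.frame[c].to_numpy()
            out[c] = float((y[i + 1] - y[i - 1]) / (x[i + 1] - x[i - 1]))
        return out


def _simulate_point(params, events, horizon, rtol, atol):
    grid = np.arange(0.0, horizon + 1e-9, _SWEEP_DT)
    return simulate_response(params, events=events, horizon=horizon,
                             output_grid=grid, rtol=rtol, atol=atol)


def sweep_gr(
    base_params: HPAParameters,
    gr_grid=None,
    events=None,
    scheme: SamplingScheme | None = None,
    horizon: float = 180.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SweepResult:
    """Labelled GC levels and response summaries across GR abundance.

    Every other parameter is held at its value in ``base_params``; one
    simulation (with the injection protocol, default DEX at minute 30 and
    ACTH at minute 80) is run per grid point.  Because GR drives negative
    feedback, GC at every sampling class decreases with G_tot, most
    steeply where GC — and hence GR occupancy — is highest (post-ACTH),
    and barely at all at baseline.
    """
    base_params.validate()
    gr_grid = default_gr_grid(base_params) if gr_grid is None else np.asarray(gr_grid, dtype=float)
    if gr_grid.size < 3:
        raise ValueError("gr_grid needs at least 3 points")
    if np.any(gr_grid <= 0):
        raise ValueError("gr_grid values must be > 0")
    events = default_events() if events is None else list(events)
    scheme = scheme or default_scheme()

    rows = []
    for g in gr_grid:
        p = base_params.replace(G_tot=float(g))
        traj = _simulate_point(p, events, horizon, rtol, atol)
        row = {"G_tot": float(g)}
        row.update(measure(traj, scheme))
        row.update(response_summary(traj))
        rows.append(row)
    return SweepResult(pd.DataFrame(rows), swept=("G_tot",), base_params=base_params)


def sweep_stressor(
    base_params: HPAParameters,
    gr_grid=None,
    b_grid=None,
    scheme: SamplingScheme | None = None,
    events=(),
    horizon: float = 180.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> SweepResult:
    """Full-factorial GR x stressor-intensity sweep of the stress response.

    By default no injections are applied: the readouts describe the pure
    stressor response.  Reported per cell are the GC range, the
    physiological-response range (range of the GC-GR complex), peak levels
    and timings, and integrated exposures.
    """
    base_params.validate()
    gr_grid = default_gr_grid(base_params) if gr_grid is None else np.asarray(gr_grid, dtype=float)
    b_grid = default_b_grid(base_params) if b_grid is None else np.asarray(b_grid, dtype=float)
    if np.any(gr_grid <= 0) or np.any(b_grid < 0):
        raise ValueError("grids must be positive (b may include 0)")
    scheme = scheme or default_scheme()

    rows = []
    for g in gr_grid:
        for b in b_grid:
            p = base_params.replace(G_tot=float(g), b=float(b))
            traj = _simulate_point(p, list(events), horizon, rtol, atol)
            row = {"G_tot": float(g), "b": float(b)}
            row.update(response_summary(traj))
            rows.append(row)
    return SweepResult(pd.DataFrame(rows), swept=("G_tot", "b"), base_params=base_params)


def sensitivity_index(sweep: SweepResult) -> pd.DataFrame:
    """Saturation diagnostic of endocrine flexibility, per GR level.

    For each G_tot, the ratio of the physiological-response range at the
    highest stressor intensity to the range at the mid-grid intensity.  In
    the linear (unsaturated) regime the response range grows proportionally
    to b and the ratio approaches b_high/b_mid; a ratio near 1 means the
    response has saturated and the individual can no longer scale its
    response to stronger stressors.  Low-GR individuals saturate earlier,
    so their ratio sits closer to 1.
    """
    if "b" not in sweep.swept:
        raise ValueError("sensitivity_index requires a stressor-intensity sweep")
    df = sweep.frame
    out = []
    for g, sub in df.groupby("G_tot", sort=True):
        b = np.sort(sub["b"].unique())
        if b.size < 2:
            raise ValueError("sensitivity_index needs at least 2 stressor intensities per G_tot")
        b_mid = b[b.size // 2]
        b_high = b[-1]
        if b_high == b_mid:
            raise ValueError("highest and mid stressor intensities coincide")
        r_mid = float(sub.loc[sub["b"] == b_mid, "range_O_G"].iloc[0])
        r_high = float(sub.loc[sub["b"] == b_high, "range_O_G"].iloc[0])
        out.append({
            "G_tot": float(g),
            "b_mid": float(b_mid),
            "b_high": float(b_high),
            "range_mid": r_mid,
            "range_high": r_high,
            "ratio": r_high / r_mid if r_mid > 0 else float("nan"),
            "linear_ratio": float(b_high / b_mid),
        })
    return pd.DataFrame(out)


@dataclass
class AssociationTable:
    """Simulated population linking single-timepoint GC to response magnitude.

    ``frame`` holds one row per simulated individual (drawn G_tot, plasma
    GC at each sampling time, and the physiological-response magnitude =
    peak GC-GR complex).  ``correlations`` gives the rank (Spearman) and
    Pearson correlation between GC at each sampling time and the response
    magnitude; ``None`` entries mark degenerate (zero-variance) input.
    """

    frame: pd.DataFrame
    correlations: pd.DataFrame
    sampling_times: tuple[float, ...]
    base_params: HPAParameters = field(repr=False, default=None)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _draw_gr(gr_distribution, base: HPAParameters, n: int, rng: np.random.Generator):
    if gr_distribution is None:
        gr_distribution = {"median": base.G_tot, "cv": 0.5}
    if callable(gr_distribution):
        vals = np.asarray(gr_distribution(rng, n), dtype=float)
    elif isinstance(gr_distribution, dict):
        median = float(gr_distribution["median"])
        cv = float(gr_distribution.get("cv", 0.5))
        if median <= 0 or cv < 0:
            raise ValueError("gr_distribution median must be > 0 and cv >= 0")
        sigma = np.sqrt(np.log1p(cv**2))
        vals = median * np.exp(sigma * rng.standard_normal(n))
    else:
        vals = np.asarray(gr_distribution, dtype=float)
        if vals.size != n:
            raise ValueError(f"gr_distribution array must have length n={n}")
    if np.any(vals <= 0):
        raise ValueError("drawn G_tot values must be > 0")
    return vals


def association_analysis(
    base_params: HPAParameters,
    gr_distribution=None,
    b: float | None = None,
    sampling_times=(0.0, 30.0, 120.0),
    n: int = 200,
    seed: int | None = None,
    horizon: float = 180.0,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> AssociationTable:
    """Single-timepoint GC vs physiological response across individuals.

    Draws ``n`` individuals differing (by default) only in total GR
    abundance, simulates each one's pure stressor response (no injections),
    and tabulates plasma GC at the requested sampling times — baseline
    (0 min), stress-induced (30 min) and recovery (120 min) — against the
    response magnitude (peak GC-GR complex).  Because GR raises the
    response but lowers circulating GC, the among-individual correlation
    at a single timepoint can be negative, masking (or inverting) the
    strictly increasing within-individual dose-response curve.
    """
    base_params.validate()
    if n < 10:
        raise ValueError("association analysis needs n >= 10 individuals")
    sampling_times = tuple(float(t) for t in sampling_times)
    if any(t < 0 or t > horizon for t in sampling_times):
        raise ValueError("sampling times must lie within [0, horizon]")
    rng = np.random.default_rng(seed)
    gr_vals = _draw_gr(gr_distribution, base_params, n, rng)
    if b is None:
        b = base_params.b

    grid = np.union1d(np.arange(0.0, horizon + 1e-9, _SWEEP_DT), np.asarray(sampling_times))
    rows = []
    for i, g in enumerate(gr_vals):
        p = base_params.replace(G_tot=float(g), b=float(b))
        traj = simulate_response(p, events=(), horizon=horizon, output_grid=grid,
                                 rtol=rtol, atol=atol)
        s = response_summary(traj)
        row = {"individual": i, "G_tot": float(g)}
        for t in sampling_times:
            row[f"gc_{t:g}min"] = float(np.interp(t, traj.t, traj.O))
        row["response_magnitude"] = s["peak_O_G"]
        row["response_range"] = s["range_O_G"]
        row["response_auc"] = s["auc_O_G"]
        rows.append(row)
    frame = pd.DataFrame(rows)

    cors = []
    resp = frame["response_magnitude"].to_numpy()
    for t in sampling_times:
        gc = frame[f"gc_{t:g}min"].to_numpy()
        if np.ptp(gc) == 0 or np.ptp(resp) == 0:
            cors.append({"time_min": t, "spearman": None, "pearson": None,
                         "n": n, "degenerate": True})
            continue
        rho = stats.spearmanr(gc, resp).statistic
        r = stats.pearsonr(gc, resp).statistic
        cors.append({"time_min": t, "spearman": float(rho), "pearson": float(r),
                     "n": n, "degenerate": False})
    return AssociationTable(frame, pd.DataFrame(cors), sampling_times, base_params)
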