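"""Time-domain simulation of the HPA-axis model.

Simulations start from the baseline steady state (the axis at rest under
basal demand only), apply the acute stressor through the stimulus function,
and optionally inject timed boluses of ACTH (probing maximal GC production)
or dexamethasone (a synthetic GR ligand probing maximal negative feedback).
Plasma-GC readouts are extracted at labelled sampling classes mirroring
standard field protocols: baseline within ~3 min of disturbance,
stress-induced at 20-30 min, post-DEX at 60-80 min, post-ACTH at 100 min.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import ODEintWarning, odeint, solve_ivp
from scipy.optimize import brentq

from .core import _rhs, _rhs_fast, equilibrium_binding, params_to_array
from .params import HPAParameters, STATE_FIELDS, SystemState

__all__ = [
    "InjectionEvent",
    "SamplingScheme",
    "Trajectory",
    "default_scheme",
    "default_events",
    "baseline_state",
    "simulate_response",
    "gc_at",
    "measure",
    "response_summary",
    "integrate_rk4",
]

_TARGET_INDEX = {"ACTH": STATE_FIELDS.index("A"), "DEX": STATE_FIELDS.index("D")}

#: Default bolus sizes (concentration units), chosen so that the post-ACTH
#: GC level exceeds the stress-induced peak (maximal-production probe) and
#: the post-DEX level falls clearly below it (maximal-feedback probe).
DEFAULT_ACTH_AMOUNT = 60.0
DEFAULT_DEX_AMOUNT = 15.0


@dataclass(frozen=True)
class InjectionEvent:
    """A timed bolus applied during simulation.

    ``target`` is ``"ACTH"`` (increment to the pituitary hormone A) or
    ``"DEX"`` (increment to the free exogenous GR ligand D).
    """

    time: float
    target: str
    amount: float

    def __post_init__(self):
        if self.target not in _TARGET_INDEX:
            raise ValueError(f"event target must be one of {sorted(_TARGET_INDEX)}")
        if self.time < 0:
            raise ValueError("event time must be >= 0")
        if self.amount < 0:
            raise ValueError("event amount must be >= 0")


@dataclass(frozen=True)
class SamplingScheme:
    """Labelled sampling times and the time windows they represent.

    ``times`` maps each sampling-class label to the representative minute at
    which the class is read off a trajectory; ``windows`` gives the interval
    within which field protocols actually draw the sample (used by the
    synthetic-data generator to jitter sampling times).
    """

    times: dict[str, float]
    windows: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.times)) != len(self.times):
            raise ValueError("sampling-class labels must be unique")
        for label, (lo, hi) in self.windows.items():
            if label not in self.times:
                raise ValueError(f"window for unknown label {label!r}")
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid window for {label!r}: ({lo}, {hi})")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.times)

    def horizon(self) -> float:
        hi = max(self.times.values())
        for lo, w_hi in self.windows.values():
            hi = max(hi, w_hi)
        return hi


def default_scheme() -> SamplingScheme:
    """The four-class sampling protocol of standardized stress series."""
    return SamplingScheme(
        times={
            "baseline": 1.5,
            "stress_induced": 25.0,
            "post_dex": 70.0,
            "post_acth": 100.0,
        },
        windows={
            "baseline": (0.0, 3.0),
            "stress_induced": (20.0, 30.0),
            "post_dex": (60.0, 80.0),
            "post_acth": (100.0, 100.0),
        },
    )


def default_events(
    dex_time: float = 30.0,
    dex_amount: float = DEFAULT_DEX_AMOUNT,
    acth_time: float = 80.0,
    acth_amount: float = DEFAULT_ACTH_AMOUNT,
) -> list[InjectionEvent]:
    """DEX bolus after the stress-induced sample, ACTH bolus at minute 80."""
    return [
        InjectionEvent(dex_time, "DEX", dex_amount),
        InjectionEvent(acth_time, "ACTH", acth_amount),
    ]


@dataclass
class Trajectory:
    """A simulated time course of all nine model species.

    ``t`` is the strictly increasing output grid (minutes) and ``y`` the
    corresponding state matrix with columns in ``STATE_FIELDS`` order.  The
    event log records, for each applied bolus, the state immediately before
    and after, so that the discontinuity is available exactly.
    """

    t: np.ndarray
    y: np.ndarray
    events: tuple[InjectionEvent, ...] = ()
    event_log: tuple[dict, ...] = ()

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.y.shape != (self.t.size, len(STATE_FIELDS)):
            raise ValueError("trajectory shape mismatch")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("trajectory time grid must be strictly increasing")

    def component(self, name: str) -> np.ndarray:
        return self.y[:, STATE_FIELDS.index(name)]

    @property
    def O(self) -> np.ndarray:  # noqa: E743 - model symbol
        return self.component("O")

    @property
    def O_G(self) -> np.ndarray:
        return self.component("O_G")

    def state_at(self, i: int) -> SystemState:
        return SystemState.from_array(self.y[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(STATE_FIELDS))
        df.insert(0, "time_min", self.t)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def conservation_error(self, params: HPAParameters) -> dict[str, float]:
        """Max relative violation of receptor conservation over the grid."""
        g_sum = self.component("G") + self.component("O_G") + self.component("D_G")
        m_sum = self.component("M") + self.component("O_M")
        err = {
            "GR": float(np.max(np.abs(g_sum - params.G_tot)) / max(params.G_tot, 1e-30)),
            "MR": float(np.max(np.abs(m_sum - params.M_tot)) / max(params.M_tot, 1e-30)),
        }
        return err


def baseline_state(
    params: HPAParameters,
    tol: float = 1e-10,
    max_expand: int = 60,
) -> SystemState:
    """Steady state of the axis at rest (stressor off, stimulus = B).

    With b = 0 the stationary conditions reduce to a single scalar equation
    in free GC: receptor complexes sit on their equilibrium saturation
    curves, CRH and ACTH follow from balancing production against
    degradation and feedback (floored at zero, since feedback cannot drive
    a concentration negative), and GC production must balance clearance.
    The root is bracketed and solved with Brent's method, then verified
    against the full right-hand side (residual norm < 1e-8).
    """
    params.validate()
    rest = params.replace(b=0.0)
    if rest.B == 0:
        return SystemState(G=params.G_tot, M=params.M_tot)
    if rest.b_C <= 0 or rest.b_A <= 0 or rest.b_O <= 0:
        raise ValueError("baseline steady state requires positive degradation rates when B > 0")
    k_CG, k_CM, k_AG, k_AM = rest.fb

    def chain(O: float) -> tuple[float, float, float, float]:
        OG = equilibrium_binding(O, rest.G_tot, rest.K_G)
        OM = equilibrium_binding(O, rest.M_tot, rest.K_M)
        C = max(0.0, (rest.B - k_CG * OG - k_CM * OM) / rest.b_C)
        A = max(0.0, (rest.k_A * C - k_AG * OG - k_AM * OM) / rest.b_A)
        return C, A, OG, OM

    def f(O: float) -> float:
        _, A, _, _ = chain(O)
        return rest.k_O * A - rest.b_O * O

    lo, hi = 0.0, max(rest.B, 1.0)
    f_lo = f(lo)
    if f_lo <= 0:
        O_star = 0.0
    else:
        n = 0
        while f(hi) > 0:
            hi *= 2.0
            n += 1
            if n > max_expand:
                raise RuntimeError("baseline_state: could not bracket the GC steady state")
        O_star = brentq(f, lo, hi, xtol=tol, rtol=8.9e-16)

    C, A, OG, OM = chain(O_star)
    state = SystemState(
        C=C, A=A, O=O_star, O_G=OG, O_M=OM,
        G=rest.G_tot - OG, M=rest.M_tot - OM,
    )
    resid = _rhs(0.0, state.as_array(), rest, clamp=True)
    norm = float(np.linalg.norm(resid))
    if norm > 1e-8:
        raise RuntimeError(
            f"baseline_state did not converge: residual RHS norm {norm:.3e} > 1e-8"
        )
    return state


def _validate_events(events, horizon: float) -> list[InjectionEvent]:
    evs = sorted(events, key=lambda e: e.time)
    for e in evs:
        if e.time > horizon:
            raise ValueError(f"event at t={e.time} outside horizon {horizon}")
    return evs


def simulate_response(
    params: HPAParameters,
    events=(),
    horizon: float = 180.0,
    output_grid=None,
    y0: SystemState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the model through an acute stress response.

    Integration starts from :func:`baseline_state` (so "baseline" samples
    measure a true resting level, not a transient), proceeds with adaptive
    error control, and is hard-restarted at every injection event, whose
    amount is added instantaneously to the target species.

    Parameters
    ----------
    events : iterable of InjectionEvent
        Timed ACTH/DEX boluses; must lie within the horizon.
    horizon : float
        End time in minutes.
    output_grid : array_like, optional
        Times at which to store the solution.  Defaults to a 0.1-min grid.
        Event times are always included (holding the post-event state).
    """
    params.validate()
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    evs = _validate_events(events, horizon)
    if output_grid is None:
        grid = np.arange(0.0, horizon + 1e-9, 0.1)
        if grid[-1] < horizon:
            grid = np.append(grid, horizon)
    else:
        grid = np.unique(np.asarray(output_grid, dtype=float))
        if grid.size == 0:
            raise ValueError("output_grid is empty")
        if grid[0] < 0 or grid[-1] > horizon:
            raise ValueError("output_grid must lie within [0, horizon]")

    y = (y0 if y0 is not None else baseline_state(params)).as_array().copy()
    boundaries = sorted({0.0, horizon, *[e.time for e in evs]})

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    log: list[dict] = []
    ev_by_time: dict[float, list[InjectionEvent]] = {}
    for e in evs:
        ev_by_time.setdefault(e.time, []).append(e)

    t_cur = boundaries[0]
    # events exactly at t=0 are applied before integration starts
    for e in ev_by_time.get(t_cur, []):
        before = y.copy()
        y[_TARGET_INDEX[e.target]] += e.amount
        log.append({"event": e, "state_before": before, "state_after": y.copy()})
    if grid[0] == t_cur:
        times_out.append(np.array([t_cur]))
        states_out.append(y[None, :].copy())

    for t_next in boundaries[1:]:
        seg_mask = (grid > t_cur) & (grid <= t_next)
        t_eval = np.unique(np.concatenate([grid[seg_mask], [t_next]]))
        sol = solve_ivp(
            _rhs, (t_cur, t_next), y, method=method,
            t_eval=t_eval, args=(params,), rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise RuntimeError(
                f"integrator failed on [{t_cur}, {t_next}]: {sol.message} "
                f"(last time reached: {sol.t[-1] if sol.t.size else t_cur})"
            )
        y = sol.y[:, -1].copy()
        keep = np.isin(sol.t, grid[seg_mask])
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep].T.copy())
        for e in ev_by_time.get(t_next, []):
            before = y.copy()
            y[_TARGET_INDEX[e.target]] += e.amount
            log.append({"event": e, "state_before": before, "state_after": y.copy()})
            # stored value at an event time is the post-event state
            if times_out[-1].size and times_out[-1][-1] == t_next:
                states_out[-1][-1] = y
        t_cur = t_next

    t_all = np.concatenate(times_out)
    y_all = np.vstack(states_out)
    y_all = np.clip(y_all, 0.0, None)  # shave solver-level negative round-off
    return Trajectory(t_all, y_all, tuple(evs), tuple(log))


def gc_at(
    params: HPAParameters,
    times,
    events=(),
    rtol: float = 1e-6,
    atol: float = 1e-8,
    y0: SystemState | None = None,
) -> np.ndarray:
    """Free plasma GC at the requested times (sparse-output fast path).

    Produces the same model GC as simulating a dense trajectory and
    reading it off, but integrates segment-by-segment with ``odeint``
    (LSODA) and a compiled right-hand side, evaluating the solution only
    where needed.  This is the hot path of likelihood evaluation during
    fitting; :func:`simulate_response` remains the general route when the
    full trajectory is wanted.
    """
    params.validate()
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return np.array([])
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    horizon = float(max(times.max(), max((e.time for e in events), default=0.0)))
    horizon = max(horizon, 1e-6)
    evs = _validate_events(events, horizon)

    c = params_to_array(params)
    y = (y0 if y0 is not None else baseline_state(params)).as_array().copy()
    boundaries = sorted({0.0, horizon, *[e.time for e in evs]})
    ev_by_time: dict[float, list[InjectionEvent]] = {}
    for e in evs:
        ev_by_time.setdefault(e.time, []).append(e)

    values: dict[float, float] = {}
    t_cur = boundaries[0]
    for e in ev_by_time.get(t_cur, []):
        y[_TARGET_INDEX[e.target]] += e.amount
    if 0.0 in times:
        values[0.0] = max(y[STATE_FIELDS.index("O")], 0.0)
    for t_next in boundaries[1:]:
        seg = np.unique(times[(times > t_cur) & (times <= t_next)])
        tarr = np.unique(np.concatenate([[t_cur], seg, [t_next]]))
        with warnings.catch_warnings():
            # failures are re-raised below with context; the warning is noise
            warnings.simplefilter("ignore", ODEintWarning)
            sol, info = odeint(
                _rhs_fast, y, tarr, args=(c,), rtol=rtol, atol=atol,
                tfirst=True, full_output=True, printmessg=False, mxstep=10000,
            )
        if info["message"] != "Integration successful.":
            raise RuntimeError(
                f"odeint failed on [{t_cur}, {t_next}]: {info['message']}"
            )
        y = sol[-1].copy()
        o_col = sol[:, STATE_FIELDS.index("O")]
        for t_i, o_i in zip(tarr, o_col):
            if t_i in seg:
                values[t_i] = max(float(o_i), 0.0)
        for e in ev_by_time.get(t_next, []):
            y[_TARGET_INDEX[e.target]] += e.amount
        t_cur = t_next
    return np.array([values[t] for t in times])


def measure(traj: Trajectory, scheme: SamplingScheme) -> dict[str, float]:
    """Plasma GC at each labelled sampling time (linear interpolation).

    Only the endogenous hormone O is measured; circulating dexamethasone D
    is a distinct molecule and is invisible to the GC assay.
    """
    out = {}
    for label, t in scheme.times.items():
        if t < traj.t[0] or t > traj.t[-1]:
            raise ValueError(f"sampling time {t} for {label!r} outside trajectory range")
        out[label] = float(np.interp(t, traj.t, traj.O))
    return out


def response_summary(traj: Trajectory) -> dict[str, float]:
    """Peak/range/exposure summaries of a stress-response trajectory.

    ``peak_O_G`` (the maximal GC-GR complex concentration) is the model's
    proxy for the magnitude of the GC-mediated physiological response;
    ``range_*`` is max - min across the response; ``auc_*`` the
    time-integrated exposure.
    """
    if traj.t.size == 0:
        raise ValueError("empty trajectory")
    O = traj.O
    OG = traj.O_G
    i_peak = int(np.argmax(O))
    return {
        "peak_O": float(O[i_peak]),
        "t_peak_O": float(traj.t[i_peak]),
        "peak_O_G": float(OG.max()),
        "t_peak_O_G": float(traj.t[int(np.argmax(OG))]),
        "range_O": float(O.max() - O.min()),
        "range_O_G": float(OG.max() - OG.min()),
        "auc_O": float(np.trapezoid(O, traj.t)),
        "auc_O_G": float(np.trapezoid(OG, traj.t)),
    }


def integrate_rk4(
    params: HPAParameters,
    events=(),
    horizon: float = 180.0,
    dt: float = 0.001,
    y0: SystemState | None = None,
    store_every: int | None = None,
) -> Trajectory:
    """Fixed-step classical Runge-Kutta integration (verification path).

    A deliberately simple integrator kept independent of the adaptive
    solver's stepping machinery, used to cross-check `simulate_response`.
    Event times must fall on the step grid.
    """
    params.validate()
    evs = _validate_events(events, horizon)
    for e in evs:
        if abs(e.time / dt - round(e.time / dt)) > 1e-9:
            raise ValueError(f"event time {e.time} is not a multiple of dt={dt}")
    n_steps = int(math.ceil(horizon / dt - 1e-9))
    if store_every is None:
        store_every = max(1, int(round(0.1 / dt)))

    y = (y0 if y0 is not None else baseline_state(params)).as_array().copy()
    ev_by_step: dict[int, list[InjectionEvent]] = {}
    for e in evs:
        ev_by_step.setdefault(int(round(e.time / dt)), []).append(e)

    times = [0.0]
    states = [y.copy()]
    log: list[dict] = []
    for e in ev_by_step.get(0, []):
        before = y.copy()
        y[_TARGET_INDEX[e.target]] += e.amount
        log.append({"event": e, "state_before": before, "state_after": y.copy()})
        states[-1] = y.copy()

    for step in range(1, n_steps + 1):
        t = (step - 1) * dt
        k1 = _rhs(t, y, params)
        k2 = _rhs(t + dt / 2, y + dt / 2 * k1, params)
        k3 = _rhs(t + dt / 2, y + dt / 2 * k2, params)
        k4 = _rhs(t + dt, y + dt * k3, params)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        np.clip(y, 0.0, None, out=y)
        for e in ev_by_step.get(step, []):
            before = y.copy()
            y[_TARGET_INDEX[e.target]] += e.amount
            log.append({"event": e, "state_before": before, "state_after": y.copy()})
        if step % store_every == 0 or step == n_steps:
            times.append(step * dt)
            states.append(y.copy())

    return Trajectory(np.array(times), np.vstack(states), tuple(evs), tuple(log))
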