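"""Maximum-likelihood fitting of the HPA-axis model to GC profiles.

The entry point is :class:`HPAModel`, a statsmodels-style model object built
from an :class:`~hpaxis.dataset.ObservedDataset`; its :meth:`~HPAModel.fit`
runs a derivative-free Nelder-Mead simplex search over a user-chosen set of
free parameters (positivity enforced by a log transform) and returns an
:class:`HPAResults` carrying estimates, the maximized log-likelihood,
convergence diagnostics and fitted values.

The likelihood treats residuals between observed and model GC as iid
Gaussian, either on the raw scale (default) or on the log scale (GC data
are typically right-skewed); the residual variance is profiled at its MLE
unless a fixed sigma is supplied.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .dataset import ObservedDataset
from .params import HPAParameters
from .simulate import InjectionEvent, SamplingScheme, baseline_state, default_events, default_scheme, gc_at

__all__ = [
    "ParameterMask",
    "HPAModel",
    "HPAResults",
    "neg_log_likelihood",
    "visual_start",
]

logger = logging.getLogger(__name__)

#: Parameters that may be freed in a fit (all positive rate/abundance
#: constants plus the stimulus parameters).
FITTABLE = (
    "B", "b", "alpha", "b_C", "b_A", "b_O", "k_A", "k_O", "k_fb",
    "k_G", "k_mG", "k_M", "k_mM", "G_tot", "M_tot",
)

#: The parameter set adjusted in the reference fitting protocol: hormone
#: production/degradation rates, the binding/release constants of both
#: receptors and the initial receptor abundances.
PROTOCOL_FREE = ("b_C", "k_A", "b_A", "k_O", "b_O", "k_G", "k_mG", "k_M", "k_mM", "G_tot", "M_tot")

_LOG_2PI = float(np.log(2.0 * np.pi))
_MIN_SIGMA2 = 1e-12


@dataclass
class ParameterMask:
    """Which parameters are free, where they start, and optional bounds.

    ``free`` lists parameter names optimized by the simplex search; all
    other parameters stay fixed at their value in ``start``.  Optional
    ``bounds[name] = (lo, hi)`` boxes are enforced by a logistic transform;
    unbounded free parameters are log-transformed (positivity by
    construction).
    """

    free: tuple[str, ...]
    start: HPAParameters = field(default_factory=HPAParameters)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.free = tuple(self.free)
        if len(self.free) == 0:
            raise ValueError("at least one parameter must be free")
        unknown = [p for p in self.free if p not in FITTABLE]
        if unknown:
            raise ValueError(f"unknown free parameters: {unknown}; fittable: {FITTABLE}")
        if len(set(self.free)) != len(self.free):
            raise ValueError("duplicate names in free parameter list")
        for name, (lo, hi) in self.bounds.items():
            if name not in self.free:
                raise ValueError(f"bounds given for non-free parameter {name!r}")
            if not (0 <= lo < hi):
                raise ValueError(f"invalid bounds for {name!r}: ({lo}, {hi})")
        self.start.validate()
        for p in self.free:
            v = getattr(self.start, p)
            if p in self.bounds:
                lo, hi = self.bounds[p]
                if not (lo < v < hi):
                    raise ValueError(f"start value of {p} ({v}) outside bounds ({lo}, {hi})")
            elif v <= 0:
                raise ValueError(
                    f"start value of log-transformed free parameter {p} must be > 0, got {v}"
                )

    # -- transform between natural and unconstrained optimizer space -------
    def to_opt(self, params: HPAParameters) -> np.ndarray:
        x = np.empty(len(self.free))
        for i, p in enumerate(self.free):
            v = getattr(params, p)
            if p in self.bounds:
                lo, hi = self.bounds[p]
                u = (v - lo) / (hi - lo)
                x[i] = np.log(u / (1.0 - u))
            else:
                x[i] = np.log(v)
        return x

    def to_params(self, x: np.ndarray) -> HPAParameters:
        kw = {}
        for i, p in enumerate(self.free):
            if p in self.bounds:
                lo, hi = self.bounds[p]
                kw[p] = lo + (hi - lo) / (1.0 + np.exp(-x[i]))
            else:
                kw[p] = float(np.exp(x[i]))
        return self.start.replace(**kw)

    @classmethod
    def protocol(cls, start: HPAParameters | None = None) -> "ParameterMask":
        """The reference free-parameter set (production/degradation rates,
        binding constants and receptor totals); a deliberately rich mask,
        generally over-parameterized for a four-timepoint profile."""
        return cls(free=PROTOCOL_FREE, start=start or HPAParameters())

    @classmethod
    def gr_only(cls, start: HPAParameters | None = None) -> "ParameterMask":
        """Free only total GR abundance (all shared kinetics fixed); the
        mask used when inferring per-individual GR from GC profiles."""
        return cls(free=("G_tot",), start=start or HPAParameters())


def neg_log_likelihood(
    params: HPAParameters,
    data: ObservedDataset,
    events=None,
    error_model: str = "gaussian",
    sigma: float | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> float:
    """Gaussian negative log-likelihood of a GC dataset under the model.

    The model is simulated once and evaluated at every observation time.
    With ``sigma=None`` the residual variance is profiled at its MLE
    (sigma_hat^2 = RSS/n), giving ``n/2 * (log(2 pi sigma_hat^2) + 1)``;
    passing a fixed ``sigma`` evaluates the ordinary Gaussian sum.  With
    ``error_model="lognormal"`` residuals are taken between log-observed
    and log-predicted GC.

    Simulation failures return ``+inf`` (with a logged warning) so that an
    optimizer retreats from pathological parameter regions.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    if error_model not in ("gaussian", "lognormal"):
        raise ValueError("error_model must be 'gaussian' or 'lognormal'")
    if events is None:
        events = default_events()
    times = data.times
    obs = data.values
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # affinity-order warnings during search
            pred = gc_at(params, times, events=events, rtol=rtol, atol=atol)
    except Exception as exc:  # noqa: BLE001 - optimizer robustness
        logger.warning("simulation failed during likelihood evaluation: %s", exc)
        return float("inf")
    if not np.all(np.isfinite(pred)):
        logger.warning("non-finite model prediction during likelihood evaluation")
        return float("inf")
    if error_model == "lognormal":
        resid = np.log(np.maximum(obs, 1e-12)) - np.log(np.maximum(pred, 1e-12))
    else:
        resid = obs - pred
    n = resid.size
    rss = float(resid @ resid)
    if sigma is None:
        s2 = max(rss / n, _MIN_SIGMA2)
        return 0.5 * n * (_LOG_2PI + np.log(s2) + 1.0)
    return 0.5 * n * (_LOG_2PI + 2.0 * np.log(sigma)) + rss / (2.0 * sigma**2)


def visual_start(data: ObservedDataset, base: HPAParameters | None = None) -> HPAParameters:
    """Deterministic starting values from coarse features of the data.

    A reproducible replacement for choosing starting values by eye:

    * the GC production rate ``k_O`` is scaled by the ratio of the observed
      baseline mean to the baseline level the reference parameters produce
      (so the heuristic is scale-equivariant: multiplying all GC values by
      c multiplies the production-rate start by c);
    * the stressor intensity ``b`` is scaled by the observed relative
      stress contrast (stress-induced minus baseline, over baseline)
      against the contrast of the reference parameters — zero contrast
      gives a near-zero stressor start;
    * the GC degradation rate ``b_O`` is read off the post-peak decline
      between the stress-induced and post-DEX class means.

    Missing classes fall back to the reference values with a warning.
    """
    base = (base or HPAParameters()).validate()
    means = data.class_means()
    start = base

    ref_baseline = baseline_state(base).O
    if "baseline" in means and means["baseline"] > 0 and ref_baseline > 0:
        start = start.replace(k_O=base.k_O * float(means["baseline"]) / ref_baseline)
    else:
        warnings.warn("no usable baseline class; production-rate start kept at reference")

    if "baseline" in means and "stress_induced" in means and means["baseline"] > 0:
        obs_contrast = (means["stress_induced"] - means["baseline"]) / means["baseline"]
        ref_m = _reference_class_levels(base)
        ref_contrast = (ref_m["stress_induced"] - ref_m["baseline"]) / ref_m["baseline"]
        b_start = base.b * max(float(obs_contrast), 0.0) / max(ref_contrast, 1e-12)
        start = start.replace(b=max(b_start, 1e-6))
    else:
        warnings.warn("missing baseline/stress classes; stressor start kept at reference")

    if "stress_induced" in means and "post_dex" in means and means["post_dex"] > 0:
        t_si = 25.0, 70.0  # representative class times
        if means["stress_induced"] > means["post_dex"]:
            rate = float(np.log(means["stress_induced"] / means["post_dex"])) / (t_si[1] - t_si[0])
            start = start.replace(b_O=float(np.clip(rate, 1e-3, 1.0)))
    return start


def _reference_class_levels(base: HPAParameters) -> dict[str, float]:
    from .simulate import measure, simulate_response

    scheme = default_scheme()
    traj = simulate_response(base, events=default_events(), horizon=scheme.horizon() + 10.0,
                             rtol=1e-6, atol=1e-8)
    return measure(traj, scheme)


class HPAModel:
    """The HPA-axis model bound to a GC dataset, ready to fit.

    Parameters
    ----------
    data : ObservedDataset or pandas.DataFrame
        GC observations (validated on construction).
    events : list of InjectionEvent, optional
        Injection protocol under which the data were collected; defaults
        to a DEX bolus at minute 30 and an ACTH bolus at minute 80.
    scheme : SamplingScheme, optional
        Sampling-class metadata (labels/windows); defaults to the standard
        four-class protocol.
    error_model : {"gaussian", "lognormal"}
        Residual model of the likelihood.
    solver_rtol, solver_atol : float
        Integration tolerances used inside likelihood evaluations.
    """

    def __init__(
        self,
        data,
        events=None,
        scheme: SamplingScheme | None = None,
        error_model: str = "gaussian",
        solver_rtol: float = 1e-6,
        solver_atol: float = 1e-8,
    ):
        if isinstance(data, pd.DataFrame):
            data = ObservedDataset.from_frame(data)
        if not isinstance(data, ObservedDataset):
            raise TypeError("data must be an ObservedDataset or DataFrame")
        if error_model not in ("gaussian", "lognormal"):
            raise ValueError("error_model must be 'gaussian' or 'lognormal'")
        self.data = data
        self.events = list(events) if events is not None else default_events()
        self.scheme = scheme or default_scheme()
        self.error_model = error_model
        self.solver_rtol = solver_rtol
        self.solver_atol = solver_atol

    # -- constructors --------------------------------------------------------
    @classmethod
    def from_csv(cls, path, **kwargs) -> "HPAModel":
        from .io import read_observations

        return cls(read_observations(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "HPAModel":
        return cls(ObservedDataset.from_frame(df), **kwargs)

    # -- likelihood ----------------------------------------------------------
    def nll(self, params: HPAParameters, sigma: float | None = None) -> float:
        return neg_log_likelihood(
            params, self.data, events=self.events, error_model=self.error_model,
            sigma=sigma, rtol=self.solver_rtol, atol=self.solver_atol,
        )

    def loglike(self, params: HPAParameters, sigma: float | None = None) -> float:
        return -self.nll(params, sigma=sigma)

    def predict(self, params: HPAParameters, times=None) -> np.ndarray:
        times = self.data.times if times is None else np.asarray(times, dtype=float)
        return gc_at(params, times, events=self.events,
                     rtol=self.solver_rtol, atol=self.solver_atol)

    def default_mask(self, free=("b", "k_O", "b_O", "G_tot")) -> ParameterMask:
        """A parsimonious mask with data-driven starting values.

        Four timepoint classes cannot identify the full rate set; the
        default frees the stressor intensity, GC production/clearance and
        total GR, starting from :func:`visual_start`.
        """
        return ParameterMask(free=free, start=visual_start(self.data))

    # -- fitting ---------------------------------------------------------------
    def fit(
        self,
        mask: ParameterMask | None = None,
        maxiter: int = 5000,
        tol: float = 1e-5,
        n_starts: int = 1,
        jitter: float = 0.3,
        seed: int | None = None,
    ) -> "HPAResults":
        """Maximize the log-likelihood by Nelder-Mead simplex search.

        Free parameters are optimized in log (or bounded-logistic) space.
        ``n_starts > 1`` adds seeded multi-start: additional starting
        points jitter the transformed start by Gaussian noise of scale
        ``jitter``; the best converged start wins.  Fixing ``seed`` makes
        the whole procedure bit-reproducible.
        """
        if mask is None:
            mask = self.default_mask()
        if len(mask.free) >= len(self.data):
            warnings.warn(
                f"{len(mask.free)} free parameters for {len(self.data)} observations: "
                "the fit is likely unidentifiable"
            )

        def objective(x):
            return self.nll(mask.to_params(x))

        x0 = mask.to_opt(mask.start)
        rng = np.random.default_rng(seed)
        starts = [x0]
        for _ in range(n_starts - 1):
            starts.append(x0 + jitter * rng.standard_normal(x0.size))

        results = []
        for x_start in starts:
            res = minimize(
                objective, x_start, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": tol, "fatol": tol, "adaptive": len(x0) > 4},
            )
            results.append(res)
        ok = [r for r in results if np.isfinite(r.fun)]
        if not ok:
            raise RuntimeError(
                "all optimization starts failed; per-start diagnostics: "
                + "; ".join(f"status={r.status} message={r.message!r}" for r in results)
            )
        best = min(ok, key=lambda r: r.fun)
        params = mask.to_params(best.x)
        fitted = self.predict(params)
        obs = self.data.values
        if self.error_model == "lognormal":
            resid = np.log(np.maximum(obs, 1e-12)) - np.log(np.maximum(fitted, 1e-12))
        else:
            resid = obs - fitted
        sigma = float(np.sqrt(max(resid @ resid / resid.size, _MIN_SIGMA2)))
        return HPAResults(
            model=self,
            params=params,
            mask=mask,
            llf=-float(best.fun),
            sigma=sigma,
            converged=bool(best.success),
            nit=int(best.nit),
            nfev=int(best.nfev),
            n_starts=len(starts),
            fittedvalues=fitted,
            resid=resid,
            message=str(best.message),
        )

    def fit_individual_gr(
        self,
        shared: HPAParameters | None = None,
        maxiter: int = 1000,
        tol: float = 1e-5,
    ) -> pd.DataFrame:
        """Per-individual GR abundance with all shared kinetics fixed.

        Fits only ``G_tot`` to each individual's profile, the analysis that
        infers receptor abundance from observed GC profiles when receptors
        cannot be measured directly.  Returns one row per individual with
        the estimate and fit diagnostics.
        """
        shared = (shared or HPAParameters()).validate()
        rows = []
        for ind in self.data.individuals:
            sub = HPAModel(
                self.data.for_individual(ind), events=self.events, scheme=self.scheme,
                error_model=self.error_model, solver_rtol=self.solver_rtol,
                solver_atol=self.solver_atol,
            )
            res = sub.fit(mask=ParameterMask.gr_only(start=shared), maxiter=maxiter, tol=tol)
            rows.append({
                "individual_id": ind,
                "G_tot": res.params.G_tot,
                "llf": res.llf,
                "sigma": res.sigma,
                "converged": res.converged,
                "n_obs": len(sub.data),
            })
        return pd.DataFrame(rows)


@dataclass
class HPAResults:
    """Estimates and diagnostics from :meth:`HPAModel.fit`."""

    model: HPAModel
    params: HPAParameters
    mask: ParameterMask
    llf: float
    sigma: float
    converged: bool
    nit: int
    nfev: int
    n_starts: int
    fittedvalues: np.ndarray
    resid: np.ndarray
    message: str = ""

    @property
    def n_obs(self) -> int:
        return len(self.model.data)

    @property
    def k_free(self) -> int:
        return len(self.mask.free)

    @property
    def rss(self) -> float:
        return float(self.resid @ self.resid)

    @property
    def aic(self) -> float:
        # free structural parameters plus the profiled residual SD
        return 2.0 * (self.k_free + 1) - 2.0 * self.llf

    @property
    def bic(self) -> float:
        return (self.k_free + 1) * np.log(self.n_obs) - 2.0 * self.llf

    def fittedvalues_frame(self) -> pd.DataFrame:
        df = self.model.data.frame[["individual_id", "sampling_class", "time_min", "gc_value"]].copy()
        df["fitted"] = self.fittedvalues
        df["resid"] = self.resid
        return df

    def simulate(self, horizon: float = 180.0, events=None, **kwargs):
        """Trajectory of the fitted model under the fitting protocol."""
        from .simulate import simulate_response

        return simulate_response(
            self.params,
            events=self.model.events if events is None else events,
            horizon=horizon, **kwargs,
        )

    # prediction analyses hang off the fitted parameters
    def sweep_gr(self, **kwargs):
        from .predict import sweep_gr

        kwargs.setdefault("events", self.model.events)
        return sweep_gr(self.params, **kwargs)

    def sweep_stressor(self, **kwargs):
        from .predict import sweep_stressor

        return sweep_stressor(self.params, **kwargs)

    def association(self, **kwargs):
        from .predict import association_analysis

        return association_analysis(self.params, **kwargs)

    def summary(self) -> str:
        lines = [
            "HPA-axis model fit (Nelder-Mead maximum likelihood)",
            "=" * 55,
            f"observations:        {self.n_obs}",
            f"individuals:         {len(self.model.data.individuals)}",
            f"error model:         {self.model.error_model}",
            f"free parameters:     {self.k_free} ({', '.join(self.mask.free)})",
            f"log-likelihood:      {self.llf:.4f}",
            f"residual SD (MLE):   {self.sigma:.4f}",
            f"AIC / BIC:           {self.aic:.2f} / {self.bic:.2f}",
            f"converged:           {self.converged} ({self.nit} iterations, "
            f"{self.nfev} evaluations, {self.n_starts} start(s))",
            "-" * 55,
            f"{'parameter':<12}{'estimate':>14}  {'status':<8}",
        ]
        for name in FITTABLE:
            v = getattr(self.params, name)
            status = "free" if name in self.mask.free else "fixed"
            lines.append(f"{name:<12}{v:>14.6g}  {status:<8}")
        lines.append("-" * 55)
        lines.append(f"derived: K_G = {self.params.K_G:.4g}, K_M = {self.params.K_M:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "free": list(self.mask.free),
            "llf": self.llf,
            "sigma": self.sigma,
            "rss": self.rss,
            "converged": self.converged,
            "nit": self.nit,
            "nfev": self.nfev,
            "n_starts": self.n_starts,
            "n_obs": self.n_obs,
            "error_model": self.model.error_model,
            "message": self.message,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
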