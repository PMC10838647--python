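"""Synthetic GC-profile populations for testing fitting and prediction.

The generator emulates the structure of standardized avian stress-series
datasets: a population of individuals varying in total GR abundance
(log-normal, right-skewed like expression data), each sampled once per
sampling class at a time jittered within the class's protocol window
(baseline 0-3 min, stress-induced 20-30 min, post-DEX 60-80 min, post-ACTH
100 min), with multiplicative measurement noise.  A noisy ``gr_expression``
covariate (a proxy of true G_tot with its own error) is emitted so that
observed-vs-predicted comparisons face realistic attenuation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ObservedDataset
from .params import HPAParameters
from .simulate import SamplingScheme, default_events, default_scheme, gc_at

__all__ = [
    "PopulationSpec",
    "generate_population",
    "make_fixture_profiles",
    "load_fixture_profiles",
    "FIXTURE_SEED",
    "FIXTURE_N",
]

logger = logging.getLogger(__name__)

FIXTURE_SEED = 1234
FIXTURE_N = 12


@dataclass
class PopulationSpec:
    """Distributional description of a simulated population.

    ``gtot_median``/``gtot_cv`` parameterize the log-normal distribution of
    total GR abundance (median ``None`` means "use the base parameters'
    G_tot"); ``b_cv`` optionally adds among-individual variation in
    stressor sensitivity.  ``noise_cv`` is the coefficient of variation of
    the measurement error (log-normal by default, mean-one multiplicative;
    ``"gaussian"`` gives additive error proportional to the true value).
    ``gr_expr_cv`` controls how noisy the emitted GR-expression covariate
    is as a proxy of true G_tot.
    """

    n: int = 30
    gtot_median: float | None = None
    gtot_cv: float = 0.5
    b_median: float | None = None
    b_cv: float = 0.0
    noise_model: str = "lognormal"
    noise_cv: float = 0.10
    gr_expr_cv: float = 0.20
    scheme: SamplingScheme = field(default_factory=default_scheme)
    events: list = field(default_factory=default_events)
    seed: int | None = None

    def validate(self) -> "PopulationSpec":
        if self.n < 1:
            raise ValueError("population size n must be >= 1")
        for name in ("gtot_cv", "b_cv", "noise_cv", "gr_expr_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("gtot_median", "b_median"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_model not in ("lognormal", "gaussian"):
            raise ValueError("noise_model must be 'lognormal' or 'gaussian'")
        return self


def _lognormal_factor(cv: float, z) -> np.ndarray:
    """Mean-one multiplicative log-normal factor with the given CV."""
    if cv == 0:
        return np.ones_like(np.asarray(z, dtype=float))
    s2 = np.log1p(cv**2)
    return np.exp(np.sqrt(s2) * np.asarray(z) - s2 / 2.0)


def _median_lognormal(median: float, cv: float, z) -> np.ndarray:
    """Log-normal draw parameterized by its median and CV."""
    if cv == 0:
        return np.full(np.shape(z), median, dtype=float)
    sigma = np.sqrt(np.log1p(cv**2))
    return median * np.exp(sigma * np.asarray(z))


def generate_population(
    spec: PopulationSpec,
    base_params: HPAParameters | None = None,
) -> tuple[ObservedDataset, pd.DataFrame]:
    """Simulate a population and sample it like a field study.

    Per individual: draw G_tot (and optionally b), draw one sampling time
    per class uniformly within the class window, evaluate the model's free
    plasma GC at those times under the injection protocol, apply
    measurement noise, and emit the noisy GR-expression covariate.

    Returns the observations plus a truth table (one row per individual
    with the generating parameter values) for parameter-recovery tests.
    Individuals whose simulation fails are skipped with a logged warning;
    the count is available as ``dataset.frame.attrs["n_failed"]``.
    """
    spec.validate()
    base = (base_params or HPAParameters()).validate()
    rng = np.random.default_rng(spec.seed)
    gtot_median = spec.gtot_median if spec.gtot_median is not None else base.G_tot
    b_median = spec.b_median if spec.b_median is not None else base.b
    labels = spec.scheme.labels

    # all randomness drawn up front in a fixed order => seeded reproducibility
    z_gtot = rng.standard_normal(spec.n)
    z_b = rng.standard_normal(spec.n)
    u_times = rng.uniform(size=(spec.n, len(labels)))
    z_noise = rng.standard_normal((spec.n, len(labels)))
    z_expr = rng.standard_normal(spec.n)

    gtot = _median_lognormal(gtot_median, spec.gtot_cv, z_gtot)
    b_vals = _median_lognormal(b_median, spec.b_cv, z_b)
    gr_expr = gtot * _lognormal_factor(spec.gr_expr_cv, z_expr)

    obs_rows = []
    truth_rows = []
    n_failed = 0
    for i in range(spec.n):
        p = base.replace(G_tot=float(gtot[i]), b=float(b_vals[i]))
        times = np.empty(len(labels))
        for j, lab in enumerate(labels):
            lo, hi = spec.scheme.windows.get(lab, (spec.scheme.times[lab],) * 2)
            times[j] = lo + (hi - lo) * u_times[i, j]
        try:
            gc_true = gc_at(p, times, events=spec.events, rtol=1e-8, atol=1e-10)
        except Exception as exc:  # noqa: BLE001 - robustness of the generator
            logger.warning("simulation failed for individual %d (G_tot=%.3g): %s",
                           i, gtot[i], exc)
            n_failed += 1
            continue
        if spec.noise_model == "lognormal":
            gc_obs = gc_true * _lognormal_factor(spec.noise_cv, z_noise[i])
        else:
            gc_obs = np.maximum(gc_true * (1.0 + spec.noise_cv * z_noise[i]), 0.0)
        for j, lab in enumerate(labels):
            obs_rows.append({
                "individual_id": f"ind{i:03d}",
                "sampling_class": lab,
                "time_min": float(times[j]),
                "gc_value": float(gc_obs[j]),
                "gr_expression": float(gr_expr[i]),
            })
        truth_rows.append({
            "individual_id": f"ind{i:03d}",
            "G_tot": float(gtot[i]),
            "b": float(b_vals[i]),
            "gr_expression": float(gr_expr[i]),
            **{f"gc_true_{lab}": float(gc_true[j]) for j, lab in enumerate(labels)},
        })
    if not obs_rows:
        raise RuntimeError(f"all {spec.n} individuals failed to simulate")
    if n_failed:
        logger.warning("%d of %d individuals skipped due to simulation failure",
                       n_failed, spec.n)
    dataset = ObservedDataset.from_frame(pd.DataFrame(obs_rows))
    dataset.frame.attrs["n_failed"] = n_failed
    return dataset, pd.DataFrame(truth_rows)


def fixture_spec() -> PopulationSpec:
    """The population specification behind the packaged example dataset."""
    return PopulationSpec(n=FIXTURE_N, gtot_cv=0.5, noise_cv=0.10, seed=FIXTURE_SEED)


def make_fixture_profiles() -> tuple[ObservedDataset, pd.DataFrame]:
    """Regenerate the packaged 12-individual example dataset (deterministic)."""
    return generate_population(fixture_spec())


def _fixture_path(name: str = "fixture_profiles.csv"):
    from importlib.resources import files

    return files("hpaxis").joinpath("data", name)


def load_fixture_profiles() -> ObservedDataset:
    """The packaged example dataset (12 individuals x 4 sampling classes)."""
    import io as _io

    text = _fixture_path().read_text()
    return ObservedDataset.from_frame(pd.read_csv(_io.StringIO(text)))


def load_fixture_truth() -> pd.DataFrame:
    import io as _io

    text = _fixture_path("fixture_truth.csv").read_text()
    return pd.read_csv(_io.StringIO(text))
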