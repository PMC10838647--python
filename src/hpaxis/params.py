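"""Parameter and state containers for the dynamic HPA-axis model.

The model tracks the hormonal cascade CRH -> ACTH -> glucocorticoid (GC)
driven by a decaying stressor stimulus, with negative feedback exerted by
GC-receptor complexes (GC-GR and GC-MR) formed by mass-action binding in
hypothalamic/pituitary tissue.  All times are in minutes; hormone and
receptor amounts are in arbitrary concentration units (plasma GC is
conventionally read as ng/ml).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "HPAParameters",
    "SystemState",
    "STATE_FIELDS",
    "default_params",
]

#: Canonical ordering of the state vector used by the integrators.
STATE_FIELDS = ("C", "A", "O", "O_G", "O_M", "G", "M", "D", "D_G")


@dataclass
class HPAParameters:
    """Rate constants, receptor totals and stimulus parameters.

    Parameters
    ----------
    B : float
        Baseline stimulus level: the constant minimum energy demand that
        sustains basal HPA-axis activity (demand units).
    b : float
        Stressor intensity; scales the acute component of the stimulus
        (demand units, time-integrated contribution of the stressor).
    alpha : float
        Stressor decay rate (1/min); the acute stimulus is ``b*alpha*exp(-alpha*t)``.
    b_C, b_A, b_O : float
        First-order degradation rates of CRH, ACTH and GC (1/min).
    k_A : float
        ACTH production rate per unit CRH (1/min).
    k_O : float
        GC production rate per unit ACTH (1/min).
    k_fb : float
        Negative-feedback strength applied per unit of receptor occupancy,
        used identically for GR and MR at hypothalamus and pituitary
        (k_CG = k_CM = k_AG = k_AM).  Individual terms may be overridden.
    k_G, k_mG : float
        GR binding and release rate constants (1/(conc*min); 1/min).
    k_M, k_mM : float
        MR binding and release rate constants.
    G_tot, M_tot : float
        Total GR and MR abundance in HPA tissue (concentration units).
    b_D : float or None
        Clearance rate of the exogenous GR ligand (dexamethasone), 1/min.
        DEX persists far longer than endogenous GC — that persistence is
        what makes it usable as a negative-feedback probe — so the default
        is much slower than ``b_O``; ``None`` means "clear like GC".
    k_CG, k_CM, k_AG, k_AM : float or None
        Per-term feedback overrides; ``None`` means "use ``k_fb``".
    """

    B: float = 0.35
    b: float = 5.0
    alpha: float = 0.08
    b_C: float = 0.2
    b_A: float = 0.15
    b_O: float = 0.09
    k_A: float = 0.6
    k_O: float = 1.0
    k_fb: float = 0.1
    k_G: float = 0.02
    k_mG: float = 0.6
    k_M: float = 0.1
    k_mM: float = 0.15
    G_tot: float = 6.0
    M_tot: float = 2.0
    b_D: float | None = 0.02
    k_CG: float | None = field(default=None, repr=False)
    k_CM: float | None = field(default=None, repr=False)
    k_AG: float | None = field(default=None, repr=False)
    k_AM: float | None = field(default=None, repr=False)

    # -- derived quantities -------------------------------------------------
    @property
    def K_G(self) -> float:
        """GR Michaelis constant k_mG / k_G (ligand level at half occupancy)."""
        return self.k_mG / self.k_G

    @property
    def K_M(self) -> float:
        """MR Michaelis constant k_mM / k_M."""
        return self.k_mM / self.k_M

    @property
    def dex_clearance(self) -> float:
        """Resolved DEX clearance rate (``b_D``, or ``b_O`` if unset)."""
        return self.b_O if self.b_D is None else self.b_D

    @property
    def fb(self) -> tuple[float, float, float, float]:
        """Resolved feedback constants (k_CG, k_CM, k_AG, k_AM)."""
        d = self.k_fb
        return (
            d if self.k_CG is None else self.k_CG,
            d if self.k_CM is None else self.k_CM,
            d if self.k_AG is None else self.k_AG,
            d if self.k_AM is None else self.k_AM,
        )

    # -- validation ---------------------------------------------------------
    def validate(self) -> "HPAParameters":
        """Check invariants; raise ``ValueError`` on violation.

        Emits a warning (not an error) when K_M >= K_G, because MR is
        physiologically the higher-affinity receptor (smaller Michaelis
        constant) and a reversed affinity ordering usually indicates a
        mis-specified parameter set.
        """
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not np.isfinite(v):
                raise ValueError(f"parameter {f.name} is not finite: {v!r}")
            if v < 0:
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.k_G <= 0 or self.k_M <= 0:
            raise ValueError("binding rates k_G and k_M must be > 0")
        if not (np.isfinite(self.K_G) and self.K_G > 0):
            raise ValueError("K_G = k_mG/k_G must be finite and > 0")
        if not (np.isfinite(self.K_M) and self.K_M > 0):
            raise ValueError("K_M = k_mM/k_M must be finite and > 0")
        if self.K_M >= self.K_G:
            warnings.warn(
                f"K_M ({self.K_M:.4g}) >= K_G ({self.K_G:.4g}): MR is expected "
                "to have higher GC affinity (smaller Michaelis constant) than GR",
                UserWarning,
                stacklevel=2,
            )
        return self

    # -- conversion helpers -------------------------------------------------
    def replace(self, **kwargs) -> "HPAParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        return {k: v for k, v in d.items() if v is not None}

    @classmethod
    def from_dict(cls, d: dict) -> "HPAParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter names: {sorted(unknown)}")
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "HPAParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_params(**overrides) -> HPAParameters:
    """The package's reference parameter set, optionally modified.

    The defaults produce a songbird-like corticosterone stress series:
    baseline near 5 ng/ml, a stress-induced rise peaking within ~20 min,
    suppression toward baseline after a dexamethasone bolus, and a strong
    renewed rise after an ACTH bolus at minute 80 (the maximal-production
    probe).  MR is the high-affinity receptor (K_M = 1.5 << K_G = 30), so
    MR occupancy is nearly saturated at baseline while GR is recruited
    mainly during the acute response.
    """
    return HPAParameters(**overrides).validate()


@dataclass
class SystemState:
    """Instantaneous concentrations of the nine model species.

    ``D`` and ``D_G`` carry an exogenous GR ligand (dexamethasone) and its
    receptor complex; both are zero unless a DEX bolus is simulated.
    """

    C: float = 0.0       # CRH
    A: float = 0.0       # ACTH
    O: float = 0.0       # free plasma glucocorticoid
    O_G: float = 0.0     # GC-GR complex
    O_M: float = 0.0     # GC-MR complex
    G: float = 0.0       # free GR
    M: float = 0.0       # free MR
    D: float = 0.0       # free dexamethasone
    D_G: float = 0.0     # DEX-GR complex

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, y) -> "SystemState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_FIELDS),):
            raise ValueError(f"state vector must have shape ({len(STATE_FIELDS)},)")
        return cls(**dict(zip(STATE_FIELDS, y)))

    def validate(self, params: HPAParameters | None = None, rtol: float = 1e-6) -> "SystemState":
        y = self.as_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("state contains non-finite components")
        if np.any(y < 0):
            raise ValueError("state components must be >= 0")
        if params is not None:
            scale_G = max(params.G_tot, 1e-30)
            if abs(self.G + self.O_G + self.D_G - params.G_tot) > rtol * scale_G:
                raise ValueError("GR conservation violated: G + O_G + D_G != G_tot")
            scale_M = max(params.M_tot, 1e-30)
            if abs(self.M + self.O_M - params.M_tot) > rtol * scale_M:
                raise ValueError("MR conservation violated: M + O_M != M_tot")
        return self
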