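"""Pure mathematical core of the HPA-axis model.

Three objects are exposed:

* :func:`stimulus` — the axis input, a constant basal demand plus an
  exponentially decaying acute stressor;
* :func:`hpa_rhs` — the full nine-species ODE right-hand side (hormonal
  cascade, negative feedback, mass-action receptor binding);
* :func:`equilibrium_binding` — the closed-form receptor occupancy at
  chemical equilibrium (the saturation curve ``R_tot * O / (O + K)``), used
  both as a steady-state consistency oracle for the kinetic equations and as
  the definition of the GC-mediated physiological-response readout.

All functions are side-effect-free.
"""

from __future__ import annotations

import numbers

import numpy as np

from .params import HPAParameters, STATE_FIELDS, SystemState

__all__ = ["stimulus", "equilibrium_binding", "hpa_rhs", "binding_rhs"]

# state-vector indices, in STATE_FIELDS order
_C, _A, _O, _OG, _OM, _G, _M, _D, _DG = range(9)

#: width of the transition band over which negative derivatives of the
#: non-conserved species fade to zero (keeps the RHS Lipschitz)
_CLAMP_BAND = 1e-4
_CLAMPED = (_C, _A, _O, _D)


def stimulus(t, params: HPAParameters):
    """HPA-axis input p(t) = B + b * alpha * exp(-alpha * t).

    ``B`` is the constant basal energetic demand; the acute stressor decays
    exponentially at rate ``alpha`` and integrates to ``b`` over [0, inf),
    so ``b`` is the total extra demand imposed by the stressor.

    Parameters
    ----------
    t : float or array_like
        Time since stressor onset, minutes.  Must be >= 0.

    Returns
    -------
    float or ndarray
        Demand level, same shape as ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("stimulus time t must be >= 0")
    out = params.B + params.b * params.alpha * np.exp(-params.alpha * t_arr)
    if isinstance(t, numbers.Number):
        return float(out)
    return out


def equilibrium_binding(O, R_tot, K):
    """Equilibrium ligand-receptor complex concentration.

    At chemical equilibrium the bound fraction follows the saturation
    (Michaelis) curve: ``bound = R_tot * O / (O + K)``, with ``K`` the ratio
    of release to binding rate constants — the ligand concentration at
    half-maximal occupancy.

    Parameters
    ----------
    O : float or array_like
        Free ligand (GC) concentration, >= 0.
    R_tot : float or array_like
        Total receptor abundance, >= 0.
    K : float
        Michaelis constant, > 0.

    Returns
    -------
    Bound complex concentration in [0, R_tot], monotone increasing in O.
    """
    O_arr = np.asarray(O, dtype=float)
    R_arr = np.asarray(R_tot, dtype=float)
    if np.any(O_arr < 0):
        raise ValueError("ligand concentration O must be >= 0")
    if np.any(R_arr < 0):
        raise ValueError("receptor total R_tot must be >= 0")
    if not (np.isscalar(K) or np.ndim(K) == 0) or not K > 0:
        raise ValueError("Michaelis constant K must be a scalar > 0")
    out = R_arr * O_arr / (O_arr + K)
    if isinstance(O, numbers.Number) and isinstance(R_tot, numbers.Number):
        return float(out)
    return out


def _rhs(t: float, y, params: HPAParameters, clamp: bool = True):
    """Nine-component derivative on a raw state array (solver hot path)."""
    C, A, O, OG, OM, G, M, D, DG = y
    p = params.B + params.b * params.alpha * np.exp(-params.alpha * t)
    k_CG, k_CM, k_AG, k_AM = params.fb

    # mass-action binding fluxes
    bind_G = params.k_G * O * G          # O + G  -> O_G
    rel_G = params.k_mG * OG             # O_G    -> O + G
    bind_M = params.k_M * O * M
    rel_M = params.k_mM * OM
    bind_D = params.k_G * D * G          # DEX binds GR with GC kinetics
    rel_D = params.k_mG * DG

    # feedback is driven by total GR occupancy (GC- plus DEX-bound) and MR
    # occupancy in hypothalamus (C equation) and pituitary (A equation)
    occ_G = OG + DG
    dC = p - params.b_C * C - k_CG * occ_G - k_CM * OM
    dA = params.k_A * C - params.b_A * A - k_AG * occ_G - k_AM * OM
    dO = params.k_O * A - params.b_O * O + rel_M + rel_G - bind_M - bind_G
    dOG = bind_G - rel_G
    dOM = bind_M - rel_M
    dDG = bind_D - rel_D
    # free-receptor derivatives as negated complex sums: receptor
    # conservation is then exact in floating point, not just analytically
    dG = -(dOG + dDG)
    dM = -dOM
    dD = rel_D - bind_D - params.dex_clearance * D

    dy = np.array([dC, dA, dO, dOG, dOM, dG, dM, dD, dDG])
    if clamp:
        # Concentrations are physical: a species at (or below) zero is not
        # allowed to be pushed further negative by feedback.  A hard
        # derivative cutoff at zero makes the RHS discontinuous and stalls
        # adaptive solvers in a sliding mode, so negative derivatives are
        # instead faded out linearly across the thin band [0, _CLAMP_BAND];
        # above the band the equations are untouched.  Only the non-conserved species
        # (C, A, O, D) are treated — free receptors and complexes are
        # structurally non-negative under mass action, and leaving them
        # alone keeps the receptor conservation sums exactly zero.
        y_arr = np.asarray(y, dtype=float)
        for i in _CLAMPED:
            if dy[i] < 0.0 and y_arr[i] < _CLAMP_BAND:
                dy[i] *= min(max(y_arr[i], 0.0) / _CLAMP_BAND, 1.0)
    return dy


def hpa_rhs(t: float, state, params: HPAParameters, clamp: bool = True):
    """Time derivative of the full HPA-axis state.

    Implements the hormonal cascade with negative feedback:

    * dC/dt = p(t) − b_C·C − k_CG·(O_G + D_G) − k_CM·O_M
    * dA/dt = k_A·C − b_A·A − k_AG·(O_G + D_G) − k_AM·O_M
    * dO/dt = k_O·A − b_O·O + k_mM·O_M + k_mG·O_G − k_M·O·M − k_G·O·G

    plus the mass-action binding kinetics of the GC-GR, GC-MR and DEX-GR
    complexes.  Receptor conservation is exact by construction:
    d(G + O_G + D_G)/dt = 0 and d(M + O_M)/dt = 0.

    Parameters
    ----------
    state : SystemState or array_like of length 9
        Current concentrations, in :data:`~hpaxis.params.STATE_FIELDS` order.
    clamp : bool
        When True (default), a component at <= 0 with a negative raw
        derivative gets derivative 0, keeping concentrations physical.

    Returns
    -------
    Same type as ``state`` (SystemState in, SystemState out).
    """
    as_state = isinstance(state, SystemState)
    y = state.as_array() if as_state else np.asarray(state, dtype=float)
    if y.shape != (len(STATE_FIELDS),):
        raise ValueError(f"state must have {len(STATE_FIELDS)} components")
    if not np.all(np.isfinite(y)):
        raise ValueError("state contains non-finite components")
    dy = _rhs(float(t), y, params, clamp=clamp)
    return SystemState.from_array(dy) if as_state else dy


def params_to_array(params: HPAParameters) -> np.ndarray:
    """Flatten the rate constants into the vector used by the compiled RHS."""
    return np.array([
        params.B, params.b, params.alpha, params.b_C, params.b_A, params.b_O,
        params.k_A, params.k_O, *params.fb,
        params.k_G, params.k_mG, params.k_M, params.k_mM, params.dex_clearance,
    ])


def _rhs_flat(t, y, c):
    """RHS on a flat constant vector (pure-Python fallback for the JIT path)."""
    C, A, O, OG, OM, G, M, D, DG = y
    pstim = c[0] + c[1] * c[2] * np.exp(-c[2] * t)
    bind_G = c[12] * O * G
    rel_G = c[13] * OG
    bind_M = c[14] * O * M
    rel_M = c[15] * OM
    bind_D = c[12] * D * G
    rel_D = c[13] * DG
    occ = OG + DG
    dC = pstim - c[3] * C - c[8] * occ - c[9] * OM
    dA = c[6] * C - c[4] * A - c[10] * occ - c[11] * OM
    dO = c[7] * A - c[5] * O + rel_M + rel_G - bind_M - bind_G
    dD = rel_D - bind_D - c[16] * D
    band = _CLAMP_BAND
    if dC < 0.0 and C < band:
        dC *= C / band if C > 0.0 else 0.0
    if dA < 0.0 and A < band:
        dA *= A / band if A > 0.0 else 0.0
    if dO < 0.0 and O < band:
        dO *= O / band if O > 0.0 else 0.0
    if dD < 0.0 and D < band:
        dD *= D / band if D > 0.0 else 0.0
    dOG = bind_G - rel_G
    dOM = bind_M - rel_M
    dDG = bind_D - rel_D
    out = np.empty(9)
    out[0] = dC
    out[1] = dA
    out[2] = dO
    out[3] = dOG
    out[4] = dOM
    out[5] = -(dOG + dDG)  # exact receptor conservation
    out[6] = -dOM
    out[7] = dD
    out[8] = dDG
    return out


try:  # optional JIT of the solver hot path; semantics identical to _rhs_flat
    from numba import njit as _njit

    _rhs_fast = _njit(cache=True)(_rhs_flat)
except Exception:  # pragma: no cover - numba is normally available
    _rhs_fast = _rhs_flat


def binding_rhs(t: float, y, O_free: float, params: HPAParameters):
    """Receptor-binding kinetics at a held (chemostatted) free-GC level.

    The reduced subsystem ``y = [O_G, G, O_M, M]`` evolves under mass action
    while free GC is held at ``O_free``.  Its unique stationary point is the
    equilibrium saturation curve, which makes this the natural vehicle for
    checking the kinetic equations against :func:`equilibrium_binding`.
    """
    OG, G, OM, M = y
    bind_G = params.k_G * O_free * G
    rel_G = params.k_mG * OG
    bind_M = params.k_M * O_free * M
    rel_M = params.k_mM * OM
    return np.array([bind_G - rel_G, rel_G - bind_G, bind_M - rel_M, rel_M - bind_M])
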