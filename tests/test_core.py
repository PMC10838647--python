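"""Unit and property tests of the model's mathematical core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq

from hpaxis import HPAParameters, SystemState, equilibrium_binding, hpa_rhs, stimulus
from hpaxis.core import _rhs, _rhs_fast, params_to_array
from hpaxis.params import STATE_FIELDS

positive = st.floats(min_value=1e-3, max_value=1e3)


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------
class TestStimulus:
    def test_onset_value(self):
        p = HPAParameters(B=1.0, b=10.0, alpha=0.1)
        assert stimulus(0.0, p) == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("t", [0.0, 1.0, 50.0, 1e4])
    def test_no_stressor_gives_baseline(self, t):
        p = HPAParameters(b=0.0)
        assert stimulus(t, p) == p.B

    def test_stressor_component_integrates_to_b(self):
        p = HPAParameters(B=0.0, b=7.3, alpha=0.11)
        total, _ = quad(lambda t: stimulus(t, p), 0, np.inf)
        assert total == pytest.approx(7.3, rel=1e-8)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            stimulus(-0.1, HPAParameters())

    @settings(max_examples=50, deadline=None)
    @given(b=st.floats(min_value=0.1, max_value=1e3),
           alpha=st.floats(min_value=1e-3, max_value=0.1),
           t1=st.floats(min_value=0, max_value=50),
           dt=st.floats(min_value=0.1, max_value=50))
    def test_strictly_decreasing_with_stressor(self, b, alpha, t1, dt):
        # parameter ranges keep the stressor term well above float underflow
        p = HPAParameters(b=b, alpha=alpha)
        assert stimulus(t1 + dt, p) < stimulus(t1, p)

    def test_vectorized(self):
        p = HPAParameters()
        t = np.array([0.0, 10.0, 100.0])
        out = stimulus(t, p)
        assert out.shape == (3,)
        assert np.all(np.diff(out) < 0)


# ---------------------------------------------------------------------------
# equilibrium occupancy
# ---------------------------------------------------------------------------
class TestEquilibriumBinding:
    def test_anchor_points(self):
        assert equilibrium_binding(0.0, 5.0, 1.0) == 0.0
        # half-saturation exactly at O = K
        assert equilibrium_binding(1.0, 5.0, 1.0) == pytest.approx(2.5, abs=1e-12)
        assert equilibrium_binding(1e6, 5.0, 1.0) == pytest.approx(5.0, abs=1e-5)

    @pytest.mark.parametrize("bad_K", [0.0, -1.0])
    def test_nonpositive_K_rejected(self, bad_K):
        with pytest.raises(ValueError):
            equilibrium_binding(1.0, 5.0, bad_K)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_binding(-1.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            equilibrium_binding(1.0, -5.0, 1.0)

    @settings(max_examples=50, deadline=None)
    @given(O=st.floats(min_value=0, max_value=1e6), R=positive, K=positive)
    def test_bounded_and_monotone(self, O, R, K):
        v = equilibrium_binding(O, R, K)
        assert 0.0 <= v <= R
        assert equilibrium_binding(O + 1.0, R, K) >= v


# ---------------------------------------------------------------------------
# full right-hand side
# ---------------------------------------------------------------------------
def _random_state(rng, params):
    """A strictly positive state respecting receptor conservation."""
    fG = rng.uniform(0.05, 0.9)
    fD = rng.uniform(0.05, 0.9) * (1 - fG)
    fM = rng.uniform(0.05, 0.95)
    return SystemState(
        C=rng.uniform(0.1, 20), A=rng.uniform(0.1, 20), O=rng.uniform(0.1, 100),
        O_G=fG * params.G_tot, D_G=fD * params.G_tot,
        G=(1 - fG - fD) * params.G_tot,
        O_M=fM * params.M_tot, M=(1 - fM) * params.M_tot,
        D=rng.uniform(0, 30),
    )


def _transcribed_rhs(state, t, p):
    """Independent term-by-term transcription of the cascade and binding
    equations (no DEX), kept deliberately separate from the implementation."""
    C, A, O, OG, OM, G, M = (state.C, state.A, state.O, state.O_G,
                             state.O_M, state.G, state.M)
    pt = p.B + p.b * p.alpha * np.exp(-p.alpha * t)
    k = p.k_fb
    dC = pt - p.b_C * C - k * OG - k * OM
    dA = p.k_A * C - p.b_A * A - k * OG - k * OM
    dO = (p.k_O * A - p.b_O * O + p.k_mM * OM + p.k_mG * OG
          - p.k_M * O * M - p.k_G * O * G)
    dOG = p.k_G * O * G - p.k_mG * OG
    dG = p.k_mG * OG - p.k_G * O * G
    dOM = p.k_M * O * M - p.k_mM * OM
    dM = p.k_mM * OM - p.k_M * O * M
    return np.array([dC, dA, dO, dOG, dOM, dG, dM, 0.0, 0.0])


class TestHpaRhs:
    def test_zero_state_only_crh_production(self, base_params):
        d = hpa_rhs(0.0, SystemState(), base_params)
        assert d.C == pytest.approx(stimulus(0.0, base_params), abs=1e-12)
        for name in STATE_FIELDS[1:]:
            assert getattr(d, name) == 0.0

    def test_receptor_conservation_exact(self, base_params, rng):
        for _ in range(200):
            s = _random_state(rng, base_params)
            d = hpa_rhs(rng.uniform(0, 120), s, base_params)
            assert (d.O_G + d.D_G) + d.G == 0.0
            assert d.O_M + d.M == 0.0

    def test_matches_independent_transcription(self, rng):
        """Randomized states/params against a separate symbolic transcription
        of the cascade + binding equations (DEX-free system)."""
        for _ in range(100):
            p = HPAParameters(
                B=rng.uniform(0.1, 2), b=rng.uniform(0, 20), alpha=rng.uniform(0.01, 0.5),
                b_C=rng.uniform(0.01, 1), b_A=rng.uniform(0.01, 1), b_O=rng.uniform(0.01, 1),
                k_A=rng.uniform(0.1, 2), k_O=rng.uniform(0.1, 2), k_fb=rng.uniform(0, 0.5),
                k_G=rng.uniform(0.001, 0.1), k_mG=rng.uniform(0.1, 2),
                k_M=rng.uniform(0.01, 1), k_mM=rng.uniform(0.01, 1),
                G_tot=rng.uniform(0.5, 20), M_tot=rng.uniform(0.5, 10),
            )
            s = _random_state(rng, p)
            s.D = 0.0
            s.D_G = 0.0
            s.G = p.G_tot - s.O_G  # restore conservation without DEX
            t = rng.uniform(0, 200)
            got = hpa_rhs(t, s, p).as_array()
            want = _transcribed_rhs(s, t, p)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-14)

    def test_fast_path_matches_reference(self, base_params, rng):
        """The compiled flat-vector RHS is the same function as the reference."""
        c = params_to_array(base_params)
        for _ in range(50):
            y = _random_state(rng, base_params).as_array()
            np.testing.assert_array_equal(_rhs_fast(1.7, y, c), _rhs(1.7, y, base_params))

    def test_feedback_decoupled_when_kfb_zero(self, rng):
        p = HPAParameters(k_fb=0.0)
        s = _random_state(rng, p)
        d = hpa_rhs(5.0, s, p)
        assert d.C == pytest.approx(stimulus(5.0, p) - p.b_C * s.C, rel=1e-12)

    def test_dex_occupancy_enters_feedback(self, base_params):
        s = SystemState(C=1.0, A=1.0, O=5.0, G=base_params.G_tot, M=base_params.M_tot)
        s_dex = SystemState(C=1.0, A=1.0, O=5.0, D_G=1.0, G=base_params.G_tot - 1.0,
                            M=base_params.M_tot)
        d0 = hpa_rhs(0.0, s, base_params)
        d1 = hpa_rhs(0.0, s_dex, base_params)
        assert d1.C < d0.C  # DEX-bound GR suppresses CRH production
        assert d1.A < d0.A

    def test_nonfinite_state_rejected(self, base_params):
        y = np.ones(9)
        y[3] = np.nan
        with pytest.raises(ValueError):
            hpa_rhs(0.0, y, base_params)

    def test_binding_stationarity_equals_closed_form(self, base_params):
        """Solving dO_G/dt = 0 at fixed free GC reproduces the saturation
        curve, root-found independently of the closed-form expression."""
        p = base_params
        for O in (2.0, 15.0, 80.0):
            f = lambda og: p.k_G * O * (p.G_tot - og) - p.k_mG * og  # noqa: E731
            og_root = brentq(f, 0.0, p.G_tot)
            assert og_root == pytest.approx(
                equilibrium_binding(O, p.G_tot, p.K_G), rel=1e-10)


# ---------------------------------------------------------------------------
# parameter container
# ---------------------------------------------------------------------------
class TestHPAParameters:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            HPAParameters(b_O=-0.1).validate()

    def test_zero_binding_rate_rejected(self):
        with pytest.raises(ValueError):
            HPAParameters(k_G=0.0).validate()

    def test_affinity_order_warning(self):
        # K_M >= K_G contradicts MR being the high-affinity receptor
        with pytest.warns(UserWarning, match="higher GC affinity"):
            HPAParameters(k_mM=100.0).validate()

    def test_feedback_overrides(self):
        p = HPAParameters(k_fb=0.1, k_CG=0.2)
        assert p.fb == (0.2, 0.1, 0.1, 0.1)

    def test_dict_roundtrip(self):
        p = HPAParameters(G_tot=7.7, k_CG=0.05)
        q = HPAParameters.from_dict(p.to_dict())
        assert q == p

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            HPAParameters.from_dict({"nope": 1.0})

    def test_state_validation(self, base_params):
        good = SystemState(G=base_params.G_tot, M=base_params.M_tot)
        good.validate(base_params)
        with pytest.raises(ValueError, match="conservation"):
            SystemState(G=1.0, M=base_params.M_tot).validate(base_params)
        with pytest.raises(ValueError):
            SystemState(C=-1.0).validate()
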