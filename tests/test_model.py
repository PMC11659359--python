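"""Model definitions: right-hand sides, nondimensionalization, sampling ranges."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import emtsens as es
from emtsens.model import DIMENSIONAL_NAMES, GAMMA_PARAMETER, NONDIM_NAMES, hill


def test_rhs_zero_state_bare_production(table_params):
    # with zero state and zero inputs every Hill term vanishes
    dE, dS = es.rhs_dimensional((0.0, 0.0), table_params, 0.0, 0.0)
    assert dE == pytest.approx(0.19355, abs=0)
    assert dS == pytest.approx(0.080, abs=0)


def test_rhs_vanishes_at_epithelial_steady_state(table_params):
    # the published 4-decimal epithelial state is a fixed point up to rounding
    dE, dS = es.rhs_dimensional((0.0522, 0.0034), table_params, 6.0, 0.0)
    assert abs(dE) < 1e-3 and abs(dS) < 1e-3


def test_half_maximal_identities(table_params):
    p = table_params
    assert hill(1.0, 4) == pytest.approx(0.5, abs=0)
    # E at its half-maximal constant: the suppression term contributes k1/2
    base = es.rhs_dimensional((p.IC_E, 0.0), p, 0.0, 0.0)[1]
    assert base == pytest.approx(p.alpha2 - p.k1 / 2 - p.beta2 * 0.0, rel=1e-12)
    # contact and TGF-beta at their half-maximal constants
    dE_half = es.rhs_dimensional((0.0, 0.0), p, p.IC_C, 0.0)[0]
    assert dE_half == pytest.approx(p.alpha1 + p.k0 / 2, rel=1e-12)
    nd = es.nondimensionalize(p, 7)
    dS_half = es.rhs_nondimensional((0.0, 0.0), nd, 0.0, 1.0)[1]
    assert dS_half == pytest.approx(nd.A2 + nd.K2 / 2, rel=1e-12)


def test_rhs_rejects_invalid_inputs(table_params):
    with pytest.raises(ValueError):
        es.rhs_dimensional((0.0, 0.0), table_params, -1.0, 0.0)
    with pytest.raises(ValueError):
        es.rhs_dimensional((0.0, 0.0), table_params, 0.0, -1e-9)
    with pytest.raises(ValueError):
        es.rhs_dimensional((np.nan, 0.0), table_params, 0.0, 0.0)


# published grouped-parameter rows (3-decimal rounding); the gamma grouping is 1.00
PUBLISHED_ROWS = {
    3: {"A1": 3.207, "K0": 2.063, "B1": 1.0, "A2": 0.690, "K1": 0.690, "K2": 0.345, "B2": 0.138},
    4: {"A1": 4.645, "K0": 2.988, "B1": 1.448, "A2": 1.0, "K1": 1.000, "K2": 0.500, "B2": 0.199},
    7: {"A1": 23.319, "K0": 15.000, "B1": 7.271, "A2": 5.020, "K1": 5.020, "K2": 2.510, "B2": 1.0},
}


@pytest.mark.parametrize("set_id", sorted(PUBLISHED_ROWS))
def test_nondimensionalize_matches_published_rows(table_params, set_id):
    nd = es.nondimensionalize(table_params, set_id)
    for name, expected in PUBLISHED_ROWS[set_id].items():
        assert round(getattr(nd, name), 3) == pytest.approx(expected, abs=1e-12), name


def test_gamma_grouping_is_exactly_unity(table_params):
    for set_id, fixed in GAMMA_PARAMETER.items():
        nd = es.nondimensionalize(table_params, set_id)
        assert getattr(nd, fixed) == 1.0


def test_set1_K0_published_value_is_inconsistent(table_params):
    # k0/alpha1 = 0.6432, not the published 0.646; the packaged range table
    # (built from 0.646) is flagged by the consistency check
    nd = es.nondimensionalize(table_params, 1)
    assert nd.K0 == pytest.approx(0.64324, abs=5e-5)
    issues = es.range_consistency()
    assert [(i.frame, i.name) for i in issues] == [("set1", "K0")]
    lo, hi = issues[0].regenerated
    assert lo == pytest.approx(0.9 * 0.6432, abs=2e-4)


def test_reciprocal_grouping_relations(table_params):
    # gamma choices that are ratios of the same two rates invert each other
    s1 = es.nondimensionalize(table_params, 1)
    s2 = es.nondimensionalize(table_params, 2)
    s3 = es.nondimensionalize(table_params, 3)
    assert s2.A1 == pytest.approx(1.0 / s1.K0, rel=1e-12)
    assert s3.K0 == pytest.approx(1.0 / s2.B1, rel=1e-12)


def test_build_ranges_published_examples(table_params):
    ranges = {r.name: r for r in es.build_ranges(table_params.values(), decimals=4)}
    assert (ranges["beta1"].lo, ranges["beta1"].hi) == (5.4315, 6.6385)
    nd = {k: round(v, 3) for k, v in es.nondimensionalize(table_params, 7).values().items()}
    r7 = {r.name: r for r in es.build_ranges(nd, fixed={"B2"}, decimals=4)}
    assert (r7["A1"].lo, r7["A1"].hi) == (20.9871, 25.6509)
    assert not r7["B2"].varied
    # shifted override keeps the 20% width and passes without warning
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        out = es.build_ranges({"alpha2": 0.080}, overrides={"alpha2": (0.0772, 0.0932)})
    assert out[0].width == pytest.approx(0.016, abs=1e-12)
    with pytest.warns(UserWarning, match="width"):
        es.build_ranges({"alpha2": 0.080}, overrides={"alpha2": (0.05, 0.09)})


def test_build_ranges_midpoint_recovery(table_params):
    for r in es.build_ranges(table_params.values(), decimals=None):
        assert r.center == pytest.approx(getattr(table_params, r.name), rel=1e-12)


def test_published_range_tables_regenerate(table_params):
    # every stored endpoint matches +/-10% of its (printed-precision) center
    # to 4 decimals, except the documented Set 1 K0 cell
    issues = es.range_consistency()
    assert len(issues) == 1


def _param_strategy():
    pos = st.floats(0.01, 10.0, allow_nan=False)
    return st.builds(
        es.DimensionalParams,
        alpha1=pos, alpha2=pos, beta1=pos, beta2=pos, k0=pos, k1=pos, k2=pos,
        IC_S=pos, IC_E=pos, IC_T=pos, IC_C=pos,
    )


@given(params=_param_strategy(), set_id=st.integers(1, 7),
       E=st.floats(0.0, 5.0), S=st.floats(0.0, 5.0),
       C=st.floats(0.0, 10.0), T=st.floats(0.0, 1.0))
def test_frame_change_preserves_dynamics(params, set_id, E, S, C, T):
    """Rescaling states, inputs and time is an exact change of variables."""
    nd = es.nondimensionalize(params, set_id)
    g = es.gamma_value(params, set_id)
    dim = es.rhs_dimensional((E, S), params, C, T)
    non = es.rhs_nondimensional((E / params.IC_E, S / params.IC_S), nd,
                                C / params.IC_C, T / params.IC_T)
    assert non[0] == pytest.approx(dim[0] * g / params.IC_E, rel=1e-10, abs=1e-12)
    assert non[1] == pytest.approx(dim[1] * g / params.IC_S, rel=1e-10, abs=1e-12)


@given(x=st.floats(0.0, 1e12), n=st.integers(1, 6))
def test_hill_factor_bounded_and_monotone(x, n):
    h = hill(x, n)
    assert 0.0 <= h <= 1.0  # mathematically < 1; float rounding saturates
    assert hill(x * 1.5 + 1e-9, n) >= h
    if x <= 100.0 and n <= 3:
        assert h < 1.0
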