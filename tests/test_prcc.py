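"""PRCC: rank transform, partial correlations, validity diagnostics."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata, spearmanr

import emtsens as es
from emtsens.model import ParamRange, TreatmentGroup
from emtsens.prcc import CollinearityError, DEFAULT_THRESHOLD, PRCCResult


def inversion_oracle(X, y):
    """Independent PRCC oracle: invert the rank correlation matrix of [X, y]
    and read off rho_jy = -Omega_jy / sqrt(Omega_jj * Omega_yy)."""
    Z = np.column_stack([X, y])
    R = np.corrcoef(np.column_stack([rankdata(Z[:, j]) for j in range(Z.shape[1])]),
                    rowvar=False)
    om = np.linalg.inv(R)
    k = X.shape[1]
    return [-om[j, k] / np.sqrt(om[j, j] * om[k, k]) for j in range(k)]


@pytest.mark.parametrize(
    "values, expected",
    [
        ((0.3, 0.1, 0.2), [3, 1, 2]),
        ((0.5, 0.5, 0.1), [2.5, 2.5, 1]),
        (tuple(range(6)), [1, 2, 3, 4, 5, 6]),
    ],
)
def test_rank_transform(values, expected):
    assert list(es.rank_transform(values)) == expected


def test_prcc_perfect_monotone_dependence():
    rng = np.random.default_rng(0)
    X = rng.uniform(size=(60, 4))
    rho = es.prcc_all(X, X[:, 1] ** 3)  # ranks identical to column 1's
    assert rho["x1"] == pytest.approx(1.0, abs=1e-12)


def test_prcc_null_distribution_is_tight():
    rng = np.random.default_rng(1)
    X = rng.uniform(size=(10000, 6))
    rho = es.prcc_all(X, rng.uniform(size=10000))
    assert max(abs(v) for v in rho.values()) < 0.05


def test_matrix_inversion_oracle_agreement():
    """Regression-residual PRCC equals the inverse-correlation-matrix route."""
    rng = np.random.default_rng(7)
    for _ in range(20):
        n = int(rng.integers(20, 200))
        k = int(rng.integers(2, 8))
        X = rng.uniform(size=(n, k))
        y = X @ rng.normal(size=k) + 0.3 * rng.normal(size=n)
        got = list(es.prcc_all(X, y).values())
        assert got == pytest.approx(inversion_oracle(X, y), abs=1e-10)


def test_hand_sized_instance_against_oracle_and_pingouin():
    X = np.array([[0.1, 1.0], [0.4, 0.2], [0.2, 0.5], [0.9, 0.9],
                  [0.6, 0.1], [0.8, 0.4]])
    y = np.array([1.0, 3.0, 1.5, 5.0, 2.0, 4.0])
    got = list(es.prcc_all(X, y).values())
    assert got == pytest.approx(inversion_oracle(X, y), abs=1e-10)
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd
    df = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "y": y})
    ref = pingouin.partial_corr(df, x="a", y="y", covar=["b"], method="spearman")
    assert got[0] == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)


def test_invariance_under_monotone_transforms():
    rng = np.random.default_rng(3)
    X = rng.uniform(size=(80, 3))
    y = X[:, 0] - 2 * X[:, 2] + 0.1 * rng.normal(size=80)
    base = es.prcc_all(X, y)
    Xt = X.copy()
    Xt[:, 0] = np.exp(5 * Xt[:, 0])
    Xt[:, 2] = Xt[:, 2] ** 3
    warped = es.prcc_all(Xt, np.arctan(y))
    for k in base:
        assert warped[k] == pytest.approx(base[k], abs=1e-12)


def test_interparameter_prcc_cases():
    rng = np.random.default_rng(5)
    X = rng.uniform(size=(400, 2))
    two = es.interparameter_prcc(X)
    assert two[0, 1] == pytest.approx(spearmanr(X[:, 0], X[:, 1]).statistic, abs=1e-12)
    dup = np.column_stack([X, X[:, 0]])
    with pytest.warns(UserWarning, match="perfectly rank-correlated"):
        m = es.interparameter_prcc(dup)
    assert m[0, 2] == 1.0
    lhs = es.latin_hypercube(es.dimensional_ranges(), 10000, seed=1)
    ip = es.interparameter_prcc(lhs.values, lhs.names)
    assert np.allclose(ip, ip.T) and np.allclose(np.diag(ip), 1.0)
    assert np.abs(ip - np.eye(11)).max() < 0.5


def test_collinear_controls_are_rejected():
    rng = np.random.default_rng(6)
    X = rng.uniform(size=(50, 3))
    X[:, 2] = X[:, 1]  # ranks of controls collinear when j = 0
    Xr = np.column_stack([rankdata(X[:, j]) for j in range(3)])
    with pytest.raises(CollinearityError):
        es.partial_rank_correlation(Xr, rankdata(rng.uniform(size=50)), 0,
                                    names=["a", "b", "c"])


def test_classify_significance_threshold():
    res = PRCCResult(output_name="S", group=None,
                     rho={"alpha2": 0.93, "beta2": -0.88, "k1": 0.2})
    assert es.classify_significance(res) == {"alpha2", "beta2"}
    assert res.threshold == DEFAULT_THRESHOLD
    loose = PRCCResult(output_name="S", group=None, rho=res.rho, threshold=0.1)
    assert es.classify_significance(loose) == {"alpha2", "beta2", "k1"}


def test_monotonicity_scan_directions(table_params):
    group = TreatmentGroup(contact=6.0, tgfb=0.0, initial_state=(0.0522, 0.0034))
    ranges = [r for r in es.dimensional_ranges() if r.name in ("beta1", "alpha2")]
    reports = {r.parameter: r for r in
               es.monotonicity_scan(table_params, ranges, group, points_per_param=5)}
    assert reports["beta1"].all_monotone
    # higher E-cadherin degradation always lowers its steady state
    assert reports["beta1"].direction["E"] == "decreasing"
    assert reports["alpha2"].direction["S"] == "increasing"
    assert not reports["beta1"].negative_values


def test_monotonicity_scan_preconditions(table_params):
    group = TreatmentGroup(contact=6.0, tgfb=0.0, initial_state=(0.0522, 0.0034))
    with pytest.raises(ValueError, match="points_per_param"):
        es.monotonicity_scan(table_params, es.dimensional_ranges(), group,
                             points_per_param=2)
    # a zero-width perturbation range is rejected at construction
    with pytest.raises(ValueError, match="lo < hi"):
        ParamRange("beta1", 6.0, 6.0, varied=True)
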