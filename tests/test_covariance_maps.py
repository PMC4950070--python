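import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from surrometa.covariance_maps import (
    BetweenParams,
    ConditionalParams,
    between_to_conditional,
    conditional_to_between,
    implied_covariance,
)


def _between(tau, rho_flat, structure="unstructured"):
    tau = np.asarray(tau, dtype=float)
    n = tau.size
    rho = np.eye(n)
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            rho[i, j] = rho[j, i] = rho_flat[k]
            k += 1
    return BetweenParams(tau=tau, rho=rho, structure=structure)


class TestBetweenToConditional:
    def test_equicorrelated_example(self):
        b = _between([0.5, 0.5, 0.5], [0.8, 0.8, 0.8])
        c = between_to_conditional(b)
        assert c.slopes[1] == pytest.approx([0.8], rel=1e-12)
        assert c.slopes[2] == pytest.approx([4 / 9, 4 / 9], rel=1e-9)
        assert c.psi[1] ** 2 == pytest.approx(0.09, rel=1e-9)
        assert c.psi[2] ** 2 == pytest.approx(0.25 - (4 / 9) * 0.2 * 2, rel=1e-9)

    def test_matches_conditional_normal_oracle(self, rng):
        """Slopes/psi equal the conditional moments of the joint normal."""
        b = _between([0.4, 0.7, 0.3], [0.5, -0.2, 0.3])
        c = between_to_conditional(b)
        T, _ = implied_covariance(b)
        for j in (1, 2):
            pa = list(range(j))
            lam = np.linalg.solve(T[np.ix_(pa, pa)], T[pa, j])
            schur = T[j, j] - T[j, pa] @ lam
            assert c.slopes[j] == pytest.approx(lam, rel=1e-10)
            assert c.psi[j] ** 2 == pytest.approx(schur, rel=1e-10)

    def test_independence(self):
        b = _between([0.3, 0.5, 0.9], [0.0, 0.0, 0.0])
        c = between_to_conditional(b)
        assert all(np.allclose(s, 0) for s in c.slopes)
        assert c.psi == pytest.approx(b.tau, rel=1e-12)

    def test_sequential_example_and_product_rule(self):
        rho = np.array([[1, 0.8, np.nan], [0.8, 1, 0.8], [np.nan, 0.8, 1.0]])
        b = BetweenParams(tau=np.full(3, 0.5), rho=rho, structure="sequential")
        c = between_to_conditional(b)
        assert c.slopes[1] == pytest.approx([0.8]) and c.slopes[2] == pytest.approx([0.8])
        assert c.psi[1] ** 2 == pytest.approx(0.09) and c.psi[2] ** 2 == pytest.approx(0.09)
        T, pd = implied_covariance(b)
        assert pd
        assert T[0, 2] / (0.5 * 0.5) == pytest.approx(0.64, rel=1e-12)

    def test_sequential_product_rule_violation_errors(self):
        rho = np.array([[1, 0.8, 0.2], [0.8, 1, 0.8], [0.2, 0.8, 1.0]])
        b = BetweenParams(tau=np.full(3, 0.5), rho=rho, structure="sequential")
        with pytest.raises(ValueError, match="structure"):
            between_to_conditional(b)

    def test_non_pd_errors(self):
        b = _between([0.5, 0.5, 0.5], [0.9, 0.9, -0.9])
        with pytest.raises(ValueError, match="positive definite"):
            between_to_conditional(b)

    def test_legacy_psi_formula(self):
        """The literal cascade drops the parent cross-covariance term."""
        b = _between([0.5, 0.5, 0.5], [0.8, 0.8, 0.8])
        c = between_to_conditional(b, legacy_psi=True)
        lam = 4 / 9
        legacy = 0.25 - lam**2 * 0.25 - lam**2 * 0.25
        assert c.psi[2] ** 2 == pytest.approx(legacy, rel=1e-9)
        exact = between_to_conditional(b).psi[2] ** 2
        assert abs(legacy - exact) > 0.05  # materially different when parents correlate


class TestConditionalToBetween:
    def test_round_trip_equicorrelated(self):
        b = _between([0.5, 0.5, 0.5], [0.8, 0.8, 0.8])
        b2 = conditional_to_between(between_to_conditional(b))
        assert np.allclose(b2.tau, b.tau, atol=1e-10)
        assert np.allclose(b2.rho, b.rho, atol=1e-10)

    def test_zero_slopes(self):
        c = ConditionalParams(psi=[0.2, 0.4, 0.6], slopes=[[], [0.0], [0.0, 0.0]])
        b = conditional_to_between(c)
        assert np.allclose(b.rho, np.eye(3))
        assert b.tau == pytest.approx([0.2, 0.4, 0.6], rel=1e-12)

    def test_sequential_forward_substitution(self):
        c = ConditionalParams(
            psi=[0.5, 0.3, 0.3], slopes=[[], [0.8], [0.8]], structure="sequential"
        )
        b = conditional_to_between(c)
        assert b.tau[1] == pytest.approx(0.5, rel=1e-12)  # sqrt(0.09 + 0.64*0.25)
        assert b.rho[0, 1] == pytest.approx(0.8, rel=1e-12)


class TestImpliedCovariance:
    def test_identity(self):
        b = _between([1.0, 1.0, 1.0], [0.0, 0.0, 0.0])
        T, pd = implied_covariance(b)
        assert np.allclose(T, np.eye(3)) and pd

    def test_pd_flags(self):
        _, pd_ok = implied_covariance(_between([0.5, 0.5, 0.5], [0.8, 0.8, 0.8]))
        _, pd_bad = implied_covariance(_between([0.5, 0.5, 0.5], [0.9, 0.9, -0.9]))
        assert pd_ok and not pd_bad


@st.composite
def random_chain(draw, n=3):
    """Random PD between-parameters, built via a valid chain."""
    psi = [draw(st.floats(0.1, 1.0)) for _ in range(n)]
    slopes = [[]] + [
        [draw(st.floats(-0.9, 0.9)) for _ in range(j)] for j in range(1, n)
    ]
    return ConditionalParams(psi=np.array(psi), slopes=[np.array(s) for s in slopes])


@given(random_chain())
@settings(max_examples=40, deadline=None)
def test_round_trip_property(c):
    b = conditional_to_between(c)
    c2 = between_to_conditional(b)
    assert np.allclose(c2.psi, c.psi, atol=1e-10)
    for s, s2 in zip(c.slopes, c2.slopes):
        assert np.allclose(s, s2, atol=1e-10)


def test_monte_carlo_chain_covariance(rng):
    """Sampling through the chain reproduces the implied covariance."""
    b = _between([0.5, 0.6, 0.4], [0.8, 0.5, 0.6])
    c = between_to_conditional(b)
    T, _ = implied_covariance(b)
    n = 10**5
    x = np.empty((n, 3))
    x[:, 0] = c.psi[0] * rng.standard_normal(n)
    x[:, 1] = c.slopes[1][0] * x[:, 0] + c.psi[1] * rng.standard_normal(n)
    x[:, 2] = x[:, :2] @ c.slopes[2] + c.psi[2] * rng.standard_normal(n)
    emp = np.cov(x.T)
    # MC standard error of a covariance entry is ~ sqrt((T_jj T_kk + T_jk^2)/n)
    for j in range(3):
        for k in range(3):
            se = np.sqrt((T[j, j] * T[k, k] + T[j, k] ** 2) / n)
            assert abs(emp[j, k] - T[j, k]) < 3 * se


def test_sequential_precision_is_tridiagonal():
    rho = np.full((5, 5), np.nan)
    np.fill_diagonal(rho, 1.0)
    for j in range(1, 5):
        rho[j, j - 1] = rho[j - 1, j] = 0.6
    b = BetweenParams(tau=np.full(5, 0.5), rho=rho, structure="sequential")
    T, pd = implied_covariance(b)
    assert pd
    P = np.linalg.inv(T)
    off = np.abs(P[np.abs(np.subtract.outer(range(5), range(5))) > 1])
    assert np.all(off < 1e-10)


def test_custom_adjacency_precision_zeros():
    """A five-outcome sequence with one extra final-outcome edge.

    Parents: 2<-1, 3<-2, 4<-3, 5<-{3,4}; the precision matrix is zero
    exactly at the non-modelled conditional independences, while the
    extra [3,5] edge stays free.
    """
    adjacency = [[], [0], [1], [2], [2, 3]]
    rho = np.full((5, 5), np.nan)
    np.fill_diagonal(rho, 1.0)
    vals = {(0, 1): 0.7, (1, 2): 0.6, (2, 3): 0.5, (2, 4): 0.45, (3, 4): 0.55}
    for (i, j), v in vals.items():
        rho[i, j] = rho[j, i] = v
    b = BetweenParams(
        tau=np.full(5, 0.5), rho=rho, structure="custom", adjacency=adjacency
    )
    T, pd = implied_covariance(b)
    assert pd
    P = np.linalg.inv(T)
    zero_pairs = [(0, 2), (0, 3), (0, 4), (1, 3), (1, 4)]
    for i, j in zero_pairs:
        assert abs(P[i, j]) < 1e-10
    assert abs(P[2, 4]) > 1e-6  # the declared extra edge is not zeroed
    # modelled correlations reproduced entry-for-entry
    for (i, j), v in vals.items():
        assert T[i, j] / 0.25 == pytest.approx(v, rel=1e-10)


def test_json_round_trip():
    b = _between([0.5, 0.5, 0.5], [0.8, 0.8, 0.8])
    b2 = BetweenParams.from_dict(b.to_dict())
    assert np.allclose(b2.rho, b.rho) and np.allclose(b2.tau, b.tau)
    c = between_to_conditional(b)
    c2 = ConditionalParams.from_dict(c.to_dict())
    assert np.allclose(c2.psi, c.psi)
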