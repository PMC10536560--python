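"""PCA-based indicator weighting against independent closed-form oracles."""

import math

import numpy as np
import pytest

from eqiscope import WeightSet, average_weights, correlation_matrix, pca_weights


# ---------------------------------------------------------------------------
# independent brute-force oracle: correlation -> eigenstructure -> weights,
# via analytic characteristic-polynomial roots (n = 2, 3), never np.linalg

def _analytic_eigenvalues(R):
    n = R.shape[0]
    if n == 2:
        r = R[0, 1]
        return sorted([1 + abs(r), 1 - abs(r)], reverse=True)
    # n = 3: roots of det(R - lam I) = 0 by the trigonometric cubic formula
    a = -float(np.trace(R))
    b = float(R[0, 0] * R[1, 1] - R[0, 1] ** 2 + R[0, 0] * R[2, 2] - R[0, 2] ** 2
              + R[1, 1] * R[2, 2] - R[1, 2] ** 2)
    c = -(R[0, 0] * (R[1, 1] * R[2, 2] - R[1, 2] ** 2)
          - R[0, 1] * (R[0, 1] * R[2, 2] - R[1, 2] * R[0, 2])
          + R[0, 2] * (R[0, 1] * R[1, 2] - R[1, 1] * R[0, 2]))
    p = b - a * a / 3
    q = 2 * a ** 3 / 27 - a * b / 3 + c
    m = 2 * math.sqrt(max(-p / 3, 0))
    arg = np.clip(3 * q / (p * m) if p != 0 else 0.0, -1, 1)
    theta = math.acos(arg) / 3
    roots = [m * math.cos(theta - 2 * math.pi * k / 3) - a / 3 for k in range(3)]
    return sorted(roots, reverse=True)


def _analytic_eigenvector(R, lam):
    """Unit eigenvector of a 3x3 symmetric matrix via row cross products."""
    A = R - lam * np.eye(3)
    candidates = [np.cross(A[0], A[1]), np.cross(A[0], A[2]), np.cross(A[1], A[2])]
    v = max(candidates, key=lambda c: np.linalg.norm(c))
    v = v / np.linalg.norm(v)
    i = int(np.argmax(np.abs(v)))
    return v if v[i] > 0 else -v


def brute_force_weights(R, rho):
    """Weights computed directly from the eigenstructure definition."""
    n = R.shape[0]
    alpha = _analytic_eigenvalues(R)
    if n == 2:
        r = R[0, 1]
        s = 1.0 if r >= 0 else -1.0
        vecs = [np.array([1.0, s]) / math.sqrt(2), np.array([1.0, -s]) / math.sqrt(2)]
        vecs = [v if v[int(np.argmax(np.abs(v)))] > 0 else -v for v in vecs]
    else:
        vecs = [_analytic_eigenvector(R, lam) for lam in alpha]
    e = np.array(alpha) / sum(alpha)
    cum, p = 0.0, 0
    for i, ei in enumerate(e):
        cum += ei
        p = i + 1
        if cum >= rho:
            break
    C = np.stack(vecs, axis=1)
    gamma = np.abs(C[:, :p]) @ e[:p] / e[:p].sum()
    return gamma / gamma.sum(), np.array(alpha), e, p


def dominant_indicator_observations(rng, m=100_000):
    """Three indicators where the first dominates the shared variance.

    x1 loads 0.95 on the main common factor f; x2 and x3 load 0.5 on f and
    share a secondary factor g, so no contrast component can overtake x1's
    lead among the retained components.
    """
    f = rng.standard_normal(m)
    g = rng.standard_normal(m)
    return np.stack([
        0.95 * f + 0.31 * rng.standard_normal(m),
        0.50 * f + 0.60 * g + 0.62 * rng.standard_normal(m),
        0.50 * f + 0.60 * g + 0.62 * rng.standard_normal(m),
    ], axis=1)


def random_correlation(rng, n):
    """Well-conditioned random correlation matrix with separated eigenvalues."""
    while True:
        X = rng.standard_normal((50, n)) @ rng.standard_normal((n, n))
        R = np.corrcoef(X, rowvar=False)
        lam = np.sort(np.linalg.eigvalsh(R))
        if lam[0] > 1e-3 and np.min(np.diff(lam)) > 1e-2:
            return R


class TestCorrelationMatrix:
    def test_identical_columns_give_unit_correlation(self, rng):
        x = rng.standard_normal(50)
        R = correlation_matrix(np.stack([x, x], axis=1))
        assert R[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_sum_of_products(self):
        X = np.array([[1.0, 2.0, 0.5], [2.0, 1.5, 1.0], [3.0, 3.5, 0.2],
                      [4.0, 3.0, 1.8], [5.0, 5.5, 0.9], [6.0, 5.0, 2.1]])
        R = correlation_matrix(X)
        m = X.shape[0]
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        for i in range(3):
            for j in range(3):
                expected = float(np.sum(Z[:, i] * Z[:, j]) / (m - 1))
                assert R[i, j] == pytest.approx(expected, abs=1e-12)

    def test_independent_columns_nearly_uncorrelated(self):
        rng = np.random.default_rng(77)
        X = rng.standard_normal((100_000, 2))
        R = correlation_matrix(X)
        assert abs(R[0, 1]) < 0.02

    def test_constant_column_errors(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(X)

    def test_too_few_observations_errors(self):
        with pytest.raises(ValueError, match="observations"):
            correlation_matrix(np.ones((2, 3)))


class TestPcaWeights:
    def test_identity_correlation_gives_equal_weights(self):
        ws, pca = pca_weights(None, rho=0.85, R=np.eye(3))
        np.testing.assert_allclose(ws.weights, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)
        np.testing.assert_allclose(pca.contribution_rates, [1 / 3] * 3, atol=1e-12)
        assert pca.n_retained == 3

    def test_equicorrelation_closed_form(self):
        R = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        # eigenvalues are 1 + 2r = 2.0 and 1 - r = 0.5 (twice)
        ws, pca = pca_weights(None, rho=0.6, R=R)
        np.testing.assert_allclose(np.sort(pca.eigenvalues)[::-1], [2.0, 0.5, 0.5], atol=1e-10)
        assert pca.n_retained == 1  # 2/3 cumulative contribution >= 0.6
        # single retained component loads symmetrically: weights all equal
        np.testing.assert_allclose(ws.weights, [1 / 3] * 3, atol=1e-10)

    @pytest.mark.parametrize("n", [2, 3])
    def test_matches_brute_force_oracle_on_random_matrices(self, n):
        rng = np.random.default_rng(123)
        for _ in range(100):
            R = random_correlation(rng, n)
            rho = rng.uniform(0.3, 1.0)
            ws, pca = pca_weights(None, rho=rho, R=R)
            expected_w, expected_alpha, expected_e, expected_p = brute_force_weights(R, rho)
            assert pca.n_retained == expected_p
            np.testing.assert_allclose(pca.eigenvalues, expected_alpha, atol=1e-8)
            np.testing.assert_allclose(ws.weights, expected_w, atol=1e-8)

    def test_weights_nonnegative_and_sum_to_one(self, rng):
        for _ in range(50):
            R = random_correlation(rng, 3)
            ws, _ = pca_weights(None, rho=rng.uniform(0.3, 1.0), R=R)
            assert np.all(ws.weights >= 0)
            assert float(ws.weights.sum()) == pytest.approx(1.0, abs=1e-10)

    def test_permutation_equivariance(self, rng):
        X = rng.standard_normal((500, 3)) @ rng.standard_normal((3, 3))
        ws, _ = pca_weights(X, rho=0.85)
        perm = [2, 0, 1]
        ws_p, _ = pca_weights(X[:, perm], rho=0.85)
        np.testing.assert_allclose(ws_p.weights, ws.weights[perm], atol=1e-10)

    def test_dominant_indicator_gets_largest_weight(self):
        # the first indicator carries the dominant loading on the main shared
        # factor f; the minors split theirs with a secondary factor g
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = dominant_indicator_observations(rng)
            ws, _ = pca_weights(X, rho=0.85)
            assert int(np.argmax(ws.weights)) == 0, f"seed {seed}: {ws.weights}"

    def test_invalid_rho_errors(self):
        with pytest.raises(ValueError, match="rho"):
            pca_weights(None, rho=0.0, R=np.eye(3))
        with pytest.raises(ValueError, match="rho"):
            pca_weights(None, rho=1.5, R=np.eye(3))

    def test_non_finite_correlation_errors(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            pca_weights(None, rho=0.85, R=R)


class TestAverageWeights:
    def test_idempotent_on_identical_inputs(self):
        ws = WeightSet(names=("a", "b", "c"), weights=np.array([0.2, 0.3, 0.5]))
        avg = average_weights([ws, ws])
        np.testing.assert_allclose(avg.weights, ws.weights, atol=1e-15)

    def test_forced_arithmetic(self):
        a = WeightSet(names=("a", "b", "c"), weights=np.array([0.2, 0.3, 0.5]))
        b = WeightSet(names=("a", "b", "c"), weights=np.array([0.4, 0.3, 0.3]))
        np.testing.assert_allclose(average_weights([a, b]).weights, [0.3, 0.3, 0.4],
                                   atol=1e-12)

    def test_renormalization_is_noop_for_valid_inputs(self, rng):
        sets = []
        for _ in range(3):
            w = rng.uniform(0.1, 1.0, size=3)
            sets.append(WeightSet(names=("a", "b", "c"), weights=w / w.sum()))
        mean = np.mean([s.weights for s in sets], axis=0)
        np.testing.assert_allclose(average_weights(sets).weights, mean, atol=1e-12)

    def test_mismatched_names_error(self):
        a = WeightSet(names=("a", "b"), weights=np.array([0.5, 0.5]))
        b = WeightSet(names=("a", "c"), weights=np.array([0.5, 0.5]))
        with pytest.raises(ValueError, match="names"):
            average_weights([a, b])

    def test_weight_contract_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            WeightSet(names=("a", "b"), weights=np.array([0.5, 0.6]))
        with pytest.raises(ValueError, match="nonnegative"):
            WeightSet(names=("a", "b"), weights=np.array([-0.1, 1.1]))
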