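import numpy as np
import pytest

from pinnode.identifiability import (linearize_in_params, profile_over_time,
                                     rref_analysis)
from pinnode.simulate import integrate
from pinnode.systems import ODESystem, ParamSpec

from conftest import exponential_inverse_system

MOSQUITO_UNKNOWNS = ["f_E", "f_P", "f_L", "f_Ag", "m_L", "m_P", "m_A",
                     "gamma_Aem", "gamma_Ab", "gamma_Ao"]


class TestLinearize:
    def test_scalar_decay_system(self):
        sys = exponential_inverse_system()
        A, b = linearize_in_params(sys, 0.0, [2.0], [-1.0], ["theta"])
        np.testing.assert_allclose(A, [[-2.0]])
        np.testing.assert_allclose(b, [-1.0])

    def test_zero_state_kills_coefficient(self):
        sys = exponential_inverse_system()
        A, _ = linearize_in_params(sys, 0.0, [0.0], [0.0], ["theta"])
        np.testing.assert_allclose(A, [[0.0]])

    def test_mosquito_zero_state_gives_zero_matrix(self, mosquito):
        u = np.zeros(10)
        A, b = linearize_in_params(mosquito, 100.0, u, mosquito(100.0, u),
                                   MOSQUITO_UNKNOWNS)
        np.testing.assert_allclose(A, 0.0, atol=1e-12)

    def test_nonaffine_dependence_detected(self):
        sys = ODESystem("sq", 1, rhs=lambda t, u, th: -th[:, [0]] ** 2 * u,
                        param_spec=[ParamSpec("k", "learn_constant", 1.0, bounds=(0, 2))])
        with pytest.raises(ValueError, match="affinely"):
            linearize_in_params(sys, 0.0, [1.0], [-1.0], ["k"])


class TestRref:
    def test_identity_full_rank(self):
        rank, pivots, free = rref_analysis(np.eye(4))
        assert rank == 4 and free == ()

    def test_dependent_columns(self):
        rank, pivots, free = rref_analysis(np.array([[1.0, 2.0], [2.0, 4.0]]))
        assert rank == 1
        assert pivots == (0,)
        assert free == (1,)

    def test_rounding_kills_tiny_entries(self):
        rank, _, free = rref_analysis(np.array([[1e-9]]), precision_digits=6)
        assert rank == 0 and free == (0,)

    def test_rank_matches_svd_on_random_matrices(self):
        """Exact rational RREF rank equals SVD numerical rank on 100 random
        matrices, including rank-deficient constructions."""
        rng = np.random.default_rng(0)
        for i in range(100):
            m, n = rng.integers(2, 7, 2)
            r = int(rng.integers(1, min(m, n) + 1))
            # integer factors keep the rank exact under 6-digit rounding
            A = (rng.integers(-4, 5, size=(m, r))
                 @ rng.integers(-4, 5, size=(r, n))).astype(float)
            svd_rank = np.linalg.matrix_rank(A, tol=1e-6 * max(1.0, np.abs(A).max()))
            rref_rank, _, _ = rref_analysis(A, precision_digits=6)
            assert rref_rank == svd_rank, f"matrix {i}"

    def test_row_scaling_invariance(self):
        rng = np.random.default_rng(1)
        A = np.round(rng.normal(size=(4, 3)), 3)
        _, _, free = rref_analysis(A)
        scaled = A * np.array([[2.0], [1.0], [4.0], [0.5]])
        _, _, free_scaled = rref_analysis(scaled)
        assert free == free_scaled

    def test_duplicated_row_changes_nothing(self):
        A = np.array([[1.0, 2.0, 0.0], [0.0, 1.0, 1.0]])
        _, _, free = rref_analysis(A)
        _, _, free_dup = rref_analysis(np.vstack([A, A[0]]))
        assert free == free_dup


class TestProfile:
    def test_cold_period_frees_larval_and_pupal_mortality(self, mosquito):
        """When L = P = 0 their mortality rates receive no information:
        m_L and m_P must be flagged free while adult-stage parameters
        with non-zero compartments stay identifiable."""
        u = np.zeros(10)
        u[5], u[8] = 50.0, 30.0  # gestating adults survive the cold
        A, _ = linearize_in_params(mosquito, 1000.0, u, mosquito(1000.0, u),
                                   MOSQUITO_UNKNOWNS)
        _, _, free = rref_analysis(A)
        free_names = {MOSQUITO_UNKNOWNS[j] for j in free}
        assert {"m_L", "m_P"} <= free_names
        assert "f_Ag" not in free_names

    def test_positive_state_structural_rank(self, mosquito):
        """At a generic all-positive state the rank is 9, not 10: f_L, m_L
        and m_P appear only in the dL/dP equations (3 unknowns, 2 rows), so
        exactly one of them is always pointwise-dependent.  The RREF rank
        must agree with the SVD oracle and the free column must come from
        that trio."""
        rng = np.random.default_rng(0)
        u = rng.uniform(100, 5000, 10)
        A, _ = linearize_in_params(mosquito, 50.0, u, mosquito(50.0, u),
                                   MOSQUITO_UNKNOWNS)
        rank, _, free = rref_analysis(A)
        svd_rank = np.linalg.matrix_rank(A, tol=1e-6 * np.abs(A).max())
        assert rank == svd_rank == 9
        assert {MOSQUITO_UNKNOWNS[j] for j in free} <= {"f_L", "m_L", "m_P"}

    def test_profile_over_scalar_benchmark(self):
        sys = exponential_inverse_system()
        traj = integrate(sys, [1.0], (0.0, 2.0), np.linspace(0, 2, 21),
                         params={"theta": 0.5})
        prof = profile_over_time(sys, traj, ["theta"], np.linspace(0.1, 1.9, 7))
        assert prof.identifiable.all()  # state never vanishes
        assert (prof.rank == 1).all()
        df = prof.to_frame()
        assert list(df.columns) == ["t", "theta", "rank"]

    def test_empty_unknown_set_is_vacuous(self, mosquito, mosquito_truth_1y):
        prof = profile_over_time(mosquito, mosquito_truth_1y, [], [10.0, 100.0])
        assert prof.identifiable.shape == (2, 0)
        assert (prof.rank == 0).all()
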