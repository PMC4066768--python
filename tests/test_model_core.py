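"""Rigid-base model: estimation, energy, entropy, marginalization, scaling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dnamech.model_core as mc
from dnamech import (
    KB,
    ConditioningError,
    CoordinateSchema,
    CoordinateTrajectory,
    InsufficientSamplesError,
    RigidBaseModel,
    conformational_entropy,
    deformation_energy,
    estimate_model,
    force_constant,
    half_trajectory_error,
    nondimensionalize,
    redimensionalize,
    relax,
    trim_ends,
)
from conftest import random_spd

KBT = KB * 300.0


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n", [2, 3, 18])
def test_schema_counts_and_ordering(n):
    sch = CoordinateSchema(n)
    assert sch.N == 12 * n - 6
    labels = sch.labels()
    assert len(labels) == sch.N == len(set(labels))
    # the flat index map is the inverse of the label list
    for k, lab in enumerate(labels):
        name, _, pos = lab.rpartition("_")
        assert sch.index(name, int(pos)) == k
    assert labels[0] == "buckle_1" and labels[6 * n] == "tilt_1"
    assert labels[-1] == f"rise_{n - 1}"


def test_schema_rejects_short_duplex_and_bad_indices():
    with pytest.raises(ValueError):
        CoordinateSchema(1)
    sch = CoordinateSchema(4)
    with pytest.raises(IndexError):
        sch.index("twist", 4)  # only 3 steps
    with pytest.raises(KeyError):
        sch.index("bogus", 1)


def test_trim_ends_drops_terminal_pairs_and_flanking_steps():
    sch = CoordinateSchema(5)
    M = 3
    values = np.arange(M * sch.N, dtype=float).reshape(M, sch.N)
    traj = CoordinateTrajectory(sch, values)
    trimmed = trim_ends(traj, 1)
    assert trimmed.schema.n == 3
    # interior propeller column survives untouched
    col_old = sch.index("propeller", 3)
    col_new = trimmed.schema.index("propeller", 2)
    np.testing.assert_array_equal(trimmed.values[:, col_new], values[:, col_old])
    # interior step 3 (pairs 3-4) becomes step 2 of the trimmed duplex
    np.testing.assert_array_equal(
        trimmed.values[:, trimmed.schema.index("roll", 2)],
        values[:, sch.index("roll", 3)],
    )


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------


def _whitened_trajectory(n=2, M=40, seed=0):
    """Trajectory whose ML sample covariance is exactly the identity."""
    sch = CoordinateSchema(n)
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((M, sch.N))
    X -= X.mean(axis=0)
    C = X.T @ X / M
    X = X @ np.linalg.inv(np.linalg.cholesky(C)).T
    return CoordinateTrajectory(sch, X)


def test_estimate_on_whitened_data_gives_kbt_identity():
    traj = _whitened_trajectory()
    model = estimate_model(traj, temperature=300.0)
    np.testing.assert_allclose(model.K, KBT * np.eye(traj.schema.N), atol=1e-10)


def test_estimated_model_satisfies_fluctuation_relation(small_trajectory):
    # K C = k_B T I: inversion consistency of every estimated model
    model = estimate_model(small_trajectory)
    C = mc.sample_covariance(small_trajectory.included_values)
    np.testing.assert_allclose(
        model.K @ C, KBT * np.eye(model.N), rtol=1e-8, atol=1e-10
    )


def test_estimate_errors_on_degenerate_input():
    sch = CoordinateSchema(2)
    const = CoordinateTrajectory(sch, np.ones((50, sch.N)))
    with pytest.raises(ConditioningError):
        estimate_model(const)
    few = CoordinateTrajectory(sch, np.random.default_rng(0).normal(size=(10, sch.N)))
    with pytest.raises(InsufficientSamplesError):
        estimate_model(few)


# ---------------------------------------------------------------------------
# Deformation energy
# ---------------------------------------------------------------------------


def test_energy_minimum_and_single_coordinate_closed_form():
    model = RigidBaseModel(np.zeros(1), np.array([[1.0 * KBT]]), 300.0)
    assert deformation_energy(model, model.w_hat) == 0.0
    # K = 1 k_BT/deg^2, 2 deg displacement: E = 2 k_BT
    e = deformation_energy(model, np.array([2.0]))
    assert e == pytest.approx(2.0 * KBT)
    assert e == pytest.approx(1.1923, abs=1e-4)


@settings(derandomize=True, max_examples=25)
@given(st.integers(min_value=0, max_value=10_000))
def test_energy_is_even_in_the_displacement(seed):
    rng = np.random.default_rng(seed)
    K = random_spd(5, rng)
    model = RigidBaseModel(rng.standard_normal(5), K, 300.0)
    d = rng.standard_normal(5)
    assert deformation_energy(model, model.w_hat + d) == pytest.approx(
        deformation_energy(model, model.w_hat - d)
    )


def test_energy_rejects_wrong_dimension():
    model = RigidBaseModel(np.zeros(2), np.eye(2))
    with pytest.raises(ValueError):
        deformation_energy(model, np.zeros(3))


# ---------------------------------------------------------------------------
# Entropy
# ---------------------------------------------------------------------------


def test_entropy_of_unit_gaussian():
    S, s = conformational_entropy(np.array([[1.0]]))
    assert S == pytest.approx(0.5 * KB * np.log(2 * np.pi * np.e))
    assert S == pytest.approx(1.41894 * KB, abs=1e-5 * KB)
    assert s == S


def test_entropy_diagonal_closed_form_matches_logdet():
    rng = np.random.default_rng(3)
    var = rng.uniform(0.1, 30.0, size=12)
    S, s = conformational_entropy(np.diag(var))
    closed = 0.5 * KB * (12 * np.log(2 * np.pi * np.e) + np.log(var).sum())
    assert S == pytest.approx(closed, rel=1e-12)
    assert s == pytest.approx(closed / 12, rel=1e-12)


def test_entropy_rejects_indefinite_covariance():
    with pytest.raises(ConditioningError):
        conformational_entropy(np.diag([1.0, -1.0]))


def test_entropy_per_coordinate_differences_are_scale_invariant(small_truth):
    from dnamech import GroundTruthSpec, build_ground_truth

    other = build_ground_truth(GroundTruthSpec("GGC"))

    def s_c(model, ls, as_):
        return conformational_entropy(nondimensionalize(model, ls, as_))[1]

    d_default = s_c(small_truth, 1.0, 360 / 34) - s_c(other, 1.0, 360 / 34)
    d_other = s_c(small_truth, 2.5, 7.0) - s_c(other, 2.5, 7.0)
    assert d_other == pytest.approx(d_default, abs=1e-12)


# ---------------------------------------------------------------------------
# Marginalization and force constants
# ---------------------------------------------------------------------------


def test_relax_two_by_two_schur_example():
    model = RigidBaseModel(np.zeros(2), KBT * np.array([[2.0, 1.0], [1.0, 2.0]]))
    marg = relax(model, [0])
    assert marg.K_tilde[0, 0] == pytest.approx(1.5 * KBT)


def test_relax_full_subset_is_identity(small_truth):
    marg = relax(small_truth, np.arange(small_truth.N))
    np.testing.assert_allclose(marg.K_tilde, small_truth.K, rtol=1e-12)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_relax_dual_paths_agree_on_random_spd(seed):
    rng = np.random.default_rng(seed)
    K = random_spd(8, rng, scale=KBT)
    model = RigidBaseModel(rng.standard_normal(8), K)
    idx = rng.choice(8, size=3, replace=False)
    marg = relax(model, idx)
    C_AA = model.covariance[np.ix_(idx, idx)]
    np.testing.assert_allclose(
        marg.K_tilde, KBT * np.linalg.inv(C_AA), rtol=1e-10
    )


def test_relax_input_validation(small_truth):
    with pytest.raises(ValueError):
        relax(small_truth, [])
    with pytest.raises(IndexError):
        relax(small_truth, [small_truth.N])
    with pytest.raises(ValueError):
        relax(small_truth, [0, 0])


def test_force_constant_closed_form_and_marginal_consistency(small_truth):
    # twist variance 25 deg^2 at 300 K
    model = RigidBaseModel(np.zeros(1), np.array([[KBT / 25.0]]))
    assert force_constant(model, 0) == pytest.approx(0.023846, abs=1e-6)
    for a in [0, 7, small_truth.N - 1]:
        assert force_constant(small_truth, a) == pytest.approx(
            relax(small_truth, [a]).K_tilde[0, 0], rel=1e-10
        )


@pytest.mark.parametrize("seed", [0, 5])
def test_relaxed_force_constant_never_exceeds_diagonal_stiffness(seed):
    rng = np.random.default_rng(seed)
    K = random_spd(10, rng)
    model = RigidBaseModel(np.zeros(10), K)
    for a in range(10):
        assert force_constant(model, a) <= K[a, a] + 1e-12


# ---------------------------------------------------------------------------
# Non-dimensionalization
# ---------------------------------------------------------------------------


def test_default_angle_scale_prints_as_10_6():
    assert round(mc.DEFAULT_ANGLE_SCALE, 1) == 10.6


def test_nondimensionalize_round_trip_and_double_application(small_truth):
    scaled = nondimensionalize(small_truth)
    assert scaled.scaling == (1.0, 360.0 / 34.0)
    back = redimensionalize(scaled)
    np.testing.assert_allclose(back.K, small_truth.K, rtol=1e-12)
    np.testing.assert_allclose(back.w_hat, small_truth.w_hat, rtol=1e-12)
    with pytest.raises(ValueError):
        nondimensionalize(scaled)
    with pytest.raises(ValueError):
        redimensionalize(small_truth)


def test_deformation_energy_invariant_under_scaling(small_truth):
    rng = np.random.default_rng(11)
    scaled = nondimensionalize(small_truth)
    s = small_truth.schema.scale_vector(*scaled.scaling)
    for _ in range(5):
        d = rng.standard_normal(small_truth.N)
        e_native = deformation_energy(small_truth, small_truth.w_hat + d)
        e_scaled = deformation_energy(scaled, scaled.w_hat + d / s)
        assert e_scaled == pytest.approx(e_native, rel=1e-10)


# ---------------------------------------------------------------------------
# Half-trajectory error bars
# ---------------------------------------------------------------------------


def _traj_with_first_column(values):
    sch = CoordinateSchema(2)
    X = np.zeros((len(values), sch.N))
    X[:, 0] = values
    # fill other columns with noise so nothing else is degenerate
    X[:, 1:] = np.random.default_rng(0).normal(size=(len(values), sch.N - 1))
    return CoordinateTrajectory(sch, X)


def test_half_error_direct_arithmetic():
    traj = _traj_with_first_column([1.0, 1.0, 3.0, 3.0])
    est = half_trajectory_error(lambda t: t.values[:, 0].mean(), traj)
    assert est.value == pytest.approx(2.0)
    assert est.half_error == pytest.approx(1.0)


def test_half_error_zero_for_constant_series():
    traj = _traj_with_first_column([5.0] * 8)
    est = half_trajectory_error(lambda t: t.values[:, 0].mean(), traj)
    assert est.half_error == 0.0


def test_half_error_shrinks_with_sample_size():
    def mean_error(M, seed):
        rng = np.random.default_rng(seed)
        traj = _traj_with_first_column(rng.standard_normal(M))
        return half_trajectory_error(lambda t: t.values[:, 0].mean(), traj).half_error

    seeds = range(40)
    small = np.mean([mean_error(40, s) for s in seeds])
    large = np.mean([mean_error(4000, s) for s in seeds])
    assert large < small


def test_half_error_vector_statistic_componentwise():
    traj = _traj_with_first_column([1.0, 1.0, 3.0, 3.0])
    est = half_trajectory_error(lambda t: t.values[:, :2].mean(axis=0), traj)
    assert est.half_error[0] == pytest.approx(1.0)
    assert est.half_error.shape == (2,)


# ---------------------------------------------------------------------------
# Archive round-trip
# ---------------------------------------------------------------------------


def test_model_json_round_trip(small_truth, tmp_path):
    from dnamech import load_model, save_model

    scaled = nondimensionalize(small_truth)
    for model in (small_truth, scaled):
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(back.K, model.K)
        np.testing.assert_array_equal(back.w_hat, model.w_hat)
        assert back.temperature == model.temperature
        assert back.scaling == model.scaling
        assert back.schema.n == model.schema.n
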