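"""Covariance selection: constrained MLE, deviance/NFI, backward elimination."""

import numpy as np
import pytest

from chillgm import (
    GraphModel,
    backward_eliminate,
    correlation_matrix,
    fit_constrained_mle,
    nfi,
    partial_correlation,
)
from chillgm.covselect import ConvergenceError, all_pairs, canonical_pair
from conftest import logdet_oracle_fit, random_correlation


def _names(p):
    return [f"X{i + 1}" for i in range(p)]


# --- fit_constrained_mle -----------------------------------------------------

def test_full_model_returns_sample_matrix(beef):
    R = correlation_matrix(beef)
    fit = fit_constrained_mle(R, [], beef.n)
    np.testing.assert_array_equal(fit.pi_hat.to_numpy(), R.to_numpy())
    assert fit.deviance == 0.0
    assert fit.nfi == 1.0


def test_null_model_recovers_identity(beef):
    R = correlation_matrix(beef)
    fit = fit_constrained_mle(R, all_pairs(beef.variable_names), beef.n)
    assert np.abs(fit.pi_hat.to_numpy() - np.eye(beef.p)).max() < 1e-8
    expected = -beef.n * np.linalg.slogdet(R.to_numpy())[1]
    assert fit.deviance == pytest.approx(expected, rel=1e-10)
    assert fit.nfi == pytest.approx(0.0, abs=1e-10)


@pytest.mark.parametrize("seed", range(5))
def test_matching_conditions(seed):
    """Free entries match R; constrained entries vanish in the inverse."""
    rng = np.random.default_rng(seed)
    p = 5
    R = random_correlation(rng, p)
    zero = {canonical_pair("X1", "X4"), canonical_pair("X2", "X5")}
    fit = fit_constrained_mle(R, zero, 44, tolerance=1e-12)
    sigma = fit.pi_hat.to_numpy()
    K = np.linalg.inv(sigma)
    names = _names(p)
    for i in range(p):
        for j in range(i, p):
            pair = canonical_pair(names[i], names[j]) if i != j else None
            if pair in zero:
                assert abs(K[i, j]) < 1e-9
            else:
                assert sigma[i, j] == pytest.approx(R[i, j], abs=1e-9)


def test_ips_agrees_with_logdet_oracle():
    """50 random small instances against an independent convex-oracle fit."""
    rng = np.random.default_rng(42)
    worst = 0.0
    for _ in range(50):
        p = int(rng.integers(3, 5))
        R = random_correlation(rng, p)
        pairs = [(i, j) for i in range(p) for j in range(i + 1, p)]
        k = int(rng.integers(1, len(pairs)))
        chosen = {pairs[t] for t in rng.choice(len(pairs), size=k, replace=False)}
        names = _names(p)
        zero = {canonical_pair(names[i], names[j]) for i, j in chosen}
        fit = fit_constrained_mle(R, zero, 44, tolerance=1e-12)
        oracle = logdet_oracle_fit(R, chosen)
        worst = max(worst, np.abs(fit.pi_hat.to_numpy() - oracle).max())
    assert worst < 1e-6


@pytest.mark.parametrize("seed", range(5))
def test_single_constraint_closed_form(seed):
    """One zero in a 3-variable model: Dev = -n log(1 - r_ij.rest^2)."""
    rng = np.random.default_rng(200 + seed)
    R = random_correlation(rng, 3)
    _, partial = partial_correlation(R)
    n = 44
    fit = fit_constrained_mle(R, [("X1", "X2")], n, tolerance=1e-12)
    assert fit.deviance == pytest.approx(-n * np.log(1 - partial[0, 1] ** 2), abs=1e-8)


def test_deviance_monotone_in_nested_zero_sets(beef):
    R = correlation_matrix(beef)
    names = beef.variable_names
    pairs = sorted(all_pairs(names))
    rng = np.random.default_rng(3)
    order = [pairs[i] for i in rng.permutation(len(pairs))]
    prev = 0.0
    zero = set()
    for pair in order[:10]:
        zero.add(pair)
        dev = fit_constrained_mle(R, zero, beef.n).deviance
        assert dev >= prev - 1e-9
        prev = dev


def test_non_convergence_signals_residual():
    rng = np.random.default_rng(5)
    R = random_correlation(rng, 4)
    with pytest.raises(ConvergenceError) as err:
        fit_constrained_mle(R, [("X1", "X2"), ("X3", "X4")], 44,
                            tolerance=1e-15, max_iterations=1)
    assert err.value.residual > 0


def test_invalid_inputs_rejected():
    bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # not PD
    with pytest.raises(ValueError, match="positive definite"):
        fit_constrained_mle(bad, [], 10)
    rng = np.random.default_rng(0)
    R = random_correlation(rng, 3)
    with pytest.raises(ValueError, match="unknown variables"):
        fit_constrained_mle(R, [("X1", "X9")], 10)


# --- nfi ---------------------------------------------------------------------

@pytest.mark.parametrize("dev_rm, dev_nm, expected", [(0.0, 7.0, 1.0), (7.0, 7.0, 0.0)])
def test_nfi_endpoints(dev_rm, dev_nm, expected):
    assert nfi(dev_rm, dev_nm) == expected


def test_nfi_rejects_uninformative_null():
    with pytest.raises(ValueError, match="null-model deviance"):
        nfi(1.0, 0.0)


def test_nfi_end_to_end_via_oracle(beef):
    """NFI of one removed edge recomputed through the independent oracle."""
    R = correlation_matrix(beef)
    names = beef.variable_names
    pair = canonical_pair("Outside_humidity", "Preset_temp")
    fit = fit_constrained_mle(R, [pair], beef.n, tolerance=1e-12)
    idx = {nm: i for i, nm in enumerate(names)}
    oracle = logdet_oracle_fit(R.to_numpy(), {(idx[pair[0]], idx[pair[1]])})
    n = beef.n
    dev_oracle = n * (np.linalg.slogdet(oracle)[1] - np.linalg.slogdet(R.to_numpy())[1])
    dev_nm = -n * np.linalg.slogdet(R.to_numpy())[1]
    assert fit.nfi == pytest.approx(1.0 - dev_oracle / dev_nm, abs=1e-8)


# --- backward_eliminate ------------------------------------------------------

def test_no_thresholds_returns_full_model(beef):
    trace = backward_eliminate(beef, pcor_thresholds=())
    assert trace.steps == []
    assert trace.final_model.zero_set == frozenset()
    assert trace.final_fit.nfi == 1.0


@pytest.mark.parametrize("fixture", ["beef", "pork"])
def test_selection_respects_thresholds_and_nfi_guard(fixture, request):
    data = request.getfixturevalue(fixture)
    trace = backward_eliminate(data)
    assert trace.final_fit.nfi >= 0.9
    for step in trace.steps:
        assert abs(step.partial_r) < step.threshold
        if step.decision == "removed":
            assert step.nfi >= 0.9
        else:
            assert step.nfi < 0.9
    # at most one terminal restore per threshold pass
    for threshold in trace.pcor_thresholds:
        restores = [s for s in trace.steps
                    if s.threshold == threshold and s.decision == "restored"]
        assert len(restores) <= 1
    # removed pairs and final zero set agree
    assert set(trace.removed_pairs) == set(trace.final_model.zero_set)
    # edges/zero_set partition all pairs
    names = data.variable_names
    assert trace.final_model.edges | trace.final_model.zero_set == frozenset(all_pairs(names))


def test_trace_is_deterministic(beef):
    t1 = backward_eliminate(beef)
    t2 = backward_eliminate(beef)
    assert t1.to_json() == t2.to_json()


def test_nfi_non_increasing_along_path(pork):
    trace = backward_eliminate(pork)
    removed_nfis = [s.nfi for s in trace.steps if s.decision == "removed"]
    assert all(b <= a + 1e-12 for a, b in zip(removed_nfis, removed_nfis[1:]))


@pytest.mark.parametrize("policy", ["unrestricted", "batch"])
def test_alternative_policies_run_and_respect_guard(beef, policy):
    trace = backward_eliminate(beef, layer_policy=policy)
    assert trace.final_fit.nfi >= 0.9
    assert trace.layer_policy == policy


def test_layered_policy_requires_layers(seasonal):
    with pytest.raises(ValueError, match="layer"):
        backward_eliminate(seasonal, layer_policy="layered")


def test_invalid_configuration_rejected(beef):
    with pytest.raises(ValueError, match="policy"):
        backward_eliminate(beef, layer_policy="sideways")
    with pytest.raises(ValueError, match="thresholds"):
        backward_eliminate(beef, pcor_thresholds=(0.2, 0.1))
    with pytest.raises(ValueError, match="NFI threshold"):
        backward_eliminate(beef, nfi_threshold=0.0)


def test_graph_model_constructors(beef):
    fm = GraphModel.full(tuple(beef.variables))
    nm = GraphModel.null(tuple(beef.variables))
    assert fm.edges == frozenset(all_pairs(beef.variable_names))
    assert nm.edges == frozenset()
    assert len(nm.zero_set) == beef.p * (beef.p - 1) // 2
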