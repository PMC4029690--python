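"""Seven-resistor network forward models and the pairwise inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isfextract import (
    ElectrodeNetwork,
    PairwiseResistances,
    estimate_rb,
    estimator_bias,
    pairwise_approx,
    pairwise_full,
)

# ---------------------------------------------------------------------------
# independent oracle: generic nodal analysis (graph-Laplacian effective
# resistance) of the seven-resistor circuit.  During a pairwise measurement
# the third electrode is switched out, so its longitudinal branch is removed.

_NODES = {"A": 0, "B": 1, "C": 2, "a": 3, "b": 4, "c": 5}


def _edges(net):
    return {
        "r_a": ("A", "a", net.r_a), "r_b": ("B", "b", net.r_b),
        "r_c": ("C", "c", net.r_c), "r_1": ("b", "c", net.r_1),
        "r_2": ("a", "b", net.r_2), "r_3": ("B", "C", net.r_3),
        "r_4": ("A", "B", net.r_4),
    }


def _effective_resistance(edges, u, v):
    lap = np.zeros((6, 6))
    for n1, n2, r in edges:
        i, j = _NODES[n1], _NODES[n2]
        g = 1.0 / r
        lap[i, i] += g
        lap[j, j] += g
        lap[i, j] -= g
        lap[j, i] -= g
    pinv = np.linalg.pinv(lap)
    e = np.zeros(6)
    e[_NODES[u]], e[_NODES[v]] = 1.0, -1.0
    return float(e @ pinv @ e)


def nodal_pairwise(net):
    """Oracle pairwise resistances by Laplacian solve, third electrode open."""
    edges = _edges(net)
    r_ab = _effective_resistance([edges[k] for k in edges if k != "r_c"], "A", "B")
    r_bc = _effective_resistance([edges[k] for k in edges if k != "r_a"], "B", "C")
    r_ac = _effective_resistance([edges[k] for k in edges if k != "r_b"], "A", "C")
    return r_ab, r_bc, r_ac


def random_network(rng, lateral=(1e3, 1e6)):
    r = 10.0 ** rng.uniform(0.5, 3.0, size=5)  # 3.2 Ω … 1 MΩ in kΩ terms
    r34 = 10.0 ** rng.uniform(np.log10(lateral[0]), np.log10(lateral[1]), size=2)
    return ElectrodeNetwork(r_a=r[0], r_b=r[1], r_c=r[2], r_1=r[3], r_2=r[4],
                            r_3=r34[0], r_4=r34[1])


# ---------------------------------------------------------------------------
# forward models

def test_pairwise_full_fixture_values(fixture_net):
    """Two-branch parallel model on the reference network, hand-checked."""
    meas = pairwise_full(fixture_net)
    assert meas.r_ab == pytest.approx(176.817, abs=5e-4)
    assert meas.r_bc == pytest.approx(147.783, abs=5e-4)
    assert meas.r_ac == pytest.approx(227.385, abs=5e-4)


def test_pairwise_full_infinite_laterals_delegates():
    net = ElectrodeNetwork(100, 50, 80, 20, 30)  # lateral paths absent
    meas = pairwise_full(net)
    assert (meas.r_ab, meas.r_bc, meas.r_ac) == (180.0, 150.0, 230.0)
    assert meas == pairwise_approx(net)


def test_pairwise_full_equal_branches_halve():
    """A lateral path equal to its series branch halves the measurement."""
    series_ab = 100 + 30 + 50
    net = ElectrodeNetwork(100, 50, 80, 20, 30, r_3=10000.0, r_4=float(series_ab))
    assert pairwise_full(net).r_ab == pytest.approx(series_ab / 2, rel=1e-12)


@pytest.mark.parametrize("fields, expected", [
    ((100, 50, 80, 20, 30), (180.0, 150.0, 230.0)),
    ((1, 1, 1, 1, 1), (3.0, 3.0, 4.0)),
])
def test_pairwise_approx_series_sums(fields, expected):
    meas = pairwise_approx(ElectrodeNetwork(*fields))
    assert (meas.r_ab, meas.r_bc, meas.r_ac) == expected


def test_mixed_lateral_flags_rejected():
    net = ElectrodeNetwork(100, 50, 80, 20, 30, r_3=1000.0, r_4=None)
    with pytest.raises(ValueError, match="both"):
        pairwise_full(net)


@pytest.mark.parametrize("bad", [
    dict(r_a=-1.0), dict(r_b=0.0), dict(r_1=float("nan")), dict(r_3=float("inf")),
])
def test_invalid_resistances_rejected(bad):
    fields = dict(r_a=100.0, r_b=50.0, r_c=80.0, r_1=20.0, r_2=30.0)
    fields.update(bad)
    with pytest.raises(ValueError):
        ElectrodeNetwork(**fields)


# ---------------------------------------------------------------------------
# inversion

@pytest.mark.parametrize("triple, expected, valid", [
    ((180.0, 150.0, 230.0), 50.0, True),
    ((176.817, 147.783, 227.385), 48.6075, True),
    ((10.0, 10.0, 30.0), -5.0, False),
])
def test_estimate_rb(triple, expected, valid):
    est = estimate_rb(PairwiseResistances(*triple))
    assert est.r_b_hat == pytest.approx(expected, abs=1e-9)
    assert est.valid is valid
    assert est.valid == (est.r_b_hat > 0)


def test_estimator_bias_fixture(fixture_net):
    """Finite lateral paths shunt current and bias the inversion low."""
    assert estimator_bias(fixture_net) == pytest.approx(-1.392, abs=5e-4)


def test_estimator_bias_zero_without_laterals():
    assert estimator_bias(ElectrodeNetwork(100, 50, 80, 20, 30)) == 0.0


def test_estimator_bias_shrinks_with_larger_laterals(fixture_net):
    biases = []
    for r34 in (1e2, 1e3, 1e4, 1e5):
        net = ElectrodeNetwork(100, 50, 80, 20, 30, r34, r34)
        biases.append(abs(estimator_bias(net)))
    assert all(b1 > b2 for b1, b2 in zip(biases, biases[1:]))
    assert abs(estimator_bias(ElectrodeNetwork(100, 50, 80, 20, 30, 23000.0, 23000.0))) \
        < abs(estimator_bias(fixture_net))


# ---------------------------------------------------------------------------
# properties

@settings(max_examples=200, derandomize=True)
@given(st.lists(st.floats(min_value=0.5, max_value=3.0), min_size=5, max_size=5))
def test_approx_inversion_exact(log_rs):
    """Series-sum forward model composed with the inversion recovers r_b."""
    r = [10.0 ** v for v in log_rs]
    net = ElectrodeNetwork(*r)
    est = estimate_rb(pairwise_approx(net))
    assert est.valid
    assert est.r_b_hat == pytest.approx(net.r_b, rel=1e-11)


@settings(max_examples=100, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_full_model_shunting(seed):
    """Every parallel-path output is below the corresponding series sum."""
    net = random_network(np.random.default_rng(seed))
    full, approx = pairwise_full(net), pairwise_approx(net)
    assert full.r_ab < approx.r_ab
    assert full.r_bc < approx.r_bc
    assert full.r_ac < approx.r_ac
    # and below the lateral branch itself
    assert full.r_ab < net.r_4
    assert full.r_bc < net.r_3


def test_full_model_matches_nodal_oracle():
    """Closed-form pairwise model vs independent Laplacian circuit solver."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        net = random_network(rng)
        meas = pairwise_full(net)
        r_ab, r_bc, r_ac = nodal_pairwise(net)
        assert meas.r_ab == pytest.approx(r_ab, rel=1e-9)
        assert meas.r_bc == pytest.approx(r_bc, rel=1e-9)
        assert meas.r_ac == pytest.approx(r_ac, rel=1e-9)


@pytest.mark.parametrize("scale", [0.1, 1.0, 10.0])
def test_bias_small_once_laterals_dominate(scale):
    """|bias| < 5% of r_b once the lateral paths are 100× the series sums.

    Checked on the reference network and uniform rescalings of it; for
    strongly asymmetric branch sums the residual bias is dominated by the
    (mismatch)²/lateral term instead and this bound does not apply.
    """
    series_max = scale * max(100 + 30 + 50, 50 + 20 + 80, 100 + 30 + 20 + 80)
    net = ElectrodeNetwork(100 * scale, 50 * scale, 80 * scale,
                           20 * scale, 30 * scale,
                           100.0 * series_max, 100.0 * series_max)
    assert abs(estimator_bias(net)) < 0.05 * net.r_b
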