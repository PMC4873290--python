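import math

import numpy as np
import pytest

import shelfweb as sw
from shelfweb.balance import FlowNetwork
from shelfweb.network import (
    NetworkError,
    ascendency,
    attribute_report,
    connectance,
    finn_indices,
    summary_statistics,
    system_omnivory,
)


def make_network(flows, imports, exports, respiration, categories=None):
    n = len(imports)
    names = [f"n{i}" for i in range(n)]
    cats = categories or ["consumer"] * n
    return FlowNetwork(names, cats, np.asarray(flows, dtype=float),
                       np.asarray(imports, dtype=float),
                       np.asarray(exports, dtype=float),
                       np.asarray(respiration, dtype=float))


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def test_summary_statistics_production_blocks(chain_model):
    net = sw.build_flow_network(chain_model)
    rep = summary_statistics(chain_model, net)
    assert rep.sum_of_production == pytest.approx(10 * 5 + 1 * 2 + 0.2 * 1)
    assert rep.total_net_pp == pytest.approx(50.0)
    assert rep.total_biomass_excl_detritus == pytest.approx(11.2)
    assert rep.total_catch == pytest.approx(0.1)


def test_tst_equals_componentwise_recomputation(synthetic_model):
    net = sw.build_flow_network(synthetic_model)
    consumers = np.array([c == "consumer" for c in net.categories])
    detritus = np.array([c == "detritus" for c in net.categories])
    inflow = net.flows.sum(axis=0) + net.imports
    expected = (inflow[consumers].sum() + net.exports.sum()
                + net.respiration.sum() + inflow[detritus].sum())
    assert net.tst() == pytest.approx(expected, rel=1e-12)


def test_empty_fishery_zero_catch(chain_inputs):
    for g in chain_inputs.groups:
        g.landings = 0.0
    model = sw.solve_balance(chain_inputs)
    rep = summary_statistics(model, sw.build_flow_network(model))
    assert rep.total_catch == 0.0


# ---------------------------------------------------------------------------
# connectance & system omnivory
# ---------------------------------------------------------------------------

def test_connectance_linear_chain_counts_links():
    names = ["a", "b", "c", "d", "det"]
    cats = ["producer", "consumer", "consumer", "consumer", "detritus"]
    dc = np.zeros((5, 5))
    dc[0, 1] = dc[1, 2] = dc[2, 3] = 1.0
    assert connectance(sw.DietMatrix(names, dc), cats) == pytest.approx(
        3 / 12)


def test_connectance_saturated_web():
    names = ["p", "c1", "c2", "c3", "det"]
    cats = ["producer", "consumer", "consumer", "consumer", "detritus"]
    dc = np.zeros((5, 5))
    for j in (1, 2, 3):
        others = [i for i in (0, 1, 2, 3) if i != j]
        dc[others, j] = 1 / 3
    # all 12 ordered non-self pairs among 4 living groups realized except
    # links into the producer; count = 3 predators * 3 prey each = 9
    assert connectance(sw.DietMatrix(names, dc), cats) == pytest.approx(
        9 / 12)


def test_connectance_excludes_cannibalism_by_default():
    names = ["p", "c", "det"]
    cats = ["producer", "consumer", "detritus"]
    dc = np.zeros((3, 3))
    dc[0, 1] = 0.7
    dc[1, 1] = 0.3
    diet = sw.DietMatrix(names, dc)
    assert connectance(diet, cats) == pytest.approx(1 / 2)
    assert connectance(diet, cats, include_cannibalism=True) == pytest.approx(
        2 / 2)


def test_connectance_needs_two_living_groups():
    names = ["p", "det"]
    with pytest.raises(NetworkError):
        connectance(sw.DietMatrix(names, np.zeros((2, 2))),
                    ["producer", "detritus"])


def test_system_omnivory_constant_field(chain_model):
    oi = np.array([0.0, 0.25, 0.25, 0.0])
    assert system_omnivory(oi, chain_model) == pytest.approx(0.25)


def test_system_omnivory_zero_for_single_prey_consumers(synthetic_model):
    rep = sw.trophic_report(synthetic_model)
    soi = system_omnivory(rep.oi, synthetic_model)
    assert soi >= 0
    zero_oi = np.zeros_like(rep.oi)
    assert system_omnivory(zero_oi, synthetic_model) == 0.0


# ---------------------------------------------------------------------------
# ascendency
# ---------------------------------------------------------------------------

def test_chain_network_is_fully_determinate():
    # import -> n0 -> n1 -> export: one inflow and one outflow everywhere
    flows = [[0.0, 1.0], [0.0, 0.0]]
    net = make_network(flows, imports=[1.0, 0.0], exports=[0.0, 1.0],
                       respiration=[0.0, 0.0])
    asc = ascendency(net)
    assert asc["ascendency_pct"] == pytest.approx(100.0)
    assert asc["overhead_pct"] == pytest.approx(0.0, abs=1e-9)


def test_ascendency_bounded_by_capacity_and_partition(synthetic_model):
    net = sw.build_flow_network(synthetic_model)
    asc = ascendency(net)
    assert asc["ascendency"] <= asc["capacity"] + 1e-9
    assert asc["ascendency_pct"] + asc["overhead_pct"] == pytest.approx(
        100.0, abs=1e-6)


def test_ascendency_percentages_scale_free(synthetic_model):
    net = sw.build_flow_network(synthetic_model)
    doubled = FlowNetwork(net.names, net.categories, 2 * net.flows,
                          2 * net.imports, 2 * net.exports,
                          2 * net.respiration)
    a, b = ascendency(net), ascendency(doubled)
    assert b["ascendency_pct"] == pytest.approx(a["ascendency_pct"])
    # both A and C are homogeneous of degree one in the flows
    assert b["capacity"] == pytest.approx(2 * a["capacity"], rel=1e-12)
    assert b["ascendency"] == pytest.approx(2 * a["ascendency"], rel=1e-12)


def test_ascendency_branch_network_direct_summation_oracle():
    """4-compartment network with a branch point, checked against an
    explicit hand-expanded double sum over the extended matrix."""
    flows = np.zeros((4, 4))
    flows[0, 1] = 2.0
    flows[0, 2] = 1.0
    flows[1, 3] = 2.0
    flows[2, 3] = 1.0
    net = make_network(flows, imports=[3.0, 0, 0, 0],
                       exports=[0, 0, 0, 2.0], respiration=[0, 0, 0, 1.0])

    # independent oracle: loop over the bordered matrix
    n = 4
    T = np.zeros((n + 1, n + 2))
    T[:n, :n] = flows
    T[n, :n] = net.imports
    T[:n, n] = net.exports
    T[:n, n + 1] = net.respiration
    total = T.sum()
    A = C = 0.0
    for i in range(n + 1):
        for j in range(n + 2):
            t = T[i, j]
            if t > 0:
                A += t * math.log(t * total / (T[i, :].sum() * T[:, j].sum()))
                C -= t * math.log(t / total)
    asc = ascendency(net)
    assert asc["ascendency"] == pytest.approx(A, rel=1e-12)
    assert asc["capacity"] == pytest.approx(C, rel=1e-12)


def test_zero_total_flow_is_error():
    net = make_network(np.zeros((2, 2)), [0, 0], [0, 0], [0, 0])
    with pytest.raises(NetworkError):
        ascendency(net)


# ---------------------------------------------------------------------------
# Finn cycling
# ---------------------------------------------------------------------------

def test_acyclic_web_has_zero_cycling(synthetic_model):
    # generator diets point strictly down trophic bands, and nothing flows
    # back out of detritus in this web unless a consumer eats it
    net = sw.build_flow_network(synthetic_model)
    res = finn_indices(net)
    if not net.flows[net.names.index("detritus_1"), :].any():
        assert res.finn_cycling_pct == pytest.approx(0.0, abs=1e-10)


def test_acyclic_feedforward_zero_cycling():
    flows = np.zeros((3, 3))
    flows[0, 1] = 1.0
    flows[1, 2] = 1.0
    net = make_network(flows, [1.0, 0, 0], [0, 0, 1.0], [0, 0, 0])
    res = finn_indices(net)
    assert res.throughput_cycled == 0.0
    assert res.finn_cycling_pct == 0.0


def test_two_compartment_loop_matches_geometric_series():
    """import→A (1.0), A→B (1.0), B→A (0.5), B→export (0.5): the cycled
    fraction of each compartment's inflow is the geometric series of the
    loop gain g = 1 * (0.5/1.5) = 1/3."""
    flows = np.array([[0.0, 1.0], [0.5, 0.0]])
    net = make_network(flows, imports=[1.0, 0.0], exports=[0.0, 0.5],
                       respiration=[0.0, 0.0])
    res = finn_indices(net)
    g = (1.0 / 1.0) * (0.5 / 1.5)  # G[A,B] * G[B,A]
    # L_ii = sum_k g^k = 1/(1-g), so (L_ii - 1)/L_ii = g for both nodes and
    # cycled_i = g * inflow_i
    assert res.throughput_cycled == pytest.approx(g * 1.5 + g * 1.0,
                                                  rel=1e-10)


def test_mean_path_length_definition(synthetic_model):
    net = sw.build_flow_network(synthetic_model)
    res = finn_indices(net)
    assert res.mean_path_length == pytest.approx(
        net.tst() / (net.exports.sum() + net.respiration.sum()))


def test_path_enumeration_oracle_small_web():
    """On a ≤5-compartment web, cycled throughput from the Leontief inverse
    must match summing powers of the fractional-flow matrix."""
    rng = np.random.default_rng(5)
    flows = rng.uniform(0, 1, size=(4, 4))
    np.fill_diagonal(flows, 0.0)
    flows *= 0.4  # keep the loop gains well under one
    imports = rng.uniform(1.0, 2.0, 4)
    exports = np.zeros(4)
    inflow = flows.sum(axis=0) + imports
    exports = inflow - flows.sum(axis=1)  # balance each compartment
    net = make_network(flows, imports, exports, np.zeros(4))
    res = finn_indices(net)

    G = flows / inflow[np.newaxis, :]
    L = np.eye(4)
    P = np.eye(4)
    for _ in range(2000):  # geometric series of G^T
        P = P @ G.T
        L += P
    diag = np.diag(L)
    expected = (((diag - 1) / diag) * inflow).sum()
    assert res.throughput_cycled == pytest.approx(expected, abs=1e-8)


def test_removing_zero_flow_link_changes_nothing(synthetic_model):
    net = sw.build_flow_network(synthetic_model)
    res = finn_indices(net)
    asc = ascendency(net)
    # explicit zero entries are already absent from every sum
    zeroed = FlowNetwork(net.names, net.categories, net.flows.copy(),
                         net.imports, net.exports, net.respiration)
    zeroed.flows[zeroed.flows < 0] = 0.0
    assert finn_indices(zeroed).finn_cycling_pct == res.finn_cycling_pct
    assert ascendency(zeroed)["ascendency_pct"] == asc["ascendency_pct"]


def test_attribute_report_complete(synthetic_model):
    net = sw.build_flow_network(synthetic_model)
    rep = attribute_report(synthetic_model, net)
    vals = rep.as_dict()
    assert all(v is not None for v in vals.values()), vals
    assert vals["ascendency_pct"] + vals["overhead_pct"] == pytest.approx(100)
    assert 0 <= vals["finn_cycling_pct"] < 100
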