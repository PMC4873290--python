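import numpy as np
import pytest
from scipy.optimize import fsolve

import shelfweb as sw
from shelfweb.balance import BalanceError

from conftest import make_chain_inputs


def test_chain_ecotrophic_efficiencies_hand_solved(chain_model):
    ee = [g.ee for g in chain_model.groups if g.is_living]
    assert ee == pytest.approx([0.2, 0.5, 0.5], abs=1e-12)


def test_group_without_predators_or_catch_has_zero_ee():
    inputs = make_chain_inputs(landings=0.0)
    model = sw.solve_balance(inputs)
    assert model.group("c2").ee == 0.0


def test_unknown_biomass_recovered_from_ee():
    """Fixing EE at the solved value and withholding one biomass must give
    back the original biomass through the linear system."""
    base = sw.solve_balance(make_chain_inputs())
    for name in ("prod", "c1", "c2"):
        inputs = make_chain_inputs()
        for g in inputs.groups:
            if g.is_living:
                g.ee = base.group(g.name).ee
        target = inputs.groups[inputs.index(name)]
        truth = target.biomass
        target.biomass = None
        resolved = sw.solve_balance(inputs)
        assert resolved.group(name).biomass == pytest.approx(truth, rel=1e-8)


def test_simultaneous_unknown_biomasses(synthetic_web):
    """Withholding several biomasses at once (EE fixed at truth) exercises
    the genuinely coupled linear system."""
    base = sw.solve_balance(synthetic_web.inputs)
    inputs = synthetic_web.inputs.permuted(range(synthetic_web.inputs.n))
    withheld = [g.name for g in inputs.groups if g.is_consumer][:5]
    for g in inputs.groups:
        if g.is_living:
            g.ee = base.group(g.name).ee
        if g.name in withheld:
            g.biomass = None
    resolved = sw.solve_balance(inputs)
    for name in withheld:
        assert resolved.group(name).biomass == pytest.approx(
            base.group(name).biomass, rel=1e-8)


def test_residuals_vanish_for_solved_model(chain_model):
    assert np.abs(sw.balance_residuals(chain_model)).max() < 1e-12


def test_residual_linear_in_ee_perturbation(chain_model):
    g = chain_model.group("c1")
    g.ee += 0.1
    res = sw.balance_residuals(chain_model)
    assert res[chain_model.index("c1")] == pytest.approx(
        0.1 * g.biomass * g.pb)


def test_brute_force_root_find_agrees_on_small_webs():
    """On webs of ≤ 6 groups the solver output must coincide with a
    nonlinear root-find of the raw balance equations."""
    for seed in range(5):
        web = sw.generate_foodweb(sw.WebGenConfig(
            n_groups=6, n_producers=1, n_bands=2, seed=seed))
        model = sw.solve_balance(web.inputs)
        living = [g for g in model.groups if g.is_living]
        DC = model.diet.values
        names = model.names

        def residual(ee):
            vals = dict(zip((g.name for g in living), ee))
            out = []
            for g in living:
                i = names.index(g.name)
                pred = sum(
                    h.biomass * h.qb * DC[i, names.index(h.name)]
                    for h in model.groups if h.is_consumer)
                out.append(g.biomass * g.pb * vals[g.name]
                           - pred - g.landings)
            return out

        root = fsolve(residual, np.full(len(living), 0.5), full_output=False)
        assert np.allclose(root, [g.ee for g in living], atol=1e-8)


def test_scale_equivariance_of_dimensionless_outputs(synthetic_web):
    """Multiplying all biomasses and landings by c leaves EE, TL and every
    dimensionless index unchanged."""
    c = 3.7
    base = sw.solve_balance(synthetic_web.inputs)
    scaled_inputs = synthetic_web.inputs.permuted(
        range(synthetic_web.inputs.n))
    for g in scaled_inputs.groups:
        if g.biomass is not None:
            g.biomass *= c
        g.landings *= c
    scaled = sw.solve_balance(scaled_inputs)
    for name in base.names:
        if base.group(name).is_living:
            assert scaled.group(name).ee == pytest.approx(
                base.group(name).ee, rel=1e-9)

    rep_a = sw.trophic_report(base)
    rep_b = sw.trophic_report(scaled)
    assert rep_b.tl == pytest.approx(rep_a.tl, rel=1e-9)
    assert rep_b.oi == pytest.approx(rep_a.oi, rel=1e-9)

    from shelfweb.network import attribute_report
    net_a = sw.build_flow_network(base)
    net_b = sw.build_flow_network(scaled)
    at_a = attribute_report(base, net_a)
    at_b = attribute_report(scaled, net_b)
    # system omnivory is excluded: its log-consumption weights change with
    # absolute flow magnitude by definition
    for key in ("pp_over_respiration", "pp_over_biomass", "connectance",
                "ascendency_pct", "overhead_pct",
                "finn_cycling_pct", "finn_mean_path_length"):
        assert getattr(at_b, key) == pytest.approx(getattr(at_a, key),
                                                   rel=1e-9), key


def test_singular_biomass_system_names_groups():
    # two consumers with identical balance equations and zero production
    # cannot be separated
    groups = [
        sw.GroupInput("prod", "producer", biomass=10, pb=5, ee=0.5),
        sw.GroupInput("c1", "consumer", pb=0.0, qb=10, ee=0.0),
        sw.GroupInput("det", "detritus", biomass=1.0),
    ]
    dc = np.zeros((3, 3))
    dc[0, 1] = 1.0
    inputs = sw.EcopathInputs(groups, sw.DietMatrix(["prod", "c1", "det"], dc))
    with pytest.raises(BalanceError, match="c1"):
        sw.solve_balance(inputs)


def test_zero_production_with_demand_is_an_error():
    inputs = make_chain_inputs()
    inputs.groups[1].pb = 0.0  # c1 produces nothing but is eaten by c2
    with pytest.raises(BalanceError, match="zero production"):
        sw.solve_balance(inputs)


def test_ee_above_one_flagged_not_clipped():
    inputs = make_chain_inputs()
    inputs.groups[2].landings = 1.0  # catch five times c2's production
    model = sw.solve_balance(inputs)
    assert model.group("c2").ee == pytest.approx(5.0)
    assert any("EE" in w.message and w.where == "c2" for w in model.warnings)
    assert not model.balanced


def test_flow_network_respiration_and_balance(chain_model):
    net = sw.build_flow_network(chain_model)
    # consumer1: Q(1-GS) - P = 1*10*0.8 - 1*2
    assert net.respiration[chain_model.index("c1")] == pytest.approx(6.0)
    assert net.respiration[chain_model.index("prod")] == 0.0
    assert np.abs(net.balance_check()).max() < 1e-9
    assert (net.flows >= 0).all()


def test_negative_respiration_rejected():
    groups = [
        sw.GroupInput("prod", "producer", biomass=100, pb=5),
        sw.GroupInput("c1", "consumer", biomass=1, pb=9, qb=10),
        sw.GroupInput("det", "detritus", biomass=1.0),
    ]
    dc = np.zeros((3, 3))
    dc[0, 1] = 1.0
    inputs = sw.EcopathInputs(groups, sw.DietMatrix(["prod", "c1", "det"], dc))
    model = sw.solve_balance(inputs)
    with pytest.raises(BalanceError, match="negative respiration"):
        sw.build_flow_network(model)


def test_synthetic_web_residuals_tiny(synthetic_model):
    assert np.abs(sw.balance_residuals(synthetic_model)).max() < 1e-9
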