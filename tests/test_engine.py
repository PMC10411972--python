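"""Engine: discretization geometry, analytic passive limits, solver
conservation, synapse placement statistics and spike detection."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.linalg import expm

from msnsim import engine as en
from msnsim import morphology as mm
from msnsim.engine import (
    CurrentStep,
    IntegrationMethod,
    SimulationConfig,
    Trace,
    VoltageClamp,
)
from msnsim.biophysics import SynapseKind

from conftest import random_tree


# -- discretization -----------------------------------------------------------


def test_sphere_discretization(passive_sphere, fixtures, wt_spec):
    assert passive_sphere.n_comp == 1  # no Na channels -> no AIS appended
    r_um = 10.0
    assert passive_sphere.total_area_cm2() == pytest.approx(
        4 * math.pi * r_um**2 * 1e-8
    )
    with_na = en.discretize(fixtures["sphere"], wt_spec, 10.0)
    assert (with_na.kind == en.KIND_AXON).sum() == 5  # 50 µm AIS in 10 µm pieces
    ais_area = math.pi * 0.5 * 50.0 * 1e-8
    assert with_na.area_cm2[with_na.kind == en.KIND_AXON].sum() == pytest.approx(
        ais_area
    )


def test_stick_compartment_count(fixtures, passive_spec):
    model = en.discretize(fixtures["stick100"], passive_spec, 10.0)
    assert (model.kind == en.KIND_DEND).sum() == 10
    assert np.all(model.length_um[model.kind == en.KIND_DEND] <= 10.0 + 1e-9)


def test_area_conserved_against_frustum_oracle(passive_spec):
    for seed in range(10):
        tree = random_tree(seed)
        model = en.discretize(tree, passive_spec, 7.0)
        # independent frustum-area sum straight from the morphology
        index = {n.id: n for n in tree.nodes}
        soma_r = next(n.radius for n in tree.nodes if n.kind is mm.NodeKind.soma)
        expected = 4 * math.pi * soma_r**2 * 1e-8
        for child in tree.nodes:
            if child.parent_id == -1 or child.kind is mm.NodeKind.soma:
                continue
            p = index[child.parent_id]
            length = float(np.linalg.norm(child.xyz - p.xyz))
            r0 = child.radius if p.kind is mm.NodeKind.soma else p.radius
            r1 = child.radius
            slant = math.sqrt(length**2 + (r1 - r0) ** 2)
            expected += math.pi * (r0 + r1) * slant * 1e-8
        assert model.total_area_cm2() == pytest.approx(expected, rel=1e-6)


# -- analytic passive limits --------------------------------------------------


def test_rc_charging_matches_closed_form(passive_sphere, passive_spec):
    p = passive_spec.passive
    area = passive_sphere.total_area_cm2()
    r_in = 1e-6 / (p.g_leak_s_cm2 * area)  # MΩ
    tau = p.cm_uf_cm2 / p.g_leak_s_cm2 * 1e-3  # ms
    cfg = SimulationConfig(dt_ms=0.025, duration_ms=1400.0, v_init_mv=p.e_leak_mv)
    trace = en.integrate(
        passive_sphere, cfg, stimuli=[CurrentStep(0, 20.0, 100.0, 1300.0)]
    )[0]
    t = trace.times()
    analytic = p.e_leak_mv + 0.02 * r_in * (1 - np.exp(-np.clip(t - 100.0, 0, None) / tau))
    assert np.max(np.abs(trace.values - analytic)) < 0.1  # mV
    # steady-state input resistance within 1%
    deflection = trace.values[-1] - p.e_leak_mv
    assert deflection / 0.02 == pytest.approx(r_in, rel=0.01)


def test_no_stimulus_rests_at_leak_reversal(passive_sphere, passive_spec):
    # membrane time constant is 125 ms; run long enough to fully relax
    cfg = SimulationConfig(dt_ms=0.05, duration_ms=1500.0, v_init_mv=-60.0)
    trace = en.integrate(passive_sphere, cfg)[0]
    assert trace.values[-1] == pytest.approx(passive_spec.passive.e_leak_mv, abs=1e-3)


def test_dt_halving_convergence(passive_sphere):
    final = {}
    for dt in (0.05, 0.025):
        cfg = SimulationConfig(dt_ms=dt, duration_ms=300.0, v_init_mv=-70.0)
        trace = en.integrate(
            passive_sphere, cfg, stimuli=[CurrentStep(0, 20.0, 50.0, 250.0)]
        )[0]
        final[dt] = trace.values[-1]
    assert abs(final[0.05] - final[0.025]) < 0.05  # mV


def _two_comp_model(passive_spec):
    nodes = [
        mm.MorphNode(1, -1, mm.NodeKind.soma, 0.0, 0.0, 0.0, 8.0),
        mm.MorphNode(2, 1, mm.NodeKind.dendrite, 30.0, 0.0, 0.0, 1.0),
    ]
    return en.discretize(mm.Morphology(nodes), passive_spec, 50.0)


def test_two_compartment_matches_eigen_oracle(passive_spec):
    """Coupled two-compartment passive ODE solved by matrix exponential."""
    model = _two_comp_model(passive_spec)
    assert model.n_comp == 2
    cm = model.capacitance_nf()
    gl = model.leak_us()
    gax = model.axial_us()[1]
    e = passive_spec.passive.e_leak_mv
    i_inj = 0.02  # nA at the soma

    a_mat = np.array(
        [
            [-(gl[0] + gax) / cm[0], gax / cm[0]],
            [gax / cm[1], -(gl[1] + gax) / cm[1]],
        ]
    )
    b = np.array([(gl[0] * e + i_inj) / cm[0], gl[1] * e / cm[1]])
    v0 = np.array([e, e])
    t_end = 120.0
    v_inf = np.linalg.solve(a_mat, -b)
    v_exact = v_inf + expm(a_mat * t_end) @ (v0 - v_inf)

    cfg = SimulationConfig(
        dt_ms=0.025,
        duration_ms=t_end,
        v_init_mv=e,
        method=IntegrationMethod.crank_nicolson,
    )
    model2 = dataclasses.replace(model, recording_sites=[0, 1])
    trace = en.integrate(model2, cfg, stimuli=[CurrentStep(0, 20.0, 0.0, t_end)])
    v_num = np.array([trace[0].values[-1], trace[1].values[-1]])
    deflection = np.abs(v_exact - e).max()
    assert np.max(np.abs(v_num - v_exact)) < 0.01 * deflection


def test_backward_euler_residual_conservation(passive_spec):
    """The solved voltages satisfy the discrete branched-cable balance
    (capacitive + ionic = axial + injected) to solver precision."""
    tree = random_tree(3)
    model = en.discretize(tree, passive_spec, 10.0)
    model = dataclasses.replace(model, recording_sites=list(range(model.n_comp)))
    dt = 0.05
    cfg = SimulationConfig(dt_ms=dt, duration_ms=20.0, v_init_mv=-70.0)
    res = en.integrate(model, cfg, stimuli=[CurrentStep(0, 50.0, 5.0, 10.0)])
    v = np.array([res[i].values for i in range(model.n_comp)])
    cm, gl, gax = model.capacitance_nf(), model.leak_us(), model.axial_us()
    e = passive_spec.passive.e_leak_mv
    n_steps = v.shape[1] - 1
    for step in (150, 250):  # mid-stimulus and after
        vn, vn1 = v[:, step], v[:, step + 1]
        resid = cm * (vn1 - vn) / dt + gl * (vn1 - e)
        for i in range(1, model.n_comp):
            p = model.parent[i]
            flow = gax[i] * (vn1[p] - vn1[i])
            resid[i] -= flow
            resid[p] += flow
        on = int(round(5.0 / dt)) <= step < int(round(15.0 / dt))
        if on:
            resid[0] -= 0.05
        assert np.max(np.abs(resid)) < 1e-8  # nA


def test_integration_is_bitwise_deterministic(wt_model):
    cfg = SimulationConfig(dt_ms=0.05, duration_ms=300.0)
    sim = dataclasses.replace(wt_model, synapses=[])
    site = en.place_synapses(sim, 5, SynapseKind.AMPA, 11)
    for s in site:
        sim.attach_synapse(s, sim.spec.synapses[SynapseKind.AMPA], [50.0, 120.0])
    a = en.integrate(sim, cfg, stimuli=[CurrentStep(0, 60.0, 20.0, 250.0)])[0]
    b = en.integrate(sim, cfg, stimuli=[CurrentStep(0, 60.0, 20.0, 250.0)])[0]
    assert np.array_equal(a.values, b.values)


# -- synapse placement --------------------------------------------------------


def test_place_synapses_count_and_determinism(wt_model):
    sites = en.place_synapses(wt_model, 100, SynapseKind.AMPA, 7)
    assert len(sites) == 100
    assert np.array_equal(sites, en.place_synapses(wt_model, 100, SynapseKind.AMPA, 7))
    dend = set(wt_model.dendritic.tolist())
    assert all(int(s) in dend for s in sites)


def test_place_synapses_uniform_per_length(passive_spec):
    # two equal 100 µm branches from the soma
    nodes = [mm.MorphNode(1, -1, mm.NodeKind.soma, 0.0, 0.0, 0.0, 7.0)]
    for k, direction in enumerate([(1.0, 0, 0), (-1.0, 0, 0)]):
        parent = 1
        for i in range(1, 11):
            nodes.append(
                mm.MorphNode(
                    len(nodes) + 1,
                    parent,
                    mm.NodeKind.dendrite,
                    direction[0] * 10.0 * i,
                    0.0,
                    0.0,
                    0.5,
                )
            )
            parent = len(nodes)
    model = en.discretize(mm.Morphology(nodes), passive_spec, 10.0)
    sites = en.place_synapses(model, 10_000, SynapseKind.AMPA, 3)
    # branch membership via compartment index split (branch 1 discretized first)
    dend = model.dendritic
    first_branch = dend[: len(dend) // 2]
    n_first = np.isin(sites, first_branch).sum()
    sigma = math.sqrt(10_000 * 0.5 * 0.5)
    assert abs(n_first - 5000) < 4 * sigma


def test_place_synapses_requires_dendrites(fixtures, passive_spec):
    model = en.discretize(fixtures["sphere"], passive_spec, 10.0)
    with pytest.raises(en.EngineError):
        en.place_synapses(model, 10, SynapseKind.AMPA, 0)


# -- spike detection ----------------------------------------------------------


def test_detect_spikes_flat_and_pulses():
    dt = 0.1
    flat = Trace(0.0, dt, np.full(5000, -70.0), "mV")
    assert len(en.detect_spikes(flat, 0.0)) == 0

    v = np.full(10000, -70.0)
    for k in range(5):
        v[1000 + 1800 * k : 1010 + 1800 * k] = 10.0
    pulses = Trace(0.0, dt, v, "mV")
    assert len(en.detect_spikes(pulses, 0.0, refractory_ms=2.0)) == 5


def test_detect_spikes_sinusoid_counts_upward_crossings():
    dt = 0.1
    t = np.arange(0, 1000.0, dt)
    period = 50.0  # ms >> refractory
    v = -40.0 + 45.0 * np.sin(2 * np.pi * t / period)
    trace = Trace(0.0, dt, v, "mV")
    k = int(1000.0 / period)
    assert len(en.detect_spikes(trace, 0.0, refractory_ms=2.0)) == k


def test_clamp_records_synaptic_current(passive_sphere, wt_spec):
    """Ideal-clamp limit: a somatic synapse produces an electrode current
    with peak ~ gpeak * driving force."""
    spec = wt_spec.synapses[SynapseKind.AMPA]
    sim = dataclasses.replace(passive_sphere, synapses=[])
    sim.attach_synapse(0, spec, [20.0])
    cfg = SimulationConfig(dt_ms=0.025, duration_ms=60.0, v_init_mv=-70.0)
    current = en.integrate(sim, cfg, clamp=VoltageClamp(0, -70.0))["clamp"]
    base = current.values[int(15 / 0.025) : int(20 / 0.025)].mean()
    peak = (current.values - base).min()  # inward negative
    expected = -spec.gpeak_us * (0.0 - (-70.0)) * 1e3  # pA
    assert peak == pytest.approx(expected, rel=0.05)
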