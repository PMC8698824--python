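"""ODE simulation, trace properties, normalization and readout calls."""

from dataclasses import replace

import numpy as np
import pytest

from dzmatrix import (
    BOOLEAN_GRID,
    DesignConstraints,
    KineticParams,
    ReadoutConfig,
    SimulationGrid,
    StemConfig,
    THREE_PRONGED_GRID,
    build_network,
    call_boolean,
    call_weighted,
    compile_system,
    design_four_pronged,
    normalize,
    simulate,
)
from dzmatrix.kinetics_sim import conservation_residual
from dzmatrix.matrix_compiler import ConcentrationConfig, \
    compile_single_three_pronged

FAST = SimulationGrid(4.0, 75)  # 300 min; enough to saturate positives


def _single_run(lib, aux1, aux2, params, grid=FAST, conc=None):
    M = [[1 if aux1 else 0]]
    X = [[1 if aux2 else 0]]
    sys = compile_system(M, X, conc=conc, lib=lib)
    return simulate(build_network(sys, params), grid)


def test_no_reactions_means_constant_traces(matlib22):
    sys = compile_system(np.zeros((2, 2), int), np.zeros((2, 1), int),
                         lib=matlib22)
    net = build_network(sys, KineticParams(k_cat=0.0))
    net.reactions = []
    tr = simulate(net, SimulationGrid(4.0, 10))
    for trace in tr.species_traces.values():
        assert np.allclose(trace, trace[0])


def test_default_four_pronged_positive_crosses_threshold(lib4, params,
                                                         readout):
    tr = _single_run(lib4, True, True, params, grid=BOOLEAN_GRID)
    total_sub = 0.3e-6
    assert tr.endpoint("FAM") > readout.boolean_threshold * total_sub
    # in fact nearly all substrate is cleaved at the standard horizon
    assert tr.endpoint("FAM") == pytest.approx(total_sub, rel=1e-3)


def test_missing_auxiliary_gives_exact_zero_without_leak(lib4, params):
    # k_leak = 0: no cleavage channel exists at all
    for aux1, aux2 in ((True, False), (False, True), (False, False)):
        tr = _single_run(lib4, aux1, aux2, params)
        assert np.all(tr.channels["FAM"] == 0.0)


def test_endpoint_ordering_both_one_none(lib4):
    params = KineticParams(k_leak=2e-5)
    both = _single_run(lib4, True, True, params).endpoint("FAM")
    one_a = _single_run(lib4, True, False, params).endpoint("FAM")
    one_b = _single_run(lib4, False, True, params).endpoint("FAM")
    none = _single_run(lib4, False, False, params).endpoint("FAM")
    assert both > one_a > none
    assert both > one_b > none
    assert none == 0.0  # no one-armed complex can even form


def test_three_pronged_leak_without_auxiliary(lib3):
    """A mid-length S2 leaks slowly without the auxiliary when k_leak>0."""
    cfg = replace(StemConfig.three_pronged_default(), s2=5)
    from dzmatrix import design_three_pronged
    lib = design_three_pronged(DesignConstraints(stem_config=cfg, seed=4))
    sys = compile_single_three_pronged(lib, aux_present=False)
    tr = simulate(build_network(sys, KineticParams(k_leak=2e-5)),
                  THREE_PRONGED_GRID)
    assert tr.endpoint("FAM") > 0.0
    with_zero_leak = simulate(build_network(sys, KineticParams()),
                              THREE_PRONGED_GRID)
    assert with_zero_leak.endpoint("FAM") == 0.0


def test_cleaved_traces_are_non_negative_and_non_decreasing(lib4, params):
    tr = _single_run(lib4, True, True, params)
    v = tr.channels["FAM"]
    assert np.all(v >= 0)
    assert np.all(np.diff(v) >= -1e-13)


def test_strand_mass_conservation_along_trajectory(matlib22, params):
    sys = compile_system([[1, 1], [0, 1]], [[1], [1]], lib=matlib22)
    net = build_network(sys.well(0), params)
    tr = simulate(net, FAST)
    assert conservation_residual(net, tr) < 1e-6


def test_stem_shortening_monotonicity():
    """Cleavage slows as the auxiliary-enzyme arms S1/S5 shrink 11->8 bp;
    compared in the pre-saturation kinetic regime (60 min)."""
    grid = SimulationGrid(4.0, 15)
    params = KineticParams()
    ends = []
    for L in (11, 10, 9, 8):
        cfg = replace(StemConfig.four_pronged_default(), s1=L, s5=L)
        lib = design_four_pronged(DesignConstraints(stem_config=cfg,
                                                    seed=3))
        ends.append(_single_run(lib, True, True, params,
                                grid=grid).endpoint("FAM"))
    assert all(a > b for a, b in zip(ends, ends[1:]))


def test_normalize_single_monotone_run_ends_at_one(lib4, params):
    tr = _single_run(lib4, True, True, params)
    (norm,) = normalize([tr])
    assert norm.normalized_endpoint("FAM") == pytest.approx(1.0)
    assert np.all(norm.normalized["FAM"] <= 1.0 + 1e-12)


def test_normalize_all_zero_channel_stays_zero(lib4, params):
    tr = _single_run(lib4, False, False, params)
    (norm,) = normalize([tr])
    assert np.all(norm.normalized["FAM"] == 0.0)


def test_normalize_uses_global_maximum_across_runs(lib4):
    fast = KineticParams()
    slow_grid = SimulationGrid(4.0, 8)
    a = _single_run(lib4, True, True, fast)            # saturates
    b = _single_run(lib4, True, True, fast, grid=slow_grid)
    b2, a2 = normalize([b, a])
    assert a2.normalized_endpoint("FAM") == pytest.approx(1.0)
    assert b2.normalized_endpoint("FAM") < 1.0


def test_call_boolean_against_controls(lib4, params, readout):
    pos = _single_run(lib4, True, True, params)
    neg = _single_run(lib4, True, False, params)
    controls = {"FAM": pos.endpoint("FAM")}
    calls = call_boolean([pos, neg], readout, controls,
                         channel_order=["FAM"])
    assert calls[0].to_list() == [[1]]
    assert calls[1].to_list() == [[0]]


def test_call_boolean_missing_control_raises(lib4, params, readout):
    tr = _single_run(lib4, True, True, params)
    with pytest.raises(ValueError, match="control"):
        call_boolean([tr], readout, {}, channel_order=["FAM"])


def test_readout_config_validation():
    with pytest.raises(ValueError):
        ReadoutConfig(boolean_threshold=0.0)
    with pytest.raises(ValueError):
        ReadoutConfig(boolean_threshold=1.0)


def test_call_weighted_levels_and_saturation():
    """2x substrate resolves levels 1 and 2; 1x substrate caps level 2 at
    the substrate amount and is flagged saturated."""
    from dzmatrix import design_matrix_library
    libw22 = design_matrix_library(2, 2, 1, DesignConstraints(
        stem_config=StemConfig.weighted_default(), seed=6))
    params = KineticParams()
    grid = SimulationGrid(7.0, 100)
    conc2 = ConcentrationConfig.weighted_default()

    def run(m_row, conc):
        sys = compile_system([m_row, [0, 0]], [[1], [1]], conc=conc,
                             lib=libw22)
        return simulate(build_network(sys.well(0), params), grid)

    single = run([1, 0], conc2)
    both = run([1, 1], conc2)
    unit = single.endpoint("FAM")
    cfg = ReadoutConfig(unit_level=unit)
    sub_total = conc2.base_conc * conc2.substrate_multiplier
    calls = call_weighted([single, both], cfg, substrate_total=sub_total,
                          channel_order=["FAM", "ROX"])
    assert calls[0]["FAM"]["level"] == 1
    assert calls[0]["FAM"]["flags"] == []   # half the substrate remains
    assert calls[1]["FAM"]["level"] == 2
    # a level-2 call with 2x substrate sits at the ceiling: the flag marks
    # it as a lower bound
    assert "indeterminate" not in calls[1]["FAM"]["flags"]

    conc1 = ConcentrationConfig(substrate_multiplier=1.0)
    starved = run([1, 1], conc1)
    sub1 = conc1.base_conc
    (call,) = call_weighted([starved], cfg, substrate_total=sub1,
                            channel_order=["FAM", "ROX"])
    assert "saturated" in call["FAM"]["flags"]
    assert call["FAM"]["level"] < 2  # substrate-limited


def test_call_weighted_requires_calibration(lib4, params):
    tr = _single_run(lib4, True, True, params)
    with pytest.raises(ValueError, match="unit_level"):
        call_weighted([tr], ReadoutConfig())


def test_integrator_reports_grid_shape(lib4, params):
    tr = _single_run(lib4, True, True, params,
                     grid=SimulationGrid(4.0, 25))
    assert tr.times_min.shape == (26,)
    assert tr.channels["FAM"].shape == (26,)
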