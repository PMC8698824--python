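"""Reaction-network construction: off-rate law, complex enumeration,
strand conservation and structural reductions."""

import numpy as np
import pytest

from dzmatrix import (
    KineticParams,
    build_network,
    compile_system,
    enumerate_complexes,
    stem_off_rate,
)
from dzmatrix.matrix_compiler import compile_single_three_pronged
from dzmatrix.reaction_network import default_ph_activity


def test_stem_off_rate_zero_length_equals_k_on(params):
    assert stem_off_rate(0, params) == pytest.approx(params.k_on)


def test_stem_off_rate_strictly_decreasing(params):
    rates = [stem_off_rate(L, params) for L in range(0, 15)]
    assert all(a > b for a, b in zip(rates, rates[1:]))
    # the trend behind the bench observation: 11-bp arms hold far more
    # stably than 8-bp arms
    assert stem_off_rate(11, params) < stem_off_rate(8, params)


def test_stem_off_rate_rejects_negative_length(params):
    with pytest.raises(ValueError):
        stem_off_rate(-1, params)


def test_ph_activity_profile():
    assert default_ph_activity(8.0) == 1.0
    assert default_ph_activity(8.5) == 1.0
    assert default_ph_activity(9.0) == 1.0
    assert default_ph_activity(7.0) < 1.0
    assert default_ph_activity(10.0) < 1.0
    assert default_ph_activity(5.0) == 0.0
    # non-increasing away from the peak window
    lows = [default_ph_activity(p) for p in (8.0, 7.5, 7.0, 6.5, 6.0)]
    assert all(a >= b for a, b in zip(lows, lows[1:]))


def test_mg_absent_forces_zero_cleavage_with_warning():
    with pytest.warns(UserWarning, match="Mg"):
        p = KineticParams(mg_present=False, k_cat=1e-3, k_leak=1e-5)
    assert p.k_cat == 0.0
    assert p.k_leak == 0.0


def test_enumerate_complexes_2x2_all_ones(matlib22):
    sys = compile_system(np.ones((2, 2), int), np.ones((2, 1), int),
                         lib=matlib22)
    specs = enumerate_complexes(sys)
    competent = [c for c in specs if c.cleavage_competent]
    # one four-pronged complex type per (i,j) cell
    assert len(competent) == 4


def test_enumerate_complexes_3x3_all_ones():
    from dzmatrix import DesignConstraints, design_matrix_library
    lib = design_matrix_library(3, 3, 1, DesignConstraints(seed=2))
    sys = compile_system(np.ones((3, 3), int), np.ones((3, 1), int),
                         lib=lib)
    competent = [c for c in enumerate_complexes(sys)
                 if c.cleavage_competent]
    assert len(competent) == 9


def test_single_auxiliary_gives_no_competent_complex(matlib22):
    sys = compile_system([[1, 0], [0, 0]], [[0], [0]], lib=matlib22)
    assert not any(c.cleavage_competent for c in enumerate_complexes(sys))


def test_empty_inputs_leave_only_binary_enzyme_substrate_set(matlib22):
    sys = compile_system(np.zeros((2, 2), int), np.zeros((2, 1), int),
                         lib=matlib22)
    assert enumerate_complexes(sys) == []
    net = build_network(sys, KineticParams())
    assert not [r for r in net.reactions if r.kind in ("cleave", "leak")]


def test_strand_conservation_structural(matlib22, params):
    sys = compile_system(np.ones((2, 2), int), np.ones((2, 1), int),
                         lib=matlib22)
    net = build_network(sys, params)
    net.check_strand_conservation()  # raises on violation
    # every bind is bimolecular, everything else unimolecular
    for r in net.reactions:
        assert len(r.reactants) == (2 if r.kind == "bind" else 1)


def test_zero_k_cat_emits_no_cleave_reactions(matlib22):
    sys = compile_system(np.ones((2, 2), int), np.ones((2, 1), int),
                         lib=matlib22)
    net = build_network(sys, KineticParams(k_cat=0.0))
    assert not [r for r in net.reactions if r.kind == "cleave"]


def test_1x1_network_reduces_to_single_four_pronged(lib4):
    """The matrix network restricted to a 1x1 all-ones instance is
    isomorphic to the single four-pronged mechanism's network."""
    from dzmatrix import DesignConstraints, design_matrix_library
    mat1 = design_matrix_library(1, 1, 1, DesignConstraints(seed=9))
    params = KineticParams()

    def signature(lib):
        sys = compile_system([[1]], [[1]], lib=lib)
        net = build_network(sys, params)
        return sorted((r.kind, round(r.rate, 9), len(r.reactants),
                       len(r.products)) for r in net.reactions)

    assert signature(mat1) == signature(lib4)


def test_three_pronged_network_has_leak_complex(lib3):
    sys = compile_single_three_pronged(lib3, aux_present=False)
    net = build_network(sys, KineticParams(k_leak=1e-5))
    leaks = [r for r in net.reactions if r.kind == "leak"]
    assert len(leaks) == 1
    # without the auxiliary there is no catalytic cleavage channel
    assert not [r for r in net.reactions if r.kind == "cleave"]


def test_reaction_table_export(matlib22, params):
    sys = compile_system([[1, 0], [0, 1]], [[1], [0]], lib=matlib22)
    net = build_network(sys, params)
    table = net.reaction_table()
    assert "->" in table
    assert "bind" in table and "cleave" in table
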