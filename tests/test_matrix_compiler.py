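"""Arithmetic oracles and presence/absence compilation."""

import itertools

import numpy as np
import pytest

from dzmatrix import (
    BooleanMatrix,
    ConcentrationConfig,
    WeightConfig,
    compile_system,
    reference_product,
    reference_weighted_sum,
)
from dzmatrix.matrix_compiler import DimensionError


def brute_force_product(M, X):
    """Independent oracle: explicit AND/OR loops, no linear algebra."""
    n, m = len(M), len(X[0])
    out = [[0] * m for _ in range(n)]
    for i in range(n):
        for k in range(m):
            out[i][k] = 1 if any(M[i][j] == 1 and X[j][k] == 1
                                 for j in range(len(X))) else 0
    return out


def test_reference_product_examples():
    assert reference_product([[1, 0], [0, 1]], [[1], [0]]) == \
        BooleanMatrix([[1], [0]])
    assert reference_product([[1, 1], [1, 1]], [[1], [1]]) == \
        BooleanMatrix([[1], [1]])


def test_reference_product_matches_brute_force_exhaustively():
    # all 16 possible 2x2 M times all 4 X column vectors: 64 cases
    for mbits in itertools.product((0, 1), repeat=4):
        M = [[mbits[0], mbits[1]], [mbits[2], mbits[3]]]
        for xbits in itertools.product((0, 1), repeat=2):
            X = [[xbits[0]], [xbits[1]]]
            assert reference_product(M, X).to_list() == \
                brute_force_product(M, X)


def test_reference_product_matrix_times_matrix():
    M = [[1, 0, 1], [0, 0, 1]]
    X = [[1, 0], [0, 0], [0, 1]]
    assert reference_product(M, X).to_list() == brute_force_product(M, X)


@pytest.mark.parametrize("M,X,w,expected", [
    ([[1, 1], [0, 0]], [[1], [1]], (1, 1), [[2], [0]]),
    ([[1, 0], [0, 0]], [[1], [0]], (1, 1), [[1], [0]]),
    ([[1, 1], [1, 1]], [[1], [1]], (0, 0), [[0], [0]]),
    ([[1, 1], [0, 1]], [[1], [1]], (2, 3), [[5], [3]]),
])
def test_reference_weighted_sum(M, X, w, expected):
    out = reference_weighted_sum(M, X, WeightConfig(np.array(w)))
    assert out.tolist() == expected


def test_weighted_sum_thresholded_equals_boolean_product():
    rng = np.random.default_rng(3)
    for _ in range(25):
        M = rng.integers(0, 2, (3, 3))
        X = rng.integers(0, 2, (3, 2))
        ws = reference_weighted_sum(M, X, WeightConfig.ones(3))
        assert ((ws >= 1).astype(int) ==
                reference_product(M, X).data).all()


def test_shape_mismatch_raises_with_both_shapes():
    with pytest.raises(DimensionError, match=r"\(2, 2\).*\(3, 1\)"):
        reference_product([[1, 0], [0, 1]], [[1], [0], [1]])
    with pytest.raises(DimensionError):
        reference_weighted_sum([[1]], [[1]], WeightConfig(np.ones(4)))


def test_boolean_matrix_rejects_non_binary():
    with pytest.raises(ValueError):
        BooleanMatrix([[0, 2]])


def test_compile_presence_absence_encoding(matlib22):
    sys = compile_system([[1, 0], [0, 1]], [[1], [0]], lib=matlib22)
    present = set(sys.initial)
    assert {"M11", "M22", "X11"} <= present
    assert not {"M12", "M21", "X21"} & present
    # enzymes and substrates are always present
    assert {"E1", "E2", "R1", "R2"} <= present


def test_compile_all_zero_matrix(matlib22):
    sys = compile_system([[0, 0], [0, 0]], [[0], [0]], lib=matlib22)
    assert set(sys.initial) == {"E1", "E2", "R1", "R2"}


def test_compile_roundtrip_decodes_matrices(matlib22):
    rng = np.random.default_rng(7)
    for _ in range(20):
        M = rng.integers(0, 2, (2, 2))
        X = rng.integers(0, 2, (2, 1))
        sys = compile_system(M, X, lib=matlib22)
        Md, Xd = sys.decode()
        assert Md == BooleanMatrix(M)
        assert Xd == BooleanMatrix(X)


def test_compile_concentrations(matlib22):
    conc = ConcentrationConfig(base_conc=0.3e-6, substrate_multiplier=2.0)
    w = WeightConfig(np.array([1.0, 1.0]))
    sys = compile_system([[1, 1], [1, 1]], [[1], [1]], weights=w,
                         conc=conc, lib=matlib22)
    assert sys.initial["R1"] == pytest.approx(0.6e-6)
    assert sys.initial["E1"] == pytest.approx(0.3e-6)
    assert sys.initial["M12"] == pytest.approx(0.3e-6)


def test_compile_shape_mismatch(matlib22):
    with pytest.raises(DimensionError):
        compile_system([[1, 0], [0, 1]], [[1], [0], [0]], lib=matlib22)
    with pytest.raises(DimensionError):
        compile_system([[1]], [[1]], lib=matlib22)


def test_boolean_mode_rejects_non_unit_weights(matlib22):
    with pytest.raises(ValueError, match="weights"):
        compile_system([[1, 0], [0, 1]], [[1], [0]],
                       weights=WeightConfig(np.array([2.0, 1.0])),
                       lib=matlib22)


def test_sixteen_demo_systems_enumerable(matlib22):
    from dzmatrix.demo import DEFAULT_M_SET, DEFAULT_X_SET
    systems = [compile_system(np.array(m), np.array(x).reshape(2, 1),
                              lib=matlib22)
               for m in DEFAULT_M_SET for x in DEFAULT_X_SET]
    assert len(systems) == 16
    # each system decodes back to a distinct (M, X) pair
    decoded = {(s.decode()[0], s.decode()[1]) for s in systems}
    assert len(decoded) == 16
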