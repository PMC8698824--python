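"""Designed libraries: stem lengths, core conservation, determinism,
matrix-library structure and the crosstalk screen."""

import pytest
from dataclasses import replace

from dzmatrix import (
    CATALYTIC_CORE,
    DesignConstraints,
    StemConfig,
    StrandKind,
    crosstalk_screen,
    design_four_pronged,
    design_matrix_library,
    design_three_pronged,
    make_complex,
    validate_complex,
)
from dzmatrix.sequence_designer import (
    ChannelExhaustionError,
    DesignFailure,
    CHANNEL_PALETTE,
)
from dzmatrix.strand_model import DomainRole, gc_fraction, \
    max_homopolymer_run


def _stem_len(lib, strand, dom_id):
    return len(lib.strands[strand].domain(dom_id).seq)


def test_three_pronged_default_stem_lengths(lib3):
    # measured from the emitted strands, not from the config
    assert _stem_len(lib3, "enzyme", "S1") == 7
    assert _stem_len(lib3, "enzyme", "S2") == 3
    assert _stem_len(lib3, "enzyme", "S3") == 11
    assert _stem_len(lib3, "aux", "S4") == 10
    # TA buffer sits between the S2 and S4 complements on the substrate
    roles = [d.role for d in lib3.strands["substrate"].domains]
    i_buf = roles.index(DomainRole.BUFFER)
    assert roles[i_buf - 1] is DomainRole.S2
    assert roles[i_buf + 1] is DomainRole.S4


def test_four_pronged_default_stem_lengths(lib4):
    assert _stem_len(lib4, "enzyme", "S1[0]") == 11
    assert _stem_len(lib4, "enzyme", "S5[0]") == 11
    assert _stem_len(lib4, "aux1", "S3[0]") == 10
    assert _stem_len(lib4, "aux2", "S6") == 10
    assert _stem_len(lib4, "enzyme", "S2") == 3
    assert _stem_len(lib4, "enzyme", "S4") == 3


def test_weighted_mode_rebalanced_stems(libw):
    assert _stem_len(libw, "aux1", "S3[0]") == 14
    assert _stem_len(libw, "aux2", "S6") == 9


def test_every_enzyme_contains_core_exactly_once(lib3, lib4, matlib22):
    for lib in (lib3, lib4, matlib22):
        for strand in lib.strands.values():
            n = strand.seq.count(CATALYTIC_CORE)
            assert n == (1 if strand.kind is StrandKind.ENZYME else 0)


def test_same_seed_gives_byte_identical_library():
    a = design_three_pronged(DesignConstraints(
        stem_config=StemConfig.three_pronged_default(), seed=42))
    b = design_three_pronged(DesignConstraints(
        stem_config=StemConfig.three_pronged_default(), seed=42))
    assert {n: s.seq for n, s in a.strands.items()} == \
        {n: s.seq for n, s in b.strands.items()}
    c = design_three_pronged(DesignConstraints(
        stem_config=StemConfig.three_pronged_default(), seed=43))
    assert {n: s.seq for n, s in a.strands.items()} != \
        {n: s.seq for n, s in c.strands.items()}


def test_zero_length_s2_is_still_designable():
    cfg = replace(StemConfig.three_pronged_default(), s2=0)
    lib = design_three_pronged(DesignConstraints(stem_config=cfg, seed=1))
    assert "S2" not in [d.dom_id for d in lib.strands["enzyme"].domains]
    # the canonical complex is no longer cleavage-competent
    cspec = make_complex(lib, ["enzyme", "aux", "substrate"])
    assert not cspec.cleavage_competent


def test_designed_stems_respect_gc_and_homopolymer_limits(matlib22):
    cons = matlib22.constraints
    for strand in matlib22.strands.values():
        for d in strand.domains:
            if d.role.name.startswith("S") and len(d.seq) >= 3:
                assert cons.gc_min <= gc_fraction(d.seq) <= cons.gc_max
                assert max_homopolymer_run(d.seq) <= cons.forbidden_runs


def test_unsatisfiable_gc_window_raises_naming_the_stem():
    cfg = StemConfig.four_pronged_default()
    cons = DesignConstraints(stem_config=cfg, gc_min=0.49, gc_max=0.51,
                             seed=0, retry_budget=50)
    with pytest.raises(DesignFailure, match="S"):
        design_four_pronged(cons)


def test_matrix_library_counts_2x2():
    lib = design_matrix_library(2, 2, 1, DesignConstraints(seed=5))
    assert len(lib.aux_m) == 4
    assert len(lib.aux_x) == 2
    assert len(lib.enzymes) == 2
    assert len(lib.substrates) == 2
    assert [lib.channel_of_row(i) for i in range(2)] == ["FAM", "ROX"]


def test_matrix_library_1x1_reduces_to_four_pronged_single():
    cons = DesignConstraints(seed=9)
    single = design_four_pronged(cons)
    mat = design_matrix_library(1, 1, 1, cons)
    # identical sequences, just the single-design naming
    assert single.strands["enzyme"].seq == mat.strands["E1"].seq
    assert single.strands["aux1"].seq == mat.strands["M11"].seq
    assert single.strands["aux2"].seq == mat.strands["X11"].seq
    assert single.strands["substrate"].seq == mat.strands["R1"].seq


def test_matrix_aux_arms_are_complementary_to_their_partners(matlib22):
    # every designed stem in the library is a perfect duplex
    for (sa, da, sb, db, ln) in matlib22.stems.values():
        a = matlib22.strands[sa].domain(da).seq
        b = matlib22.strands[sb].domain(db).seq
        from dzmatrix import reverse_complement
        assert b.upper() == reverse_complement(a)
        assert len(a) == ln


def test_row_and_column_domain_sharing(matlib22):
    # row-shared: both M-aux of row 1 carry the same substrate arm
    assert matlib22.strands["M11"].domain("S3[0]").seq == \
        matlib22.strands["M12"].domain("S3[0]").seq
    # column-shared: both substrates carry the same X-side common arm
    assert matlib22.strands["R1"].domain("S6*").seq == \
        matlib22.strands["R2"].domain("S6*").seq


def test_channel_exhaustion_error():
    n = len(CHANNEL_PALETTE) + 1
    with pytest.raises(ChannelExhaustionError):
        design_matrix_library(n, 1, 1, DesignConstraints(seed=0))


def test_crosstalk_screen_passes_designed_libraries(lib3, lib4, matlib22):
    for lib in (lib3, lib4, matlib22):
        report = crosstalk_screen(lib, lib.constraints.crosstalk_k)
        assert report.passed, report.offenders


def test_crosstalk_partner_stems_are_excluded(lib4):
    # a full 11-bp designed duplex would dominate the report if included
    report = crosstalk_screen(lib4, lib4.constraints.crosstalk_k)
    assert report.max_run < 11


def test_crosstalk_screen_rejects_planted_offender(lib4):
    report = crosstalk_screen(lib4, 1)
    assert not report.passed  # at k=1 random sequences always collide
    with pytest.raises(ValueError):
        crosstalk_screen(lib4, 0)


def test_validate_complex_passes_for_all_canonical_designs(matlib22):
    for (i, j), m in matlib22.aux_m.items():
        members = [matlib22.enzymes[j], m, matlib22.aux_x[(j, 0)],
                   matlib22.substrates[i]]
        cspec = make_complex(matlib22, members)
        assert cspec.cleavage_competent
        assert validate_complex(cspec, matlib22).passed
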