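"""De-novo design of strand libraries under the stem-length, core-conservation
and buffer-region constraints, with an exact-complementarity crosstalk screen.

The designer draws random stem sequences (seeded, hence byte-reproducible),
rejecting candidates that violate the GC window, the homopolymer cap, or
that share a complementary run longer than ``crosstalk_k`` with any sequence
already in the library (including the fixed catalytic core).  This replaces
a thermodynamic secondary-structure check with a purely combinatorial
screen: no unintended domain pair may form more than ``crosstalk_k``
consecutive Watson-Crick pairs.

Library layout (matrix mode, N rows x N cols x K output columns):

* one enzyme per column j, arms ``S1[j]``/``S5[j]``, shared junctions
  ``S2``/``S4`` and a shared designed hairpin;
* one reporter substrate per output row i with a distinct fluorescence
  channel: ``S3[i]* - TA - S2* - rA - S4* - TA - S6*``; the row-specific
  arm is S3, the X-side arm S6 is common to all substrates so that every
  column element can reach every reporter;
* M-auxiliary (i,j): bridges substrate arm S3[i] and enzyme arm S1[j];
* X-auxiliary (j,k): bridges enzyme arm S5[j] and the common substrate
  arm S6 (sequence-identical across k; distinct named species).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .strand_model import (
    BUFFER_SEQ,
    CATALYTIC_CORE,
    RIBO_A,
    ComplexSpec,
    Domain,
    DomainRole,
    Mode,
    StemConfig,
    Strand,
    StrandKind,
    gc_fraction,
    is_cleavage_competent,
    longest_complementary_run,
    max_homopolymer_run,
    reverse_complement,
)

__all__ = [
    "CHANNEL_PALETTE",
    "ChannelExhaustionError",
    "CrosstalkReport",
    "DesignConstraints",
    "DesignFailure",
    "MatrixLibrary",
    "StrandLibrary",
    "crosstalk_screen",
    "design_four_pronged",
    "design_matrix_library",
    "design_three_pronged",
    "make_complex",
]

#: Default fluorophore channels assigned to reporter rows, in order.
CHANNEL_PALETTE = ("FAM", "ROX", "Cy3", "Cy5", "HEX", "TexasRed",
                   "AF488", "AF647")

_QUENCHERS = {"FAM": "BHQ1", "ROX": "BHQ2", "Cy3": "BHQ2", "Cy5": "BHQ3",
              "HEX": "BHQ1", "TexasRed": "BHQ2", "AF488": "BHQ1",
              "AF647": "BHQ3"}

_HAIRPIN_LEN = 12  # opaque stem-loop domain of the enzyme; sequence variable


class DesignFailure(RuntimeError):
    """Raised when a stem cannot be drawn within the retry budget."""


class ChannelExhaustionError(RuntimeError):
    """More reporter rows requested than distinct fluorescence channels."""


@dataclass(frozen=True)
class DesignConstraints:
    """Sequence-design heuristics applied to every drawn stem."""

    stem_config: StemConfig = field(
        default_factory=StemConfig.four_pronged_default)
    gc_min: float = 0.3
    gc_max: float = 0.7
    forbidden_runs: int = 4
    crosstalk_k: int = 5
    seed: int = 0
    retry_budget: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_min <= self.gc_max <= 1.0):
            raise ValueError("need 0 <= gc_min <= gc_max <= 1")
        if self.crosstalk_k < 1:
            raise ValueError("crosstalk_k must be >= 1")


@dataclass
class CrosstalkReport:
    """Longest unintended complementary run over all non-partner domain
    pairs.  ``passed`` iff ``max_run <= k``."""

    k: int
    max_run: int
    n_pairs: int
    offenders: List[Tuple[str, str, int]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.max_run <= self.k

    def __bool__(self) -> bool:
        return self.passed


@dataclass
class StrandLibrary:
    """A designed set of strands plus the pairing (partner) annotations.

    ``stems`` maps a stem id (e.g. ``"S1[0]"``) to
    (strand_a, dom_id_a, strand_b, dom_id_b, length_bp); partner domains
    are excluded from the crosstalk screen.  Index maps (``enzymes``,
    ``substrates``, ``aux_m``, ``aux_x``) are populated for matrix
    libraries and for single four-pronged designs (as the 1x1 case).
    """

    strands: Dict[str, Strand]
    stem_config: StemConfig
    mode: Mode
    stems: Dict[str, Tuple[str, str, str, str, int]]
    constraints: DesignConstraints
    design_report: Dict[str, object] = field(default_factory=dict)
    enzymes: Dict[int, str] = field(default_factory=dict)
    substrates: Dict[int, str] = field(default_factory=dict)
    aux_m: Dict[Tuple[int, int], str] = field(default_factory=dict)
    aux_x: Dict[Tuple[int, int], str] = field(default_factory=dict)

    def fragment_names(self, substrate: str) -> Tuple[str, str]:
        return f"{substrate}_5p", f"{substrate}_3p"

    def channel_of_row(self, i: int) -> str:
        return self.strands[self.substrates[i]].fluorophore

    @property
    def n_rows(self) -> int:
        return len(self.substrates)

    @property
    def n_cols(self) -> int:
        return len(self.enzymes)

    @property
    def k_cols(self) -> int:
        ks = {k for (_, k) in self.aux_x}
        return len(ks) if ks else 1


class MatrixLibrary(StrandLibrary):
    """A :class:`StrandLibrary` shaped for an (N x N) x (N x K) product."""


# ---------------------------------------------------------------------------
# random sequence drawing

_BASES = np.array(list("ACGT"))


def _draw_domain(rng: np.random.Generator, name: str, length: int,
                 constraints: DesignConstraints,
                 existing: List[str]) -> str:
    """Draw one stem sequence satisfying all heuristics, or raise
    :class:`DesignFailure` naming the stem after the retry budget."""
    for _ in range(constraints.retry_budget):
        seq = "".join(rng.choice(_BASES, size=length))
        if length >= 3 and not (
                constraints.gc_min <= gc_fraction(seq) <= constraints.gc_max):
            continue
        if max_homopolymer_run(seq) > constraints.forbidden_runs:
            continue
        # screen against everything drawn so far, their complements, itself
        ok = True
        for other in existing + [seq]:
            if longest_complementary_run(seq, other) > constraints.crosstalk_k:
                ok = False
                break
            # unintended co-linear identity would create shared partners
            if other is not seq and _longest_common_run(seq, other) > \
                    constraints.crosstalk_k:
                ok = False
                break
        if ok:
            return seq
    raise DesignFailure(
        f"could not design stem {name} (length {length}) within "
        f"{constraints.retry_budget} redraws; constraints unsatisfiable")


def _longest_common_run(a: str, b: str) -> int:
    """Longest common substring (identity, not complementarity)."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    best = 0
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, 1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def _primary_pool(rng, names_lengths, constraints):
    """Draw the primary (non-complement) stem sequences in a fixed order."""
    existing = [CATALYTIC_CORE]
    out: Dict[str, str] = {}
    for name, length in names_lengths:
        if length == 0:
            continue
        seq = _draw_domain(rng, name, length, constraints, existing)
        existing.append(seq)
        out[name] = seq
    return out


# ---------------------------------------------------------------------------
# library assembly helpers

def _stem_table(cfg: StemConfig) -> Dict[str, int]:
    return {"S1": cfg.s1, "S2": cfg.s2, "S3": cfg.s3,
            "S4": cfg.s4, "S5": cfg.s5, "S6": cfg.s6}


def _report(constraints: DesignConstraints, lib: StrandLibrary,
            warnings: List[str]) -> Dict[str, object]:
    gc = {name: round(gc_fraction(s.seq), 3)
          for name, s in lib.strands.items()
          if s.kind not in (StrandKind.FRAGMENT_F, StrandKind.FRAGMENT_Q)}
    screen = crosstalk_screen(lib, constraints.crosstalk_k)
    return {
        "mode": lib.mode.value,
        "seed": constraints.seed,
        "stem_table": _stem_table(constraints.stem_config),
        "buffer_counted_as_separate_domain": True,
        "gc_fraction": gc,
        "crosstalk_max_run": screen.max_run,
        "crosstalk_k": constraints.crosstalk_k,
        "crosstalk_pass": screen.passed,
        "warnings": warnings,
        "ra_annotation": {
            s.name: s.seq.index(RIBO_A)
            for s in lib.strands.values() if RIBO_A in s.seq
        },
    }


def _add_fragments(strands: Dict[str, Strand], sub: Strand) -> None:
    """Register the two cleavage products of a substrate.  The cut is at
    the rA site; the 5' fragment keeps the fluorophore (and the rA), the
    3' fragment keeps the quencher."""
    doms = list(sub.domains)
    cut = next(i for i, d in enumerate(doms)
               if d.role is DomainRole.CLEAVAGE_SITE)
    f5 = Strand(name=f"{sub.name}_5p", domains=tuple(doms[:cut + 1]),
                kind=StrandKind.FRAGMENT_F, fluorophore=sub.fluorophore,
                index=sub.index)
    f3 = Strand(name=f"{sub.name}_3p", domains=tuple(doms[cut + 1:]),
                kind=StrandKind.FRAGMENT_Q, quencher=sub.quencher,
                index=sub.index)
    strands[f5.name] = f5
    strands[f3.name] = f3


def make_complex(lib: StrandLibrary, members: Sequence[str]) -> ComplexSpec:
    """Build a :class:`ComplexSpec` for the given member strands: all
    designed stems whose two half-domains both sit on members are declared
    paired, and competence follows the structural rule."""
    mem = tuple(sorted(members))
    paired = tuple(
        (sa, da, sb, db)
        for (sa, da, sb, db, _ln) in lib.stems.values()
        if sa in mem and sb in mem
    )
    competent = is_cleavage_competent(
        [lib.strands[m] for m in mem], lib.mode, lib.stem_config)
    return ComplexSpec(members=mem, paired_stems=paired,
                       cleavage_competent=competent)


# ---------------------------------------------------------------------------
# designers

def design_three_pronged(constraints: Optional[DesignConstraints] = None
                         ) -> StrandLibrary:
    """Design the enzyme / single-auxiliary / substrate triple.

    Enzyme: ``S1 - core - hairpin - S2 - S3``; the auxiliary bridges the
    enzyme's S3 arm and the substrate's S4 arm; the substrate
    ``S1* - rA - S2* - [TA] - S4*`` carries one rA between the two
    enzyme-binding stems, adjacent to the catalytic core.
    """
    if constraints is None:
        constraints = DesignConstraints(
            stem_config=StemConfig.three_pronged_default())
    cfg = constraints.stem_config
    if cfg.mode is not Mode.THREE_PRONGED:
        raise ValueError("constraints.stem_config.mode must be three_pronged")
    rng = np.random.default_rng(constraints.seed)
    pool = _primary_pool(rng, [("S1", cfg.s1), ("S2", cfg.s2),
                               ("S3", cfg.s3), ("S4", cfg.s4),
                               ("HP", _HAIRPIN_LEN)], constraints)

    def dom(role, dom_id, seq):
        return Domain(role=role, dom_id=dom_id, seq=seq)

    hp = dom(DomainRole.HAIRPIN, "HP", pool["HP"])
    core = dom(DomainRole.CATALYTIC_CORE, "core", CATALYTIC_CORE)

    enz_doms = []
    if cfg.s1:
        enz_doms.append(dom(DomainRole.S1, "S1", pool["S1"]))
    enz_doms += [core, hp]
    if cfg.s2:
        enz_doms.append(dom(DomainRole.S2, "S2", pool["S2"]))
    if cfg.s3:
        enz_doms.append(dom(DomainRole.S3, "S3", pool["S3"]))
    enzyme = Strand("enzyme", tuple(enz_doms), StrandKind.ENZYME)

    aux_doms = []
    if cfg.s4:
        aux_doms.append(dom(DomainRole.S4, "S4", pool["S4"]))
    if cfg.s3:
        aux_doms.append(dom(DomainRole.S3, "S3*",
                            reverse_complement(pool["S3"])))
    aux = Strand("aux", tuple(aux_doms), StrandKind.AUX)

    sub_doms = []
    if cfg.s1:
        sub_doms.append(dom(DomainRole.S1, "S1*",
                            reverse_complement(pool["S1"])))
    sub_doms.append(dom(DomainRole.CLEAVAGE_SITE, "rA", RIBO_A))
    if cfg.s2:
        sub_doms.append(dom(DomainRole.S2, "S2*",
                            reverse_complement(pool["S2"])))
    if cfg.buffer_s2_s4:
        sub_doms.append(dom(DomainRole.BUFFER, "bufA", BUFFER_SEQ))
    if cfg.s4:
        sub_doms.append(dom(DomainRole.S4, "S4*",
                            reverse_complement(pool["S4"])))
    substrate = Strand("substrate", tuple(sub_doms), StrandKind.SUBSTRATE,
                       fluorophore="FAM", quencher="BHQ1")

    strands = {s.name: s for s in (enzyme, aux, substrate)}
    _add_fragments(strands, substrate)

    stems = {}
    if cfg.s1:
        stems["S1"] = ("enzyme", "S1", "substrate", "S1*", cfg.s1)
    if cfg.s2:
        stems["S2"] = ("enzyme", "S2", "substrate", "S2*", cfg.s2)
    if cfg.s3:
        stems["S3"] = ("enzyme", "S3", "aux", "S3*", cfg.s3)
    if cfg.s4:
        stems["S4"] = ("aux", "S4", "substrate", "S4*", cfg.s4)

    warnings: List[str] = []
    if not cfg.buffer_s2_s4:
        warnings.append("buffer area between S2 and S4 disabled; expect "
                        "reduced catalysis (flexibility spacer missing)")
    lib = StrandLibrary(strands=strands, stem_config=cfg,
                        mode=Mode.THREE_PRONGED, stems=stems,
                        constraints=constraints,
                        enzymes={0: "enzyme"}, substrates={0: "substrate"},
                        aux_m={(0, 0): "aux"})
    lib.design_report = _report(constraints, lib, warnings)
    return lib


def design_four_pronged(constraints: Optional[DesignConstraints] = None
                        ) -> StrandLibrary:
    """Design the enzyme / two-auxiliary / substrate quadruple (the 1x1
    matrix cell).  ``weighted`` mode uses the same architecture with the
    S3/S6 lengths rebalanced for quantitative readout."""
    if constraints is None:
        constraints = DesignConstraints(
            stem_config=StemConfig.four_pronged_default())
    cfg = constraints.stem_config
    if cfg.mode is Mode.THREE_PRONGED:
        raise ValueError("constraints.stem_config.mode must be four_pronged "
                         "or weighted")
    lib = design_matrix_library(1, 1, 1, constraints,
                                _names=("enzyme", "aux1", "aux2",
                                        "substrate"))
    return lib


def design_matrix_library(n_rows: int, n_cols: int, k_cols: int,
                          constraints: Optional[DesignConstraints] = None,
                          _names: Optional[Tuple[str, str, str, str]] = None,
                          ) -> MatrixLibrary:
    """Design the full species set for an (n_rows x n_cols) matrix M times
    an (n_cols x k_cols) matrix X: one enzyme per column, one reporter per
    row (distinct channel), one M-auxiliary per (i,j) and one X-auxiliary
    per (j,k)."""
    if constraints is None:
        constraints = DesignConstraints(
            stem_config=StemConfig.four_pronged_default())
    cfg = constraints.stem_config
    if cfg.mode is Mode.THREE_PRONGED:
        raise ValueError("matrix libraries use four_pronged or weighted mode")
    if min(n_rows, n_cols, k_cols) < 1:
        raise ValueError("n_rows, n_cols, k_cols must all be >= 1")
    if n_rows > len(CHANNEL_PALETTE):
        raise ChannelExhaustionError(
            f"{n_rows} reporter rows requested but only "
            f"{len(CHANNEL_PALETTE)} distinct channels are configured")

    rng = np.random.default_rng(constraints.seed)
    names_lengths = [("S2", cfg.s2), ("S4", cfg.s4), ("S6", cfg.s6),
                     ("HP", _HAIRPIN_LEN)]
    names_lengths += [(f"S1[{j}]", cfg.s1) for j in range(n_cols)]
    names_lengths += [(f"S5[{j}]", cfg.s5) for j in range(n_cols)]
    names_lengths += [(f"S3[{i}]", cfg.s3) for i in range(n_rows)]
    pool = _primary_pool(rng, names_lengths, constraints)

    def dom(role, dom_id, primary_name=None, seq=None, comp=False):
        if seq is None:
            seq = pool[primary_name]
            if comp:
                seq = reverse_complement(seq)
        return Domain(role=role, dom_id=dom_id, seq=seq)

    single = _names is not None
    e_name = (lambda j: _names[0]) if single else (lambda j: f"E{j + 1}")
    m_name = (lambda i, j: _names[1]) if single else \
        (lambda i, j: f"M{i + 1}{j + 1}")
    x_name = (lambda j, k: _names[2]) if single else \
        (lambda j, k: f"X{j + 1}{k + 1}")
    r_name = (lambda i: _names[3]) if single else (lambda i: f"R{i + 1}")

    strands: Dict[str, Strand] = {}
    stems: Dict[str, Tuple[str, str, str, str, int]] = {}
    core = dom(DomainRole.CATALYTIC_CORE, "core", seq=CATALYTIC_CORE)
    hp = dom(DomainRole.HAIRPIN, "HP", "HP")

    for j in range(n_cols):
        doms = []
        if cfg.s1:
            doms.append(dom(DomainRole.S1, f"S1[{j}]", f"S1[{j}]"))
        if cfg.s2:
            doms.append(dom(DomainRole.S2, "S2", "S2"))
        doms += [core, hp]
        if cfg.s4:
            doms.append(dom(DomainRole.S4, "S4", "S4"))
        if cfg.s5:
            doms.append(dom(DomainRole.S5, f"S5[{j}]", f"S5[{j}]"))
        strands[e_name(j)] = Strand(e_name(j), tuple(doms),
                                    StrandKind.ENZYME, index=(j,))

    for i in range(n_rows):
        doms = []
        if cfg.s3:
            doms.append(dom(DomainRole.S3, f"S3[{i}]*", f"S3[{i}]",
                            comp=True))
        if cfg.buffer_s2_s3:
            doms.append(dom(DomainRole.BUFFER, "bufA", seq=BUFFER_SEQ))
        if cfg.s2:
            doms.append(dom(DomainRole.S2, "S2*", "S2", comp=True))
        doms.append(dom(DomainRole.CLEAVAGE_SITE, "rA", seq=RIBO_A))
        if cfg.s4:
            doms.append(dom(DomainRole.S4, "S4*", "S4", comp=True))
        if cfg.buffer_s4_s6:
            doms.append(dom(DomainRole.BUFFER, "bufB", seq=BUFFER_SEQ))
        if cfg.s6:
            doms.append(dom(DomainRole.S6, "S6*", "S6", comp=True))
        channel = CHANNEL_PALETTE[i]
        strands[r_name(i)] = Strand(r_name(i), tuple(doms),
                                    StrandKind.SUBSTRATE,
                                    fluorophore=channel,
                                    quencher=_QUENCHERS[channel],
                                    index=(i,))
        _add_fragments(strands, strands[r_name(i)])

    for i in range(n_rows):
        for j in range(n_cols):
            doms = []
            if cfg.s3:
                doms.append(dom(DomainRole.S3, f"S3[{i}]", f"S3[{i}]"))
            if cfg.s1:
                doms.append(dom(DomainRole.S1, f"S1[{j}]*", f"S1[{j}]",
                                comp=True))
            strands[m_name(i, j)] = Strand(m_name(i, j), tuple(doms),
                                           StrandKind.AUX_M, index=(i, j))

    for j in range(n_cols):
        for k in range(k_cols):
            doms = []
            if cfg.s5:
                doms.append(dom(DomainRole.S5, f"S5[{j}]*", f"S5[{j}]",
                                comp=True))
            if cfg.s6:
                doms.append(dom(DomainRole.S6, "S6", "S6"))
            strands[x_name(j, k)] = Strand(x_name(j, k), tuple(doms),
                                           StrandKind.AUX_X, index=(j, k))

    # stem / partner annotations (one entry per pairing instance)
    for i in range(n_rows):
        for j in range(n_cols):
            if cfg.s1:
                stems[f"S1[{j}]~M{i}{j}"] = (e_name(j), f"S1[{j}]",
                                             m_name(i, j), f"S1[{j}]*",
                                             cfg.s1)
            if cfg.s3:
                stems[f"S3[{i}]~M{i}{j}"] = (m_name(i, j), f"S3[{i}]",
                                             r_name(i), f"S3[{i}]*", cfg.s3)
    for j in range(n_cols):
        for k in range(k_cols):
            if cfg.s5:
                stems[f"S5[{j}]~X{j}{k}"] = (e_name(j), f"S5[{j}]",
                                             x_name(j, k), f"S5[{j}]*",
                                             cfg.s5)
            for i in range(n_rows):
                if cfg.s6:
                    stems[f"S6~X{j}{k}~R{i}"] = (x_name(j, k), "S6",
                                                 r_name(i), "S6*", cfg.s6)
    for i in range(n_rows):
        for j in range(n_cols):
            if cfg.s2:
                stems[f"S2~E{j}~R{i}"] = (e_name(j), "S2", r_name(i),
                                          "S2*", cfg.s2)
            if cfg.s4:
                stems[f"S4~E{j}~R{i}"] = (e_name(j), "S4", r_name(i),
                                          "S4*", cfg.s4)

    warnings: List[str] = []
    if not cfg.buffer_s2_s3 or not cfg.buffer_s4_s6:
        warnings.append("one or both substrate buffer areas disabled; "
                        "expect reduced catalysis")

    lib = MatrixLibrary(strands=strands, stem_config=cfg, mode=cfg.mode,
                        stems=stems, constraints=constraints,
                        enzymes={j: e_name(j) for j in range(n_cols)},
                        substrates={i: r_name(i) for i in range(n_rows)},
                        aux_m={(i, j): m_name(i, j)
                               for i in range(n_rows)
                               for j in range(n_cols)},
                        aux_x={(j, k): x_name(j, k)
                               for j in range(n_cols)
                               for k in range(k_cols)})
    lib.design_report = _report(constraints, lib, warnings)
    if not lib.design_report["crosstalk_pass"]:  # pragma: no cover
        raise DesignFailure("library failed its own crosstalk screen; "
                            "re-run with a different seed")
    return lib


# ---------------------------------------------------------------------------
# crosstalk screen

def crosstalk_screen(lib: StrandLibrary, k: int) -> CrosstalkReport:
    """Longest exact complementary run over every ordered pair of domain
    instances that is not an annotated partner pair.

    Instances of a domain and its ``*`` complement are by construction
    partners wherever they occur (row/column domain sharing is intended),
    so exclusion is by domain id.  Fragment strands duplicate substrate
    domains and are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    instances = []
    for s in lib.strands.values():
        if s.kind in (StrandKind.FRAGMENT_F, StrandKind.FRAGMENT_Q):
            continue
        for d in s.domains:
            instances.append((s.name, d))
    max_run = 0
    offenders: List[Tuple[str, str, int]] = []
    n_pairs = 0
    seen_id_pairs: Dict[Tuple[str, str], int] = {}
    for a_strand, a in instances:
        for b_strand, b in instances:
            if a_strand == b_strand and a.dom_id == b.dom_id:
                continue
            if a.is_complement_of(b):
                continue
            key = (a.dom_id, b.dom_id)
            n_pairs += 1
            if key in seen_id_pairs:      # same sequences; reuse the run
                run = seen_id_pairs[key]
            else:
                run = longest_complementary_run(a.seq, b.seq)
                seen_id_pairs[key] = run
            if run > max_run:
                max_run = run
            if run > k:
                offenders.append((f"{a_strand}:{a.dom_id}",
                                  f"{b_strand}:{b.dom_id}", run))
    # deduplicate offender id pairs
    offenders = sorted(set(offenders))
    return CrosstalkReport(k=k, max_run=max_run, n_pairs=n_pairs,
                           offenders=offenders)
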