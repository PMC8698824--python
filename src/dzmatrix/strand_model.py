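"""Core data model: domains, strands, stem configurations and complexes.

The molecular architecture modelled here is the E6 DNAzyme regulated by
auxiliary strands.  The enzyme carries a strictly conserved 15-nt catalytic
core flanked by two short substrate-binding junction stems (S2/S4) and, at
its termini, longer arms that recruit auxiliary strands.  Each auxiliary
strand bridges one enzyme arm and one arm of the fluorogenic substrate, so
the enzyme is only held on the substrate -- and hence cleavage-competent --
when the full auxiliary complement is bound:

* three-pronged mode: enzyme + one auxiliary + substrate (stems S1..S4,
  where S1/S2 are the enzyme's substrate-binding stems and S3/S4 are the
  auxiliary's enzyme- and substrate-binding arms);
* four-pronged mode: enzyme + two auxiliaries + substrate (S1/S5 bind the
  auxiliaries to the enzyme, S3/S6 bind them to the substrate, S2/S4 are
  the 3-bp junction stems flanking the catalytic core);
* weighted mode: the four-pronged geometry with S3 lengthened to 14 bp and
  S6 shortened to 9 bp for quantitative readout.

Sequences are plain 5'->3' strings over {A,C,G,T} with a single lowercase
``a`` marking the ribo-adenosine cleavage site of a substrate strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Tuple

__all__ = [
    "ALPHABET",
    "CATALYTIC_CORE",
    "BUFFER_SEQ",
    "RIBO_A",
    "AlphabetError",
    "ComplexSpec",
    "Domain",
    "DomainRole",
    "LookupError2",
    "Mode",
    "StemConfig",
    "Strand",
    "StrandKind",
    "ValidationReport",
    "gc_fraction",
    "longest_complementary_run",
    "max_homopolymer_run",
    "reverse_complement",
]

#: Conserved E6 catalytic loop, stored as one contiguous 15-nt string.
CATALYTIC_CORE = "AGCGATCACCCATGT"

#: Two-base flexibility spacer inserted between stems on the substrate.
BUFFER_SEQ = "TA"

#: Lowercase marker for the ribo-adenosine cleavage site.
RIBO_A = "a"

ALPHABET = frozenset("ACGT" + RIBO_A)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", RIBO_A: "T"}


class AlphabetError(ValueError):
    """A sequence contains characters outside {A,C,G,T,a}."""


class LookupError2(KeyError):
    """A referenced strand name is absent from the library."""


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - ALPHABET
    if bad:
        raise AlphabetError(f"invalid nucleotide characters: {sorted(bad)!r}")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of a 5'->3' sequence.

    The ribo-adenosine marker ``a`` pairs with (maps to) ``T``.  On pure
    DNA strings the operation is an involution; a string containing ``a``
    maps to pure DNA, so the round trip returns the deoxy form.
    """
    if not seq:
        raise AlphabetError("empty sequence")
    _check_alphabet(seq)
    return "".join(_COMPLEMENT[c] for c in reversed(seq))


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(c in "GC" for c in seq.upper()) / len(seq)


def max_homopolymer_run(seq: str) -> int:
    best = run = 0
    prev = None
    for c in seq.upper():
        run = run + 1 if c == prev else 1
        prev = c
        best = max(best, run)
    return best


def longest_complementary_run(a: str, b: str) -> int:
    """Length of the longest exact Watson-Crick complementary stretch
    between two 5'->3' sequences (longest common substring of ``a`` and
    the reverse complement of ``b``)."""
    if not a or not b:
        return 0
    rb = reverse_complement(b)
    n, m = len(a), len(rb)
    prev = [0] * (m + 1)
    best = 0
    au = a.upper()
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = au[i - 1]
        for j in range(1, m + 1):
            if ai == rb[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


class DomainRole(str, Enum):
    S1 = "S1"
    S2 = "S2"
    S3 = "S3"
    S4 = "S4"
    S5 = "S5"
    S6 = "S6"
    CATALYTIC_CORE = "catalytic_core"
    HAIRPIN = "hairpin"
    BUFFER = "buffer"
    CLEAVAGE_SITE = "cleavage_site"


class Mode(str, Enum):
    THREE_PRONGED = "three_pronged"
    FOUR_PRONGED = "four_pronged"
    WEIGHTED = "weighted"


class StrandKind(str, Enum):
    ENZYME = "enzyme"
    AUX = "aux"          # the single auxiliary of the three-pronged mode
    AUX_M = "aux_m"      # binds the enzyme's 5' arm (S1); matrix-M element
    AUX_X = "aux_x"      # binds the enzyme's 3' arm (S5); matrix-X element
    SUBSTRATE = "substrate"
    FRAGMENT_F = "fragment_f"   # 5' cleavage product, carries the fluorophore
    FRAGMENT_Q = "fragment_q"   # 3' cleavage product, carries the quencher


@dataclass(frozen=True)
class StemConfig:
    """The six stem lengths (bp) plus buffer-region flags for one mode.

    Field meaning depends on ``mode``.  Three-pronged: S1/S2 are the
    enzyme-substrate stems (7/3 bp), S3 the auxiliary-enzyme stem (11 bp),
    S4 the auxiliary-substrate stem (10 bp), S5/S6 unused.  Four-pronged
    and weighted: S1/S5 auxiliary-enzyme (11 bp), S3/S6 auxiliary-substrate
    (10 bp, or 14/9 bp weighted), S2/S4 enzyme-substrate junctions (3 bp).
    """

    s1: int
    s2: int
    s3: int
    s4: int
    s5: int = 0
    s6: int = 0
    buffer_s2_s4: bool = False
    buffer_s4_s6: bool = False
    buffer_s2_s3: bool = False
    mode: Mode = Mode.FOUR_PRONGED

    def __post_init__(self) -> None:
        for name in ("s1", "s2", "s3", "s4", "s5", "s6"):
            if getattr(self, name) < 0:
                raise ValueError(f"stem length {name} must be >= 0")

    @classmethod
    def three_pronged_default(cls) -> "StemConfig":
        return cls(s1=7, s2=3, s3=11, s4=10, buffer_s2_s4=True,
                   mode=Mode.THREE_PRONGED)

    @classmethod
    def four_pronged_default(cls) -> "StemConfig":
        return cls(s1=11, s2=3, s3=10, s4=3, s5=11, s6=10,
                   buffer_s4_s6=True, buffer_s2_s3=True,
                   mode=Mode.FOUR_PRONGED)

    @classmethod
    def weighted_default(cls) -> "StemConfig":
        return cls(s1=11, s2=3, s3=14, s4=3, s5=11, s6=9,
                   buffer_s4_s6=True, buffer_s2_s3=True,
                   mode=Mode.WEIGHTED)

    @classmethod
    def default_for(cls, mode: Mode) -> "StemConfig":
        return {
            Mode.THREE_PRONGED: cls.three_pronged_default,
            Mode.FOUR_PRONGED: cls.four_pronged_default,
            Mode.WEIGHTED: cls.weighted_default,
        }[mode]()

    def length_of(self, role: DomainRole) -> int:
        return {
            DomainRole.S1: self.s1, DomainRole.S2: self.s2,
            DomainRole.S3: self.s3, DomainRole.S4: self.s4,
            DomainRole.S5: self.s5, DomainRole.S6: self.s6,
        }[role]


@dataclass(frozen=True)
class Domain:
    """One named sequence segment of a strand.

    ``dom_id`` identifies the sequence instance (e.g. ``"S1[1]"``); the
    complement of domain ``d`` is by convention ``d + "*"``.
    """

    role: DomainRole
    dom_id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError(f"domain {self.dom_id} has empty sequence")
        _check_alphabet(self.seq)
        if self.role is DomainRole.CATALYTIC_CORE and self.seq != CATALYTIC_CORE:
            raise ValueError("catalytic core must be the conserved 15-nt loop")
        if self.role is DomainRole.BUFFER and self.seq != BUFFER_SEQ:
            raise ValueError("buffer domain must be exactly 'TA'")

    @property
    def base_id(self) -> str:
        return self.dom_id[:-1] if self.dom_id.endswith("*") else self.dom_id

    def is_complement_of(self, other: "Domain") -> bool:
        return (self.dom_id == other.dom_id + "*"
                or other.dom_id == self.dom_id + "*")


@dataclass(frozen=True)
class Strand:
    """A named 5'->3' strand as an ordered tuple of domains.

    The full sequence is the concatenation of the domain sequences.  The
    fluorophore/quencher labels are channel metadata, not chemistry: a
    cleaved fluorophore-bearing fragment is what produces signal.
    """

    name: str
    domains: Tuple[Domain, ...]
    kind: StrandKind
    fluorophore: Optional[str] = None
    quencher: Optional[str] = None
    index: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.domains:
            raise ValueError(f"strand {self.name} has no domains")
        n_ra = self.seq.count(RIBO_A)
        if n_ra > 1:
            raise ValueError(f"strand {self.name}: more than one rA site")
        if n_ra == 1 and self.kind not in (StrandKind.SUBSTRATE,
                                           StrandKind.FRAGMENT_F):
            raise ValueError(
                f"strand {self.name}: rA allowed only in substrate strands")
        if (self.fluorophore is None) != (self.quencher is None) and \
                self.kind is StrandKind.SUBSTRATE:
            raise ValueError(
                f"strand {self.name}: a labeled substrate needs both a "
                f"fluorophore and a quencher")

    @property
    def seq(self) -> str:
        return "".join(d.seq for d in self.domains)

    @property
    def channel(self) -> Optional[str]:
        return self.fluorophore

    def __len__(self) -> int:
        return len(self.seq)

    def domain(self, dom_id: str) -> Domain:
        for d in self.domains:
            if d.dom_id == dom_id:
                return d
        raise KeyError(f"strand {self.name} has no domain {dom_id!r}")


@dataclass(frozen=True)
class ComplexSpec:
    """A declared multi-strand complex: members plus the stems holding it.

    ``paired_stems`` entries are (strand_a, dom_id_a, strand_b, dom_id_b).
    ``cleavage_competent`` follows the structural rule: the complex holds
    an enzyme, the full auxiliary complement for its mode, and a substrate
    engaged on both enzyme junction stems.
    """

    members: Tuple[str, ...]
    paired_stems: Tuple[Tuple[str, str, str, str], ...]
    cleavage_competent: bool

    @property
    def name(self) -> str:
        return "+".join(sorted(self.members))


def required_aux_kinds(mode: Mode) -> Tuple[StrandKind, ...]:
    if mode is Mode.THREE_PRONGED:
        return (StrandKind.AUX,)
    return (StrandKind.AUX_M, StrandKind.AUX_X)


def is_cleavage_competent(member_strands: Iterable[Strand], mode: Mode,
                          stem_config: StemConfig) -> bool:
    """Structural competence: enzyme + full auxiliary complement +
    an uncleaved substrate, with both enzyme junction stems present
    (a 0-bp junction cannot engage the cleavage site)."""
    kinds = [s.kind for s in member_strands]
    if kinds.count(StrandKind.ENZYME) != 1:
        return False
    if kinds.count(StrandKind.SUBSTRATE) != 1:
        return False
    for needed in required_aux_kinds(mode):
        if needed not in kinds:
            return False
    if mode is Mode.THREE_PRONGED:
        return stem_config.s1 > 0 and stem_config.s2 > 0
    return stem_config.s2 > 0 and stem_config.s4 > 0


@dataclass
class ValidationReport:
    """Result of checking a declared complex against a strand library."""

    passed: bool
    stems: List[Dict[str, object]] = field(default_factory=list)
    messages: List[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_complex(cspec: ComplexSpec, lib) -> ValidationReport:
    """Check every declared stem of a complex for full Watson-Crick
    complementarity and for length agreement with the library's stem
    configuration; recompute the cleavage-competence flag structurally.

    ``lib`` is any object with ``strands`` (name -> Strand), ``stem_config``
    and ``mode`` attributes (a :class:`~dzmatrix.sequence_designer.StrandLibrary`).
    """
    report = ValidationReport(passed=True)
    if not cspec.members:
        report.passed = False
        report.messages.append("no members")
        return report
    try:
        strands = {n: lib.strands[n] for n in cspec.members}
    except KeyError as exc:
        raise LookupError2(f"unknown strand name {exc.args[0]!r}") from exc

    for (sa, da, sb, db) in cspec.paired_stems:
        if sa not in strands or sb not in strands:
            raise LookupError2(f"stem references non-member strand "
                               f"({sa!r} or {sb!r})")
        dom_a = strands[sa].domain(da)
        dom_b = strands[sb].domain(db)
        complementary = dom_b.seq.upper() == reverse_complement(dom_a.seq)
        expected = lib.stem_config.length_of(dom_a.role) \
            if dom_a.role.name.startswith("S") else len(dom_a.seq)
        length_ok = len(dom_a.seq) == len(dom_b.seq) == expected
        report.stems.append({
            "stem": dom_a.base_id,
            "length_bp": len(dom_a.seq),
            "expected_bp": expected,
            "complementary": complementary,
        })
        if not complementary:
            report.passed = False
            report.messages.append(f"stem {dom_a.base_id} not complementary")
        if not length_ok:
            report.passed = False
            report.messages.append(
                f"stem {dom_a.base_id} length {len(dom_a.seq)} != "
                f"configured {expected}")

    competent = is_cleavage_competent(strands.values(), lib.mode,
                                      lib.stem_config)
    if competent != cspec.cleavage_competent:
        report.messages.append(
            f"declared cleavage_competent={cspec.cleavage_competent} but "
            f"structural rule gives {competent}")
        report.passed = False
    return report
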