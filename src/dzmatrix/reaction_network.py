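"""Expand a compiled species system into a mass-action reaction network.

Mechanistic model (four-pronged / matrix mode), per matrix cell (i,j) and
output column k:

    E_j + M_ij          <-> E_j.M_ij            off = k(S1)
    E_j + X_jk          <-> E_j.X_jk            off = k(S5)
    E_j.M_ij + X_jk     <-> E_j.M_ij.X_jk       off = k(S5)
    E_j.X_jk + M_ij     <-> E_j.M_ij.X_jk       off = k(S1)
    E_j.M_ij.X_jk + R_i <-> full complex        off = k(S2+S3+S4+S6)
    E_j.M_ij + R_i      <-> one-armed (M side)  off = k(S2+S3)
    E_j.X_jk + R_i'     <-> one-armed (X side)  off = k(S4+S6)   (any row i';
                             the X-side substrate arm is a shared domain)
    one-armed + partner aux -> full complex     (assembly completion)
    full  -> cleaved complex                    k_cat * pH * junction factor
    cleaved -> E.M.X + 5' frag + 3' frag        off-rate of the more stably
                                                held fragment
    one-armed -> E.aux + frags                  k_leak (leak channel)

where k(L) = k_on * exp(-dG_bp * L) is the stem off-rate for L engaged
base pairs (strictly decreasing in L).  The complex set is bounded: each
enzyme arm binds at most one auxiliary, each auxiliary at most one
substrate, no auxiliary.substrate binaries and no enzyme.substrate binary
in four-pronged mode (the two 3-bp junctions alone do not hold).  The
three-pronged mechanism is the analogous network with a single auxiliary
and a direct 7-bp enzyme-substrate stem, whose enzyme.substrate binary IS
the leak-competent complex.

Strand conservation holds structurally for every reaction when the two
cleavage fragments of a substrate are counted as its halves.
"""

from __future__ import annotations

import math
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Tuple

from .matrix_compiler import SpeciesSystem
from .sequence_designer import StrandLibrary, make_complex
from .strand_model import ComplexSpec, Mode, StrandKind

__all__ = [
    "KineticParams",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "default_ph_activity",
    "enumerate_complexes",
    "stem_off_rate",
]


def default_ph_activity(ph: float) -> float:
    """Relative DNAzyme activity vs pH: 1.0 on the peak window [8.0, 9.0],
    linear falloff to 0 at pH 6.0 below and pH 10.5 above."""
    if 8.0 <= ph <= 9.0:
        return 1.0
    if ph < 8.0:
        return max(0.0, (ph - 6.0) / 2.0)
    return max(0.0, (10.5 - ph) / 1.5)


@dataclass
class KineticParams:
    """Rate constants and environmental modifiers.

    k_on      bimolecular association rate, 1/M/s
    dG_bp     stem stability increment per base pair (dimensionless
              exponent unit): off-rate = k_on * exp(-dG_bp * L)
    k_cat     cleavage rate from a cleavage-competent complex, 1/s
    k_leak    cleavage rate from a one-armed substrate complex, 1/s
    ph        reaction pH; activity multiplier from ``ph_activity``
    mg_present  the enzyme is Mg2+-dependent; without the cofactor all
              cleavage rates are forced to zero

    Defaults are chosen so the default designs separate positive and
    negative endpoints by far more than 10x within the standard sampling
    horizon; no rate constants are fitted to bench data.
    """

    k_on: float = 1.0e5
    dG_bp: float = 1.5
    k_cat: float = 1.0e-3
    k_leak: float = 0.0
    ph: float = 8.0
    ph_activity: Callable[[float], float] = default_ph_activity
    mg_present: bool = True

    def __post_init__(self) -> None:
        for name in ("k_on", "dG_bp", "k_cat", "k_leak"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.mg_present and (self.k_cat > 0 or self.k_leak > 0):
            _warnings.warn("mg_present is False: cleavage rates forced to "
                           "zero (Mg2+-dependent enzyme)", stacklevel=2)
            self.k_cat = 0.0
            self.k_leak = 0.0
        mult = self.ph_activity(self.ph)
        if not (0.0 <= mult <= 1.0):
            raise ValueError("ph_activity must map into [0, 1]")

    @property
    def ph_multiplier(self) -> float:
        return self.ph_activity(self.ph)

    def effective_k_cat(self, junction_lengths: Iterable[int]) -> float:
        """Cleavage rate scaled by pH activity and by the occupancy of
        the enzyme-substrate junction stems: a 0-bp junction cannot
        engage the cleavage site at all."""
        rate = self.k_cat * self.ph_multiplier
        for L in junction_lengths:
            rate *= 1.0 - math.exp(-self.dG_bp * L)
        return rate

    def effective_k_leak(self) -> float:
        return self.k_leak * self.ph_multiplier


def stem_off_rate(length_bp: int, params: KineticParams) -> float:
    """Unimolecular dissociation rate of a duplex held by ``length_bp``
    base pairs: ``k_on * exp(-dG_bp * length_bp)`` (concentration-matched
    units; strictly decreasing in length)."""
    if length_bp < 0:
        raise ValueError("stem length must be >= 0")
    return params.k_on * math.exp(-params.dG_bp * length_bp)


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction."""

    reactants: Tuple[str, ...]
    products: Tuple[str, ...]
    rate: float
    kind: str  # bind | unbind | cleave | leak | release

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.kind == "bind" and len(self.reactants) != 2:
            raise ValueError("bind reactions are bimolecular")
        if self.kind in ("unbind", "cleave", "leak", "release") and \
                len(self.reactants) != 1:
            raise ValueError(f"{self.kind} reactions are unimolecular")


@dataclass
class ReactionNetwork:
    """Species (with initial concentrations and member strands) plus the
    mass-action reaction list."""

    species: Dict[str, float]                   # name -> initial conc (M)
    members: Dict[str, Tuple[str, ...]]         # name -> member strands
    reactions: List[Reaction]
    library: StrandLibrary
    params: KineticParams
    channel_species: Dict[str, List[Tuple[str, int]]] = \
        field(default_factory=dict)

    def atoms_of(self, species_name: str) -> Tuple[str, ...]:
        """Elementary strand atoms of a species; a substrate counts as its
        two cleavage halves so that cleavage conserves atoms."""
        out: List[str] = []
        for m in self.members[species_name]:
            strand = self.library.strands[m]
            if strand.kind is StrandKind.SUBSTRATE:
                f5, f3 = self.library.fragment_names(m)
                out += [f5, f3]
            else:
                out.append(m)
        return tuple(sorted(out))

    def check_strand_conservation(self) -> None:
        """Structural invariant: the multiset of strand atoms is identical
        on both sides of every reaction."""
        for rxn in self.reactions:
            lhs: List[str] = []
            rhs: List[str] = []
            for s in rxn.reactants:
                lhs += self.atoms_of(s)
            for s in rxn.products:
                rhs += self.atoms_of(s)
            if sorted(lhs) != sorted(rhs):
                raise AssertionError(
                    f"strand conservation violated in {rxn}")

    def reaction_table(self) -> str:
        lines = ["# reactants -> products\trate_per_s_or_per_M_s\tkind"]
        for r in self.reactions:
            lines.append(
                f"{' + '.join(r.reactants)} -> {' + '.join(r.products)}"
                f"\t{r.rate:.6g}\t{r.kind}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# species naming

def _cname(*members: str) -> str:
    return ".".join(sorted(members))


def enumerate_complexes(sys: SpeciesSystem) -> List[ComplexSpec]:
    """All complex types reachable from the present species, as
    :class:`ComplexSpec` objects (free single strands excluded)."""
    lib = sys.library
    specs: Dict[Tuple[str, ...], ComplexSpec] = {}

    def add(members: Iterable[str]) -> None:
        key = tuple(sorted(members))
        if key not in specs:
            specs[key] = make_complex(lib, key)

    present = set(sys.initial)
    if lib.mode is Mode.THREE_PRONGED:
        e = lib.enzymes[0]
        a = lib.aux_m[(0, 0)]
        s = lib.substrates[0]
        add((e, s))
        if a in present:
            add((e, a))
            add((e, a, s))
        return list(specs.values())

    k = sys.column if sys.column is not None else 0
    for j in range(sys.n_cols):
        e = lib.enzymes[j]
        if e not in present:
            continue
        x = lib.aux_x.get((j, k))
        x_present = x in present
        if x_present:
            add((e, x))
        for i in range(sys.n_rows):
            m = lib.aux_m[(i, j)]
            if m not in present:
                continue
            r = lib.substrates[i]
            add((e, m))
            add((e, m, r))
            if x_present:
                add((e, m, x))
                add((e, m, x, r))
        if x_present:
            for i in range(sys.n_rows):
                add((e, x, lib.substrates[i]))
    return list(specs.values())


# ---------------------------------------------------------------------------
# network construction

def build_network(sys: SpeciesSystem,
                  params: Optional[KineticParams] = None) -> ReactionNetwork:
    """Build the mass-action network for a single-well species system."""
    if params is None:
        params = KineticParams()
    if sys.k_cols != 1 and sys.column is None:
        raise ValueError("multi-column systems must be split into wells; "
                         "use sys.well(k)")
    lib = sys.library
    if lib.mode is Mode.THREE_PRONGED:
        return _build_three_pronged(sys, params)
    return _build_four_pronged(sys, params)


class _NetBuilder:
    def __init__(self, sys: SpeciesSystem, params: KineticParams):
        self.sys = sys
        self.lib = sys.library
        self.params = params
        self.species: Dict[str, float] = {}
        self.members: Dict[str, Tuple[str, ...]] = {}
        self.reactions: List[Reaction] = []

    def sp(self, *strands: str, conc: float = 0.0) -> str:
        name = _cname(*strands)
        if name not in self.species:
            self.species[name] = conc
            self.members[name] = tuple(sorted(strands))
        return name

    def rxn(self, reactants, products, rate, kind):
        if rate <= 0 and kind in ("cleave", "leak"):
            return  # zero-rate catalytic channels are omitted entirely
        self.reactions.append(Reaction(tuple(reactants), tuple(products),
                                       rate, kind))

    def bind(self, a: str, b: str, complex_name: str, off_bp: int):
        """Reversible a + b <-> complex with off-rate from engaged bp."""
        self.rxn([a, b], [complex_name], self.params.k_on, "bind")
        self.rxn([complex_name], [a, b],
                 stem_off_rate(off_bp, self.params), "unbind")

    def done(self) -> ReactionNetwork:
        net = ReactionNetwork(species=self.species, members=self.members,
                              reactions=self.reactions, library=self.lib,
                              params=self.params,
                              channel_species=_channel_map(
                                  self.lib, self.members))
        net.check_strand_conservation()
        return net


def _channel_map(lib: StrandLibrary, members: Dict[str, Tuple[str, ...]]
                 ) -> Dict[str, List[Tuple[str, int]]]:
    """channel -> [(species, multiplicity of the fluorophore fragment)].
    Signal counts every cleaved fluorophore-bearing fragment, free or in
    a complex (backbone scission separates it from the quencher)."""
    out: Dict[str, List[Tuple[str, int]]] = {}
    for i, sub in lib.substrates.items():
        f5, _ = lib.fragment_names(sub)
        channel = lib.strands[sub].fluorophore
        pairs = []
        for name, mem in members.items():
            mult = sum(1 for m in mem if m == f5)
            if mult:
                pairs.append((name, mult))
        out[channel] = pairs
    return out


def _build_four_pronged(sys: SpeciesSystem,
                        params: KineticParams) -> ReactionNetwork:
    b = _NetBuilder(sys, params)
    lib, cfg = sys.library, sys.library.stem_config
    present = set(sys.initial)
    k = sys.column if sys.column is not None else 0
    k_cat = params.effective_k_cat((cfg.s2, cfg.s4))
    k_leak = params.effective_k_leak()
    sup_f = cfg.s3 + cfg.s2          # 5' fragment: aux-M arm + S2 junction
    sup_q = cfg.s4 + cfg.s6          # 3' fragment: S4 junction + aux-X arm
    k_release = stem_off_rate(max(sup_f, sup_q), params)

    # free species
    for name, conc in sys.initial.items():
        b.sp(name, conc=conc)
    for i in range(sys.n_rows):
        f5, f3 = lib.fragment_names(lib.substrates[i])
        b.sp(f5)
        b.sp(f3)

    for j in range(sys.n_cols):
        e = lib.enzymes[j]
        if e not in present:      # zero-weight column: no enzyme species
            continue
        x = lib.aux_x.get((j, k))
        x_present = x in present
        if x_present:
            ex = b.sp(e, x)
            b.bind(e, x, ex, cfg.s5)
        for i in range(sys.n_rows):
            m = lib.aux_m[(i, j)]
            if m not in present:
                continue
            r = lib.substrates[i]
            f5, f3 = lib.fragment_names(r)
            em = b.sp(e, m)
            b.bind(e, m, em, cfg.s1)
            # one-armed substrate complex, M side
            ems = b.sp(e, m, r)
            b.bind(em, r, ems, cfg.s2 + cfg.s3)
            if k_leak > 0:
                b.rxn([ems], [em, f5, f3], k_leak, "leak")
            if x_present:
                emx = b.sp(e, m, x)
                b.bind(em, x, emx, cfg.s5)
                b.bind(b.sp(e, x), m, emx, cfg.s1)
                full = b.sp(e, m, x, r)
                b.bind(emx, r, full, cfg.s2 + cfg.s3 + cfg.s4 + cfg.s6)
                # assembly completion through the one-armed intermediates
                b.rxn([ems, x], [full], params.k_on, "bind")
                b.rxn([full], [ems, x],
                      stem_off_rate(cfg.s5 + cfg.s6, params), "unbind")
                exs = b.sp(e, x, r)
                b.rxn([exs, m], [full], params.k_on, "bind")
                b.rxn([full], [exs, m],
                      stem_off_rate(cfg.s1 + cfg.s3, params), "unbind")
                if k_cat > 0:
                    cleaved = b.sp(e, m, x, f5, f3)
                    b.rxn([full], [cleaved], k_cat, "cleave")
                    b.rxn([cleaved], [emx, f5, f3], k_release, "release")
        # one-armed substrate complexes on the X side (shared S6 domain:
        # every reporter row can park on an E.X complex)
        if x_present:
            for i in range(sys.n_rows):
                r = lib.substrates[i]
                f5, f3 = lib.fragment_names(r)
                exs = b.sp(e, x, r)
                b.bind(ex, r, exs, cfg.s4 + cfg.s6)
                if k_leak > 0:
                    b.rxn([exs], [ex, f5, f3], k_leak, "leak")
    return b.done()


def _build_three_pronged(sys: SpeciesSystem,
                         params: KineticParams) -> ReactionNetwork:
    b = _NetBuilder(sys, params)
    lib, cfg = sys.library, sys.library.stem_config
    e, s = lib.enzymes[0], lib.substrates[0]
    a = lib.aux_m[(0, 0)]
    aux_present = a in sys.initial
    f5, f3 = lib.fragment_names(s)
    k_cat = params.effective_k_cat((cfg.s2,)) if cfg.s1 > 0 else 0.0
    k_leak = params.effective_k_leak()
    sup_f = cfg.s1                   # 5' fragment keeps the S1 stem
    sup_q = cfg.s2 + cfg.s4          # 3' fragment: junction + aux arm
    k_release = stem_off_rate(max(sup_f, sup_q), params)

    for name, conc in sys.initial.items():
        b.sp(name, conc=conc)
    b.sp(f5)
    b.sp(f3)

    # direct enzyme-substrate binary: held by S1 (+S2); leak-competent
    es = b.sp(e, s)
    b.bind(e, s, es, cfg.s1 + cfg.s2)
    if k_leak > 0:
        b.rxn([es], [e, f5, f3], k_leak, "leak")

    if aux_present:
        ea = b.sp(e, a)
        b.bind(e, a, ea, cfg.s3)
        full = b.sp(e, a, s)
        b.bind(ea, s, full, cfg.s1 + cfg.s2 + cfg.s4)
        b.rxn([es, a], [full], params.k_on, "bind")
        b.rxn([full], [es, a],
              stem_off_rate(cfg.s3 + cfg.s4, params), "unbind")
        if k_cat > 0:
            cleaved = b.sp(e, a, f5, f3)
            b.rxn([full], [cleaved], k_cat, "cleave")
            b.rxn([cleaved], [ea, f5, f3], k_release, "release")
    return b.done()
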