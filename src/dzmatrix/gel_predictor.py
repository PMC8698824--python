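"""Native-PAGE lane prediction: which complexes assemble from a declared
lane mixture and which bands (ordered by size) the lane shows.

Assembly is a greedy maximal rule at the same structural abstraction as
the kinetic model:

* an auxiliary strand joins an enzyme (or enzyme complex) iff its
  enzyme-arm stem meets the ``stability_min`` cutoff;
* the substrate joins only a complex that carries the full auxiliary
  complement for the library's mode, with every substrate anchor stem
  meeting the cutoff -- a one-armed or bare enzyme leaves the substrate
  free in solution (junction stems alone, 3+3 bp, do not hold);
* if the assembled complex is cleavage-competent and the kinetic
  parameters allow cleavage, the substrate is replaced by its two
  cleavage products, which run as separate bands (the nicked halves
  dissociate on the electrophoresis timescale).

Migration is modelled by total nucleotide count only: the band list is
ordered by decreasing size (slowest first).  Band intensities, staining
and migration distances are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .reaction_network import KineticParams
from .sequence_designer import StrandLibrary
from .strand_model import LookupError2, Mode, StrandKind

__all__ = ["BandList", "LaneSpec", "predict_lane", "DEFAULT_STABILITY_MIN"]

#: Minimum engaged base pairs (summed over the stems of one contact) for a
#: binary association to survive native PAGE.
DEFAULT_STABILITY_MIN = 6


@dataclass(frozen=True)
class LaneSpec:
    """One lane: member strand names with relative stoichiometry."""

    lane_id: str
    members: Dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.members.values()):
            raise ValueError("stoichiometries must be > 0")


@dataclass(frozen=True)
class Band:
    members: Tuple[str, ...]
    total_nt: int
    amount: float

    @property
    def label(self) -> str:
        return "+".join(self.members)


@dataclass
class BandList:
    """Bands of one lane, ordered by decreasing total nucleotide count."""

    lane_id: str
    bands: List[Band] = field(default_factory=list)

    def total_nucleotides(self) -> float:
        return sum(b.total_nt * b.amount for b in self.bands)

    def band_members(self) -> List[Tuple[str, ...]]:
        return [b.members for b in self.bands]

    def has_band_containing(self, *strands: str) -> bool:
        return any(all(s in b.members for s in strands) for b in self.bands)

    def __len__(self) -> int:
        return len(self.bands)


def _strand_nt(lib: StrandLibrary, name: str) -> int:
    return len(lib.strands[name].seq)


def predict_lane(lane: LaneSpec, lib: StrandLibrary,
                 params: Optional[KineticParams] = None,
                 stability_min: int = DEFAULT_STABILITY_MIN) -> BandList:
    """Predict the ordered band list for one lane."""
    if params is None:
        params = KineticParams()
    for name in lane.members:
        if name not in lib.strands:
            raise LookupError2(f"unknown strand {name!r} in lane "
                               f"{lane.lane_id}")
    cfg = lib.stem_config
    avail = dict(lane.members)
    complexes: List[Tuple[List[str], float]] = []

    def take(names: List[str]) -> float:
        amt = min(avail[n] for n in names)
        if amt > 0:
            for n in names:
                avail[n] -= amt
        return amt

    enzymes = [n for n in lane.members
               if lib.strands[n].kind is StrandKind.ENZYME]
    substrates = [n for n in lane.members
                  if lib.strands[n].kind is StrandKind.SUBSTRATE]

    # 1. auxiliaries join enzymes via their enzyme-arm stems
    for e in enzymes:
        e_idx = lib.strands[e].index
        partners: List[str] = []
        for n in lane.members:
            s = lib.strands[n]
            if s.kind is StrandKind.AUX and cfg.s3 >= stability_min:
                partners.append(n)
            elif s.kind is StrandKind.AUX_M and cfg.s1 >= stability_min \
                    and (not e_idx or s.index[1] == e_idx[0]):
                partners.append(n)
            elif s.kind is StrandKind.AUX_X and cfg.s5 >= stability_min \
                    and (not e_idx or s.index[0] == e_idx[0]):
                partners.append(n)
        group = [e] + partners
        amt = take(group)
        if amt > 0:
            complexes.append((group, amt))

    # 2. substrate joins only a full-auxiliary-complement complex
    for r in substrates:
        r_row = lib.strands[r].index
        for idx, (group, amt) in enumerate(list(complexes)):
            kinds = [lib.strands[n].kind for n in group]
            if lib.mode is Mode.THREE_PRONGED:
                complete = StrandKind.AUX in kinds
                anchors = [cfg.s4, cfg.s1]
            else:
                m_ok = any(lib.strands[n].kind is StrandKind.AUX_M
                           and (not r_row or lib.strands[n].index[0] ==
                                r_row[0]) for n in group)
                complete = m_ok and StrandKind.AUX_X in kinds
                anchors = [cfg.s3, cfg.s6]
            if not complete or any(a < stability_min for a in anchors):
                continue
            if avail.get(r, 0) <= 0:
                continue
            joined = min(amt, avail[r])
            avail[r] -= joined
            complexes[idx] = (group, amt - joined)
            complexes.append((group + [r], joined))

    # 3. cleavage of competent complexes; products run separately
    final: List[Tuple[List[str], float]] = []
    for group, amt in complexes:
        if amt <= 0:
            continue
        subs = [n for n in group
                if lib.strands[n].kind is StrandKind.SUBSTRATE]
        if subs:
            from .strand_model import is_cleavage_competent
            competent = is_cleavage_competent(
                [lib.strands[n] for n in group], lib.mode, cfg)
            k_cat = params.effective_k_cat(
                (cfg.s2, cfg.s4) if lib.mode is not Mode.THREE_PRONGED
                else (cfg.s2,))
            if competent and k_cat > 0:
                rest = [n for n in group if n not in subs]
                final.append((rest, amt))
                for sname in subs:
                    f5, f3 = lib.fragment_names(sname)
                    final.append(([f5], amt))
                    final.append(([f3], amt))
                continue
        final.append((group, amt))
    for n, amt in avail.items():
        if amt > 0:
            final.append(([n], amt))

    # merge identical species, order by decreasing size
    merged: Dict[Tuple[str, ...], float] = {}
    for group, amt in final:
        key = tuple(sorted(group))
        merged[key] = merged.get(key, 0.0) + amt
    bands = [Band(members=key,
                  total_nt=sum(_strand_nt(lib, n) for n in key),
                  amount=amt)
             for key, amt in merged.items() if amt > 0]
    bands.sort(key=lambda b: (-b.total_nt, b.members))
    out = BandList(lane_id=lane.lane_id, bands=bands)

    # nucleotide conservation: bands account for all input nucleotides
    total_in = sum(_strand_nt(lib, n) * s for n, s in lane.members.items())
    if abs(out.total_nucleotides() - total_in) > 1e-9 * max(total_in, 1):
        raise AssertionError(
            f"lane {lane.lane_id}: nucleotide conservation violated")
    return out
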