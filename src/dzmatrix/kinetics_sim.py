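"""Deterministic ODE integration of the reaction network, fluorescence
trace extraction, normalization and Boolean / integer-level readout.

Fluorescence on a channel is the total concentration of that channel's
cleaved fluorophore-bearing fragment (free or complexed), scaled 1:1;
arbitrary-unit scaling is absorbed by the normalization step, which
divides every run by the per-channel global maximum across a run set --
the same "unified normalization" applied to the bench fluorescence data
this simulator emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .matrix_compiler import BooleanMatrix
from .reaction_network import ReactionNetwork

__all__ = [
    "BOOLEAN_GRID",
    "IntegrationError",
    "ReadoutConfig",
    "SimulationGrid",
    "THREE_PRONGED_GRID",
    "TraceSet",
    "WEIGHTED_GRID",
    "call_boolean",
    "call_weighted",
    "normalize",
    "simulate",
]


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last valid time (minutes)."""

    def __init__(self, message: str, last_time_min: float):
        super().__init__(message)
        self.last_time_min = last_time_min


@dataclass(frozen=True)
class SimulationGrid:
    """Sampling grid: ``cycles`` samples every ``interval_min`` minutes
    (plus the t=0 sample); t_end = interval * cycles."""

    interval_min: float
    cycles: int

    def __post_init__(self) -> None:
        if self.interval_min <= 0:
            raise ValueError("interval must be > 0")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    @property
    def t_end_min(self) -> float:
        return self.interval_min * self.cycles

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.cycles + 1) * self.interval_min


#: Grids used by the packaged demos (sampling interval x cycle counts of
#: the corresponding bench kinetics runs).
THREE_PRONGED_GRID = SimulationGrid(4.0, 150)
BOOLEAN_GRID = SimulationGrid(4.0, 300)
WEIGHTED_GRID = SimulationGrid(7.0, 200)


@dataclass
class TraceSet:
    """Per-channel time courses of cleaved-reporter concentration (M)."""

    times_min: np.ndarray
    channels: Dict[str, np.ndarray]
    metadata: Dict[str, object] = field(default_factory=dict)
    species_traces: Dict[str, np.ndarray] = field(default_factory=dict)
    normalized: Optional[Dict[str, np.ndarray]] = None

    def endpoint(self, channel: str) -> float:
        return float(self.channels[channel][-1])

    def normalized_endpoint(self, channel: str) -> float:
        if self.normalized is None:
            raise ValueError("run normalize() first")
        return float(self.normalized[channel][-1])


@dataclass(frozen=True)
class ReadoutConfig:
    """Readout thresholds.

    ``boolean_threshold``: a channel calls "1" iff its endpoint reaches
    this fraction of the positive-control endpoint.  ``unit_level`` is
    the endpoint of a single-combination weight-1 calibration run;
    ``level_tolerance`` is the accepted fractional deviation from an
    integer multiple of it.
    """

    boolean_threshold: float = 0.5
    unit_level: Optional[float] = None
    level_tolerance: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.boolean_threshold < 1.0):
            raise ValueError("boolean_threshold must be in (0, 1)")
        if self.level_tolerance <= 0:
            raise ValueError("level_tolerance must be > 0")


def simulate(net: ReactionNetwork, grid: SimulationGrid,
             rtol: float = 1e-8, atol: float = 1e-12,
             keep_species: bool = True,
             metadata: Optional[Dict[str, object]] = None) -> TraceSet:
    """Integrate the network over the grid with a stiff-capable solver.

    Returns the per-channel cleaved-reporter traces; species trajectories
    are retained for conservation checks unless ``keep_species=False``.
    """
    names = list(net.species)
    index = {n: i for i, n in enumerate(names)}
    y0 = np.array([net.species[n] for n in names], dtype=float)

    n_rxn = len(net.reactions)
    times_s = grid.times_min * 60.0

    if n_rxn == 0:
        y = np.tile(y0[:, None], (1, len(times_s)))
        return _package(net, grid, names, y, keep_species, metadata)

    rates = np.array([r.rate for r in net.reactions])
    ia = np.empty(n_rxn, dtype=int)
    ib = np.full(n_rxn, -1, dtype=int)
    stoich = np.zeros((len(names), n_rxn))
    for r_i, rxn in enumerate(net.reactions):
        ra = [index[s] for s in rxn.reactants]
        ia[r_i] = ra[0]
        if len(ra) == 2:
            ib[r_i] = ra[1]
        for s_i in ra:
            stoich[s_i, r_i] -= 1
        for s in rxn.products:
            stoich[index[s], r_i] += 1
    bimol = ib >= 0
    ib_safe = np.where(bimol, ib, 0)

    def rhs(_t, y):
        flux = rates * y[ia]
        flux = np.where(bimol, flux * y[ib_safe], flux)
        return stoich @ flux

    sol = solve_ivp(rhs, (0.0, times_s[-1]), y0, method="LSODA",
                    t_eval=times_s, rtol=rtol, atol=atol)
    if not sol.success:
        last = sol.t[-1] / 60.0 if sol.t.size else 0.0
        raise IntegrationError(
            f"integrator failed: {sol.message}", last_time_min=last)
    y = np.clip(sol.y, 0.0, None)   # clip integrator noise below zero
    return _package(net, grid, names, y, keep_species, metadata)


def _package(net, grid, names, y, keep_species, metadata) -> TraceSet:
    index = {n: i for i, n in enumerate(names)}
    channels: Dict[str, np.ndarray] = {}
    for channel, pairs in net.channel_species.items():
        total = np.zeros(y.shape[1])
        for sp, mult in pairs:
            total += mult * y[index[sp]]
        channels[channel] = total
    species_traces = {n: y[i] for n, i in index.items()} if keep_species \
        else {}
    return TraceSet(times_min=grid.times_min.copy(), channels=channels,
                    metadata=dict(metadata or {}),
                    species_traces=species_traces)


def conservation_residual(net: ReactionNetwork, traces: TraceSet
                          ) -> float:
    """Largest relative drift of any elementary-strand total over the
    trajectory (0 for a perfectly conservative integration)."""
    if not traces.species_traces:
        raise ValueError("simulate with keep_species=True")
    atom_totals: Dict[str, np.ndarray] = {}
    for name, trace in traces.species_traces.items():
        for atom in net.atoms_of(name):
            atom_totals[atom] = atom_totals.get(atom, 0.0) + trace
    worst = 0.0
    for total in atom_totals.values():
        ref = total[0]
        if ref <= 0:
            worst = max(worst, float(np.abs(total).max()))
        else:
            worst = max(worst, float(np.abs(total - ref).max() / ref))
    return worst


def normalize(traces: Sequence[TraceSet]) -> List[TraceSet]:
    """Unified per-channel normalization across a run collection: every
    run's channel is divided by the global maximum of that channel over
    the whole collection.  An all-zero channel is left at zero."""
    if not traces:
        raise ValueError("empty trace collection")
    channels = set(traces[0].channels)
    for t in traces:
        if set(t.channels) != channels:
            raise ValueError("all runs must share the same channels")
    global_max = {c: max(float(t.channels[c].max()) for t in traces)
                  for c in channels}
    out = []
    for t in traces:
        norm = {}
        for c in channels:
            gm = global_max[c]
            norm[c] = t.channels[c] / gm if gm > 0 else \
                np.zeros_like(t.channels[c])
        out.append(replace(t, normalized=norm))
    return out


def call_boolean(traces: Sequence[TraceSet], readout: ReadoutConfig,
                 controls: Dict[str, float],
                 channel_order: Optional[Sequence[str]] = None
                 ) -> List[BooleanMatrix]:
    """Call each run's output column: entry 1 iff the channel endpoint
    reaches ``boolean_threshold`` x the positive-control endpoint.

    ``controls`` maps channel -> positive-control endpoint (same units as
    the traces).  Returns one (n_rows x 1) Boolean matrix per run, rows
    ordered by ``channel_order`` (default: metadata ``channels`` of each
    run, else sorted channel names).
    """
    out = []
    for t in traces:
        order = list(channel_order or t.metadata.get("channels")
                     or sorted(t.channels))
        col = []
        for c in order:
            if c not in controls:
                raise ValueError(f"missing positive control for channel {c}")
            if controls[c] <= 0:
                raise ValueError(f"non-positive control endpoint for {c}")
            col.append(1 if t.endpoint(c) >=
                       readout.boolean_threshold * controls[c] else 0)
        out.append(BooleanMatrix.column(col))
    return out


def call_weighted(traces: Sequence[TraceSet], readout: ReadoutConfig,
                  substrate_total: Optional[float] = None,
                  channel_order: Optional[Sequence[str]] = None
                  ) -> List[Dict[str, Dict[str, object]]]:
    """Quantize each channel endpoint to an integer level against the
    single-combination calibration endpoint ``readout.unit_level``.

    Flags: ``indeterminate`` when the endpoint is not within
    ``level_tolerance`` (fractionally) of an integer multiple of the unit
    level; ``saturated`` when the endpoint has consumed (>= 95% of) the
    total substrate, i.e. the level may be substrate-limited.
    """
    if readout.unit_level is None or readout.unit_level <= 0:
        raise ValueError("a positive unit_level calibration is required")
    unit = readout.unit_level
    out = []
    for t in traces:
        order = list(channel_order or t.metadata.get("channels")
                     or sorted(t.channels))
        calls: Dict[str, Dict[str, object]] = {}
        for c in order:
            end = t.endpoint(c)
            ratio = end / unit
            level = int(round(ratio))
            dev = abs(ratio - level)
            flags: List[str] = []
            if level > 0 and dev > readout.level_tolerance * level:
                flags.append("indeterminate")
            elif level == 0 and ratio > readout.level_tolerance:
                flags.append("indeterminate")
            if substrate_total is not None and end >= 0.95 * substrate_total:
                flags.append("saturated")
            calls[c] = {"level": level, "ratio": ratio, "flags": flags}
        out.append(calls)
    return out
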