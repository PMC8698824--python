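"""Packaged demo experiments: the 16-run Boolean 2x2 product and the
three-run weighted-sum experiment, each reported against its arithmetic
oracle.

The Boolean demo enumerates 4 M matrices x 4 X vectors (16 independent
wells), simulates each on the standard 4 min x 300 cycle grid, applies
the unified per-channel normalization across the whole set, thresholds
against a dedicated all-ones positive control, and compares the called
output with the Boolean product oracle.  The default M set (identity,
all-ones, lower-triangular, anti-diagonal) covers every output pattern
and is overridable.

The weighted demo runs, per output row, the two single-combination wells
and the both-combinations well with substrate in 2x excess, calibrates
the unit level on the first single-combination endpoint and quantizes the
levels (expected 1, 1, 2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kinetics_sim import (
    BOOLEAN_GRID,
    WEIGHTED_GRID,
    ReadoutConfig,
    SimulationGrid,
    TraceSet,
    call_boolean,
    call_weighted,
    normalize,
    simulate,
)
from .matrix_compiler import (
    BooleanMatrix,
    ConcentrationConfig,
    WeightConfig,
    compile_system,
    reference_product,
    reference_weighted_sum,
)
from .reaction_network import KineticParams, build_network
from .sequence_designer import (
    DesignConstraints,
    MatrixLibrary,
    design_matrix_library,
)
from .strand_model import StemConfig

__all__ = [
    "DEFAULT_M_SET",
    "DEFAULT_X_SET",
    "RunRecord",
    "RunReport",
    "export_bundle",
    "run_boolean_demo",
    "run_weighted_demo",
]

#: Demo M matrices: identity, all-ones, lower-triangular, anti-diagonal.
DEFAULT_M_SET: Tuple[Tuple[Tuple[int, int], ...], ...] = (
    ((1, 0), (0, 1)),
    ((1, 1), (1, 1)),
    ((1, 0), (1, 1)),
    ((0, 1), (1, 0)),
)

#: All four Boolean input vectors.
DEFAULT_X_SET: Tuple[Tuple[int, int], ...] = ((0, 0), (0, 1), (1, 0), (1, 1))


@dataclass
class RunRecord:
    label: str
    M: List[List[int]]
    X: List[List[int]]
    weights: List[float]
    called: List[List[int]]
    reference: List[List[int]]
    match: bool
    endpoints: Dict[str, float] = field(default_factory=dict)


@dataclass
class RunReport:
    runs: List[RunRecord]
    seed: int
    config: Dict[str, object]
    traces: List[TraceSet] = field(default_factory=list)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_matches(self) -> int:
        return sum(r.match for r in self.runs)

    @property
    def all_match(self) -> bool:
        return self.n_matches == self.n_runs

    def to_dict(self) -> Dict[str, object]:
        return {
            "seed": self.seed,
            "config": self.config,
            "summary": {"runs": self.n_runs, "matches": self.n_matches},
            "runs": [
                {"label": r.label, "M": r.M, "X": r.X,
                 "weights": r.weights, "called": r.called,
                 "reference": r.reference, "match": r.match,
                 "endpoints": r.endpoints}
                for r in self.runs
            ],
        }


def _simulate_run(lib, M, X, weights, conc, params, grid, label):
    sys = compile_system(M, X, weights=weights, conc=conc, lib=lib)
    net = build_network(sys.well(0), params)
    channels = [lib.channel_of_row(i) for i in range(lib.n_rows)]
    return simulate(net, grid,
                    metadata={"label": label, "M": M.to_list(),
                              "X": X.to_list(), "channels": channels})


def run_boolean_demo(seed: int = 0,
                     m_set: Optional[Sequence] = None,
                     x_set: Optional[Sequence] = None,
                     params: Optional[KineticParams] = None,
                     grid: SimulationGrid = BOOLEAN_GRID,
                     readout: Optional[ReadoutConfig] = None,
                     constraints: Optional[DesignConstraints] = None,
                     ) -> RunReport:
    """Design a 2x2 library, run the 16-well Boolean product demo and
    report agreement with the Boolean-product oracle."""
    if params is None:
        params = KineticParams()
    if readout is None:
        readout = ReadoutConfig()
    if constraints is None:
        constraints = DesignConstraints(
            stem_config=StemConfig.four_pronged_default(), seed=seed)
    m_set = [BooleanMatrix.coerce(np.array(m)) for m in
             (m_set if m_set is not None else DEFAULT_M_SET)]
    x_set = [BooleanMatrix.column(x) for x in
             (x_set if x_set is not None else DEFAULT_X_SET)]

    lib = design_matrix_library(2, 2, 1, constraints)
    conc = ConcentrationConfig.boolean_default()
    weights = WeightConfig.ones(2)
    channels = [lib.channel_of_row(i) for i in range(2)]

    # dedicated positive control: all-ones M and X saturate every channel
    control_trace = _simulate_run(
        lib, BooleanMatrix([[1, 1], [1, 1]]), BooleanMatrix.column([1, 1]),
        weights, conc, params, grid, "positive-control")
    controls = {c: control_trace.endpoint(c) for c in channels}

    traces: List[TraceSet] = []
    pairs: List[Tuple[BooleanMatrix, BooleanMatrix]] = []
    for mi, M in enumerate(m_set):
        for xi, X in enumerate(x_set):
            label = f"M{mi + 1}-X{xi + 1}"
            traces.append(_simulate_run(lib, M, X, weights, conc, params,
                                        grid, label))
            pairs.append((M, X))

    traces = normalize(traces + [control_trace])[:-1]
    calls = call_boolean(traces, readout, controls, channel_order=channels)

    runs = []
    for (M, X), trace, called in zip(pairs, traces, calls):
        ref = reference_product(M, X)
        runs.append(RunRecord(
            label=str(trace.metadata["label"]), M=M.to_list(), X=X.to_list(),
            weights=list(weights.w), called=called.to_list(),
            reference=ref.to_list(), match=called == ref,
            endpoints={c: trace.endpoint(c) for c in channels}))
    config = {
        "mode": "boolean", "grid": {"interval_min": grid.interval_min,
                                    "cycles": grid.cycles},
        "base_conc_M": conc.base_conc,
        "boolean_threshold": readout.boolean_threshold,
        "k_on": params.k_on, "dG_bp": params.dG_bp,
        "k_cat": params.k_cat, "k_leak": params.k_leak, "ph": params.ph,
    }
    return RunReport(runs=runs, seed=seed, config=config,
                     traces=traces)


def run_weighted_demo(seed: int = 0,
                      weights: Optional[WeightConfig] = None,
                      params: Optional[KineticParams] = None,
                      grid: SimulationGrid = WEIGHTED_GRID,
                      readout: Optional[ReadoutConfig] = None,
                      rows: Sequence[int] = (0, 1),
                      ) -> RunReport:
    """Weighted-sum demo: per output row, the two single-combination wells
    and the both-combinations well, substrate at 2x, levels quantized
    against the first single-combination calibration endpoint."""
    if params is None:
        params = KineticParams()
    if readout is None:
        readout = ReadoutConfig()
    if weights is None:
        weights = WeightConfig.ones(2)
    constraints = DesignConstraints(
        stem_config=StemConfig.weighted_default(), seed=seed)
    lib = design_matrix_library(2, 2, 1, constraints)
    conc = ConcentrationConfig.weighted_default()
    channels = [lib.channel_of_row(i) for i in range(2)]

    runs: List[RunRecord] = []
    all_traces: List[TraceSet] = []
    config = {
        "mode": "weighted", "grid": {"interval_min": grid.interval_min,
                                     "cycles": grid.cycles},
        "base_conc_M": conc.base_conc,
        "substrate_multiplier": conc.substrate_multiplier,
        "weights": list(weights.w),
        "level_tolerance": readout.level_tolerance,
    }

    for row in rows:
        channel = channels[row]
        m_single_1 = np.zeros((2, 2), int); m_single_1[row, 0] = 1
        m_single_2 = np.zeros((2, 2), int); m_single_2[row, 1] = 1
        m_both = np.zeros((2, 2), int); m_both[row, :] = 1
        cases = [
            (f"F{row + 1}-combo1", m_single_1, [1, 0]),
            (f"F{row + 1}-combo2", m_single_2, [0, 1]),
            (f"F{row + 1}-both", m_both, [1, 1]),
        ]
        traces = []
        for label, m, x in cases:
            M = BooleanMatrix(m)
            X = BooleanMatrix.column(x)
            traces.append(_simulate_run(lib, M, X, weights, conc, params,
                                        grid, label))
        # dedicated weight-1 single-combination calibration well
        calib = _simulate_run(lib, BooleanMatrix(m_single_1),
                              BooleanMatrix.column([1, 0]),
                              WeightConfig.ones(2), conc, params, grid,
                              f"F{row + 1}-calibration")
        unit = calib.endpoint(channel)
        row_readout = ReadoutConfig(
            boolean_threshold=readout.boolean_threshold,
            unit_level=unit, level_tolerance=readout.level_tolerance)
        sub_total = conc.base_conc * conc.substrate_multiplier
        calls = call_weighted(traces, row_readout, substrate_total=sub_total,
                              channel_order=channels)
        for (label, m, x), trace, call in zip(cases, traces, calls):
            M = BooleanMatrix(m)
            X = BooleanMatrix.column(x)
            ref = reference_weighted_sum(M, X, weights)
            called_levels = [[call[c]["level"]] for c in channels]
            # only the row's own channel is meaningful in a row experiment
            match = called_levels[row][0] == int(ref.ravel()[row])
            runs.append(RunRecord(
                label=label, M=M.to_list(), X=X.to_list(),
                weights=list(weights.w), called=called_levels,
                reference=ref.tolist(), match=match,
                endpoints={c: trace.endpoint(c) for c in channels}))
        all_traces.extend(traces)

    return RunReport(runs=runs, seed=seed, config=config,
                     traces=all_traces)


def export_bundle(report: RunReport, lib: Optional[MatrixLibrary],
                  directory: Path,
                  network=None) -> Dict[str, object]:
    """Write FASTA, trace CSVs, the run report and (optionally) the
    reaction table, plus a checksum manifest."""
    from .io import library_to_fasta, sha256_of, traces_to_dataframe

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files: List[str] = []

    if lib is not None:
        fasta = directory / "library.fasta"
        library_to_fasta(lib, fasta)
        files.append(fasta.name)
        report_path = directory / "design_report.json"
        with open(report_path, "w") as fh:
            json.dump(lib.design_report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        files.append(report_path.name)

    for trace in report.traces:
        label = str(trace.metadata.get("label", "run"))
        path = directory / f"trace_{label}.csv"
        traces_to_dataframe([trace]).to_csv(path, index=False)
        files.append(path.name)

    run_report = directory / "run_report.json"
    with open(run_report, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    files.append(run_report.name)

    if network is not None:
        table = directory / "reactions.txt"
        table.write_text(network.reaction_table() + "\n")
        files.append(table.name)

    manifest = {
        "seed": report.seed,
        "config": report.config,
        "files": {name: sha256_of(directory / name) for name in
                  sorted(files)},
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
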