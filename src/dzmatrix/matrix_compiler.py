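"""Translate a Boolean matrix instance into an initial species system.

Presence/absence encoding: element ``M_ij = 1`` means the M-auxiliary
strand (i,j) is present at the base concentration, ``0`` means it is
absent; likewise for X.  Enzymes and reporter substrates are always
present -- enzymes at ``base_conc * w_j`` (weights are concentration
multipliers), substrates at ``base_conc * substrate_multiplier`` (1x in
Boolean mode, 2x in weighted mode so that a level-2 sum is not
substrate-limited).

The module also owns the exact arithmetic oracles the simulation must
agree with: the Boolean product ``F_ik = OR_j (M_ij AND X_jk)`` and the
weighted sum ``F_ik = sum_j w_j * M_ij * X_jk``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

from .sequence_designer import StrandLibrary
from .strand_model import Mode

__all__ = [
    "BooleanMatrix",
    "ConcentrationConfig",
    "DimensionError",
    "SpeciesSystem",
    "WeightConfig",
    "compile_system",
    "reference_product",
    "reference_weighted_sum",
]


class DimensionError(ValueError):
    """Incompatible matrix shapes."""


MatrixLike = Union["BooleanMatrix", Sequence[Sequence[int]], np.ndarray]


@dataclass(frozen=True)
class BooleanMatrix:
    """A {0,1} matrix; rows of 0/1 ints."""

    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.atleast_2d(np.asarray(self.data, dtype=np.int64))
        if arr.ndim != 2:
            raise ValueError("a Boolean matrix must be 2-dimensional")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("entries must all be 0 or 1")
        object.__setattr__(self, "data", arr)

    @classmethod
    def coerce(cls, m: MatrixLike) -> "BooleanMatrix":
        if isinstance(m, BooleanMatrix):
            return m
        return cls(np.asarray(m))

    @classmethod
    def column(cls, entries: Sequence[int]) -> "BooleanMatrix":
        return cls(np.asarray(entries).reshape(-1, 1))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape

    def __getitem__(self, idx):
        return int(self.data[idx])

    def __eq__(self, other) -> bool:
        if not isinstance(other, BooleanMatrix):
            return NotImplemented
        return self.shape == other.shape and bool(
            (self.data == other.data).all())

    def __hash__(self):
        return hash((self.shape, self.data.tobytes()))

    def to_list(self) -> List[List[int]]:
        return self.data.tolist()

    def __repr__(self) -> str:
        return f"BooleanMatrix({self.to_list()})"


@dataclass(frozen=True)
class WeightConfig:
    """Per-column non-negative weights, encoded as enzyme concentration
    multipliers.  Boolean mode requires all weights equal to 1."""

    w: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.w, dtype=float).ravel()
        if (arr < 0).any():
            raise ValueError("weights must be non-negative")
        object.__setattr__(self, "w", arr)

    @classmethod
    def ones(cls, n: int) -> "WeightConfig":
        return cls(np.ones(n))

    def __len__(self) -> int:
        return len(self.w)


@dataclass(frozen=True)
class ConcentrationConfig:
    """Initial-concentration policy, in molar units.

    ``base_conc`` defaults to 0.3 uM (3e-7 M), the working concentration
    of the fluorescence experiments this simulator emulates.
    """

    base_conc: float = 0.3e-6
    substrate_multiplier: float = 1.0
    overrides: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.base_conc < 0 or self.substrate_multiplier < 0:
            raise ValueError("concentrations must be >= 0")
        if any(v < 0 for v in self.overrides.values()):
            raise ValueError("concentration overrides must be >= 0")

    @classmethod
    def boolean_default(cls) -> "ConcentrationConfig":
        return cls(substrate_multiplier=1.0)

    @classmethod
    def weighted_default(cls) -> "ConcentrationConfig":
        return cls(substrate_multiplier=2.0)


def reference_product(M: MatrixLike, X: MatrixLike) -> BooleanMatrix:
    """Boolean matrix product: ``F_ik = OR_j (M_ij AND X_jk)``.

    Pure arithmetic -- this is the oracle the simulated readout is
    checked against.
    """
    Mb, Xb = BooleanMatrix.coerce(M), BooleanMatrix.coerce(X)
    _check_shapes(Mb, Xb)
    return BooleanMatrix((Mb.data @ Xb.data > 0).astype(np.int64))


def reference_weighted_sum(M: MatrixLike, X: MatrixLike,
                           weights: Optional[WeightConfig] = None
                           ) -> np.ndarray:
    """Weighted sum ``F_ik = sum_j w_j * M_ij * X_jk`` (integer matrix for
    integer weights)."""
    Mb, Xb = BooleanMatrix.coerce(M), BooleanMatrix.coerce(X)
    _check_shapes(Mb, Xb)
    if weights is None:
        weights = WeightConfig.ones(Mb.shape[1])
    if len(weights) != Mb.shape[1]:
        raise DimensionError(
            f"weight vector length {len(weights)} != n_cols {Mb.shape[1]}")
    out = (Mb.data * weights.w[None, :]) @ Xb.data
    if np.allclose(out, np.round(out)):
        return np.round(out).astype(np.int64)
    return out


def _check_shapes(M: BooleanMatrix, X: BooleanMatrix) -> None:
    if M.shape[1] != X.shape[0]:
        raise DimensionError(
            f"cannot multiply shapes {M.shape} x {X.shape}: "
            f"cols(M) != rows(X)")


@dataclass
class SpeciesSystem:
    """Initial species and concentrations compiled from (M, X, weights).

    ``initial`` holds only species present at nonzero concentration;
    decoding presence/absence of auxiliaries recovers (M, X) exactly.
    A K-column X compiles to K independent reaction wells (one tube per
    output column, as in the bench protocol); :meth:`well` extracts one.
    """

    library: StrandLibrary
    M: BooleanMatrix
    X: BooleanMatrix
    weights: WeightConfig
    conc: ConcentrationConfig
    initial: Dict[str, float]
    mode: str  # "boolean" | "weighted"
    column: Optional[int] = None

    @property
    def n_rows(self) -> int:
        return self.M.shape[0]

    @property
    def n_cols(self) -> int:
        return self.M.shape[1]

    @property
    def k_cols(self) -> int:
        return self.X.shape[1]

    def well(self, k: int) -> "SpeciesSystem":
        """The single-output-column subsystem for column ``k``."""
        if not (0 <= k < self.k_cols):
            raise IndexError(f"column {k} out of range")
        if self.k_cols == 1 and self.column is not None:
            return self
        lib = self.library
        keep = set()
        for j in range(self.n_cols):
            keep.add(lib.enzymes[j])
        for i in range(self.n_rows):
            keep.add(lib.substrates[i])
            for j in range(self.n_cols):
                keep.add(lib.aux_m[(i, j)])
        for j in range(self.n_cols):
            keep.add(lib.aux_x[(j, k)])
        initial = {n: c for n, c in self.initial.items() if n in keep}
        return replace(self, X=BooleanMatrix(self.X.data[:, [k]]),
                       initial=initial, column=k)

    def decode(self) -> Tuple[BooleanMatrix, BooleanMatrix]:
        """Recover (M, X) from auxiliary presence/absence (round-trip)."""
        lib = self.library
        m = np.zeros(self.M.shape, dtype=np.int64)
        for (i, j), name in lib.aux_m.items():
            m[i, j] = 1 if self.initial.get(name, 0.0) > 0 else 0
        x = np.zeros(self.X.shape, dtype=np.int64)
        for (j, k), name in lib.aux_x.items():
            if self.column is not None and k != self.column:
                continue
            col = 0 if self.column is not None else k
            x[j, col] = 1 if self.initial.get(name, 0.0) > 0 else 0
        return BooleanMatrix(m), BooleanMatrix(x)


def compile_system(M: MatrixLike, X: MatrixLike,
                   weights: Optional[WeightConfig] = None,
                   conc: Optional[ConcentrationConfig] = None,
                   lib: Optional[StrandLibrary] = None) -> SpeciesSystem:
    """Compile a matrix instance against a designed library.

    Raises :class:`DimensionError` if cols(M) != rows(X) or if the library
    is shaped for different dimensions.
    """
    if lib is None:
        raise ValueError("a designed library is required")
    Mb, Xb = BooleanMatrix.coerce(M), BooleanMatrix.coerce(X)
    _check_shapes(Mb, Xb)
    n_rows, n_cols = Mb.shape
    k_cols = Xb.shape[1]
    if (lib.n_rows, lib.n_cols) != (n_rows, n_cols) or k_cols > lib.k_cols:
        raise DimensionError(
            f"library shaped for ({lib.n_rows}x{lib.n_cols}) x "
            f"({lib.n_cols}x{lib.k_cols}), got ({n_rows}x{n_cols}) x "
            f"({n_cols}x{k_cols})")

    mode = "weighted" if lib.mode is Mode.WEIGHTED else "boolean"
    if weights is None:
        weights = WeightConfig.ones(n_cols)
    if len(weights) != n_cols:
        raise DimensionError(
            f"weight vector length {len(weights)} != n_cols {n_cols}")
    if mode == "boolean" and not np.allclose(weights.w, 1.0):
        raise ValueError("Boolean mode forces all weights to 1; use a "
                         "weighted-mode library for other weights")
    if conc is None:
        conc = (ConcentrationConfig.weighted_default() if mode == "weighted"
                else ConcentrationConfig.boolean_default())

    initial: Dict[str, float] = {}

    def put(name: str, value: float) -> None:
        value = conc.overrides.get(name, value)
        if value > 0:
            initial[name] = value

    for j in range(n_cols):
        put(lib.enzymes[j], conc.base_conc * weights.w[j])
    for i in range(n_rows):
        put(lib.substrates[i], conc.base_conc * conc.substrate_multiplier)
    for i in range(n_rows):
        for j in range(n_cols):
            if Mb[i, j]:
                put(lib.aux_m[(i, j)], conc.base_conc)
    for j in range(n_cols):
        for k in range(k_cols):
            if Xb[j, k]:
                put(lib.aux_x[(j, k)], conc.base_conc)

    return SpeciesSystem(library=lib, M=Mb, X=Xb, weights=weights,
                         conc=conc, initial=initial, mode=mode,
                         column=0 if k_cols == 1 else None)


def compile_single_three_pronged(lib: StrandLibrary, aux_present: bool,
                                 conc: Optional[ConcentrationConfig] = None
                                 ) -> SpeciesSystem:
    """Species system for the single three-pronged mechanism: enzyme and
    substrate always present, the one auxiliary present iff ``aux_present``."""
    if lib.mode is not Mode.THREE_PRONGED:
        raise ValueError("library is not a three-pronged design")
    if conc is None:
        conc = ConcentrationConfig.boolean_default()
    initial = {
        lib.enzymes[0]: conc.base_conc,
        lib.substrates[0]: conc.base_conc * conc.substrate_multiplier,
    }
    if aux_present:
        initial[lib.aux_m[(0, 0)]] = conc.base_conc
    M = BooleanMatrix([[1 if aux_present else 0]])
    X = BooleanMatrix([[1]])
    return SpeciesSystem(library=lib, M=M, X=X,
                         weights=WeightConfig.ones(1), conc=conc,
                         initial=initial, mode="boolean", column=0)
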