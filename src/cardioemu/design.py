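"""Latin-hypercube design generation and dataset I/O.

The emulators are trained on paired matrices of normalized conductance
inputs (n x 6, in [0,1]) and biomarker outputs (n x 8).  Inputs are
sampled by Latin hypercube over the design ranges nominal +/- 25%, with
the nominal conductances mapping to 0.5 on the normalized scale.
Datasets are stored as plain CSV in the supplementary-data layout: six
input columns followed by eight output columns.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .biomarkers import (
    CouplingScan,
    extract_ap_biomarkers,
    fit_restitution,
    restitution_protocol,
)
from .errors import CardioEmuError, DatasetError, FormatError, RangeWarning
from .lr1991 import Conductances, StimulusProtocol, run_s1_protocol

__all__ = [
    "INPUT_NAMES",
    "OUTPUT_NAMES",
    "InputSpace",
    "DesignSet",
    "lhs_sample",
    "generate_dataset",
    "read_dataset",
    "write_dataset",
]

logger = logging.getLogger(__name__)

INPUT_NAMES = ("G_Na", "G_si", "G_K", "G_K1", "G_Kp", "G_b")
OUTPUT_NAMES = ("max_dvdt", "peak_v", "dome_v", "apd90", "resting_v",
                "apd50", "apdr_slope", "min_di")


@dataclass(frozen=True)
class InputSpace:
    """Affine map between natural conductances and the normalized design
    cube.  Bounds are nominal*(1 -/+ 1/4); the nominal values map to 0.5."""

    nominal: np.ndarray = field(
        default_factory=lambda: Conductances().as_array()
    )

    def __post_init__(self):
        object.__setattr__(self, "nominal", np.asarray(self.nominal, dtype=float))
        if self.nominal.shape != (6,) or np.any(self.nominal <= 0):
            raise ValueError("nominal must be 6 positive conductances")

    @property
    def lower(self) -> np.ndarray:
        return 0.75 * self.nominal

    @property
    def upper(self) -> np.ndarray:
        return 1.25 * self.nominal

    def normalize(self, g) -> np.ndarray:
        """Map natural conductances to [0,1]^6 (0.5 = nominal).

        Values outside the design range are flagged with a
        :class:`RangeWarning` but returned unclipped.
        """
        arr = g.as_array() if isinstance(g, Conductances) else np.asarray(g, float)
        x = (arr - self.lower) / (self.upper - self.lower)
        if np.any((x < -1e-12) | (x > 1 + 1e-12)):
            warnings.warn("conductances outside the design range", RangeWarning,
                          stacklevel=2)
        return x

    def denormalize(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.lower + x * (self.upper - self.lower)

    def conductances(self, x) -> Conductances:
        return Conductances.from_array(self.denormalize(x))


@dataclass
class DesignSet:
    """Paired normalized inputs (n x 6) and biomarker outputs (n x 8)."""

    x: np.ndarray
    y: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.x = np.atleast_2d(np.asarray(self.x, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.x.shape[0] != self.y.shape[0]:
            raise ValueError("x and y must have the same number of rows")
        if self.x.shape[1] != 6 or self.y.shape[1] != 8:
            raise ValueError("expected 6 input and 8 output columns")

    @property
    def n(self) -> int:
        return self.x.shape[0]

    def output(self, name: str) -> np.ndarray:
        return self.y[:, OUTPUT_NAMES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.hstack([self.x, self.y]), columns=list(INPUT_NAMES + OUTPUT_NAMES)
        )

    def combined_with(self, other: "DesignSet") -> "DesignSet":
        return DesignSet(
            x=np.vstack([self.x, other.x]),
            y=np.vstack([self.y, other.y]),
            metadata={"combined_from": [self.metadata, other.metadata]},
        )


def lhs_sample(n: int, d: int, seed: Optional[int] = None) -> np.ndarray:
    """Latin hypercube sample: one point, uniformly placed, in each of the
    n axis-aligned strata of every coordinate.  Deterministic per seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if d < 1:
        raise ValueError("d must be >= 1")
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    return sampler.random(n)


def _run_point(x_row, space, protocol, include_restitution, scan, method):
    g = space.conductances(x_row)
    trace = run_s1_protocol(g, protocol, method=method)
    bm = extract_ap_biomarkers(trace)
    if include_restitution:
        curve = restitution_protocol(g, protocol, scan=scan, s1_trace=trace,
                                     method=method)
        fit = fit_restitution(curve)
        bm = bm.with_restitution(fit.max_slope, curve.min_di)
    return bm.as_array()


def generate_dataset(
    n: int,
    space: InputSpace = InputSpace(),
    protocol: StimulusProtocol = StimulusProtocol(),
    seed: Optional[int] = None,
    include_restitution: bool = True,
    restitution_n: Optional[int] = None,
    scan: CouplingScan = CouplingScan(),
    method: str = "rl",
    max_failure_fraction: float = 0.05,
) -> DesignSet:
    """Generate an n-point Latin-hypercube design and run the simulator.

    ``restitution_n`` restricts the (expensive) S1-S2 restitution scan to
    the first ``restitution_n`` design points; the remaining rows carry
    NaN in the two restitution columns.  Failed runs are logged and
    excluded; more than ``max_failure_fraction`` failures aborts with a
    :class:`DatasetError` since that indicates a protocol or range fault.
    """
    x = lhs_sample(n, 6, seed=seed)
    rows_x, rows_y, failures = [], [], []
    for i, xi in enumerate(x):
        with_rest = include_restitution and (restitution_n is None or i < restitution_n)
        try:
            yi = _run_point(xi, space, protocol, with_rest, scan, method)
        except CardioEmuError as exc:
            failures.append((i, str(exc)))
            logger.warning("design point %d failed: %s", i, exc)
            continue
        rows_x.append(xi)
        rows_y.append(yi)
    if len(failures) > max_failure_fraction * n:
        raise DatasetError(
            f"{len(failures)}/{n} simulator runs failed: {failures[:5]}"
        )
    return DesignSet(
        x=np.array(rows_x),
        y=np.array(rows_y),
        metadata={
            "seed": seed,
            "n_requested": n,
            "failures": failures,
            "include_restitution": include_restitution,
            "restitution_n": restitution_n,
            "protocol": protocol.__dict__.copy(),
        },
    )


def write_dataset(ds: DesignSet, path) -> None:
    """Write a design set as CSV (6 input + 8 output columns, with header)."""
    ds.to_frame().to_csv(path, index=False, float_format="%.12g")


def read_dataset(path) -> DesignSet:
    """Read a design set CSV (header optional, auto-detected).

    Accepts any file with >= 14 numeric columns in the supplementary-data
    layout; extra trailing columns are ignored.
    """
    try:
        probe = pd.read_csv(path, header=None, nrows=1)
    except Exception as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    first_numeric = pd.to_numeric(probe.iloc[0], errors="coerce")
    has_header = bool(first_numeric.isna().any())
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] < 14:
        raise FormatError(
            f"{path}: expected >= 14 columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :14]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    # literal NaN cells are allowed (e.g. restitution columns computed on a
    # subset); anything else that fails to parse is a format error
    literal_nan = df.astype(str).apply(
        lambda s: s.str.strip().str.lower().isin(["nan", ""])
    )
    bad_mask = numeric.isna().values & ~literal_nan.values
    if bad_mask.any():
        bad = np.argwhere(bad_mask)[0]
        raise FormatError(
            f"{path}: non-numeric value at row {bad[0]}, column {bad[1]}"
        )
    values = numeric.to_numpy(dtype=float)
    return DesignSet(x=values[:, :6], y=values[:, 6:14],
                     metadata={"source": str(path)})
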