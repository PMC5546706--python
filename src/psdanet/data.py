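"""Core containers and tabular I/O for protein time-series analysis.

The whole pipeline operates on three ingredients measured (or synthesised)
per condition: per-gene protein abundance traces ``P(t)`` in arbitrary
fluorescence units, a condition-level dilution-rate trace ``gamma(t)`` in
1/min (the exponential cell-mass accumulation rate), and per-gene first-order
degradation rates ``d`` in 1/min derived from protein half-lives.

File dialect: genes in rows, time points (minutes) in columns, tab-separated,
with one reserved row ``__growth_rate__`` carrying gamma(t) for the condition.
Degradation tables are two-column TSV (gene_id, half_life).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROWTH_ROW = "__growth_rate__"

#: Fallback degradation rate, 1/min, for genes missing from the half-life
#: table (ln 2 / 43 min -- a typical yeast protein half-life).
DEFAULT_DEGRADATION_RATE = math.log(2.0) / 43.0


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


@dataclass(frozen=True)
class TimeGrid:
    """Shared sampling grid, minutes since stimulation onset.

    Times must be finite, strictly increasing, and at least 3 long. The
    pre-stimulus baseline is the last point with time <= 0 when one exists,
    otherwise the first sample.
    """

    times: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1 or t.size < 3:
            raise ValidationError("time grid needs at least 3 points")
        if not np.all(np.isfinite(t)):
            raise ValidationError("time grid contains non-finite values")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("time grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def step(self) -> float:
        """Nominal sampling interval (median of the finite differences)."""
        return float(np.median(np.diff(self.times)))

    @property
    def dt(self) -> np.ndarray:
        """Per-interval widths, length ``len(self) - 1``."""
        return np.diff(self.times)

    @property
    def baseline_index(self) -> int:
        pre = np.nonzero(self.times <= 0)[0]
        return int(pre[-1]) if pre.size else 0

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TimeGrid) and np.array_equal(self.times, other.times)

    def __hash__(self) -> int:
        return hash(self.times.tobytes())


@dataclass(frozen=True)
class ExpressionSeries:
    """Protein concentration P(t) for one gene on a grid (a.u., >= 0)."""

    gene_id: str
    grid: TimeGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.grid),):
            raise ValidationError(
                f"{self.gene_id}: values length {v.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError(f"{self.gene_id}: non-finite expression values")
        if np.any(v < 0):
            raise ValidationError(f"{self.gene_id}: negative expression values")

    @property
    def baseline(self) -> float:
        """Pre-stimulus protein level P(t<=0) (or the first sample)."""
        return float(self.values[self.grid.baseline_index])


@dataclass(frozen=True)
class GrowthProfile:
    """Dilution rate gamma(t), 1/min, for one condition."""

    grid: TimeGrid
    gamma: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", g)
        if g.shape != (len(self.grid),):
            raise ValidationError("gamma length != grid length")
        if not np.all(np.isfinite(g)) or np.any(g < 0):
            raise ValidationError("gamma must be finite and >= 0")

    @property
    def baseline(self) -> float:
        return float(self.gamma[self.grid.baseline_index])


@dataclass
class DegradationTable:
    """gene_id -> degradation rate d (1/min), with a logged fallback."""

    rates: dict[str, float] = field(default_factory=dict)
    default_rate: float = DEFAULT_DEGRADATION_RATE

    def __post_init__(self) -> None:
        if self.default_rate < 0:
            raise ValidationError("default_rate must be >= 0")
        for g, r in self.rates.items():
            if not (r >= 0 and math.isfinite(r)):
                raise ValidationError(f"degradation rate for {g} must be finite and >= 0")

    def lookup(self, gene_id: str) -> float:
        try:
            return self.rates[gene_id]
        except KeyError:
            logger.info(
                "gene %s absent from degradation table; using default %.4g /min",
                gene_id, self.default_rate,
            )
            return self.default_rate

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.rates


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path) -> tuple[list[ExpressionSeries], GrowthProfile]:
    """Read a per-condition expression TSV into series plus a growth profile.

    Header row gives time points in minutes; one reserved row
    ``__growth_rate__`` carries gamma(t). Genes with any missing value are
    dropped with a warning. All returned series share one :class:`TimeGrid`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                     float_precision="round_trip")
    try:
        times = df.columns.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        bad = [c for c in df.columns if not _is_number(c)]
        raise ValidationError(f"malformed header: non-numeric time cell(s) {bad}") from exc
    grid = TimeGrid(times)  # raises on non-monotone times
    if GROWTH_ROW not in df.index:
        raise ValidationError(f"missing reserved growth-rate row {GROWTH_ROW!r}")
    growth = GrowthProfile(grid, df.loc[GROWTH_ROW].to_numpy(dtype=float))
    series: list[ExpressionSeries] = []
    for gene, row in df.drop(index=GROWTH_ROW).iterrows():
        vals = pd.to_numeric(row, errors="coerce").to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            warnings.warn(f"gene {gene}: missing value(s); dropped", stacklevel=2)
            continue
        series.append(ExpressionSeries(str(gene), grid, vals))
    return series, growth


def write_expression_matrix(path, series: Sequence[ExpressionSeries],
                            growth: GrowthProfile | None = None,
                            header_comment: str | None = None) -> None:
    """Write series (and optionally growth) in the expression TSV dialect."""
    grid = series[0].grid if series else (growth.grid if growth else None)
    if grid is None:
        raise ValidationError("nothing to write")
    rows: dict[str, np.ndarray] = {}
    if growth is not None:
        if growth.grid != grid:
            raise ValidationError("growth grid differs from series grid")
        rows[GROWTH_ROW] = growth.gamma
    for s in series:
        if s.grid != grid:
            raise ValidationError(f"{s.gene_id}: grid differs from first series")
        rows[s.gene_id] = s.values
    df = pd.DataFrame(rows, index=grid.times).T
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.17g")


def read_degradation_table(path, half_life_units: str = "minutes",
                           default_rate: float = DEFAULT_DEGRADATION_RATE) -> DegradationTable:
    """Read a two-column (gene_id, half_life) TSV into per-minute rates.

    rate = ln(2) / half_life, half-lives converted to minutes first.
    Non-positive or non-numeric half-lives reject the row with a log entry.
    """
    if half_life_units not in ("minutes", "hours"):
        raise ValidationError(f"unknown half_life_units {half_life_units!r}")
    scale = 60.0 if half_life_units == "hours" else 1.0
    df = pd.read_csv(path, sep="\t", comment="#", header=0)
    if df.shape[1] < 2:
        raise ValidationError("degradation table needs two columns (gene_id, half_life)")
    rates: dict[str, float] = {}
    for _, row in df.iterrows():
        gene = str(row.iloc[0])
        hl = pd.to_numeric(row.iloc[1], errors="coerce")
        if not np.isfinite(hl):
            raise ValidationError(f"non-numeric half-life for gene {gene}")
        if hl <= 0:
            logger.warning("gene %s: non-positive half-life %s rejected", gene, hl)
            continue
        rates[gene] = math.log(2.0) / (float(hl) * scale)
    return DegradationTable(rates, default_rate)


def write_degradation_table(path, table: DegradationTable) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\thalf_life_minutes\n")
        for gene, rate in table.rates.items():
            fh.write(f"{gene}\t{math.log(2.0) / rate:.17g}\n")


def zscore_normalize(series: ExpressionSeries) -> np.ndarray:
    """Z-score a trace (population sd). Constant traces map to zeros + warning."""
    v = series.values
    sd = float(np.std(v))
    if sd == 0.0:
        warnings.warn(f"gene {series.gene_id}: constant trace, z-score set to zeros",
                      stacklevel=2)
        return np.zeros_like(v)
    return (v - np.mean(v)) / sd


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False
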