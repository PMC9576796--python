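"""Two-stage nitrogen and electron balance analysis of batch time series.

The analysis mirrors how a nitrate-fed anaerobic propane-oxidising batch test
is interpreted:

* **Stage segmentation** — nitrate reduction proceeds in two stages: Stage 1
  (nitrate present) converts nitrate to nitrite and dinitrogen with negligible
  ammonium; Stage 2 (after nitrate depletion) consumes the accumulated nitrite
  to dinitrogen and ammonium.  The boundary is the first time nitrate drops
  below a threshold (default 2% of its initial amount), located by linear
  interpolation between the bracketing samples.

* **Nitrogen balance** — total nitrate-N consumed over the run divided by the
  sum of N recovered in products (N2-N + NH4-N + residual nitrite-N), all
  deltas taken start-to-end.  Closure gives 1.0.

* **Electron balance** — electrons released by propane oxidation (20 e- per
  propane, or 20/3 per CO2 produced) against electrons required to reduce
  nitrate to the observed products (5 e- per N to N2, 8 to NH4+, 2 to residual
  nitrite).  The coefficients are taken from the packaged redox couples, not
  hard-coded.

* **Product partition** — percentage of reduced N ending as N2 vs NH4+,
  excluding residual nitrite from the denominator.

Replicate vessels are aggregated as mean +/- standard error.
All balances operate on amounts (umol; N species as umol N, with N2 counted
as N atoms), making the closure ratios unit-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_core import RedoxCouple, default_library, electron_equivalents

__all__ = [
    "TIME_COLUMN",
    "MAIN_COLUMNS",
    "ISOTOPE_COLUMNS",
    "BalanceError",
    "BatchTimeSeries",
    "StageSegmentation",
    "ElectronBalance",
    "BalanceReport",
    "segment_stages",
    "nitrogen_balance",
    "electron_balance",
    "product_partition",
    "analyze_replicate",
    "aggregate_replicates",
]

logger = logging.getLogger("ndapo")

TIME_COLUMN = "time_h"
#: Canonical amount columns (umol; N species as umol N, N2 as N atoms).
MAIN_COLUMNS = (
    "no3_umolN",
    "no2_umolN",
    "nh4_umolN",
    "n2_umolN",
    "propane_umol",
    "co2_umol",
)
#: Optional labelled-quantity columns.
ISOTOPE_COLUMNS = (
    "c13_propane_umol",
    "c13_co2_umol",
    "n15_no3_umol",
    "n15_no2_umol",
    "n15_nh4_umol",
    "n2_29_frac",
    "n2_30_frac",
)

#: Statistics carried per replicate and aggregated across replicates.
REPORT_STATISTICS = (
    "dno3_umolN",
    "dn2_umolN",
    "dnh4_umolN",
    "dno2_residual_umolN",
    "nitrogen_ratio",
    "e_produced_umol",
    "e_consumed_umol",
    "electron_ratio",
    "partition_n2_pct",
    "partition_nh4_pct",
)


class BalanceError(ValueError):
    """Invalid time series or degenerate balance."""


@dataclass
class BatchTimeSeries:
    """Timestamped pool amounts for a single vessel.

    ``data`` must contain :data:`TIME_COLUMN` and all :data:`MAIN_COLUMNS`
    (isotope columns optional).  Times must be strictly increasing; negative
    amounts (measurement noise) are clipped to zero with a logged warning.
    """

    data: pd.DataFrame
    replicate: int | str = 0

    def __post_init__(self) -> None:
        missing = [c for c in (TIME_COLUMN, *MAIN_COLUMNS) if c not in self.data.columns]
        if missing:
            raise BalanceError(f"time series is missing required columns {missing}")
        self.data = self.data.reset_index(drop=True)
        t = self.data[TIME_COLUMN].to_numpy(dtype=float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise BalanceError(
                f"replicate {self.replicate!r}: time must be strictly increasing"
            )
        amount_cols = [c for c in self.data.columns if c != TIME_COLUMN]
        values = self.data[amount_cols].to_numpy(dtype=float)
        if (values < 0).any():
            n_neg = int((values < 0).sum())
            logger.warning(
                "replicate %r: clipped %d negative amount(s) to zero",
                self.replicate,
                n_neg,
            )
            self.data[amount_cols] = np.clip(values, 0.0, None)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def time(self) -> np.ndarray:
        return self.data[TIME_COLUMN].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def start(self, name: str) -> float:
        return float(self.data[name].iloc[0])

    def end(self, name: str) -> float:
        return float(self.data[name].iloc[-1])

    def scaled(self, k: float) -> "BatchTimeSeries":
        """Series with every amount column rescaled by ``k`` (units change)."""
        if k <= 0:
            raise BalanceError("scale factor must be positive")
        out = self.data.copy()
        for col in (*MAIN_COLUMNS, *ISOTOPE_COLUMNS[:5]):
            if col in out.columns:
                out[col] = out[col] * k
        return BatchTimeSeries(out, self.replicate)

    def window(self, t_lo: float, t_hi: float) -> "BatchTimeSeries":
        """Sub-series with time in [t_lo, t_hi]."""
        mask = (self.time >= t_lo) & (self.time <= t_hi)
        return BatchTimeSeries(self.data.loc[mask].copy(), self.replicate)


@dataclass(frozen=True)
class StageSegmentation:
    """Stage boundaries around the nitrate-depletion time.

    Stage 1 covers [t0, depletion_time]; Stage 2 covers (depletion_time,
    t_end].  If nitrate never drops below the threshold, ``depletion_time``
    is None and Stage 2 is empty.
    """

    depletion_time: float | None
    t_start: float
    t_end: float
    threshold: float

    @property
    def has_stage2(self) -> bool:
        return self.depletion_time is not None and self.depletion_time < self.t_end

    def stage1(self, series: BatchTimeSeries) -> BatchTimeSeries:
        t_hi = self.t_end if self.depletion_time is None else self.depletion_time
        return series.window(self.t_start, t_hi)

    def stage2(self, series: BatchTimeSeries) -> BatchTimeSeries:
        if not self.has_stage2:
            return series.window(self.t_end, self.t_start)  # empty
        sub = series.data.loc[series.time > self.depletion_time]
        return BatchTimeSeries(sub.copy(), series.replicate)


def segment_stages(
    series: BatchTimeSeries, threshold: float | None = None
) -> StageSegmentation:
    """Locate the nitrate-depletion boundary between the two stages.

    ``threshold`` is in umol N; default 2% of the initial nitrate.  The
    crossing time is linearly interpolated between the last sample at or above
    the threshold and the first sample below it.
    """
    if len(series) < 3:
        raise BalanceError("need at least 3 timepoints to segment stages")
    t = series.time
    no3 = series.column("no3_umolN")
    if threshold is None:
        threshold = 0.02 * no3[0]
    if threshold < 0:
        raise BalanceError("threshold must be non-negative")
    below = no3 < threshold if threshold > 0 else no3 <= 0.0
    if not below.any():
        return StageSegmentation(None, float(t[0]), float(t[-1]), threshold)
    i = int(np.argmax(below))
    if i == 0:
        depletion = float(t[0])
    else:
        n_prev, n_here = no3[i - 1], no3[i]
        if n_prev == n_here:  # flat segment straddling the threshold
            depletion = float(t[i])
        else:
            frac = (n_prev - threshold) / (n_prev - n_here)
            depletion = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return StageSegmentation(depletion, float(t[0]), float(t[-1]), threshold)


def _consumed(series: BatchTimeSeries, column: str) -> float:
    delta = series.start(column) - series.end(column)
    if delta < 0:
        logger.warning(
            "replicate %r: negative consumption of %s (%g) clipped to 0",
            series.replicate,
            column,
            delta,
        )
        return 0.0
    return delta


def _produced(series: BatchTimeSeries, column: str) -> float:
    delta = series.end(column) - series.start(column)
    if delta < 0:
        logger.warning(
            "replicate %r: negative production of %s (%g) clipped to 0",
            series.replicate,
            column,
            delta,
        )
        return 0.0
    return delta


def nitrogen_balance(series: BatchTimeSeries) -> float:
    """Nitrate-N consumed over N recovered in products (closure ratio).

    ratio = dNO3-N / (dN2-N + dNH4-N + residual dNO2-N), deltas start-to-end.
    """
    consumed = _consumed(series, "no3_umolN")
    produced = (
        _produced(series, "n2_umolN")
        + _produced(series, "nh4_umolN")
        + _produced(series, "no2_umolN")
    )
    if produced <= 0:
        raise BalanceError("no nitrogen products formed; balance undefined")
    return consumed / produced


def _electron_coefficients(source: str) -> tuple[float, float, float]:
    """(e- per N to N2, to NH4+, per residual NO2-) for a terminal N source."""
    registry = default_library().table.species
    e_n2 = float(electron_equivalents(RedoxCouple(source, "N2", "N"), registry))
    e_nh4 = float(electron_equivalents(RedoxCouple(source, "NH4+", "N"), registry))
    if source == "NO2-":
        e_no2 = 0.0  # residual nitrite required no electrons from nitrite
    else:
        e_no2 = float(electron_equivalents(RedoxCouple(source, "NO2-", "N"), registry))
    return e_n2, e_nh4, e_no2


@dataclass(frozen=True)
class ElectronBalance:
    """Electron production, consumption and their ratio (umol e-)."""

    e_produced: float
    e_consumed: float

    @property
    def ratio(self) -> float:
        return self.e_produced / self.e_consumed


def electron_balance(
    series: BatchTimeSeries,
    mode: str = "from-propane",
    source: str = "NO3-",
) -> ElectronBalance:
    """Electron-equivalent closure between propane oxidation and N reduction.

    ``mode`` anchors electron production on propane consumed (20 e- per
    propane) or on CO2 produced (20/3 e- per CO2); the two differ when carbon
    is assimilated into biomass.  ``source`` is the terminal N electron source
    ("NO3-" for whole-run balances, "NO2-" for Stage-2-only analysis).
    """
    registry = default_library().table.species
    if mode == "from-propane":
        e_per = float(electron_equivalents(RedoxCouple("C3H8", "CO2", "C"), registry))
        e_produced = e_per * _consumed(series, "propane_umol")
    elif mode == "from-co2":
        e_per = float(electron_equivalents(RedoxCouple("C3H8", "CO2", "C"), registry))
        carbons = default_library().table.species["C3H8"].elements["C"]
        e_produced = (e_per / carbons) * _produced(series, "co2_umol")
    else:
        raise BalanceError(f"unknown electron mode {mode!r}")
    e_n2, e_nh4, e_no2 = _electron_coefficients(source)
    e_consumed = (
        e_n2 * _produced(series, "n2_umolN")
        + e_nh4 * _produced(series, "nh4_umolN")
        + e_no2 * _produced(series, "no2_umolN")
    )
    if e_consumed <= 0:
        raise BalanceError("no electron-consuming products formed; balance undefined")
    return ElectronBalance(e_produced, e_consumed)


def product_partition(series: BatchTimeSeries) -> tuple[float, float]:
    """(% N2-N, % NH4-N) of the N recovered in terminal products.

    Residual nitrite is excluded from the denominator (it is an intermediate,
    reported separately in the balance report).
    """
    d_n2 = _produced(series, "n2_umolN")
    d_nh4 = _produced(series, "nh4_umolN")
    total = d_n2 + d_nh4
    if total <= 0:
        raise BalanceError("no terminal products formed; partition undefined")
    return 100.0 * d_n2 / total, 100.0 * d_nh4 / total


def analyze_replicate(
    series: BatchTimeSeries,
    threshold: float | None = None,
    electron_mode: str = "from-propane",
    electron_source: str = "NO3-",
) -> dict[str, float]:
    """All per-replicate balance statistics as a flat mapping."""
    seg = segment_stages(series, threshold)
    eb = electron_balance(series, electron_mode, electron_source)
    p_n2, p_nh4 = product_partition(series)
    return {
        "replicate": series.replicate,
        "depletion_time_h": math.nan if seg.depletion_time is None else seg.depletion_time,
        "dno3_umolN": _consumed(series, "no3_umolN"),
        "dn2_umolN": _produced(series, "n2_umolN"),
        "dnh4_umolN": _produced(series, "nh4_umolN"),
        "dno2_residual_umolN": _produced(series, "no2_umolN"),
        "nitrogen_ratio": nitrogen_balance(series),
        "e_produced_umol": eb.e_produced,
        "e_consumed_umol": eb.e_consumed,
        "electron_ratio": eb.ratio,
        "partition_n2_pct": p_n2,
        "partition_nh4_pct": p_nh4,
    }


@dataclass
class BalanceReport:
    """Per-replicate statistics plus mean +/- standard error aggregates.

    ``aggregate`` maps statistic name -> (mean, standard error); the SE is
    the sample standard deviation over sqrt(n) and is NaN (flagged) for a
    single replicate.
    """

    per_replicate: pd.DataFrame
    aggregate: dict[str, tuple[float, float]]
    n_replicates: int

    @property
    def se_defined(self) -> bool:
        return self.n_replicates >= 2

    def mean(self, statistic: str) -> float:
        return self.aggregate[statistic][0]

    def se(self, statistic: str) -> float:
        return self.aggregate[statistic][1]

    def to_dict(self) -> dict:
        return {
            "n_replicates": self.n_replicates,
            "se_defined": self.se_defined,
            "per_replicate": self.per_replicate.to_dict(orient="records"),
            "aggregate": {
                k: {"mean": m, "se": None if math.isnan(s) else s}
                for k, (m, s) in self.aggregate.items()
            },
        }

    def summary_table(self) -> str:
        rows = [
            {
                "statistic": k,
                "mean": m,
                "se": s,
            }
            for k, (m, s) in self.aggregate.items()
        ]
        return pd.DataFrame(rows).to_string(index=False, float_format=lambda x: f"{x:.6g}")


def aggregate_replicates(reports: Sequence[Mapping[str, float]]) -> BalanceReport:
    """Aggregate per-replicate statistics into a :class:`BalanceReport`.

    With a single replicate the standard errors are NaN and flagged via
    ``se_defined``.
    """
    if not reports:
        raise BalanceError("no replicate reports to aggregate")
    frame = pd.DataFrame(list(reports))
    n = len(frame)
    if n < 2:
        logger.warning("single replicate: standard errors undefined")
    aggregate: dict[str, tuple[float, float]] = {}
    for stat in REPORT_STATISTICS:
        values = frame[stat].to_numpy(dtype=float)
        mean = float(np.mean(values))
        se = float(np.std(values, ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
        aggregate[stat] = (mean, se)
    return BalanceReport(frame, aggregate, n)
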