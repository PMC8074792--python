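"""Flow-cytometric dipole-potential readout with the ESIPT probe F66.

F66 is a 3-hydroxyflavone dye whose excited state partitions between a normal
(N*) and a tautomer (T*) form with well-separated emission bands; the
per-cell emission ratio N*/T* falls as the intramembrane dipole potential
rises. This module computes the ratio event-wise on gated, compensated event
tables, summarizes samples, normalizes treatments to their matched controls
and produces the ratio histograms used to visualize population shifts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from memprobe.cytometry import EventTable

__all__ = [
    "EmissionRatios",
    "RatioSummary",
    "per_cell_emission_ratio",
    "summarize_sample",
    "normalize_to_control",
    "ratio_histogram",
]

DEFAULT_MIN_EVENTS = 20_000
DEFAULT_N_BINS = 256
#: Central quantile span of the default histogram range.
DEFAULT_RANGE_COVERAGE = 0.995


@dataclass(frozen=True)
class EmissionRatios:
    """Per-cell N*/T* ratios plus the exclusion report."""

    values: np.ndarray
    n_excluded: int
    n_total: int


@dataclass(frozen=True)
class RatioSummary:
    mean_ratio: float
    sd: float
    n_events: int
    sample_meta: dict = field(default_factory=dict)


def per_cell_emission_ratio(table: EventTable, channel_N: str,
                            channel_T: str) -> EmissionRatios:
    """Event-wise emission intensity ratio I_N / I_T.

    The ratio is computed for each cell; events with I_T <= 0 (ratio
    undefined) are excluded and counted in the report, never clamped. The
    table is expected to be compensated/gated upstream as desired.
    """
    i_n = table.column(channel_N)
    i_t = table.column(channel_T)
    valid = i_t > 0
    n_excluded = int((~valid).sum())
    if n_excluded == table.n_events:
        raise ValueError(
            f"all {table.n_events} events have {channel_T} <= 0; no ratios defined")
    return EmissionRatios(values=i_n[valid] / i_t[valid],
                          n_excluded=n_excluded, n_total=table.n_events)


def _as_values(ratios) -> np.ndarray:
    values = ratios.values if isinstance(ratios, EmissionRatios) else np.asarray(ratios, dtype=float)
    if values.size == 0:
        raise ValueError("ratio vector is empty")
    return values


def summarize_sample(ratios, min_events: int = DEFAULT_MIN_EVENTS,
                     sample_meta: dict | None = None,
                     statistic: str = "mean") -> RatioSummary:
    """Sample summary: mean (or median) ratio and sample SD (n-1 denominator).

    Warns, without failing, when fewer than ``min_events`` events contribute —
    the conventional floor for a stable per-sample mean is 20,000 living
    cells, but synthetic desk tests legitimately run far smaller.
    """
    values = _as_values(ratios)
    n = values.size
    if n < min_events:
        warnings.warn(f"sample summary from {n} events (< {min_events})", stacklevel=2)
    if statistic == "mean":
        center = float(values.mean())
    elif statistic == "median":
        center = float(np.median(values))
    else:
        raise ValueError(f"unknown statistic {statistic!r}; use 'mean' or 'median'")
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return RatioSummary(mean_ratio=center, sd=sd, n_events=n,
                        sample_meta=dict(sample_meta or {}))


def normalize_to_control(summaries: pd.DataFrame,
                         control_selector="is_control") -> pd.DataFrame:
    """Dose-response table: each treated mean divided by its replicate-matched control.

    ``summaries`` is a tidy frame with columns ``treatment``,
    ``concentration_um``, ``replicate``, ``mean_ratio`` plus a boolean control
    indicator (column named by ``control_selector``, or a callable
    row-predicate). Exactly one control row must match per replicate; control
    rows normalize to 1. Returns one row per (treatment, concentration) with
    the across-replicate mean, SD and replicate count of the normalized ratio.
    """
    df = summaries.copy()
    required = {"treatment", "concentration_um", "replicate", "mean_ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"summaries missing columns: {sorted(missing)}")
    if callable(control_selector):
        is_control = df.apply(control_selector, axis=1).astype(bool)
    else:
        is_control = df[control_selector].astype(bool)

    control_means = {}
    for replicate, sub in df.groupby("replicate"):
        controls = sub[is_control.loc[sub.index]]
        if len(controls) != 1:
            candidates = controls[["treatment", "concentration_um"]].to_dict("records")
            raise ValueError(
                f"replicate {replicate!r} has {len(controls)} matching controls "
                f"(need exactly 1): {candidates}")
        mean = float(controls["mean_ratio"].iloc[0])
        if mean <= 0:
            raise ValueError(f"replicate {replicate!r} control mean is non-positive")
        control_means[replicate] = mean

    df["normalized_ratio"] = [
        row.mean_ratio / control_means[row.replicate] for row in df.itertuples()
    ]
    if (df["concentration_um"] < 0).any():
        raise ValueError("concentrations must be nonnegative")
    grouped = (
        df.groupby(["treatment", "concentration_um"], sort=True)["normalized_ratio"]
        .agg(normalized_mean_ratio="mean",
             sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0,
             n_replicates="size")
        .reset_index()
    )
    return grouped


def ratio_histogram(ratios, n_bins: int = DEFAULT_N_BINS,
                    range: tuple[float, float] | None = None):
    """Ratio histogram: (bin edges, counts), bins left-closed right-open,
    last bin closed.

    The default range is the central 99.5% quantile span of the data, which
    keeps extreme ratio outliers from flattening the display.
    """
    values = _as_values(ratios)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if range is None:
        tail = (1.0 - DEFAULT_RANGE_COVERAGE) / 2.0
        lo, hi = np.quantile(values, [tail, 1.0 - tail])
        if lo == hi:  # point mass: widen to a non-degenerate interval
            lo, hi = lo - 0.5, hi + 0.5
        range = (float(lo), float(hi))
    lo, hi = range
    if hi <= lo:
        raise ValueError(f"degenerate histogram range [{lo}, {hi}]")
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return edges, counts
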