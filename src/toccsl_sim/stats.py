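"""Apparent and true oligomer fractions with bootstrap confidence intervals.

Pooling detection events over independent simulation runs, the apparent
n-mer fraction is ``f_n = 100 * nu_n / sum_n nu_n`` where ``nu_n`` counts
events of summed fluorescent state ``n`` (random colocalizations included).
The true-detection fraction ``f_m`` uses the same denominator but counts
only events that are a single nonphotobleached molecule (one member with
``n = m``), i.e. excludes random colocalizations and partially bleached
higher-order oligomers.  Confidence intervals resample whole runs with
replacement (percentile method).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .recovery import DetectionEvent

__all__ = ["FractionTable", "apparent_fractions", "bootstrap_ci", "event_count_matrix"]


def event_count_matrix(
    events_per_run: Sequence[Sequence[DetectionEvent]], m_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-run event counts by apparent state.

    Returns ``(counts_n, counts_true)``, each of shape
    ``(n_runs, n_cap)`` with ``n_cap = 5 * m_max``; column ``j`` holds
    events with apparent state ``n = j + 1``.  ``counts_true`` only counts
    single-molecule events with ``n = m`` (no random colocalization).
    """
    n_cap = 5 * m_max
    n_runs = len(events_per_run)
    counts_n = np.zeros((n_runs, n_cap), dtype=np.int64)
    counts_true = np.zeros((n_runs, n_cap), dtype=np.int64)
    for i, events in enumerate(events_per_run):
        for ev in events:
            if not 1 <= ev.n <= n_cap:
                continue
            counts_n[i, ev.n - 1] += 1
            if ev.is_true_mmer:
                counts_true[i, ev.n - 1] += 1
    return counts_n, counts_true


@dataclass
class FractionTable:
    """Pooled apparent/true fractions (percent) and optional bootstrap CIs."""

    m_max: int
    counts_n: np.ndarray  # total events per apparent state n = 1..5*m_max
    counts_true: np.ndarray
    n_runs: int
    ci_n: np.ndarray | None = None  # (2, n_cap) lower/upper bounds, percent
    ci_true: np.ndarray | None = None

    @property
    def n_values(self) -> np.ndarray:
        return np.arange(1, 5 * self.m_max + 1)

    @property
    def total_events(self) -> int:
        return int(self.counts_n.sum())

    @property
    def fractions_n(self) -> np.ndarray:
        """Apparent n-mer fractions in percent (sum to 100)."""
        return 100.0 * self.counts_n / self.total_events

    @property
    def fractions_true(self) -> np.ndarray:
        """True-detection fractions in percent (same denominator)."""
        return 100.0 * self.counts_true / self.total_events

    def fraction(self, n: int, kind: str = "apparent") -> float:
        values = self.fractions_n if kind == "apparent" else self.fractions_true
        return float(values[n - 1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (n, kind)."""
        rows = []
        for kind, counts, frac, ci in (
            ("apparent", self.counts_n, self.fractions_n, self.ci_n),
            ("true", self.counts_true, self.fractions_true, self.ci_true),
        ):
            for j, n in enumerate(self.n_values):
                rows.append(
                    {
                        "n_or_m": int(n),
                        "kind": kind,
                        "fraction_pct": round(float(frac[j]), 1),
                        "ci_low": round(float(ci[0, j]), 1) if ci is not None else np.nan,
                        "ci_high": round(float(ci[1, j]), 1) if ci is not None else np.nan,
                        "count": int(counts[j]),
                    }
                )
        return pd.DataFrame(rows)


def apparent_fractions(
    events_per_run: Sequence[Sequence[DetectionEvent]], m_max: int
) -> FractionTable:
    """Pool detection events over runs into a fraction table.

    Raises if no events were detected at all (fractions undefined).
    """
    if len(events_per_run) < 1:
        raise ValueError("at least one run is required")
    counts_n, counts_true = event_count_matrix(events_per_run, m_max)
    if counts_n.sum() == 0:
        raise ValueError("no detection events: fractions are undefined")
    return FractionTable(
        m_max=m_max,
        counts_n=counts_n.sum(axis=0),
        counts_true=counts_true.sum(axis=0),
        n_runs=len(events_per_run),
    )


def bootstrap_ci(
    events_per_run: Sequence[Sequence[DetectionEvent]],
    m_max: int,
    n_boot: int = 10_000,
    level: float = 0.95,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CIs for all fractions, resampling whole runs.

    Each bootstrap sample draws ``n_runs`` runs with replacement from the
    ``n_runs`` available runs and recomputes every fraction; the interval
    spans the ``(1 - level)/2`` and ``(1 + level)/2`` percentiles.  Samples
    with zero total events are dropped from the percentile computation.

    Returns ``(ci_n, ci_true)``, each of shape ``(2, 5 * m_max)`` in percent.
    """
    n_runs = len(events_per_run)
    if n_runs < 2:
        raise ValueError("bootstrap requires at least two runs")
    counts_n, counts_true = event_count_matrix(events_per_run, m_max)
    rng = np.random.default_rng(seed)
    # Multinomial run weights are equivalent to drawing run indices.
    weights = rng.multinomial(n_runs, np.full(n_runs, 1.0 / n_runs), size=n_boot)
    tot_n = weights @ counts_n  # (n_boot, n_cap)
    tot_true = weights @ counts_true
    denom = tot_n.sum(axis=1)
    ok = denom > 0
    if not np.any(ok):
        raise ValueError("all bootstrap samples contain zero events")
    q = [100 * (1 - level) / 2, 100 * (1 + level) / 2]
    frac_n = 100.0 * tot_n[ok] / denom[ok, None]
    frac_true = 100.0 * tot_true[ok] / denom[ok, None]
    ci_n = np.percentile(frac_n, q, axis=0)
    ci_true = np.percentile(frac_true, q, axis=0)
    return ci_n, ci_true
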