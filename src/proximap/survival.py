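"""Kaplan-Meier estimation and log-rank prognostic screening.

Each candidate gene is dichotomised on its expression in a patient cohort
(median split by default, or a best-cutoff scan over the 25th-75th percentile
range of observed values) and the two groups are compared with a two-group
log-rank test. Genes with p < alpha are flagged as putative prognostic
markers. The best-cutoff mode minimises p over many candidate splits and is
therefore anti-conservative; the number of cutoffs scanned is recorded for
multiplicity disclosure, and no correction across genes is applied by default
(a Benjamini-Hochberg column is emitted for transparency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from statsmodels.stats.multitest import multipletests

from .ingest import normalize_symbol


@dataclass
class SurvivalCohort:
    """Follow-up time (months), event indicator and per-gene expression."""

    time: np.ndarray
    event: np.ndarray
    expression: pd.DataFrame  # patients x genes
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if not (self.time.shape[0] == self.event.shape[0] == len(self.expression)):
            raise ValueError("time, event and expression must share patient count")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise ValueError("follow-up times must be finite and > 0")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if not np.all(np.isfinite(self.expression.to_numpy(float))):
            raise ValueError("expression matrix must be finite")

    @property
    def n(self) -> int:
        return len(self.time)

    @property
    def genes(self) -> list[str]:
        return list(self.expression.columns)

    def write_tsv(self, path: str | Path) -> None:
        df = self.expression.copy()
        df.insert(0, "event", self.event)
        df.insert(0, "time", self.time)
        df.to_csv(path, sep="\t", index_label="patient")

    @classmethod
    def read_tsv(cls, path: str | Path, endpoint: str = "OS") -> "SurvivalCohort":
        df = pd.read_csv(path, sep="\t", index_col="patient")
        if "time" not in df.columns or "event" not in df.columns:
            raise ValueError(f"cohort table {path} needs 'time' and 'event' columns")
        expr = df.drop(columns=["time", "event"])
        expr.columns = [normalize_symbol(c) for c in expr.columns]
        return cls(
            time=df["time"].to_numpy(float),
            event=df["event"].to_numpy(int),
            expression=expr,
            endpoint=endpoint,
        )


class KaplanMeierCurve:
    """Right-continuous, non-increasing product-limit estimate with S(0) = 1."""

    def __init__(self, times: Sequence[float], events: Sequence[int]):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events, dtype=int)
        if times.size == 0:
            raise ValueError("at least one subject is required")
        if np.any(times <= 0) or not np.all(np.isfinite(times)):
            raise ValueError("times must be finite and > 0")
        kmf = KaplanMeierFitter()
        kmf.fit(times, event_observed=events)
        self._kmf = kmf
        sf = kmf.survival_function_
        self.table = pd.DataFrame(
            {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
        )

    def __call__(self, t: float | Sequence[float]) -> float | np.ndarray:
        """Survival probability at time(s) t."""
        out = self._kmf.survival_function_at_times(np.atleast_1d(t)).to_numpy(float)
        return float(out[0]) if np.isscalar(t) else out


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KaplanMeierCurve:
    """Product-limit (Kaplan-Meier) survival estimate."""
    return KaplanMeierCurve(times, events)


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank test: (1-df chi-square statistic, p-value).

    With zero events in both groups the test is undefined; (0, 1) is returned.
    """
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise ValueError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        return 0.0, 1.0
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class SurvivalScreenResult:
    """One gene's dichotomise-and-test outcome."""

    gene: str
    cutoff: float
    n_low: int
    n_high: int
    statistic: float
    p_value: float
    direction: str  # "hazardous" (high expression worse), "protective", "none"
    n_cutoffs_scanned: int
    significant: bool


def _direction(cohort: SurvivalCohort, high: np.ndarray) -> str:
    """Sign of the effect: event rate per unit follow-up, high vs low group."""
    t, e = cohort.time, cohort.event
    rate_high = e[high].sum() / max(t[high].sum(), 1e-12)
    rate_low = e[~high].sum() / max(t[~high].sum(), 1e-12)
    if rate_high > rate_low:
        return "hazardous"
    if rate_high < rate_low:
        return "protective"
    return "none"


def screen_genes(
    cohort: SurvivalCohort,
    genes: Iterable[str] | None = None,
    cutoff_mode: str = "median",
    alpha: float = 0.05,
) -> list[SurvivalScreenResult]:
    """Dichotomise each gene's expression and log-rank test the two groups.

    ``cutoff_mode='median'`` splits at the median; ``'best'`` scans the
    patient-distinct expression values between the 25th and 75th percentiles
    (median always included) and keeps the cutoff minimising the log-rank p,
    recording how many cutoffs were scanned. Genes with constant expression
    (or a split leaving a group empty) get p = 1 with a warning.
    """
    if cutoff_mode not in ("median", "best"):
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    if genes is None:
        gene_list = cohort.genes
    else:
        gene_list = [normalize_symbol(g) for g in genes]
        unknown = [g for g in gene_list if g not in cohort.expression.columns]
        if unknown:
            raise ValueError(f"gene(s) not in cohort expression: {unknown[:5]}")

    results: list[SurvivalScreenResult] = []
    for gene in gene_list:
        expr = cohort.expression[gene].to_numpy(float)
        distinct = np.unique(expr)
        if distinct.size < 2:
            warnings.warn(f"gene {gene}: constant expression, p set to 1", stacklevel=2)
            results.append(
                SurvivalScreenResult(gene, float(distinct[0]), cohort.n, 0, 0.0, 1.0,
                                     "none", 0, alpha >= 1.0)
            )
            continue
        median = float(np.median(expr))
        if cutoff_mode == "median":
            candidates = [median]
        else:
            lo, hi = np.quantile(expr, [0.25, 0.75])
            candidates = [float(v) for v in distinct if lo <= v <= hi]
            if median not in candidates:
                candidates.append(median)
        best: tuple[float, float, float, np.ndarray] | None = None
        scanned = 0
        for cut in candidates:
            high = expr > cut
            if high.all() or not high.any():
                continue
            scanned += 1
            stat, p = logrank(
                cohort.time[~high], cohort.event[~high],
                cohort.time[high], cohort.event[high],
            )
            if best is None or p < best[1]:
                best = (stat, p, cut, high)
        if best is None:
            warnings.warn(
                f"gene {gene}: no valid split between groups, p set to 1",
                stacklevel=2,
            )
            results.append(
                SurvivalScreenResult(gene, median, cohort.n, 0, 0.0, 1.0,
                                     "none", 0, alpha >= 1.0)
            )
            continue
        stat, p, cut, high = best
        results.append(
            SurvivalScreenResult(
                gene=gene,
                cutoff=cut,
                n_low=int((~high).sum()),
                n_high=int(high.sum()),
                statistic=stat,
                p_value=p,
                direction=_direction(cohort, high),
                n_cutoffs_scanned=scanned,
                significant=p < alpha,
            )
        )
    return results


def screen_table(results: Sequence[SurvivalScreenResult]) -> pd.DataFrame:
    """Screen results as a table, with a BH q-value column for transparency."""
    df = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "cutoff": r.cutoff,
                "n_low": r.n_low,
                "n_high": r.n_high,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "direction": r.direction,
                "n_cutoffs_scanned": r.n_cutoffs_scanned,
                "significant": r.significant,
            }
            for r in results
        ]
    )
    if not df.empty:
        df["q_value_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


def km_curves(
    cohort: SurvivalCohort, gene: str, cutoff: float
) -> pd.DataFrame:
    """Per-gene KM export: event times with survival in the low and high groups."""
    expr = cohort.expression[normalize_symbol(gene)].to_numpy(float)
    high = expr > cutoff
    if high.all() or not high.any():
        raise ValueError(f"cutoff {cutoff} leaves an empty group for {gene}")
    low_curve = km_estimate(cohort.time[~high], cohort.event[~high])
    high_curve = km_estimate(cohort.time[high], cohort.event[high])
    grid = np.unique(np.concatenate([low_curve.table["time"], high_curve.table["time"]]))
    return pd.DataFrame(
        {"time": grid, "S_low": low_curve(grid), "S_high": high_curve(grid)}
    )
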