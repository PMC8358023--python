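"""Cohort-level outcome statistics.

Survival is summarized by the Kaplan–Meier product-limit estimator with
two-group comparisons by the log-rank test (via lifelines); association
and correlation use the standard scipy tests.  The Mann–Whitney U test
uses full enumeration of group assignments for small samples (combined
n <= 16), which handles ties exactly, and the tie-corrected normal
approximation above that.  Raw (uncorrected) p-values are reported
throughout, and all tests are two-sided.

``binomial_power`` is an exact power computation for the two-sided exact
binomial test: the rejection region at level alpha is derived from the
test's p-values under the null, and power is the probability mass of
that region under the alternative.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .somatic_filter import SomaticSet
from .variant_io import PanelDef, get_panel

__all__ = [
    "KMResult",
    "km_estimate",
    "logrank_test",
    "correlate",
    "mann_whitney",
    "Assoc2x2Result",
    "assoc_2x2",
    "FrequencyTable",
    "summarize_frequencies",
    "binomial_power",
    "evaluable_n",
]

EXACT_MW_MAX_N = 16


@dataclass(frozen=True)
class KMResult:
    """Product-limit survival estimate for one group."""

    timeline: tuple[float, ...]  # event times, ascending
    survival: tuple[float, ...]  # S(t) at those times
    median: float | None  # earliest t with S(t) <= 0.5; None if never reached
    n: int
    n_events: int

    def survival_at(self, t: float) -> float:
        s = 1.0
        for ti, si in zip(self.timeline, self.survival):
            if ti <= t:
                s = si
            else:
                break
        return s


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMResult:
    """Kaplan–Meier estimate with median survival.

    Censored subjects (``event=False``) leave the risk set without an
    event; a fully censored group yields a valid flat curve with an
    undefined median.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival input")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_.iloc[:, 0]
    event_times = np.unique(times[events])
    surv = tuple(float(sf.loc[t]) for t in event_times)
    median = kmf.median_survival_time_
    median = None if math.isinf(median) else float(median)
    return KMResult(
        timeline=tuple(float(t) for t in event_times),
        survival=surv,
        median=median,
        n=int(times.size),
        n_events=int(events.sum()),
    )


def logrank_test(
    times_a: Sequence[float],
    events_a: Sequence[bool],
    times_b: Sequence[float],
    events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-sided log-rank chi-square (1 df) comparing two groups."""
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not (any(events_a) or any(events_b)):
        raise ValueError("log-rank requires at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def correlate(
    x: Sequence[float], y: Sequence[float], method: Literal["pearson", "spearman"] = "pearson"
) -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 paired points")
    if method == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("Pearson r is undefined for a constant vector")
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def _mw_u(x: np.ndarray, y: np.ndarray) -> float:
    # U for group x: #{x_i > y_j} + 0.5 #{x_i == y_j}
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt + 0.5 * eq)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Combined n <= 16: exact p by enumerating all C(n+m, n) group
    assignments of the pooled values (ties handled exactly).  Larger
    samples: tie-corrected normal approximation with continuity
    correction (scipy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u_obs = _mw_u(x, y)
    if n + m <= EXACT_MW_MAX_N:
        pooled = np.concatenate([x, y])
        center = n * m / 2.0
        dev_obs = abs(u_obs - center)
        total = 0
        extreme = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = _mw_u(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - center) >= dev_obs - 1e-12:
                extreme += 1
        return u_obs, extreme / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class Assoc2x2Result:
    p: float
    test_used: str  # "fisher_exact" or "chi_square"
    statistic: float  # chi2 statistic or Fisher odds ratio
    p_fisher: float
    p_chi_square: float | None


def assoc_2x2(table: Sequence[Sequence[float]]) -> Assoc2x2Result:
    """2x2 association test with the standard selection rule.

    Fisher's exact test when any expected cell count is < 5, otherwise
    the chi-square test with continuity correction.  Both p-values are
    carried in the result since published analyses do not always name
    which was applied.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    odds, p_fisher = stats.fisher_exact(tab, alternative="two-sided")
    p_chi = None
    chi2_stat = float("nan")
    if tab.sum() > 0 and (tab.sum(axis=0) > 0).all() and (tab.sum(axis=1) > 0).all():
        chi2_stat, p_chi, _, expected = stats.chi2_contingency(tab, correction=True)
        use_fisher = (expected < 5).any()
    else:
        use_fisher = True
    if use_fisher:
        return Assoc2x2Result(float(p_fisher), "fisher_exact", float(odds), float(p_fisher), p_chi)
    return Assoc2x2Result(float(p_chi), "chi_square", float(chi2_stat), float(p_fisher), float(p_chi))


@dataclass
class FrequencyTable:
    """Per-gene mutation frequency summary across a cohort.

    ``table`` has one row per mutated gene: n_mutations, n_patients (with
    at least one mutation in the gene), pct_patients (of the cohort, one
    decimal) and whether the gene is restricted to the larger panel
    version (footnoted: only a subset of samples could report it).
    """

    table: pd.DataFrame
    cohort_size: int
    total_mutations: int
    n_patients_positive: int
    fraction_positive: float
    mean_mutations_per_positive: float
    restricted_genes: tuple[str, ...] = ()


def summarize_frequencies(
    somatic_sets: Sequence[SomaticSet],
    cohort_size: int | None = None,
    panel_versions: Mapping[str, str] | None = None,
) -> FrequencyTable:
    """Tabulate per-gene mutation and patient counts from one somatic set
    per patient (e.g. all baseline sets, or all PD-emergent sets).

    ``panel_versions`` maps patient_id -> panel version; genes present
    only in v3 are marked restricted (their denominator is the v3 subset).
    """
    patients = [s.patient_id or s.sample_id for s in somatic_sets]
    if len(set(patients)) != len(patients):
        raise ValueError("expected one somatic set per patient")
    cohort_size = cohort_size if cohort_size is not None else len(somatic_sets)
    v2 = set(get_panel("v2").genes)
    v3 = get_panel("v3").genes
    rows: dict[str, dict[str, float]] = {}
    n_positive = 0
    total = 0
    for s in somatic_sets:
        if s.calls:
            n_positive += 1
        genes_here = set()
        for call in s.calls:
            total += 1
            row = rows.setdefault(call.gene, {"n_mutations": 0, "n_patients_with_mutation": 0})
            row["n_mutations"] += 1
            genes_here.add(call.gene)
        for g in genes_here:
            rows[g]["n_patients_with_mutation"] += 1
    restricted = tuple(g for g in rows if g in set(v3) - v2)
    table = pd.DataFrame(
        [
            {
                "gene": g,
                "n_mutations": int(r["n_mutations"]),
                "n_patients_with_mutation": int(r["n_patients_with_mutation"]),
                "pct_patients": round(100.0 * r["n_patients_with_mutation"] / cohort_size, 1)
                if cohort_size
                else 0.0,
                "panel_restricted": g in restricted,
            }
            for g, r in rows.items()
        ],
        columns=["gene", "n_mutations", "n_patients_with_mutation", "pct_patients", "panel_restricted"],
    ).sort_values(["n_mutations", "gene"], ascending=[False, True], kind="stable").reset_index(drop=True)
    return FrequencyTable(
        table=table,
        cohort_size=cohort_size,
        total_mutations=total,
        n_patients_positive=n_positive,
        fraction_positive=n_positive / cohort_size if cohort_size else 0.0,
        mean_mutations_per_positive=total / n_positive if n_positive else 0.0,
        restricted_genes=restricted,
    )


def binomial_power(p0: float, p1: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided exact binomial test of H0: p = p0.

    The rejection region is every outcome k whose two-sided exact-test
    p-value under p0 is <= alpha (minimum-likelihood two-sided p, as in
    scipy); power is the binomial(n, p1) mass of that region.
    """
    if not (0.0 < p0 < 1.0 and 0.0 < p1 < 1.0):
        raise ValueError("p0 and p1 must be in (0, 1)")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ks = np.arange(n + 1)
    reject = np.array(
        [stats.binomtest(int(k), n, p0, alternative="two-sided").pvalue <= alpha for k in ks]
    )
    return float(stats.binom.pmf(ks[reject], n, p1).sum())


def evaluable_n(total_n: int, prevalence: float) -> int:
    """Evaluable subjects for the detection-sensitivity power computation:
    the expected number carrying a detectable alteration at the assumed
    population prevalence."""
    if not 0.0 < prevalence <= 1.0:
        raise ValueError("prevalence must be in (0, 1]")
    return round(prevalence * total_n)
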