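"""Univariate battery: 2x2 presence-by-diagnosis tests and onset comparisons.

For each symptom the battery cross-tabulates presence against diagnosis and
applies either Pearson's chi-square (no continuity correction) or Fisher's
exact test, chosen by Cochran's rule (Fisher whenever any expected cell
count is below 5).  Onset ages among symptom-positive patients are compared
between groups with the Mann-Whitney U test.  Significance is flagged at a
raw (unadjusted) alpha = 0.05 per test, mirroring the original analysis;
the report carries an explicit note that no multiplicity correction is
applied.

The chi-square omits the Yates continuity correction: that variant
reproduces the published p-value column from the published counts (e.g.
conduct disorders 0.001, tobacco use 0.016), whereas the corrected
statistic does not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, Diagnosis

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "BatteryReport",
    "DegenerateTableError",
    "make_table",
    "pearson_chi2",
    "fisher_exact_two_sided",
    "choose_test",
    "mann_whitney_u",
    "run_battery",
    "ALPHA",
]

#: Default significance level of the battery.
ALPHA = 0.05

#: Relative tolerance treating hypergeometric point probabilities as tied
#: (two-sided Fisher, point-probability method).
_FISHER_REL_TOL = 1e-7


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is zero; the chi-square test is undefined.

    Fisher's exact test handles such tables (p = 1).
    """


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Presence-by-diagnosis counts: a/b = SZ present/absent, c/d = MSD."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_sz(self) -> int:
        return self.a + self.b

    @property
    def n_msd(self) -> int:
        return self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    def expected(self) -> np.ndarray:
        """Expected counts under independence (margins fixed)."""
        if self.n == 0:
            raise DegenerateTableError("empty table")
        obs = self.to_array()
        return np.outer(obs.sum(axis=1), obs.sum(axis=0)) / self.n


@dataclass(frozen=True)
class TestResult:
    """Outcome of one test: method, statistic (None for Fisher), p, flag."""

    method: str  # pearson_chi2 | fisher_exact | mann_whitney_u
    p_value: float
    statistic: float | None = None
    df: int | None = None
    alpha: float = ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def make_table(cohort: Cohort, symptom: str) -> ContingencyTable2x2:
    """Cross-tabulate presence of *symptom* against diagnosis."""
    if symptom not in cohort.catalog:
        raise KeyError(f"unknown symptom: {symptom!r}")
    a = sum(
        p.presence.get(symptom, 0) for p in cohort.group(Diagnosis.SZ)
    )
    c = sum(
        p.presence.get(symptom, 0) for p in cohort.group(Diagnosis.MSD)
    )
    n_sz, n_msd = cohort.group_sizes
    return ContingencyTable2x2(a=a, b=n_sz - a, c=c, d=n_msd - c)


def pearson_chi2(table: ContingencyTable2x2, alpha: float = ALPHA) -> TestResult:
    """Pearson chi-square on 1 df, without continuity correction."""
    obs = table.to_array()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise DegenerateTableError(
            "zero margin: the chi-square test is undefined; use "
            "fisher_exact_two_sided"
        )
    stat, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return TestResult(
        method="pearson_chi2", statistic=float(stat), df=int(df),
        p_value=float(p), alpha=alpha,
    )


def fisher_exact_two_sided(
    table: ContingencyTable2x2, alpha: float = ALPHA
) -> TestResult:
    """Two-sided Fisher exact test, point-probability method.

    p = sum of hypergeometric probabilities of all tables with the same
    margins whose point probability is <= that of the observed table
    (within relative tolerance 1e-7 for floating-point ties).
    """
    # scipy implements exactly this convention; the tolerance clause is
    # asserted against a full-enumeration oracle in the test suite.
    _, p = stats.fisher_exact(table.to_array(), alternative="two-sided")
    return TestResult(
        method="fisher_exact", p_value=float(min(p, 1.0)), alpha=alpha
    )


def choose_test(table: ContingencyTable2x2) -> str:
    """Cochran's rule: Fisher iff any expected cell count < 5, else chi2."""
    if table.n == 0:
        return "fisher_exact"
    obs = table.to_array()
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return "fisher_exact"
    return "fisher_exact" if (table.expected() < 5).any() else "pearson_chi2"


def _presence_test(table: ContingencyTable2x2, alpha: float) -> TestResult:
    if choose_test(table) == "fisher_exact":
        return fisher_exact_two_sided(table, alpha)
    return pearson_chi2(table, alpha)


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _mwu_statistic(ranks_x: np.ndarray, n: int, m: int) -> float:
    """U for the x-sample from its midranks in the pooled sample."""
    return float(ranks_x.sum() - n * (n + 1) / 2.0)


def mann_whitney_u(
    xs, ys, alpha: float = ALPHA, exact_threshold: int = 20
) -> TestResult:
    """Two-sided Mann-Whitney U with midrank tie handling.

    For pooled sample sizes n+m <= *exact_threshold* the p-value is exact:
    enumeration over all C(n+m, n) assignments of the pooled midranks,
    counting assignments whose U deviates from the null mean nm/2 at least
    as much as observed.  For larger samples the normal approximation with
    tie-corrected variance and continuity correction is used.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = xs.size, ys.size
    pooled = np.concatenate([xs, ys])
    ranks = _midranks(pooled)
    u_obs = _mwu_statistic(ranks[:n], n, m)

    if n + m <= exact_threshold:
        mu = n * m / 2.0
        dev_obs = abs(u_obs - mu)
        total = 0
        hits = 0
        # U depends on the assignment only through the sum of x-ranks
        for combo in itertools.combinations(range(n + m), n):
            u = ranks[list(combo)].sum() - n * (n + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
        p = hits / total
    else:
        _, p = stats.mannwhitneyu(
            xs, ys, alternative="two-sided", use_continuity=True,
            method="asymptotic",
        )
    return TestResult(
        method="mann_whitney_u", statistic=u_obs, p_value=float(min(p, 1.0)),
        alpha=alpha,
    )


@dataclass(frozen=True)
class OnsetComparison:
    """Mann-Whitney onset comparison for one symptom, or the skip reason."""

    result: TestResult | None
    n_sz: int
    n_msd: int
    skipped_reason: str | None = None


@dataclass
class BatteryReport:
    """Full univariate battery: one presence test per catalog symptom plus
    an onset-age comparison where both groups have enough recorded onsets.

    Significance flags are raw per-test p < alpha; no multiple-testing
    correction is applied (see :meth:`to_frame`'s ``note``).
    """

    presence: dict[str, TestResult]
    tables: dict[str, ContingencyTable2x2]
    onset: dict[str, OnsetComparison]
    alpha: float = ALPHA

    #: Printed prominently with any rendering of the report.
    note: str = (
        "Significance flags are per-test p < alpha with NO multiple-testing "
        "adjustment."
    )

    @property
    def n_significant(self) -> int:
        """Significant presence tests at alpha (unadjusted)."""
        return sum(r.significant for r in self.presence.values())

    @property
    def significant_symptoms(self) -> list[str]:
        return [s for s, r in self.presence.items() if r.significant]

    def to_frame(self) -> pd.DataFrame:
        """Tabular report mirroring the published table layout."""
        rows = []
        for name, result in self.presence.items():
            t = self.tables[name]
            onset = self.onset[name]
            o = onset.result
            rows.append(
                {
                    "symptom": name,
                    "n_sz": t.a,
                    "pct_sz": 100.0 * t.a / t.n_sz if t.n_sz else np.nan,
                    "n_msd": t.c,
                    "pct_msd": 100.0 * t.c / t.n_msd if t.n_msd else np.nan,
                    "method": result.method,
                    "p_value": result.p_value,
                    "significant": result.significant,
                    "onset_method": None if o is None else o.method,
                    "onset_p_value": np.nan if o is None else o.p_value,
                    "onset_skipped": onset.skipped_reason,
                }
            )
        return pd.DataFrame(rows)


def run_battery(cohort: Cohort, alpha: float = ALPHA) -> BatteryReport:
    """Run presence tests and onset comparisons for every catalog symptom.

    The onset comparison is restricted to symptom-positive patients with a
    recorded onset age and is skipped (with a reason) when either group has
    fewer than 2 such patients.
    """
    presence: dict[str, TestResult] = {}
    tables: dict[str, ContingencyTable2x2] = {}
    onset: dict[str, OnsetComparison] = {}
    for name in cohort.catalog.names:
        table = make_table(cohort, name)
        tables[name] = table
        presence[name] = _presence_test(table, alpha)
        ages_sz = cohort.onset_ages(name, Diagnosis.SZ)
        ages_msd = cohort.onset_ages(name, Diagnosis.MSD)
        if ages_sz.size < 2 or ages_msd.size < 2:
            onset[name] = OnsetComparison(
                result=None,
                n_sz=ages_sz.size,
                n_msd=ages_msd.size,
                skipped_reason=(
                    "fewer than 2 recorded onset ages in at least one group "
                    f"(SZ: {ages_sz.size}, MSD: {ages_msd.size})"
                ),
            )
        else:
            onset[name] = OnsetComparison(
                result=mann_whitney_u(ages_sz, ages_msd, alpha),
                n_sz=ages_sz.size,
                n_msd=ages_msd.size,
            )
    return BatteryReport(presence=presence, tables=tables, onset=onset, alpha=alpha)
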