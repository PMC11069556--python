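"""2x2 association tests, response screens, Kaplan-Meier and log-rank.

The two-sided Fisher exact p is the sum of hypergeometric point
probabilities no larger than the observed table's (the convention of R's
``fisher.test``); the chi-squared test is the Pearson statistic without
continuity correction, which is what reproduces published statistics of
the form chi2 = 0.009 on small tables.  ``auto`` selects Fisher whenever
any expected cell count is below 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .variant_model import Cohort, Lesion, mutation_key


class AssociationError(ValueError):
    """Degenerate or empty association input."""


@dataclass(frozen=True)
class Contingency2x2:
    """Counts with rows = groups and columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise AssociationError("negative cell count")
        if self.total == 0:
            raise AssociationError("all-zero 2x2 table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)

    def expected(self) -> np.ndarray:
        t = self.to_array().astype(float)
        return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


@dataclass(frozen=True)
class TestResult:
    method: str                 # fisher_two_sided | chi2_pearson
    p_value: float
    statistic: float | None     # chi-squared statistic; None for Fisher
    odds_ratio: float           # cross-product a*d / (b*c); inf/0 allowed


def test_2x2(table: Contingency2x2, method: str = "auto") -> TestResult:
    """Fisher exact (point-probability two-sided rule) or Pearson chi2.

    ``auto`` uses Fisher when any expected count < 5, Pearson chi-squared
    without continuity correction otherwise.
    """
    if method == "auto":
        method = "fisher" if (table.expected() < 5).any() else "chi2"
    arr = table.to_array()
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = (
            float("nan")
            if table.b * table.c == 0 and table.a * table.d == 0
            else float(np.divide(table.a * table.d, table.b * table.c))
        )
    if method == "fisher":
        _, p = stats.fisher_exact(arr, alternative="two-sided")
        return TestResult("fisher_two_sided", float(p), None, odds)
    if method == "fisher_doubled":
        # doubled smaller one-tail alternative, for cross-checking
        less = stats.fisher_exact(arr, alternative="less")[1]
        greater = stats.fisher_exact(arr, alternative="greater")[1]
        return TestResult("fisher_two_sided", float(min(1.0, 2 * min(less, greater))), None, odds)
    if method == "chi2":
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise AssociationError("chi2 undefined: zero row or column margin")
        chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
        return TestResult("chi2_pearson", float(p), float(chi2), odds)
    raise ValueError(f"unknown method {method!r}")


def fisher_exact_bruteforce(table: Contingency2x2) -> float:
    """Independent enumeration oracle for the two-sided Fisher p.

    Enumerates every table with the observed margins and sums the point
    probabilities <= the observed one (with a tiny relative tolerance for
    floating-point ties).  Intended for testing at small N.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, n1 = a + b, a + c
    n = table.total
    rv = stats.hypergeom(n, n1, r1)
    p_obs = rv.pmf(a)
    lo, hi = max(0, r1 + n1 - n), min(r1, n1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = rv.pmf(k)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, float(total))


def gene_response_screen(
    cohort: Cohort,
    lesion: Lesion | None = None,
    min_count: int = 3,
    method: str = "fisher",
) -> pd.DataFrame:
    """Per-gene mutated x effective 2x2 screen among evaluable patients.

    Patients without a response label are excluded (their number is in
    ``attrs['n_excluded']``).  Genes mutated in fewer than ``min_count``
    evaluable patients are omitted.  BH q-values accompany raw p-values;
    ``direction`` marks whether mutation frequency is higher among
    effective or ineffective patients.
    """
    from .pathway_score import benjamini_hochberg

    evaluable = [p for p in cohort.pairs if p.clinical.effective is not None]
    n_excluded = len(cohort.pairs) - len(evaluable)
    if not evaluable:
        raise AssociationError("no patients with a response label")
    eff_ids = {p.patient_id for p in evaluable if p.clinical.effective}
    ineff_ids = {p.patient_id for p in evaluable} - eff_ids

    mutated: dict[str, set[str]] = {}
    for pair in evaluable:
        for prof in (pair.primary, pair.metastasis):
            if prof is None or (lesion is not None and prof.lesion != lesion):
                continue
            for v in prof.variants:
                mutated.setdefault(v.gene, set()).add(pair.patient_id)

    rows = []
    for gene, carriers in sorted(mutated.items()):
        if len(carriers) < min_count:
            continue
        a = len(carriers & eff_ids)
        c = len(carriers & ineff_ids)
        tab = Contingency2x2(a, len(eff_ids) - a, c, len(ineff_ids) - c)
        res = test_2x2(tab, method=method)
        f_eff = a / len(eff_ids) if eff_ids else 0.0
        f_ineff = c / len(ineff_ids) if ineff_ids else 0.0
        rows.append(
            {
                "gene": gene,
                "n_effective_mutated": a,
                "n_effective": len(eff_ids),
                "n_ineffective_mutated": c,
                "n_ineffective": len(ineff_ids),
                "direction": "effective_enriched" if f_eff >= f_ineff else "ineffective_enriched",
                "method": res.method,
                "p_value": res.p_value,
                "odds_ratio": res.odds_ratio,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_effective_mutated", "n_effective", "n_ineffective_mutated",
            "n_ineffective", "direction", "method", "p_value", "odds_ratio",
        ],
    )
    if len(df):
        df["q_value"] = benjamini_hochberg(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "gene"], ignore_index=True)
    df.attrs["n_excluded"] = n_excluded
    return df


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray            # event/censoring times, ascending
    survival: np.ndarray         # S(t) at each time, non-increasing from 1
    at_risk: np.ndarray          # risk-set size just before each time

    def survival_at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_curve(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier product-limit estimator (event=True means death)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise AssociationError("empty survival input")
    if (t < 0).any():
        raise AssociationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_["KM_estimate"]
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    # S(0)=1 is implicit in survival_at; keep t=0 only if a death occurs there
    keep = (grid > 0) | (surv < 1.0)
    return KMCurve(times=grid[keep], survival=surv[keep], at_risk=at_risk[keep])


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    df: int
    p_value: float
    note: str = ""


def logrank_test(
    group_times: Mapping[str, Sequence[float]],
    group_events: Mapping[str, Sequence[bool]],
) -> LogRankResult:
    """k-sample log-rank test (observed minus expected, hypergeometric
    variance, df = k - 1)."""
    if len(group_times) < 2:
        raise AssociationError("log-rank requires at least two groups")
    durations, labels, observed = [], [], []
    for g, ts in group_times.items():
        ev = list(group_events[g])
        if len(ts) == 0:
            raise AssociationError(f"empty group {g!r}")
        durations.extend(float(x) for x in ts)
        observed.extend(bool(x) for x in ev)
        labels.extend([g] * len(ts))
    if not any(observed):
        return LogRankResult(0.0, len(group_times) - 1, 1.0, note="no events in any group")
    res = multivariate_logrank_test(
        np.asarray(durations), np.asarray(labels), np.asarray(observed, dtype=int)
    )
    return LogRankResult(
        chi2=float(res.test_statistic),
        df=len(group_times) - 1,
        p_value=float(res.p_value),
    )


def clinical_response_association(cohort: Cohort, factor: str) -> TestResult:
    """2x2 test of a binary clinical factor against effective response.

    ``factor`` is a ClinicalRecord field name ('metastasis_subtype',
    'extent', ...); records with unknown factor level or missing response
    are excluded.
    """
    levels: dict[str, int] = {}
    counts: dict[str, list[int]] = {}
    for pair in cohort.pairs:
        rec = pair.clinical
        if rec.effective is None:
            continue
        value = getattr(rec, factor)
        value = value.value if hasattr(value, "value") else str(value)
        if value in {"unknown", ""}:
            continue
        if value not in levels:
            levels[value] = len(levels)
        counts.setdefault(value, [0, 0])[0 if rec.effective else 1] += 1
    if not counts:
        raise AssociationError(f"factor {factor!r} missing for all evaluable patients")
    if len(counts) != 2:
        raise AssociationError(
            f"factor {factor!r} is not binary among evaluable patients: "
            f"{sorted(counts)}"
        )
    (a, b), (c, d) = (counts[k] for k in sorted(counts, key=levels.get))
    return test_2x2(Contingency2x2(a, b, c, d), method="auto")
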