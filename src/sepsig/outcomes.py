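"""Clinical outcome adjudication and two-group comparison statistics.

Covers the outcome definitions used for septic ICU cohorts:

* chronic critical illness (CCI): ICU stay of 14 days or more with
  persistent organ dysfunction on day-14 SOFA components (cardiovascular
  >= 1, or any other organ system >= 2); early death is death within 14
  days of sepsis onset; everyone else is non-CCI — an exhaustive,
  mutually exclusive trichotomy;
* "free days" to a 28-day horizon: days free of a resource (ICU,
  ventilator, RRT, hospital) within the lesser of 28 days or the days
  from sepsis onset to death;
* per-variable group comparisons: Fisher's exact test for categoricals,
  Wilcoxon rank-sum (default) or Student's t for continuous variables,
  with n (%) / median (25th, 75th) summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutcomeRecord",
    "ComparisonRow",
    "SOFA_SYSTEMS",
    "classify_cci",
    "free_days",
    "fisher_exact_2x2",
    "rxc_exact_test",
    "compare_groups",
    "format_count_pct",
    "format_median_iqr",
    "days_between",
    "outcomes_to_frame",
    "outcomes_from_frame",
]

SOFA_SYSTEMS = ["cardiovascular", "respiratory", "cns", "liver", "coagulation", "renal"]

EARLY_DEATH_CUTOFF_DAYS = 14
CCI_ICU_LOS_DAYS = 14
FREE_DAYS_HORIZON = 28


class OutcomeError(ValueError):
    pass


@dataclass
class OutcomeRecord:
    """Per-patient outcome fields used by CCI adjudication and free-days math."""

    patient_id: str
    death_day: float | None = None        # days since sepsis onset
    icu_los: float = 0.0
    hospital_los: float = 0.0
    ventilator_days: float = 0.0
    rrt_days: float = 0.0
    day14_sofa: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        for name in ("icu_los", "hospital_los", "ventilator_days", "rrt_days"):
            if getattr(self, name) < 0:
                raise OutcomeError(f"{name} must be nonnegative")
        if self.death_day is not None and self.death_day < 0:
            raise OutcomeError("death_day must be nonnegative")


def days_between(onset, event) -> float:
    """Whole days from onset to event, truncating partial days.

    Accepts anything ``pandas.Timestamp`` can parse; 'within 14 days'
    decisions compare the truncated difference with <= 14.
    """
    delta = pd.Timestamp(event) - pd.Timestamp(onset)
    return float(math.floor(delta.total_seconds() / 86400.0))


def classify_cci(rec: OutcomeRecord) -> str:
    """Adjudicate one record into ``early_death`` / ``CCI`` / ``non_CCI``.

    Early death wins (death within 14 days of onset); otherwise CCI
    requires an ICU stay of >= 14 days *and* persistent organ dysfunction
    on day-14 SOFA components.
    """
    if rec.death_day is not None and rec.death_day <= EARLY_DEATH_CUTOFF_DAYS:
        return "early_death"
    if rec.icu_los >= CCI_ICU_LOS_DAYS:
        sofa = rec.day14_sofa
        if sofa is None or any(sofa.get(s) is None for s in SOFA_SYSTEMS):
            raise OutcomeError(
                f"patient {rec.patient_id}: ICU stay >= {CCI_ICU_LOS_DAYS} d but "
                "day-14 SOFA components are missing; CCI adjudication impossible"
            )
        persistent = sofa["cardiovascular"] >= 1 or any(
            sofa[s] >= 2 for s in SOFA_SYSTEMS[1:]
        )
        if persistent:
            return "CCI"
    return "non_CCI"


def free_days(outcome_days: float, death_day: float | None = None, horizon: int = FREE_DAYS_HORIZON) -> int:
    """Days free of an outcome within the 28-day window, censored at death.

    window = min(horizon, death day if any); the result is
    max(0, window - min(outcome_days, window)), reported as whole days.
    A survivor with zero outcome days scores the full horizon.
    """
    if outcome_days < 0:
        raise OutcomeError("outcome_days must be nonnegative")
    if death_day is not None and death_day < 0:
        raise OutcomeError("death_day must be nonnegative")
    window = horizon if death_day is None else min(horizon, death_day)
    return int(max(0, window - min(outcome_days, window)))


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided by the point-probability rule: the p-value sums the
    hypergeometric probabilities of every table with the same margins
    whose probability does not exceed the observed table's.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise OutcomeError("cells must be nonnegative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise OutcomeError("every margin of the 2x2 table must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _rxc_tables(row_sums, col_sums):
    """Yield all nonnegative integer tables with the given margins."""
    rows = list(row_sums)
    cols = list(col_sums)

    def fill(r, remaining_cols):
        if r == len(rows) - 1:
            last = tuple(remaining_cols)
            if all(v >= 0 for v in last) and sum(last) == rows[r]:
                yield (last,)
            return

        def choose(c, left, row_acc):
            if c == len(cols) - 1:
                v = left
                if 0 <= v <= remaining_cols[c]:
                    row = tuple(row_acc + [v])
                    new_cols = [rc - rv for rc, rv in zip(remaining_cols, row)]
                    for rest in fill(r + 1, new_cols):
                        yield (row,) + rest
                return
            for v in range(min(left, remaining_cols[c]) + 1):
                yield from choose(c + 1, left - v, row_acc + [v])

        yield from choose(0, rows[r], [])

    yield from fill(0, cols)


def _log_table_prob(table, log_fact):
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    n = sum(rows)
    lp = sum(log_fact[x] for x in rows) + sum(log_fact[x] for x in cols) - log_fact[n]
    lp -= sum(log_fact[v] for r in table for v in r)
    return lp


def rxc_exact_test(table, max_exact_n: int = 30, seed: int = 0, n_mc: int = 20000) -> float:
    """Two-sided exact test for an r x c contingency table.

    Full enumeration of tables with fixed margins when the grand total is
    <= ``max_exact_n``; otherwise Monte-Carlo sampling from the
    margin-conditional distribution with a fixed seed.  The 2x2 case is
    delegated to Fisher's exact test.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape == (2, 2):
        return fisher_exact_2x2(*arr.ravel())
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise OutcomeError("every margin must be positive")
    n = int(arr.sum())
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])
    obs_lp = _log_table_prob([tuple(r) for r in arr.tolist()], log_fact)
    slack = 1e-7
    if n <= max_exact_n:
        p = 0.0
        for t in _rxc_tables(rows.tolist(), cols.tolist()):
            lp = _log_table_prob(t, log_fact)
            if lp <= obs_lp + slack:
                p += math.exp(lp)
        return float(min(1.0, p))
    sampler = stats.random_table(rows, cols, seed=np.random.default_rng(seed))
    samples = sampler.rvs(n_mc)
    hits = 0
    for s in np.asarray(samples).reshape(n_mc, *arr.shape):
        lp = _log_table_prob([tuple(int(v) for v in r) for r in s], log_fact)
        if lp <= obs_lp + slack:
            hits += 1
    return (hits + 1) / (n_mc + 1)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def format_count_pct(count: int, total: int) -> str:
    """Render an event count as ``"k (pct)"`` with a whole-number percent."""
    if total <= 0:
        raise OutcomeError("total must be positive")
    return f"{count} ({round(100.0 * count / total)})"


def format_median_iqr(values) -> str:
    """Render a continuous summary as ``median (25th, 75th)``."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    med, lo, hi = np.percentile(v, [50, 25, 75])
    fmt = lambda x: f"{x:g}"
    return f"{fmt(med)} ({fmt(lo)}, {fmt(hi)})"


@dataclass
class ComparisonRow:
    variable: str
    group_summaries: dict[str, str]
    test: str                      # fisher_exact | t_test | wilcoxon
    p_value: float


def compare_groups(
    data: pd.DataFrame,
    group: np.ndarray,
    categorical: list[str] | None = None,
    normality_screen: bool = False,
    seed: int = 0,
) -> list[ComparisonRow]:
    """Per-variable two-group comparison mirroring a clinical Table 1/2.

    ``data`` holds one column per variable; ``group`` the two-level group
    label per row.  Non-numeric (or listed) columns are treated as
    categorical and tested with an exact test; continuous columns use the
    Wilcoxon rank-sum test, or Student's t when ``normality_screen`` is on
    and both groups pass a Shapiro test at 0.05.
    """
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise OutcomeError(f"exactly two groups required, got {levels.size}")
    masks = {str(l): group == l for l in levels}
    if any(m.sum() == 0 for m in masks.values()):
        raise OutcomeError("empty group")
    categorical = set(categorical or [])

    rows: list[ComparisonRow] = []
    for col in data.columns:
        series = data[col]
        is_cat = col in categorical or not pd.api.types.is_numeric_dtype(series) or \
            pd.api.types.is_bool_dtype(series)
        if is_cat:
            cats = pd.unique(series.dropna())
            table = np.array(
                [[int(((series == c) & m).sum()) for c in cats] for m in masks.values()]
            )
            table = table[:, table.sum(axis=0) > 0]
            p = rxc_exact_test(table, seed=seed) if table.shape[1] >= 2 else 1.0
            # binary categoricals summarized as n (%) of the "positive" level
            positive = max(cats) if len(cats) == 2 else None
            summaries = {}
            for name, m in masks.items():
                if positive is not None:
                    summaries[name] = format_count_pct(
                        int(((series == positive) & m).sum()), int(m.sum())
                    )
                else:
                    summaries[name] = ", ".join(
                        f"{c}: {int(((series == c) & m).sum())}" for c in cats
                    )
            rows.append(ComparisonRow(str(col), summaries, "fisher_exact", float(p)))
        else:
            vals = {n: series[m].dropna().to_numpy(dtype=float) for n, m in masks.items()}
            a, b = vals.values()
            use_t = False
            if normality_screen and min(a.size, b.size) >= 3:
                use_t = all(stats.shapiro(v).pvalue > 0.05 for v in (a, b))
            if use_t:
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
                test = "t_test"
            else:
                p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
                test = "wilcoxon"
            summaries = {n: format_median_iqr(v) for n, v in vals.items()}
            rows.append(ComparisonRow(str(col), summaries, test, float(p)))
    return rows


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def outcomes_to_frame(records: list[OutcomeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "death_day": r.death_day,
            "icu_los": r.icu_los,
            "hospital_los": r.hospital_los,
            "ventilator_days": r.ventilator_days,
            "rrt_days": r.rrt_days,
        }
        for s in SOFA_SYSTEMS:
            row[f"sofa14_{s}"] = None if r.day14_sofa is None else r.day14_sofa.get(s)
        rows.append(row)
    return pd.DataFrame(rows)


def outcomes_from_frame(df: pd.DataFrame) -> list[OutcomeRecord]:
    records = []
    for _, row in df.iterrows():
        sofa_vals = {s: row.get(f"sofa14_{s}") for s in SOFA_SYSTEMS}
        sofa = None
        if not all(pd.isna(v) for v in sofa_vals.values()):
            sofa = {s: (None if pd.isna(v) else int(v)) for s, v in sofa_vals.items()}
        records.append(
            OutcomeRecord(
                patient_id=str(row["patient_id"]),
                death_day=None if pd.isna(row.get("death_day")) else float(row["death_day"]),
                icu_los=float(row["icu_los"]),
                hospital_los=float(row["hospital_los"]),
                ventilator_days=float(row["ventilator_days"]),
                rrt_days=float(row["rrt_days"]),
                day14_sofa=sofa,
            )
        )
    return records
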