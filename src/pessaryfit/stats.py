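"""Group-comparison statistics for the baseline-characteristics table.

Continuous characteristics are compared with an independent-samples t-test
(pooled variance by default, Welch optional), ordinal ones with an exact
Mann-Whitney U test (full enumeration with midranks for combined n <= 20,
normal approximation with tie correction above), and nominal ones with an
exact conditional test on the r x c contingency table (hypergeometric for
2 x 2; full enumeration of margin-fixed tables otherwise).  The two-sided
exact rule sums the probabilities of all tables no more probable than the
observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import AVULSION_LEVELS, CohortTable, FITTING

#: Largest total count for which the r x c exact test enumerates all tables.
EXACT_TEST_LIMIT = 30

#: Largest combined sample size for which Mann-Whitney U is fully enumerated.
MWU_EXACT_LIMIT = 20

_REL_TOL = 1 + 1e-7  # relative slack when comparing table probabilities


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one group, in the variable's own units."""

    n: int
    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def summarize(values) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    return GroupSummary(
        n=len(values),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    )


def pooled_mean_sd(groups: list[GroupSummary]) -> GroupSummary:
    """Combine group summaries into the whole-sample mean and SD.

    The pooled SD reconstructs the total sum of squares as within-group plus
    between-group contributions, i.e. the SD the raw pooled sample would
    show (n-1 denominator).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to pool")
    n_total = sum(g.n for g in groups)
    if n_total == 0:
        raise ValueError("zero total sample size")
    grand_mean = sum(g.n * g.mean for g in groups) / n_total
    ss = sum((g.n - 1) * g.sd**2 + g.n * (g.mean - grand_mean) ** 2 for g in groups)
    sd = math.sqrt(ss / (n_total - 1)) if n_total > 1 else 0.0
    return GroupSummary(n=n_total, mean=grand_mean, sd=sd)


def _as_summary(g) -> GroupSummary:
    return g if isinstance(g, GroupSummary) else summarize(g)


def t_test_independent(g1, g2, welch: bool = False) -> dict[str, float]:
    """Two-sided independent-samples t-test from raw values or summaries.

    Pooled-variance by default; ``welch=True`` drops the equal-variance
    assumption.  Raw-value and summary inputs give identical results for the
    same data.
    """
    s1, s2 = _as_summary(g1), _as_summary(g2)
    if s1.n < 2 or s2.n < 2:
        raise ValueError("both groups need n >= 2")
    if s1.sd == 0 and s2.sd == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind_from_stats(
        s1.mean, s1.sd, s1.n, s2.mean, s2.sd, s2.n, equal_var=not welch
    )
    if welch:
        # Welch-Satterthwaite degrees of freedom
        v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
        df = (v1 + v2) ** 2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    else:
        df = s1.n + s2.n - 2
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(g1, g2) -> dict[str, float]:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Exact for combined n <= 20 by enumerating every assignment of ranks to
    the first group (the permutation null conditions on the observed value
    multiset, so ties are handled exactly); normal approximation with tie
    correction for larger samples.  U counts pairs where a group-1 value
    exceeds a group-2 value, plus half the tied pairs.
    """
    x = np.asarray(g1, dtype=float)
    y = np.asarray(g2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    r1 = float(ranks[:n1].sum())
    u_obs = r1 - n1 * (n1 + 1) / 2

    if n1 + n2 <= MWU_EXACT_LIMIT:
        mu = n1 * n2 / 2
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
            if abs(u - mu) >= dev_obs - 1e-9:
                hits += 1
            total += 1
        p = hits / total
    else:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return {"U": float(u_obs), "p": min(1.0, float(p))}


def _log_table_prob(table: np.ndarray, log_fact_margins: float, log_fact_n: float) -> float:
    return log_fact_margins - log_fact_n - sum(
        math.lgamma(v + 1) for v in table.ravel()
    )


def _enumerate_tables(row_margins, col_margins):
    """All non-negative integer tables with the given margins."""
    r = len(row_margins)

    def rows(row_i: int, cols_left: tuple[int, ...], acc: list[list[int]]):
        if row_i == r - 1:
            if all(c >= 0 for c in cols_left):
                yield acc + [list(cols_left)]
            return
        target = row_margins[row_i]

        def cells(j: int, remaining: int, row: list[int]):
            if j == len(cols_left) - 1:
                if remaining <= cols_left[j]:
                    yield row + [remaining]
                return
            for v in range(min(remaining, cols_left[j]) + 1):
                yield from cells(j + 1, remaining - v, row + [v])

        for row in cells(0, target, []):
            yield from rows(
                row_i + 1,
                tuple(c - v for c, v in zip(cols_left, row)),
                acc + [row],
            )

    yield from rows(0, tuple(col_margins), [])


def exact_contingency_test(table, limit: int = EXACT_TEST_LIMIT) -> dict[str, float]:
    """Two-sided exact conditional test of independence on an r x c table.

    Conditions on both margins; the p-value sums the probabilities of all
    margin-fixed tables whose point probability does not exceed the observed
    one.  A 2 x 2 table uses the hypergeometric distribution directly;
    larger tables are fully enumerated (total count capped at ``limit``).
    Degenerate margins (a zero row or column) give p = 1.
    """
    table = np.asarray(table, dtype=int)
    if table.ndim != 2 or (table < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    n = int(table.sum())
    if n == 0 or (row_m == 0).any() or (col_m == 0).any():
        return {"p": 1.0}

    if table.shape == (2, 2):
        # k = top-left cell; hypergeometric over its support
        K, nn = int(row_m[0]), int(col_m[0])
        rv = sps.hypergeom(n, K, nn)
        k_obs = int(table[0, 0])
        p_obs = rv.pmf(k_obs)
        support = np.arange(max(0, nn - (n - K)), min(K, nn) + 1)
        probs = rv.pmf(support)
        return {"p": min(1.0, float(probs[probs <= p_obs * _REL_TOL].sum()))}

    if n > limit:
        raise ValueError(f"table total {n} exceeds the exact-enumeration limit {limit}")
    log_fact_margins = sum(math.lgamma(v + 1) for v in row_m) + sum(
        math.lgamma(v + 1) for v in col_m
    )
    log_fact_n = math.lgamma(n + 1)
    logp_obs = _log_table_prob(table, log_fact_margins, log_fact_n)
    p_obs = math.exp(logp_obs)
    total = 0.0
    for t in _enumerate_tables(row_m.tolist(), col_m.tolist()):
        p_t = math.exp(_log_table_prob(np.asarray(t), log_fact_margins, log_fact_n))
        if p_t <= p_obs * _REL_TOL:
            total += p_t
    return {"p": min(1.0, float(total))}


def baseline_table(cohort: CohortTable) -> pd.DataFrame:
    """Group comparison of baseline characteristics, one row per variable.

    Continuous variables get mean +/- SD per group and a pooled t-test,
    parity gets a median (range) and an exact Mann-Whitney U test, binary
    and categorical variables get percentages and the exact contingency
    test.
    """
    if not len(cohort.baseline):
        raise ValueError("cohort has no baseline characteristics")
    fit_rows = np.array([o == FITTING for o in cohort.outcomes])
    base = cohort.baseline
    rows = []

    def _cont(name: str, label: str) -> None:
        v = base[name].to_numpy(dtype=float)
        g1, g2 = v[fit_rows], v[~fit_rows]
        s1, s2 = summarize(g1), summarize(g2)
        pooled = pooled_mean_sd([s1, s2])
        res = t_test_independent(g1, g2)
        rows.append(
            {
                "variable": label,
                "test": "t",
                "total": f"{pooled.mean:.1f} ± {pooled.sd:.1f}",
                "fitting": f"{s1.mean:.1f} ± {s1.sd:.1f}",
                "non_fitting": f"{s2.mean:.1f} ± {s2.sd:.1f}",
                "p": res["p"],
            }
        )

    def _binary(name: str, label: str) -> None:
        v = base[name].astype(bool).to_numpy()
        tab = [
            [int(v[fit_rows].sum()), int((~v[fit_rows]).sum())],
            [int(v[~fit_rows].sum()), int((~v[~fit_rows]).sum())],
        ]
        res = exact_contingency_test(tab)
        rows.append(
            {
                "variable": label,
                "test": "exact",
                "total": f"{100 * v.mean():.1f}%",
                "fitting": f"{100 * v[fit_rows].mean():.1f}%",
                "non_fitting": f"{100 * v[~fit_rows].mean():.1f}%",
                "p": res["p"],
            }
        )

    _cont("age_years", "Age (years)")
    _cont("bmi_kg_m2", "BMI (kg/m2)")

    parity = base["parity"].to_numpy(dtype=float)
    res = mann_whitney_u(parity[fit_rows], parity[~fit_rows])
    rows.append(
        {
            "variable": "Parity",
            "test": "mann_whitney",
            "total": f"{np.median(parity):.0f} ({parity.min():.0f}-{parity.max():.0f})",
            "fitting": f"{np.median(parity[fit_rows]):.0f}",
            "non_fitting": f"{np.median(parity[~fit_rows]):.0f}",
            "p": res["p"],
        }
    )

    _binary("family_history_pop", "Family history of POP")
    _binary("hysterectomy", "Hysterectomy")

    stage3 = (base["popq_stage"].to_numpy(dtype=int) == 3)
    tab = [
        [int(stage3[fit_rows].sum()), int((~stage3)[fit_rows].sum())],
        [int(stage3[~fit_rows].sum()), int((~stage3)[~fit_rows].sum())],
    ]
    rows.append(
        {
            "variable": "POP-Q stage 3",
            "test": "exact",
            "total": f"{100 * stage3.mean():.1f}%",
            "fitting": f"{100 * stage3[fit_rows].mean():.1f}%",
            "non_fitting": f"{100 * stage3[~fit_rows].mean():.1f}%",
            "p": exact_contingency_test(tab)["p"],
        }
    )

    _cont("tvl_exam_cm", "TVL (cm)")
    _binary("postmenopausal", "Postmenopausal")

    av = base["avulsion"].astype(str).to_numpy()
    tab = [
        [int((av[fit_rows] == lvl).sum()) for lvl in AVULSION_LEVELS],
        [int((av[~fit_rows] == lvl).sum()) for lvl in AVULSION_LEVELS],
    ]
    rows.append(
        {
            "variable": "Levator ani avulsion",
            "test": "exact",
            "total": " / ".join(
                f"{lvl} {100 * (av == lvl).mean():.1f}%" for lvl in AVULSION_LEVELS
            ),
            "fitting": " / ".join(
                f"{100 * (av[fit_rows] == lvl).mean():.1f}%" for lvl in AVULSION_LEVELS
            ),
            "non_fitting": " / ".join(
                f"{100 * (av[~fit_rows] == lvl).mean():.1f}%" for lvl in AVULSION_LEVELS
            ),
            "p": exact_contingency_test(tab)["p"],
        }
    )

    return pd.DataFrame(rows)
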