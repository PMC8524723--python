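"""Patient-level marker-response association on 2x2 tables.

Rows are marker status (present / absent), columns are response
(responder / non-responder). The headline statistic is the two-sided
Pearson chi-square without continuity correction; Fisher's exact p and
a Haldane-corrected odds ratio are reported alongside, together with
per-row response rates as percentages. Reported p-values are *floored*
to two decimals for display; full precision is always stored.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .dynamics import fisher_exact_two_sided

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Table2x2:
    a: int  # marker present, responder
    b: int  # marker present, non-responder
    c: int  # marker absent, responder
    d: int  # marker absent, non-responder
    row_labels: tuple[str, str] = ("marker_present", "marker_absent")
    col_labels: tuple[str, str] = ("responder", "non_responder")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")
        if self.n == 0:
            raise ValueError("empty table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass
class AssociationResult:
    chi2_stat: float
    chi2_p: float
    fisher_p: float
    odds_ratio: float
    rate_row1: float  # % responders among marker-present
    rate_row2: float  # % responders among marker-absent
    n: int

    def display_p(self, which: str = "chi2") -> str:
        """P-value floored (not rounded) to two decimals, as displayed."""
        p = self.chi2_p if which == "chi2" else self.fisher_p
        return f"{math.floor(p * 100) / 100:.2f}"


def pearson_chi2(table: Table2x2 | np.ndarray) -> tuple[float, float]:
    """Pearson chi-square statistic (1 df, no Yates correction) and p."""
    t = table.as_array() if isinstance(table, Table2x2) else np.asarray(table)
    a, b, c, d = t.ravel()
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if n == 0:
        raise ValueError("empty table")
    if 0 in margins:
        warnings.warn("degenerate 2x2 table (zero margin); chi2 p = 1")
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / float(np.prod(margins, dtype=np.float64))
    return float(stat), float(stats.chi2.sf(stat, df=1))


def response_rates(table: Table2x2) -> tuple[float, float, float]:
    """Per-row response rates (percent) and the Haldane-corrected odds ratio."""
    r1_total = table.a + table.b
    r2_total = table.c + table.d
    if r1_total == 0 or r2_total == 0:
        raise ValueError("zero row total")
    rate1 = 100.0 * table.a / r1_total
    rate2 = 100.0 * table.c / r2_total
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if 0.0 in (a, b, c, d):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return rate1, rate2, (a * d) / (b * c)


def associate(table: Table2x2) -> AssociationResult:
    chi2_stat, chi2_p = pearson_chi2(table)
    fisher_p = fisher_exact_two_sided(table.as_array())
    rate1, rate2, oratio = response_rates(table)
    return AssociationResult(
        chi2_stat=chi2_stat, chi2_p=chi2_p, fisher_p=fisher_p,
        odds_ratio=oratio, rate_row1=rate1, rate_row2=rate2, n=table.n,
    )


def build_marker_table(
    sample_calls: pd.Series | dict,
    responses: pd.Series | dict,
    responder_labels: tuple[str, ...] = ("responder",),
) -> Table2x2:
    """Cross-tabulate per-patient marker calls against response labels.

    ``sample_calls`` maps patient -> bool (marker present); ``responses``
    maps patient -> response label. Patients with a missing value on
    either side are excluded and counted in the log.
    """
    calls = pd.Series(sample_calls)
    resp = pd.Series(responses)
    patients = calls.index.union(resp.index)
    joined = pd.DataFrame({"marker": calls.reindex(patients),
                           "response": resp.reindex(patients)})
    dropped = joined.isna().any(axis=1)
    if dropped.any():
        log.info("%d patient(s) excluded for missing marker or response", int(dropped.sum()))
    joined = joined[~dropped]
    if joined.empty:
        raise ValueError("no patients left after exclusions")
    is_resp = joined["response"].isin(responder_labels)
    marker = joined["marker"].astype(bool)
    t = Table2x2(
        a=int((marker & is_resp).sum()),
        b=int((marker & ~is_resp).sum()),
        c=int((~marker & is_resp).sum()),
        d=int((~marker & ~is_resp).sum()),
    )
    if t.a + t.b == 0 or t.c + t.d == 0:
        warnings.warn("degenerate marker table: one marker stratum is empty")
    return t


def result_to_dict(result: AssociationResult) -> dict:
    d = asdict(result)
    d["chi2_p_display"] = result.display_p("chi2")
    return d
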