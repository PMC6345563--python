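"""Median-split red/green classification of cell fate and its statistics.

A cell is called "red" when its per-neuromast median-normalized
red:green ratio is strictly above 1 (i.e. above its neuromast's median)
and "green" otherwise; cells exactly at the median classify green and
are counted. The classifier is scored against the live/die outcome with
sensitivity, specificity, the diagnostic odds ratio, Fisher's exact
test, and the probability of superiority (the Mann-Whitney effect
size).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ConfigError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts linking the red/green call to the die/live outcome.

    tp: dying & red, fn: dying & green, fp: living & red, tn: living & green.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def n_dying(self) -> int:
        return self.tp + self.fn

    @property
    def n_living(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_dying + self.n_living


@dataclass
class ClassificationReport:
    """All statistics the median-split classifier reports."""

    table: ContingencyTable2x2
    sensitivity: float
    specificity: float
    dor: float
    dor_is_finite: bool
    fisher_p: float
    pos: Optional[float] = None      # P(surviving ratio < dying ratio)
    n_ties: int = 0
    n_outcome_na: int = 0

    def as_dict(self) -> dict:
        return {
            "schema_version": 1,
            "counts": {"tp": self.table.tp, "fn": self.table.fn,
                       "fp": self.table.fp, "tn": self.table.tn},
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "diagnostic_odds_ratio": self.dor if self.dor_is_finite else None,
            "dor_is_finite": self.dor_is_finite,
            "fisher_p": self.fisher_p,
            "probability_of_superiority": self.pos,
            "n_ties_at_median": self.n_ties,
            "n_outcome_na": self.n_outcome_na,
        }


def median_split_classify(normalized_ratios: Sequence[float]) -> np.ndarray:
    """Label cells 'red' when normalized ratio > 1, else 'green'.

    Values exactly at 1 (the neuromast median itself, including the
    middle cell of any odd-sized neuromast) are green under the strict
    inequality; their count is logged for accounting.
    """
    r = np.asarray(normalized_ratios, dtype=float)
    labels = np.where(r > 1.0, "red", "green")
    n_ties = int(np.sum(r == 1.0))
    if n_ties:
        log.info("median-split: %d cell(s) exactly at the median -> green", n_ties)
    return labels


def count_median_ties(normalized_ratios: Sequence[float]) -> int:
    return int(np.sum(np.asarray(normalized_ratios, dtype=float) == 1.0))


def build_contingency(labels: Sequence[str],
                      outcomes: Sequence[str]) -> ContingencyTable2x2:
    """Cross-tabulate red/green calls against die/live outcomes.

    Cells with outcome 'na' are excluded (and logged). Raises when there
    are no dying and no living cells at all.
    """
    labels = np.asarray(labels)
    outcomes = np.asarray(outcomes)
    if labels.shape != outcomes.shape:
        raise ConfigError("labels and outcomes must be aligned")
    keep = outcomes != "na"
    n_na = int(np.sum(~keep))
    if n_na:
        log.info("contingency: excluded %d cell(s) with outcome 'na'", n_na)
    labels, outcomes = labels[keep], outcomes[keep]
    bad = set(np.unique(outcomes)) - {"live", "die"}
    if bad:
        raise ConfigError(f"unknown outcome values: {sorted(bad)}")
    die = outcomes == "die"
    red = labels == "red"
    if not die.any() and not (~die).any():
        raise ConfigError("no cells with a live or die outcome")
    return ContingencyTable2x2(
        tp=int(np.sum(red & die)), fn=int(np.sum(~red & die)),
        fp=int(np.sum(red & ~die)), tn=int(np.sum(~red & ~die)))


def sensitivity_specificity(table: ContingencyTable2x2) -> Tuple[float, float]:
    """sens = tp/(tp+fn); spec = tn/(fp+tn). Full precision."""
    if table.n_dying == 0:
        raise ConfigError("no dying cells: sensitivity undefined")
    if table.n_living == 0:
        raise ConfigError("no living cells: specificity undefined")
    return table.tp / table.n_dying, table.tn / table.n_living


def diagnostic_odds_ratio(table: ContingencyTable2x2,
                          zero_cell_policy: str = "flag") -> float:
    """DOR = (tp*tn)/(fn*fp).

    With a zero cell the default policy returns a flagged non-finite
    value (inf, or nan when the numerator is also zero) instead of
    silently correcting; policy 'haldane' adds 0.5 to every cell.
    """
    if zero_cell_policy not in ("flag", "haldane"):
        raise ConfigError("zero_cell_policy must be 'flag' or 'haldane'")
    tp, fn, fp, tn = table.tp, table.fn, table.fp, table.tn
    if zero_cell_policy == "haldane":
        tp, fn, fp, tn = tp + 0.5, fn + 0.5, fp + 0.5, tn + 0.5
        return (tp * tn) / (fn * fp)
    if fn * fp == 0:
        log.warning("DOR has a zero cell; returning non-finite flag value")
        return math.nan if tp * tn == 0 else math.inf
    return (tp * tn) / (fn * fp)


def _log_hypergeom_pmf(x: int, row1: int, col1: int, n: int) -> float:
    """log P(X = x) for X ~ Hypergeom(n, row1, col1), via log-gamma."""
    def lchoose(a: int, b: int) -> float:
        if b < 0 or b > a:
            return -math.inf
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)
    return lchoose(row1, x) + lchoose(n - row1, col1 - x) - lchoose(n, col1)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p for a 2x2 table with fixed margins.

    Sums hypergeometric probabilities of every table (same margins)
    whose probability does not exceed the observed table's, the
    conventional two-sided rule; log-factorial arithmetic keeps the
    terms stable. A small relative tolerance absorbs floating-point ties
    between equal-probability tables.
    """
    row1, col1, n = table.n_dying, table.tp + table.fp, table.n
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    if lo > hi:
        return 1.0
    log_obs = _log_hypergeom_pmf(table.tp, row1, col1, n)
    cutoff = log_obs + 1e-7
    logs = [_log_hypergeom_pmf(x, row1, col1, n) for x in range(lo, hi + 1)]
    m = max(logs)
    p = sum(math.exp(lp - m) for lp in logs if lp <= cutoff) * math.exp(m)
    return min(1.0, float(p))


def probability_of_superiority_empirical(group_a: Sequence[float],
                                         group_b: Sequence[float]) -> float:
    """P(A < B) over all cross-group pairs, counting ties as 1/2.

    Equals U_B/(nA*nB) for the Mann-Whitney statistic; computed in
    O(n log n) with sorted-array rank counting.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.sort(np.asarray(group_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ConfigError("both groups must be nonempty")
    left = np.searchsorted(b, a, side="left")    # b < a
    right = np.searchsorted(b, a, side="right")  # b <= a
    n_greater = (b.size - right).sum()           # pairs with a < b
    n_ties = (right - left).sum()
    return float((n_greater + 0.5 * n_ties) / (a.size * b.size))


def probability_of_superiority_normal(mean_a: float, sd_a: float,
                                      mean_b: float, sd_b: float) -> float:
    """P(A < B) for independent normals: Phi((mu_B - mu_A)/sqrt(sd_A^2 + sd_B^2)).

    Reconstructs the effect size from printed group summaries when raw
    per-cell values are unavailable. With both SDs zero the result is
    0, 0.5 or 1 by the sign of the mean difference.
    """
    if sd_a < 0 or sd_b < 0:
        raise ConfigError("standard deviations must be >= 0")
    denom = math.hypot(sd_a, sd_b)
    diff = mean_b - mean_a
    if denom == 0:
        return 0.5 if diff == 0 else (1.0 if diff > 0 else 0.0)
    return float(norm.cdf(diff / denom))


def percent_change(before: float, after: float) -> float:
    """Percent decrease from before to after: 100*(before-after)/before."""
    if before == 0:
        raise ConfigError("percent change undefined for before = 0")
    return 100.0 * (before - after) / before


@dataclass
class MannWhitneyResult:
    u_a: float        # pairs where A exceeds B (ties as 1/2)
    u_b: float        # pairs where B exceeds A
    p_value: float    # two-sided, normal approximation


def mann_whitney_u(group_a: Sequence[float],
                   group_b: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U from midranks with a tie- and continuity-corrected
    two-sided normal-approximation p-value.

    U_B/(nA*nB) equals probability_of_superiority_empirical(A, B)
    exactly, including under ties.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na == 0 or nb == 0:
        raise ConfigError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = ranks[:na].sum()
    u_a = r_a - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    n = na + nb
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    mu = na * nb / 2.0
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1))) if n > 1 else 0.0
    if var <= 0:
        p = 1.0
    else:
        z = (abs(u_a - mu) - 0.5) / math.sqrt(var)
        p = float(2.0 * norm.sf(max(z, 0.0)))
    return MannWhitneyResult(u_a=float(u_a), u_b=float(u_b), p_value=min(1.0, p))


def classification_report(normalized_ratios: Sequence[float],
                          outcomes: Sequence[str],
                          zero_cell_policy: str = "flag") -> ClassificationReport:
    """Median-split the cohort and compute the full statistics bundle."""
    ratios = np.asarray(normalized_ratios, dtype=float)
    outcomes = np.asarray(outcomes)
    labels = median_split_classify(ratios)
    table = build_contingency(labels, outcomes)
    sens, spec = sensitivity_specificity(table)
    dor = diagnostic_odds_ratio(table, zero_cell_policy)
    keep = outcomes != "na"
    live = ratios[keep & (outcomes == "live")]
    die = ratios[keep & (outcomes == "die")]
    pos = (probability_of_superiority_empirical(live, die)
           if live.size and die.size else None)
    return ClassificationReport(
        table=table, sensitivity=sens, specificity=spec,
        dor=dor, dor_is_finite=math.isfinite(dor),
        fisher_p=fisher_exact_two_sided(table), pos=pos,
        n_ties=count_median_ties(ratios),
        n_outcome_na=int(np.sum(~keep)))


def report_from_counts(tp: int, fn: int, fp: int, tn: int,
                       zero_cell_policy: str = "flag") -> ClassificationReport:
    """Statistics bundle straight from 2x2 counts (no per-cell data)."""
    table = ContingencyTable2x2(tp=tp, fn=fn, fp=fp, tn=tn)
    sens, spec = sensitivity_specificity(table)
    dor = diagnostic_odds_ratio(table, zero_cell_policy)
    return ClassificationReport(
        table=table, sensitivity=sens, specificity=spec,
        dor=dor, dor_is_finite=math.isfinite(dor),
        fisher_p=fisher_exact_two_sided(table))
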